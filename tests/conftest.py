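import pytest

from ampedit import generate_random_panel
from ampedit.panel import SiteConfig, revcomp

RAG2_GUIDE = "TGAGAAGCCTGGCTGAATTA"


@pytest.fixture(scope="session")
def tiny_site() -> SiteConfig:
    """Minimal hand-built locus: 4-nt flanks around protospacer + NGG PAM."""
    amplicon = "GGGG" + RAG2_GUIDE + "TGG" + "CCCC"
    return SiteConfig(
        site_id="S1",
        grna=RAG2_GUIDE,
        amplicon=amplicon,
        fwd_primer="GGGGT",
        rev_primer=revcomp("GCCCC"),
        on_target=True,
    ).validate()


@pytest.fixture(scope="session")
def panel3():
    """Three random loci sharing one protospacer (deterministic)."""
    return generate_random_panel(3, amplicon_len=220, seed=11)


@pytest.fixture(scope="session")
def panel2():
    return generate_random_panel(2, amplicon_len=200, seed=7)
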