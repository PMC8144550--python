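"""Synthetic paired treatment/mock amplicon-read generator with ground truth.

The generator emulates the structure of a comparative multiplex-amplicon
editing experiment:

* per-site read depths for treatment (Tx) and mock (M);
* true editing as an indel spectrum concentrated at the expected cut-site
  (each Tx read is edited independently with the site's true rate);
* sequencing/process noise — per-base substitutions and per-position
   1-bp indels — drawn from the *same* distribution in Tx and M, which is
  the comparative design's core assumption;
* chimeric fusion reads: explicit spiked fusions (Tx only) and an optional
  symmetric chimera-noise rate (both samples) emulating PCR artifacts.

Everything is deterministic given the seed. Reads are emitted merged
(full-amplicon length) by default; a paired-end mode splits each read into
an R1/R2 pair to exercise the merger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .panel import CutSite, Read, SiteConfig, locate_cut_sites, revcomp
from .translocation import build_fusion_amplicon

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class EditingSpectrum:
    """Distribution over (kind, length, offset-from-cut) editing events.

    The default concentrates all mass at offset 0: the event's 5'-most
    affected base is the base immediately 5' of the blunt break (insertions
    are placed exactly at the break). Deletion lengths 1-10 and insertion
    lengths 1-3 with geometrically decaying weights."""

    kinds: tuple[str, ...] = ("deletion", "insertion")
    kind_probs: tuple[float, ...] = (0.7, 0.3)
    deletion_lengths: tuple[int, ...] = tuple(range(1, 11))
    insertion_lengths: tuple[int, ...] = (1, 2, 3)
    length_decay: float = 0.6  # P(L) ~ decay**(L-1)
    offset: int = 0            # shift of the event start relative to the cut

    def sample(self, rng: np.random.Generator) -> tuple[str, int]:
        kind = self.kinds[rng.choice(len(self.kinds), p=np.asarray(self.kind_probs))]
        lengths = self.deletion_lengths if kind == "deletion" else self.insertion_lengths
        w = self.length_decay ** (np.arange(len(lengths)))
        w /= w.sum()
        return kind, int(np.asarray(lengths)[rng.choice(len(lengths), p=w)])


@dataclass
class FusionSpec:
    site_a: str
    site_b: str
    rule: int = 1
    fraction: float = 0.0  # fraction of site_a's Tx depth emitted as fusion reads


@dataclass
class SimSpec:
    panel: Sequence[SiteConfig]
    depth_tx: int | Mapping[str, int] = 5000
    depth_m: int | Mapping[str, int] = 5000
    editing_rate: float | Mapping[str, float] = 0.0
    spectrum: EditingSpectrum = field(default_factory=EditingSpectrum)
    sub_rate: float = 0.0          # per-base substitution noise probability
    indel_noise_rate: float = 0.0  # per-position 1-bp indel noise probability
    tx_noise_bias: float = 1.0     # multiplies Tx noise rates (1.0 = shared noise)
    fusions: Sequence[FusionSpec] = ()
    chimera_noise_rate: float = 0.0  # symmetric PCR-chimera fraction per sample
    seed: int = 0
    paired_end: bool = False
    read_length: int = 150         # R1/R2 length in paired-end mode

    def depth(self, which: str, site_id: str) -> int:
        d = self.depth_tx if which == "tx" else self.depth_m
        return int(d[site_id]) if isinstance(d, Mapping) else int(d)

    def rate(self, site_id: str) -> float:
        r = self.editing_rate
        return float(r[site_id]) if isinstance(r, Mapping) else float(r)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    edited_counts: dict[str, int]          # true edited Tx reads per site
    depths_tx: dict[str, int]
    depths_m: dict[str, int]
    fusion_counts: dict[tuple, int]        # (site_a, site_b, rule, sample) -> reads
    read_labels: dict[str, dict]           # read_id -> {site|pair, edited, sample}

    def as_json_dict(self) -> dict:
        return {
            "edited_counts": self.edited_counts,
            "depths_tx": self.depths_tx,
            "depths_m": self.depths_m,
            "fusion_counts": {
                "|".join(map(str, k)): v for k, v in self.fusion_counts.items()
            },
        }


@dataclass
class SimResult:
    tx_reads: list[Read]
    m_reads: list[Read]
    truth: SimTruth
    # paired-end mode only:
    tx_pairs: tuple[list[Read], list[Read]] | None = None
    m_pairs: tuple[list[Read], list[Read]] | None = None


def generate_random_panel(
    n_sites: int,
    amplicon_len: int = 240,
    seed: int = 0,
    primer_len: int = 22,
) -> list[SiteConfig]:
    """Random panel sharing one 20-nt protospacer (as an on/off-target panel
    of a single guide would); site 0 is flagged on-target."""
    if n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    min_len = 2 * primer_len + 23 + 10
    if amplicon_len < min_len:
        raise ConfigError(
            f"amplicon_len={amplicon_len} too short for primers + protospacer "
            f"(need >= {min_len})"
        )
    rng = np.random.default_rng(seed)
    protospacer = _random_seq(rng, 20)
    sites = []
    for k in range(n_sites):
        for _ in range(200):
            amp = _random_seq(rng, amplicon_len)
            insert = protospacer + _random_choice(rng, "ACGT") + "GG"
            strand = rng.random() < 0.5
            if strand:
                insert = revcomp(insert)
            lo = primer_len + 2
            hi = amplicon_len - primer_len - len(insert) - 2
            pos = int(rng.integers(lo, hi + 1))
            amp = amp[:pos] + insert + amp[pos + len(insert):]
            if amp.count(protospacer) + amp.count(revcomp(protospacer)) != 1:
                continue
            site = SiteConfig(
                site_id=f"site{k}",
                grna=protospacer,
                amplicon=amp,
                fwd_primer=amp[:primer_len],
                rev_primer=revcomp(amp[-primer_len:]),
                on_target=(k == 0),
            )
            try:
                site.validate()
            except Exception:
                continue
            sites.append(site)
            break
        else:
            raise ConfigError("failed to embed a unique protospacer; widen amplicon_len")
    return sites


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _random_choice(rng: np.random.Generator, alphabet: str) -> str:
    return alphabet[int(rng.integers(0, len(alphabet)))]


def apply_edit(
    amplicon: str,
    cut: CutSite,
    kind: str,
    length: int,
    offset: int = 0,
    insert_seq: str | None = None,
) -> str:
    """Apply one editing event. The event's 5'-most affected base sits at
    ``cut.index + offset`` (insertions are placed immediately 3' of that
    base)."""
    pos = cut.index + offset
    if kind == "deletion":
        return amplicon[:pos] + amplicon[pos + length:]
    if kind == "insertion":
        if insert_seq is None or len(insert_seq) != length:
            raise ValueError("insertion requires insert_seq of matching length")
        return amplicon[: pos + 1] + insert_seq + amplicon[pos + 1:]
    raise ValueError(f"unknown event kind {kind!r}")


def _apply_noise(seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> str:
    arr = bytearray(seq.encode())
    if indel_rate > 0:
        n_events = rng.binomial(len(arr), indel_rate)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(arr)))
            if rng.random() < 0.5 and len(arr) > 1:
                del arr[pos]
            else:
                arr.insert(pos, int(_BASES[rng.integers(0, 4)]))
    if sub_rate > 0:
        n_subs = rng.binomial(len(arr), sub_rate)
        for _ in range(n_subs):
            pos = int(rng.integers(0, len(arr)))
            arr[pos] = int(_BASES[rng.integers(0, 4)])
    return arr.decode()


def simulate_experiment(spec: SimSpec) -> SimResult:
    """Generate Tx and M read pools plus the truth record.

    Unmodified reads share one amplicon string, so downstream per-sequence
    caches stay small even at deep coverage. Insertion events reuse one
    random insert sequence per length (NHEJ insertions are typically
    templated and short; cell counts are keyed by length class anyway).
    """
    rng = np.random.default_rng(spec.seed)
    panel_map = {s.site_id: s for s in spec.panel}
    cuts = locate_cut_sites(spec.panel)
    for f in spec.fusions:
        if f.site_a not in panel_map or f.site_b not in panel_map:
            raise ConfigError(f"fusion pair ({f.site_a}, {f.site_b}) not in panel")

    insert_seqs = {L: _random_seq(rng, L) for L in range(1, 64)}
    tx_reads: list[Read] = []
    m_reads: list[Read] = []
    truth = SimTruth({}, {}, {}, {}, {})

    for site in spec.panel:
        sid = site.site_id
        cut = cuts[sid]
        rate = spec.rate(sid)
        d_tx = spec.depth("tx", sid)
        d_m = spec.depth("m", sid)
        truth.depths_tx[sid] = d_tx
        truth.depths_m[sid] = d_m
        truth.edited_counts[sid] = 0
        for sample, depth, reads in (("tx", d_tx, tx_reads), ("mock", d_m, m_reads)):
            edited_flags = (
                rng.random(depth) < rate if sample == "tx" else np.zeros(depth, bool)
            )
            bias = spec.tx_noise_bias if sample == "tx" else 1.0
            sub_rate = spec.sub_rate * bias
            indel_rate = spec.indel_noise_rate * bias
            p_read_noise = 0.0
            if sub_rate > 0 or indel_rate > 0:
                L = len(site.amplicon)
                p_read_noise = 1.0 - (1.0 - sub_rate) ** L * (1.0 - indel_rate) ** L
            noisy_flags = rng.random(depth) < p_read_noise
            for k in range(depth):
                rid = f"{sample}:{sid}:{k}"
                seq = site.amplicon
                edited = bool(edited_flags[k])
                if edited:
                    kind, length = spec.spectrum.sample(rng)
                    seq = apply_edit(
                        site.amplicon, cut, kind, length,
                        offset=spec.spectrum.offset,
                        insert_seq=insert_seqs.get(length) if kind == "insertion" else None,
                    )
                    truth.edited_counts[sid] += 1
                if noisy_flags[k]:
                    seq = _apply_noise(seq, rng, sub_rate, indel_rate)
                reads.append(Read(rid, seq, "I" * len(seq)))
                truth.read_labels[rid] = {"site": sid, "edited": edited, "sample": sample}

    # Spiked fusion reads (treatment only; the titration-experiment design).
    for f in spec.fusions:
        n_fus = int(round(f.fraction * spec.depth("tx", f.site_a)))
        if n_fus <= 0:
            continue
        amp = build_fusion_amplicon(
            panel_map[f.site_a], panel_map[f.site_b], f.rule,
            cuts[f.site_a], cuts[f.site_b],
        )
        key = (f.site_a, f.site_b, f.rule, "tx")
        truth.fusion_counts[key] = truth.fusion_counts.get(key, 0) + n_fus
        for k in range(n_fus):
            rid = f"tx:fusion:{f.site_a}-{f.site_b}:{k}"
            tx_reads.append(Read(rid, amp, "I" * len(amp)))
            truth.read_labels[rid] = {
                "pair": (f.site_a, f.site_b), "rule": f.rule, "sample": "tx",
            }

    # Symmetric chimera noise: random-pair fusion reads at equal expected
    # rates in both samples (PCR artifacts, not true translocations).
    if spec.chimera_noise_rate > 0 and len(spec.panel) >= 2:
        sids = [s.site_id for s in spec.panel]
        for sample, reads in (("tx", tx_reads), ("mock", m_reads)):
            total_depth = sum(spec.depth(sample if sample == "tx" else "m", s) for s in sids)
            n_chim = rng.binomial(total_depth, spec.chimera_noise_rate)
            for k in range(n_chim):
                a, b = rng.choice(len(sids), size=2, replace=False)
                rule = int(rng.integers(1, 5))
                amp = build_fusion_amplicon(
                    panel_map[sids[a]], panel_map[sids[b]], rule,
                    cuts[sids[a]], cuts[sids[b]],
                )
                rid = f"{sample}:chimera:{k}"
                reads.append(Read(rid, amp, "I" * len(amp)))
                key = (sids[a], sids[b], rule, sample)
                truth.fusion_counts[key] = truth.fusion_counts.get(key, 0) + 0  # noise, not truth
                truth.read_labels[rid] = {
                    "pair": (sids[a], sids[b]), "rule": rule, "sample": sample,
                    "chimera_noise": True,
                }

    result = SimResult(tx_reads=tx_reads, m_reads=m_reads, truth=truth)
    if spec.paired_end:
        result.tx_pairs = _split_pairs(tx_reads, spec.read_length)
        result.m_pairs = _split_pairs(m_reads, spec.read_length)
    return result


def _split_pairs(reads: Sequence[Read], read_length: int):
    r1s, r2s = [], []
    for r in reads:
        L = min(read_length, len(r.sequence))
        r1s.append(Read(r.read_id, r.sequence[:L], "I" * L))
        tail = r.sequence[-L:]
        r2s.append(Read(r.read_id, revcomp(tail), "I" * L))
    return r1s, r2s
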