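"""Experiment panel configuration: per-locus amplicons, primers, guides, cut-sites.

A multiplex amplicon panel has one row per interrogated locus (the on-target
site plus candidate off-target sites of one guide RNA). Each row carries the
reference amplicon, the forward/reverse PCR primers that delimit it, and the
20-nt protospacer so the expected Cas9 cut-site can be derived from the PAM
position (SpCas9 cuts bluntly 3 bp 5' of the NGG PAM).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio.Seq import reverse_complement

from .errors import ConfigError, PanelValidationError

PANEL_COLUMNS = ("site_id", "grna", "amplicon", "fwd_primer", "rev_primer", "on_target")

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (delegates to Biopython)."""
    return str(reverse_complement(seq))


def _check_dna(seq: str, what: str, site_id: str, allow_n: bool = False) -> str:
    seq = seq.strip().upper()
    alphabet = _DNA_N if allow_n else _DNA
    if not seq or not set(seq) <= alphabet:
        raise PanelValidationError(
            f"site {site_id!r}: {what} is not a plain ACGT sequence: {seq!r}"
        )
    return seq


@dataclass(frozen=True)
class SiteConfig:
    """One locus of the panel.

    Invariants (enforced by :func:`parse_panel` / ``validate``):

    * ``fwd_primer`` is an exact prefix of ``amplicon``;
    * ``revcomp(rev_primer)`` is an exact suffix of ``amplicon``;
    * the protospacer (``grna``) or its reverse-complement occurs exactly
      once in ``amplicon``.
    """

    site_id: str
    grna: str
    amplicon: str
    fwd_primer: str
    rev_primer: str
    on_target: bool

    def validate(self) -> "SiteConfig":
        sid = self.site_id
        if not sid:
            raise PanelValidationError("empty site_id")
        grna = _check_dna(self.grna, "grna", sid)
        if len(grna) != 20:
            raise PanelValidationError(
                f"site {sid!r}: gRNA protospacer must be 20 nt, got {len(grna)}"
            )
        amplicon = _check_dna(self.amplicon, "amplicon", sid)
        fwd = _check_dna(self.fwd_primer, "fwd_primer", sid)
        rev = _check_dna(self.rev_primer, "rev_primer", sid)
        if not amplicon.startswith(fwd):
            raise PanelValidationError(
                f"site {sid!r}: fwd_primer is not a prefix of the amplicon"
            )
        if not amplicon.endswith(revcomp(rev)):
            raise PanelValidationError(
                f"site {sid!r}: reverse-complement of rev_primer is not a suffix "
                f"of the amplicon"
            )
        n_hits = amplicon.count(grna) + amplicon.count(revcomp(grna))
        if n_hits != 1:
            raise PanelValidationError(
                f"site {sid!r}: protospacer occurs {n_hits} times in the amplicon "
                f"(expected exactly once on either strand)"
            )
        object.__setattr__(self, "grna", grna)
        object.__setattr__(self, "amplicon", amplicon)
        object.__setattr__(self, "fwd_primer", fwd)
        object.__setattr__(self, "rev_primer", rev)
        return self


@dataclass(frozen=True)
class CutSite:
    """Expected blunt double-strand break position.

    ``index`` is the 0-based amplicon position of the base immediately 5'
    (left, in forward amplicon coordinates) of the break; ``strand`` is the
    strand on which the protospacer matches.
    """

    index: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class Read:
    """A (merged) sequencing read."""

    read_id: str
    sequence: str
    qualities: str | None = None  # Phred+33 encoded, same length as sequence


def parse_panel(source: Union[str, os.PathLike, pd.DataFrame]) -> list[SiteConfig]:
    """Parse and validate the experiment configuration table.

    ``source`` is a CSV/TSV path (delimiter sniffed) or a DataFrame with
    columns ``site_id, grna, amplicon, fwd_primer, rev_primer, on_target``.

    Raises
    ------
    ConfigError
        on missing columns or an empty table.
    PanelValidationError
        when a row violates a sequence invariant or site_ids repeat.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        try:
            df = pd.read_csv(source, sep=None, engine="python", dtype=str)
        except FileNotFoundError:
            raise ConfigError(f"panel file not found: {source}")
        except pd.errors.EmptyDataError:
            raise ConfigError(f"panel file is empty: {source}")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"panel table is missing columns: {missing}")
    if len(df) == 0:
        raise ConfigError("panel table has no rows")

    sites: list[SiteConfig] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        on_target = _parse_bool(row["on_target"])
        site = SiteConfig(
            site_id=str(row["site_id"]).strip(),
            grna=str(row["grna"]),
            amplicon=str(row["amplicon"]),
            fwd_primer=str(row["fwd_primer"]),
            rev_primer=str(row["rev_primer"]),
            on_target=on_target,
        ).validate()
        if site.site_id in seen:
            raise PanelValidationError(f"duplicate site_id {site.site_id!r}")
        seen.add(site.site_id)
        sites.append(site)
    return sites


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "t", "y"}:
        return True
    if text in {"0", "false", "no", "f", "n"}:
        return False
    raise ConfigError(f"cannot interpret on_target value {value!r} as boolean")


def write_panel(sites: Sequence[SiteConfig], path: Union[str, os.PathLike]) -> None:
    """Serialize a panel back to CSV (round-trips through :func:`parse_panel`)."""
    pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "grna": s.grna,
                "amplicon": s.amplicon,
                "fwd_primer": s.fwd_primer,
                "rev_primer": s.rev_primer,
                "on_target": s.on_target,
            }
            for s in sites
        ]
    ).to_csv(path, index=False)


# SpCas9 cuts bluntly between protospacer positions 17 and 18 (1-based from
# the PAM-distal end), i.e. 3 nt from the PAM-proximal protospacer end.
_CUT_OFFSET_FROM_5P = 17  # forward-strand protospacer: break after start+16


def locate_cut_site(site: SiteConfig) -> CutSite:
    """Derive the expected blunt cut position from the protospacer match.

    The cut index is reported in forward amplicon coordinates regardless of
    the protospacer strand, as the base immediately left of the break.
    """
    amp = site.amplicon
    fwd_hits = _find_all(amp, site.grna)
    rev_hits = _find_all(amp, revcomp(site.grna))
    total = len(fwd_hits) + len(rev_hits)
    if total != 1:
        raise PanelValidationError(
            f"site {site.site_id!r}: protospacer matches {total} times; "
            f"cut-site is ambiguous"
        )
    if fwd_hits:
        start = fwd_hits[0]
        # PAM at start+20..start+22; break between start+16 and start+17.
        return CutSite(index=start + _CUT_OFFSET_FROM_5P - 1, strand="+")
    start = rev_hits[0]
    # Protospacer on the minus strand: its PAM-proximal end is at `start` in
    # forward coordinates (PAM occupies start-3..start-1); the break falls
    # between forward positions start+2 and start+3.
    return CutSite(index=start + 2, strand="-")


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    pos = haystack.find(needle)
    while pos != -1:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def locate_cut_sites(sites: Iterable[SiteConfig]) -> dict[str, CutSite]:
    return {s.site_id: locate_cut_site(s) for s in sites}
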