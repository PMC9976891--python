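"""Extraction of the extended anti-Shine-Dalgarno tail from 16S rRNA.

The extended ASD (16S nucleotides 1532–1544, 13 nt) sits a fixed distance
downstream of a highly conserved 16S motif (AAGTCGTAACAAGGTAGCCGT).  For
each annotated 16S rRNA gene, the region from 100 nt upstream of the 3'
end to 10 nt downstream (110 nt, strand-corrected) is taken, the motif is
located by semi-global alignment allowing up to 5 errors over the full
21-nt motif (substitutions and indels, i.e. adapter matching with an
error rate of 0.25), and the 13 nt beginning 19 nt past the matched motif
end are isolated as the extended ASD.

Organisms carrying more than one distinct ASD across their 16S copies are
flagged AMBIGUOUS and excluded downstream; organisms where no copy yields
a tail are MISSING.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import edlib

from .genome_io import Feature, Organism, reverse_complement, transcribe

__all__ = [
    "CONSERVED_MOTIF",
    "TailWindow",
    "MotifMatch",
    "ExtendedASD",
    "ASDStatus",
    "tail_windows",
    "locate_motif",
    "extract_asd",
    "consolidate_asd",
    "organism_asd",
]

CONSERVED_MOTIF = "AAGUCGUAACAAGGUAGCCGU"  # RNA form of the conserved 16S motif
MAX_ERRORS = 5  # floor(0.25 * 21)
TAIL_OFFSET = 19  # nt between the matched motif end and the ASD 5' end
TAIL_LENGTH = 13
WINDOW_UPSTREAM = 100
WINDOW_DOWNSTREAM = 10
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM


@dataclass(frozen=True)
class TailWindow:
    """110-nt RNA window around a 16S 3' end (N-padded at contig edges)."""

    organism: str
    source: str  # feature ID of the 16S gene
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != WINDOW_LENGTH:
            raise ValueError(
                f"tail window {self.source!r}: length {len(self.seq)}"
                f" != {WINDOW_LENGTH}"
            )


@dataclass(frozen=True)
class MotifMatch:
    window: TailWindow
    match_end: int  # 0-based index just past the matched motif
    n_errors: int


@dataclass(frozen=True)
class ExtendedASD:
    organism: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != TAIL_LENGTH or set(self.seq) - set("ACGU"):
            raise ValueError(f"not a 13-nt RNA tail: {self.seq!r}")

    def __str__(self) -> str:
        return self.seq


class ASDStatus(enum.Enum):
    UNIQUE = "UNIQUE"
    AMBIGUOUS = "AMBIGUOUS"
    MISSING = "MISSING"


def tail_windows(org: Organism) -> list:
    """One :class:`TailWindow` per annotated 16S rRNA feature."""
    windows = []
    for f in org.rrna16s_features():
        seq = org.contig(f.contig_id).seq
        if f.strand == "+":
            lo, hi = f.end - WINDOW_UPSTREAM, f.end + WINDOW_DOWNSTREAM
            raw = _pad(seq, lo, hi)
        else:
            lo, hi = f.start - 1 - WINDOW_DOWNSTREAM, f.start - 1 + WINDOW_UPSTREAM
            raw = reverse_complement(_pad(seq, lo, hi))
        windows.append(
            TailWindow(organism=org.id, source=f.feature_id or f.gene, seq=transcribe(raw))
        )
    return windows


def _pad(seq: str, lo: int, hi: int) -> str:
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(seq))
    return left + seq[max(0, lo) : min(len(seq), hi)] + right


def locate_motif(window: TailWindow) -> MotifMatch | None:
    """Best approximate occurrence of the conserved motif, or None.

    Semi-global alignment with unit-cost substitutions/insertions/
    deletions; the full 21-nt motif must be covered.  A match requires at
    most 5 errors; among equal-error matches the leftmost end is returned.
    """
    res = edlib.align(
        CONSERVED_MOTIF, window.seq, mode="HW", task="locations", k=MAX_ERRORS
    )
    if res["editDistance"] < 0:
        return None
    end = min(loc[1] for loc in res["locations"])
    return MotifMatch(window=window, match_end=end + 1, n_errors=res["editDistance"])


def extract_asd(window: TailWindow, match: MotifMatch) -> ExtendedASD | None:
    """13-nt tail starting 19 nt past the matched motif end, or None.

    None when the slice runs past the window or contains N.
    """
    start = match.match_end + TAIL_OFFSET
    stop = start + TAIL_LENGTH
    if stop > len(window.seq):
        return None
    tail = window.seq[start:stop]
    if "N" in tail:
        return None
    return ExtendedASD(organism=window.organism, seq=tail)


def consolidate_asd(candidates: list):
    """Reduce per-copy tails to one organism-level call.

    Returns ``(ASDStatus.UNIQUE, ExtendedASD)`` when all copies agree,
    ``(ASDStatus.AMBIGUOUS, None)`` when more than one distinct sequence
    was found (the organism is excluded downstream), and
    ``(ASDStatus.MISSING, None)`` when no tail was recovered.
    """
    if len({c.organism for c in candidates}) > 1:
        raise ValueError("candidates from more than one organism")
    distinct = sorted({c.seq for c in candidates})
    if len(distinct) == 1:
        return ASDStatus.UNIQUE, candidates[0]
    if len(distinct) > 1:
        return ASDStatus.AMBIGUOUS, None
    return ASDStatus.MISSING, None


def organism_asd(org: Organism):
    """Run the full extraction for one organism.

    Returns ``(status, asd_or_None, n_16s_copies)``.
    """
    candidates = []
    windows = tail_windows(org)
    for w in windows:
        match = locate_motif(w)
        if match is None:
            continue
        tail = extract_asd(w, match)
        if tail is not None:
            candidates.append(tail)
    status, asd = consolidate_asd(candidates) if candidates else (ASDStatus.MISSING, None)
    return status, asd, len(windows)
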