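"""Per-gene SD/MSD screening of translation initiation regions.

For every protein-coding gene the translation initiation region (TIR,
public positions −40…+12 around the start codon, 52 nt) is extracted and
the extended ASD is scanned across it.  The SD statistic is the minimum
pairing free energy over registers whose helix lies entirely inside the
SD window (−25…+12); the mock-SD (MSD) statistic uses a window 25–40 nt
upstream of the start codon, too far out to act as a real SD, and serves
as the chance-level null.  The shared boundary position −25 is assigned
to the SD window, so the two windows are disjoint (MSD = −40…−26) and a
helix can never contribute to both.  Helices that straddle a window
boundary are excluded rather than truncated and scored.

Ribosomal-protein gene sets are selected from GFF metadata; the
identical-twin proteins bL7/bL12 (gene *rplL*) are excluded, and
organisms with fewer than 25 remaining r-protein annotations are
discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .duplex_energy import PAIRS, _WEAK_PAIRS, NNParameterTable
from .genome_io import Feature, Organism, feature_sequence

__all__ = [
    "TIRWindow",
    "GeneAffinity",
    "ORGANISM_DISCARDED",
    "SD_WINDOW",
    "MSD_WINDOW",
    "tir_window",
    "select_ribosomal_genes",
    "is_ribosomal_protein",
    "is_bl7_bl12",
    "is_rpsu",
    "sd_min_energy",
    "msd_min_energy",
    "scan_organism",
]

TIR_UPSTREAM = 40
TIR_DOWNSTREAM = 12
TIR_LENGTH = TIR_UPSTREAM + TIR_DOWNSTREAM

# Internal TIR coordinates: the first start-codon base is offset 0, so the
# public windows −25…+12 and −40…−26 are [−25, 11] and [−40, −26].
SD_WINDOW = (-25, 11)
MSD_WINDOW = (-40, -26)

ORGANISM_DISCARDED = "ORGANISM_DISCARDED"


@dataclass(frozen=True)
class TIRWindow:
    """52-nt RNA window −40…+12 around a start codon (N-padded at edges)."""

    gene: str
    seq: str
    start_index: int = TIR_UPSTREAM

    def __post_init__(self) -> None:
        if len(self.seq) != TIR_LENGTH:
            raise ValueError(
                f"TIR for {self.gene!r}: length {len(self.seq)} != {TIR_LENGTH}"
            )


@dataclass(frozen=True)
class GeneAffinity:
    organism: str
    gene: str
    product: str
    is_rprotein: bool
    sd_dG: float
    sd_offset: int | None
    sd_helix_len: int
    msd_dG: float


def tir_window(org: Organism, f: Feature) -> TIRWindow:
    seq = feature_sequence(org, f, upstream=TIR_UPSTREAM, downstream=0)
    seq = seq[:TIR_LENGTH]
    if len(seq) < TIR_LENGTH:  # CDS shorter than the downstream span
        seq = seq + "N" * (TIR_LENGTH - len(seq))
    return TIRWindow(gene=f.gene or f.feature_id, seq=seq)


# ---------------------------------------------------------------------------
# Ribosomal-protein selection
# ---------------------------------------------------------------------------

_RPROT_PRODUCT = re.compile(r"ribosomal\s+protein", re.IGNORECASE)
_RPROT_GENE = re.compile(r"^rp(s|l|m)[A-Z]")
_BL7L12 = re.compile(r"L7/L12|L7/12|\bbL12\b|\bbL7\b|\bL12\b", re.IGNORECASE)
_RPSU = re.compile(r"\bbS21\b|\bS21\b", re.IGNORECASE)


def is_ribosomal_protein(f: Feature) -> bool:
    return bool(_RPROT_PRODUCT.search(f.product) or _RPROT_GENE.match(f.gene))


def is_bl7_bl12(f: Feature) -> bool:
    return f.gene == "rplL" or bool(_BL7L12.search(f.product))


def is_rpsu(f) -> bool:
    """Identify the bS21 gene from metadata (works on Feature or GeneAffinity)."""
    return f.gene == "rpsU" or bool(_RPSU.search(f.product))


def select_ribosomal_genes(org: Organism, min_count: int = 25):
    """R-protein CDS of an organism, or ``ORGANISM_DISCARDED`` if < 25."""
    selected = [
        f
        for f in org.cds_features()
        if is_ribosomal_protein(f) and not is_bl7_bl12(f)
    ]
    if len(selected) < min_count:
        return ORGANISM_DISCARDED
    return selected


# ---------------------------------------------------------------------------
# Window-constrained minimum energies
# ---------------------------------------------------------------------------

def _window_min(asd: str, tir: TIRWindow, lo: int, hi: int, params: NNParameterTable):
    """Minimum ΔG over registers whose helix lies wholly in [lo, hi].

    Registers are the distance ``o`` between the ASD 5' end and the first
    start-codon base (ASD base i sits at TIR offset −o−i).  Every maximal
    run of consecutive pairs is scored independently; runs with any base
    pair outside the window are ineligible.  Ties go to the smallest
    offset.  Returns (dG, offset, helix_len) with dG = 0, offset None when
    nothing stabilizing is found.
    """
    seq, s0, L = tir.seq, tir.start_index, len(asd)
    n = len(seq)
    stacks, init, term = params.stacks, params.init, params.terminal_au
    best = (0.0, None, 0)
    for o in range(-hi - (L - 1), -lo + 1):
        # full pairing mask at this register (window applied per run below,
        # so boundary-straddling helices are excluded, never truncated)
        mask = []
        for i in range(L):
            j = s0 - o - i
            mask.append(0 <= j < n and (asd[i], seq[j]) in PAIRS)
        i = 0
        while i < L:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j < L and mask[j]:
                j += 1
            # run coords span -o-(j-1) … -o-i; require full containment
            if j - i >= 2 and -o - i <= hi and -o - (j - 1) >= lo:
                total = init
                for k in range(i, j - 1):
                    key = asd[k] + asd[k + 1] + "/" + seq[s0 - o - k] + seq[s0 - o - k - 1]
                    total += stacks[key]
                for k in (i, j - 1):
                    if (asd[k], seq[s0 - o - k]) in _WEAK_PAIRS:
                        total += term
                if total < best[0]:
                    best = (total, o, j - i)
            i = j
    return best


def sd_min_energy(
    asd: str, tir: TIRWindow, params: NNParameterTable, window: tuple = SD_WINDOW
):
    """Minimum SD pairing energy: helices wholly inside −25…+12."""
    return _window_min(str(asd), tir, window[0], window[1], params)


def msd_min_energy(
    asd: str, tir: TIRWindow, params: NNParameterTable, window: tuple = MSD_WINDOW
) -> float:
    """Minimum mock-SD pairing energy: helices wholly inside −40…−26."""
    return _window_min(str(asd), tir, window[0], window[1], params)[0]


# ---------------------------------------------------------------------------
# Whole-organism scan
# ---------------------------------------------------------------------------

def scan_organism(
    org: Organism,
    asd,
    params: NNParameterTable,
    sd_window: tuple = SD_WINDOW,
    msd_window: tuple = MSD_WINDOW,
) -> list:
    """One :class:`GeneAffinity` per CDS feature (all protein-coding genes).

    Genes whose annotated 5' end lacks 40 nt of upstream sequence are
    scored on N-padded windows rather than dropped.
    """
    asd_seq = str(asd)
    out = []
    for f in org.cds_features():
        tir = tir_window(org, f)
        sd_dg, sd_off, sd_len = sd_min_energy(asd_seq, tir, params, sd_window)
        msd_dg = msd_min_energy(asd_seq, tir, params, msd_window)
        out.append(
            GeneAffinity(
                organism=org.id,
                gene=f.gene or f.feature_id,
                product=f.product,
                is_rprotein=is_ribosomal_protein(f) and not is_bl7_bl12(f),
                sd_dG=sd_dg,
                sd_offset=sd_off,
                sd_helix_len=sd_len,
                msd_dG=msd_dg,
            )
        )
    return out
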