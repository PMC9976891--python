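"""Organism-level statistics on per-gene TIR affinities.

Per organism, the cumulative histogram N(E) counts the genes whose
minimum pairing free energy is at least as strong as E (dG ≤ E) at
integer edges in 1 kcal/mol steps.  Weak chance pairings decay
geometrically, so on a log axis the tail of N(E) is a straight line; an
exponential ``ln N(E) = a + b E`` is fit over the −6…−1 kcal/mol range,
and the energy at which the fitted curve reaches a count of one,
``E* = −a/b``, is the *expected maximal TIR affinity*: the strongest
affinity one gene is expected to reach by chance alone.  Genes stronger
than E* by at least k kcal/mol (k = 0…8) are counted as excess genes.

An organism is classified RPSU_STRONG_SD when *rpsU* (bS21) is the
unique minimum among its ribosomal-protein genes and that minimum is
stronger than −13 kcal/mol — the signature of bS21 autoregulation.
Classifications can be exported as an iTOL color-strip annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tir_scan import is_rpsu

__all__ = [
    "CumulativeHistogram",
    "ChanceTailFit",
    "OrganismSummary",
    "FitFailure",
    "RPSU_STRONG_SD",
    "OTHER",
    "UNCLASSIFIED",
    "cumulative_histogram",
    "fit_chance_tail",
    "count_excess_genes",
    "classify_organism",
    "summarize_organism",
    "write_tree_annotation",
    "read_tree_annotation",
    "plot_cumulative",
]

FIT_RANGE = (-6.0, -1.0)
DEFAULT_THRESHOLD = -13.0
EXCESS_THRESHOLDS = range(9)

RPSU_STRONG_SD = "RPSU_STRONG_SD"
OTHER = "OTHER"
UNCLASSIFIED = "UNCLASSIFIED"

CLASS_COLORS = {
    RPSU_STRONG_SD: "#1f78b4",
    OTHER: "#e31a1c",
    UNCLASSIFIED: "#bdbdbd",
}


class FitFailure(RuntimeError):
    """The chance tail could not be fit (too few bins or no decay)."""


@dataclass(frozen=True)
class CumulativeHistogram:
    """Cumulative gene counts over 1 kcal/mol bins.

    Genes are binned at floor(dG) and accumulated from the strong side,
    so N(E) counts the genes whose binned affinity is at least as strong
    as the edge E: N(E) = #{genes : dG < E + 1}.
    """

    organism: str
    source: str  # "SD" or "MSD"
    edges: np.ndarray  # integer kcal/mol edges, ascending to 0
    counts: np.ndarray  # N(E) = #genes with floor(dG) <= E

    def count_at(self, edge: float) -> int:
        idx = np.where(self.edges == edge)[0]
        return int(self.counts[idx[0]]) if len(idx) else 0


@dataclass(frozen=True)
class ChanceTailFit:
    intercept: float  # a in ln N(E) = a + b E
    slope: float  # b > 0
    E_star: float  # -a/b, kcal/mol
    n_bins: int
    residual: float


@dataclass(frozen=True)
class OrganismSummary:
    organism: str
    n_genes: int
    n_rproteins: int
    E_star: float | None
    excess_counts: tuple | None
    rprotein_min_gene: str | None
    classification: str


def cumulative_histogram(affinities, source: str = "SD") -> CumulativeHistogram:
    """N(E) at integer edges from the weakest floor(dG) up to 0."""
    if not affinities:
        raise ValueError("empty affinity list")
    if source not in ("SD", "MSD"):
        raise ValueError("source must be 'SD' or 'MSD'")
    values = np.array(
        [a.sd_dG if source == "SD" else a.msd_dG for a in affinities]
    )
    lo = int(math.floor(values.min()))
    edges = np.arange(lo, 1)
    counts = np.array([(values < e + 1).sum() for e in edges])
    return CumulativeHistogram(
        organism=affinities[0].organism, source=source, edges=edges, counts=counts
    )


def fit_chance_tail(hist: CumulativeHistogram) -> ChanceTailFit:
    """OLS of ln N(E) on E over edges in the −6…−1 kcal/mol range.

    Only edges with N ≥ 1 enter the fit; at least three are required and
    the counts must decay toward negative E (b > 0), otherwise
    :class:`FitFailure` is raised and the organism is left unclassified.
    """
    sel = (
        (hist.edges >= FIT_RANGE[0])
        & (hist.edges <= FIT_RANGE[1])
        & (hist.counts >= 1)
    )
    e = hist.edges[sel].astype(float)
    n = hist.counts[sel].astype(float)
    if len(e) < 3:
        raise FitFailure(f"{hist.organism}: only {len(e)} usable bins in the tail")
    b_slope, a = np.polyfit(e, np.log(n), 1)
    if b_slope <= 0:
        raise FitFailure(f"{hist.organism}: no decay in the chance tail")
    resid = float(np.sum((np.log(n) - (a + b_slope * e)) ** 2))
    return ChanceTailFit(
        intercept=float(a),
        slope=float(b_slope),
        E_star=float(-a / b_slope),
        n_bins=int(len(e)),
        residual=resid,
    )


def count_excess_genes(
    affinities, fit: ChanceTailFit, thresholds=EXCESS_THRESHOLDS
) -> tuple:
    """#genes with sd_dG ≤ E* − k for each threshold k (kcal/mol)."""
    values = np.array([a.sd_dG for a in affinities])
    return tuple(int((values <= fit.E_star - k).sum()) for k in thresholds)


def classify_organism(
    rprotein_affinities, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Apply the rpsU rule to an organism's r-protein affinities.

    RPSU_STRONG_SD iff the rpsU gene attains the unique minimum sd_dG
    among ribosomal-protein genes and that minimum is stronger than the
    threshold (default −13 kcal/mol).  Ties involving another gene, or a
    weaker minimum, give OTHER; no identifiable rpsU gives UNCLASSIFIED.
    """
    if not rprotein_affinities:
        return UNCLASSIFIED
    rpsu = [a for a in rprotein_affinities if is_rpsu(a)]
    if len(rpsu) != 1:
        return UNCLASSIFIED
    rpsu_dg = rpsu[0].sd_dG
    others = [a.sd_dG for a in rprotein_affinities if not is_rpsu(a)]
    unique_min = all(rpsu_dg < d for d in others)
    return RPSU_STRONG_SD if unique_min and rpsu_dg < threshold else OTHER


def summarize_organism(
    affinities,
    threshold: float = DEFAULT_THRESHOLD,
) -> OrganismSummary:
    """Full per-organism summary from its gene affinities.

    The chance-tail fit runs on all protein-coding genes; classification
    uses the r-protein subset.  A fit failure leaves E*/excess counts
    empty and the organism UNCLASSIFIED.
    """
    rprots = [a for a in affinities if a.is_rprotein]
    organism = affinities[0].organism if affinities else ""
    rmin = min(rprots, key=lambda a: a.sd_dG).gene if rprots else None
    try:
        fit = fit_chance_tail(cumulative_histogram(affinities, "SD"))
    except (FitFailure, ValueError):
        return OrganismSummary(
            organism=organism,
            n_genes=len(affinities),
            n_rproteins=len(rprots),
            E_star=None,
            excess_counts=None,
            rprotein_min_gene=rmin,
            classification=UNCLASSIFIED,
        )
    return OrganismSummary(
        organism=organism,
        n_genes=len(affinities),
        n_rproteins=len(rprots),
        E_star=fit.E_star,
        excess_counts=count_excess_genes(affinities, fit),
        rprotein_min_gene=rmin,
        classification=classify_organism(rprots, threshold),
    )


# ---------------------------------------------------------------------------
# iTOL annotation
# ---------------------------------------------------------------------------

_ITOL_HEADER = """DATASET_COLORSTRIP
SEPARATOR SPACE
DATASET_LABEL rpsU_SD_class
COLOR #1f78b4
LEGEND_TITLE rpsU_SD_class
LEGEND_SHAPES 1 1 1
LEGEND_COLORS {c_strong} {c_other} {c_unclassified}
LEGEND_LABELS RPSU_STRONG_SD OTHER UNCLASSIFIED
DATA
"""


def write_tree_annotation(summaries, path) -> None:
    """iTOL DATASET_COLORSTRIP file: one ``organism color`` line each."""
    with open(path, "w") as fh:
        fh.write(
            _ITOL_HEADER.format(
                c_strong=CLASS_COLORS[RPSU_STRONG_SD],
                c_other=CLASS_COLORS[OTHER],
                c_unclassified=CLASS_COLORS[UNCLASSIFIED],
            )
        )
        for s in sorted(summaries, key=lambda s: s.organism):
            fh.write(f"{s.organism} {CLASS_COLORS[s.classification]}\n")


def read_tree_annotation(path) -> dict:
    """Recover the organism → classification map from an annotation file."""
    color_to_class = {v: k for k, v in CLASS_COLORS.items()}
    out = {}
    in_data = False
    for line in open(path):
        line = line.strip()
        if line == "DATA":
            in_data = True
            continue
        if in_data and line:
            organism, color = line.split(" ")
            out[organism] = color_to_class[color]
    return out


def plot_cumulative(hists, path) -> None:
    """Cumulative SD/MSD histograms on a log y-axis (cosmetic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"SD": "tab:red", "MSD": "tab:blue"}
    for h in hists:
        ax.step(
            h.edges,
            np.maximum(h.counts, 0.5),
            where="post",
            color=colors.get(h.source, "k"),
            label=f"{h.organism} {h.source}",
        )
    ax.set_yscale("log")
    ax.set_xlabel("pairing free energy E (kcal/mol)")
    ax.set_ylabel("genes with dG <= E")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
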