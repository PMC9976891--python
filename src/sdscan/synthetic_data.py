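"""Synthetic genomes with planted ASD/SD truth, and simulated kinetic data.

The genome generator emulates the statistical structure the screen
assumes: multi-copy 16S rRNA genes carrying the conserved 21-nt motif a
fixed distance upstream of a configurable 13-nt extended-ASD tail,
protein-coding genes with i.i.d. upstream sequence at a chosen GC
content, a designated *rpsU* gene with a planted extended SD of tunable
strength, and a full complement of annotated ribosomal-protein genes.
Everything is reproducible from a single integer seed, and each build
returns a truth table recording what was planted.

Backgrounds can optionally be SD-depleted (upstream windows resampled
until no helix stronger than a threshold remains), mimicking the
SD-avoidance of Bacteroidia genomes and guaranteeing that planted SDs
are the only strong hits.

Kinetic simulators produce single-exponential time courses
``A*(1 - exp(-k t))``, equilibrium toeprint binding curves
``F = Fmax*bc/(bc + 1/KA)`` and Arrhenius rate series
``k(T) = k_ref*exp(-(Ea/R)(1/T - 1/T_ref))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex_energy import NNParameterTable
from .genome_io import Contig, Feature, Organism, reverse_complement, transcribe
from .kinetics_fit import R_KCAL, ArrheniusSeries, BindingCurve, TimeCourse
from .tir_scan import TIRWindow, sd_min_energy

__all__ = [
    "DEFAULT_ASD_TAIL",
    "CONSERVED_MOTIF_DNA",
    "OrganismSpec",
    "PlantedSD",
    "TruthTable",
    "SpecError",
    "build_organism",
    "flavobacteriales_like_spec",
    "simulate_time_course",
    "simulate_binding_curve",
    "simulate_arrhenius",
]

CONSERVED_MOTIF_DNA = "AAGTCGTAACAAGGTAGCCGT"

# Bacteroidia-like extended ASD (16S nt 1532-1544 analogue).  Its perfect
# 13-bp complement scores -20.66 kcal/mol under the shipped Turner-2004
# table, matching the strongest rpsU SDs observed in Flavobacteriales.
DEFAULT_ASD_TAIL = "GAUCACCUCCUUU"

_UPSTREAM_LEN = 45  # nt of intergenic sequence ahead of each start codon
_BODY_LEN = 48  # ATG + 14 codons + stop
_RRNA_LEN = 150  # annotated span of each synthetic 16S gene

# (gene, product) roster; rplL (bL7/bL12) is present so the downstream
# exclusion rule is exercised.  rpsU is always entry 0.
_RPROTEIN_ROSTER = (
    [("rpsU", "30S ribosomal protein S21")]
    + [("rplL", "50S ribosomal protein L7/L12")]
    + [
        (f"rps{chr(ord('A') + n - 1)}", f"30S ribosomal protein S{n}")
        for n in range(2, 21)
    ]
    + [
        (f"rpl{chr(ord('A') + n - 1)}", f"50S ribosomal protein L{n}")
        for n in range(1, 25)
        if n != 12  # rplL already included
    ]
)


class SpecError(ValueError):
    """Invalid organism specification."""


@dataclass(frozen=True)
class OrganismSpec:
    seed: int = 0
    organism_id: str | None = None
    n_rrna_copies: int = 3
    asd_tail: str = DEFAULT_ASD_TAIL
    n_cds: int = 400
    n_rproteins: int = 28
    planted_sd: tuple = ()  # (gene, SD sequence 5'->3', spacer) triples
    background_gc: float = 0.35
    divergent_asd: str | None = None
    sd_depletion_threshold: float | None = None

    def __post_init__(self) -> None:
        for tail in filter(None, [self.asd_tail, self.divergent_asd]):
            if len(tail) != 13 or set(tail) - set("ACGU"):
                raise SpecError(f"ASD tail must be 13 nt over ACGU: {tail!r}")
        if not 0.0 < self.background_gc < 1.0:
            raise SpecError("background_gc must be in (0, 1)")
        if self.n_rrna_copies < 1:
            raise SpecError("need at least one 16S copy")
        if self.n_rproteins > len(_RPROTEIN_ROSTER):
            raise SpecError(
                f"at most {len(_RPROTEIN_ROSTER)} r-protein genes available"
            )
        for gene, sd, spacer in self.planted_sd:
            if spacer < 0:
                raise SpecError(f"negative spacer for {gene!r}")
            if len(sd) + spacer > _UPSTREAM_LEN:
                raise SpecError(
                    f"planted SD for {gene!r} longer than the upstream region"
                )

    @property
    def id(self) -> str:
        return self.organism_id or f"syn{self.seed:08d}"


@dataclass(frozen=True)
class PlantedSD:
    gene: str
    seq: str  # RNA, 5'->3'
    spacer: int  # nt strictly between SD 3' end and the start codon
    sd_dG: float  # energy of the planted TIR under the default table


@dataclass(frozen=True)
class TruthTable:
    organism: str
    asd_tail: str
    planted: dict  # gene -> PlantedSD
    expected_class: str  # AMBIGUOUS / RPSU_STRONG_SD / OTHER


def flavobacteriales_like_spec(seed: int, **overrides) -> OrganismSpec:
    """Study conditions for a Flavobacteriales-like organism.

    One *rpsU* gene carries the full 13-nt complement of the extended
    ASD at a 5-nt spacer (ΔG ≈ −20 kcal/mol); all other upstream regions
    are SD-depleted at −6 kcal/mol, the depth to which chance pairing is
    treated as coincidental.
    """
    tail = overrides.pop("asd_tail", DEFAULT_ASD_TAIL)
    kwargs = dict(
        seed=seed,
        asd_tail=tail,
        planted_sd=((("rpsU", transcribe(reverse_complement(tail)), 5)),),
        sd_depletion_threshold=-6.0,
    )
    kwargs.update(overrides)
    return OrganismSpec(**kwargs)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=probs))


def _rrna_block(rng, tail_rna: str, gc: float) -> str:
    """Sense sequence of one synthetic 16S gene (length _RRNA_LEN).

    The conserved motif is placed so that the extraction rule (motif end
    + 19 … + 31 within the 110-nt window around the 3' end) lands exactly
    on the tail.
    """
    body = list(_random_dna(rng, _RRNA_LEN, gc))
    w0 = int(rng.integers(25, 46))  # motif offset within the tail window
    insert = CONSERVED_MOTIF_DNA + _random_dna(rng, 19, gc) + tail_rna.replace("U", "T")
    at = (_RRNA_LEN - 100) + w0  # window starts 100 nt before the 3' end
    body[at : at + len(insert)] = insert
    return "".join(body)


def _gene_block(rng, spec, planted_sd, asd_rna, params) -> tuple:
    """Draw one gene's (upstream, body), with planting or depletion applied.

    Depletion resamples upstream and body together against the gene's
    actual TIR (upstream tail plus the first 12 nt of the coding body),
    so pairings rooted in the early coding region are rejected too.
    """
    gc = spec.background_gc

    def draw_body() -> str:
        return "ATG" + _random_dna(rng, _BODY_LEN - 6, gc) + "TAA"

    if planted_sd is not None:
        sd_dna = planted_sd[0].replace("U", "T")
        spacer = planted_sd[1]
        up = list(_random_dna(rng, _UPSTREAM_LEN, gc))
        lo = _UPSTREAM_LEN - spacer - len(sd_dna)
        up[lo : lo + len(sd_dna)] = sd_dna
        return "".join(up), draw_body()
    if spec.sd_depletion_threshold is None:
        return _random_dna(rng, _UPSTREAM_LEN, gc), draw_body()
    for _ in range(500):
        up = _random_dna(rng, _UPSTREAM_LEN, gc)
        body = draw_body()
        tir = TIRWindow(gene="candidate", seq=transcribe(up[-40:] + body[:12]))
        if sd_min_energy(asd_rna, tir, params)[0] >= spec.sd_depletion_threshold:
            return up, body
    raise SpecError("SD depletion failed to converge; threshold too strict")


def build_organism(spec: OrganismSpec, params: NNParameterTable | None = None):
    """Build one synthetic organism and its truth table."""
    rng = np.random.default_rng(spec.seed)
    params = params or NNParameterTable.default()
    gc = spec.background_gc
    planted_by_gene = {g: (sd, spacer) for g, sd, spacer in spec.planted_sd}

    contig_id = f"{spec.id}_c1"
    parts: list = []
    features: list = []
    pos = 0  # 0-based cursor

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    emit(_random_dna(rng, 60, gc))

    # --- 16S rRNA copies -------------------------------------------------
    for copy in range(spec.n_rrna_copies):
        tail = spec.asd_tail
        if spec.divergent_asd is not None and copy == spec.n_rrna_copies - 1:
            tail = spec.divergent_asd
        block = _rrna_block(rng, tail, gc)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            block = reverse_complement(block)
        start = emit(block)
        features.append(
            Feature(
                contig_id,
                start + 1,
                start + _RRNA_LEN,
                strand,
                "rRNA16S",
                {"ID": f"{spec.id}_rrna{copy + 1}", "product": "16S ribosomal RNA"},
            )
        )
        emit(_random_dna(rng, 15, gc))

    # --- protein-coding genes --------------------------------------------
    roster = list(_RPROTEIN_ROSTER[: spec.n_rproteins]) + [
        (None, "hypothetical protein") for _ in range(spec.n_cds)
    ]
    truth_planted: dict = {}
    for idx, (gene_name, product) in enumerate(roster, start=1):
        feat_id = f"{spec.id}_g{idx:05d}"
        name = gene_name or feat_id
        planted = planted_by_gene.pop(name, None)
        upstream, body = _gene_block(rng, spec, planted, spec.asd_tail, params)
        strand = "+" if rng.random() < 0.5 else "-"
        block = upstream + body
        if strand == "+":
            start = emit(block)
            f_start, f_end = start + _UPSTREAM_LEN + 1, start + len(block)
        else:
            start = emit(reverse_complement(block))
            f_start, f_end = start + 1, start + _BODY_LEN
        attrs = {"ID": feat_id, "product": product}
        if gene_name:
            attrs["gene"] = gene_name
        features.append(Feature(contig_id, f_start, f_end, strand, "CDS", attrs))
        if planted is not None:
            tir = TIRWindow(
                gene=name, seq=transcribe(upstream[-40:] + body[:12])
            )
            dg = sd_min_energy(spec.asd_tail, tir, params)[0]
            truth_planted[name] = PlantedSD(
                gene=name, seq=transcribe(planted[0]), spacer=planted[1], sd_dG=dg
            )
    if planted_by_gene:
        raise SpecError(
            f"planted_sd names unknown genes: {sorted(planted_by_gene)}"
        )

    emit(_random_dna(rng, 30, gc))
    org = Organism(spec.id, [Contig(contig_id, "".join(parts))], features)
    return org, TruthTable(
        organism=spec.id,
        asd_tail=spec.asd_tail,
        planted=truth_planted,
        expected_class=_expected_class(spec, truth_planted),
    )


def _expected_class(spec: OrganismSpec, planted: dict) -> str:
    if spec.divergent_asd is not None:
        return "AMBIGUOUS"
    rpsu = planted.get("rpsU")
    if rpsu is None or rpsu.sd_dG >= -13.0:
        return "OTHER"
    others = [p.sd_dG for g, p in planted.items() if g != "rpsU"]
    return "RPSU_STRONG_SD" if all(rpsu.sd_dG < d for d in others) else "OTHER"


# ---------------------------------------------------------------------------
# Kinetic simulators
# ---------------------------------------------------------------------------

def _check_noise(noise_sd: float) -> None:
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")


def simulate_time_course(
    k_app: float,
    amplitude: float,
    times,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TimeCourse:
    """Single-exponential product formation ``A*(1 - exp(-k t))``.

    Gaussian noise (sd = ``noise_sd``) is added and the signal truncated
    at zero; ``noise_sd=0`` gives the exact curve.
    """
    _check_noise(noise_sd)
    if k_app <= 0:
        raise ValueError("k_app must be positive")
    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must be in (0, 1]")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    y = amplitude * (1.0 - np.exp(-k_app * t))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.shape)
    return TimeCourse(t=t, y=np.maximum(y, 0.0))


def simulate_binding_curve(
    F_max: float,
    K_A: float,
    b_values,
    c: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BindingCurve:
    """Toeprint isotherm ``F = Fmax*bc/(bc + 1/KA)`` over tRNA inputs."""
    _check_noise(noise_sd)
    if K_A <= 0:
        raise ValueError("K_A must be positive")
    if not 0 < F_max <= 1:
        raise ValueError("F_max must be in (0, 1]")
    if c <= 0:
        raise ValueError("c must be positive")
    b = np.asarray(b_values, dtype=float)
    F = F_max * (b * c) / (b * c + 1.0 / K_A)
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=b.shape)
    return BindingCurve(b=b, c=c, F=np.clip(F, 0.0, 1.0))


def simulate_arrhenius(
    E_a: float,
    k_ref: float,
    T_ref: float,
    temperatures,
    noise_sd_lnk: float = 0.0,
    seed: int | None = None,
) -> ArrheniusSeries:
    """Rates ``k(T) = k_ref*exp(-(Ea/R)(1/T - 1/T_ref))``, R in kcal/mol/K.

    Optional lognormal noise multiplies each rate by ``exp(N(0, sd))``.
    """
    _check_noise(noise_sd_lnk)
    if k_ref <= 0 or T_ref <= 0:
        raise ValueError("k_ref and T_ref must be positive")
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    k = k_ref * np.exp(-(E_a / R_KCAL) * (1.0 / T - 1.0 / T_ref))
    if noise_sd_lnk > 0:
        k = k * np.exp(
            np.random.default_rng(seed).normal(0.0, noise_sd_lnk, size=T.shape)
        )
    return ArrheniusSeries(T=T, k_app=k)
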