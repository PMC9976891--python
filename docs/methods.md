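# Methods

This note records the models implemented in `sdscan`, the conventions and
defaults they rely on, and the limits of what the synthetic benchmarks
demonstrate.

## Coordinates and windows

Genomic features are GFF3 (1-based, inclusive); all window arithmetic is
0-based half-open internally. TIR positions use the field's notation in
which +1 is the first nucleotide of the start codon and there is no
position 0; internally the first start-codon base is offset 0. The TIR is
the 52-nt window −40…+12 (N-padded at contig edges; genes at contig edges
are scored on padded windows rather than dropped). The SD search window is
−25…+12 and the mock-SD (MSD) window −40…−26: the shared endpoint −25 is
assigned to the SD side so the windows are disjoint and no helix can be
counted twice.

A *register* is the distance in nucleotides between the ASD 5' end (16S
nt 1532) and the first start-codon base; the ASD lies antiparallel on the
message, so its 5' base pairs the most downstream position of the duplex.

## ASD extraction

For every annotated 16S gene, the strand-corrected region from 100 nt
upstream to 10 nt downstream of the 3' end (110 nt) is searched for the
conserved motif `AAGUCGUAACAAGGUAGCCGU` by semi-global alignment: the
full 21-mer must be covered, substitutions and indels cost 1, and at most
5 errors (an error rate of 0.25 on a 21-nt adapter) are allowed. Among
equal-error alignments the leftmost end is taken; alignment is performed
with `edlib` (infix mode) and is cross-checked in the test suite against
an independent dynamic-programming oracle. The extended ASD is the 13-nt
slice starting 19 nt after the matched motif end — the stated downstream
range spans positions 19–32, but every downstream use of the tail is
13 nt (16S nt 1532–1544), so the 13-nt reading (offsets +19…+31) is
implemented. Extraction is anchored at the *aligned* motif end, so indels
in the motif shift the slice as adapter trimming would. Slices containing
N, or running off the window, yield no candidate. Organisms whose copies
yield more than one distinct tail are AMBIGUOUS (excluded); organisms
with no recoverable tail are MISSING.

## Duplex energy model

Hybridization is scored under a rigid, gapless register model: at each
register the aligned positions that form Watson-Crick or G·U pairs are
marked (N never pairs), maximal runs of consecutive pairs are enumerated,
and each run of ≥ 2 pairs is scored as

    dG(run) = dG_init + Σ stack(step) + terminal penalties,

with the terminal penalty applied to A·U or G·U pairs closing either
helix end. A register's energy is the best run, capped at zero; when no
run is stabilizing the reported helix length is 0. Only the single best
contiguous run is scored — no bulges, internal loops, or multi-helix sums
— so absolute values are comparable only under this convention.

Parameters are the Turner 2004 RNA/RNA set (Watson-Crick stacks of Xia et
al. 1998; G·U stacks of Mathews et al. 1999) at 37 °C, with duplex
initiation +4.09 kcal/mol and terminal A·U/G·U penalty +0.45 kcal/mol,
shipped as a versioned TSV (`turner2004-1.0`) whose version label is
recorded in run manifests; `--params` substitutes a table. No temperature
rescaling is applied. Because the energy model behind published screens
of this kind is not uniquely determined, absolute thresholds (e.g.
−13 kcal/mol) are model-relative.

For the windowed minima (SD and MSD), runs are enumerated on the full
pairing mask and a run qualifies only if *every* base pair lies inside
the window; boundary-straddling helices are excluded, never truncated —
truncation would manufacture weak artifactual hits at window edges. Ties
across registers go to the smallest offset. The effective upper register
bound is set by the requirement that the helix fit the TIR; no separate
spacing cap is imposed.

## Chance-tail statistics

Per organism, per-gene minima are binned at floor(ΔG) in 1 kcal/mol steps
and accumulated from the strong side: N(E) = #{genes : ΔG < E + 1}. The
weak tail of N(E) decays geometrically for sequence of i.i.d. composition,
so ln N(E) is fit by unweighted OLS over integer edges in [−6, −1] with
N ≥ 1 (at least 3 such edges required; the weighting choice is recorded in
the fit diagnostics so it can be revisited). The expected maximal TIR
affinity is E\* = −a/b, the energy where the fitted curve reaches a count
of one. Excess-gene counts use the exact (unbinned) comparison
#{ΔG ≤ E\* − k} for k = 0…8. Fit failures (too few bins, or no decay)
leave the organism UNCLASSIFIED rather than guessing.

Classification: ribosomal-protein genes are selected by metadata
(products matching "ribosomal protein", gene names rps*/rpl*/rpm*),
excluding the identical twins bL7/bL12 (*rplL*); organisms with fewer
than 25 remaining annotations are discarded. `RPSU_STRONG_SD` requires
*rpsU* (gene name, or product naming S21/bS21) to be the *unique*
minimum — ties are conservatively `OTHER` — and stronger than the
−13 kcal/mol threshold (strictly).

## Kinetic and binding fits

* Time courses are fit to the single-exponential burst y = A(1 − e^(−kt)).
  The functional form is an assumption: only apparent rates are reported
  for dipeptide assays, and a single exponential is the minimal model
  consistent with that. Multi-start Levenberg-Marquardt (three
  deterministic, data-derived starts: initial-slope rate, half-rise rate,
  unit rate) with non-negative bounds; standard errors from the fit
  covariance.
* Arrhenius: OLS of ln k on 1/T, E_a = −slope·R with R = 1.987×10⁻³
  kcal·mol⁻¹·K⁻¹ (kcal units throughout to avoid J/kcal mix-ups);
  unweighted, which the result objects note via their residuals.
* Toeprint isotherms: F = F_max·bc/(bc + 1/K_A) with F_max ∈ [0, 1] and
  K_A > 0, multi-start from the half-max crossing. When every titration
  point satisfies bc·K_A > 10 the curve is on its plateau and the fit
  carries a `saturated` flag: F_max is reliable, K_A only a rough lower
  estimate.

## Synthetic data: what it emulates, what it does not

`build_organism` plants, on a single contig: (i) n 16S genes (default 3)
each carrying the conserved motif at a randomized position followed by a
19-nt spacer and the 13-nt tail, placed so the extraction rule lands
exactly on the tail; minus-strand copies exercise strand correction;
(ii) background CDS genes (default 400) with 45-nt i.i.d. upstream
regions at configurable GC (default 0.35, Flavobacteria-like); (iii) a
ribosomal-protein complement (default 28 genes, including exactly one
*rpsU* and one *rplL*). The default tail `GAUCACCUCCUUU` carries the core
CCUCC and its perfect 13-bp complement scores −20.66 kcal/mol — the
strength of the strongest observed rpsU SDs. Everything derives from one
integer seed; equal seeds give byte-identical FASTA/GFF.

Optional *SD depletion* resamples each non-planted gene's upstream+body
TIR until its SD minimum is ≥ −6 kcal/mol, emulating the SD avoidance of
Bacteroidia genomes and guaranteeing the planted SD is the only strong
hit. The Flavobacteriales-like preset combines depletion with a planted
full-complement rpsU SD at a 5-nt spacer.

Deliberately not modeled: codon usage, operons, phylogenetic covariance,
annotation errors, and rRNA gene prediction (16S coordinates come from
the GFF). Gene counts default to hundreds rather than the thousands of a
real genome — chance-tail fits are correspondingly noisier, which the
tests absorb — and a passing synthetic screen demonstrates correctness of
the machinery, not that real genomes satisfy the model's assumptions.

Two structural caveats discovered during design: (1) the SD window (37
positions) offers more registers than the MSD window (15), so on i.i.d.
sequence the full-window SD minima are stochastically stronger than MSD
minima (~1 kcal/mol in the mean at these settings); the null-equivalence
test therefore compares equal-width windows, and the MSD-vs-SD "rightward
shift" of depleted genomes is asserted on the deep tail (counts beyond
−6 kcal/mol), which is the feature that matters. (2) With backgrounds
depleted at −6 and rpsU planted at ≈ −20, the planted excess over E\*
is ~9–13 kcal/mol, so excess-gene counts stay at exactly 1 through
threshold 8; the modal single-gene law at thresholds 0–4 holds, but the
transition to zero counts seen in real genome ensembles (whose chance
tails run deeper) is outside this construction.

## Noise models and robustness

Additive Gaussian noise on fractions (time courses truncated at 0,
binding fractions clipped to [0, 1]) and lognormal noise on rates keep
simulated values in their physical domains. At the benchmark noise levels
(sd 0.02 on fractions; 0.05 on ln k) the true parameters fall within ±3
standard errors in ≥ 95% of 200 replicates for k_app, E_a and F_max; K_A
is covered only when the titration is unsaturated.

## Determinism

All randomness flows through `numpy.random.default_rng` seeds; pipeline
reruns with the same configuration are byte-identical, and the manifest
records seed, parameter-table version, window bounds and the
kept/ambiguous/missing/discarded funnel.
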