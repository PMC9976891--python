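# sdscan

Genome-scale screening for Shine-Dalgarno (SD) sequences using the
**extended anti-SD (ASD)** of 16S rRNA, with the statistics needed to
detect genes whose SD is stronger than chance, plus fits for translation
initiation kinetics and toeprint binding curves.

## The problem

Ribosomes of the class Bacteroidia do not use SD sequences for initiation:
the 3' tail of their 16S rRNA — the ASD — is sequestered in a pocket on
the 30S platform formed by proteins bS21, bS18 and bS6. Yet in many of
these organisms one gene, *rpsU* (encoding bS21 itself), carries an
exceptionally strong extended SD. Ribosomes that lack bS21 leave the ASD
free, initiate efficiently on *rpsU* mRNA, and thereby autoregulate bS21
synthesis. The genomic signature of this mechanism is a single gene per
genome whose ASD pairing free energy is far stronger than expected by
chance, and `sdscan` implements the screen that finds it:

1. **ASD extraction** — each annotated 16S rRNA gene is cut to the 110-nt
   window around its 3' end; the conserved motif `AAGTCGTAACAAGGTAGCCGT`
   is located by semi-global alignment (≤ 5 errors over the full 21-mer,
   substitutions and indels); the 13 nt beginning 19 nt past the motif end
   (16S nt 1532–1544) are the extended ASD. Organisms whose 16S copies
   disagree are excluded as AMBIGUOUS.
2. **Register scanning** — the ASD is slid rigidly across each gene's
   translation initiation region (TIR, positions −40…+12 around the start
   codon). At each register, the best run of consecutive Watson-Crick /
   G·U pairs is scored with nearest-neighbor thermodynamics (Turner 2004):
   ΔG = ΔG_init + Σ stacks + terminal A·U/G·U penalties. The SD statistic
   is the minimum ΔG over helices inside −25…+12; the mock-SD (MSD)
   statistic uses the window −40…−26, too far upstream to act as an SD,
   as a chance-level control.
3. **Chance-tail statistics** — per organism, the cumulative histogram
   N(E) of per-gene minima (1 kcal/mol bins) is exponential in its weak
   tail; fitting ln N(E) = a + bE over −6…−1 kcal/mol and solving N = 1
   gives the *expected maximal TIR affinity* E\* = −a/b. Genes with
   ΔG ≤ E\* − k are "excess" genes at threshold k.
4. **Classification** — an organism is `RPSU_STRONG_SD` when *rpsU* is the
   unique minimum among its ≥ 25 ribosomal-protein genes (bL7/bL12
   excluded) *and* that minimum is stronger than −13 kcal/mol. Results
   export as an iTOL color strip for tree annotation.
5. **Kinetics** — apparent rates from single-exponential time courses
   y = A·(1 − e^(−kt)); Arrhenius activation energies from OLS of ln k on
   1/T (E_a = −slope·R, R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹); toeprint
   titrations fit to F = F_max·bc/(bc + 1/K_A).

Real screens run on thousands of RefSeq genomes; `sdscan` ships a
synthetic-genome generator that plants 16S motifs, ASD tails, and SDs of
known strength with a truth table, so the entire pipeline is testable at
desk scale.

## Worked example

```bash
python examples/01_screen_synthetic_genome.py
```

```
organism syn00000001: 428 CDS, 3 16S copies
extended ASD: GAUCACCUCCUUU (UNIQUE); planted tail recovered: True
strongest SD: rpsU at -20.66 kcal/mol (helix 13 bp, ASD 5' end 6 nt upstream)
expected maximal TIR affinity E* = -11.77 kcal/mol
genes beyond E* by 0..8 kcal/mol: (1, 1, 1, 1, 1, 1, 1, 1, 1)
classification: RPSU_STRONG_SD
```

The organism carries a planted full 13-bp complement of its extended ASD
upstream of *rpsU*: the screen recovers the tail from the 16S copies,
finds the planted helix as the genome-wide minimum (−20.66 kcal/mol, ~9
kcal/mol beyond the strongest affinity expected by chance), and exactly
one gene exceeds E\* at every threshold — the single-strong-SD signature
of bS21 autoregulation. Other examples cover the register-wise energy
profile (`02`), the three kinetic fits with standard errors (`03`) and
the cohort pipeline with funnel accounting (`04`).

The same stages are scriptable from a shell:

```bash
sdscan simulate genome --seed 4 --out-prefix org
sdscan extract-asd --fasta org.fasta --gff org.gff3 --out asd.tsv
sdscan scan --fasta org.fasta --gff org.gff3 --asd asd.tsv --out genes.tsv
sdscan stats --genes genes.tsv --out summary.tsv --itol tree.txt
sdscan run --out-dir out --n-organisms 10 --seed 1
```

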