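# Methods

This note documents the models, estimators and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Expression screen

The statistic for a gene *g* in a glue-producing focal species is the fold
ratio r(g) = TPM_glue(g) / TPM_nonglue(g), with TPM_nonglue the maximum of
the gene's TPM over all species annotated `nonglue`. Using the per-species
maximum makes the screen conservative: a focal gene only scores highly if it
exceeds its best-expressed homologue anywhere outside the glue lineage. When
several homologues exist per species, the caller decides which TPM enters
the table (conventionally the per-species maximum); the pipeline does not
re-derive orthology, and reference-gene selection (e.g. BUSCO single-copy
genes plus housekeeping genes) is likewise supplied via `gene_class`.

Significance is empirical, not parametric: the same ratio is computed for
every reference-class gene, and the focal gene is ranked within that null
with the add-one estimator p = (1 + k)/(1 + n), k the number of null ratios
≥ the focal ratio (ties count toward k, the conservative direction). The
estimator never returns 0, its floor is 1/(n+1), and leave-one-out ranking
of the reference genes themselves is super-uniform under exchangeability —
the calibration property the test suite checks at n = 500. A zero
denominator (gene silent in every non-glue species) is handled by adding a
pseudocount (default 0.01 TPM) to both numerator and denominator, which
avoids infinities while preserving the ordering of ratios. No
multiple-testing correction is applied across focal genes; p-values are
reported per gene.

## Tandem-repeat detection

Candidate periods p are proposed by positional autocorrelation: the
fraction of positions i with s[i] = s[i+p], windowed over one unit length.
Windows at or above the identity threshold seed candidate regions (dips
shorter than one unit are bridged); each region is refined against a phased
majority consensus — greedy extension while flanking residues match the
consensus phase, trimming of mismatching termini by at most one unit — and
scored by mean identity to the tiled consensus. Copy number is region
length / period and may be fractional.

Two rules make the output deterministic and biologically sensible:

- **Smallest period within tolerance.** A majority consensus at any integer
  multiple of the true period always scores at least as high (splitting a
  phase column can only raise its majority count), so a strict argmax would
  report 36 for an 18-mer array. Overlapping candidates therefore compete on
  matched residues (length × identity); all candidates within 0.03 identity
  of the best are deemed to explain the region equally well and the smallest
  period among them wins. Exact tandems thereby report the primitive period
  of their unit, and homopolymers period 1. The 0.03 tolerance is far below
  the identity drop (tens of percent) of a genuinely wrong period, and above
  the overfitting inflation (< 0.01 at realistic copy numbers) of a period
  multiple.
- **Coverage-weighted resolution.** Scoring overlap groups by matched
  residues rather than raw identity prevents a short perfect sub-array (for
  example a chance homopolymer inside a noisy repeat region) from
  displacing the long imperfect array that actually explains the region.

Defaults — periods 2–60, ≥ 3 copies, ≥ 0.6 identity — bracket both known
PRIT repeat unit lengths (8 and 18) with ample margin; the detector is
validated against an independent full period-scan oracle and recovers the
18-mer unit exactly in ≥ 95/100 synthetic proteins at 10% substitution.
"Tandem PG" is counted as the longest run of consecutive PG dipeptides
(starting at any offset), matching the "up to four tandem PG motifs"
phrasing: run-length, not total count. Glycosylation candidates are Ser/Thr
positions, optionally filtered by an external per-residue score track at an
inclusive 0.5 threshold; both the raw and filtered counts are exposed
because published repeat-unit Ser/Thr counts do not state which convention
they use.

## Domain properties

GRAVY uses the Kyte–Doolittle scale (shipped as data, asserted against the
published constants in the tests); unknown residues (X) are excluded from
the average and from composition denominators but flagged. Molecular weight
uses average (not monoisotopic) residue masses plus one water, the
ProtParam convention. The theoretical pI solves net charge = 0 by bisection
on [0, 14] with the Bjellqvist pKa set (side chains D 4.05, E 4.45, C 9.0,
Y 10.0, H 5.98, K 10.0, R 12.0; C-terminus 3.55; residue-specific
N-terminal values); net charge is strictly decreasing in pH so the root is
unique, and the result matches a 0.001-pH grid scan to within 0.01.
Disorder and secondary structure are consumed as per-residue tracks from
external predictors — re-implementing those predictors is explicitly out of
scope — with the inclusive ≥ 0.5 disorder call. The comparative table
reports per-species min/median/max of each metric and a glue-minus-nonglue
difference of medians; with a single group the contrast is flagged NaN.

## Selection summaries

The branch-site likelihood machinery that produces per-site posterior
probabilities of positive selection is consumed, not re-implemented: its
output enters as a `site<TAB>posterior` table and the comparative metric is
the proportion of sites with posterior ≥ 0.5 (threshold exposed as a flag;
the convention "more likely than not" motivates 0.5).

As an internal, assumption-light estimator the package implements NG86
counting: per-codon synonymous site fractions from single-nucleotide
neighbours with mutations to stop codons counted as nonsynonymous;
pairwise differences averaged over all shortest mutational paths that avoid
stop codons (falling back to all paths, stop steps nonsynonymous, in the
rare fully blocked case); Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation); ω = dN/dS,
undefined when dS is 0 or saturated (None, never a sentinel number).
Gapped codons are skipped pairwise and counted. The implementation is
checked exhaustively against an independent path-enumeration oracle over
all 61 × 61 sense-codon pairs. NG86 serves recovery tests on synthetic
alignments (class-mean ω ordering), not as a substitute for the likelihood
analysis on real data.

## Pull tests

Tensile strength is σ = 1000·F/A (kPa from N and mm²); the standard brick
bonding face is 9.6 mm × 15.8 mm = 151.68 mm². Trials where the blocks
never bond enter as force 0, hence σ = 0. Group summaries use the sample SD
(n − 1), reported as NA for singletons. Treatment contrasts use a
two-sided permutation test on the difference of group means: labels are
shuffled within each animal that contributed trials to both treatments and
freely among the remaining trials, with the add-one p estimator. A mixed
model with animal as random effect is the classical alternative; the
permutation test was chosen because it needs no distributional assumptions,
remains valid at the small group sizes typical of these assays (n = 7–15),
and keeps the package free of a mixed-model dependency. Published z- and
p-values from mixed-model fits are therefore not reproduction targets.

## Synthetic generators

All generators take one integer seed (`numpy.random.default_rng`), are
deterministic given (parameters, seed), and return a `GeneratorTruth`
record; recovery tests consume truth only through the test harness, never
through analysis code paths.

- **Expression**: per gene a baseline TPM log-uniform on [1, 1000]; each
  species multiplies it by exp(N(0, σ²)) with σ = 0.5 by default — a free
  choice (no published dispersion estimate exists for cross-species TPM
  ratios of single-copy genes) fixed once and used unchanged in all tests;
  focal genes are further multiplied by their spike fold in the glue
  species. Default panel: 1 glue + 7 non-glue species, 200 reference genes.
  Not emulated: read-level sampling noise, mapping bias, homolog
  mis-assignment — so passing tests show the screen's statistical
  behaviour, not robustness to quantification artefacts.
- **Proteins**: signal peptide (20 residues, hydrophobic-biased), 1–4
  uniform-random 390-residue domains, inter-domain arrays of 12–24 copies
  (uniform unless fixed) of an 18-mer unit carrying two tandem PGs and
  three S/T sites, each copy independently substituted at the given rate.
  Real structured domains are not compositionally random; this only matters
  for detector false positives, which the random-background tests bound.
- **Disorder tracks**: N(0.85, 0.1) over repeats, N(0.2, 0.1) elsewhere,
  clipped to [0, 1] — the separation the predictors report, without their
  positional autocorrelation.
- **Codon alignments**: sitewise-independent evolution along a balanced
  tree (default 6 taxa), Gillespie simulation over single-nucleotide
  neighbour rates with transitions scaled by κ (default 2) and
  nonsynonymous changes by the site's ω; rates normalised so branch lengths
  (default 0.2) are expected substitutions per codon site at neutrality;
  stop codons unreachable; uniform root codons. This is deliberately a
  minimal ω/κ model, not GY94 with codon frequencies: the tests assert
  ordering and recovery, not likelihood values.
- **Pull tests**: strengths N(μ, σ) truncated at 0 per treatment (defaults
  are the published per-treatment mean/SD/n triples), forces back-computed
  via F = σ·A/1000, masses uniform on the 6–10 mg protocol window, animals
  cycled through a pool of 6.

## Problem sizes and determinism

The statistical acceptance tests run at: 500 reference genes
(calibration), 200 seeded replicates of the 119-fold spike (power), 100
synthetic proteins at 10% substitution (repeat recovery), 100 seeded
alignments of 6 taxa × 900 codons (ω ordering), the full 61 × 61 codon
table (NG86), and 100 random ≤ 50-mers (pI). These sizes were chosen so
each property is measured at, or above, the scale of the original study
design while the whole suite completes in well under a minute per
property. Pipeline reports are byte-identical across reruns for a fixed
config and seed except for the timestamp field.

## Limitations

- The screen assumes comparable TPM normalisation across libraries; it
  inherits whatever cross-library bias the input tables carry.
- The repeat detector targets tandem arrays of a single unit; it does not
  model higher-order repeat structure (repeats of repeats beyond period
  reduction) or nucleotide-level repeats.
- NG86 counting is downward-biased at high divergence and ignores codon
  frequencies; it is a recovery-test instrument, not a replacement for
  likelihood-based ω estimation.
- The per-site selection metric depends entirely on the upstream
  branch-site analysis that produced the posteriors; the package only
  thresholds and summarises them.
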