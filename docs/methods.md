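# Methods

## Study system and data model

The package models an advanced intercross line (AIL) between two nearly
identical inbred mouse lines, S1 and S2, phenotyped weekly for body weight
from week 3 (weaning) to week 25. Diet changes twice: standard chow until
week 20, a high-fat/low-carbohydrate diet in weeks 21–22, then a
high-fat/high-carbohydrate diet in weeks 23–25 (`DietSchedule.study_default`).
Genotypes are biallelic calls coded 2 = S1/S1, 1 = heterozygous, 0 = S2/S2,
−1 = missing; because the founders are inbred, every informative marker is
opposite-homozygous between them, and code 2 is fixed to the line whose
allele increases weight so that all effect signs are comparable. Coordinates
are 1-based inclusive throughout; BED input is converted on read.

## Association model

Each week is tested independently — no longitudinal covariance model, which
matches the analysis the package re-implements and keeps every weekly result
interpretable on its own. The default test is a one-way fixed-effects ANOVA
with genotype as a (up to) three-level factor; this directly produces the
genotype-class means reported alongside QTLs and makes no additivity
assumption. An additive allele-dosage regression (slope t-test on codes
0/1/2) is provided as an option. Genotype classes with fewer than
`min_class_n` (default 5) animals are excluded from a marker's test; markers
left with fewer than two classes carry an explicit `tested = False` flag
rather than a silent NA. R² is the between-group share of the total sum of
squares (ANOVA) or the squared genotype–phenotype correlation (regression);
with two classes the two coincide. Evidence is LOD = −log10(p). P-values
are floored at 1e-300 so a degenerate zero-residual fit cannot yield an
infinite LOD.

## Multiple testing

m_eff follows the simpleM idea: map-ordered, chromosome-bounded windows of
at most `window_size` (default 820) markers; per window, the Pearson
correlation matrix of genotype codes (missing calls mean-imputed per marker)
is eigendecomposed and the window's count is the smallest k whose top-k
eigenvalues reach C (default 0.995, the published simpleM default) of the
eigenvalue sum. Windows are disjoint — whether the original usage was
sliding or disjoint is not documented, so the simpler reading is implemented
and stated here; a final short window is kept as-is. Numerical-noise
eigenvalues below zero are clamped before the cumulative sum; zero-variance
markers are excluded from a window with a warning (their correlation is
undefined). The genome-wide LOD cutoff at level α is −log10(α/m_eff).

## Support intervals

The weekly 1.5-LOD-drop interval walks outward from the top marker through
the contiguous run of markers with LOD ≥ top − drop and takes the first
marker beyond the run on each side (the terminal marker when the run reaches
a chromosome end). The contiguous-run reading — rather than global
thresholding of the chromosome — keeps disjoint secondary peaks from
extending the interval. Per the two-stage design, the drop can be computed
on the array-genotyped subset only (`marker_ids=` restriction). The final
QTL region is the min-start/max-end union across weeks; by default only
significant weeks contribute, because a flat-profile week would otherwise
inflate the region toward the whole chromosome — a documented divergence
risk from an "all measured weeks" reading, switchable via
`only_significant=False`. Significance spans are maximal runs of consecutive
significant weeks; a gap in week numbering breaks a run.

## Outlier rule and QC

Weekly outliers are weights more than k (default 3, strict inequality) SDs
from that week's population mean. Mean and SD are computed once per week
over non-missing values — a single pass, never iterated, so the rule is not
idempotent under recomputation and is deliberately specified this way.
Sample SD (ddof = 1) is used. Weeks with fewer than two values are skipped
with a warning. Marker QC drops monomorphic markers and markers with a
missing rate above 0.10 (configurable; the underlying array QC is out of
scope and consumed as done).

## Two-stage merge

Targeted-assay calls for the non-array animals are merged into the array
matrix: union of animals, missing where untyped, error on conflicting
non-missing duplicates, every non-missing input call preserved. Scans on
the merged matrix use ~397 animals at targeted markers and ~200 elsewhere,
reproducing the sample-size discontinuities seen in the real LOD curves.

## Prioritization

Scores are additive over evidence categories. Default weights: deleterious
domain missense 8, tolerated domain missense 3, UTR 1, promoter 1.5,
enhancer 1, CTCF 1.5, splice site 1, differential expression 2 per tissue
(BH-adjusted p < 0.05), pathway membership 1, and 0.5 per tissue whose
expression could not be measured — "no data" ranks between "DE" and
"measured, not DE", which is what separates an unmeasured candidate from a
measured-negative one with identical variant evidence. The original
decision-tree weights are not published; these defaults are the package's
own calibration and reproduce the published candidate ordering on the
bundled fixture (exact score values are not claimed). Missense records with
a SIFT score are relabelled by the SIFT convention (deleterious < 0.05);
without a score the incoming label is trusted. BH adjustment is the
standard step-up (via statsmodels), applied jointly per tissue across the
interval's genes. A 1000 bp up/downstream padding for variant-to-gene
assignment is configurable at flag-assembly time; the bundled VEP-style
records already carry gene assignments, so the padding only matters when
positional records are supplied.

## ChoRE motif scanning

Consensus-to-PWM uses unit weights: informative positions contribute 1 for
the consensus base, N positions are all-zero and excluded from the score
denominator, so the window score is the matched fraction of the 12
informative positions and min.score 90 % admits at most one mismatch. This
deterministic reading reproduces the published one-mismatch promoter hit
while keeping letters at N positions irrelevant (degenerate-consensus
semantics). Upstream extraction takes 2000 bp from the gene-level TSS
([tss−L, tss−1] for + genes, reverse complement of [tss+1, tss+L] for −
genes), truncating at chromosome ends with a warning; transcript-level 5'UTR
placement is out of scope. Both strands are scanned; hits are mapped back to
forward-genome coordinates and report the forward-strand letters plus the
genome strand of the match.

## Synthetic data generator

Founders are opposite-homozygous everywhere. F1 is produced from the
initial S1 × S2 pair; subsequent generations pair parents uniformly at
random, re-drawing to avoid full-sib matings when possible (at F2 all
animals are full sibs, so the exclusion is vacuous there) — an approximation
to scheduled random-mating programs, adequate because only the genotype
correlation structure matters downstream. Gametes recombine between
consecutive loci with Haldane probability r = ½(1 − e^(−2d)) at the default
0.5 cM/Mb; chromosome boundaries recombine freely. Intermediate generations
hold 100 breeding animals (a drift level that keeps F10 genotype frequencies
near ¼/½/¼ while realistic for a managed AIL); the final generation has
`n_animals` (default 397). QTLs are inserted as hidden loci in the
haplotypes and removed from the emitted marker panel, so scans must localise
them through linkage.

Weights are logistic-growth means (asymptote 45 g, rate 0.25/week,
inflection week 9 — chosen to track the reported weekly population means
from ~11 g at week 3 to mid-40s g in adults) plus per-QTL additive and
dominance effects, a per-animal polygenic deviation, and independent weekly
noise. Effects and SDs scale with the growth fraction by default, so
juveniles show proportionally smaller effects and spreads; adult residual SD
defaults to 3.5 g and polygenic SD to 2.0 g, together ~4 g — the reported
adult within-class spread. A per-week effect multiplier implements
diet-switch attenuation (the study conditions use 0.2 in weeks 21–23,
spanning the low-carbohydrate phase and the first high-carbohydrate week);
a helper expands phase-level multipliers over a diet schedule. Selective
genotyping takes the n/2 lowest and highest animals by a proxy (default:
last-week weight; the real design selected on adiposity-related traits,
which this proxy stands in for), with ties broken by animal id.

## Study and calibration conditions

The replicate studies in `ailqtl.evaluation` (used by tests and the
acceptance script) run the 397-animal F10 design at a reduced density of
500 markers over five 100-Mb chromosomes — the pipeline's statistics are
density-independent, and this size keeps 20-replicate studies near half a
minute. One QTL (additive 2.7 g, homozygote contrast 5.4 g ≈ 13 % of adult
weight) is detected when any marker within 15 Mb exceeds LOD 4.2 in any
week of the merged scan; coverage asks whether the aggregated array-stage
interval contains the true position. Null calibration uses a no-QTL panel
of 200 markers on 20 mouse-like chromosomes at 10 Mb spacing (moderate LD,
so the pooled empirical p-value distribution reflects test calibration
rather than LD clustering), redrawing phenotype noise per scan: KS distance
of pooled p-values against U(0,1), and family-wise error as the fraction of
scans whose maximum LOD crosses the −log10(0.05/m_eff) threshold.

## Numerical and design choices

* Ties at the top of a scan break by smaller p, then smaller position, then
  earlier week; ranked candidates tie-break alphabetically — all outputs are
  deterministic given inputs and seed.
* Readers canonicalise marker order (chromosome natural order, then
  position) so results do not depend on input row order; written/read
  round-trips are exact.
* The pipeline writes one immutable run directory per config, echoes every
  stage's parameters into the log, and records a config hash: identical
  hash implies identical numeric outputs.

## What the simulations do and do not show

The generator reproduces the design's sampling structure (AIL LD, selective
genotyping, two-stage sample sizes, diet-window attenuation) but idealises
biology: no X chromosome or sex effects (the modelled population is male),
no epistasis, no litter/cage effects, equal marker informativeness, and a
shared growth curve. Passing the replicate studies therefore demonstrates
that the statistical machinery is correct and well calibrated under the
stated model, not that real data meet these assumptions. Real-data quirks —
array QC, segregation distortion, map errors — are out of scope and must be
handled upstream.
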