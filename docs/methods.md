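# Methods

Modeling assumptions and conventions of the `icbreed` simulator, in the
order a simulation executes them.

## Founder genomes

Founders are simulated per crop with msprime under a piecewise-constant
demography: effective population size ramping from 50 (recent) to 32,000
over 20 epochs ending 100,000 generations ago, mimicking a domestication
bottleneck. Each chromosome is simulated as an independent tree sequence;
founder DH lines are drawn as single haplotypes (ploidy-1 samples) and
duplicated — the DH conversion of a Hardy–Weinberg base individual.

The full-scale genome has 10 chromosome pairs, each 1.43 Morgans and
8×10⁸ bp, giving a per-bp recombination rate of 1.43 / 8×10⁸ ≈ 1.8×10⁻⁹;
binary mutations arise at 2×10⁻⁹ per bp. From the sites segregating among
the founders, 1,000 QTN and 2,000 SNP-array markers per chromosome are
sampled uniformly and assigned roles at random. The desk preset keeps the
map length but shrinks to 2 chromosomes × (100 QTN + 200 SNP) on 1 Mb
with a proportionally raised mutation rate.

Meiosis places Poisson(map length) crossovers uniformly on the genetic
map (no interference). A DH line is one gamete doubled; an F1 of two DH
parents carries exactly the two parental haplotypes.

## Traits and phenotypes

Each crop has two correlated additive traits: monocrop yield and
intercrop yield (general intercropping ability, GIA). Per-QTN effect
pairs are drawn from a bivariate standard normal with the chosen genetic
correlation and rescaled so each trait's founder genetic variance is
exactly 1 (population, divide-by-n convention).

Phenotypes are entry means with fixed, founder-anchored error variances:
a stage with target entry-mean heritability h² uses σ²ₑ/r = (1 − h²)/h²
(σ²_A = 1). The target h² is a design property defined against founder
variance, so as selection erodes variance the realized heritability of
later cohorts falls below target — plots do not become more precise as
the material narrows. Examples: DH stage h² = 0.10 → σ²ₑ = 9; PYT
h² = 0.33 with r = 4 → per-plot σ²ₑ ≈ 8.12.

The intercrop yield of a pair (i from crop A, j from crop B) is the mean
of the two genotypes' intercrop genetic values plus noise. A GIA record
of one candidate is its intercrop plot against a probe variety of the
other crop (GIA1 uses one probe, GIA2 a small probe set, recorded as
entry means).

## Pipeline structure

Both crops run the same yearly cycle, staggered stages overlapping:

1. crossing block (80 parents full scale) → F1
2. DH production, taking **2 years** (a FIFO of cross batches)
3. PYT (monocrop), GIA1, GIA2 (intercrop vs probes) — per crop
4. SIA1, SIA2 (candidate pairs, shared between the crops), release

Parents selected at GIA1 spend one year in seed increase before entering
the block, giving generation intervals of 5 (Pheno, Baseline-GS),
3 (PYT-GS), and 2 years (DH-GS, Grid-GS). In the 2-year-interval arms,
parents are DH lines crossed the year they are selected, so even- and
odd-year cohorts form two closed lineages that never recombine — an
inherent property of the design, not an implementation choice.

Crossing is random without replacement in Pheno/Baseline-GS/PYT-GS. The
DH-stage arms use truncation selection (best n by genomic GIA) followed
by relative-avoiding pairing: parents are ordered by family, the block
is split in halves, and slot k of the first half is crossed to slot
(k + generation) mod n/2 of the second, so every parent enters exactly
one cross per round and full sibs never meet when the family profile
permits; the rotating shift defers the re-meeting of relatives.

Grid-GS replaces PYT/GIA with the grid stage: the best `grid_keep` DH
per crop by genomic GIA span a factorial grid of candidate pairs
(500 × 500 = 250,000 full scale) of which 900 are field-tested; the 50
best-*predicted* combinations advance to SIA1. Before a program switches
to Grid-GS, an initialization phase in the last 5 burn-in years selects
`init_keep` PYT lines per crop per year and field-tests all init_keep²
combinations, seeding the grid model's training window.

## Genomic models

Conventional genomic programs fit, per crop, a two-trait RR-BLUP on a
5-year sliding window: the SNP genotypes of the last 5 PYT cohorts and
their PYT/GIA1/GIA2 records (5 × 500 = 2,500 genotypes; 2,739 records at
full scale). Monocrop records load centered SNP dosages into the
monocrop-effect block; intercrop records load **half** the dosages into
the intercrop block, because a GIA record contains half of each
contributor's genetic value — this keeps predicted GIA on the
genetic-value scale. Fixed effects are year×stage cell means;
residual variances are heterogeneous per record (the stage's calibrated
entry-mean error variance). The marker-effect prior is G ⊗ I / Σ2pₖqₖ
with G the 2×2 genetic (co)variance matrix, treated as known and
recomputed each year from the training window's true genetic values
(floored and correlation-clipped near fixation). The mixed-model
equations are solved exactly (dense).

The grid model is the two-crop analogue on pair records: each record's
design row carries half of each member's centered dosages in that crop's
marker block, with independent per-crop priors. Its training window is
the last 5 years of grid-kept genotypes plus grid/SIA pair records
(5 × (900 + 50 + 8) = 4,790 records at full scale).

Predicted GIA (gGIA) is the centered dosage times the intercrop marker
effects; a pair's gGIA is the mean of its members'. All uses are
rankings, so no intercept is added.

## Costing

Annual cost = 2 crops × (DH lines × $35 + monocrop plots × $20) +
intercrop plots × $50 (GIA plots count twice — one per crop; SIA and
grid plots once, being shared) + genotyped samples × $20. Genomic
programs genotype the PYT entries (Baseline-GS, PYT-GS) or every DH line
(DH-GS, Grid-GS). The DH-per-cross count is the budget lever: it is set
so each program's total meets the phenotypic program's budget
(~$493,200/year full scale), reproducing 47, 47, 80, and 90 DH per cross
for the four genomic programs.

## Experiments and evaluation

A replicate simulates fresh founders, runs a 20-year phenotypic burn-in
once, and branches every program arm off a deep copy of the burn-in
state — arms are seed-paired. The future phase is 20 years. Gain is the
mean intercrop genetic value of the year's DH cohorts (both crops),
centered at the end-of-burn-in mean; variance is the pooled intercrop
genetic variance; accuracy is the correlation of each crop's DH-stage
selection criterion with true intercrop values.

Endpoint gain is the mean of the last **two** future years: in the
2-year-interval arms the final-year cohort belongs to one of the two
closed lineages only, and averaging adjacent years removes that parity
lottery (a negligible smoothing for yearly-turnover arms). The gain
ratio of two arms is the back-transformed mean of per-replicate paired
log-ratios (a geometric mean) with a paired-t confidence interval;
replicates with a non-positive endpoint gain in either arm are excluded
with a logged count.

The desk preset shrinks the phenotypic program to 20 crosses × 25 DH
(PYT 100, GIA1 20, GIA2 8) and budget-matches the other arms with the
same lever; the DH-stage arms keep the full-scale 40-cross, 80-parent
structure (family size absorbs the budget), because the number of
parents per cycle — not family size — keeps each closed lineage viable
at small scale. Desk-scale contrasts are compressed relative to full
scale (selection intensity at the DH stage is i ≈ 1.3 instead of
i ≈ 2.4, and the small closed populations approach their selection limit
within the horizon), which is why acceptance bands on gain ratios are
wide (±30%).

## Reproducibility

Every random stream descends from one base seed through named
`SeedSequence` spawn keys `[base, rep, (corr), component]`; msprime seeds
are drawn as integers in [1, 2³¹−1). Identical configurations reproduce
byte-identical outputs (`icbreed selfcheck` verifies this).
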