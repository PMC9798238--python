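# Methods

`binqtl` reconstructs the genetic analysis chain used for QTL mapping in
dense biparental populations genotyped by sequencing: parental-origin SNP
calls are smoothed into recombination bins, the bins become markers of a
Kosambi linkage map, and composite interval mapping (CIM) with permutation
thresholds locates trait loci that are then merged across environments.
A synthetic-data module generates populations with the statistical structure
this chain assumes, so every stage is testable without sequencing data.

## Synthetic populations

**Crossover model.** Each meiosis places a Poisson number of crossovers with
mean equal to the chromosome's genetic length in Morgans, positions uniform
on the cM scale — a no-interference (Haldane) process. This is the simplest
process consistent with the downstream use of a map function; crossover
interference is deliberately not modelled, and because adjacent-bin map
distances are small (~0.2–0.3 cM) the choice of Kosambi vs. Haldane for
those intervals is numerically immaterial.

**Lines.** RILs descend from the F1 of an A × B cross by single-seed
descent; the default is six selfing generations (F7), leaving ≈1.6% residual
heterozygosity. The expected density of parental-origin junctions in the
final mosaic approaches 2 per Morgan (the selfed-RIL map expansion); at F7
the realized density is ~93–96% of that limit because unfixed heterozygous
tracts remain. Tests compare the simulator against an independent
discrete-locus gamete tracker.

**Genotype corruption.** Observed GBS-derived calls are emulated by flipping
each call to one of the other two codes with probability 1% and masking to
missing with probability 5% (the defaults throughout). Allele-depth-level
simulation is out of scope: the pipeline starts from genotype calls.

**Genome dimensions.** The default template mirrors a dense maize map: ten
chromosomes, 2.06 Gb, 2,180.9 cM, ~78k informative SNPs, with a uniform
bp→cM rate per chromosome. Real recombination landscapes are strongly
non-uniform (pericentromeric suppression); the uniform default means
physical bin sizes are more homogeneous than in real data, which affects
nothing that is computed on the cM scale.

**Phenotypes.** The genetic value of a line is Σᵢ aᵢxᵢ over additive QTLs
with x = +1/0/−1 for the A/H/B genotype at the QTL. Environment (year ×
location cell), replicate-within-environment, G×Y, G×L, G×Y×L and residual
deviations are independent normals. `architecture_for_h2` scales a noise
profile — proportions (0.1, 0.1, 0.2, 0.15) across (G×Y, G×L, G×Y×L,
residual) — so that the entry-mean H² formula evaluates to a target (0.81 by
default) given the realized genetic variance of the simulated lines. An
unbalanced preset reproduces a three-environment layout (one location in two
years plus a second location in one year).

## Genotype QC

SNPs are retained when both parents are homozygous for different alleles;
progeny alleles carried by neither parent are unscorable (N). Segregation
distortion is tested per SNP by a 1-df χ² of A:B counts against 1:1 with H
and N excluded (RILs are near-homozygous, and the transmission of residual
heterozygotes is not modelled); SNPs with p < 0.001 are removed. Continuity
correction is off by default (counts are large) but available. Call-rate
screening removes SNPs below a 20% call rate, then lines below 20%; the
order is fixed and documented. Unanchored scaffolds are dropped by a
chromosome-name allow-list.

On error-free, undistorted simulations the χ² filter loses at most the
nominal 0.1% type-I fraction of SNPs (verified over 50 matrices).

## Bin calling

A 15-SNP window slides one SNP at a time over each line's non-missing calls;
a window is called A or B when at least 11 of its 15 sites come from that
parent, otherwise H. Runs of equal window calls merge into blocks. Each
block supports the center SNPs of its windows; the first/last blocks extend
to the line's first/last informative SNP.

**Crossover localization.** A single clean crossover necessarily produces a
short H run while the window crosses it (six windows for the 11/15 rule), so
an H run of at most `window` windows flanked by opposite homozygous blocks
is collapsed into a single A↔B breakpoint before counting and localization.
Genuine residual-heterozygous tracts span many more windows and keep both of
their flanking breakpoints. The breakpoint interval is then refined inside
the physical zone spanned by the two transition windows: it runs from the
last raw call matching the left block to the first raw call matching the
right block, padded by one observed SNP on each side; if call errors invert
that order the full zone is kept. Under 1% error this leaves >95% of true
crossovers inside their reported interval while keeping intervals a few SNP
spacings wide. The midpoint of the interval places the breakpoint on the
grid.

**Bins.** The chromosome is divided into 100-kb grid intervals; every grid
interval containing at least one breakpoint midpoint (any line) starts a new
bin, and a bin is the maximal run of grid intervals between boundaries. Per
line, a bin inside a block takes the block call; a bin overlapping the
line's own breakpoint interval takes the majority of the line's raw calls in
the bin (ties → N); a bin with no raw calls takes the flanking-block call
when both flanks agree, else N. Bin-genotype accuracy is evaluated against
the length-majority true label of the bin, over non-missing calls. No
smoothing beyond the window rule (e.g. minimum block length) is applied.

## Linkage map

Marker order is fixed by physical position. For adjacent bins, the observed
discordance fraction R among lines homozygous at both is converted to the
meiotic recombination fraction by the selfed-RIL relation r = R/(2(1−R))
(capped at 0.4999) and to cM by Kosambi, d = 25·ln((1+2r)/(1−2r)).

Lines whose call at one or more intervening bins is H or N would silently
lose their recombination events under a purely pairwise rule, shortening the
map by ~10–15% at realistic heterozygosity; `build_map` therefore apportions
each recombination event between a line's nearest informative bins uniformly
across the spanned intervals, with the line counting once toward each
spanned interval's denominator. With no gaps this reduces exactly to the
pairwise estimate. Intervals covered by fewer than two informative lines
yield no distance: the right bin is merged into the left and logged.

Two conventions worth noting: the per-chromosome summary reports mean
adjacent distance as total cM divided by interval count; and at finite
selfing generations the realized junction density is slightly below the
F∞ expansion the r-inversion assumes, so estimated totals on error-free
simulations land ~4–8% below the simulated truth (within the 10% recovery
bound the tests enforce).

## Mixed models, BLUEs and heritability

Two REML fits are used. The BLUE model treats lines as fixed (cell-means
coding, so the estimates are adjusted line means on the trait scale) with
random replicate-within-environment, environment and line×environment terms.
The variance-component model treats lines as random with fixed
environment-cell means and random G×year, G×location, G×cell and
replicate-within-environment terms (terms whose factor has one level are
fixed at zero; without year/location columns, environments are treated as
locations of one year). Entry-mean broad-sense heritability is

    H² = σG² / (σG² + σGY²/Y + σGL²/L + σGLY²/(Y·L) + σE²/(Y·L·R)).

REML is computed by EM iteration on Henderson's mixed-model equations
(Cholesky factorization per iteration; block traces of the inverse from the
triangular inverse), with three safeguards: componentwise Aitken
extrapolation accepted only when it does not decrease the restricted
likelihood (evaluated cheaply via the MME determinant identity), components
collapsing toward zero pinned at the boundary, and a secondary stop when the
monotone likelihood has plateaued for ten iterations while a tiny
near-boundary component is still drifting geometrically. Primary
convergence is a relative change below 1e-8 (1e-6 in the simulation
studies). Negative component iterates cannot occur under EM; the boundary
pin plays the role of truncation at zero. On balanced designs with interior
estimates REML coincides with the closed-form ANOVA expected-mean-square
estimators, which serve as the test-suite oracle. Significance of random
terms, when wanted, comes from likelihood-ratio comparisons via
`reml_loglik` rather than classical mean-square F tests.

Environment correlations are Pearson correlations of per-line environment
means, pairwise-complete, undefined below three shared lines.

## QTL scan

The scan is Haley–Knott regression on expected genotype scores. At a
genotyped bin the score is the observed call (+1/0/−1); at missing calls and
pseudomarkers it is the conditional expectation under a two-state selfed-RIL
Markov chain between the nearest informative flanking bins, with interval
switch probabilities R = 2r/(1+2r) from Kosambi-inverted map distances. The
model is additive-only: a selfed-RIL cross has two genotype classes, and the
standard analysis treats it as such; retaining a dominance column would add
a degree of freedom to the null at every position and inflate the
genome-wide threshold by ~0.2–0.5 LOD. (A `dominance` flag retains the
heterozygote indicator for exploratory use.)

Cofactors are chosen by forward selection on partial F statistics with a
Bonferroni entry criterion over the candidate markers — a pure-noise
phenotype therefore usually selects none — up to 5 cofactors, with
candidates within 10 cM of a chosen cofactor blocked. During the scan,
cofactors within 10 cM of the test position are dropped from both the null
and the QTL model, and LOD(t) = (n/2)·log₁₀(RSS₀/RSS₁). With no cofactors
this is simple interval mapping, which the test suite checks against an
independent per-position regression oracle at 1e-10.

**Thresholds.** Phenotypes are permuted across lines (each permutation drawn
from its own seed substream, so the set is reproducible under any batching);
the genome-wide maximum LOD is recorded per permutation and the threshold is
the type-7 empirical 95th percentile of 1,000 permutations. Cofactors are
fixed across permutations by default (`reselect` re-runs selection per
permutation). On the full-scale simulated map (275 lines, ~2,060 cM
realized, ~9k bins) the threshold lands at ≈3.4–3.6; an idealized
Markov-field simulation of the same dimensions gives ≈3.4, so this is the
inherent value for a genome of this genetic length at n=275 rather than an
artifact of the bin calling.

**Intervals, effects, merging.** The support interval is the outermost span
of chromosome positions within 1.5 LOD of the peak, expanded one evaluation
point outward (the convention of the standard `lodint` utility; secondary
bumps within the drop widen the interval), with Mb bounds taken from the
outer physical extents of the flanking bins. ADD is the regression
coefficient on the score (half the A-minus-B class difference; positive =
female-parent allele increases the trait). PVE comes from the joint
additive multi-QTL fit by drop-one R² differences when several peaks exist,
else from 100·(1−10^(−2·LOD/n)). QTLs from different environments merge
into consensus loci by single-linkage under (interval overlap) OR (peak
distance ≤ 20 Mb), named by trait prefix and chromosome with positional
ordinals when a chromosome hosts several loci.

## Downstream statistics

Marker-group phenotype differences use Welch's two-sided t-test.
Expression–trait association uses Pearson correlation with the t-transform
p-value, pairwise-complete, plus Benjamini–Hochberg adjusted q-values across
genes. qPCR relative expression is 2^(−ΔΔCq) on replicate means, with
replicate standard errors propagated into a fold-change range.

## Calibration evidence and problem sizes

The simulation studies in the test suite and acceptance script use: the full
ten-chromosome template at n=275 for the permutation threshold and map
recovery; 2 chromosomes × 2,000 SNPs × 200 lines for bin-calling fidelity;
3 chromosomes × 150 cM at n=275 with 400 null scans and 200 planted-QTL
scans (10% PVE) for error and power; and 50 trials of 60 lines × 12 plots
for H² recovery. Because null phenotypes are exchangeable, the 400 null
scans are compared against the permutation distribution of one of them.
Measured behaviour at these sizes: bin-genotype accuracy ≈99.9%, crossover
recovery ≈98%, map recovery ≈92–94% of simulated truth, type-I ≈5–6%,
power ≈98%, interval coverage ≈97%, mean recovered H² ≈0.80 for a 0.81
architecture. Passing these tests shows the chain is internally consistent
and well calibrated under its own assumptions — uniform recombination rate,
no interference, symmetric call errors, normal G×E structure — not that it
is robust to features real data add (non-uniform marker density,
depth-dependent error, segregation distortion hotspots, field spatial
trends).

## Known limitations

- Pairwise/apportioned recombination estimation, not hidden-Markov
  multipoint; fine for dense bins, not for sparse maps.
- The F∞ selfed-RIL correction slightly understates distances at F6–F7.
- Crossovers closer than the window's resolution (~11 SNP spacings) are
  invisible by construction, as in any sliding-window caller.
- CIM here is Haley–Knott with fixed-count forward-selected cofactors;
  EM-mixture likelihood and model-search refinements are out of scope.
- The BLUE model assumes homoscedastic environments; no spatial adjustment.
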