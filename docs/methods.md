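# Methods

`haplodyn` reimplements, as one tested pipeline, the analyses typical of a
chloroplast phylogeography study of a narrowly distributed plant: per-
population sequence diversity, hierarchical population structure, a
statistical-parsimony haplotype network, climatic-suitability trajectories
across Quaternary epochs, and regressions of genetic diversity on
environmental variance. Every stage can be exercised on synthetic data with
closed-form ground truth, and the three polymorphic populations of the
motivating study design are recoverable exactly from their printed summary
rows.

## Sequence handling and haplotypes

Chloroplast regions are aligned upstream; the package concatenates them,
recodes each insertion/deletion event as a single binary character, and
collapses identical coded sequences into haplotypes. One "indel event" is a
maximal run of gap-containing columns sharing one presence/absence pattern
across sequences: this single-event treatment keeps a multi-base indel from
counting as several mutations, while leaving the coding scheme (which no
standard is prescribed for) as simple as possible. Indel characters
participate in haplotype identity — so the haplotype count with indels can
exceed the count without — but are excluded from the nucleotide statistics
S, pi, theta and D. Columns containing `N` are treated as ambiguous and
excluded from segregating-site and distance computations (conservative).
Positions are 0-based and intervals half-open internally; ids are matched
case-sensitively.

## Diversity statistics

For a population of n sequences with haplotype counts c_i and L sites:

- Hd = n/(n-1) · (1 − Σ (c_i/n)²)  (Nei's unbiased gene diversity)
- pi = mean pairwise nucleotide differences / L
- theta_W = S / (a1 · L), a1 = Σ_{i<n} 1/i
- Tajima's D = (k̂ − S/a1) / sqrt(e1·S + e2·S(S−1)) with the standard
  variance constants a1, a2, b1, b2, c1, c2, e1, e2 as functions of n.

D is reported as 0 (not missing) when S = 0, matching the convention of the
programs that produce such summary tables. Printed-value comparisons use a
tolerance of ±0.0002 on D because those programs truncate rather than round
(a recomputed −1.14916 prints as −1.1491).

**Configuration inversion.** `derive_configuration` enumerates integer
partitions of n into h positive haplotype counts, labeled tree topologies
on the h haplotypes (Prüfer enumeration, h ≤ 6), and assignments of the S
segregating sites to tree edges, keeping every configuration whose Hd and
pi round to the printed values. For the three polymorphic populations of
the motivating design the match is unique — (16,2,1,1) on a star with site
splits {2,1,1}; (16,4) with two sites on the single edge; (12,1) with one
singleton site — which is what makes the printed rows exactly reproducible
from scratch: the recovered configuration is turned into sequences and
pushed through the ordinary pipeline.

## AMOVA, GST/NST, SAMOVA, Mantel

AMOVA partitions squared pairwise haplotype distances (character
differences, with coded indels as a fifth state). For populations k with
sizes n_k, SSD(total) = Σ_{i<j} d²_ij / N and SSD(within) sums the
analogous per-population terms; mean squares against df P−1 and N−P give
σ²_within = MS_w and σ²_among = (MS_a − MS_w)/n′ with
n′ = (N − Σ n_k²/N)/(P−1). The two-level design adds the among-group
stratum with the standard unequal-size coefficients. Negative variance
components are reported as computed and flagged, never clamped: truncation
would silently distort Φ statistics. Significance is by permutation:
individuals among populations for Φ_ST; whole populations among groups for
F_CT; individuals among populations within groups for F_SC.

GST and NST follow the ordered/unordered estimator pair with small-sample
corrections: within-population diversity v_k = n_k/(n_k−1) Σ π_ij p_ki p_kj,
v_S the unweighted population mean, and v_T = Σ π_ij p̄_i p̄_j + v_S/(ñP)
with ñ the harmonic mean sample size — with π_ij = 1(i≠j) this reduces
exactly to the unordered gene-diversity case, so one routine serves both.
The N_ST > G_ST test permutes haplotype identities on the distance matrix
(1,000 permutations by default), which leaves G_ST fixed and asks whether
related haplotypes co-occur within populations more than chance allows.
Because the estimators are unbiased rather than plug-in, identical observed
compositions leave a small O(1/n) remainder around zero instead of exactly
zero.

SAMOVA searches partitions of populations into K groups, each contiguous on
the Delaunay triangulation of the population coordinates, maximizing F_CT.
The search is simulated annealing with boundary moves (move one population
to an adjacent group when both groups stay connected and non-empty),
geometric cooling at 0.95, 50·P proposals per temperature, the initial
temperature calibrated so a typical worsening move is accepted with
probability ½, and independent restarts (100 by default) under one seeded
stream — so the best F_CT is non-decreasing in the number of restarts and
runs are reproducible. K is capped at P−1; at K = P the design degenerates
(no within-group stratum). The annealing schedule length (40 temperature
steps with a stall cutoff) keeps a full 100-restart search on eight
populations under a minute while saturating the tiny contiguous-partition
space many times over.

The Mantel test correlates off-diagonal entries of the genetic and
geographic (haversine, Earth radius 6371 km) distance matrices, with a
one-sided permutation p-value over row/column permutations. A constant
matrix leaves r undefined and yields a flagged result rather than a number.

## Statistical-parsimony network

The network joins haplotype pairs in increasing mutational distance while
the parsimony probability of that distance stays at or above the 95%
connection limit, inserting distance−1 unsampled intermediates per new
path; all equally parsimonious alternative connections at a level are
retained, so loops can appear. The connection probability is derived under
an explicit finite-sites Jukes–Cantor model: with per-site expected hit
count t estimated by JC inversion of the observed difference fraction j/L,

    P_j = (t·e^{−t} / p_diff)^j · (e^{−t} / (1 − p_diff))^{L−j},
    p_diff = ¾(1 − e^{−4t/3}),

the conditional probability that each differing site was hit exactly once
and no identical site hides changes, given the observed pattern. P_0 = 1,
P_j is non-increasing, and for L = 2,188 the 95% limit is 14 steps — wide
enough to cover a seven-intermediate connection. The computed P_j sequence
is exposed on the model for audit. Because figure captions and methods
sections often disagree about whether such networks are TCS-style or
minimum-spanning, both builders are provided (the MSN keeps all tied
spanning edges and infers no intermediates); neither is privileged.

## Suitability trajectories and range change

One suitability surface per epoch (LIG, LGM, MH, PRE; values in [0,1];
ESRI ASCII grids sharing one WGS84 geometry). Per population, 100
replicate localities are drawn uniformly from a square buffer of side
0.08° centered on the sampling coordinate — the stated ~10 km² buffer and
the stated 0.08° figure are mutually inconsistent (a 0.08° square at this
latitude is ~79 km²), so the precise 0.08° figure is adopted and the width
is configurable. Extraction is nearest-cell (floor convention at cell
boundaries, no interpolation); nodata cells are dropped with a report.

Each epoch's replicate sample is summarized by the half-sample mode:
recursively keep the contiguous ⌈k/2⌉-point window of the sorted sample
with minimal range (ties toward the lower index) until ≤2 points remain,
then average. The HSM is affine-equivariant and robust to secondary mass,
which is why it is preferred over the mean for skewed suitability samples.

Suitable range area per epoch counts cells with suitability ≥ a threshold,
weighted by cos(latitude), and is reported as a percentage of the present-
day area. No threshold is stated for the published expansion/contraction
percentages, so 0.5 is the default, the value is configurable, and those
percentages are treated as non-reproducible.

## Environmental variance and diversity

Environmental conditions (19 bioclim-style layers plus elevation) are
extracted at the jittered replicates and decorrelated by a standardized
(correlation-matrix) PCA — the variables mix °C, mm and m, so unit-variance
scaling is the only defensible choice when none is stated. Components are
ordered by variance with signs fixed so the largest-magnitude loading is
positive. Within-group variances of the first two component scores (ddof 1)
are the predictors in unweighted OLS regressions of group-level genetic
diversity, with two-sided t-tests on the slope; sample-size control
regressions are attached when group sizes are supplied. Whether the rows
of such a PCA are populations or jitter replicates is ambiguous in
published descriptions; both are supported, with replicates as the default
(group variances then need no minimum population count per group).

## Synthetic data: what it emulates and what it does not

The generator builds alignments from an explicit haplotype graph — a random
A/C/G/T backbone with single-base substitutions at distinct columns per
edge — so S, h, Hd, pi, pairwise-difference totals and D are all computable
in closed form before any sequence exists, and brute-force column scans
verify the generated data against that truth. Indel fixtures use
single-column gap characters. The eight-population study fixture places the
printed sample sizes and the three recovered polymorphic configurations on
one global star-shaped graph whose central haplotype is shared by the three
northern populations (the per-individual assignments behind the published
totals are not machine-readable, so total-sample statistics are emulated,
not reproduced; the fixture's totals differ from the printed totals by
design and are never asserted).

Suitability surfaces are partition-of-unity Gaussian interpolations of
per-locality target values plus smoothed bounded noise (default amplitude
0.02), clipped to [0,1]. Environmental layers are affine transforms of one
smooth scalar gradient field whose per-locality values carry planted
within-group variances; the first layer is the gradient itself, and group
diversity values are drawn around `intercept + slope · E[var(PC1 score)]`
with the expectation computed from the generator's own realized draws, so
an OLS fit downstream recovers the planted slope in expectation. The
planted structure is exact only for localities separated by clearly more
than the interpolation kernel width (0.02° default); closely spaced
localities blend. None of this emulates real climate-layer covariance
structure, spatial autocorrelation at landscape scale, or niche-model
fitting error — passing tests show the post-processing chain is correct,
not that any particular species' projections are.

Problem sizes throughout the test-suite simulations (500-replicate
permutation-calibration nulls, 200-dataset slope recovery, 100 annealing
restarts, 128-sequence fixtures) were chosen as the smallest designs whose
Monte-Carlo error is comfortably below the tolerances being asserted.

## Degenerate inputs and tie-breaks

Monomorphic datasets skip the structure stages with a warning rather than
failing. Haplotype labels are assigned by decreasing total count with ties
broken by first occurrence. HSM window ties break toward the lower index.
Co-located populations are rejected by SAMOVA (the Delaunay graph is
degenerate); collinear coordinate sets are joggled. Permutation p-values
use the (count + 1)/(n_perm + 1) convention, so they are never zero.

## Known limitations

- No coalescent significance for Tajima's D (the beta-distribution
  approximation is deliberately not bundled; permutation machinery covers
  the structure statistics instead).
- Raster I/O is ESRI ASCII grid only; no GeoTIFF, no projections other
  than geographic WGS84, no resampling.
- The AMOVA permutation engine recomputes components per permutation;
  it is sized for hundreds of individuals, not tens of thousands.
- The statistical-parsimony probability is a model-based derivation (see
  above), not a transcription of any particular program's constants; its
  limits agree with published networks at the hundreds-to-thousands-of-
  sites scale but exact step counts may differ from legacy software by
  ±1 near the threshold.
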