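# Methods

This note records the models, conventions and design choices behind
`planktraits`, in the order the pipeline runs them.

## Trait coding

Four categorical traits with a fixed catalogue of 17 modalities (4
body-length + 4 feeding + 5 trophic + 4 reproductive) are one-hot encoded
into the species × trait matrix; every row sums to 4 overall and to 1
within each trait block, and the encoder refuses anything else.
Body-length class boundaries are half-open and lower-inclusive —
[0,1) small, [1,2) medium, [2,5) large, [5,∞) giant mm — because the
conventional class labels ("<1 mm", "1–2 mm", …) leave boundary
membership ambiguous; 1.0 mm is medium, 2.0 mm is large, 5.0 mm is giant.
Planktonic larvae are carried in abundance tables but excluded from trait
analysis by an explicit exclusion list, never by a name heuristic: trait
catalogues describe mature stages only.

## Gower dissimilarity

Two algebraically equivalent modes are provided. `binary_columns` is the
mean absolute difference over the 17 one-hot columns; `categorical_traits`
is the fraction of the four traits whose modalities differ. A mismatching
trait flips exactly two binary columns, so d_bin = (8/17)·d_cat on every
one-hot input (asserted as a property test), and both modes produce the
same clustering.

## Ward clustering

Agglomeration uses the Lance–Williams recurrence with Ward coefficients on
*squared* dissimilarities (the Ward.D2 convention, the common default of
hierarchical-clustering toolkits); merge heights are the square roots of
the merged values. The classic unsquared variant (Ward.D) is available
behind `squared=False`. Gower dissimilarities are not Euclidean in
general; Ward is applied to them as a dispersion criterion, which is the
established practice for trait matrices.

Two numerical choices matter:

* **Tie-breaking.** When several pairs share the minimal merge cost, the
  pair with the smallest (row, column) node-id pair merges first. Costs
  within a relative 1e-9 of the minimum are treated as exact ties;
  without that tolerance, genuinely tied rational costs (Gower values are
  multiples of 1/4 or 1/17) would be ordered by floating-point noise and
  the two Gower modes could yield different trees.
* **Correctness oracle.** The implementation is tested against an
  exhaustive agglomerator that recomputes the Ward cost from scratch at
  every step (ΔSS with SS(C) = (1/|C|) Σ_{i<j} d²; the Lance–Williams
  value equals 2·ΔSS, heights √(2·ΔSS)), and against
  scipy.cluster.hierarchy on metric data.

## Elbow selection of k

W(k) is the total within-cluster dispersion Σ_C (1/(2|C|)) Σ_{i,j∈C} d²
of the k-cluster cut, evaluated for k = 2..k_max (default
k_max = min(n−1, 15)). The named "elbow" is operationalized as the k
maximizing the second difference W(k−1) − 2W(k) + W(k+1) over interior
points, ties to the smallest k. The full curve is always returned and the
pipeline accepts `k_override`, because curvature maxima on real trait
matrices are often shallow and practitioners routinely pick k by
inspection of the dendrogram.

Cut partitions are relabelled 1..k by decreasing group size (ties by
first-species order), so outputs are deterministic.

## Dominance, composition, tests

The dominance index of species i in one season is Y = (nᵢ/N)·fᵢ with
nᵢ/N the species' share of abundance summed over the season's stations
and fᵢ the fraction of those stations with abundance > 0 (presence means
strictly positive standardized abundance; no detection-limit threshold).
Y ≥ 0.02 is dominant, threshold inclusive. These are the standard
regional conventions; published dominance tables in this literature are
sometimes not exactly reproducible from their own abundance columns under
any convention, so when screening a published table the printed Y values
are used as given rather than recomputed.

Composition shares sum abundance per grouping key (taxon group, trait
modality via the one-hot matrix, or functional group) and divide by the
summed abundance of all mapped species, per season or station; excluded
species leave both numerator and denominator. Trait-modality shares
attribute each species' full abundance to exactly one modality per trait.

Seasonal differences use one-way fixed-effects ANOVA on untransformed
abundances (scipy.stats.f_oneway behind the package surface) and the
two-sided Wilcoxon rank-sum test. The rank-sum p value comes from exact
enumeration of all C(n, n_x) rank splits whenever n_x + n_y ≤ 12 —
midranks make the enumeration well defined under ties — and otherwise
from the normal approximation with tie and continuity corrections
(scipy.stats.mannwhitneyu). At n_x = n_y = 6 the two routes agree within
0.05, which the calibration tests verify.

## Redundancy analysis

The response (station × group abundances) is ln(x+1)-transformed and
column-centered; predictors are column-standardized. With X the design
and Y the transformed response, Ŷ = X(XᵀX)⁻¹XᵀY; the constrained axes are
the SVD of Ŷ, residual axes the SVD of Y − Ŷ, eigenvalues S²/(n−1), and

    explained_fraction = trace(ŶᵀŶ) / trace(YᵀY).

The natural log is used for log(x+1): changing the base rescales every
response column by the same constant, which cancels from the ratio after
centering (log_b(x+1) = ln(x+1)/ln b scales Y, Ŷ and the trace ratio's
numerator and denominator identically). Scores follow one fixed
convention: site scores U·S (projections of fitted values), species
scores V·S/√(n−1) (covariance loadings), biplot scores the Pearson
correlation of each standardized predictor with each site-score axis.
Constant predictors are dropped with a warning; collinear predictors are
pruned by repeatedly dropping the later column of the most correlated
remaining pair until the design has full rank.

The permutation test permutes station rows of the response and recomputes
the explained fraction; p = (1 + #{perm ≥ observed})/(1 + n_perm). Row
permutation commutes with column centering, so the statistic reduces to
the squared norm of the projection of the permuted centered response onto
a QR basis of the predictor space — exact and fast. Type-I error at
nominal 0.05 is verified to lie in [0.01, 0.10] over 200 null simulations
(20 stations × 8 groups × 6 predictors, 199 permutations each), the
problem size chosen to mirror the pooled survey design.

## Synthetic cruises

The generator emulates the study conditions: 11/16/16 stations in
spring/summer/autumn; a 98-species pool whose trait profiles cycle
round-robin through the cartesian modality lists of the published
eight-group catalogue (sizes 30, 7, 29, 12, 9, 2, 3, 6), making the
fixture seed-free and byte-stable; seasonal environments drawn
Normal(mean, sd) per variable with the published seasonal means/sds
(SST 10.1/27.2/16.6 ± 1.4/0.8/0.8 °C and so on), Chl *a* truncated at 0.
Surface and bottom salinity means are not published (only the ordering
SSS > SBS each season); the defaults (≈30.5–31.6) are realistic shelf
values chosen once to respect that ordering.

Abundance is presence-thinned log-normal: species s of group g at
station i is present with probability occupancy(g, season) and, if
present, has abundance max(exp(μ_g + Σ_v β_gv·z_iv + ε) − 1, 0) with z
the standardized environment and ε ~ Normal(0, 0.6). The coupling signs
transcribe the reported group–environment associations (e.g. the
omnivore–herbivore group positive on SST and surface Chl *a*, the
detritivore group positive on SST and SBT); magnitudes default to 0.8 —
strong couplings, sized for planted-recovery testing. Baselines μ are
calibrated once so the omnivore–herbivore group holds >60 % of total
abundance in expectation, as in the field data; occupancies peak in
summer for the gelatinous, detritivore and cladoceran groups and in
autumn for the ambush omnivore–carnivore group, mirroring the reported
seasonal richness pattern.

The generator deliberately omits spatial autocorrelation between
stations, water-mass structure, larval dynamics and ontogeny. Passing
recovery tests therefore show that the pipeline's statistics are
consistent and well calibrated under the assumed generative structure —
not that field data satisfy that structure.

## Known limitations

* The round-robin fixture spreads within-group trait profiles over the
  *entire* cartesian modality list of each group, which maximizes
  within-group dispersion: some species are closer to members of other
  groups than to their own (e.g. each planted cladoceran sits at Gower
  distance 0.25 from omnivore–herbivore/omnivore–carnivore copepods but
  up to 0.5 from its own partner). The planted eight-way partition is
  consequently not the dispersion-optimal eight-cluster structure of
  this fixture, and no Ward-criterion agglomeration can return it
  exactly: the acceptance checks report the Ward cut's adjusted Rand
  index against the planted partition (≈0.7) and the elbow's curvature
  maximum (k = 5) honestly. Real species × trait tables concentrate on
  far fewer profile combinations per group, which is why the published
  workflow resolves eight groups on field data.
* Gower + Ward is used as a dispersion heuristic on non-Euclidean
  dissimilarities; no embedding correction (e.g. square-root transform)
  is applied.
* Published dominance indices are screened as printed; the package never
  claims to reproduce them from the printed abundance columns (they are
  not mutually consistent under any share/frequency convention).
* The permutation test permutes rows freely; with strong seasonal
  structure a restricted (within-season) permutation scheme would be
  more conservative and is not implemented.
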