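# Methods

This note records the model, the parameter choices and the numerical
conventions behind `kna`, and what the synthetic validation does and does
not establish about real data.

## Neighbourhood description

Each localisation *i* of a 2D point pattern is described by the distances
to its first K nearest neighbours, self excluded, sorted ascending.  The
tree search (`scipy.spatial.cKDTree`) is bit-identical to an all-pairs
brute-force computation (asserted in the tests up to N = 1000); ties in
distance are irrelevant because only the distance values are retained.
Coincident duplicate localisations — common in real SMLM exports — yield
zero distances; they are kept and flagged rather than rejected, and any
row whose K-th distance is zero is marked invalid and excluded from every
downstream statistic, with counts reported.

Dividing a row by its own K-th entry makes the profile scale-free: the
result depends only on the *shape* of the neighbourhood, not on
magnification or density.  For a homogeneous Poisson process
E[*D*<sub>*ij*</sub>] = Γ(j+½)/(Γ(j)√(πλ)) ≈ √(j/(πλ)), so the expected
normalised profile is ≈ √(j/K) (writing the CSR expectation as α√j, the
normalisation corresponds to α = 1/√K).  The local density estimator
Den = (K/2)/(π·D̄²) with D̄ the row-mean distance is deliberately simple;
on CSR data E[D̄] ≈ (2/3)√(K/(πλ)) makes it overshoot the true intensity
by the factor 9/8, a bias that is constant across images analysed at the
same K and therefore harmless for comparisons.  Density enters all
downstream analyses as log₁₀Den.

**Choice of K.**  Default K = 100, exposed everywhere as a parameter.  K
must exceed the number of localisations produced by one blinking
molecule, or a molecule's own blink cloud saturates the profile; beyond
that the analysis is robust over a broad range of K, and long-range
structure can be probed separately via single k-th NN distances
(`kth_nn_distances`, e.g. k = 200 or 500).

## The universal basis (SNPCA)

A PCA basis fitted per image would change from image to image and defeat
comparison, so the basis is fitted once, on normalised profiles of a
Poisson process with intensity λ = 10⁵ on the unit square at K = 100.
Points whose distance to the window boundary is smaller than their own
K-th NN distance are discarded before fitting — the minimal condition for
an untruncated K-neighbourhood disk (≈7% of points at these parameters).
The PCA is computed on the covariance (not correlation) matrix of the
mean-centred profiles; no variance scaling, since the columns share
units.  Sign indeterminacy is removed by flipping each loading so its
largest-magnitude entry is positive; with this convention background
noise projects to higher SNPC1 than cluster localisations, and the
within-cluster SNPC1 gradient increases with distance from the cluster
centre.  The shipped basis (`kna/data/snpca_basis_k100.json`, schema
version 1, training seed recorded inside) is reproduced bit-for-bit by
`train_basis()` with default arguments; its first two components carry
≈72% of the CSR training variance (measured, and re-reported by the
acceptance script), and independently seeded trainings agree to
per-component correlation > 0.99.  Projections use (SNPC1, SNPC2) and the
polar form r = √(SNPC1²+SNPC2²), θ = atan2(SNPC2, SNPC1) ∈ (−π, π], with
θ defined as 0 at the origin.

**Edge handling for experimental images.**  Edge exclusion is essential
for the CSR *training* set but is optional (off by default) for analysed
images: near-boundary profiles are biased but often still informative,
and discarding them changes localisation counts.  `RunConfig.edge_filter`
enables the same rule when wanted.

## Synthetic data

The generator emulates an image of spatially random binding sites:
parents ~ Poisson(intensity 5) on a 10 × 10 window (arbitrary units);
per-parent localisation count uniform on the inclusive integers
[10, 90]; localisations i.i.d. bivariate normal around the parent with
per-axis variance 0.000625 (sd 0.025) and zero correlation; background
noise ~ Poisson(intensity 50).  Ground truth per localisation: noise
flag, parent id, distance to (nearest) parent D_B, the parent's distance
to its nearest other parent D_BNN, and the parent's count N_clus.
Separate random sub-streams drive parents, counts, offsets and noise, so
raising the noise intensity leaves the signal draw untouched.  Cluster
points falling outside the window are kept (no clipping); noise may fall
inside clusters, as a homogeneous overlay does.  Higher-noise scenarios
are the same generator with a larger noise intensity.

What the generator does *not* model: blinking kinetics and frame
structure, localisation-precision error, multi-emitter artefacts, drift.
Passing tests therefore establish that the statistics behave as designed
on idealised two-level patterns, not that any biological conclusion
transfers; on real data, batch effects mean comparisons are only valid
between images acquired under the same conditions.

## Grouping

All images are binned on one grid in (log₁₀Den, SNPC1, SNPC2), 50 bins
per axis by default, spanning the pooled range; bins are half-open with
the last bin closed, values at the maximum fall in the last bin, and the
flattened index i_den·n² + i_pc1·n + i_pc2 is part of the file format.
The 50-bin default matches the reference analysis of large experimental
images (10⁵–10⁶ localisations); the packaged desk-scale ensembles use
10–12 bins per axis, because with ~3·10⁴ localisations per image a 50³
grid leaves no bin occupied in every image.

Two grouping paths: a generic average-linkage hierarchical cut
(Euclidean metric on normalised bin profiles, both exposed as
parameters), and the nine-group scheme — k-means (k = 4, 50 restarts,
fixed seed) on the bins occupied in all images; the leftover bins form
one category split in two at the median bin-centre log₁₀Den (median
chosen, configurable; count-weighting optional); then every cluster
whose member bins place ≥ `split_min_frac` (default 0.10) of the
cluster's pooled localisations on each side of SNPC1 = 0 is split at
that boundary.  The split rule is a deterministic surrogate for a manual
"large extent in SNPC1" judgement; in the reference configuration three
of six clusters split, giving nine groups, but the code does not force
nine — the partition and its provenance (which clusters split) are
always reported.  k-means runs on normalised frequencies, not counts,
for image-size invariance.

## Ensemble statistics

Frequency rows are compositional, so comparisons use the centred
log-ratio: add a pseudocount of 0.5 to every cell when any cell is zero
(strict mode errors instead), close rows, log, row-centre, then
column-centre for PCA.  Between-component analysis is the
size-weighted PCA of condition-mean rows with all images projected onto
the resulting axes; because the image matrix is column-centred first,
scores are exactly mean-centred.  Correspondence analysis is provided as
an alternative ordination of the same table; the log-ratio route is
primary.

Both hypothesis tests are label permutations with the add-one p-value
(1 + #{null ≥ observed})/(1 + n_perm), default n_perm = 9999, seeded.
The dispersion test computes each image's Euclidean distance to its
condition centroid (the multivariate mean; the spatial median is an
option) and permutes those distances under a one-way F statistic — the
standard homogeneity-of-multivariate-dispersions construction.  The
mean-difference test uses the size-weighted between-condition sum of
squares Σ n_g‖m_g − m‖².  Calibration (type-I error 3–7% at α = 0.05,
power ≥ 80% at the packaged effect sizes) is verified by simulation in
the acceptance suite.

## Enrichment

A channel-A localisation is co-localised when any channel-B localisation
lies within the threshold (inclusive; default 10 nm, with a
10/20/30/500 nm ladder available — scores shrink to zero as the
threshold exceeds the pattern diameter).  Enrichment is log base 10, so
a doubled share scores 0.301.  Groups with zero co-localised members
receive a pseudocount of 0.5 on the co-localised count before closure
and are flagged (strict mode returns −∞ instead); unflagged infinities
would poison downstream tests.  The null draws
Multinomial(n_p, group frequencies), normalises, scores and reports
per-group 5th/95th percentiles; across an ensemble the per-group min/max
of the bands is also available.  Cross-condition comparison of per-image
enrichment vectors reuses the mean-difference permutation test.
Per-image frequency vectors are used throughout (not pooled across
images).

## Visualisation

θ maps bijectively onto hue, ((θ + offset) mod 2π)/2π, saturation and
value constant; the automatic offset places the circular-mean angle of
the densest decile of localisations at hue 0.75 (blue/violet), which
leaves background points in the yellow/green range.  Encoding r as
saturation is possible (`hue_to_rgb(saturation=...)`) but off by
default — it reads as visually confusing.  Renders are plain rasters
drawn point by point (PIL), byte-deterministic for fixed inputs.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeds;
  sub-streams come from `SeedSequence.spawn`.  Every seeded artefact
  (feature CSV, basis JSON, PNG) is bit-identical across reruns.
- Localisation CSVs round-trip coordinates exactly (`repr` on write,
  `float_precision="round_trip"` on read).  Window boundaries are closed;
  windows are never degenerate.
- Basis JSON and group-assignment JSON carry schema version fields.
- Problem sizes in the tests and acceptance script: CSR calibration at
  λ = 10⁵ (the training scale); the reference simulation ≈3·10⁴
  localisations; ensembles of 9 images on a 12³ grid; 500 simulations ×
  199 permutations for test calibration; 10⁴ multinomial null replicates.
  These sizes give Monte-Carlo error comfortably inside the asserted
  tolerances.

## Known limitations

Strictly 2D (no 3D neighbourhoods) and no periodic boundaries.  The
grouping is not a spatial clustering method: a discrete structure can
straddle groups by design.  The density estimator is biased (9/8 on CSR)
and is used as a comparable coordinate, not an intensity estimate.  CSV
and JSON are the only I/O formats; proprietary microscope formats, drift
correction and channel alignment are out of scope.
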