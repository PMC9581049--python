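# kna — K-neighbourhood analysis of SMLM point patterns

Single-molecule localisation microscopy (SMLM) produces point sets, not
pixel images: every detected fluorophore is a localisation with sub-pixel
coordinates.  Receptors at a cell surface form nanoclusters, microclusters
and dispersed background all at once, so no single clustering bandwidth or
density threshold describes the image.  `kna` describes each localisation
by its **K-neighbourhood** — the vector of distances to its first K
nearest neighbours — and turns whole images, and ensembles of images,
into comparable statistical objects.  It is written for microscopists and
image analysts working with 2D localisation tables (ThunderSTORM-style
CSV and similar).

## The method

For localisation *i*, let *D*<sub>*ij*</sub> be the distance to its
*j*-th nearest neighbour (self excluded) and
**NNV**<sub>*i*</sub> = (*D*<sub>*i*1</sub>, …, *D*<sub>*iK*</sub>),
with K = 100 by default.  Dividing by the last entry gives the scale-free
profile **nNNV**<sub>*i*</sub> = **NNV**<sub>*i*</sub>/*D*<sub>*iK*</sub> ∈ (0, 1]<sup>K</sup>.
Under complete spatial randomness (CSR) E[*D*<sub>*ij*</sub>] ∝ √*j*, so
the CSR profile is √(*j*/K); clustering and segregation bend the profile
away from it in characteristic ways.

A PCA basis is fitted **once** on the profiles of a Poisson process
(λ = 10⁵ on the unit square, edge points discarded) and shipped with the
package, so every image is projected into the same
(SNPC1, SNPC2) plane — the *spatial-neighbourhood PCA*.  In polar form,
the radius *r* measures departure from randomness and the angle *θ* the
kind of departure; the local density
Den<sub>*i*</sub> = (K/2)/(π·D̄<sub>*i*</sub>²) adds the scale back.

Downstream, per-localisation (log₁₀Den, SNPC1, SNPC2) triples are binned
on a 50×50×50 grid common to all images; each image becomes a row of a
compositional frequency table.  Bins are merged into colour-key groups
(k-means k = 4 on bins occupied everywhere, leftover bins split by
density, clusters straddling SNPC1 = 0 split at the boundary — nine
groups in the reference configuration).  Ensembles are compared with
centred-log-ratio PCA, between-component analysis and permutation tests
for multivariate means and dispersions, and two-channel images are scored
with a per-group co-localisation enrichment,
Enrichment(*k*) = log₁₀[Freq(*k* ∧ co-localised)/Freq(*k*)], calibrated
against a multinomial null.

## Worked example

Project a simulated pattern (≈500 clusters of 10–90 localisations plus
Poisson background) onto the shipped universal basis
(`examples/03_project_onto_basis.py`):

```
basis: K=100, first two components carry 71.8% of CSR training variance
localisations analysed: 31108 (4940 noise)
Spearman rho(r, D_BNN) over signal:  0.545  (isolation is radial)
KS(theta | signal vs noise):         0.592  (noise is angular)
mean SNPC1 signal vs noise:          -2.19 vs 0.72
```

Reading the numbers: the radius *r* correlates with the ground-truth
isolation of each localisation's cluster (*D*<sub>BNN</sub>, the parent
molecule's distance to its nearest neighbouring molecule), background
noise occupies a distinct angular sector (Kolmogorov–Smirnov statistic
0.59 between the θ distributions), and noise sits at higher SNPC1 than
cluster localisations — the three trends that make the coordinate system
interpretable.  `examples/04_group_ensemble.py` continues to the grouped
frequency table and `examples/06_enrichment.py` to the two-channel
enrichment score (a group holding twice its expected share of
co-localised points scores log₁₀2 ≈ 0.301).

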