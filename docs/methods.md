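# Methods

This note documents the models, conventions and numerical choices behind
`nucpipe`, what the synthetic-data generator does and does not emulate, and
the known limitations of each estimator.

## Coordinate and metadata conventions

All grids are indexed (z, y, x); all physical lengths are micrometres.
Voxel size is a mandatory 3-vector (z pitch typically coarsest, as in
confocal stacks) and is carried on every container — it is never inferred
from file metadata unless the caller explicitly trusts a sidecar, and a
missing voxel size is an error rather than a silent 1 µm assumption.
Positions refer to voxel centres: grid index *i* maps to `(i + 0.5) ·
pitch`. Centroids are unweighted means of voxel-centre positions. 2D images
are handled throughout as single-slice 3D grids.

## Per-nucleus quantification

Marker expression of a segmented nucleus is the arithmetic mean voxel
intensity of the channel over the label's voxels; volume is voxel count ×
voxel volume. Nuclei with any voxel on the grid boundary are flagged
(`touches_border`) but never dropped by the quantifier itself; the analysis
configuration's `border_policy` ("include" by default, "exclude" optional)
decides downstream. No exclusion rule is hard-wired because clipped nuclei
bias intensity and geometry differently and the right choice depends on the
question.

Boundary voxels — the mask's proxy for the nuclear membrane — are voxels of
a label with at least one face-adjacent (6-connected) neighbour of a
different value; the outside of the grid counts as "different", so every
label has at least one boundary voxel. Membership is purely topological and
ignores anisotropy; all *distances* computed from boundary voxels use
physically scaled coordinates.

## Neighbour graphs and edge distances

**Adjacency.** Nearest neighbours are all Delaunay-adjacent nuclei — every
pair sharing a simplex in the triangulation of the image's centroids — not
a k-nearest rule. Single-slice data is triangulated in 2D (axes with zero
spread are dropped); up to dim+1 points are mutually adjacent; collinear
points form a chain.

**Degeneracy.** Co-circular/co-spherical centroid sets make Delaunay
adjacency ill-defined. Before triangulation every point is displaced by a
deterministic jitter of magnitude 1e−6 × the bounding-box diagonal, drawn
from a stream seeded by the point's *index* only. Adjacency is therefore
reproducible across runs, platforms and subset sizes, which we value above
any particular resolution of exact ties. The jittered points are exposed
(`jittered_points`) so correctness oracles test exactly what was
triangulated.

**Edge distance.** For an adjacent pair, the minimum over boundary-voxel
pairs of the anisotropy-scaled Euclidean distance between voxel centres.
Integer index differences are taken before scaling, so the computation is
bit-identical to a naive per-pair scan and exactly symmetric. Because voxel
*centres* are compared, face-touching labels report one voxel pitch rather
than zero and all values carry a half-pitch-scale positive bias relative to
true surface distance; tests allow one voxel pitch where geometry is
asserted. No sub-voxel surface model is attempted.

**Retention radius.** Pairs are kept when their *centroid* distance is
within `radius_um` (default 40 µm) — the capture circle is drawn around the
nucleus centre. Applying the cutoff to edge distance instead is a
configuration change away (filter the edge table), but centroid distance is
the package's definition.

**Summaries.** Each unordered pair contributes once; the per-replicate mean
pools all images of the replicate. An optional seeded subsample without
replacement fixes the number of distances entering the density estimate so
curves are comparable at matched n across samples. Densities are Gaussian
KDEs (Silverman bandwidth) evaluated on an explicit 512-point grid spanning
the data ± 3 bandwidths and renormalised to unit trapezoid area; a summary
with zero edges reports an undefined mean explicitly (NaN + flag), never a
silent zero.

## Threshold calls, co-expression and the overlap estimator

Threshold calls use one user-supplied scalar per biological replicate,
constant across that replicate's images; equality at the threshold is
negative. No automatic threshold selection (Otsu, mixture fitting) is
offered — thresholds are empirical inputs, and pretending otherwise would
overstate what the method does. Co-expression tables restrict to a
conditioning state (e.g. Oct4⁺) and tabulate joint target states with
counts and percentages that sum to the conditioned subpopulation.

The density-overlap estimator compares a sample against a negative-control
population: both are KDE-estimated on one shared grid (pooled span ± 3× the
larger bandwidth, 512 points), each curve renormalised to unit area, and

    positive fraction (%) = 100 · (1 − OVL),  OVL = ∫ min(f̂_s, f̂_c).

Numerically the non-overlap is computed as half the integrated absolute
difference of the curves — identical for unit-area curves and exactly zero
for identical inputs. Two behaviours are documented rather than corrected:

* The non-overlap convention counts *all* non-shared mass, including mass
  where the control exceeds the sample, so a sample that is a mixture
  (1−π)·control + π·positive converges to 100π only when the positive
  component is well separated; at moderate separation the estimate sits
  between the component overlap and the mixing fraction.
* With a single Silverman bandwidth per sample the estimator is *not*
  consistent as the separation grows without bound at fixed n: the pooled
  SD (and hence the bandwidth) grows with the separation and over-smooths
  both components. The mixture-recovery validation therefore runs at a
  separation of 6 negative-component SDs — component overlap Φ(−3) ≈ 0.1%,
  bandwidth still sane — where the estimator recovers π ∈ {0.25, 0.5, 0.75}
  within 2 percentage points at n = 10⁵.

## RPPA quantification

Per antibody × sample: median over technical spots within each dilution
step; ordinary least squares through log2(median) vs log2(dilution factor)
(a doubling series is linear in log space); RFI is the back-transformed
intercept at factor 1. "Median RFI" is read as median-across-spots-then-fit;
the alternative (median of per-spot fits) changes nothing for symmetric
noise and is not implemented. Slope and r² are diagnostics: an ideal series
has slope −1, and r² < 0.2 flags a non-dilutional series without failing
the run (a constant series fits with slope 0 and r² defined as 0, hence
flagged). Steps with non-positive medians are dropped before the log fit;
fewer than two usable steps is an error. No background subtraction is
modelled, so the companion simulator applies multiplicative noise only.

Loading correction divides each sample's RFI by the same sample's
total-protein RFI (e.g. a Fast Green slide); a missing or zero total is an
error. Enrichment is the per-replicate ratio of loading-corrected RFIs of
an experimental line over its matched control line (matched genetic
background), averaged over biological replicates; log2 values feed the
antibody × line heat-map matrix. The chain is scale-equivariant: a global
rescaling of all spot intensities cancels from every enrichment.

At the simulator's 5% multiplicative spot noise, the fitted RFI is
essentially unbiased (signed relative bias ≈ 0.1% over 100 series) while
the per-series absolute relative error averages ≈ 2%; the intercept sits at
the end of the dilution range, which is what limits per-series precision.

## Statistics

Replicate values (one per biological replicate) are compared by Student's
t-test: paired when the design pairs replicates, otherwise the
pooled-variance two-sample form; Welch's correction is available behind a
flag but is not the default. Zero-variance inputs return explicit
degenerate results (t = 0, p = 1 for no difference; infinite t, p = 0 for a
constant nonzero difference) instead of NaN. Stars follow 0.05/0.01/0.001.
No multiple-testing correction is applied anywhere — enrichment tables and
comparison tables report raw p-values, and users running many antibodies
should correct externally.

For the synthetic cohesion experiment (compact vs dispersed hard-core
scenes with independently seeded replicates) the unpaired form is the
correct model: there is no pairing structure between conditions, and a
paired test would spend degrees of freedom (df = 2 at n = 3) for no
variance reduction.

## The synthetic generator: what it does and does not show

Scenes emulate exactly the statistical structure the estimators assume:
ellipsoidal nuclei (per-axis semi-axes with uniform jitter) rasterised into
anisotropic voxel grids, voxels in overlapping ellipsoids resolved to the
nearest scaled centre so the mask is always a valid partition; hard-core or
Thomas-cluster placement; per-nucleus true intensities from a
negative/positive Gaussian mixture (clipped at 0) plus i.i.d. additive
voxel noise, background carrying noise only. One seed per scene drives
independent, deterministically derived substreams for placement, shapes,
class assignment and per-channel noise, so any stage can be regenerated
bit-identically.

Deliberately absent: point-spread functions, depth attenuation,
chromatic/registration error, segmentation error (masks are perfect by
construction), irregular nuclear shapes, and spatial intensity
correlations. Passing tests therefore demonstrate correctness of the
*computations* given a segmentation — recovery of painted means at CLT
precision, of mixture fractions, of imposed enrichments, of spatial
ordering between packing regimes. They do not certify robustness to
segmentation failures or optical artefacts in real stacks, which enter
upstream of this package.

Default study conditions used by the validation experiments, chosen once to
resemble confocal practice: 30 × 300 × 300 µm domains at (2, 1, 1) µm
voxels; 300 nuclei of 2.5 µm semi-axes for the cohesion contrast (hard-core
6 µm vs 14 µm, three replicate seeds per condition); 500 nuclei of 3 µm
semi-axes with a 40%-positive marker (negative N(100, 10²), positive
N(300, 20²), voxel noise SD 20) for intensity-recovery checks. Hard-core
feasibility is bounded: rejection sampling gives up with an explicit error
naming the attempted density rather than looping forever (the 14 µm
condition sits at ≈ 0.16 packing fraction, well inside the random
sequential adsorption regime).

## Numerical details and edge cases

* KDE grids: 512 points; curves renormalised so unit area holds to 1e−6
  by construction; degenerate (constant) inputs raise with a pointer to
  threshold-based calling.
* Dilution fits use `numpy.polyfit` on ≤ 4 points; r² is clipped to [0, 1].
* Edge-distance broadcasting is chunked (≈ 4 × 10⁶ pair entries per block)
  so large boundary sets stay within memory without changing results.
* Empty masks quantify to an empty record list; graphs with fewer than two
  nuclei have zero edges (logged, not fatal); an absent label, identical
  labels, or an unpaired RPPA replicate raise informative errors.
* The pipeline runner hashes every output (sha256) into a manifest and
  skips stages whose outputs are current for an identical config; rerunning
  with the same config reproduces identical hashes for every stage.

## Limitations

Edge distances inherit mask resolution (one-voxel quantisation and the
voxel-centre bias above). Delaunay adjacency near image borders connects
nuclei across empty space because no alpha-shape or border correction is
applied; the 40 µm radius bounds but does not remove this. The overlap
estimator's bandwidth caveat above applies whenever sample and control
differ grossly in spread. RPPA fits assume log-linearity across the whole
dilution range — saturation or background floor would need masking steps,
which the flag (r²) surfaces but does not automate.
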