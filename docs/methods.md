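# Methods

## The problem

Human-brain parcellations ("atlases") are integer-labeled 3-D images: voxel
value 0 is background, values 1..n index regions of interest (ROIs). Atlases
from different sources come at different resolutions with different sidecar
conventions, which makes them hard to use interchangeably and hard to compare.
`parcstd` implements one standardization contract — a label-volume convention,
a JSON metadata sidecar, and a file-naming scheme — plus the two similarity
statistics used to relate parcellations that share a grid: per-region Dice
coefficient maps and the adjusted mutual information (AMI) with an exact
expected-MI term.

## Label volumes and contingency tables

A `Parcellation` holds an `int64` label array and a 4x4 voxel-to-world affine;
voxel sizes are defined as the affine's column norms, so they can never drift
out of sync with the transform. On disk, volumes are gzipped NIfTI with the
smallest unsigned integer dtype that fits the maximum label; float-stored
volumes are accepted only when every value is within 1e-6 of an integer —
anything else indicates interpolated (and therefore corrupted) labels.

Every pairwise statistic is a function of the joint contingency table: cell
counts `h_ij` of voxels labeled `i` in atlas A and `j` in atlas B, with
marginals `a_i`, `b_j` and total `N`. Building the table requires the two
volumes to share one grid (shape equal, affines within 1e-4): comparing
atlases at different resolutions is an explicit resampling step, never an
implicit one.

**Comparison domain.** Which voxels enter the table is a real modeling choice:

* `all` — every grid voxel, background included;
* `union_foreground` (default) — voxels non-background in at least one atlas.
  Label 0 then appears as an ordinary region wherever one atlas covers tissue
  the other calls background; this keeps the two labelings exhaustive
  partitions of the same `N` voxels, which the expected-MI model assumes, and
  makes coverage differences visible as a nonzero background row in the Dice
  map;
* `intersection_foreground` — voxels non-background in both.

With `include_background=False`, voxels that are background in either atlas
are dropped from the domain entirely (shrinking `N`) rather than keeping
rows/columns whose marginals would no longer sum to `N`.

## Similarity statistics

**Dice map.** For each region pair, `CI_ij = 2 h_ij / (a_i + b_j)`, in
[0, 1], equal to 1 exactly when the two regions occupy identical voxel sets.
This is a region-level map, not a single score; it answers "which region of B
does region i of A correspond to".

**AMI.** Entropies `H(A) = -sum_i (a_i/N) ln(a_i/N)` and mutual information
`MI = sum_ij (h_ij/N) ln(N h_ij / (a_i b_j))` are computed in natural log
(nats). Raw MI between unrelated parcellations grows with region count, so it
is chance-corrected:

    AMI = (MI - E[MI]) / ( (H(A)+H(B))/2 - E[MI] )

with the arithmetic mean in the denominator (not the max variant used by some
implementations). `E[MI]` is the exact expectation of MI under uniformly
random permutation of one labeling with both marginal size vectors held
fixed: each cell count then follows a hypergeometric law, and the expectation
sums the MI contribution of each feasible `n_ij` weighted by its probability
over the support `max(1, a_i + b_j - N) .. min(a_i, b_j)` (the `n_ij = 0`
term contributes nothing, so starting at 1 is equivalent to the max(0, ..)
convention). AMI is invariant under relabeling of either side, is 1 for
identical partitions, and is ~0 for independent labelings. AMI itself is
base-invariant since it is a ratio of MI-scale quantities.

Numerical choices:

* factorial ratios are evaluated in log-gamma space;
* for large `N` the inner sum is restricted to a window around the
  hypergeometric mean `a_i b_j / N` outside which Hoeffding's inequality for
  sampling without replacement bounds the cell probability below 1e-40; the
  truncated mass is far below double-precision resolution, and on small
  instances the window covers the whole support, so tiny-N results are exact.
  This keeps `expected_mi` at N = 1e7 with ~100 regions per side around two
  seconds instead of minutes;
* degenerate denominator (|mean(H) - EMI| < 1e-12, e.g. both sides a single
  region): AMI is defined as 1.0 when the two labelings are identical as
  partitions (the contingency table is a scaled permutation matrix) and 0.0
  otherwise — the convention most implementations use; nothing else is
  well-defined there.

Two independent oracles guard the EMI implementation: `emi_exhaustive`
averages MI over all `N!` voxel permutations (feasible to N=8) and
`emi_monte_carlo` samples permutations at any size. Tests additionally
cross-check the full AMI against scikit-learn's arithmetic-mean AMI to 1e-6;
scikit-learn is never used in the implementation itself.

## Metadata sidecars

The JSON document has two blocks. `"rois"` maps each voxel value (stringified
integer key) to a record with keys `"label"` (the anatomical name, null for
algorithmically generated atlases), `"center"`, `"size"`, and optional
`"description"` and `"color"` ([R, G, B] in 0..255). `"metadata"` holds the
atlas-wide block: `name`, `description`, `native_space`, `source` are
mandatory; `region_count`, `average_region_volume`, `hierarchical`,
`symmetrical` optional. The schema is pinned as `METADATA_SCHEMA` (a
JSON-Schema-shaped document); the validator enforces exactly those
constraints in code. This exact rubric — key names included — is fixed by
this package as its own convention.

Design choices in this module:

* **Center frame.** Whether an ROI "center" is in voxel indices or world mm
  is genuinely underdetermined by common practice, so both are supported; the
  document records which was used (`center_frame`, default `voxel`, 0-based
  continuous indices) so validation is self-consistent. Nothing treats either
  frame as canonical.
* **Lost ROIs.** `(center is null) <=> (size is null) <=>` the region has no
  voxels at this resolution. Records are never deleted: a region that existed
  natively but vanished on downsampling stays cataloged with nulls.
* **region_count** counts records with non-null size (present regions), not
  catalog entries.
* **hierarchical** is user-supplied only; there is no operational definition
  that could compute it from a flat label volume.
* **symmetrical** is computed as support symmetry: the foreground mask,
  flipped about the first-axis grid midline, must reproduce >= 95% (default)
  of foreground voxels. Label identity is deliberately ignored — left/right
  homologues usually carry different labels.
* Validation reports violations rather than raising, so one pass lists every
  problem; size mismatches are exact, center mismatches allowed 0.5 voxel.
  Anatomical names containing spaces are warnings, not errors (the convention
  is largest-to-smallest structures joined by underscores).

Filenames follow `<atlas>_space-<space>_res-<dx>x<dy>x<dz>.nii.gz` (`.json`
for sidecars). The resolution token uses a plain `x` separator for
filesystem-safe names; atlas and space fields are single tokens without
underscores or spaces, since those are the convention's separators.

## Resampling and ROI loss

`resample_labels` performs nearest-neighbor resampling between voxel sizes:
the output grid spans the same world extent (`ceil(extent / target)` voxels
per axis), keeps the source origin and direction with rescaled spacing (so
the standard 1/2/4 mm grids nest), and each output voxel takes the label of
the source voxel whose center is nearest in world space, with exact halfway
ties rounded toward the lower index — a deterministic tie-break, stated
rather than left to a library's internals. Nearest-neighbor can never invent
a label, so the output label set is a subset of the input's; resampling to
the source resolution is the identity.

Downsampling can delete small regions entirely. Every call returns a
`ResampleReport` (per-label counts before/after, lost labels), and
`apply_lost_labels` pushes the losses into a metadata document as null
center/size. The probability of loss rises as region size falls; the test
suite checks the resulting ordering (mean lost size <= mean surviving size)
over many random atlases rather than any particular loss count, which depends
on geometry.

Registration to a template is out of scope: it is the province of dedicated
registration tools, and this package assumes its inputs already share a
space.

## Synthetic parcellations

The `synthetic` module generates the test universe: Voronoi tessellations of
an ellipsoidal "brain" mask. Seed voxels are drawn uniformly without
replacement from the mask; every mask voxel joins its nearest seed in world
distance (ties to the lowest seed index), so anisotropic voxels behave
correctly and every label is guaranteed present. `refine_parcellation`
re-tessellates each region independently (a strict refinement, emulating
atlas families built by one algorithm at several granularities),
`subregion_atlas` blanks all but a few regions (emulating limited-coverage
atlases of a single structure), and `permute_labels` relabels bijectively.
All generators use numpy's PCG64 (`default_rng`) and are bitwise-reproducible
under a fixed seed; that generator choice is part of the contract so seeds
stay portable.

What the synthetic data does and does not emulate: it reproduces exhaustive
partitions with controllable granularity, nested families, partial coverage
and region-size heterogeneity, which is what the similarity statistics and
the loss accounting are sensitive to. It has no cortical geometry, no
left/right anatomical correspondence, and no registration error, so passing
tests demonstrate correctness of the statistics and conventions — not any
claim about particular published atlases.

One subtlety the test suite documents: two *intact* Voronoi tessellations of
the same mask are not independent labelings — both are spatially contiguous
partitions of the same geometry and genuinely share information (AMI around
0.6 at moderate granularity). The chance-level null that AMI corrects for is
permutation of voxels, so the null-behavior check scrambles one labeling
spatially within the mask (keeping its region sizes) before asserting
|AMI| < 0.05.

## Problem sizes

Default verification sizes, chosen to exercise the regimes that matter while
staying desk-scale: the exhaustive EMI oracle runs every pair of marginal
shapes up to N = 8 (917 instances); AMI self/relabeling agreement runs 50
atlases on 64-cube grids with 2..200 regions; the null check uses 20 pairs on
~12.5k-voxel masks; the loss ordering uses 100 atlases at 150 regions
downsampled 1 mm to 4 mm. `scripts/acceptance.py` recomputes all of these
from scratch.

## Known limitations

* Surface formats (GIFTI/CIFTI), 4-D probabilistic atlases, and registration
  are out of scope by design.
* `expected_mi` loops over rows in Python with vectorized inner sums; at
  1000x1000 regions and N = 1e7 it takes minutes, not seconds. Exactness was
  preferred over a faster approximate EMI.
* The symmetry heuristic compares support about the grid midline, not the
  anatomical midplane; for volumes whose affine places the midline elsewhere
  it will report asymmetry.
* The Dice map is reported in full; display conventions (thresholding,
  normalization of heat maps) are left to the caller.
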