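# Methods

## Pipeline model

The classifier operates on the regular tile grid of a slide image.
Geometry: square tiles of `tile_size_px` (default 1000 px) cut row-major
from the image origin; partial border tiles are dropped, not padded, so
every classifier input has identical statistics. Each kept tile is
downscaled to `model_input_px` (default 112 px) with anti-aliased
area-style interpolation. Coordinates are 0-based half-open pixel
intervals throughout.

Background removal: a tile is empty background iff its channel-averaged
mean intensity **at source resolution** is strictly greater than
`background_mean_threshold` (default 210 on the 0–255 scale). A tile at
exactly the threshold counts as tissue. Background tiles are never sent to
any classifier, never vote, and are never relabelled by refine.

Classification is a chain of binary stages — Root (T vs NT), Node
(super-group vs super-group), Leaves (within-pair subtype) — each trained
independently on only the tiles carrying its two label groups, balanced by
random under-sampling of the majority class (both classes end at the
minority count; removals are uniform under the training seed). The 0/1
encoding is fixed per stage so scores are comparable across runs: T = 1 at
the Root, `cc+pap` = 1 at the Node, ONCO = 1 at Leaf1, papRCC = 1 at
Leaf2 (and analogously, second-listed group = 1, for the naive
topologies). Stage training seeds are derived from the master seed via a
seed sequence, so a fit is fully reproducible.

Tree topologies. The four subtypes are partitioned 2+2 by the Node; the
expert layout pairs (ccRCC, papRCC) against (chrRCC, ONCO); `naive1` and
`naive2` are the other two possible pairings and exist as comparison arms.

## Refine

After each stage, every non-sentinel tile is relabelled with the plurality
label of its 3×3 neighborhood, itself included. Cells outside the grid,
background cells and cells outside the stage's label domain (e.g. NT cells
during the Node stage) neither vote nor change. Conventions chosen where
the operator is otherwise underdetermined:

* **Synchronous update**: all new labels are computed from the input map in
  one pass, making the result independent of scan order (filter
  semantics).
* **Single pass** per stage, not iterated to convergence.
* **Ties keep the original label.** Tied votes occur at region borders and
  near masks; preserving the original is the least destructive choice.
* Votes are over labels only; confidences are ignored.

One pass removes any isolated dissenter (a cell whose existing neighbors
all agree on another label) and, on piecewise-constant maps with i.i.d.
label noise up to ε = 0.2, empirically reduces the expected tile error
well below ε (measured in the acceptance run).

## Node pruning

For a test patient, let n0 and n1 be the tile counts assigned to the two
super-groups, pooled over all the patient's slides. The imbalance is
`|n1 − n0| / (n1 + n0)` — a relative (scale-free) fraction, so patients
with different tile counts are treated alike. Under the `selective`
policy the Node is distrusted when the imbalance is **strictly below**
the threshold (default 0.30); a patient at exactly 0.30 trusts the Node.
As a boundary convention, a threshold of 1 means "never trust the Node",
so threshold 0 reproduces the `unpruned` variant exactly and threshold 1
reproduces `node_pruned` exactly (the strict rule alone would leave
perfectly unanimous patients, imbalance exactly 1.0, on the Node route).

When pruning fires, each tumor tile is scored by both leaves and takes the
label of the leaf with the higher confidence (|score − 0.5| rescaled to
[0, 1]); ties go to Leaf1 with a logged warning. This keeps one vote per
tile and leaves the patient-vote rule unchanged. An alternative mode in
which each tile contributes both leaf labels to the patient tally is
available (`pruned_vote="double"`), since either reading is defensible.
A patient with no tumor-labelled tile at all has no imbalance; the outcome
is the distinct `NO_TUMOR`, never a subtype.

## Aggregation and metrics

The patient vote is the plurality over final tile labels with NT excluded;
ties break by the fixed prevalence order ccRCC > papRCC > chrRCC > ONCO
(with a warning). Balanced accuracy is the mean of per-class recalls; the
reported spread is the population standard deviation over the exactly four
recall values. The multiclass MCC uses the standard covariance-form
generalization computed from the confusion matrix. `NO_TUMOR` predictions
are tallied separately from the 4×4 subtype confusion matrix but count
against the true class's recall; when they occur, MCC is computed on the
matrix extended by a `NO_TUMOR` outcome column. A degenerate confusion
matrix (zero covariance denominator) defines MCC as 0 with a warning.

The flat baseline is a single five-class tile classifier (four subtypes +
NT) followed by the identical patient vote — the comparison arm
representing a conventional CNN pipeline.

## Synthetic cohorts

The generator produces the statistical situation the method assumes, not
H&E realism. Each slide is a grayscale raster composed of a near-white
margin (clipped ≥ 242, so the 210 background rule separates it by
construction), one not-tumor region drawn from three distinct NT textures
(fiber / necrosis / normal parenchyma, distinguishable from all tumor
textures mainly by mean intensity), and a tumor region carrying the
patient's subtype texture.

Class textures are band-limited Gaussian random fields with three
parameters: mean gray level, contrast (field standard deviation σ) and
spatial correlation length ℓ. The subtype hierarchy is imposed on (ℓ, σ):

* ℓ separates the super-groups — (cc, pap) coarse, (chr, ONCO) fine —
  at strength `delta_between` (factor (1+δ)±1 on ℓ);
* σ separates the two members within each pair at strength
  `delta_within`, with the contrast direction **opposed** across pairs
  (cc and ONCO high-σ, pap and chr low-σ). This makes the expert layout
  the unique grouping with a single clean separating axis: `naive2`'s
  grouping must separate on the harder within-pair axis and `naive1`'s is
  an XOR-type configuration of the two axes — mirroring the clinical
  claim that the expert super-class layout is easier than any other.
  At `delta_within = 0` the two members of a pair are drawn from the
  identical distribution.

Every region additionally draws multiplicative lognormal jitter on σ and ℓ
(log-sd 0.25 and 0.12). This is the within-class variability that the
deltas compete against; without it any positive delta is trivially
separable and "hard" versus "easy" would not exist. Pixel-level Gaussian
noise (`noise_level`, default 6 gray levels) is added on top.

Defaults define the study conditions: 10 patients per subtype (40 total),
60/40 patient-level train/test split, slides per patient from a geometric
law with mean 2.2 truncated at 6, tumor region ≈ 70% of annotated tissue,
`delta_between = 2.0`, `delta_within = 0.3`. With the shipped texture
backbone these defaults place the within-pair tile accuracy around 0.8–0.9
and the super-group split near 1.0 — the between-easy / within-hard regime
the tree design exploits. Geometry is scaled down for CPU speed: 448 px
images with 64 px tiles downscaled to 32 px (a 7×7 grid per slide).

Region boundaries snap to the tile grid. At clinical scale a slide yields
thousands of tiles and boundary tiles (partial tissue) are a negligible
fraction; on a 7×7 grid unaligned regions would make boundary mixtures the
*majority* of tiles, a regime the method never faces. Aligning regions
keeps the scaled-down cohort representative; consequently the generator
does not exercise robustness to partial-tissue tiles (see Limitations).

The ambiguous-patient generator tiles the tumor region with two textures —
the patient's subtype and its counterpart in the other super-group — at a
given area balance, to exercise the pruning rule deterministically:
balance 0.5 yields node imbalance near 0 (pruning fires), balance 1.0
yields imbalance near 1.

All randomness flows from a master seed through seed sequences;
regenerating a cohort with the same configuration is byte-identical.

## What passing tests do and do not show

The synthetic cohorts demonstrate that the pipeline machinery is correct
(routing, conservation, voting, pruning semantics, determinism) and that
the expert grouping dominates the naive ones *when the data truly have the
assumed hierarchical difficulty structure*. They do not show that real
H&E morphology has that structure to the same degree, nor do they
reproduce clinical accuracy figures; stain variation, scanner effects,
polygonal lesions, partial-tissue tiles and class imbalance at clinical
prevalence are all outside the generator's scope.

## Numerical choices and degenerate inputs

* Background rule: strictly greater than the threshold, evaluated on the
  source-resolution tile (not the downscaled patch).
* Downscaling: `skimage.transform.resize` with anti-aliasing,
  `preserve_range=True`.
* A backbone fitted on a single class predicts that class constantly with
  a logged warning rather than failing.
* `balance_by_undersampling` requires both classes present and fails
  naming the absent one; `fit_stage` fails naming its stage.
* Patient-level problem sizes in tests and the acceptance script (40
  patients, 448 px slides, three ablation replicates) were chosen so a
  full run completes in about a minute on one CPU while keeping ≥ 48
  patient-level test decisions per reported score.

## Known limitations

* Patient-level balanced accuracy on 16 test patients per cohort is coarse
  (steps of 1/16 per class); single-cohort arm comparisons are noisy, which
  is why the acceptance run averages three replicate cohorts.
* The default backbone is near-linear on hand-crafted texture features; it
  cannot represent arbitrarily complex class boundaries, and the naive-tree
  penalty partly depends on that (a sufficiently powerful backbone could
  learn even the XOR grouping at tile level).
* Only rectangular ROIs and plain rasters (PNG/TIFF) are supported;
  pyramidal scanner formats would plug in at the image-reading boundary.
* The tree structure is fixed at four subtypes + NT; the `TreeSpec` type
  admits other partitions of four labels but no five-subtype topology is
  provided.
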