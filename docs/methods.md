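# Methods

## Imaging model and projection

The pipeline analyses bright-field z-stacks of cells embedded in a thick
(~1 mm) gel, scanned in 10 µm z-steps at 30 s intervals. Because cells
scatter light, they appear as dark blobs in the **minimum intensity
projection** of each stack; the z-plane index at which each pixel attains
its minimum (the **z-map**) carries an estimate of the axial position of
whatever object darkened that pixel. The projector is streaming — it folds
in one z-plane at a time — because acquisition systems typically discard
planes as they project. Ties in the minimum are resolved toward the lowest
z index, which makes the z-map deterministic and invariant under plane
duplication.

## Detection

Detection is a deterministic classical procedure: pixels darker than
`background_mean − c·background_sd` (default c = 4) are thresholded and
connected components become candidate objects. Background statistics are
taken robustly (median and 1.4826·MAD) from the projection itself, since
cells occupy a small area fraction. Object size is summarised as the
equivalent diameter 2·√(area/π)·pixel_size and classified by the study's
size rules: objects under 4 µm are discarded as cell fragments (the bound
is inclusive upward — a 4.0 µm object is kept), objects strictly larger
than 14 µm are K562 targets, and the interval [4, 14] µm is an NK cell.
Objects above 30 µm — in practice merged neighbours — are flagged
`ambiguous` and excluded from counts and linking. The axial estimate of an
object is the median z-map value under its mask. c = 4 was fixed on
synthetic fixtures; it is a detector parameter, not a claim about any
particular microscope.

## K562 viability

Live K562 cells are round and wiggle with a 1–2 µm amplitude; dying cells
stop wiggling and change contrast and shape. The classifier works on a
track of detections: wiggle is the RMS frame-to-frame planar centroid
displacement over a trailing 10-frame window (5 min at 2 frames/min), and
death is called at the first frame where wiggle < 0.5 µm **and** either the
mean bright-field contrast changes by more than 15% or the eccentricity
rises by more than 0.2 relative to the first-window baseline. Requiring
the wiggle cessation *and* an appearance change makes transient blebs with
recovery stay "live", and the transition is enforced to be one-way (no
resurrection). The thresholds are calibrated on the synthetic renderer and
documented here for reproducibility; they are not claimed to reproduce any
manual annotation standard. Tracks shorter than the window are reported
live with an `indeterminate` flag.

## Tracking

Detections in consecutive frames are linked per cell class by an exact
minimum-total-cost bipartite assignment with cost d_xy² + z_weight·d_z²
(z_weight = 1 by default). Using the z-map estimate in the cost is what
separates two cells whose paths cross in the projection but lie at
different depths. Links are forbidden when the *planar* displacement
exceeds `max_link_distance` (default 15 µm per 30 s, generous against
observed NK speeds of a few µm/min); the gate is planar rather than 3-D
because the z estimate is quantised to the 10 µm z-step and would otherwise
dominate the gate. There is no gap closing and no motion model: a track
ends the first time it goes unmatched. Detections are brought into a
canonical spatial order per frame before matching, so results do not depend
on detector output order.

## Motility metrics

All metrics are planar (x–y imaging plane); z is used only for tracking.

* **Motile rule**: a cell is motile if its displacement from the first
  position reaches 13 µm (inclusive) at *any* frame within a 5 min window.
  The at-any-time reading (rather than endpoint displacement) is the
  natural reading of "moves away within 5 min"; cells whose tracks do not
  cover the window are excluded from the denominator. The displacement is
  planar for consistency with the speed definition (configurable).
* **Speed**: diagonal of the axis-aligned planar bounding box of the
  trajectory divided by the 5 min measurement time. Note this is *not*
  rotation invariant for curved paths (the box is axis-aligned); it is for
  straight ones.
* **Persistence**: mean cosine of turning angles between consecutive
  steps, computed from `arctan2` headings so that ballistic (+1) and
  reversing (−1) limits are numerically exact. Steps shorter than 0.2 µm
  are dropped first — the turning angle of a near-zero step is undefined
  and sub-pixel jitter would otherwise dominate.

Aggregation follows the study design: motile fraction per field of view,
then mean ± standard error over the (typically five) fields of view per
sample; speed and persistence are averaged over motile cells per FOV and
then over FOVs.

## Killing kinetics

Target death is modeled as a first-order reaction NK + K562_live →ᵏ
NK + K562_dead with three assumptions: the killing efficiency k is constant
(no exhaustion), the motile NK concentration is constant over the
observation window, and death is irreversible. The live-target
concentration then decays exponentially, and the endpoint estimator

    k = (ln live₀ − ln live_T) / ([NK_motile] · T)

inverts that solution exactly. All concentrations are cells per 10⁶ µm³
(a 100 µm cube) and T is in hours, so k has units (10⁶ µm³/cell)/h. The
composite efficiency divides the same log-decay by the total NK
concentration and satisfies k_composite = k·[NK_motile]/([NK_motile] +
[NK_nonmotile]) identically. Both the motile and nonmotile concentrations
are time-averaged (configurable): the model treats them as constants, and
the time average is the natural estimate of that constant.

Experiments with different cell concentrations are combined by the weighted
mean with weights [K562_live,0]·[NK_motile]; group comparisons bootstrap
experiments within each group (default B = 10,000, seed required), with a
two-sided p equal to twice the smaller tail of the bootstrap difference
distribution, floored at 2/B — the honest resolution of a B-sample
bootstrap. A final live count of zero makes the estimator unbounded; the
count-level API substitutes half a cell and flags the value as a lower
bound. The event-resolved decay rate is fitted by ordinary least squares
of ln(live count) against time on the step series of individual killing
events (maximum likelihood would weight events differently; least squares
on log counts is the simplest defensible choice and is reported alongside
the endpoint-only rate).

## Statistics

* **Wilcoxon signed-rank (paired, two-sided)**: zero differences are
  dropped and tied absolute differences receive mid-ranks. For n ≤ 12 the
  p-value is exact by enumerating all 2ⁿ sign assignments of the observed
  ranks (conditioning on the observed rank pattern, which remains valid
  under ties); 2¹² = 4096 assignments are instant, and the study's sample
  sizes (6–10) all fall inside the exact regime. Larger n uses the normal
  approximation with tie correction. The two-sided p is twice the smaller
  tail, capped at 1.
* **Spearman correlation**: mid-ranked Pearson ρ with the small-sample
  test statistic t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom; at
  |ρ| = 1 the t statistic diverges and the reported p is the permutation
  limit 2/n!.
* **Power-law fits**: OLS of ln y on ln x; a = exp(intercept), b = slope,
  R² on the log–log residuals (defined as 0 when ln y has zero variance).
  A t-test of b = 0 accompanies the fit; a paired-Wilcoxon construction of
  the same null on per-sample pairs is available through the Wilcoxon
  function and is reported separately when used, since the two tests answer
  slightly different questions.
* **Lysis fraction**: (experimental − spontaneous)/(maximum − spontaneous),
  returned unclamped with a warning outside [0, 1].

## Synthetic scenes

The generator is the test bed for every stage and encodes the study
conditions as defaults:

* **Geometry**: cells uniform in a box of the configured volume (default
  1.15 × 1.15 mm field of view × 1 mm depth = 1.32·10⁹ µm³); at the
  motility-assay seeding density (150,000 cells in 2.5 ml) this gives ~80
  NK cells per field of view. The cytotoxicity preset reproduces the assay
  concentrations (600,000 NK + 120,000 K562 in 2.5 ml → 0.24 and 0.048
  cells per 10⁶ µm³). Boundaries reflect, which keeps concentrations
  constant as the kinetic model assumes.
* **Motile NK cells** (a binomial subpopulation of size n_nk with
  probability motile_fraction): fixed-length planar steps of
  speed_mean·Δt with wrapped-normal turning angles. The wrapped normal has
  mean resultant cosine exp(−σ²/2) exactly, so σ = √(−2 ln p) realizes a
  target mean turning cosine p in closed form; p = 0 falls back to uniform
  headings and p = 1 to straight lines. Defaults speed_mean = 6 µm/min and
  persistence_true = 0.85: the bounding-box speed statistic of such walks
  lands at the few-µm/min scale reported for NK cells, and truly motile
  cells then satisfy the 13 µm / 5 min rule with probability ≈ 0.98, so the
  motile flag is recoverable from images. Motion is planar at constant z —
  adequate for planar metrics and z-disambiguation tests, though real cells
  also migrate axially.
* **Nonmotile NK / live K562**: anchored isotropic Gaussian jitter
  (σ = 0.3 µm per frame for NK; for K562 the per-axis σ is
  wiggle_amplitude/2, which makes the RMS planar frame-to-frame
  displacement equal the configured 1.5 µm wiggle amplitude).
* **Killing**: each live target draws an exponential death time at rate
  k_true·[NK_motile]; the deterministic mode evaluates the exponential
  solution exactly instead. Dead targets freeze (zero wiggle).
* **Rendering**: dark Gaussian blobs (dip 60% of background) on a bright
  background with additive Gaussian noise (default σ = 2% of background);
  NK cells are drawn at 9 µm, K562 at 18 µm. The axial footprint is
  max(diameter/4, 0.6·z_step) — bright-field cells remain dark over a wide
  defocus range, and the footprint must span the 10 µm z-sampling for cells
  between planes to be visible. Dead K562 are rendered with a 30% weaker
  dip, a 1.5:1 axis ratio and no wiggle, which encodes the visual death
  criteria (contrast change, shape change, wiggle cessation) as measurable
  image features. No point-spread function or shot-noise physics is
  modeled.
* **Seeding**: one root seed; every stochastic draw comes from a spawned
  `SeedSequence` stream, so identical configurations are bit-identical.

What the generator does **not** emulate: optical aberrations and
depth-dependent contrast, NK–NK and NK–target contact dynamics (deaths are
drawn from the rate law, not from simulated encounters), chemotaxis,
cell-size heterogeneity, and axial migration. Tests passing on synthetic
scenes therefore validate the *analysis* (projection, detection, linking,
metric definitions, estimators) against known ground truth; they do not
validate segmentation performance on real microscopy.

## Problem sizes

Image-level tests and the acceptance script use scaled-down fields of view
(333 µm box, 16 z-planes at 10 µm, 11 frames, ~25 cells per FOV, aggregated
over 10–16 FOVs to reach ~400 cells) rather than the full 1.15 mm / 100
plane geometry; the density per unit volume and all optical parameters are
unchanged, so detection and linking operate in the same regime. Killing
recovery uses 500 targets × 100 replicates. These sizes are the package's
own test-scale choices.

## Known limitations

* The detector has no merge/split resolution: two cells closer than about
  one diameter in the projection become one object (flagged ambiguous only
  if very large). At ~80 cells per 1.15 mm FOV this is rare; at much higher
  densities a learned segmenter would be needed.
* The death classifier needs a 10-frame baseline and trailing window, so
  deaths in the first or last 5 min of a track are not callable.
* The motile rule is evaluated on tracked positions; cells lost by the
  tracker before covering the 5 min window drop out of the denominator,
  which can bias the motile fraction slightly at low tracking quality.
* `fit_exponential` treats event times as exact; censoring at the
  observation end is handled only through the endpoint-rate comparison.
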