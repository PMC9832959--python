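# Methods

## The screening model

The pipeline analyses a proliferation screen in which compounds (or
siRNAs) are applied to cultured genital-tubercle mesenchyme (GTme) cells
in 384-well plates, and the readout per well is the total nucleus count
and mean nuclear area obtained by fluorescence imaging of a DNA
counterstain at four fields per well. GTme proliferation is
androgen-driven and sex-dimorphic — male cultures grow faster — so every
analysis is stratified by sex.

### Growth model

Well counts follow discrete multiplicative (exponential) growth:

    E[count] = n0 · r_sex^t · effect_sex

with `t` in days, per-day growth factors `rate_male = 1.35` and
`rate_female = 1.25` by default (male doubling time ≈ 2.3 d, female
≈ 3.1 d, male/female count ratio ≈ 1.6 after 6 days — the qualitative
size of the culture growth advantage), and a compound effect that
multiplies the final count (1.0 = null). Observed counts carry
multiplicative lognormal noise with mean 1 and coefficient of variation
`count_cv` (default 0.08, a typical well-to-well CV for an imaging
readout), floored at zero and rounded to integers.

The seeding density `n0` is drawn **once per run** from the protocol
window `n0_range = (300, 500)` cells/well and shared by all wells,
replicates and conditions: a plate (or the arms of a time course) is
seeded from a single cell suspension, so the 300–500 range expresses
between-experiment variation in plating density, not well-to-well
scatter — that scatter is `count_cv`'s job. Modelling `n0` per-well
would inject an artificial ~14% well-to-well CV that no real plate
shows. A practical consequence is that treatment arms of a growth course
are paired on seeding density, so zero-noise comparisons are exactly
monotone in the planted rate effects.

Hormonal modulators act multiplicatively on the sex rate and compose:
methyltestosterone (`MT`) defaults to ×1.08 on the female rate and ×1.02
on the male (females respond strongly, males are already androgen-
saturated); the androgen antagonist flutamide (`FLUT`) to ×0.92 on the
male rate and ×1.00 on the female. siRNA silencing is modelled the same
way (per-gene per-sex rate factors).

### Nuclear-size model

Mean nuclear area follows an exponential approach to a plateau,

    size(t) = size_plateau − (size_plateau − size0) · (1 − size_rate)^t

with defaults `size0 = 80 px²`, `size_plateau = 150 px²`,
`size_rate = 0.35`/day — nuclei enlarge over the first days of culture
and level off, the signature of progressive differentiation. Compounds
may add a declared shift in px² (shrinkage < 0). Observed sizes carry a
separate lognormal CV `size_cv` (default 0.02; size is an average over
hundreds of nuclei, hence much tighter than the count CV). An optional
coupling `size_growth_coupling ∈ [0, 1]` (off by default) scales the
instantaneous log growth rate by `(1 − coupling · plateau-progress)`,
reproducing the observation that proliferation slows as nuclear size
saturates; with it on, interval growth rate and interval-start size are
perfectly anti-ranked at zero noise.

### Image rendering

Synthetic fields are 16-bit grayscale with a flat background (default
1200 counts), Gaussian read noise (`noise_sd = 150`), and each nucleus
drawn as a **flat-top radial profile** — an order-8 super-Gaussian
`peak · exp(−(d/r)^8)` with `peak = 30000`. The flat top with a sharp
shoulder is deliberate: any threshold between background and peak
recovers an area within a few percent of the intended πr², so the
generator's ground-truth areas are meaningful for *any* reasonable
segmenter. (A plain Gaussian profile has no well-defined thresholded
area: the measured size would be an artifact of the threshold level.)
Radii are N(6, 0.8) px truncated at 2. Placement is hard-disk (centres
at least `r_i + r_j + 2` px apart, full disk inside the field) by
rejection sampling with a bounded attempt budget; overlap is an opt-in
stress mode. Per-well counts are split across the four fields by a
multinomial draw, so field truths always sum to the well's count. No
point-spread function, vignetting or autofluorescence is simulated.

### Randomness

All randomness descends from one integer seed through named substreams
(`layout`, `counts`, `sizes`, `images/<plate>/<well>`, `qpcr`, …), so
regenerating one component never perturbs another, and identical seeds
give byte-identical tables and images.

## Imaging readout

`segment_nuclei` reproduces the function (not the internals) of a
commercial high-content readout:

1. **Background subtraction**: white top-hat with a disk of radius
   3 × the expected nucleus radius (a rolling-ball-style flattening).
2. **Global threshold**: Otsu by default. Two guards make Otsu safe on
   screening data: a constant image raises an explicit degenerate-image
   error (blank wells are legal via the fixed-threshold path), and the
   threshold is floored at `median + 6 · (1.4826 · MAD)` of the
   processed image — on a sparse field Otsu otherwise lands inside the
   read noise and shatters the background into hundreds of false
   objects.
3. **Touching-object splitting** (optional, default on): seeded
   watershed on the negated Euclidean distance transform, seeds from
   distance maxima at least one nucleus radius apart; deterministic.
4. **Area filter**: objects kept in `[min_area, max_area]` =
   [20, 5000] px² by default; labels relabelled contiguously from 1.

Border-touching objects are kept: the truncation bias is symmetric
across wells and cancels in plate-level MAD statistics (a flag excludes
them if needed). "Nuclear size" is object area in px²; physical
calibration (µm²/px²) is a reporting-time scalar, never applied
internally. A well's measurement is the sum of its fields' counts and
the unweighted mean over the pooled object areas; an empty pool yields
count 0 with the area flagged NaN.

On rendered plates this readout is exact: noiseless non-overlapping
mini-plates segment to 100% count agreement with ground truth and mean
areas within 5% of πr²; with default read noise, well counts stay within
5% for ≥95% of wells (in practice, all of them).

## Hit calling

Per plate and sex, the null band is set by the **median** and the **raw
median absolute deviation** of well counts — the MAD is deliberately
*unscaled* (no 1.4826 normal-consistency factor): the screen's unit of
deviation is raw MADs, and all thresholds are quoted in it.

* **Wells entering the statistics**: all measured compound *and* control
  wells (empty wells never; configurable to compound-only). Controls
  stabilise the null when many compounds on a plate are active.
* **Compound calls**: the quadruplet *mean* count, as a signed deviation
  `(mean − median)/MAD`; hyper at `≥ +k`, hypo at `≤ −k`, `k = 3`.
  The band is **inclusive** ("3 MAD or more") by default; the strict
  variant (`> +3 MAD`) differs only on exact ties and is a config
  switch, echoed in every report.
* **Controls**: judged **per well**, not averaged — an intentional
  asymmetry (the FDR counts individual control wells). FDR per direction
  is `100 · flagged/total` %; zero flagged reports 0% (below the
  threshold of detection at that control count).
* **Degenerate plates** (MAD = 0) yield no calls and a loud warning
  rather than infinite deviations.
* A compound is a **screen hit** if it is a hit in either sex;
  sex-specific means hit in exactly one sex (set partition, no
  effect-size contrast test).

Median and MAD are shift- and scale-equivariant, so hit directions are
invariant under `count → count + c` and `count → m · count, m > 0` —
asserted as a property test.

### Categories

Hits are placed on the count-vs-size plane using the same median/MAD
machinery on mean nuclear area (`size_k = 3` by default): shrinkage is a
size shift ≤ −size_k; C1 = hypo ∧ shrinkage (the cytotoxic signature),
C2 = hyper ∧ shrinkage, C3 = any hit without shrinkage, with
size-*enlarged* C3 hits carrying an extra flag. The C1/C2/C3 boundary is
a quantified choice — the published categorisation is a qualitative
scatter — so `size_k` is a first-class config value.

### Enrichment

Kinase-family enrichment of the hit set uses a two-sided Fisher exact
test computed with exact rational arithmetic (hypergeometric
probabilities accumulated as `fractions.Fraction`, summing all tables
with probability ≤ the observed one), so p-values are correct to float
rounding; families are labelled enriched when their hit fraction
strictly exceeds the library-wide fraction (ties → disenriched) and
ranked by p within each label.

## Supporting statistics

* **Welch t-test**: `t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b)` with
  Welch–Satterthwaite df; two-sided p from the t distribution. Also
  accepts summary form (mean, sd *or* sem, n; sd = sem·√n). Convention:
  both variances zero → p = 1 for equal means, 0 otherwise. Growth
  curves are compared per timepoint with flags at 0.05 and 0.01 and **no
  multiple-testing correction anywhere** — single readouts per
  condition are compared; every report states this.
* **Size–growth trend**: Spearman (the claim is monotone, not linear)
  between per-interval growth rate (log count ratio per day) and
  interval-start mean area; constant series are flagged undefined.
* **ΔΔCt**: per sample `ΔCt = Ct_target − Ct_reference`; `ΔΔCt = ΔCt −
  mean(ΔCt_calibrator)`; fold = `2^(−ΔΔCt)`. Calibrator aggregation is
  the arithmetic mean of ΔCt (equivalently the geometric mean of folds,
  which is exactly 1 for the calibrator group); no amplification-
  efficiency correction. Folds are invariant to adding a constant to
  both Ct values of a sample. Group summaries report mean with **both**
  sd and sem, labelled — published "±" values are ambiguous between the
  two, and the ambiguity must not corrupt downstream comparisons.
* **BrdU density**: positive points strictly inside or on the boundary
  of a simple polygon, divided by its area; outside points are excluded
  but counted in a QC field. Invariant under rigid motion of polygon and
  points together. Absolute densities depend on the (unknown) pixel
  scale of the source images and are treated as data, never recomputed.

## Problem sizes and numerical choices

* Planted-hit recovery is validated on the full screen geometry — 438
  compounds, 80/plate, quadruplets, 32 controls/plate, six plates per
  sex — with 60 hypo (×0.3) and 20 hyper (×1.8) compounds at
  `count_cv = 0.08`, aggregated over 20 seeds in the test suite and 5
  seeds in the acceptance script; sensitivity is 1.0 in both directions
  with no null compound flagged at these effect sizes.
* The imaging round-trip uses a 24-well mini-plate, 4 fields/well,
  256×256 px fields at ~30 nuclei/field (hard-disk packing fraction
  ≈ 0.05) — small enough to segment in seconds, dense enough to
  exercise the watershed.
* Control count per plate defaults to 32 (≈ the screen-wide budget of
  160 negative-control wells spread over the library plates, exact
  distribution unknowable); fully configurable.
* Ties in watershed seeding are broken by deterministic pixel order;
  plate statistics are recomputable from the measurement table; every
  report embeds the config and a hash of its numerically relevant
  fields (equal hash ⇒ identical numeric output).

## What the generator does and does not show

Passing on synthetic data shows the *analysis* is correct under the
stated model: exponential sex-dimorphic growth, lognormal observation
noise, additive size shifts, clean round nuclei. Real screens add plate
gradients and edge effects (deliberately not corrected here — the
analysis applies none), epithelial contamination (available only as an
optional second-population fraction), debris and clumping, non-round and
fragmenting nuclei, and compound effects that alter morphology in ways a
single area statistic cannot see. Equivalence to any commercial
segmentation package cannot be asserted — only functional equivalence on
known ground truth. Dose–response is out of scope (single-dose screen),
as is any ontology/pathway analysis beyond the in-repo family enrichment.
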