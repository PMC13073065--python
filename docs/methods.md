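# Methods

## Growth model and fitting

Each spot culture is modeled by the logistic growth equation
`G(t) = K / (1 + e^(−r(t−L)))` with carrying capacity `K` (intensity units),
maximum specific growth rate `r` (h⁻¹) and half-rise time `L` (h). The
curve's maximum slope is `rK/4`, attained at `t = L`; these identities anchor
the analytic tests.

Fitting is bounded nonlinear least squares (trust-region reflective, analytic
Jacobian) on the raw intensities with an **additive baseline parameter**
initialized at the series minimum. Subtracting the minimum before fitting —
the obvious alternative — destroys the logistic form whenever `G(0)` is not
negligible and biases `K` by several percent; fitting the offset instead
restores exact noiseless identifiability (≤ 10⁻⁶ relative error in the
tests). `K` is reported on the background-subtracted scale.

Numerical choices: initialization `K₀` = dynamic range, `L₀` = time nearest
the half-range crossing, `r₀ = 4·(max finite-difference slope)/K₀`; bounds
`K ∈ (0, 2·max]`, `r ∈ (0, 5 h⁻¹]`, `L ∈ [0, 2·t_max]`, baseline `∈ [0, max]`;
`xtol = ftol = 10⁻¹²`. A spot is a **non-grower** when its dynamic range is
below 10% of its plate's median dynamic range (relative, so it adapts to
imaging gain); series with fewer than 5 points are flagged
`insufficient_data`; optimizer failure flags `poor_fit`. Fits take ~2 ms per
35-point curve, so a full plate set fits in seconds.

Array QC fails a (plate, condition) when more than 10% of spots carry flags
or when any contiguous 4×4 block holds ≥ 8 failures (spatially clustered
failures indicate pinning/imaging artifacts). Failed arrays are excluded from
scoring.

## Interaction model

Per deletion array and condition,
`z = (CPP − median over the array's valid CPPs) / SD(matched 384-spot
reference array)`, the median taken over QC-passing converged fits only. The
interaction statistic is the adjusted z-score `z_drug − z_nodrug`, zero under
the proportional-response null. Calls at threshold `|z| ≥ 2` (configurable):
suppressor if `adjK ≥ 2` or `adjL ≤ −2`, enhancer for the opposite signs;
when rules for both classes fire the larger |value| wins and an exact tie is
neutral. Duplicate ORF strains are scored independently per spot lineage and
only collapsed where the enrichment background requires it.

The reference-array SD is an *estimate* (SE ≈ 3.6% over 384 spots). Genes
with huge baseline defects therefore inherit adjusted-z noise proportional to
their own baseline z — a real limitation of the standardization, visible in
screens as replicate-to-replicate spread of the adjusted scores of sick
strains.

## Clustering and the BIC cut

Profiles are the vectors (adjK2, adjK3, adjL2, adjL3), used unscaled since
they are already z-standardized; unperturbed z-scores ride along for display
only. Rows missing > 50% of features are dropped (logged); remaining gaps are
median-imputed. Ward linkage on Euclidean distance (configurable) gives a
deterministic tree.

The tree is cut at each `k = 1..k_max` (default 60) and scored with the BIC
of a hard-assignment Gaussian model: per-cluster means, one pooled spherical
variance, and multinomial mixing proportions,
`BIC = −2[Σ_j n_j ln(n_j/n) − (nd/2)(ln 2πσ̂² + 1)] + p·ln(nd)` with
`p = kd + (k−1) + 1`. The mixing (entropy) term is essential: without it,
splitting even a single spherical Gaussian reduces the pooled variance enough
(one axis falls to `1 − 2/π` of its variance under a balanced cut) that any
means-only BIC prefers `k ≥ 2`; the entropy term cancels that spurious gain
asymptotically and makes the single-cluster control select `k = 1`. A
means-only variant remains available (`mixing_term=False`), as does a
per-cluster-variance model (`pooled_variance=False`).

Two degeneracy guards keep the criterion honest: the pooled variance uses the
degrees-of-freedom-corrected `σ̂² = RSS/((n−k)d)`, and any cut whose σ̂² falls
below the **resolution floor** — half the per-coordinate median
nearest-*distinct*-neighbor spacing, `median(d_NN²)/(2d)` — is scored +∞.
Cuts below that scale are isolating duplicated or near-duplicated rows, where
the hard-assignment likelihood is unbounded; the floor never binds for
`k_max ≪ n` on continuous data, and it makes the selected `k` invariant to
duplicating every row. Ties in the BIC curve select the smallest `k`.

## GO enrichment

Background = unique gene symbols with QC-passing data (duplicates collapse to
one entry). Cluster test lists follow the duplicate rules: a gene in several
clusters is tested in each, within one cluster it counts once, and entries
outside any cluster are ignored. Each term with ≥ 2 background members
(configurable) is tested one-sided for over-representation; the p-value is
the exact hypergeometric upper tail. BH correction is applied **per cluster**
by default (each cluster's tested terms are one reporting family, matching
per-cluster representative-term reporting); a global family is a flag away.
Reporting threshold q < 0.005, with the lowest-q term per cluster flagged as
representative (ties alphabetical). No ontology ancestor propagation:
annotations are taken as given in the flat table.

## Dose response and ZIP synergy

4PL fits `y = bottom + (top − bottom)/(1 + (x/ec50)^hill)` run on log₁₀ dose;
0-dose wells anchor the untreated response but do not enter the logistic fit.
IC50 is the concentration where the fitted response is 50% of the fitted
untreated response (equal to EC50 when bottom = 0). Flat responses (< 10%
relative range) are rejected rather than fit.

Growth metrics smooth the curve with a centered moving average (default 3
points at 30-min cadence), then report lag = time of maximum slope and
max rate = that slope in absorbance×1000/min; for a noiseless logistic these
converge to `L` and `rK/4`.

ZIP surfaces: monotherapy margins are fit with increasing Hill curves on
fractional inhibition, baseline fixed at 0 and top bounded in [0, 1]; the
zero-interaction expectation at a combination is `y₁ + y₂ − y₁y₂`; the
observed potency-shifted response refits each row (conditioning on drug B,
baseline pinned to drug B's fitted monotherapy effect) and each column
(conditioning on drug A) and averages the two; `δ = observed − expected` in
percentage points, defined at combination cells only. Negative inhibitions
are retained, not clipped. Near-flat conditional fits may exhaust the
iteration cap with hill/EC50 unidentifiable; their fitted values are valid
and are used. Summary = mean δ over combination cells; 3×3 window means
locate the region of maximal synergy (ties → lowest doses).

Because the observed response is constrained to Hill-shaped conditionals, a
sharp planted δ block is recovered with some attenuation (≈ 10% in the
sub-EC50 quadrant of the benchmark geometry) and is strongly damped in the
saturating corner, where the [0, 1] response ceiling absorbs it. The planted
synergy benchmark therefore places its window in the sub-EC50 quadrant —
where real interaction landscapes typically peak — and scores the mean of
three replicate matrices, as a triplicate assay would.

## Synthetic screen generator

The generator emulates the statistical structure the analysis assumes:
384-spot deletion arrays at 0/10/20 µg/mL with matched reference arrays,
imaging every 3.5 h over 120 h, reference response `K₀ = 150`, `r₀ = 0.18 h⁻¹`,
`L₀ = 40 h`, and a shared drug effect multiplying K by (1, 0.9, 0.8) and
adding (0, 5, 10) h to L. Gene effects compose multiplicatively on K and
additively on L; interactions are planted as deviations beyond the shared
response, in units of the nominal reference SD, so "a 6-SD suppressor" means
exactly that on the z scale.

Key modeling decisions:

- **Shared spot-lineage noise.** The same source culture is pinned to every
  condition plate, so part of spot-level variation travels with the strain
  across conditions. Spot noise is split into a shared and an independent
  component (K: CV 2.60%/1.83%; L: SD 0.715/0.49 h). Only the independent
  part survives the `z_drug − z_nodrug` subtraction; with the fit noise at
  the default cadence this calibrates the null adjusted-z SD to ≈ 0.82–0.83
  (per-condition z-scores keep unit spread), which in turn sets the
  false-positive rate of the default |z| ≥ 2 call at ≈ 1.5% per test. Fully
  independent noise would give a null adjusted-z SD of √2.
- **Baseline fitness defects** hit 30% of genes with exponential tails
  (mean 6% K loss capped at 35%; mean 3 h L delay capped at 12 h) — most
  deletion strains grow near wild type, a minority are sick. Capping the
  tails matters because the adjusted score of a sick gene carries
  denominator-estimation noise proportional to its baseline z (see above).
- **Interactions**: 5% enhancers and 5% suppressors with magnitudes uniform
  in 4–10 reference SDs, applied to both K and L with class-appropriate
  signs and scaled by dose (half effect at 10 µg/mL).
- **Batch effects**: per-plate K gain CV 1% and additive L offsets (SD 1 h).
  The additive L offset cancels exactly in the plate-median subtraction; the
  multiplicative K gain does not fully cancel for genes with fitness defects
  (the deletion plate's scale and its reference plate's scale differ by the
  gain ratio), which is why realistic gains must be small.
- 0.5% random spot dropout (flat traces); observation noise is 1%
  multiplicative lognormal plus additive Gaussian SD 1.5 intensity units,
  under which fitted L is far more precise than fitted r, as expected of
  spot-array imaging.

What the generator does **not** emulate: spatial gradients and neighbor
effects within plates, non-logistic growth (diauxie, filamentation), pinning
geometry artifacts beyond random dropout, and condition-dependent imaging
gain. Passing recovery tests therefore demonstrate the statistical machinery
under the stated noise model, not robustness to every artifact of real
scanner data.

## Study problem sizes

The calibration and recovery studies run at sizes chosen to finish in
seconds to a couple of minutes on one core: 500 seeded curves for CPP
recovery; three 500-gene null screens and three 384-gene planted screens
(≈ 18,000 curve fits total) for interaction calibration; 20 seeds of the
n = 400 planted 5-cluster benchmark plus an n = 300 single-Gaussian control;
a ~160-table Fisher sweep with backgrounds up to 2000 against an exact
rational-arithmetic oracle, 1000 random p-vectors against a direct step-up
BH oracle, and 20 random-annotation null screens (30,000 tests) for type-I
calibration; 16 noiseless Bliss-consistent matrices across hill slopes
{0.5, 1, 2, 4} and triplicate planted-window recoveries for ZIP; triplicate
two-fold-ladder endpoint reads for the IC50 study (true values 6.9 and
2.3 µg/mL for the wild-type-like and sensitized strain).

## Known limitations

- The z-score denominator is a per-array estimate; adjusted scores of genes
  with extreme baseline defects are noisier than those of typical genes, and
  no shrinkage is applied (the formula is kept as stated).
- The BIC-selected k depends on the likelihood variant; the default
  (mixing proportions + pooled spherical variance) is a choice among
  defensible options, and different variants can select different k on
  weakly separated data.
- ZIP δ recovery of sharp, localized interactions is attenuated by the
  Hill-shaped conditional fits, increasingly so near response saturation.
- Per-cluster BH controls the FDR within each cluster's family, not across
  the whole screen; the global-family mode is provided for the stricter
  reading.
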