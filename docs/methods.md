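# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it: well counts → RBF → scores →
classification → clinical endpoints, plus the synthetic generators that
stand in for patient data.

## Relative blast fraction and pharmacoscopy scores

A well's marker-positive viable fraction is `pos / (pos + neg)` over the
viable cells assigned to one marker. The RBF divides this by the *mean*
fraction across all of the patient's DMSO control wells; by construction
the mean of the per-control-well RBFs is exactly 1, which the test suite
asserts as an invariant. RBF is a ratio of fractions, so it is invariant
to uniformly scaling all counts, and to any toxicity that kills
marker-positive and marker-negative cells at the same rate
(proportional-killing identity).

Aggregation order: replicate wells are averaged within each
concentration first, then concentrations are averaged unweighted. This
makes the per-drug mean robust to losing replicates at one concentration.
Wells with zero viable cells carry no fraction and are excluded with a
logged warning; if every well of a drug is excluded the drug's RBF is
missing (NaN), never imputed. Raw RBFs are never capped; the 1.2 cap is a
*display* convention and appears only in the report writer's
`rbf_display` column.

Per-drug significance is a two-tailed Welch t-test of the drug wells'
RBFs against the per-well control RBFs. Welch rather than pooled
variance: drug wells (typically n = 5) and controls (n = 16) differ in
both n and variance. p-values are reported raw — at α = 0.05 roughly 5%
of null drugs will be flagged, which calibration simulations confirm —
with Benjamini–Hochberg adjustment available behind a flag.

Pharmacoscopy scores are `(1 − RBF_d) / max_d (1 − RBF_d)` with the max
taken over drugs after replicate/concentration averaging, within one
patient × marker. When no drug beats control (`max(1 − RBF) ≤ 1e−9`) the
formula is undefined; all scores are set to 0 ("no ex-vivo effect") with
a warning rather than dividing by a non-positive number. Markers are
never averaged at scoring time; cross-marker views are derived
downstream, because per-marker discordance is itself clinically
informative. The i-PCY score sums scores over the administered drugs and
all measured markers, and is therefore additive over disjoint drug sets.

The ex-vivo chemoresistance fraction counts tested drugs with score below
a threshold, default −0.1 (alternates −0.2 … −0.4 behave identically).

Profile clustering uses average linkage on 1 − Pearson correlation with
missing values masked pairwise per distance (scipy's `pdist` cannot mask
NaNs pairwise, so the condensed distance is computed directly); columns
with fewer than two shared observations default to distance 1.

## Synthetic screen generator

Each well seeds `N ~ Poisson(cells_per_well)` cells (default 2000). The
marker-positive share is beta-binomial around the patient's blast
fraction with a single overdispersion parameter (default 0.002,
i.e. beta concentration 500) — counts are noisier than binomial, as
plate data are, but unbiased. Survival under a drug is binomial with kill
probability `kill_max · c / (c + EC50)` (Hill exponent 1, EC50 at the
geometric middle of the tested concentration range, default 0.1–10 µM).
Controls see no kill. The closed-form expectation

```
E[RBF] = s⁺ / (f·s⁺ + (1 − f)·s⁻),   s± = 1 − kill±
```

is stored in a truth table and the suite checks the simulator against it
within Monte-Carlo error; proportional killing gives exactly 1 at every
concentration. Presets reproduce the two screen geometries used
throughout: 139 drugs × 2 concentrations × 5 replicates (prospective
layout) and the 125-combination matrix in 4 replicates (retrospective
layout). Sixteen DMSO wells per 384-well plate is the package default
(the control count per plate is otherwise unspecified). Identical
config + seed reproduces byte-identical CSVs.

## AML matrix cohort generator

Twenty patients (10 complete remission, 10 non-responders by default)
are simulated over the 5 × 5 × 5 concentration grid of the three
first-line drugs (125 matrix points, ids 1–125, four replicates). Both
classes share a small baseline kill (`N(0.05, 0.03)` per drug);
responders add `effect_gap` (default 0.5) on top, so `effect_gap = 0`
makes the classes exactly exchangeable — the null-calibration tests rely
on this. Per-drug effects combine independently across the three drugs
and rise monotonically with each drug's concentration. Off-target kill
is 40% of on-target, so even responders' effects are blast-enriched
rather than purely specific.

Non-specific toxicity has two components, both killing marker-positive
and -negative cells at the same rate: a per-patient global factor
(exp(−Exponential(0.4)): overall sample fragility, e.g. biopsy quality)
and per-point noise (exp(−Exponential(0.25))). Because they hit both
populations equally they cancel in the RBF but shift a patient's whole
total-cell and total-blast profile. This is the mechanism behind the
readout-ordering property (RBF ≥ total blasts ≥ total cells in
cross-validated accuracy): population-relative normalisation discards
exactly the patient-level nuisance variation that population-absolute
readouts absorb. Blast fractions vary per patient over 0.3–0.95, which
additionally degrades the total-cell readout.

An optional outlier converts the last responder to a null ex-vivo
response while keeping the complete-remission label, emulating a patient
whose clinical response the screen does not predict; with the outlier
present the expected leave-two-out accuracy ceiling is 0.95 (the outlier
appears in 20% of held-out sets and costs a quarter of those runs'
accuracy), and simulated cohorts land in the 0.85–0.95 range.

## Hyperplane classifier

The decision surface is axis-aligned: one threshold per matrix point,
not a general linear discriminant, matching the idea of counting
per-point datapoints above or below a separating surface over the drug
grid. Per point:

* **orientation** — the responder-like side is chosen so the point's
  AUROC is ≥ 0.5 (equivalently: re-orient and keep `w = AUROC` whenever
  the raw lower-is-responder AUROC falls below 0.5);
* **weight** — the oriented AUROC (Mann–Whitney convention, ties 0.5),
  so weights live in [0.5, 1] and uninformative points get the floor;
* **threshold** — the midpoint between consecutive sorted training
  values that maximises training accuracy under the chosen orientation;
  among equally accurate candidates the one nearest the midpoint of the
  two class means is taken (deterministic tie-break).

The integrated score `Σ w_j s_j / Σ w_j` with `s_j = ±1` is bounded in
[−1, 1], antisymmetric under flipping every orientation, and diluted by
at most `~1/Σw` when an uninformative point is appended — all asserted
as properties. Values exactly on a threshold count as the non-responder
side (strict inequality), a measure-zero event for continuous data.

Cross-validation holds out every combination of k responders and k
non-responders (k = 2 by default: C(10,2)² = 2025 runs for the 10+10
cohort; the run count itself is a checked invariant). Each run refits
the surface on the remainder only — held-out patients never touch the
fit, which a poisoning test verifies — and classifies held-out patients
against the midpoint of the training scores' class means (sign-at-zero
when the classes coincide). The mean ROC is averaged vertically on a
fixed 101-point false-positive-rate grid; the reported AUROC is the mean
of per-run held-out AUROCs. The fit is vectorised (per-point cumulative
sums over the sorted training matrix), so a full 2025-run CV takes about
a second.

## Image stage

The renderer and extractor form a deliberately simple, fully specified
imaging model — not a reproduction of any production pipeline:

* intact nuclei are Gaussian blobs (σ = 3 px, amplitude 180 over
  background 5, read noise σ = 2);
* dead cells' nuclei are 3–6 small fragments (σ = 1.2 px) of equal total
  integrated intensity, placed on a jittered ring around the former
  nucleus centre. The ring radius is bounded below so fragments stay
  mutually resolved after smoothing and above so the group stays inside
  the fragment-grouping radius — free placement lets fragments merge
  into solid blobs that masquerade as viable nuclei;
* marker-positive cells add amplitude 150 in the marker channel
  (negatives 8) at the same centroid.

Extraction: Gaussian smoothing (σ = 2 px) → Otsu threshold → connected
components → drop components below half the minimum area → single-linkage
grouping of component centroids within 15 px; each group is one nucleus
with `n_fragments` recorded. An image whose threshold keeps more than
30% of pixels is treated as featureless (noise splits near half), and
returns no cells. Viability: `n_fragments == 1`, solidity ≥ 0.85, area
in [30, 400] px. These morphology defaults are declared choices tuned to
the renderer, exposed in `SegmentationConfig`, and not inferred from any
external pipeline.

Marker gating is per well on cell-wise mean marker intensities, using an
exact 1-D Otsu split (every cut between sorted values evaluated —
histogram-binned Otsu can misplace the gate by a bin width, which
matters for a few dozen cells). The split's separation score is the
normalised gap between the 90th percentile of the lower group and the
10th percentile of the upper group; below 0.1 the well is treated as
unimodal and a conservative fallback calls positive only cells above
both the 0.99 quantile and twice the median — an all-negative well
yields zero positives (the price is that a uniformly all-positive well
is also called negative; OR-combination across markers mitigates this in
multi-marker screens). The accepted gate is re-centred in the
inter-mode gap.

Segmentation and gating are invariant to multiplying both channels by a
positive constant. Against rendered ground truth, detection
recall/precision exceed 0.95 at mid noise, viable counts correlate with
truth at r ≥ 0.99, recovered marker fractions are within ±0.05, and the
image path's RBF agrees with the count path's on matched simulations.
What this does *not* show: robustness to uneven illumination, debris,
confluent clumps, or focus drift — the renderer does not produce them.

## Clinical outcome statistics

* **Kaplan–Meier**: lifelines' product-limit fit; the median is the
  smallest time with S(t) ≤ 0.5, *inclusive* at exactly 0.5 (computed
  from the fitted curve; the convention matters when S plateaus at 0.5),
  with `None` as the undefined sentinel when S never reaches 0.5.
  "Ongoing response = Yes" maps to right-censoring at the recorded PFS —
  with this mapping the bundled 17-patient table gives the median of
  22.6 weeks. With no censoring the estimator equals the empirical
  survival function exactly.
* **Log-rank / hazard ratio**: Mantel–Cox chi-square with hypergeometric
  variance (cross-checked against lifelines); the hazard ratio is the
  O/E estimate `(O1/E1)/(O2/E2)` with the Mantel–Haenszel variant
  `exp((O1−E1)/V)` alongside. Calibration note: at a true exponential
  HR of 3 the O/E estimate averages ≈ 2.7 (attenuated) and the MH
  variant ≈ 3.5 (inflated); both bracket the truth, and O/E is the
  package default. Cox regression is out of scope.
* **McNemar** (one-sided, continuity-corrected):
  `χ² = (max(|b−c|−1, 0))² / (b+c)`, p = half the χ²₁ tail when the
  discordance favours guided therapy (c ≥ b), its complement otherwise;
  p = 1 when b + c = 0. With b = 0, c = 11: χ² = 100/11, p ≈ 0.0013.
* **Odds ratio**: cross-product on the unpaired 2 × 2 margins; zero
  cells give an infinity sentinel unless Haldane–Anscombe +0.5 is
  requested. 15/17 vs 4/17 gives 24.375. The paired table can be
  reconstructed from its margins plus one discordant cell
  (`from_margins`), which is how the b = 0 analysis is driven.
* **PFS ratio**: guided/prior per patient, success at ratio ≥ 1.3
  (boundary inclusive), exact one-sided binomial test against a 15%
  null.
* **i-PCY association**: Pearson r against the ordinal response coding
  (1 = PD … 4 = CR) over all scored patients; the binary task separates
  PD from PR∪CR (stable disease excluded) at the accuracy-maximising
  i-PCY cut, with the Mann–Whitney AUC over all cuts.

The KM median confidence interval is not implemented: the interval
method behind published values of this kind is typically unstated, and
an unvalidated implementation would invite misuse.

## Clinical outcome simulator

Prior PFS is exponential (default median 6 weeks); guided PFS divides
the hazard by the configured hazard ratio. Administrative censoring at a
cutoff (default 52 weeks) sets the ongoing flag; a non-positive cutoff
censors every record at its drawn time (the all-censored degenerate
case). A simulated i-PCY score (`N(0.5, 2²)`) drives the ordinal
response through an ordered-logistic link with cutpoints (−2, 0, 2);
slope 0 severs the link for null calibration.

## Problem sizes and tolerances

Default test and acceptance problem sizes are chosen so the full suite
runs in a few minutes on one CPU: 10+10 cohorts with full 2025-run CV,
10–20 simulation seeds per property, 15–20 rendered wells per imaging
check, n = 200/arm survival recovery, and 1,000 random instances for the
oracle cross-checks. Statistical assertions use three-standard-error
bands for Monte-Carlo means (including the shared control-normalisation
error term where it dominates), sign tests at p < 0.05 for orderings,
and exact equality (to floating-point) for deterministic quantities.

## Known limitations

* The RBF's denominator is a noisy control-well mean shared by every
  drug of a patient × marker; at very low control-well counts this adds
  a correlated error term that the per-drug t-test does not model.
* The hyperplane's threshold scan optimises training accuracy; margins
  are ignored, so thresholds inside wide gaps follow the class-mean
  midpoint tie-break rather than a max-margin rule.
* The imaging model has no illumination field, debris, or clumping; its
  passing checks bound algorithmic correctness, not microscope realism.
* The clinical simulator draws prior and guided PFS independently given
  the hazard ratio; it does not model within-patient correlation of
  treatment sensitivity.
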