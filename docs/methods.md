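# Methods

## The observable

A test bolus (default 15 ml of 350 mgI/ml contrast at 5 ml/s, chased by
40 ml saline) is injected into an arm vein and the attenuation of blood in
the ascending aorta is sampled every 2 s. At fixed tube voltage, attenuation
is linear in iodine concentration:

    HU(t) = HU_baseline + κ · c_aorta(t)

Defaults: κ = 25 HU per (mgI/ml) at 120 kV, baseline 40 HU. κ is
scanner- and voltage-specific and configurable; absolute CO levels from the
dilution method scale with it, so κ must be calibrated per scanner before
absolute accuracy can be claimed on real data.

## Compartment model

### Structure

The intravascular space is a closed, strongly connected loop:

    arm vein (plug flow; injection site)
      → central veins → right heart → lungs → left heart → aorta (observed)
      → arm bed (6% of CO) → arm vein
      → body bed (94% of CO) → venous reservoir → central veins

Well-mixed compartments obey `V_i dc_i/dt = Σ_j Q_{j→i} c_j − Q_i c_i`.
Flows are fractions of CO and satisfy conservation at every node;
construction rejects any table that does not.

The arm-vein segment is a **piston (plug-flow) delay**, not a mixed pool:
injected contrast is displaced down the vein as a front, which is what makes
the simulated first pass as sharp as measured ones (replacing it with a
well-mixed pool of the same volume visibly lowers and widens the peak — a
test asserts this). The delay is implemented by cumulative carrier-volume
throughput: the mass flux entering at time t* exits once `∫Q dt` since t*
equals the segment volume. During injection the carrier flow is the
arm-path flow plus the pump rate, so the saline chaser pushes contrast
through without adding iodine. A constant-transit-time shortcut was tried
first and rejected: it misplaces the in-transit mass and breaks the
closed-system equilibrium (`c → m_I/TBV` everywhere) by ~1% at low CO.

Extracellular/intracellular exchange and renal clearance are deliberately
omitted. Over a ≤60-s first-pass window, contrast stays essentially
intravascular; omitting exchange keeps the system closed, so total iodine is
a strict invariant (conserved to ~1e-13 relative in the integrator, tested
at 0.1%).

### Individualization

* Total blood volume from Nadler's formula (height in m, weight in kg):
  male `0.3669 h³ + 0.03219 w + 0.6041` L, female
  `0.3561 h³ + 0.03308 w + 0.1833` L.
* Body surface area: Du Bois by default (`0.007184 h_cm^0.725 w^0.425`),
  Mosteller selectable. BSA does not enter the model; it is carried as the
  covariate the evaluation stage analyses.
* Heart chambers: `V = k_h · CO/HR` each (k_h = 1), i.e. the stroke volume —
  tying cardiac transit time to the pulse.
* Volume fractions of TBV: arm vein 1.6%, central veins 4.5%, lungs 6%,
  aorta/arteries 4%, arm bed 2%, body bed 12%; the venous reservoir absorbs
  the remainder (~65–70%, matching the venous pooling of real circulation).
  The central-chain fractions were calibrated once so the mean-cohort
  subject (172.89 cm, 84.16 kg, pulse 59.24, CO 5.05 L/min) reproduces the
  clinical test-bolus summaries — TTP ≈ 18.3 s, peak enhancement in the
  170–195 HU band — and then frozen. All tables are configurable per build.

### Integration

Fixed-step RK4, dt = 0.05 s (bit-reproducible runs; halving dt moves the
aortic curve by <0.01% of peak). The pump profile is a rectangle with 0.2-s
smoothstep ramps whose integral equals the nominal volume exactly; smooth
edges are what let a fixed-step integrator keep the mass budget exact.
Concentrations below −1e-9 raise a solver error; smaller undershoots clamp
to zero.

## CO estimators

**TTP inversion (primary).** Simulated aortic TTP is strictly decreasing in
CO (asserted over CO = 2…12 L/min), so `TTP_sim(CO) = TTP_obs` is solved by
bisection on a (2, 12) L/min bracket to 0.01 L/min. Both TTPs are extracted
the same way — quadratic interpolation through the peak sample and its
neighbours, after resampling the simulation onto the data's own grid
(sampling interval and scan delay) so both share interpolation bias. A peak
on the first/last sample raises peak-not-captured; an observed TTP outside
the bracket's simulated range raises a bracket failure carrying both
endpoints. Bisection was chosen over secant/Newton because discrete
resampling makes TTP(CO) piecewise-smooth; bracketing is insensitive to
that.

**Joint least squares (secondary).** Minimises Σ(HU_sim − HU_obs)² over CO
and a blood-volume scale in [0.7, 1.3]×Nadler (bounded Nelder–Mead from the
TTP solution). On noiseless synthetic data it recovers both parameters to
<0.01%; on noisy data it offers no accuracy gain over TTP matching, which is
why it is shipped but not default. Flat curves return an unconverged flag
rather than raising.

**Stewart–Hamilton.** `CO = m_I / (AUC/κ)` with AUC from the gamma-variate
fit. The fit: baseline = mean of pre-onset samples (complete curves) or a
configured constant (start-clipped curves — deliberately imperfect, see
below); onset found by walking backward from the peak to the last sample
within 3·noise of baseline (robust to isolated baseline noise spikes, which
a forward first-crossing rule mistakes for arrival); first-pass window ends
before enhancement falls below 20% of peak on the downslope (recirculation
cutoff, configurable); arrival time t0 grid-searched over [onset−10 s,
onset] at 0.1 s; at each t0 the fit is linear least squares of ln y on
(ln(t−t0), t−t0) — the log-linearised gamma variate with free peak time —
keeping the best original-units SSE. The linearisation is exact on
noise-free model-class data (recovered α, y_max, t0 to ~1e-13). Noise SD
for onset detection comes from pre-onset samples when available, else 5 HU.

## Synthetic cohort generator

Emulates the clinical cohort and acquisition, not an idealised one:

* anthropometry and true CO from independent truncated normals at the
  pooled cohort marginals — height 172.89 ± 10.28 cm, weight 84.16 ± 19.83
  kg, pulse 59.24 ± 8.98 bpm, CO 5.05 ± 1.13 L/min; sex ratio 0.5
  (per-sex counts unpublished);
* TDC = forward simulation at the subject's true CO, resampled at 2 s,
  plus Gaussian ROI noise (default 10 HU, typical for an aortic ROI);
* per-subject baseline offset N(0, 7 HU): unenhanced blood-pool attenuation
  varies with haematocrit. This is the feature that makes start-clipping
  genuinely costly — an estimator that cannot measure the baseline must
  assume one, and the assumption is wrong by a subject-specific amount.
  Without it, the fallback baseline would be exactly right and clipping
  would (unrealistically) cost nothing;
* acquisition regimes: `complete` (sampled from t = 0), `clipped_start`
  (first image at the scan delay, default 12 s — typical test-bolus
  protocols trigger 10–15 s post injection to spare dose), `clipped_end` /
  `clipped_both` (scan window, default 40 s).

What the generator does **not** emulate: reference-method (MRI) measurement
error — the generated true CO plays the reference role directly; arrhythmia
and beta-blocker pharmacology; intra-scan pulse drift; ROI partial-volume
or motion artefacts beyond additive Gaussian noise; any real correlation
between CO and body size (a config switch could add one, the default keeps
them independent). Passing tests therefore demonstrate internal consistency
and the *direction* of the truncation effect, not clinical accuracy levels.

## Evaluation statistics

* Accuracy metric: relative difference `(CO_est − CO_ref)/CO_ref`.
* Pearson r with the conventional bins none/weak/moderate/strong/very
  strong at 0.3/0.5/0.7/0.9, boundaries assigned to the upper class.
* Summaries: mean, median, sample SD, two-sided t-interval
  `mean ± t_{0.975, n−1}·SD/√n`.
* Group contrasts: pooled-variance two-sample t with df = n₁+n₂−2. Pooled
  (not Welch) variance is used deliberately: it reproduces the published
  cohort table's sex-contrast intervals exactly at df = 35, so it is
  evidently the procedure that produced them.
* Normality: Lilliefors-corrected Kolmogorov–Smirnov (statsmodels),
  advisory only (mean-vs-median presentation).
* Stratification: rank-based n-tiles, label `ceil(rank·k/n)`, ties share
  their mean rank's label.
* Collinearity screen: iteratively drop the predictor with the highest
  VIF > 5 (ties: larger p), refit, then drop the largest p ≥ 0.05 until
  only significant, low-VIF predictors remain; singular designs fall back
  to pseudo-inverse auxiliary regressions with a warning. An empty final
  model is a valid outcome.

## Numerical and degenerate-input policy

Strictly increasing times, finite HU and non-negative scan delay are
enforced at curve construction. Peaks on curve edges, unreachable TTPs, <4
usable first-pass points, zero-variance correlation inputs, and k > n
stratifications all raise typed errors; the comparison experiment catches
per-subject estimator failures and reports them as counts, never silently.
Tie-breaks: argmax takes the first of equal maxima; a degenerate
three-point parabola falls back to the peak sample.

## Problem sizes

The shipped experiments use the sizes a desk-scale replication needs: the
truncation comparison runs 50 subjects × 2 regimes (the clinical cohort had
37 analysable patients), noiseless recovery uses 10 subjects, and
convergence/equilibrium checks use single runs at 40–600 s horizons.

## Known limitations

* The fraction table is a calibrated default, not a measured physiology;
  per-patient curve *shapes* beyond TTP/peak are not expected to match real
  data, and absolute dilution-method levels depend on an uncalibrated κ.
* The plug-flow transit ignores vessel compliance and pulsatility.
* The TTP inversion assumes the injection protocol and pulse are known and
  the peak is interior; it cannot rescue curves clipped past their peak.
* The least-squares variant inherits every structural error of the forward
  model; its blood-volume estimate is an effective parameter, not a
  measurement.
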