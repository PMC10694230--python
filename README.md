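# bolusco

Cardiac output (CO) estimation from the CT **test-bolus time–density curve
(TDC)** — the short series of aortic attenuation measurements (HU, sampled
every 2 s) that every coronary CT angiography acquires anyway to time its
main scan. Because attenuation is proportional to iodine concentration at
fixed tube voltage, that throwaway timing curve carries quantitative
information about how fast the heart moves blood, and this package turns it
into a CO estimate two independent ways:

1. **Individualized compartment model.** A closed, recirculating
   whole-body loop of blood compartments — arm vein (a plug-flow segment at
   the injection site) → central veins → right heart → lungs → left heart →
   aorta → parallel systemic beds → venous reservoir → back — with
   compartment volumes set from the patient's total blood volume (Nadler's
   height/weight/sex formula), heart chambers scaled to the stroke volume
   CO/HR, and flows proportional to CO. Well-mixed pools obey
   `V_i dc_i/dt = Σ_j Q_{j→i} c_j − Q_i c_i`; the arm segment is a pure
   piston delay. Inverting the model by matching the simulated to the
   observed **time to peak** (TTP is strictly decreasing in CO) yields
   `CO_Model`; a full-curve least-squares variant additionally adjusts the
   blood volume.
2. **Stewart–Hamilton indicator dilution.** `CO = m_I / ∫c(t)dt`: injected
   iodine mass over the concentration–time integral, with the first pass
   extrapolated past recirculation by a **gamma-variate fit**
   `y(t) = y_max u^α e^{α(1−u)}`, `u = (t−t0)/(t_max−t0)`, fitted by
   log-linear least squares over a grid of arrival times, and integrated in
   closed form: `AUC = y_max (t_max−t0) e^α Γ(α+1) / α^(α+1)`.

The scientific point the package demonstrates: the dilution method needs the
*whole* curve — when the scan delay clips the baseline segment, its accuracy
degrades — whereas the model-based TTP inversion only needs an interior
peak and is nearly unaffected. A seeded synthetic cohort generator
(anthropometry and true CO drawn from the clinical cohort's pooled
marginals; TDCs forward-simulated, noised and clipped like the real
acquisition) makes that comparison reproducible without any patient data.

## Worked example

```sh
$ python analysis/01_simulate_reference_curve.py
subject: 172.89 cm, 84.16 kg, TBV 5.21 L (Nadler), BSA 1.98 m2 (Du Bois)
time to peak  : 18.18 s
peak HU       : 170.0
```

The mean-cohort subject at CO 5.05 L/min peaks 18.2 s after injection start
at ~170 HU — matching where clinical test-bolus curves put their peak
(cohort mean TTP 18.3 s). Estimating CO back from a curve:

```sh
$ bolusco simulate --co 5 --height 180 --weight 80 --sex M --pulse 60 --out tdc.csv
wrote tdc.csv: TTP 18.59 s, peak 167.8 HU, TBV 5.32 L
$ bolusco estimate --method both --tdc tdc.csv --height 180 --weight 80 --sex M --pulse 60
{
  "compartment":      { "co_l_min": 5.003, ... },
  "stewart_hamilton": { "co_l_min": 4.856, ... }
}
```

The compartment inversion returns the generating CO to three digits; the
dilution estimate runs ~3% low because recirculating contrast leaks into
the first-pass window and inflates the fitted area.

The headline experiment (`analysis/03_truncation_experiment.py`, 50
subjects, 10-HU noise, seed 1337) prints:

```
          method        regime  n  r        r_class
 compartment_ttp clipped_start 50  0.941    very_strong
 compartment_ttp      complete 50  0.941    very_strong
stewart_hamilton clipped_start 50  0.833    strong
stewart_hamilton      complete 50  0.876    strong
```

i.e. clipping the curve start costs the Stewart–Hamilton estimator
correlation (0.876 → 0.833) and more than doubles its bias (−1.8% → −5.2%),
while the compartment estimator is untouched — it sees the same interior
peak either way.

## Layout

```
src/bolusco/       library: anthropometry, compartment (forward model),
                   estimation (TTP inversion + least squares),
                   stewart_hamilton, synthetic (cohort generator),
                   evaluation (statistics), io, config, cli
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    model, assumptions, parameter choices, limitations
```
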