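# willisflow

Personalized lumped-parameter (0D) simulation of circle-of-Willis
hemodynamics, calibrated per patient from routine bedside measurements:
CT-angiography vessel diameters, cuff blood pressure, and transcranial
Doppler (TCD) velocities.

**Who it is for.**  Researchers in computational physiology and
neurovascular medicine who want patient-specific cerebral blood-flow
estimates - including the communicating arteries that TCD cannot
insonate - for populations such as aneurysmal subarachnoid hemorrhage
(aSAH), where vasospasm makes one-size-fits-all boundary conditions
invalid, plus the statistical machinery to validate such a model against
TCD.

## The model in brief

The arterial tree is an electrical-analog network: 18 intracranial
segments (the circle of Willis) and 15 main-body segments, each a uniform
thin-walled tube with

    R = 128 mu l / (pi d^4)     L = 4 rho l / (pi d^2)     C = pi d^3 l / (4 E h)

where `d` is the volume-equivalent diameter `sqrt(sum d_i^2 l_i / sum l_i)`
of the measured points and a diameter of 0 marks an absent segment
(pruned from the graph).  A prescribed flow waveform drives the aortic
root; every outlet ends in a three-element Windkessel (WK3).  The system
is linear, so the solver advances it with exact matrix-exponential steps
to the steady periodic state (ten cardiac cycles by default) and
conserves volume to machine precision.

Calibration personalizes the boundary conditions in three steps:

1. **peripheral resistances** from mean TCD velocities and mean arterial
   pressure, on the linear DC circuit;
2. **systemic stiffness and peripheral compliance** from systolic and
   diastolic cuff pressure;
3. **cerebral stiffness** from the systolic/diastolic TCD envelope
   (pulsatility matching).

Agreement between measured and simulated velocities is quantified the way
such models are validated clinically: the intraclass correlation
coefficient ICC(C,1) (two-way random model, consistency, single rater)
with its exact F-based 95% CI, and base-10 logarithmic Bland-Altman
limits of agreement reported as multiplicative factors.  A virtual aSAH
cohort generator (anatomical variants, vasospastic narrowing, noisy
observations, ground-truth parameters) makes the entire chain testable
without patient data.

## Worked example

Generate one noise-free virtual patient, calibrate the model from its
"measurements", and compare against the known truth:

```python
from willisflow.cohort import CohortSpec, NoiseSpec, generate_patient, end_to_end_agreement

spec = CohortSpec(n_patients=1, seed=7, noise=NoiseSpec(velocity_sd=0.0, diameter_sd_mm=0.0))
patient = generate_patient(spec, 0)
result = end_to_end_agreement(spec)
calib = result.calibrations["P0000"]
```

which prints (see `docs/methods.md` for the quantities):

```
truth vs recovered (patient P0000, noise-free)
  systemic stiffness x0.996 -> x0.996
  systemic compliance x1.143 -> x1.143
  cerebral stiffness x1.057 -> x1.056
  worst terminal-resistance error: 0.07%
  BA     TCD   87.9 cm/s   simulated   87.8 cm/s
  L_ACA  TCD   58.5 cm/s   simulated   58.5 cm/s
  L_ICA  TCD   42.4 cm/s   simulated   42.4 cm/s
  L_MCA  TCD   54.8 cm/s   simulated   54.8 cm/s
  L_PCA  TCD   29.9 cm/s   simulated   29.9 cm/s
  R_ACA  TCD   61.9 cm/s   simulated   61.9 cm/s
  R_ICA  TCD   33.6 cm/s   simulated   33.6 cm/s
  R_MCA  TCD   44.5 cm/s   simulated   44.5 cm/s
  R_PCA  TCD   60.7 cm/s   simulated   60.6 cm/s
pooled ICC = 1.0000, LoA factors = (0.999, 1.000)
```

The stiffness/compliance multipliers and every WK3 resistance are
recovered from the synthetic measurements alone, and the simulated
velocities reproduce the "TCD" readings at all nine sites - including
the ICA and basilar sites, which the calibration never fits directly.
With realistic 10% velocity noise the same pipeline yields ICC ~ 0.98
and limits-of-agreement factors ~ (0.86, 1.17): agreement degrades at
the unfitted consistency sites first, exactly the structure a clinical
validation sees.

The same chain is available from the shell:

```sh
willisflow synth --n 20 --seed 1 --out cohort/
willisflow calibrate --geometry cohort/geometry.csv \
    --measurements cohort/measurements.csv --vitals cohort/vitals.csv \
    --out calib.json
willisflow validate --paired paired.csv --subgroup dci_like --out report.json
```

`simulate` runs the uncalibrated (area-proportional) model; file schemas
are plain CSV/JSON, documented in `src/willisflow/fileio.py`.

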