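# Methods

## The model

The cerebral circulation is represented as a lumped-parameter (0D)
electrical-analog network: 18 intracranial segments form the circle of
Willis (bilateral distal ICA, M1, A1, A2, PComA, P1, P2, intracranial
vertebral arteries, plus the ACoA and the basilar artery) and 15 main-body
segments (aorta, subclavian, carotid, extracranial ICA/vertebral, iliac)
carry the background circulation.  A prescribed flow waveform drives the
ascending-aorta root; each of the ten outlets (six cerebral territories,
two arms, two legs) ends in a three-element Windkessel (WK3).

Each segment is a uniform, thin-walled, homogeneous deformable tube whose
diameter is the *volume-equivalent* diameter of the measured points,
`d_eq = sqrt(sum(d_i^2 l_i)/sum(l_i))` (the root-mean-square for equal
sub-lengths; equal thirds by default, halves for the two-point basilar).
A measured diameter of 0 encodes an absent segment, which is removed from
the graph; if that disconnects a terminal from the inlet the build fails
with a named non-perfusable-territory error rather than silently
simulating an impossible anatomy.

The electrical analog per segment:

| element    | law                         | meaning                 |
|------------|-----------------------------|-------------------------|
| resistance | `R = 128 mu l / (pi d^4)`   | Hagen-Poiseuille        |
| inertance  | `L = 4 rho l / (pi d^2)`    | blood momentum          |
| compliance | `C = pi d^3 l / (4 E h)`    | thin-wall elastic tube  |

with wall thickness `h = 0.1 d` and Young's modulus `E = 0.4 MPa` before
calibration (the calibration re-fits the moduli, so these only seed it).
Blood: `mu = 3.5 mPa s`, `rho = 1060 kg/m^3`.

Half of each segment's compliance lumps onto each end node.  The wall is
viscoelastic (Voigt): a resistance `R_v = tau_w / C_n` sits in series with
each nodal compliance, `tau_w = 30 ms` by default.  Without it a pure RLC
ladder rings at weakly damped inertance-compliance modes (decay rates
around 0.2 1/s) and the periodic state is not reached within ten cardiac
cycles; with it the cardiac-frequency waveforms are essentially unchanged
while the non-physical ringing disappears.

The inflow template is a half-sine systolic ejection over 35% of the
cycle and zero diastolic flow, normalized so one period integrates to the
stroke volume (default 70 ml; period from the patient's heart rate).  Any
object with `flow(t)`, `heart_period` and `mean_flow` can be substituted.

## Solver

With fixed parameters the governing equations are linear and
time-invariant: one momentum balance per segment, one volume balance per
node, one per WK3 compartment.  The transient solver therefore propagates
the state with the *exact* matrix exponential of the augmented system over
each output step (default 200 samples/cycle), treating the inflow as
piecewise linear between samples.  This is exact for any stiffness - the
terminal R*C products span several orders of magnitude - and costs one
`expm` of an ~80x80 matrix per run plus one matrix-vector product per
sample.  States are rescaled (flows in ml/s, pressures in mmHg) before
exponentiation to keep the matrix well balanced.

Integration starts from the DC operating point (the resistive nodal solve
with inertances shorted and compliances open), so only the pulsatile
transient has to settle.  The run reports the relative L2 difference
between consecutive cycles' sampled states; convergence is declared below
1% (configurable), one further cycle is run, and runs are capped at ten
cycles by default.  Cycle statistics (mean, systolic max, diastolic min)
come from the final cycle only.

Two extra states accumulate inflow and terminal outflow volume, so the
volume audit (inflow minus outflow minus compliant storage change over the
final cycle) holds to machine precision by construction and doubles as an
assembly self-check.

The DC solve is also exposed on its own; it satisfies Kirchhoff's current
law at every node to ~1e-12 and is the mean-flow model used by
calibration step 1 (the mean of the periodic response of a linear system
equals the DC response to the mean inflow).

## Three-step calibration

Inputs: systolic/diastolic (optionally mean) cuff pressure, heart period,
and TCD velocities at up to nine sites; mean arterial pressure defaults to
`DBP + (SBP - DBP)/3`.  Velocities convert to segment flows through the
insonated segment's volume-equivalent cross-section, `Q = v pi d_eq^2/4`.

**Step 1 - peripheral resistances (DC).**  The MCA, ACA and PCA site
velocities each pin one terminal territory (the ICA and BA feed several
territories jointly and serve only as consistency checks); terminals
without an instrumented site receive an area-proportional share of the
remaining cardiac output, re-estimated every iteration because a site
(segment) flow differs from its terminal flow by whatever the
communicating arteries carry.  The fit is a damped Newton iteration on the
log total resistances with a finite-difference Jacobian (the communicating
shunts couple the terminals too strongly for a per-terminal update), with
the near-null "uniform pressure level" direction truncated and handled
instead by an exact anchor: adding `dP/Q_i` to every terminal resistance
raises all nodal pressures by `dP` without changing any flow, which pins
the aortic-root mean pressure to the measured MAP.  Implied resistances
are clipped to [1e6, 1e12] Pa s/m^3 and flagged.

**Step 2 - systemic stiffness and peripheral compliance.**  Two
multipliers - one on the main-body segments' Young's moduli, one on the
main-body terminal compliances - are fitted in log space (Powell-hybrid
root find) so the simulated aortic-root systolic and diastolic pressures
match the cuff values.  Resistances are untouched, so the mean pressure
stays anchored.

**Step 3 - cerebral stiffness.**  One multiplier `m` scales every cerebral
segment's Young's modulus by `m` and every cerebral terminal compliance by
`1/m`: the downstream bed is treated as stiffening together with its
conducting arteries.  (The segment compliances alone are two orders of
magnitude below the cerebral Windkessel compliances and would leave the
multiplier unidentifiable.)  The fit matches the flow pulsatility index
`PI = (Q_sys - Q_dia)/Q_mean` at the instrumented sites in the
least-squares sense - with the means fixed by step 1 this carries the same
information as the measured envelope, but remains stable when diastolic
flows approach zero.  The squared residual is scanned on a coarse log grid
and polished by bounded scalar minimization; a plain root find on the
signed residual is unreliable because carotid/vertebral inertance
resonances can give it spurious extra zeros.  In this model the site PI
*falls* as the cerebral bed stiffens (a stiffer bed stores less of the
systolic inrush upstream of the outlet), and the property tests assert
that direction.

Steps 2 and 3 are weakly coupled, so `calibrate()` runs a second 2-3 pass;
without it the uncalibrated cerebral bed biases the systemic compliance
multiplier by several percent.  The whole procedure is deterministic.
Tolerances: step 1 relative 1e-3, steps 2-3 relative 1e-2, multiplier
bounds [0.1, 10]; internal simulations run at 160 samples/cycle with a
1e-4 periodicity tolerance and a fixed-cycle cap of 40 so the objective
stays smooth for the optimizers.

If no systolic/diastolic velocities are supplied, step 3 is skipped with a
warning and the cerebral multiplier stays 1 (documented degradation).

## TCD observation model

Nine sites (bilateral distal ICA, MCA, ACA, PCA; basilar).  Velocity is
the lumen average `v = Q/A` of the mapped segment over the final cycle,
reported in cm/s.  The ACA site maps to the pre-communicating A1 segment
by default - the insonation is proximal, and the mapping is configurable
because the A1/A2 ambiguity is a known source of disagreement.  The PCA
site maps to P1, the ICA site to the distal (intracranial) ICA element.
No Doppler physics (insonation angle, spectral envelope) is modelled.

## Agreement statistics

Subjects are (investigation, site) observations; raters are TCD and the
simulation.  `icc_consistency` computes ICC(C,1) - two-way model,
consistency definition, single rater - from the explicit ANOVA sums of
squares, `(MS_S - MS_E)/(MS_S + MS_E)` for two raters, with the exact
F-based 95% CI.  It is deliberately not the Pearson shortcut (the two
agree only for balanced, bias-free tables; a regression test enforces
this).  `log_bland_altman` antilogs `10^(mean +/- 1.96 sd)` of the paired
base-10 log differences into multiplicative limits of agreement ("x%
below to y% above").  The paired-difference test is the Wilcoxon
signed-rank (exact null for n <= 25 without ties, normal approximation
with tie correction otherwise).  Subgroup comparisons report per-level
ICCs and whether the 95% CIs overlap - no overlap is the criterion for a
genuine rather than random subgroup difference.  Two-sided tests,
alpha = 0.05, no multiplicity correction.

## Synthetic cohort

The generator emulates the target population - aSAH patients between days
5 and 10, when vasospasm peaks - one patient per `SeedSequence([seed,
index])`:

* **Anatomy.**  Absence draws for ACoA (10%), each PComA (25%), each A1
  (5%), each P1 (15%) - literature-typical incompleteness rates; draws
  that disconnect a territory are rejected and redrawn, as is bilateral
  P1 absence (the basilar would dead-end because the network carries no
  cerebellar side branches).  Diameters scatter log-normally around the
  topology defaults (8% between patients, 5% within a segment).
  Vasospasm hits 60% of patients, narrowing 1-3 cerebral segments by
  20-50%.
* **Hemodynamic truth.**  Per-territory flow demands are sampled as
  area-proportional shares times a cerebral boost (1.5) times a
  log-normal scatter (sigma 0.25) - the hallmark of this population is
  peripheral resistance far from the conventional area-proportional
  allocation.  The linear DC model run forward on those demands yields
  *anatomy-consistent* site velocity targets (sampling site velocities
  independently is usually infeasible: with a permissive ACoA the
  junction pressures pin the anterior split).  Vasospastic sites show
  elevated velocities automatically - same flow, narrowed lumen.  Sites
  below a 10 cm/s detectability floor (vasospastic steal) go unreported.
  Step 1 run on these targets gives the truth terminals; sampled
  multipliers (systemic stiffness, systemic compliance, cerebral
  stiffness) complete the truth, and a forward simulation produces the
  noise-free observables, including aortic-root SBP/DBP for the vitals.
* **Observations.**  One log-normal gain per site scales the whole
  velocity envelope (an insonation-angle error is a common gain; default
  sigma 10%); diameters get additive Gaussian noise (0.1 mm) truncated
  above zero; absent segments stay exactly 0.
* **Labels.**  "DCI-like" marks patients whose cerebral resistances
  deviate most from the area-proportional allocation (log-deviation
  spread > 0.35) - a modelling convention to exercise the subgroup
  statistics, not a clinical claim.  Fisher-like grades and aneurysm
  location are sampled with frequencies typical of such cohorts.

What the generator does **not** emulate: beaded vasospastic geometry
(uniform tubes only), autoregulation, intracranial pressure, measured
stroke volume error (the vitals carry the true value), operator-dependent
site-localization error, and any real covariance between labels and
hemodynamics beyond the DCI-resistance convention.  Passing the synthetic
end-to-end checks therefore demonstrates internal consistency of the
pipeline - that the calibration recovers exactly the information the
observation model transmits - not clinical accuracy on real patients.

`end_to_end_agreement` calibrates every patient from its noisy
observations, simulates, extracts the nine site velocities, pairs them
with the noisy "TCD" values and pools the ICC and limits of agreement.
Noise-free, the pipeline is self-consistent to ICC > 0.999 and LoA
factors within [0.999, 1.001]; the ICC falls monotonically with velocity
noise (about 0.98 at the default 10% level).

## Numerical choices and degenerate inputs

* lstsq `rcond = 1e-3` in step 1 separates the anchored pressure-level
  mode from the flow fit; Newton steps are clipped at 1.5 in log space
  with a 4-point backtracking line search, and the MAP anchor shift is
  capped at a factor 2 per iteration so a transiently mis-allocated
  terminal cannot be driven to negative resistance.
* Transiently reversed site flows map to a floored log-residual (ratio
  clamped at 1e-3) rather than a domain error.
* Degenerate agreement tables (zero between-subject variance) return
  ICC 0 with a warning; all-zero paired differences return p = 1.
* CSV numerics are written with 17 significant digits and parsed with
  round-trip precision, so writer/reader pairs are lossless and repeated
  runs byte-identical.
* Problem sizes in the test suite: recovery on 20 noise-free patients;
  pooled agreement on a 50-patient noise-free cohort; the noise sweep on
  12-patient cohorts over three seeds - sizes chosen to estimate each
  statistic stably while keeping the suite quick on one CPU.

## Known limitations

* Lumped (0D) only: no wave propagation, no beaded within-segment
  geometry, no cerebellar/external-carotid side branches (the basilar
  especially inherits this simplification), no autoregulation.
* The anterior territory split is weakly identifiable from TCD when the
  ACoA is large-bore; the calibration then settles on the junction-
  pressure-consistent solution nearest the conventional allocation.
* Flow pulsatility indices of the model (~2-3) run above typical clinical
  TCD values (~1); the calibration matches relative envelope information,
  not absolute clinical PI.
* Stroke volume is rarely measured clinically; when absent the default
  70 ml makes absolute flows (not velocities' agreement structure)
  uncertain by the same factor.
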