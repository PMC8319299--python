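# Methods

## The binding models

### Direct titration (two species)

A fluorescently labelled ligand L (a 5-FAM methyl-lysine peptide at 40 nM,
or a fluorescein DNA hairpin at 5 nM) is held at a fixed total
concentration `L0` while the protein P is titrated in 2-fold serial
dilutions. The complex concentration at equilibrium follows from the mass
balances `P0 = [P] + [PL]`, `L0 = [L] + [PL]` and mass action
`K_L = [P][L]/[PL]`:

    [PL] = ((K_L + P0 + L0) − sqrt((K_L + P0 + L0)² − 4·P0·L0)) / 2

`titrofit` evaluates the algebraically equivalent subtraction-free form
`2·P0·L0 / (b + sqrt(b² − 4·P0·L0))`, which is stable when `[PL] ≪ b`
(the trace-probe regime). The observable is the anisotropy change

    ΔRobs = Δr · [PL] / ([PL] + [L]) = Δr · (bound fraction of probe),

where Δr is the anisotropy amplitude at probe saturation. Fitting `ΔRobs`
against the protein series yields `{K_L, Δr}`.

### Displacement titration (three species)

An unlabelled competitor N is titrated into a fixed mixture of protein
(10 µM) and labelled probe (40 nM). Free protein `[P]` is a root of the
monic cubic

    [P]³ + c2·[P]² + c1·[P] + c0 = 0
    c2 = K_L + K_N + N0 + L0 − P0
    c1 = K_L·K_N + K_N·L0 − K_N·P0 + K_L·N0 − K_L·P0     (dialect "complete")
    c0 = −K_L·K_N·P0

and the bound probe follows as `[PL] = L0·[P]/(K_L + [P])`. A second
coefficient *dialect*, `"paper"`, omits the `K_N·L0` term from `c1`; that
truncated form circulates in the displacement-titration literature. The two
dialects agree to well under 1% whenever the probe is trace-level
(`L0 ≲ 10⁻³ · min(K_L, K_N, P0)`, which holds at 40 nM probe against µM
constants), but only the complete form satisfies the ligand mass balance
exactly, so `complete` is the default everywhere and `paper` is available
for reproducing legacy fits.

**Root selection.** The physical root is the unique real root in
`[0, P0]` — uniqueness follows because the cubic equals the strictly
increasing mass-balance function
`f(P) = P + L0·P/(K_L+P) + N0·P/(K_N+P) − P0` times the positive factor
`(K_L+P)(K_N+P)`. All three roots are computed in closed form
(trigonometric branch for three real roots, a subtraction-free Cardano
branch otherwise), the candidate inside `[−tol, P0+tol]` is selected,
polished with Newton steps on the cubic and clamped to `[0, P0]`. When the
roots span many orders of magnitude (for instance an almost-inert
competitor with `K_N ~ 10⁹·K_L`) the closed form loses the small root to
cancellation; a residual check then triggers a vectorised bisection
fallback on `[0, P0]`, where the root is always bracketed. `oracle_solve`
solves `f(P) = 0` directly by Brent's method and never touches the cubic;
the two solvers agree to ≤1e-9 relative over randomized draws spanning six
concentration decades, which is the package's primary correctness check.

### Hill-type binding and enzyme kinetics

DNA, RNA and nucleosome titrations (fluorescence anisotropy or EMSA
fraction bound) are fitted with specific binding with a Hill slope,

    signal(x) = floor + (B_max − floor) · x^h / (K_d^h + x^h),

with the baseline fixed at 0 by default (the common "specific binding with
Hill slope" parameterization); `h` and `floor` can each be fixed or freed.
Methyltransferase substrate titrations are fitted with the
Michaelis–Menten model `v = Vmax·S/(K_M + S)`, `k_cat = Vmax/E0`, and the
catalytic efficiency `k_cat/K_M` is reported with a delta-method standard
error that uses the full `(Vmax, K_M)` covariance. `hill_signal` with
`h = 1` and `floor = 0` is formally identical to `mm_rate`, which the test
suite uses as a cross-check.

## Background correction in the kinetics assay

The luminescent (SAH-detection) readout requires two controls per
condition. The *no-substrate* control carries enzyme automethylation plus
spontaneous SAM-to-SAH conversion; the *no-enzyme* control carries the
spontaneous conversion alone. Only the no-substrate control is subtracted
from the reaction wells: the spontaneous term is present in both and
cancels, and subtracting both controls would remove it twice. The
no-enzyme control is reported as a QC quantity, with a warning when it
exceeds 20% of the no-substrate control. Substrate concentration is
counted per nucleosome core particle (octamer concentration), with no
per-H3-tail doubling. Velocities are reported in product per time when a
luminescence-to-product conversion factor is supplied, otherwise in signal
units per time with an explicit flag on `k_cat`.

Reaction linearity is checked on progress curves by finding the longest
initial time window whose least-squares line has `R² ≥ 0.98` and an
intercept within 2 standard errors of the first observed point. The paper
of record for this assay states the linearity *goal*; the numeric criterion
is this package's convention.

## Estimation and uncertainty

All fits are unweighted ordinary least squares (matching the default
behaviour of the commercial packages these analyses are usually run in),
with optional `1/y²`-style weighting behind a flag. Each dissociation
constant is started from 8 log-spaced guesses across
`[min(x)/10, max(x)·10]`; amplitudes start from the data range. The best
residual sum of squares wins, with near-ties (≤1e-9 relative) broken
toward the smaller K. A final polish pass uses a 3-point Jacobian with
explicitly relative finite-difference steps — important because the
parameters are molar-scale (1e-9–1e-4) and absolute default steps would
both stall the optimizer and corrupt the covariance. Residuals are
internally normalised by the data scale for the same reason; the
normalisation cancels in the covariance.

Standard errors are asymptotic (Wald) from the Jacobian at the optimum;
95% intervals use Student-t quantiles at `n − p` degrees of freedom. In
simulation these intervals cover the generating truth in ≈94% of seeded
replicates for the direct, displacement and Hill designs at 1% noise
(the package's calibration tests enforce 90–99%). A dissociation constant
whose upper 95% bound exceeds 100× the largest titrant concentration is
flagged `"not determined"`: the data support only a lower bound on K in
that case, and the point estimate should not be quoted. A `K_M` more than
5× above the largest substrate concentration is flagged as extrapolated;
one below 1/100 of the smallest is flagged non-identifiable (saturation
everywhere).

Anisotropy fitting always uses unnormalised, background-subtracted ΔRobs.
For plotting-style normalisation the convention here is to divide by the
fitted Δr of the no-competitor condition; this is a package convention, as
published displacement figures typically plot "normalised anisotropy"
without documenting the exact normalisation. Δr is refit per displacement
curve rather than shared across peptides.

## The synthetic-data generator

`titrofit.synthetic` emulates the assay designs the analysis assumes:
2-fold serial dilutions, 3 replicates, additive homoscedastic Gaussian
noise on the observable (consistent with the OLS objective), and
deterministic output given `(preset, seed)`. Shipped presets:

* **Direct**: 40 nM labelled peptide probe, 12-point protein series from
  100 µM, truth `K_L = 8.07 µM`, `Δr = 0.1`, noise 1% of Δr.
* **Displacement panel**: 10 µM protein + 40 nM probe, 12-point competitor
  series, truths `K_N ∈ {7.49, 19.0, 241, 41.7, 7.59, 8.81} µM` spanning
  the measured methyl-lysine peptide affinities, plus an inert
  (unmethylated-peptide) scenario. Strong binders titrate from 400 µM; the
  two weak scenarios (41.7 and 241 µM) from 1000 µM so the series reaches
  a few multiples of K_N — the design choice a bench scientist would make
  for a weak binder.
* **Hill**: 5 nM probe; DNA scenarios (K_d 155 and 73.7 nM, h = 1,
  anisotropy amplitude 0.15) and EMSA nucleosome scenarios (K_d 2560,
  48.5, 330, 17.1 nM, h = 1.5, fraction bound), 1% noise. Hill
  coefficients and amplitudes are package choices: the source affinities
  were published with Hill slopes in figure tables not reproduced here.
* **Kinetics**: E0 = 15 nM, 2 h endpoint, 8-point substrate series from
  2000 nM, truths `K_M ∈ {224, 392} nM`, `k_cat = 0.1 min⁻¹` (a package
  choice on the order of PRC2-class methyltransferase turnover; the
  published k_cat values live in a figure table not reproduced here),
  automethylation and spontaneous backgrounds at 5% and 2% of the
  saturating signal, noise 2% of the saturating signal.

What the generator deliberately does **not** emulate: heteroscedastic or
correlated noise, plate/day batch effects, pipetting error on the
dilution series, probe depletion artefacts, or gel-image densitometry
noise structure. Passing round-trip tests therefore demonstrates that the
estimators are correct and well calibrated *under the stated noise model*,
not that real titrations will achieve the same precision.

## Numerical conventions and degenerate inputs

* All internal computation is in molar; the I/O layer converts from the
  unit declared once per file (`M`, `mM`, `uM`/`µM`, `nM`, `pM`) and the
  CLI reports constants back in the declared unit. Fitted constants are
  invariant (≤1e-6 relative) to the declared unit.
* `K_L` or `K_N` of exactly 0 is rejected (use a small positive floor for
  effectively irreversible binding); `P0 = L0 = N0 = 0` returns the
  all-zero state rather than erroring.
* Blank (probe-only) wells are averaged and subtracted at load time;
  negative corrected signals are allowed and logged.
* Problem sizes in the test suite — 100-seed recovery panels, 200-seed
  calibration runs, 1000-draw oracle-equivalence sweeps — were chosen to
  give stable pass/fail behaviour at a few minutes of total runtime.

## Known limitations

* No tight-binding (quadratic-depletion) Hill variant: at probe
  concentrations approaching K_d the Hill fit's K_d is an apparent value.
* No global fitting across datasets, no Bayesian posteriors, no outlier
  handling.
* Wald intervals undercover mildly (~94% at nominal 95%) for strongly
  curved likelihoods; profile-likelihood intervals are not implemented.
* The kinetics layer models initial velocities only — no mechanism-level
  (bi-substrate, product-inhibition) modelling, and no modelling of the
  allosteric-stimulation dose response beyond the occupancy-saturation
  consistency check in the acceptance tests.
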