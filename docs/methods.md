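# Methods

## Model

The culture is described by three balances over the retentostat phase
(time t = 0 at the switch from chemostat outflow to full cell
retention):

* feed program (stirred mixing vessel of volume V_S fed at ɸ_V):
  dC_S,in/dt = (ɸ_V/V_S)(C_S,MR − C_S,in), hence
  C_S,in(t) = (C_S,MC − C_S,MR)·e^(−t/τ) + C_S,MR with τ = V_S/ɸ_V;
* viable biomass: dC_X_V/dt = (µ − k_d)·C_X_V;
* dead biomass: dC_X_d/dt = k_d·C_X_V.

Substrate uptake follows the Pirt law q_S = µ/Y_X/S^max + m_S
(+ q_P/Y_P/S^max; the product term is carried through the code but the
cultures modelled here form no product, so it is never estimated).
Residual glucose is orders of magnitude below the feed concentration
in these cultures (tens of µM against g/L), so the substrate balance
is closed by the pseudo-steady assumption dC_S/dt ≈ 0, giving
q_S = D·C_S,in(t)/C_X_V with dilution rate D = ɸ_V/V. Dead biomass is
retained by the filter, counts toward measured dry weight, and neither
consumes substrate nor lyses.

With these assumptions the viable-biomass balance becomes linear,

    dC_X_V/dt = Y·D·C_S,in(t) − a·C_X_V,    a = Y·m_S + k_d,

and has the closed form C_X_V(t) = C_∞ + A·e^(−a·t) + B·e^(−t/τ) with
C_∞ = Y·D·C_S,MR/a, B = Y·D·(C_S,MC − C_S,MR)/(a − 1/τ) and
A = C_X_V(0) − C_∞ − B (verified by substitution into the balance;
dead biomass follows by analytic integration of k_d·C_X_V). The
resonant case a = 1/τ is excluded from the closed form and routed to
the numerical integrator. The closed form doubles as an independent
oracle for the general integrator, which evaluates the model in its
own terms (q_S from the feed balance, µ from the Pirt law) rather than
the simplified linear form; the two agree to below 10⁻⁶ relative error
across randomized parameter draws.

Asymptotics: C_X_V → Y·D·C_S,MR/(Y·m_S + k_d) and µ → k_d (zero
without death): the feed ultimately covers exactly maintenance plus
the replacement of dying cells. A negative µ anywhere on a trajectory
marks glucose starvation (uptake below maintenance demand) and raises
a flag; if viable biomass is driven to zero the integration aborts
with a starvation-collapse error.

The chemostat phase that precedes the switch is initialized at its
steady state (µ = D exactly; death is neglected there because
k_d ≪ D = 0.025 h⁻¹), giving C_X(0) = D·C_S,MC/(D/Y + m_S).

## Parameters and units

Canonical internal units are grams, litres and hours. Millimoles enter
only at conversion boundaries through the glucose molar mass
(180.16 g mol⁻¹).

| parameter | default | meaning |
|---|---|---|
| Y_X/S^max | 0.5 g g⁻¹ | maximum biomass yield on glucose (chemostat-derived literature value; fixed in fits by default) |
| m_S | 0.011 g gX⁻¹ h⁻¹ | design-stage maintenance guess, translated from the anaerobic estimate (0.5 mmol gX⁻¹ h⁻¹) at equal ATP turnover |
| V, V_S, ɸ_V | 1.4 L, 1.2 L, 0.035 L h⁻¹ | culture volume, mixing-vessel volume, medium flow (D = 0.025 h⁻¹) |
| C_S,MC → C_S,MR | 20 → 7.5 g L⁻¹ | feed glucose before/after the switch |
| k_d | 4.7·10⁻⁴ h⁻¹ | generator default death rate |
| ATP yields | 2 / 16 mol mol⁻¹ | fermentative / respiratory glucose dissimilation; the respiratory value is a plain parameter (2 × the eightfold ratio at P/O = 1.0), not derived from a finer biochemical decomposition |

The maintenance ATP turnover is m_ATP = ATP-yield × m_S expressed in
mmol glucose gX⁻¹ h⁻¹. The report against an anaerobic reference
states the computed percentage difference without rounding it to a
headline figure.

## Design criteria

A candidate feed regime passes when, over an m_S uncertainty band of
±10 %: (i) µ(336 h) < 0.001 h⁻¹ at the central m_S; (ii) µ ≥ 0
throughout for every m_S in the band; (iii) the asymptote-to-initial
biomass fold change is at least 2 (the threshold quantifies "a
sizeable biomass increase", which has no canonical number; the chosen
regime predicts ≈ 2.1); (iv) criteria (ii) and (v) hold across the
band — criterion (i) is judged centrally because its low-band edge is
inherently marginal and would make every regime fail; (v) the analytic
asymptote (conservative: biomass approaches it from below) stays below
30 g L⁻¹ for every m_S in the band. Criterion thresholds are monotone:
tightening any of them can only turn passes into failures. The report
also records the µ ratio across the band at a 480-h horizon as an m_S
sensitivity measure.

## Estimation

Viable biomass is defined as PI (membrane-integrity) viability × dry
weight; CFU viability is carried as a diagnostic only, since plating
can under-count cells that are intact but no longer divide. The fit
minimizes the sum of squared residuals of model total biomass against
measured dry weight **and** model viable biomass against measured
viable biomass, over (m_S, k_d), with the initial state pinned at the
chemostat steady state. Channels are weighted by their declared
measurement-error scales when available, equally otherwise (both are
in g L⁻¹, so equal weighting is the neutral choice). Each replicate
culture is fitted separately; cross-replicate aggregation is a
reporting layer, not a pooled model.

The optimizer is a bounded trust-region least-squares started from the
best point of a coarse 8 × 6 grid (m_S log-spaced over
(10⁻⁴, 0.05] g gX⁻¹ h⁻¹, k_d linear over [0, 10⁻²] h⁻¹) to avoid local
minima; estimates pinned at a bound are flagged. Inside the fit the
model is evaluated through the closed form (with automatic fallback to
the integrator near the resonant combination), while the synthetic
generators use the numerical integrator — generator and fitter do not
share the trajectory code path, so closed-loop recovery tests are a
genuine cross-check. On noiseless data the generating (m_S, k_d) is
recovered to optimizer precision; at the declared noise model (5 %
dry-weight CV, 10,000-cell binomial viability counts, 14 sampling
times over 480 h) m_S is recovered within ±10 % in ≥ 95 of 100 seeded
replicates.

Uncertainty: residual-resampling bootstrap (per-channel residuals
resampled with replacement, refit, percentile intervals; default 200
resamples, seeded). More than 20 % refit failures invalidates the
interval. A slope-based k_d diagnostic — regressing observed dead
biomass on the trapezoid-integrated viable biomass through the origin,
which is exact under the model — is provided for comparison with the
joint fit.

## Synthetic data

The generators emulate: multiplicative Gaussian dry-weight error (5 %
CV; dry-weight assays are precise to a few percent), binomial PI
viability from a 10,000-cell count, Poisson CFU counting around an
expectation of 150 colonies with an additional reproductive-loss
factor of 0.85 applied to the PI-viable fraction (membrane-intact
cells that no longer divide; the factor reproduces a ~70 % CFU versus
~85 % PI gap after 20 days), Gaussian assay noise on ethanol
concentrations, a logistic-in-time heat-shock survival truth crossing
50 % exactly at t₅₀, a linear ethanol accumulation consistent with the
70-mL assay volume, and a 13-array expression design (triplicate
chemostats at 0.025 h⁻¹ plus two 5-point retentostat series) with
log-normal baselines, monotone growth-rate responders (default 600 up
and 775 down of 6383 genes) and ~10 % replicate CV. Sampling defaults
to daily for the first five days, then every 48 h to 480 h.

What the generators do **not** emulate — and hence what passing tests
do not establish about real data: sampling-induced volume loss,
filter fouling, slow drifts in feed composition, flow-cytometry gating
artefacts, correlated (batch) measurement error, probe-level
microarray effects, and any growth-rate dependence of m_S itself (the
model assumes it constant, which is the hypothesis the experiment
tests rather than a property the generator can confirm).

## Assays

t₅₀ is the time at which the fitted 4PL curve reaches half of its
fitted initial value — not the midpoint parameter, which coincides
only when the bottom plateau is 0 and the top equals the initial
fraction. The constrained fit (bottom = 0, default) encodes a fully
lethal exposure; a free-bottom variant handles resistant
subpopulations. Curves that do not decrease, or whose fitted lower
plateau exceeds half the initial value, raise an explicit error;
crossings outside the sampled range are flagged as extrapolated. The
estimator is equivariant under time rescaling.

Fermentative capacity regresses ethanol *amount* (concentration ×
assay volume, so sample-addition dilutions can be handled explicitly)
on time over the first 30 min, scaled by the biomass in the assay;
negative slopes clip to zero with a warning, and the glucose
equivalent is half the ethanol rate. Results are invariant to the
declared ethanol unit (mM vs g L⁻¹, molar mass 46.07 g mol⁻¹).

## Omics

Preprocessing order is scale (per-array mean to 240) → floor (12) →
filter (across-array gene mean < 20 discarded; "average below 20 for
all arrays" is read as the mean over all arrays, matching the
companion clause of the rule) → optional per-gene average
normalization for display. The composition is idempotent. The
enrichment background defaults to the post-filter gene universe, with
the full ORF list available as an option. The hypergeometric upper
tail is accumulated in log space (logsumexp over log-pmf terms) and
Bonferroni-corrected over the categories tested; it matches exhaustive
enumeration on all small universes. The growth-rate classifier —
per-gene Spearman correlation with a seeded permutation p-value — is a
deliberately simple, clearly labelled stand-in for dedicated
differential-expression and consensus-clustering machinery, adequate
for planted-truth recovery but not a reimplementation of those tools.

## Numerical choices and problem sizes

ODE integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ on a uniform
1-h output grid (the system stiffens near starvation); these
tolerances sit far below the 10⁻⁶ oracle-agreement threshold.
Long-run quantities are simulated to ≥ 4000 h, several times the
slowest time constant 1/(Y·m_S) ≈ 182 h. The Monte-Carlo recovery
check uses 100 seeded replicates; unit tests use 30. Bootstrap
defaults to 200 resamples (100 in tests). The full-size expression
recovery check runs at 6383 × 13 with vectorized rank correlations;
most omics unit tests use a few hundred genes. The permutation
p-value uses the add-one estimator, so its resolution is
1/(n_permutations + 1).

## Known limitations

* The model has no Monod residual-substrate kinetics; regimes whose
  residual glucose is not negligible against the feed would violate
  the pseudo-steady closure.
* m_S and Y_X/S^max are not jointly identifiable from a single
  decelerating trajectory; co-estimation exists as an opt-in flag but
  is discouraged.
* The design screen assumes full viability; a substantial death rate
  shifts the biomass plateau upward relative to the k_d = 0
  prediction.
* Growth-rate predictions at day 20 are acutely sensitive to m_S: the
  ±10 % band spans roughly a sevenfold range of µ(480 h) under the
  chosen regime (and the upper band edge of a ±20 % band already
  predicts starvation). The design report exposes the computed ratio
  rather than asserting a particular figure.
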