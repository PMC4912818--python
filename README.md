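# retentostat

Growth energetics of *Saccharomyces cerevisiae* at near-zero specific
growth rates, for quantitative physiologists running (or planning)
glucose-limited retentostat cultures.

A retentostat is a chemostat whose effluent passes a cell-retention
filter: the medium supply stays constant while biomass accumulates, so
the glucose available per cell falls and the specific growth rate µ
drifts towards zero. In that regime almost all substrate is spent on
cellular maintenance, which makes the retentostat the most direct way
to measure the maintenance coefficient m_S and its ATP equivalent
m_ATP — parameters that dominate yields in slow-growing industrial
fed-batch processes.

The package implements the full quantitative workflow around such an
experiment:

* **Model** — the (extended) Pirt resource-allocation law
  q_S = µ/Y_X/S^max + m_S + q_P/Y_P/S^max, with conversions between
  glucose units and ATP turnover (respiration yields eightfold more ATP
  per glucose than alcoholic fermentation at a P/O ratio of 1.0).
* **Simulation** — retentostat dynamics with a mixing-vessel feed
  program C_S,in(t) = (C_S,MC − C_S,MR)·e^(−ɸ_V t/V_S) + C_S,MR under a
  pseudo-steady residual-substrate assumption, as a stiff-capable
  numerical integrator plus an independent closed-form oracle.
* **Design** — screening of candidate feed regimes against five
  operational criteria (near-zero growth within a deadline, no
  starvation, sizeable biomass increase, robustness across an m_S
  uncertainty band, final biomass below the filter-clogging limit).
* **Estimation** — scikit-learn-style least-squares recovery of
  (m_S, k_d) from dry-weight and viability time series, with
  residual-resampling bootstrap intervals and conversion to m_ATP.
* **Assays** — heat-shock survival t₅₀ (four-parameter logistic) and
  fermentative capacity (ethanol slope per gram biomass).
* **Omics** — expression-matrix preprocessing (array scaling, signal
  flooring, low-expression filtering), growth-rate correlation
  classification, and hypergeometric gene-set overrepresentation with
  Bonferroni correction.
* **Synthetic data** — seeded generators for every input above, with
  the generating truth returned alongside, so the entire pipeline is
  testable in closed loop.

## Worked example

Generate a synthetic 20-day retentostat run at the experimentally
motivated truth (m_S = 0.00703 g gX⁻¹ h⁻¹ ≙ 0.039 mmol gX⁻¹ h⁻¹,
k_d = 4.7·10⁻⁴ h⁻¹), then recover the parameters:

```sh
$ retentostat synth retentostat --seed 11 --out obs.tsv
wrote obs.tsv and obs.truth.json
$ retentostat fit --obs obs.tsv --out fit.json
m_S = 0.00694 g/gX/h (0.0385 mmol/gX/h), k_d = 4.73e-04 /h, m_ATP = 0.616 mmol/gX/h
```

The fitted m_S lands within ~1 % of the generating truth despite 5 %
dry-weight noise and binomial viability counting; the maintenance ATP
turnover m_ATP = 16 × m_S(mmol) ≈ 0.62 mmol ATP gX⁻¹ h⁻¹ is ~38 %
below the anaerobic reference of 1.0 mmol ATP gX⁻¹ h⁻¹ (0.5 mmol
glucose fermented at 2 ATP/glucose).

Scanning the three candidate feed regimes selects the gentle step-down
to 7.5 g/L — 20 g/L overshoots the 30 g/L biomass cap, 5 g/L starves
the culture:

```sh
$ retentostat design --scan 20,7.5,5 --out design.tsv
wrote design.tsv; passing C_S,MR regimes: [7.5]
```

The same operations are available as a library:

```python
from retentostat import (PirtParameters, STUDY_CONFIG, simulate_retentostat,
                         asymptotic_state)

params = PirtParameters(y_xs_max=0.5, m_s=0.011)
traj = simulate_retentostat(STUDY_CONFIG, params, t_end=336.0)
print(traj.mu[-1])                                    # 0.000117 1/h at day 14
print(asymptotic_state(STUDY_CONFIG, params).c_x_v_inf)  # 17.05 g/L plateau
```

## Layout

```
src/retentostat/
  pirt.py       Pirt law, ATP stoichiometry, unit conversions
  simulate.py   reactor config, ODE integrator, closed-form oracle
  design.py     five-criterion feed-regime evaluation and scan
  estimate.py   (m_S, k_d) least squares, bootstrap, m_ATP report
  synthetic.py  seeded generators for all pipeline inputs
  assays.py     viability, heat-shock t50, fermentative capacity
  omics.py      preprocessing, enrichment, growth-rate classifier
  io.py, cli.py tables/config I/O and the `retentostat` CLI
```

See `docs/methods.md` for the model derivation, parameter defaults and
numerical choices.
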