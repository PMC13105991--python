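# ricerisk

Deterministic and probabilistic dietary risk assessment of heavy metals and
metalloids in rice, built around the Nanning (Guangxi, China) food-safety
surveillance analysis: four elements (Pb, Cd, inorganic As, total Hg)
measured in rice and paddy samples, a resident dietary survey, and a
Monte Carlo propagation of cadmium exposure.

It is written for exposure-assessment practitioners and epidemiologists who
need the standard USEPA-style risk chain as tested, scriptable code rather
than spreadsheet or point-and-click workflows.

## The model

For a contaminant with concentration *C* (mg/kg) in rice, daily rice intake
*IR* (kg/day) and body weight *BW* (kg):

    ADD = C · IR / BW                      average daily dose, mg/(kg·day)
    THQ = ADD / RfD                        target hazard quotient (THQ ≥ 1 flags concern)
    HI  = Σ THQ                            hazard index across elements
    CR  = ADD · SF,   CCR = Σ CR           (cumulative) carcinogenic risk,
                                           bands at 10⁻⁶ and 10⁻⁴
    EMI = ADD · (ED·EF/AT) · 30 · 1000     estimated monthly intake, µg/(kg BW·month),
                                           compared with the JECFA PTMI (25 for Cd)

The probabilistic layer replaces the point values with distributions —
cadmium concentration as a shifted lognormal parameterised by arithmetic
mean/SD and a location shift, intake as Triangular(min, mode, max) — and
propagates them by Latin Hypercube Sampling (one draw per equal-probability
stratum per variable), yielding the THQ distribution, P(THQ ≥ 1), and a
tornado-style sensitivity ranking of the inputs. Distribution choice is
supported by maximum-likelihood fits of candidate families ranked by AIC
with Kolmogorov–Smirnov, Anderson–Darling and chi-square diagnostics.

Surveillance-side utilities cover left-censored data (half-LOD
substitution), detection/exceedance rates, rice-vs-paddy 2×2 chi-square
comparisons, stratified percentiles, and per-county township exceedance
counts. A seeded synthetic-data generator emulates the study's marginal
statistics so the whole pipeline runs without the (undeposited) raw data.

## Worked example

```python
from ricerisk import (ExposureScenario, shifted_lognormal, simulate_thq,
                      triangular, compute_thq, compute_hi, rank_inputs)

# deterministic block: published doses and reference doses
thqs = {el: compute_thq(add, rfd) for el, (add, rfd) in
        {"Cd": (0.000449, 0.0005), "Pb": (0.000146, 0.0014),
         "Hg": (0.0000273, 0.0003), "iAs": (0.0000108, 0.0003)}.items()}
print({k: round(v, 3) for k, v in thqs.items()},
      "HI =", round(compute_hi(list(thqs.values())), 2))

# probabilistic block: cadmium THQ under the fitted input distributions
scenario = ExposureScenario(
    concentration=shifted_lognormal(0.16781, 0.27126, -0.0015274),  # mg/kg
    intake_g_day=triangular(121.63, 231.56, 308.42),                # g/day
    bw=60.0, rfd=0.001, n_iterations=5000, seed=1)
mc = simulate_thq(scenario)
print("mean THQ:", round(mc.mean, 3))
print("P(THQ >= 1):", round(mc.exceedance_probability, 3))

sens = rank_inputs({"Cd concentration": mc.c_draws,
                    "rice intake": mc.ir_draws}, mc.thq_draws)
for r in sens:
    print(f"rank {r.rank}: {r.name}  swing={r.swing:.3f}  rho={r.spearman_rho:.2f}")
```

prints

```
{'Cd': 0.898, 'Pb': 0.104, 'Hg': 0.091, 'iAs': 0.036} HI = 1.13
mean THQ: 0.612
P(THQ >= 1): 0.162
rank 1: Cd concentration  swing=2.678  rho=0.99
rank 2: rice intake  swing=0.366  rho=0.16
```

Cadmium alone nearly reaches the THQ threshold and the four elements
together exceed it (HI = 1.13); the simulation says the *average* resident
is below threshold (mean THQ ≈ 0.61) but roughly one in six simulated
exposures is not, and the concentration of cadmium in rice — not how much
rice people eat — drives that risk.

A full pipeline run (synthetic data → summaries → deterministic block →
fitting → Monte Carlo → sensitivity → `report.json`):

```sh
ricerisk run-all --seed 1 --out out/
```

Single stages are available as `ricerisk synth|summarize|fit|simulate|sensitivity`.

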