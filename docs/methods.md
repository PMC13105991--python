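# Methods

## Exposure model

The package implements the ingestion-route risk chain used in Chinese
food-safety surveillance and USEPA guidance. For each element, the average
daily dose is ADD = C·IR/BW with C the concentration in raw rice (mg/kg),
IR the daily raw-rice-equivalent intake (kg/day) and BW body weight (kg).
Non-carcinogenic risk is the hazard quotient THQ = ADD/RfD, summed into a
hazard index HI across co-occurring elements; THQ or HI at or above 1 flags
potential concern, not predicted disease. Carcinogenic risk is CR = ADD·SF
with the cumulative CCR = ΣCR banded as low (< 10⁻⁶), potential
(10⁻⁶–10⁻⁴, closed interval — the source wording makes both edges
inclusive) and high (> 10⁻⁴). Long-term cadmium exposure is additionally
expressed as an estimated monthly intake EMI and compared with the JECFA
provisional tolerable monthly intake of 25 µg/(kg BW·month); EMI/PTMI is
itself a hazard quotient, and the stratified county × age × sex hazard
tables are exactly this ratio.

As printed, the EMI formula ADD·(ED·EF/AT) is a *daily* dose (the
duration factor ED·EF/AT is dimensionless and equals 1 for lifetime
exposure). Reaching the µg-per-month scale of the published tables requires
two conversion constants, 30 days/month and 1000 µg/mg, which are stored
explicitly in `EmiSettings` rather than folded silently into the formula.

### Body weight and the cadmium reference dose

The surveillance reports never state the body weight they used, and their
deterministic and probabilistic cadmium results are mutually consistent
only under different conventions: the point assessment implies BW ≈ 64 kg
(0.124 mg/kg × 0.23156 kg/day / 0.000449 mg/(kg·day)) with the tabulated
RfD of 0.0005 mg/(kg·day), while the Monte Carlo mean THQ of 0.610 is
recovered only with BW = 60 kg and RfD = 0.001 mg/(kg·day)
(closed form: 0.16628 × 0.22054 / 0.06 = 0.611). Rather than privileging
one reading, both appear as named presets — `deterministic-2020`
(64 kg, `table1` RfDs) and `mc-2020` (60 kg, `mc` RfD variant) — and every
risk operation takes BW and the dose threshold explicitly. The toxicology
fixture stores the cadmium dose thresholds side by side (0.0005, 0.001,
and the PTMI of 25 ≡ 0.833 µg/(kg·day)).

One published carcinogenic-risk value is not arithmetically recoverable:
the lead CR of 1.24×10⁻⁶ does not equal its printed ADD (0.000227) times
its SF (0.0085) = 1.93×10⁻⁶. The package exposes the formula and does not
attempt to reconcile the printed number; the iAs CR (1.63×10⁻⁵ vs
1.08×10⁻⁵ × 1.5 = 1.62×10⁻⁵) is consistent with an unrounded dose.

## Surveillance summaries

Left-censored measurements (below the analytical LOD) are substituted at
LOD/2, the standard practice for dietary exposure data; substitution can
never create a regulatory exceedance because LOD/2 is far below every
limit. "Detection" means the measurement was at or above the LOD;
"exceedance" is strictly above the limit (the criteria are stated as
"> 0.2 mg/kg"). Rice-vs-paddy exceedance comparisons use the *uncorrected*
Pearson chi-square on the 2×2 table — verified to reproduce all five
published statistics to 2 dp — with Yates correction available behind a
flag but never default. Stratified percentiles use linear interpolation
between order statistics (the common spreadsheet/statistical default);
the convention matters for small townships and is therefore explicit.
Two published LOD sets conflict (e.g. Pb 0.0040 vs < 0.050 mg/kg); the
fixture carries the analytical-method LODs as primary and the
surveillance-table values as an alternate column. Published
concentration means ± SDs are reported by the code but not used as
regression anchors, because their provenance (which censoring treatment,
which sample subset) is not recoverable.

## Distribution fitting

The cadmium concentration model is a three-parameter (shifted) lognormal,
X = τ + exp(N(µ_log, σ_log²)), parameterised in the risk-software
convention by the arithmetic mean m and SD s of the lognormal part plus
the shift τ. Conversion is exact: σ² = ln(1+(s/m)²), µ = ln m − σ²/2.
For the published cadmium parameters (m = 0.16781, s = 0.27126,
τ = −0.0015274 mg/kg) this gives µ = −2.4272, σ = 1.1334 and a median
τ + e^µ = 0.0868 mg/kg, within 5% of the observed overall P50 of 0.09.

Joint MLE of the shift is ill-conditioned, so the shift is profiled:
conditional on τ, the MLEs are µ = mean(ln(x−τ)), σ = sd(ln(x−τ)); the
profile likelihood is scanned on a 101-point grid over
(−s_sample, min(x) − ε), ε = 10⁻⁶ × range, then refined by bounded 1-D
optimisation, with a moment-matching fallback (logged) if the profile is
flat. Triangular fits put the endpoints at the sample extremes expanded by
range/(n−1) per side (raw extremes are biased inward); the mode is the
bounded 1-D MLE. Candidate families for AIC ranking (2k − 2 log L, ties
broken alphabetically) default to normal, lognormal, shifted lognormal,
gamma and triangular; families whose support excludes the data are
skipped. Goodness of fit reports the KS statistic, the standard
Anderson–Darling A² on probability-integral-transformed values, and a
chi-square over k = max(5, ⌈n/50⌉) equal-probability bins under the fitted
CDF, all with parameters treated as known — the statistics are
comparative diagnostics, not calibrated p-values.

## Monte Carlo engine

Sampling is Latin Hypercube: for each input, one uniform position per
equal-probability stratum [(i−1)/n, i/n) (random-within-stratum by
default; midpoint mode for deterministic tests), mapped through the
analytic inverse CDF and randomly permuted. Independent permutations make
the concentration–intake pairing random, i.e. the inputs are independent —
matching how they were fitted — with an optional normal-copula
(Iman–Conover-style) reordering to impose a target Spearman correlation.
Because τ < 0, the concentration support dips marginally below zero;
draws below zero (analytically ≈ 0.017% of the mass) are truncated at 0
and counted in the result. The default run is 5,000 iterations; THQ per
iteration is C·IR/(BW·RfD) with intake converted from g/day once.
Results carry the draw vectors, mean, SD, P5–P95, P(THQ ≥ 1) (threshold
inclusive), the 95% CI half-width of the mean, and the seed;
fixed seed ⇒ bit-identical output.

## Sensitivity analysis

The tornado measure is the conditional-mean swing: input draws are split
into 10 equal-count quantile bins (configurable; ties assigned stably by
draw index) and the swing is max − min of the conditional output means.
Depending only on input ranks, it is invariant under monotone transforms
of the input. Spearman rank correlation is reported alongside because the
swing alone cannot sign a relationship; ranking uses the swing. For the
cadmium scenario the concentration CV (≈ 1.62) dwarfs the intake CV
(≈ 0.17), so both measures place concentration first by a wide margin.

## Synthetic data

The raw datasets (1,844 rice samples 2014–2020; 538 samples 2019–2020;
524 survey participants) are not deposited, so the generator reproduces
the *marginal* published facts, not any joint structure. Cadmium draws
from the published shifted lognormal. Pb, iAs and Hg use lognormals solved
in closed form from two tail constraints each — P(X ≥ LOD) = the published
detection rate and P(X > limit) = the published exceedance rate — at the
LODs the rates were reported against. The published cadmium exceedance
rate (16.36%, 2019–2020 subset) and the 2014–2020 distribution fit (tail
above 0.2 mg/kg ≈ 23.3%) are not simultaneously satisfiable; the
distribution wins because it is what the probabilistic assessment
propagates, and tests check generated exceedance counts against the
analytic tail of the configured law, not against the subset rate. Layout
mirrors the sampling frame: 15 districts × 5 townships, with optional
county-level multiplicative hotspot shifts (defaults in the counties where
elevated cadmium was observed) and a paddy fraction of 180/538. Intake
draws from Triangular(121.63, 231.56, 308.42) g/day (mean ≈ 220.5). Body
weight is normal(60, 10) kg truncated below 30 kg by redrawing — a
synthetic-only choice, since no body-weight distribution was published.
The generators do not emulate spatial autocorrelation beyond county
shifts, year effects, or analytical measurement error; passing tests
therefore demonstrate pipeline correctness under the published marginals,
not recovery of the real joint exposure surface.

## Numerical choices and problem sizes

Uniform positions feeding inverse CDFs are clipped to [10⁻¹², 1−10⁻¹²] to
keep open-interval quantile functions finite. Degenerate inputs raise
typed errors (all-identical fit data, empty THQ lists, zero expected
chi-square cells, constant sensitivity inputs). Display rounding is 3
significant figures for risks and 2 dp for hazard quotients; full
precision is always retained. Test problem sizes were chosen so the whole
suite runs in seconds on one core: 2×10⁵ draws for shifted-lognormal
parameter recovery (m within 2%, s within 4%), 10⁶ plain-MC draws as the
oracle for the LHS exceedance estimate, 200 replicates × 200 draws for the
LHS-vs-plain-MC variance comparison, and 5,000-sample synthetic
surveillance tables.

## Known limitations

Single-pathway (rice only) exposure; no dermal/inhalation routes, no
age-dependent toxicokinetics, no multi-food accumulation. One-dimensional
Monte Carlo only (variability and uncertainty are not separated). The
carcinogenic block is deterministic — the probabilistic layer covers
cadmium THQ only, as in the source analysis. Censoring is handled by
substitution, not by censoring-aware likelihoods. GOF statistics are not
re-calibrated for estimated parameters.
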