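# Methods

## Data model

All tables are long-format with a fixed stratum convention: dataset
(country, region or neighbour), calendar year, sex (male/female), site
group, and 18 five-year age bands (0–4 … 80–84, 85+). Inputs with a
19-band axis (85–89/90+) are collapsed into 85+ with a warning. A
missing stratum means zero cases, not missing data, so sparse extracts
are valid. Rates are per 100 000 person-years throughout; person-years
are mid-year population × 1 year.

Sites are the standard ICD-10 rubric groups of registry comparison
tables (21 male, 23 female including "Other and unspecified"); the
grouping partitions C00–C97 except non-melanoma skin (C44), which is
dropped by convention. Unspecified uterus (C55) is a staging group:
before estimation its counts are reallocated to cervix (C53) and corpus
(C54) in proportion to their recorded counts within the same (dataset,
year, age) cell, falling back to dataset-level proportions when the cell
has neither, and finally to a 50/50 split with a warning. The fallback
hierarchy is this package's choice — the convention in the field fixes
only the proportional-reallocation idea — and is designed to be
deterministic and to conserve the uterine total exactly per cell.
Counts become reals after reallocation; estimates are rounded to whole
cases (half away from zero) only at report time.

## Projection engines

**Age–period–cohort (method 1A and the mortality projection).** Data are
binned into 5-year × 5-year age–period grids. Expected counts follow the
Nordic projection tradition (the NORDPRED program family):

    E[count(a, p)] = PY(a, p) · (α_a + δ·p + π_p + γ_c)^5 / 10^5

fitted by Poisson maximum likelihood. δ is the common drift per 5-year
period; the residual period effects π and cohort effects γ are
constrained to zero sum *and* zero slope. (A sum-to-zero constraint
alone leaves the linear component of π confounded with δ; detrending
both residual effects is the standard identification and the one used
here.) Cells with a negative linear predictor are floored at 0 with a
warning, as the power-5 link needs a non-negative base. Age rows with no
events in the whole window are excluded and projected as rate 0.

Fitting starts from the null model (age-specific pooled rates, no
trend) and is deterministic: an L-BFGS pass followed by Newton polishing
with analytic gradient and curvature, converged when the gradient
falls below `tol` × total count (default tol 1e-8, max 100 polish
iterations; non-convergence raises with diagnostics). The drift standard
error comes from the observed information matrix and is used only for
diagnostics.

Projection carries the last period effect forward, continues each age's
cohort (cohorts beyond the last estimated one take the last estimated
value) and attenuates the drift by the "cut trend" schedule: the drift
increments for prediction periods 1–4 are multiplied by 1.00, 0.75,
0.50, 0.25 (0%, 25%, 50%, 75% cuts), extended with the last value
beyond four periods. All of these are configurable arguments. The
projected 2008–2012 period rate is used as the 2010 annual rate (period
midpoint), matching the pairing of a 2008–2012 projection with 2010
estimates.

**Age-linear trend (method 1B).** Per age group, expected count =
PY · max(0, a + b·t)/10^5 with t in years centred on the fit-window
midpoint, fitted by Poisson maximum likelihood (identity-style trend in
the rate). This is the simplest model consistent with projecting ten
years of data a few years ahead; the program it emulates (DEPPRED) has
no published internals. Projected rates are floored at 0. All-zero age
rows fit as (0, 0).

**Sparsity fallback.** A (sex, site) with fewer than 50 events in the
fit window (configurable) is too sparse for trend fitting and falls
back to window-average rates — method-2 behaviour — with a warning.

**Mortality projection.** Methods 3–5 need target-year national
mortality. It is produced by the same APC engine (default attenuation)
on the 1988–2007 window projected to 2008–2012, with the same sparse
fallback. Whether the reference implementations used the identical
engine for mortality is not documented; the engine and windows are
arguments, so a simpler trend model can be substituted.

## Estimators 2–9

Rate transport always pools counts and person-years (person-year
weighting), never averages country- or region-level rates. M:I ratios
are age-specific, pooled over the proxy datasets for 2003–2007; sites
with fewer than 100 average annual national deaths (the configurable
pooling threshold, motivated by rare-death sites with ~13 deaths a
year) add neighbouring countries to the pool. Age groups with zero
pooled incidence merge into the adjacent younger group until the
denominator is positive; age groups whose merged cell still has zero
deaths *borrow* the ratio of the nearest death-bearing (preferably
older) cell rather than pooling into it — pooling would dilute that
cell's case fatality with young cases and destabilise the inversion.
The inversion is applied on rates (ratio applied per age to the
projected mortality rate), one of two equivalent-only-with-matching-
populations conventions; zero-mortality strata yield zero estimated
incidence, which is the documented rare-death failure mode, and a zero
ratio against positive mortality raises.

Method 5 inverts M = I(1 − S) with sex-site-level 5-year relative
survival (the granularity of the survival extracts), capping S at 0.99
so values at or above 1 cannot blow up the division; capped sites are
flagged as unreliable. Method 8 computes site frequencies per sex only
(an age-banded variant would be a straightforward extension) and
partitions the all-sites transported total, conserving it exactly.
Method 4's M:I reference period defaults to 2003–2007 to parallel
method 3 (the neighbour-rate methods 8 and 9 use 2009–2011).

The selection rule returns the first applicable method in the priority
order 1 → 2 → 3 → 4 → 5 → 6/7 → 8 → 9, with 6 vs 7 decided by whether
one or several regional registries exist.

## Validation arithmetic

Estimates and observed values are rounded to whole cases; diff =
estimated − observed per (sex, site); underestimated and overestimated
cases are totalled separately and their sum Σ|diff| is the aggregate
absolute difference, reported as 100·Σ|diff| / Σ observed rounded half
away from zero to one decimal. This "aggregate percentage" convention
was verified against the published summary (834/14507 → 5.7%); it is
*not* the mean of per-site percentages. Per-site percentages with
observed = 0 are reported as undefined. Combined-sex reports concatenate
the per-site rows and recompute all totals, so aggregate absolute
differences are additive across sexes.

The package ships the published Norway-2010 validation counts (observed
and ten method columns for 21 male and 23 female site groups) as a
text fixture with an integrity hash. Percentages are always recomputed
from the counts; three cells whose printed percentage disagrees with the
recomputed one (e.g. female head-and-neck, method 2: printed −3.3 vs
recomputed −13.3) are flagged as printed-value typos with the counts
taken as authoritative.

## Synthetic registry generator

The generator emulates the structure of a Nordic registry extract:
regions with population shares and rate multipliers, neighbours with
population scales and rate perturbations, years 1983–2012, a linearly
declining age pyramid with 0.5%/year growth, and Poisson counts around
log-linear expected rates. The age curve is a two-parameter
log-quadratic in the age-band midpoint — enough to produce realistic
age gradients without external data. Expected deaths are tied to
expected incidence by M = I(1 − S) per stratum; two sanctioned
departures exist for scenario design: a late-mortality factor (deaths
beyond 5-year follow-up, making the reported 5-year survival overstate
cure) and an age-varying survival profile (cure at young ages, excess
death at old ages) whose aggregate differs from the reported scalar.
Randomness uses one global seed with substreams spawned in fixed order,
so a seed reproduces a bundle bit for bit.

Preset scenarios target the documented failure modes: `stable` (flat
trends — every method should land within a few percent), `screening_bump`
(steep rise then plateau — long-term projection overshoots),
`rare_death` (high survival, a handful of deaths at ages carrying no
incidence — mortality-based methods underestimate), `good_prognosis`
(late mortality — survival inversion overestimates), `urban_rural`
(strong regional multipliers — regional proxies inherit the bias).
Magnitudes are not calibrated to any real country; the scenarios are
qualitative testbeds. Default national population is 5 million;
acceptance checks of the `stable` scenario use 20 million so Poisson
noise is small against the 5% band, and the replicate-based directional
checks trim scenarios to the site under test to keep 200 replicates
fast.

## What the tests do and do not show

Passing tests show the estimators implement their definitions exactly
(self-consistency identities hold to machine precision), the engines
recover known parameters (1e-4 on noise-free grids, drift within 3
standard errors in ≥95% of 200 Poisson replicates), and the directional
failure modes reproduce on the synthetic scenarios in ≥95% of
replicates. They do not show how any method performs on a real country:
the generator has no registration incompleteness, no cause-of-death
misclassification, no migration, and its trends and survival are
exactly the generative model's. The published-counts layer validates
the comparison arithmetic against real published numbers but takes the
published estimates themselves as given.

## Known limitations

- No uncertainty intervals on estimates (point estimates only, as in
  the framework being modelled); no age-standardised rates; no
  ICD-9/ICD-O conversion; no Bayesian APC or joinpoint detection.
- The APC engine's recent-drift variant (basing projected drift on the
  last two periods) is not implemented; attenuation is the only trend
  damping.
- Survival is sex-site level; age-specific survival enters only the
  synthetic generator's mortality link.
- The M:I ratio-borrowing rule for zero-death cells is this package's
  stabilisation; reference implementations do not document their exact
  handling.
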