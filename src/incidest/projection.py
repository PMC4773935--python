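"""Rate-projection engines for trend-based incidence estimation.

Two engines are provided, mirroring the two projection flavours used for
national estimates from historical registry data:

* an age-period-cohort (APC) model on 5-year age x 5-year period grids
  with the power-5 link of the Nordic projection tradition (NORDPRED):
  expected count = person_years x (alpha_a + delta*p + pi_p + gamma_c)^5 / 1e5,
  fitted by Poisson maximum likelihood. ``delta`` is the common linear
  drift per 5-year period; ``pi`` (period) and ``gamma`` (cohort) residual
  effects are constrained to zero sum and zero slope, which makes the
  decomposition identifiable. Projections carry the last period effect
  forward, continue each age's cohort (clamping beyond the last estimated
  cohort) and attenuate the drift by a "cut trend" schedule
  (by default the full drift in the first prediction period, then 75%,
  50% and 25%) to avoid unrealistic long-range extrapolation.

* a medium-term age-specific linear trend: per age group, expected
  count = person_years x max(0, a + b*t) / 1e5 with ``t`` in calendar
  years centred on the fit-window midpoint, fitted by Poisson maximum
  likelihood.

Both fits are deterministic: no random initialization (the APC fit starts
from the null, age-only model) and all optimization is quasi-Newton with a
Newton polish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tables import (
    PER,
    EstimateTable,
    EventTable,
    PopulationTable,
    RateTable,
    ValidationError,
    pooled_rates,
)
from .sites import N_AGE_GROUPS

DEFAULT_ATTENUATION = (1.0, 0.75, 0.50, 0.25)
#: Below this many events in the whole fit window a (sex, site) is too
#: sparse for trend fitting and falls back to window-average rates.
DEFAULT_SPARSITY_THRESHOLD = 50.0


class ConvergenceError(RuntimeError):
    """Raised when an engine fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class PeriodGrid:
    """Counts and person-years on an age-group x 5-year-period grid."""

    counts: np.ndarray  # (n_ages, n_periods)
    person_years: np.ndarray  # same shape, positive where counts can occur
    periods: list[tuple[int, int]]  # ordered, contiguous, 5 years wide

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.counts.shape != self.person_years.shape:
            raise ValidationError("counts and person_years grids are not congruent")
        if self.counts.shape[1] != len(self.periods):
            raise ValidationError("period labels do not match grid width")
        for (a0, a1), (b0, b1) in zip(self.periods, self.periods[1:]):
            if b0 != a1 + 1:
                raise ValidationError("periods must be contiguous")
        if any(hi - lo != 4 for lo, hi in self.periods):
            raise ValidationError("periods must be 5 years wide")
        if (self.counts < 0).any():
            raise ValidationError("negative counts in period grid")

    @property
    def n_ages(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]


def aggregate_to_periods(
    events: EventTable,
    population: PopulationTable,
    window: tuple[int, int],
    *,
    sex: str,
    site: str,
    dataset: str | None = None,
) -> PeriodGrid:
    """Bin one (dataset, sex, site)'s annual data into 5-year periods.

    The window length must be divisible by 5 (no partial final bin).
    """
    lo, hi = window
    n_years = hi - lo + 1
    if n_years <= 0 or n_years % 5 != 0:
        raise ValidationError(f"window {window} is not a whole number of 5-year periods")
    ev = events.subset(years=window, sexes=[sex], sites=[site]).data
    pop = population.subset(years=window).data
    pop = pop[pop["sex"] == sex]
    if dataset is not None:
        ev = ev[ev["dataset"] == dataset]
        pop = pop[pop["dataset"] == dataset]
    if pop.empty:
        raise ValidationError("no person-years in projection window")
    periods = [(lo + 5 * i, lo + 5 * i + 4) for i in range(n_years // 5)]
    period_of = lambda y: (y - lo) // 5  # noqa: E731
    counts = np.zeros((N_AGE_GROUPS, len(periods)))
    py = np.zeros_like(counts)
    for _, r in ev.iterrows():
        counts[int(r["age_group"]), period_of(int(r["year"]))] += r["count"]
    for _, r in pop.iterrows():
        py[int(r["age_group"]), period_of(int(r["year"]))] += r["person_years"]
    return PeriodGrid(counts, py, periods)


@dataclass
class APCFit:
    """Fitted APC decomposition on the 5th-root-of-rate scale."""

    age_effects: np.ndarray  # (n_ages,) alpha_a; NaN for all-zero ages excluded from fit
    drift: float  # delta, per 5-year period
    period_effects: np.ndarray  # (n_periods,), zero sum and zero slope
    cohort_effects: dict[int, float]  # synthetic cohort index -> gamma, zero sum/slope
    link_power: float
    converged: bool
    drift_se: float
    n_iter: int
    ages_included: np.ndarray  # bool mask of fitted age rows

    def linear_predictor(self, age: int, period: int) -> float:
        """eta at an estimated grid position (period may exceed the grid)."""
        if not self.ages_included[age]:
            return 0.0
        c = (N_AGE_GROUPS - 1 - age) + period
        cmax = max(self.cohort_effects)
        gamma = self.cohort_effects.get(c, self.cohort_effects[min(c, cmax)])
        n_periods = len(self.period_effects)
        pi = self.period_effects[min(period, n_periods - 1)]
        return float(self.age_effects[age] + self.drift * period + pi + gamma)

    def fitted_rates(self) -> np.ndarray:
        """(n_ages, n_periods) fitted rates per 100 000."""
        P = len(self.period_effects)
        out = np.zeros((len(self.age_effects), P))
        for a in range(len(self.age_effects)):
            for p in range(P):
                out[a, p] = max(self.linear_predictor(a, p), 0.0) ** self.link_power
        return out


def _detrended_basis(n: int) -> np.ndarray:
    """Basis for vectors of length n orthogonal to the constant and trend."""
    if n < 3:
        return np.zeros((n, 0))
    x = np.arange(n, dtype=float)
    constraints = np.vstack([np.ones(n), x - x.mean()])
    return linalg.null_space(constraints)


def _power_nll_parts(theta, X, y, n_over, power, eps=1e-9):
    """Poisson nll, gradient and curvature weights for mu = n (eta)^k / 1e5."""
    eta = X @ theta
    eta_c = np.maximum(eta, eps)
    mu = n_over * eta_c**power
    mu = np.maximum(mu, 1e-300)
    nll = float(np.sum(mu - y * np.log(mu)))
    dmu = np.where(eta > eps, n_over * power * eta_c ** (power - 1), 0.0)
    d2mu = np.where(eta > eps, n_over * power * (power - 1) * eta_c ** (power - 2), 0.0)
    g_eta = (1.0 - y / mu) * dmu
    w = (1.0 - y / mu) * d2mu + (y / mu**2) * dmu**2
    return nll, X.T @ g_eta, w, eta


def fit_apc_power5(
    grid: PeriodGrid,
    *,
    link_power: float = 5.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> APCFit:
    """Fit the power-link APC model to a period grid by Poisson ML.

    Requires at least 3 periods. Age rows with zero counts in every period
    are excluded (their fitted and projected rates are 0). Deterministic:
    the optimizer starts from the null model (age-specific average rates,
    no drift, no period/cohort effects).
    """
    A_all, P = grid.counts.shape
    if P < 3:
        raise ValidationError("APC fit requires at least 3 periods")
    included = grid.counts.sum(axis=1) > 0
    ages = np.flatnonzero(included)
    if len(ages) == 0:
        return APCFit(
            np.full(A_all, np.nan), 0.0, np.zeros(P), {0: 0.0}, link_power, True, 0.0, 0, included
        )
    A = len(ages)

    cohorts = sorted({(N_AGE_GROUPS - 1 - a) + p for a in ages for p in range(P)})
    c_index = {c: i for i, c in enumerate(cohorts)}
    C = len(cohorts)
    Bp = _detrended_basis(P)
    Bc = _detrended_basis(C)

    cells = [(ai, a, p) for ai, a in enumerate(ages) for p in range(P) if grid.person_years[a, p] > 0]
    y = np.array([grid.counts[a, p] for _, a, p in cells])
    n_over = np.array([grid.person_years[a, p] / PER for _, a, p in cells])

    n_par = A + 1 + Bp.shape[1] + Bc.shape[1]
    X = np.zeros((len(cells), n_par))
    for r, (ai, a, p) in enumerate(cells):
        X[r, ai] = 1.0
        X[r, A] = float(p)
        X[r, A + 1 : A + 1 + Bp.shape[1]] = Bp[p]
        c = c_index[(N_AGE_GROUPS - 1 - a) + p]
        X[r, A + 1 + Bp.shape[1] :] = Bc[c]

    # null-model start: age-specific pooled rates, no trend
    theta0 = np.zeros(n_par)
    for ai, a in enumerate(ages):
        pooled = grid.counts[a].sum() / max(grid.person_years[a].sum(), 1e-300) * PER
        theta0[ai] = max(pooled, 1e-6) ** (1.0 / link_power)

    obj = lambda th: _power_nll_parts(th, X, y, n_over, link_power)[:2]  # noqa: E731
    res = optimize.minimize(
        obj, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": max(200, 4 * max_iter), "ftol": 1e-14, "gtol": 1e-10},
    )
    theta = res.x
    scale = max(1.0, float(y.sum()))
    n_newton = 0
    grad_norm = np.inf
    for n_newton in range(1, max_iter + 1):
        nll, grad, w, eta = _power_nll_parts(theta, X, y, n_over, link_power)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm <= tol * scale:
            break
        H = (X * w[:, None]).T @ X + 1e-10 * scale * np.eye(n_par)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the nll
        t = 1.0
        for _ in range(30):
            cand = theta - t * step
            if _power_nll_parts(cand, X, y, n_over, link_power)[0] <= nll:
                theta = cand
                break
            t *= 0.5
        else:
            break
    nll, grad, w, eta = _power_nll_parts(theta, X, y, n_over, link_power)
    grad_norm = float(np.max(np.abs(grad)))
    converged = grad_norm <= max(tol * scale, 1e-4)
    if not converged:
        raise ConvergenceError(
            f"APC fit did not converge (|grad|={grad_norm:.3g})",
            {"grad_norm": grad_norm, "nll": nll, "iterations": n_newton, "n_cells": len(cells)},
        )
    if (eta <= 0).any():
        warnings.warn(
            "negative linear predictor in APC fit floored at 0 (power link requires "
            "a non-negative base)",
            stacklevel=2,
        )

    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H + 1e-12 * scale * np.eye(n_par))
        drift_se = float(np.sqrt(max(cov[A, A], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        drift_se = float("nan")

    alpha = np.full(A_all, np.nan)
    alpha[ages] = theta[:A]
    pi = Bp @ theta[A + 1 : A + 1 + Bp.shape[1]] if Bp.shape[1] else np.zeros(P)
    gamma_vec = Bc @ theta[A + 1 + Bp.shape[1] :] if Bc.shape[1] else np.zeros(C)
    gamma = {c: float(gamma_vec[i]) for c, i in c_index.items()}
    return APCFit(alpha, float(theta[A]), pi, gamma, link_power, True, drift_se, n_newton, included)


def project_apc(
    fit: APCFit,
    grid: PeriodGrid,
    n_ahead: int = 1,
    attenuation: tuple[float, ...] = DEFAULT_ATTENUATION,
) -> np.ndarray:
    """Project rates ``n_ahead`` 5-year periods past the grid.

    Returns an (n_ages, n_ahead) array of rates per 100 000. The drift
    increment of prediction period k is ``drift * attenuation[k-1]``
    (the schedule is extended with its last value beyond its length);
    the last period effect is carried forward and cohorts beyond the last
    estimated one take the last estimated cohort's value. Rates are
    floored at 0.
    """
    if n_ahead < 1:
        raise ValidationError("n_ahead must be >= 1")
    P = grid.n_periods
    sched = list(attenuation) + [attenuation[-1]] * max(0, n_ahead - len(attenuation))
    out = np.zeros((grid.n_ages, n_ahead))
    for k in range(1, n_ahead + 1):
        cut = float(np.sum(sched[:k]))
        for a in range(grid.n_ages):
            if not fit.ages_included[a]:
                continue
            base = fit.linear_predictor(a, P - 1 + k) - fit.drift * (P - 1 + k)
            eta = base + fit.drift * (P - 1) + fit.drift * cut
            out[a, k - 1] = max(eta, 0.0) ** fit.link_power
    return out


@dataclass
class AgeLinearFit:
    """Per-age-group linear rate trends (rate per 100 000 per year)."""

    intercepts: np.ndarray  # (n_ages,) rate at the window midpoint
    slopes: np.ndarray  # (n_ages,) rate change per year
    midpoint: float  # calendar-year centre of the fit window

    def predict(self, year: int | float) -> np.ndarray:
        """Projected rates for a calendar year, floored at 0."""
        t = float(year) - self.midpoint
        return np.maximum(self.intercepts + self.slopes * t, 0.0)


def fit_age_linear(
    events: EventTable,
    population: PopulationTable,
    window: tuple[int, int] = (1998, 2007),
    *,
    sex: str,
    site: str,
    dataset: str | None = None,
    tol: float = 1e-10,
) -> AgeLinearFit:
    """Fit per-age linear rate trends by Poisson ML over annual data.

    Expected count(t) = person_years(t) x max(0, a + b t)/1e5 with t
    centred at the window midpoint. Requires >= 5 years of data; all-zero
    age rows get a = b = 0.
    """
    lo, hi = window
    if hi - lo + 1 < 5:
        raise ValidationError("age-linear fit requires at least 5 years of data")
    ev = events.subset(years=window, sexes=[sex], sites=[site]).data
    pop = population.subset(years=window).data
    pop = pop[pop["sex"] == sex]
    if dataset is not None:
        ev = ev[ev["dataset"] == dataset]
        pop = pop[pop["dataset"] == dataset]
    if pop.empty:
        raise ValidationError("no person-years in fit window")
    mid = (lo + hi) / 2.0
    intercepts = np.zeros(N_AGE_GROUPS)
    slopes = np.zeros(N_AGE_GROUPS)
    pop_g = pop.groupby(["age_group", "year"])["person_years"].sum()
    ev_g = ev.groupby(["age_group", "year"])["count"].sum()
    for a in range(N_AGE_GROUPS):
        years = sorted(pop_g.loc[a].index) if a in pop_g.index.get_level_values(0) else []
        if not years:
            continue
        t = np.array(years, dtype=float) - mid
        n_over = np.array([pop_g.loc[(a, yr)] for yr in years]) / PER
        y = np.array([ev_g.get((a, yr), 0.0) for yr in years], dtype=float)
        if y.sum() == 0:
            continue
        X = np.column_stack([np.ones_like(t), t])
        theta0 = np.array([y.sum() / n_over.sum(), 0.0])
        obj = lambda th: _power_nll_parts(th, X, y, n_over, 1.0)[:2]  # noqa: E731
        res = optimize.minimize(
            obj, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-15, "gtol": tol},
        )
        intercepts[a], slopes[a] = res.x
    return AgeLinearFit(intercepts, slopes, mid)


# ---------------------------------------------------------------------------
# estimate-producing wrappers


def _sites_by_sex(events: EventTable):
    return events.data.groupby("sex")["site"].unique().to_dict()


def _window_average_estimate(events, population, window, target_year, sex, site):
    """Fallback for sparse sites: transport window-average rates."""
    rates = pooled_rates(
        events.subset(sexes=[sex], sites=[site]), population, datasets=None, years=window
    )
    dataset = population.data["dataset"].iloc[0]
    est = apply_rates_to_target(rates, population, dataset, target_year)
    return est


def apply_rates_to_target(rates: RateTable, population: PopulationTable, dataset, year) -> pd.DataFrame:
    """Expected cases per (sex, site, age_group) for one population-year."""
    pop = population.data
    pop = pop[(pop["dataset"] == dataset) & (pop["year"] == year)]
    if pop.empty:
        raise ValidationError(f"population has no ({dataset}, {year}) strata")
    merged = rates.data.merge(pop[["sex", "age_group", "person_years"]], on=["sex", "age_group"], how="left")
    if merged["person_years"].isna().any():
        row = merged[merged["person_years"].isna()].iloc[0]
        raise ValidationError(
            f"target population missing stratum ({row['sex']}, age_group={row['age_group']})"
        )
    merged["cases"] = merged["rate"] * merged["person_years"] / PER
    return merged[["sex", "site", "age_group", "cases"]]


def _projection_estimate(
    incidence: EventTable,
    population: PopulationTable,
    *,
    method: str,
    fit_window: tuple[int, int],
    target_year: int,
    engine: str,
    attenuation: tuple[float, ...] = DEFAULT_ATTENUATION,
    sparsity_threshold: float = DEFAULT_SPARSITY_THRESHOLD,
) -> EstimateTable:
    dataset = population.data["dataset"].iloc[0]
    details = []
    for sex, sites in _sites_by_sex(incidence.subset(years=fit_window)).items():
        for site in sorted(sites):
            sub = incidence.subset(years=fit_window, sexes=[sex], sites=[site])
            if sub.total() < sparsity_threshold:
                logger_msg = f"sparse site ({sex}, {site}): falling back to window-average rates"
                warnings.warn(logger_msg, stacklevel=2)
                det = _window_average_estimate(
                    incidence, population, fit_window, target_year, sex, site
                )
                details.append(det)
                continue
            if engine == "apc":
                grid = aggregate_to_periods(sub, population, fit_window, sex=sex, site=site)
                fit = fit_apc_power5(grid)
                n_ahead = (target_year - fit_window[1] - 1) // 5 + 1
                proj = project_apc(fit, grid, n_ahead=n_ahead, attenuation=attenuation)
                rates = pd.DataFrame(
                    {
                        "sex": sex,
                        "site": site,
                        "age_group": np.arange(N_AGE_GROUPS),
                        "rate": proj[:, -1],
                    }
                )
            else:
                fit = fit_age_linear(sub, population, fit_window, sex=sex, site=site)
                rates = pd.DataFrame(
                    {
                        "sex": sex,
                        "site": site,
                        "age_group": np.arange(N_AGE_GROUPS),
                        "rate": fit.predict(target_year),
                    }
                )
            det = apply_rates_to_target(RateTable(rates), population, dataset, target_year)
            details.append(det)
    detail = pd.concat(details, ignore_index=True)
    return EstimateTable.from_detail(method, target_year, detail)


def method_1a(
    incidence: EventTable,
    population: PopulationTable,
    fit_window: tuple[int, int] = (1983, 2007),
    target_year: int = 2010,
    *,
    attenuation: tuple[float, ...] = DEFAULT_ATTENUATION,
    sparsity_threshold: float = DEFAULT_SPARSITY_THRESHOLD,
) -> EstimateTable:
    """Long-term projection: APC power-5 model per (sex, site).

    Fits 5x5 grids over the fit window (default 1983-2007, five periods),
    projects to the 5-year period containing the target year and applies
    the projected period rates to the target-year population.
    """
    return _projection_estimate(
        incidence,
        population,
        method="1A",
        fit_window=fit_window,
        target_year=target_year,
        engine="apc",
        attenuation=attenuation,
        sparsity_threshold=sparsity_threshold,
    )


def method_1b(
    incidence: EventTable,
    population: PopulationTable,
    fit_window: tuple[int, int] = (1998, 2007),
    target_year: int = 2010,
    *,
    sparsity_threshold: float = DEFAULT_SPARSITY_THRESHOLD,
) -> EstimateTable:
    """Medium-term projection: per-age linear rate trend per (sex, site)."""
    return _projection_estimate(
        incidence,
        population,
        method="1B",
        fit_window=fit_window,
        target_year=target_year,
        engine="linear",
        sparsity_threshold=sparsity_threshold,
    )


def project_mortality(
    mortality: EventTable,
    population: PopulationTable,
    window: tuple[int, int] = (1988, 2007),
    target: tuple[int, int] = (2008, 2012),
    *,
    attenuation: tuple[float, ...] = DEFAULT_ATTENUATION,
    sparsity_threshold: float = DEFAULT_SPARSITY_THRESHOLD,
) -> RateTable:
    """Project national mortality rates to a future 5-year period.

    Runs the APC engine per (sex, site) over the window (default
    1988-2007) and returns the target-period (default 2008-2012) mortality
    rates per (sex, site, age_group). Sites with fewer events in the
    window than the sparsity threshold (and sites with zero deaths) fall
    back to window-average rates.
    """
    if (target[1] - target[0]) != 4 or target[0] != window[1] + 1:
        # non-adjacent targets are still projectable, just further ahead
        pass
    n_ahead = (target[0] - window[1] - 1) // 5 + 1
    if n_ahead < 1 or (target[0] - window[1] - 1) % 5 != 0:
        raise ValidationError("target period must start a whole number of 5-year periods after the window")
    rows = []
    for sex, sites in _sites_by_sex(mortality.subset(years=window)).items():
        for site in sorted(sites):
            sub = mortality.subset(years=window, sexes=[sex], sites=[site])
            if sub.total() < sparsity_threshold:
                avg = pooled_rates(sub, population, datasets=None, years=window)
                by_age = avg.data.set_index("age_group")["rate"]
                proj_rates = np.array([by_age.get(a, 0.0) for a in range(N_AGE_GROUPS)])
            else:
                grid = aggregate_to_periods(sub, population, window, sex=sex, site=site)
                fit = fit_apc_power5(grid)
                proj_rates = project_apc(fit, grid, n_ahead=n_ahead, attenuation=attenuation)[:, -1]
            for a in range(N_AGE_GROUPS):
                rows.append({"sex": sex, "site": site, "age_group": a, "rate": proj_rates[a]})
    return RateTable(pd.DataFrame(rows))
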