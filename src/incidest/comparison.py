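"""Validation arithmetic against the recorded gold standard.

Because different sites can be over- and underestimated simultaneously, a
net total would hide compensating errors; under- and overestimated cases
are therefore totalled separately and their sum (the aggregate absolute
difference) is expressed as a percentage of the observed total. Published
comparison tables round estimates to whole cases and percentage
differences to one decimal (half away from zero); raw reals are retained
internally and rounding is applied at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import EstimateTable, ValidationError


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (publication convention, not banker's)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class ComparisonReport:
    """Per-site and aggregate differences of one method vs the observed data.

    ``per_site`` columns: sex, site, observed, estimated (whole cases),
    diff = estimated - observed, pct_diff (1 decimal; NaN where observed is
    zero and the difference is not).
    """

    method: str
    sex: str  # "male" | "female" | "both"
    per_site: pd.DataFrame
    under_total: float
    over_total: float
    aggregate_abs: float
    aggregate_pct: float

    @property
    def observed_total(self) -> float:
        return float(self.per_site["observed"].sum())

    @property
    def estimated_total(self) -> float:
        return float(self.per_site["estimated"].sum())


def _from_per_site(method: str, sex: str, per_site: pd.DataFrame) -> ComparisonReport:
    diff = per_site["diff"]
    under = float(-diff[diff < 0].sum())
    over = float(diff[diff > 0].sum())
    agg = under + over
    observed_total = float(per_site["observed"].sum())
    pct = round_half_away(100.0 * agg / observed_total, 1) if observed_total > 0 else float("nan")
    return ComparisonReport(method, sex, per_site.reset_index(drop=True), under, over, agg, pct)


def compare(estimate: EstimateTable, observed: EstimateTable, *, sex: str | None = None) -> ComparisonReport:
    """Compare one method's estimate against the observed gold standard.

    Both tables are rounded to whole cases first (report-time rounding);
    site keys must match. With ``sex`` unset, a single-sex pair is expected
    and the sex is inferred.
    """
    est = estimate.data if sex is None else estimate.data[estimate.data["sex"] == sex]
    obs = observed.data if sex is None else observed.data[observed.data["sex"] == sex]
    merged = obs.merge(est, on=["sex", "site"], how="outer", suffixes=("_obs", "_est"))
    if merged["cases_obs"].isna().any() or merged["cases_est"].isna().any():
        bad = merged[merged["cases_obs"].isna() | merged["cases_est"].isna()]
        raise ValidationError(
            f"site keys differ between estimate and observed: "
            f"{sorted(zip(bad['sex'], bad['site']))[:5]}"
        )
    sexes = sorted(merged["sex"].unique())
    report_sex = sexes[0] if len(sexes) == 1 else "both"
    per_site = pd.DataFrame(
        {
            "sex": merged["sex"],
            "site": merged["site"],
            "observed": [round_half_away(v) for v in merged["cases_obs"]],
            "estimated": [round_half_away(v) for v in merged["cases_est"]],
        }
    )
    per_site["diff"] = per_site["estimated"] - per_site["observed"]
    per_site["pct_diff"] = [
        round_half_away(100.0 * d / o, 1) if o != 0 else (0.0 if d == 0 else float("nan"))
        for d, o in zip(per_site["diff"], per_site["observed"])
    ]
    return _from_per_site(estimate.method, report_sex, per_site)


def combine_sexes(*reports: ComparisonReport) -> ComparisonReport:
    """Concatenate single-sex reports for one method; aggregates recomputed."""
    methods = {r.method for r in reports}
    if len(methods) != 1:
        raise ValidationError(f"cannot combine reports of different methods: {sorted(methods)}")
    per_site = pd.concat([r.per_site for r in reports], ignore_index=True)
    return _from_per_site(reports[0].method, "both", per_site)


def exclusion_variant(report: ComparisonReport, excluded_sites) -> ComparisonReport:
    """The same report with the given sites removed and totals recomputed."""
    excluded = set(excluded_sites)
    keep = report.per_site[~report.per_site["site"].isin(excluded)]
    return _from_per_site(report.method, report.sex, keep)


@dataclass
class RangeSummary:
    """Extremes of the aggregate percentage difference across reports."""

    min_pct: float
    min_abs: float
    max_pct: float
    max_abs: float


def method_range_summary(reports, exclude_methods=()) -> RangeSummary:
    """Min/max aggregate % difference over reports, with companion case counts."""
    kept = [r for r in reports if r.method not in set(exclude_methods)]
    if not kept:
        raise ValidationError("no reports left after method exclusions")
    lo = min(kept, key=lambda r: (r.aggregate_pct, r.aggregate_abs))
    hi = max(kept, key=lambda r: (r.aggregate_pct, r.aggregate_abs))
    return RangeSummary(lo.aggregate_pct, lo.aggregate_abs, hi.aggregate_pct, hi.aggregate_abs)


_METHOD_ORDER = ["1A", "1B", "2", "3", "4", "5", "6", "7", "8", "9"]


def render_tables(reports, *, site_order=None) -> str:
    """Publication-style text table: observed column then one per method.

    Cells show "estimated (pct)" with percentages to one decimal; column
    order is fixed (observed, methods 1A..9) so output is deterministic.
    All reports must refer to the same sex and observed column.
    """
    by_method = {r.method: r for r in reports}
    methods = [m for m in _METHOD_ORDER if m in by_method] + [
        m for m in by_method if m not in _METHOD_ORDER
    ]
    first = by_method[methods[0]].per_site.set_index("site")
    sites = list(site_order) if site_order is not None else list(first.index)
    lines = ["site\tobserved\t" + "\t".join(f"method {m}" for m in methods)]
    for site in sites:
        obs = first.loc[site, "observed"]
        cells = []
        for m in methods:
            row = by_method[m].per_site.set_index("site").loc[site]
            pct = row["pct_diff"]
            pct_str = "n/a" if isinstance(pct, float) and np.isnan(pct) else f"{pct:.1f}"
            cells.append(f"{row['estimated']:.0f} ({pct_str})")
        lines.append(f"{site}\t{obs:.0f}\t" + "\t".join(cells))
    lines.append(
        "under/over\t-\t"
        + "\t".join(
            f"-{by_method[m].under_total:.0f}/+{by_method[m].over_total:.0f}" for m in methods
        )
    )
    lines.append(
        "aggregate\t-\t"
        + "\t".join(
            f"{by_method[m].aggregate_abs:.0f} ({by_method[m].aggregate_pct:.1f}%)" for m in methods
        )
    )
    return "\n".join(lines) + "\n"


def write_report(report: ComparisonReport, path) -> None:
    """Delimited long-format dump of a comparison report (round-trips)."""
    df = report.per_site.copy()
    df.insert(0, "method", report.method)
    df.to_csv(path, index=False)


def read_report(path) -> ComparisonReport:
    df = pd.read_csv(path, dtype={"site": str})
    method = str(df["method"].iloc[0])
    per_site = df[["sex", "site", "observed", "estimated", "diff", "pct_diff"]]
    sexes = sorted(per_site["sex"].unique())
    sex = sexes[0] if len(sexes) == 1 else "both"
    return _from_per_site(method, sex, per_site)
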