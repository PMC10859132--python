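"""Performance measures with Monte Carlo standard errors.

Given the estimates data set of a study, each dgm x method cell yields:

* bias               mean(theta_hat) - theta
* emp_se             SD of the point estimates (actual precision)
* mod_se             root mean square of the SE estimates (claimed precision)
* rel_err_mod_se     100 * (mod_se / emp_se - 1), in percent
* coverage           percent of nominal CIs containing theta
* rejection_rate     percent of two-sided Wald tests of theta0 with p < alpha
* failure_rate       percent of repetitions with failed estimation
* backup_rate        percent of repetitions where a hybrid's backup ran

Failed repetitions are excluded from the moment-based measures but always
counted: the failure rate is itself a performance measure. Every estimate
carries its Monte Carlo standard error (MCSE), the standard error due to the
finite number of repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

__all__ = [
    "MeasureEstimate",
    "bias",
    "empirical_se",
    "model_se",
    "relative_error_mod_se",
    "coverage",
    "rejection_rate",
    "failure_rate",
    "performance_table",
    "format_performance_table",
    "MEASURES",
]

MEASURES = (
    "bias", "emp_se", "mod_se", "rel_err_mod_se",
    "coverage", "rejection_rate", "failure_rate", "backup_rate",
)

_PERCENT_MEASURES = {"rel_err_mod_se", "coverage", "rejection_rate", "failure_rate", "backup_rate"}


@dataclass
class MeasureEstimate:
    estimate: float
    mcse: float
    n_used: int


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def bias(estimates, theta: float) -> MeasureEstimate:
    """mean(theta_hat) - theta; MCSE = SD(theta_hat) / sqrt(n)."""
    q = _clean(estimates)
    n = len(q)
    if n < 2:
        return MeasureEstimate(math.nan, math.nan, n)
    s = q.std(ddof=1)
    return MeasureEstimate(float(q.mean() - theta), float(s / math.sqrt(n)), n)


def empirical_se(estimates) -> MeasureEstimate:
    """SD of the point estimates; MCSE = empSE / sqrt(2 (n - 1))."""
    q = _clean(estimates)
    n = len(q)
    if n < 2:
        return MeasureEstimate(math.nan, math.nan, n)
    s = float(q.std(ddof=1))
    return MeasureEstimate(s, s / math.sqrt(2.0 * (n - 1)), n)


def model_se(ses) -> MeasureEstimate:
    """Root mean square of the SE estimates; delta-method MCSE.

    MCSE = sqrt( Var(se_hat^2) / (4 n modSE^2) ).
    """
    s = _clean(ses)
    n = len(s)
    if n < 2:
        return MeasureEstimate(math.nan, math.nan, n)
    msq = float(np.mean(s**2))
    mod = math.sqrt(msq)
    if mod == 0.0:
        return MeasureEstimate(0.0, 0.0, n)
    var_sq = float(np.var(s**2, ddof=1))
    return MeasureEstimate(mod, math.sqrt(var_sq / (4.0 * n * msq)), n)


def relative_error_mod_se(
    mod: MeasureEstimate, emp: MeasureEstimate
) -> MeasureEstimate:
    """100 * (modSE / empSE - 1) in percent, MCSE by the delta method.

    Var(ratio) ~= ratio^2 * (Var(mod)/mod^2 + Var(emp)/emp^2), treating the
    two components as independent.
    """
    if not (math.isfinite(emp.estimate) and emp.estimate > 0) or not math.isfinite(
        mod.estimate
    ):
        return MeasureEstimate(math.nan, math.nan, min(mod.n_used, emp.n_used))
    ratio = mod.estimate / emp.estimate
    rel_var = 0.0
    if mod.estimate > 0:
        rel_var += (mod.mcse / mod.estimate) ** 2
    rel_var += (emp.mcse / emp.estimate) ** 2
    return MeasureEstimate(
        100.0 * (ratio - 1.0),
        100.0 * ratio * math.sqrt(rel_var),
        min(mod.n_used, emp.n_used),
    )


def coverage(ci_lows, ci_highs, theta: float) -> MeasureEstimate:
    """Percent of intervals with ci_low <= theta <= ci_high; binomial MCSE."""
    lo = np.asarray(ci_lows, dtype=float)
    hi = np.asarray(ci_highs, dtype=float)
    keep = ~(np.isnan(lo) | np.isnan(hi))
    lo, hi = lo[keep], hi[keep]
    n = len(lo)
    if n < 1:
        return MeasureEstimate(math.nan, math.nan, 0)
    p = float(np.mean((lo <= theta) & (theta <= hi)))
    return MeasureEstimate(100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / n), n)


def rejection_rate(
    estimates, ses, dfs=None, alpha: float = 0.05, theta0: float = 0.0
) -> MeasureEstimate:
    """Percent of repetitions rejecting H0: theta = theta0 at level alpha.

    Two-sided Wald test; a finite df uses the t reference distribution.
    Generating under no effect this is the type I error rate; under an
    effect it is power — which is which depends on the truth, not the code.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if dfs is None:
        df = np.full(len(q), np.inf)
    else:
        df = np.asarray(dfs, dtype=float)
    keep = np.isfinite(q) & np.isfinite(s) & (s > 0)
    q, s, df = q[keep], s[keep], df[keep]
    n = len(q)
    if n < 1:
        return MeasureEstimate(math.nan, math.nan, 0)
    stat = np.abs(q - theta0) / s
    pvals = np.where(
        np.isfinite(df), 2.0 * t_dist.sf(stat, np.where(np.isfinite(df), df, 1.0)),
        2.0 * norm.sf(stat),
    )
    p = float(np.mean(pvals < alpha))
    return MeasureEstimate(100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / n), n)


def failure_rate(statuses) -> tuple[MeasureEstimate, int]:
    """Percent and count of failed repetitions; binomial MCSE."""
    st = list(statuses)
    n = len(st)
    n_failed = sum(1 for s in st if s != "ok")
    if n == 0:
        return MeasureEstimate(math.nan, math.nan, 0), 0
    p = n_failed / n
    return (
        MeasureEstimate(100.0 * p, 100.0 * math.sqrt(p * (1.0 - p) / n), n),
        n_failed,
    )


def performance_table(
    estimates: pd.DataFrame,
    theta: float = 0.0,
    alpha: float = 0.05,
    theta0: float | None = None,
) -> pd.DataFrame:
    """Long-format performance table: one row per dgm x method x measure.

    Columns: dgm, method, measure, estimate, mcse, n_used, n_failed.
    Percent-scale measures (coverage, rates, relative SE error) are on the
    0–100 scale. Failed repetitions contribute only to failure_rate and the
    n_failed column.
    """
    if len(estimates) == 0:
        raise ValueError("estimates data set is empty")
    if theta0 is None:
        theta0 = theta
    rows: list[dict] = []
    for (dgm, method), grp in estimates.groupby(["dgm", "method"], sort=False):
        ok = grp[grp["status"] == "ok"]
        n_failed = len(grp) - len(ok)

        fr, _count = failure_rate(grp["status"])
        br = float(100.0 * grp["backup_used"].mean()) if "backup_used" in grp else 0.0
        b = bias(ok["estimate"], theta)
        e = empirical_se(ok["estimate"])
        m = model_se(ok["se"])
        r = relative_error_mod_se(m, e)
        c = coverage(ok["ci_low"], ok["ci_high"], theta)
        rej = rejection_rate(
            ok["estimate"], ok["se"],
            ok["df"] if "df" in ok else None,
            alpha=alpha, theta0=theta0,
        )
        named = {
            "bias": b, "emp_se": e, "mod_se": m, "rel_err_mod_se": r,
            "coverage": c, "rejection_rate": rej, "failure_rate": fr,
            "backup_rate": MeasureEstimate(br, math.nan, len(grp)),
        }
        for measure in MEASURES:
            est = named[measure]
            rows.append(
                {
                    "dgm": dgm,
                    "method": method,
                    "measure": measure,
                    "estimate": est.estimate,
                    "mcse": est.mcse,
                    "n_used": est.n_used,
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)


def get_cell(
    table: pd.DataFrame, dgm: str, method: str, measure: str
) -> MeasureEstimate:
    """Pull one cell of a long-format performance table."""
    sel = table[
        (table["dgm"] == dgm) & (table["method"] == method) & (table["measure"] == measure)
    ]
    if len(sel) == 0:
        raise KeyError(f"no cell ({dgm!r}, {method!r}, {measure!r})")
    row = sel.iloc[0]
    return MeasureEstimate(float(row["estimate"]), float(row["mcse"]), int(row["n_used"]))


def format_performance_table(table: pd.DataFrame) -> str:
    """Render the long table as measure-by-DGM rows with methods as columns."""
    methods = list(dict.fromkeys(table["method"]))
    dgms = list(dict.fromkeys(table["dgm"]))
    width = max(12, *(len(m) + 2 for m in methods))
    lines = [
        "Performance measure".ljust(28)
        + "DGM".ljust(8)
        + "".join(m.ljust(width) for m in methods)
    ]
    for measure in MEASURES:
        sub = table[table["measure"] == measure]
        if len(sub) == 0:
            continue
        for i, dgm in enumerate(dgms):
            cells = []
            for method in methods:
                row = sub[(sub["dgm"] == dgm) & (sub["method"] == method)]
                if len(row) == 0:
                    cells.append("-".ljust(width))
                    continue
                v = row.iloc[0]["estimate"]
                if measure in _PERCENT_MEASURES:
                    cells.append((f"{v:.1f}%" if math.isfinite(v) else "-").ljust(width))
                else:
                    cells.append((f"{v:.3f}" if math.isfinite(v) else "-").ljust(width))
            label = measure if i == 0 else ""
            lines.append(label.ljust(28) + dgm.ljust(8) + "".join(cells))
    return "\n".join(lines)
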