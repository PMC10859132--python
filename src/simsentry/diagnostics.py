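"""Checking instruments for an estimates data set.

These are the tools for the analysis stage of a simulation study: scatter
data of SE estimates against point estimates (the single most revealing
outlier display), rule-based outlier flagging, zip-plot data (all CIs ranked
by their Wald p-value against the truth, exposing whether poor coverage
comes from bias or from intervals of the wrong width), two-MCSE
compatibility verdicts, and a known-answer sanity suite for settings whose
properties are understood in advance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .performance import get_cell

__all__ = [
    "OutlierRules",
    "OutlierReport",
    "scatter_data",
    "flag_outliers",
    "zip_plot_data",
    "CompatibilityVerdict",
    "mc_compatibility_check",
    "CheckResult",
    "known_property_checks",
]


def scatter_data(estimates: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Per dgm x method, the (estimate, se) pairs of non-failed repetitions.

    The contract is the data; rendering a scatter plot is a thin layer on
    top (see :func:`simsentry.plotting.plot_scatter`).
    """
    ok = estimates[estimates["status"] == "ok"]
    return {
        (str(dgm), str(method)): grp[["rep_id", "estimate", "se"]].reset_index(drop=True)
        for (dgm, method), grp in ok.groupby(["dgm", "method"], sort=False)
    }


@dataclass(frozen=True)
class OutlierRules:
    """Thresholds beyond which an estimate would not be believed in practice.

    A log odds ratio in the tens, an SE in the hundreds, or an SE that is
    exactly zero all indicate a broken fit rather than a real result. Any
    rule can be disabled by setting it to None.
    """

    max_abs_estimate: float | None = 10.0
    max_se: float | None = 100.0
    min_se: float | None = 1e-8

    def __post_init__(self):
        for name in ("max_abs_estimate", "max_se", "min_se"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive or None")


@dataclass
class OutlierReport:
    flagged: pd.DataFrame  # rep_id, dgm, method, estimate, se, rule
    rules: OutlierRules
    counts: pd.DataFrame = field(default=None)  # per dgm x method flag counts

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    def summary(self) -> str:
        if self.n_flagged == 0:
            return "no outliers flagged"
        lines = [f"{self.n_flagged} outlying repetition(s) flagged:"]
        for _, r in self.flagged.iterrows():
            lines.append(
                f"  {r['dgm']}/{r['method']} rep {r['rep_id']}: "
                f"estimate={r['estimate']:.4g} se={r['se']:.4g} [{r['rule']}]"
            )
        return "\n".join(lines)


def flag_outliers(
    estimates: pd.DataFrame, rules: OutlierRules = OutlierRules()
) -> OutlierReport:
    """Flag non-failed rows violating any outlier rule, with the rule named."""
    ok = estimates[estimates["status"] == "ok"].copy()
    est = ok["estimate"].to_numpy(dtype=float)
    se = ok["se"].to_numpy(dtype=float)
    fired = []
    for i in range(len(ok)):
        hit = []
        if rules.max_abs_estimate is not None and abs(est[i]) > rules.max_abs_estimate:
            hit.append("max_abs_estimate")
        if rules.max_se is not None and se[i] > rules.max_se:
            hit.append("max_se")
        if rules.min_se is not None and se[i] < rules.min_se:
            hit.append("min_se")
        fired.append(",".join(hit))
    ok["rule"] = fired
    flagged = ok[ok["rule"] != ""][
        ["rep_id", "dgm", "method", "estimate", "se", "rule"]
    ].reset_index(drop=True)
    counts = (
        flagged.groupby(["dgm", "method"]).size().rename("n_flagged").reset_index()
        if len(flagged)
        else pd.DataFrame(columns=["dgm", "method", "n_flagged"])
    )
    return OutlierReport(flagged=flagged, rules=rules, counts=counts)


def zip_plot_data(
    estimates: pd.DataFrame, theta: float = 0.0
) -> pd.DataFrame:
    """Zip-plot rows for one dgm x method slice of an estimates data set.

    Each non-failed repetition gets a two-sided Wald p-value for H0:
    theta_hat = theta, p = 2 Phi(-|theta_hat - theta| / se). Rows are sorted
    by ascending p (least compatible with the truth first; ties broken by
    rep_id) and given rank_fraction = (rank - 0.5) / n. ``covers`` is read
    off the stored CI, so zip coverage agrees exactly with the coverage
    performance measure. Zero-SE rows have no defined p and are excluded
    with a warning; the count is in ``.attrs['n_excluded']``.
    """
    ok = estimates[estimates["status"] == "ok"]
    if len(ok) == 0:
        raise ValueError("no non-failed repetitions to rank")
    if ok[["dgm", "method"]].drop_duplicates().shape[0] > 1:
        raise ValueError("zip_plot_data expects a single dgm x method slice")
    se = ok["se"].to_numpy(dtype=float)
    bad = ~(se > 0)
    n_excluded = int(bad.sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} repetition(s) with zero or invalid SE "
            "(no defined p-value)",
            stacklevel=2,
        )
    ok = ok[~bad]
    est = ok["estimate"].to_numpy(dtype=float)
    se = ok["se"].to_numpy(dtype=float)
    p = 2.0 * norm.cdf(-np.abs(est - theta) / se)
    out = pd.DataFrame(
        {
            "rep_id": ok["rep_id"].to_numpy(),
            "p_value": p,
            "ci_low": ok["ci_low"].to_numpy(dtype=float),
            "ci_high": ok["ci_high"].to_numpy(dtype=float),
        }
    )
    out["covers"] = (out["ci_low"] <= theta) & (theta <= out["ci_high"])
    out = out.sort_values(["p_value", "rep_id"], kind="mergesort").reset_index(drop=True)
    n = len(out)
    out["rank_fraction"] = (np.arange(1, n + 1) - 0.5) / n
    out = out[["rep_id", "rank_fraction", "p_value", "ci_low", "ci_high", "covers"]]
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class CompatibilityVerdict:
    compatible: bool
    margin: float  # 2 * mcse
    difference: float

    def __str__(self) -> str:
        word = "compatible" if self.compatible else "NOT compatible"
        return (
            f"{word} with Monte Carlo error: |difference| = {abs(self.difference):.4g} "
            f"vs 2*MCSE margin {self.margin:.4g}"
        )


def mc_compatibility_check(
    estimate: float, mcse: float, reference: float
) -> CompatibilityVerdict:
    """Is an observed performance value within 2 MCSE of a reference?

    Strict inequality: a difference of exactly 2 MCSE is not compatible.
    """
    if not mcse > 0:
        raise ValueError("mcse must be positive")
    diff = estimate - reference
    return CompatibilityVerdict(
        compatible=abs(diff) < 2.0 * mcse, margin=2.0 * mcse, difference=diff
    )


@dataclass
class CheckResult:
    name: str
    status: str  # "pass", "fail", "skipped"
    detail: str = ""


def known_property_checks(
    table: pd.DataFrame,
    mcar_dgm: str = "mcar",
    theta: float = 0.0,
    nominal_coverage: float = 95.0,
) -> list[CheckResult]:
    """Known-answer checks for the MCAR setting.

    Full-data analysis should be unbiased with nominal coverage; under MCAR
    the complete-case analysis should also be unbiased with nominal coverage
    and less precise than multiple imputation, which in turn is less precise
    than the full data. Each verdict is a 2-MCSE compatibility check (or an
    ordering); absent cells skip their check rather than fail it.
    """
    results: list[CheckResult] = []

    def cell(method, measure):
        try:
            return get_cell(table, mcar_dgm, method, measure)
        except KeyError:
            return None

    def compat_check(name, method, measure, reference):
        c = cell(method, measure)
        if c is None or not math.isfinite(c.estimate):
            results.append(CheckResult(name, "skipped", f"cell {method}/{measure} absent"))
            return
        if not (math.isfinite(c.mcse) and c.mcse > 0):
            results.append(
                CheckResult(name, "skipped",
                            f"cell {method}/{measure} has no usable MCSE "
                            "(too few repetitions)")
            )
            return
        v = mc_compatibility_check(c.estimate, c.mcse, reference)
        results.append(
            CheckResult(name, "pass" if v.compatible else "fail", str(v))
        )

    compat_check("full-data bias ~ 0", "full", "bias", 0.0)
    compat_check("full-data coverage ~ nominal", "full", "coverage", nominal_coverage)
    compat_check("MCAR complete-case bias ~ 0", "cca", "bias", 0.0)
    compat_check("MCAR complete-case coverage ~ nominal", "cca", "coverage", nominal_coverage)

    full_se = cell("full", "emp_se")
    mi_se = cell("mi", "emp_se")
    cca_se = cell("cca", "emp_se")
    if None in (full_se, mi_se, cca_se):
        results.append(
            CheckResult("empirical-SE ordering full <= MI <= CCA", "skipped",
                        "a required method is absent")
        )
    else:
        ordered = full_se.estimate <= mi_se.estimate <= cca_se.estimate
        results.append(
            CheckResult(
                "empirical-SE ordering full <= MI <= CCA",
                "pass" if ordered else "fail",
                f"full {full_se.estimate:.4f} / MI {mi_se.estimate:.4f} / "
                f"CCA {cca_se.estimate:.4f}",
            )
        )
    return results
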