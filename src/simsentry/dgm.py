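"""Data-generating mechanisms for the missing-confounder simulation study.

Each simulated data set holds a quantitative confounder C ~ N(0, 1), a binary
exposure E and a binary outcome D drawn from logistic models that both depend
on C (E has no causal effect on D, so the true conditional E–D log odds ratio
is zero), and a missingness indicator M_C for C generated by one of three
mechanisms:

* MCAR — missingness independent of everything,
* MAR  — missingness depends on the observed E and D,
* MNAR — missingness depends on the unobserved C itself.

True C values are retained even where M_C = 1; analysis code masks them.
This lets oracle checks compare incomplete-data analyses against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "MECHANISMS",
    "DGMSpec",
    "SimulatedDataset",
    "CoefficientCheck",
    "CheckReport",
    "default_specs",
    "generate_full",
    "apply_missingness",
    "generate_dataset",
    "large_sample_check",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class DGMSpec:
    """Parameters of one data-generating mechanism.

    The exposure model is ``logit P(E=1|C) = alpha0 + alphaC*C``; the outcome
    model is ``logit P(D=1|E,C) = beta0 + betaE*E + betaC*C`` (``betaE`` is
    the true estimand, default 0); the missingness model is
    ``logit P(M_C=1|E,D,C) = gamma0 + gammaE*E + gammaD*D + gammaC*C``.
    """

    label: str = "mcar"
    n_obs: int = 500
    alpha0: float = -1.0
    alphaC: float = 1.0
    beta0: float = -1.0
    betaE: float = 0.0
    betaC: float = 1.0
    mechanism: str = "MCAR"
    gamma0: float = field(default_factory=lambda: logit(0.3))
    gammaE: float = 0.0
    gammaD: float = 0.0
    gammaC: float = 0.0

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )
        if self.mechanism == "MCAR" and not (
            self.gammaE == self.gammaD == self.gammaC == 0.0
        ):
            raise ValueError("MCAR requires gammaE = gammaD = gammaC = 0")
        if self.mechanism == "MAR" and self.gammaC != 0.0:
            raise ValueError("MAR requires gammaC = 0 (missingness may not depend on C)")

    @property
    def theta(self) -> float:
        """True value of the estimand (the E coefficient in the outcome model)."""
        return self.betaE

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_obs": self.n_obs,
            "alpha0": self.alpha0,
            "alphaC": self.alphaC,
            "beta0": self.beta0,
            "betaE": self.betaE,
            "betaC": self.betaC,
            "mechanism": self.mechanism,
            "gamma0": self.gamma0,
            "gammaE": self.gammaE,
            "gammaD": self.gammaD,
            "gammaC": self.gammaC,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DGMSpec":
        return cls(**d)


def default_specs(n_obs: int = 500) -> list[DGMSpec]:
    """The three study mechanisms at their default coefficients.

    Exposure and outcome prevalences are both near 30% (avoiding sparse-data
    failures), and each mechanism removes roughly 30% of the C values.
    """
    return [
        DGMSpec(label="mcar", n_obs=n_obs, mechanism="MCAR", gamma0=logit(0.3)),
        DGMSpec(
            label="mar", n_obs=n_obs, mechanism="MAR",
            gamma0=-1.5, gammaE=1.0, gammaD=1.0,
        ),
        DGMSpec(
            label="mnar", n_obs=n_obs, mechanism="MNAR",
            gamma0=-1.0, gammaC=1.0,
        ),
    ]


@dataclass
class SimulatedDataset:
    """One repetition's data: columns C, E, D, M_C in generation order."""

    rep_id: int
    dgm_label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = {"C", "E", "D", "M_C"} - set(self.df.columns)
        if missing_cols:
            raise ValueError(f"data set lacks columns {sorted(missing_cols)}")

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def validate(self, expected_n: int | None = None) -> None:
        """Structural checks: row count, binary codings, finite C."""
        if expected_n is not None and len(self.df) != expected_n:
            raise ValueError(
                f"rep {self.rep_id}: expected {expected_n} rows, found {len(self.df)}"
            )
        for col in ("E", "D", "M_C"):
            vals = self.df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"rep {self.rep_id}: column {col} is not 0/1")
        if not np.isfinite(self.df["C"].to_numpy()).all():
            raise ValueError(f"rep {self.rep_id}: non-finite C values")

    def observed_view(self) -> pd.DataFrame:
        """Copy with C set to NaN wherever M_C = 1 (the analyst's view)."""
        out = self.df.copy()
        out.loc[out["M_C"] == 1, "C"] = np.nan
        return out

    def complete_cases(self) -> pd.DataFrame:
        return self.df[self.df["M_C"] == 0]

    def equals(self, other: "SimulatedDataset") -> bool:
        return (
            self.rep_id == other.rep_id
            and self.dgm_label == other.dgm_label
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


def generate_full(spec: DGMSpec, rng: np.random.Generator, rep_id: int = 1) -> SimulatedDataset:
    """Draw one full data set (no missingness yet; M_C all zero).

    The random stream is consumed in a fixed order — the C vector, then the
    uniforms for E, then those for D — so a stored generator state fully
    determines the data set.
    """
    n = spec.n_obs
    C = rng.standard_normal(n)
    E = (rng.random(n) < expit(spec.alpha0 + spec.alphaC * C)).astype(np.int64)
    D = (rng.random(n) < expit(spec.beta0 + spec.betaE * E + spec.betaC * C)).astype(np.int64)
    df = pd.DataFrame(
        {"C": C, "E": E, "D": D, "M_C": np.zeros(n, dtype=np.int64)}
    )
    return SimulatedDataset(rep_id=rep_id, dgm_label=spec.label, df=df)


def apply_missingness(
    full: SimulatedDataset, spec: DGMSpec, rng: np.random.Generator
) -> SimulatedDataset:
    """Rewrite M_C by the mechanism's logistic model; C, E, D untouched."""
    if full.df["M_C"].any():
        raise ValueError("apply_missingness expects a full data set (M_C all zero)")
    df = full.df
    lin = (
        spec.gamma0
        + spec.gammaE * df["E"].to_numpy()
        + spec.gammaD * df["D"].to_numpy()
        + spec.gammaC * df["C"].to_numpy()
    )
    M_C = (rng.random(len(df)) < expit(lin)).astype(np.int64)
    out = df.copy()
    out["M_C"] = M_C
    return SimulatedDataset(rep_id=full.rep_id, dgm_label=full.dgm_label, df=out)


def generate_dataset(
    spec: DGMSpec, rng: np.random.Generator, rep_id: int = 1
) -> SimulatedDataset:
    """Full data followed by missingness, on one continuous stream."""
    return apply_missingness(generate_full(spec, rng, rep_id), spec, rng)


# ---------------------------------------------------------------------------
# Large-sample self-check


@dataclass
class CoefficientCheck:
    name: str
    truth: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    covers: bool


@dataclass
class CheckReport:
    """Result of fitting the generating models to one very large data set."""

    n: int
    log_or_de: float | None       # unconditional D–E log odds ratio
    log_or_de_se: float | None
    missing_fraction: float
    coefficients: list[CoefficientCheck]
    degenerate_table: bool = False

    @property
    def all_covered(self) -> bool:
        return not self.degenerate_table and all(c.covers for c in self.coefficients)

    def summary(self) -> str:
        lines = [f"Large-sample check, N = {self.n}"]
        if self.degenerate_table:
            lines.append("  D x E cross-tabulation is degenerate (a zero margin) -- CHECK FAILED")
        else:
            lines.append(
                f"  unconditional D-E log OR = {self.log_or_de:.4f} (SE {self.log_or_de_se:.4f})"
            )
        lines.append(f"  missingness fraction = {self.missing_fraction:.4f}")
        for c in self.coefficients:
            verdict = "ok" if c.covers else "OUTSIDE CI"
            lines.append(
                f"  {c.name}: truth {c.truth:+.3f}, fitted {c.estimate:+.4f} "
                f"[{c.ci_low:+.4f}, {c.ci_high:+.4f}] {verdict}"
            )
        lines.append(f"  all generating coefficients covered: {self.all_covered}")
        return "\n".join(lines)


def large_sample_check(
    spec: DGMSpec,
    N: int = 100_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CheckReport:
    """Generate one very large data set and fit the generating models back.

    Reports the unconditional D–E log odds ratio (confounding through C makes
    it non-zero even though E does not cause D), every generating-model
    coefficient with its 95% CI and a truth-in-CI flag, and the missingness
    fraction. A degenerate 2x2 table is reported as a failed check, never
    raised.
    """
    if N < 1000:
        raise ValueError("large_sample_check needs N >= 1000")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    big = replace(spec, n_obs=N)
    data = generate_dataset(big, rng)
    df = data.df

    # 2x2 cross-tabulation of D by E
    n11 = int(((df["D"] == 1) & (df["E"] == 1)).sum())
    n10 = int(((df["D"] == 1) & (df["E"] == 0)).sum())
    n01 = int(((df["D"] == 0) & (df["E"] == 1)).sum())
    n00 = int(((df["D"] == 0) & (df["E"] == 0)).sum())
    degenerate = min(n11 + n10, n01 + n00, n11 + n01, n10 + n00) == 0
    if degenerate or 0 in (n11, n10, n01, n00):
        log_or = None
        log_or_se = None
        degenerate = True
    else:
        log_or = math.log(n11 * n00 / (n10 * n01))
        log_or_se = math.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)

    from .methods import fit_logistic_ml  # local import to avoid a cycle

    z = norm.ppf(0.975)
    checks: list[CoefficientCheck] = []

    def add_checks(fit, names, truths):
        for nm, tr in zip(names, truths):
            est, se = fit.coef[nm], fit.se[nm]
            lo, hi = est - z * se, est + z * se
            checks.append(CoefficientCheck(nm, tr, est, se, lo, hi, lo <= tr <= hi))

    C = df["C"].to_numpy()
    E = df["E"].to_numpy(dtype=float)
    D = df["D"].to_numpy(dtype=float)
    X_exp = np.column_stack([np.ones(N), C])
    fit_e = fit_logistic_ml(E, X_exp, names=("alpha0", "alphaC"))
    add_checks(fit_e, ("alpha0", "alphaC"), (spec.alpha0, spec.alphaC))

    X_out = np.column_stack([np.ones(N), E, C])
    fit_d = fit_logistic_ml(D, X_out, names=("beta0", "betaE", "betaC"))
    add_checks(fit_d, ("beta0", "betaE", "betaC"), (spec.beta0, spec.betaE, spec.betaC))

    return CheckReport(
        n=N,
        log_or_de=log_or,
        log_or_de_se=log_or_se,
        missing_fraction=float(df["M_C"].mean()),
        coefficients=checks,
        degenerate_table=degenerate,
    )
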