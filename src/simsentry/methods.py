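"""Analysis methods for one simulated data set, with failure capture.

The estimand is the E coefficient (conditional log odds ratio) in the
logistic regression of D on E and C. Three pure methods are provided:

* ``full`` — fit to the true, pre-deletion data;
* ``cca``  — complete-case analysis, rows with C observed;
* ``mi``   — multiple imputation of C by a proper normal-linear model on
  (E, D), analysis of each completed data set, Rubin's-rules pooling with
  Barnard–Rubin degrees of freedom;

plus a hybrid that falls back to Firth penalized logistic regression when
the primary analysis separates or returns an absurd result.

Every method runs guarded: any failure (separation, singular information,
too few complete rows, an unexpected exception) is converted into an
``AnalysisOutcome`` with ``status='failed:<code>'`` and missing numeric
fields, so a simulation loop never halts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm, t as t_dist

from .dgm import SimulatedDataset

__all__ = [
    "FitResult",
    "AnalysisOutcome",
    "PooledResult",
    "TriggerRules",
    "MethodSettings",
    "fit_logistic_ml",
    "fit_logistic_firth",
    "detect_separation",
    "analyze_complete_records",
    "impute_confounder_once",
    "pool_rubin",
    "analyze_mi",
    "run_method_guarded",
    "hybrid_with_backup",
    "analyze",
    "METHOD_LABELS",
]

METHOD_LABELS = ("full", "cca", "mi", "cca_firth_hybrid")

_Z975 = norm.ppf(0.975)


@dataclass
class FitResult:
    """A fitted logistic model: estimates, SEs, and convergence bookkeeping."""

    coef: dict[str, float]
    se: dict[str, float]
    df: float  # degrees of freedom for intervals; inf for Wald/z
    converged: bool
    n_used: int
    iterations: int


@dataclass
class AnalysisOutcome:
    """One method's result on one repetition, as stored in the estimates data set."""

    rep_id: int
    dgm_label: str
    method_label: str
    status: str = "ok"  # "ok" or "failed:<code>"
    estimate: float = math.nan
    se: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    df: float = math.inf
    separation_flag: bool = False
    backup_used: bool = False

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def p_value(self, theta0: float = 0.0) -> float:
        """Two-sided Wald p for H0: theta = theta0 (t if df finite, else z)."""
        if not self.ok or self.se <= 0:
            return math.nan
        stat = abs(self.estimate - theta0) / self.se
        if math.isfinite(self.df):
            return 2.0 * t_dist.sf(stat, self.df)
        return 2.0 * norm.sf(stat)


@dataclass
class PooledResult:
    """Rubin's rules: qbar, within (W), between (B), total (T) variance, BR df."""

    qbar: float
    W: float
    B: float
    T: float
    df_BR: float
    m: int


@dataclass(frozen=True)
class TriggerRules:
    """When the hybrid abandons the primary result for the backup.

    Defaults target the pathologies seen with separated logistic fits:
    divergent point estimates (|log OR| in the tens) and wild standard
    errors (hundreds to thousands).
    """

    on_separation: bool = True
    max_abs_estimate: float = 10.0
    max_se: float = 100.0

    def fires(self, outcome: AnalysisOutcome) -> bool:
        if not outcome.ok:
            return True
        if self.on_separation and outcome.separation_flag:
            return True
        if abs(outcome.estimate) > self.max_abs_estimate:
            return True
        if outcome.se > self.max_se:
            return True
        return False


@dataclass(frozen=True)
class MethodSettings:
    """Tunables shared by the analysis methods."""

    m_imputations: int = 20
    alpha: float = 0.05
    divergence_threshold: float = 10.0
    triggers: TriggerRules = field(default_factory=TriggerRules)


class AnalysisError(Exception):
    """A recognised analysis failure; ``code`` goes into the status field."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(message or code)


# ---------------------------------------------------------------------------
# Logistic fits


def _default_names(p: int) -> tuple[str, ...]:
    return ("const",) + tuple(f"x{j}" for j in range(1, p))


def fit_logistic_ml(
    y: np.ndarray,
    X: np.ndarray,
    names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Maximum-likelihood logistic regression by Newton iteration (IRLS).

    SEs come from the inverse observed information at the final iterate.
    Non-convergence or a singular information matrix yields
    ``converged=False`` with the last iterate's values — never an exception —
    so that a simulation loop can record the failure and continue.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise AnalysisError("too_few_rows", f"need >= 3 rows, got {n}")
    if names is None:
        names = _default_names(p)

    beta = np.zeros(p)
    converged = False
    singular = False
    it = 0
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (X.T * w) @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            singular = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    se = np.full(p, np.nan)
    if not singular:
        eta = np.clip(X @ beta, -30, 30)
        w = expit(eta) * (1.0 - expit(eta))
        H = (X.T * w) @ X
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                se = np.sqrt(diag)
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    return FitResult(
        coef=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        df=math.inf,
        converged=converged and not singular,
        n_used=n,
        iterations=it,
    )


def _firth_penalized_loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    w = mu * (1.0 - mu)
    H = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_logistic_firth(
    y: np.ndarray,
    X: np.ndarray,
    names: tuple[str, ...] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Jeffreys-penalized (Firth) logistic regression.

    Maximizes l(beta) + log det I(beta) / 2 by Newton steps on the modified
    score, with step-halving on the penalized likelihood. The penalty keeps
    estimates finite even under separation. SEs are taken from the inverse
    information at the penalized maximum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise AnalysisError("too_few_rows", f"need >= 3 rows, got {n}")
    if names is None:
        names = _default_names(p)

    beta = np.zeros(p)
    pll = _firth_penalized_loglik(beta, y, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        XtW = X.T * w
        H = XtW @ X
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        # leverages of the weighted design: h_i = w_i x_i' H^{-1} x_i
        h = w * np.einsum("ij,jk,ik->i", X, Hinv, X)
        g = X.T @ (y - mu + h * (0.5 - mu))  # modified score
        step = Hinv @ g
        # step-halving keeps the penalized likelihood non-decreasing
        for _ in range(20):
            cand = beta + step
            pll_new = _firth_penalized_loglik(cand, y, X)
            if pll_new >= pll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        moved = np.max(np.abs(step))
        beta, pll = cand, pll_new
        if moved < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -30, 30)
    w = expit(eta) * (1.0 - expit(eta))
    H = (X.T * w) @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return FitResult(
        coef=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        df=math.inf,
        converged=converged,
        n_used=n,
        iterations=it,
    )


def detect_separation(
    D: np.ndarray,
    E: np.ndarray,
    fit: FitResult | None = None,
    divergence_threshold: float = 10.0,
) -> tuple[bool, str]:
    """Flag (quasi-)separation on the analysis rows.

    True if any margin of the E x D table is zero, or if the fitted E
    coefficient wandered beyond ``divergence_threshold`` in absolute value
    (the fingerprint of an estimate heading to +/- infinity).
    """
    D = np.asarray(D)
    E = np.asarray(E)
    if len(D) and D.sum() == 0:
        return True, "no_events"
    if len(D) and (1 - D).sum() == 0:
        return True, "no_nonevents"
    if len(E) and E.sum() == 0:
        return True, "no_exposed"
    if len(E) and (1 - E).sum() == 0:
        return True, "no_unexposed"
    if fit is not None:
        est = fit.coef.get("E")
        if est is not None and (not math.isfinite(est) or abs(est) > divergence_threshold):
            return True, "divergent_fit"
        if not fit.converged:
            return True, "divergent_fit"
    return False, "none"


# ---------------------------------------------------------------------------
# Pure methods


def _design(df) -> tuple[np.ndarray, np.ndarray]:
    n = len(df)
    X = np.column_stack(
        [np.ones(n), df["E"].to_numpy(dtype=float), df["C"].to_numpy(dtype=float)]
    )
    return df["D"].to_numpy(dtype=float), X


_NAMES_DEC = ("const", "E", "C")


def _outcome_from_fit(
    fit: FitResult,
    rep_id: int,
    dgm_label: str,
    method_label: str,
    D: np.ndarray,
    E: np.ndarray,
    settings: MethodSettings,
) -> AnalysisOutcome:
    sep, _reason = detect_separation(D, E, fit, settings.divergence_threshold)
    if not fit.converged:
        raise AnalysisError("nonconvergence", "logistic fit did not converge")
    est = fit.coef["E"]
    se = fit.se["E"]
    if not (math.isfinite(est) and math.isfinite(se)):
        raise AnalysisError("nonfinite_fit", "non-finite estimate or SE")
    return AnalysisOutcome(
        rep_id=rep_id,
        dgm_label=dgm_label,
        method_label=method_label,
        estimate=est,
        se=se,
        ci_low=est - _Z975 * se,
        ci_high=est + _Z975 * se,
        df=math.inf,
        separation_flag=sep,
    )


def analyze_complete_records(
    data: SimulatedDataset,
    subset: str = "complete_cases",
    settings: MethodSettings = MethodSettings(),
    method_label: str | None = None,
    fitter=fit_logistic_ml,
) -> AnalysisOutcome:
    """Fit D ~ E + C on either all rows ('all') or rows with C observed.

    ``subset='all'`` is the full-data benchmark method; with zero
    missingness the two subsets coincide.
    """
    if subset not in ("all", "complete_cases"):
        raise ValueError(f"subset must be 'all' or 'complete_cases', got {subset!r}")
    if method_label is None:
        method_label = "full" if subset == "all" else "cca"
    df = data.df if subset == "all" else data.complete_cases()
    if len(df) < 3:
        raise AnalysisError("too_few_rows", f"{len(df)} analysis rows")
    D, X = _design(df)
    fit = fitter(D, X, names=_NAMES_DEC)
    return _outcome_from_fit(
        fit, data.rep_id, data.dgm_label, method_label, D, X[:, 1], settings
    )


def impute_confounder_once(
    data: SimulatedDataset, rng: np.random.Generator
) -> np.ndarray:
    """One proper normal-linear imputation of the missing C values.

    Among complete rows, C is regressed on (1, E, D); the residual variance
    is drawn from its scaled inverse-chi-square posterior, the coefficients
    from their conditional normal, and each missing C is filled with a
    posterior-predictive draw. With nothing missing the input C is returned
    unchanged (consuming no random numbers).
    """
    df = data.df
    miss = df["M_C"].to_numpy() == 1
    C = df["C"].to_numpy(dtype=float).copy()
    if not miss.any():
        return C
    obs = ~miss
    Z = np.column_stack(
        [np.ones(len(df)), df["E"].to_numpy(dtype=float), df["D"].to_numpy(dtype=float)]
    )
    p = Z.shape[1]
    n_cc = int(obs.sum())
    if n_cc < p + 2:
        raise AnalysisError("too_few_complete_rows", f"{n_cc} complete rows")
    Zo, Co = Z[obs], C[obs]
    ZtZ = Zo.T @ Zo
    try:
        ZtZ_inv = np.linalg.inv(ZtZ)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError("singular_imputation_model") from exc
    beta_hat = ZtZ_inv @ (Zo.T @ Co)
    resid = Co - Zo @ beta_hat
    rss = float(resid @ resid)
    # sigma*^2 ~ RSS / chi2_{n_cc - p}; beta* ~ N(beta_hat, sigma*^2 (Z'Z)^-1)
    sigma2_star = rss / rng.chisquare(n_cc - p)
    L = np.linalg.cholesky(sigma2_star * ZtZ_inv)
    beta_star = beta_hat + L @ rng.standard_normal(p)
    C[miss] = Z[miss] @ beta_star + math.sqrt(sigma2_star) * rng.standard_normal(
        int(miss.sum())
    )
    return C


def pool_rubin(
    estimates: list[float] | np.ndarray,
    variances: list[float] | np.ndarray,
    df_complete: float = math.inf,
) -> PooledResult:
    """Combine m completed-data results by Rubin's rules.

    qbar is the mean estimate; W the mean squared SE; B the between-imputation
    sample variance; T = W + (1 + 1/m) B. Degrees of freedom follow
    Barnard–Rubin, using ``df_complete`` as the complete-data df.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise AnalysisError("too_few_imputations", "pooling needs m >= 2")
    if len(v) != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    qbar = float(q.mean())
    W = float(v.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if T <= 0:
        return PooledResult(qbar, W, B, T, math.inf, m)
    lam = (1.0 + 1.0 / m) * B / T
    if lam <= 0 or lam**2 == 0.0:  # lam**2 may underflow for tiny lam
        df_old = math.inf
    else:
        df_old = (m - 1) / lam**2
    if math.isinf(df_complete):
        df_br = df_old
    else:
        df_obs = ((df_complete + 1.0) / (df_complete + 3.0)) * df_complete * (1.0 - lam)
        df_br = 1.0 / (1.0 / df_old + 1.0 / df_obs) if df_old != math.inf else df_obs
    return PooledResult(qbar, W, B, T, df_br, m)


def analyze_mi(
    data: SimulatedDataset,
    rng: np.random.Generator,
    settings: MethodSettings = MethodSettings(),
) -> AnalysisOutcome:
    """Multiple imputation: m completed-data fits pooled by Rubin's rules.

    The CI uses the t distribution with Barnard–Rubin df (complete-data
    df = n - 3). With no missing values every completed data set equals the
    original, so B = 0 and the result matches the full-data fit.
    """
    m = settings.m_imputations
    if m < 2:
        raise AnalysisError("too_few_imputations", "analyze_mi needs m >= 2")
    ests: list[float] = []
    vars_: list[float] = []
    sep_any = False
    for _ in range(m):
        C_completed = impute_confounder_once(data, rng)
        df = data.df.assign(C=C_completed)
        D, X = _design(df)
        fit = fit_logistic_ml(D, X, names=_NAMES_DEC)
        if not fit.converged:
            raise AnalysisError("nonconvergence", "completed-data fit did not converge")
        sep, _ = detect_separation(D, X[:, 1], fit, settings.divergence_threshold)
        sep_any = sep_any or sep
        ests.append(fit.coef["E"])
        vars_.append(fit.se["E"] ** 2)
    pooled = pool_rubin(ests, vars_, df_complete=data.n_obs - 3)
    if pooled.T <= 0 or not math.isfinite(pooled.qbar):
        raise AnalysisError("degenerate_pooling")
    se = math.sqrt(pooled.T)
    if math.isfinite(pooled.df_BR):
        crit = t_dist.ppf(0.975, pooled.df_BR)
    else:
        crit = _Z975
    return AnalysisOutcome(
        rep_id=data.rep_id,
        dgm_label=data.dgm_label,
        method_label="mi",
        estimate=pooled.qbar,
        se=se,
        ci_low=pooled.qbar - crit * se,
        ci_high=pooled.qbar + crit * se,
        df=pooled.df_BR,
        separation_flag=sep_any,
    )


# ---------------------------------------------------------------------------
# Guarded execution and the hybrid


def run_method_guarded(
    method, data: SimulatedDataset, *, method_label: str, **kwargs
) -> AnalysisOutcome:
    """Run ``method(data, **kwargs)``; convert any raised condition to a
    failed outcome so the simulation never halts."""
    try:
        return method(data, **kwargs)
    except AnalysisError as err:
        code = err.code
    except Exception as err:  # noqa: BLE001 -- totality is the contract
        code = type(err).__name__
    return AnalysisOutcome(
        rep_id=data.rep_id,
        dgm_label=data.dgm_label,
        method_label=method_label,
        status=f"failed:{code}",
    )


def hybrid_with_backup(
    primary,
    backup,
    data: SimulatedDataset,
    *,
    method_label: str,
    triggers: TriggerRules = TriggerRules(),
) -> AnalysisOutcome:
    """Primary analysis with an automatic backup when it fails or looks absurd.

    The trigger rules fire on failure, a separation flag, a divergent point
    estimate, or a wild SE. The returned outcome carries ``backup_used`` so
    that performance reporting can count how often the backup ran — the
    hybrid, not the pure primary method, is then what performance describes.
    """
    out = run_method_guarded(primary, data, method_label=method_label)
    if not triggers.fires(out):
        return replace(out, method_label=method_label)
    backup_out = run_method_guarded(backup, data, method_label=method_label)
    return replace(backup_out, method_label=method_label, backup_used=True)


def _cca_firth(data: SimulatedDataset, settings: MethodSettings) -> AnalysisOutcome:
    df = data.complete_cases()
    if len(df) < 3:
        raise AnalysisError("too_few_rows", f"{len(df)} analysis rows")
    D, X = _design(df)
    fit = fit_logistic_firth(D, X, names=_NAMES_DEC)
    if not fit.converged:
        raise AnalysisError("nonconvergence", "Firth fit did not converge")
    est, se = fit.coef["E"], fit.se["E"]
    return AnalysisOutcome(
        rep_id=data.rep_id,
        dgm_label=data.dgm_label,
        method_label="cca_firth_hybrid",
        estimate=est,
        se=se,
        ci_low=est - _Z975 * se,
        ci_high=est + _Z975 * se,
        df=math.inf,
        separation_flag=False,
    )


def analyze(
    data: SimulatedDataset,
    method_label: str,
    rng: np.random.Generator | None = None,
    settings: MethodSettings = MethodSettings(),
) -> AnalysisOutcome:
    """Dispatch one labelled method on one data set, guarded.

    Labels: 'full', 'cca', 'mi' (needs ``rng``), 'cca_firth_hybrid'
    (complete-case ML with a Firth backup under the trigger rules).
    """
    if method_label == "full":
        return run_method_guarded(
            analyze_complete_records,
            data,
            method_label="full",
            subset="all",
            settings=settings,
        )
    if method_label == "cca":
        return run_method_guarded(
            analyze_complete_records,
            data,
            method_label="cca",
            subset="complete_cases",
            settings=settings,
        )
    if method_label == "mi":
        if rng is None:
            raise ValueError("method 'mi' needs a random generator")
        return run_method_guarded(
            analyze_mi, data, method_label="mi", rng=rng, settings=settings
        )
    if method_label == "cca_firth_hybrid":
        return hybrid_with_backup(
            lambda d: analyze_complete_records(
                d, "complete_cases", settings, method_label="cca_firth_hybrid"
            ),
            lambda d: _cca_firth(d, settings),
            data,
            method_label="cca_firth_hybrid",
            triggers=settings.triggers,
        )
    raise ValueError(f"unknown method label {method_label!r}")
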