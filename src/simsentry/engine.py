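"""The simulation engine: DGMs x methods x repetitions, with recreatable state.

One PCG64 stream drives the whole study and is never re-seeded inside the
loop (re-seeding is the classic bug that makes the second and third
repetitions identical). Immediately before each repetition's data generation
the generator state is serialized into a states data set, so any simulated
data set can be recreated exactly; a second state, captured after data
generation and before the first method runs, allows stochastic analyses
(multiple imputation) to be replayed as well.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dgm import DGMSpec, SimulatedDataset, apply_missingness, default_specs, generate_full
from .methods import AnalysisOutcome, MethodSettings, analyze

__all__ = [
    "RunPlan",
    "StudyResult",
    "run_study",
    "recreate_dataset",
    "verify_rep_distinctness",
    "state_to_token",
    "token_to_state",
    "ESTIMATE_COLUMNS",
    "STATE_COLUMNS",
]

STATE_FORMAT_VERSION = 1

ESTIMATE_COLUMNS = [
    "rep_id", "dgm", "method", "status", "estimate", "se",
    "ci_low", "ci_high", "df", "separation", "backup_used",
]
STATE_COLUMNS = ["rep_id", "dgm", "state_token", "analysis_state_token"]

# rep_id used for the per-DGM record holding the state before the one-off
# full-data generation when fixed_full_data is set
FIXED_FULL_DATA_REP = 0


@dataclass
class RunPlan:
    """Everything that determines a study run."""

    dgm_specs: list[DGMSpec] = field(default_factory=default_specs)
    methods: tuple[str, ...] = ("full", "cca", "mi")
    n_sim: int = 1000
    seed: int = 0
    fixed_full_data: bool = False
    store_datasets: bool = False
    verbose: bool = False
    settings: MethodSettings = field(default_factory=MethodSettings)

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if len(set(self.methods)) != len(self.methods):
            raise ValueError("method labels must be unique")
        labels = [s.label for s in self.dgm_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("DGM labels must be unique")


def state_to_token(rng: np.random.Generator) -> str:
    """Serialize the generator state as a base64 JSON token (versioned)."""
    payload = {"v": STATE_FORMAT_VERSION, "state": rng.bit_generator.state}
    return base64.b64encode(json.dumps(payload).encode()).decode()


def token_to_state(token: str) -> dict:
    payload = json.loads(base64.b64decode(token.encode()).decode())
    if payload.get("v") != STATE_FORMAT_VERSION:
        raise ValueError(f"unsupported state token version {payload.get('v')!r}")
    return payload["state"]


def _restored_rng(token: str) -> np.random.Generator:
    rng = np.random.default_rng()
    rng.bit_generator.state = token_to_state(token)
    return rng


def _outcome_row(out: AnalysisOutcome) -> dict:
    return {
        "rep_id": out.rep_id,
        "dgm": out.dgm_label,
        "method": out.method_label,
        "status": out.status,
        "estimate": out.estimate,
        "se": out.se,
        "ci_low": out.ci_low,
        "ci_high": out.ci_high,
        "df": out.df,
        "separation": int(out.separation_flag),
        "backup_used": int(out.backup_used),
    }


@dataclass
class StudyResult:
    """Estimates and states data sets plus run metadata."""

    estimates: pd.DataFrame
    states: pd.DataFrame
    plan: RunPlan
    datasets: list[SimulatedDataset] | None = None

    @property
    def n_failed(self) -> int:
        return int((self.estimates["status"] != "ok").sum())


def run_study(plan: RunPlan) -> StudyResult:
    """Run the full factorial study: every DGM x repetition x method.

    Exactly one estimates row per (dgm, method, rep) is produced; analysis
    failures appear as rows with a ``failed:<code>`` status, never as
    missing rows, and never abort the run.
    """
    rng = np.random.default_rng(plan.seed)
    est_rows: list[dict] = []
    state_rows: list[dict] = []
    stored: list[SimulatedDataset] | None = [] if plan.store_datasets else None

    for spec in plan.dgm_specs:
        fixed_full: SimulatedDataset | None = None
        if plan.fixed_full_data:
            state_rows.append(
                {
                    "rep_id": FIXED_FULL_DATA_REP,
                    "dgm": spec.label,
                    "state_token": state_to_token(rng),
                    "analysis_state_token": "",
                }
            )
            fixed_full = generate_full(spec, rng, rep_id=FIXED_FULL_DATA_REP)

        for rep in range(1, plan.n_sim + 1):
            gen_token = state_to_token(rng)
            if fixed_full is not None:
                full = replace(fixed_full, rep_id=rep)
            else:
                full = generate_full(spec, rng, rep_id=rep)
            data = apply_missingness(full, spec, rng)
            data.validate(expected_n=spec.n_obs)
            analysis_token = state_to_token(rng)
            state_rows.append(
                {
                    "rep_id": rep,
                    "dgm": spec.label,
                    "state_token": gen_token,
                    "analysis_state_token": analysis_token,
                }
            )
            if stored is not None:
                stored.append(data)
            for method in plan.methods:
                out = analyze(data, method, rng=rng, settings=plan.settings)
                est_rows.append(_outcome_row(out))
                if plan.verbose:
                    print(
                        f"[{spec.label} rep {rep} {method}] status={out.status} "
                        f"estimate={out.estimate:.4f} se={out.se:.4f} "
                        f"(log odds scale)"
                    )

    estimates = pd.DataFrame(est_rows, columns=ESTIMATE_COLUMNS)
    states = pd.DataFrame(state_rows, columns=STATE_COLUMNS)
    return StudyResult(estimates=estimates, states=states, plan=plan, datasets=stored)


def _spec_for(plan: RunPlan, dgm_label: str) -> DGMSpec:
    for spec in plan.dgm_specs:
        if spec.label == dgm_label:
            return spec
    raise KeyError(f"no DGM labelled {dgm_label!r} in the plan")


def _token_for(states: pd.DataFrame, rep_id: int, dgm_label: str, col: str) -> str:
    sel = states[(states["rep_id"] == rep_id) & (states["dgm"] == dgm_label)]
    if len(sel) == 0:
        raise KeyError(f"no states record for rep {rep_id}, dgm {dgm_label!r}")
    return str(sel.iloc[0][col])


def recreate_dataset(
    states: pd.DataFrame, rep_id: int, dgm_label: str, plan: RunPlan
) -> SimulatedDataset:
    """Recreate one repetition's simulated data set from its stored state.

    The result is identical — every field — to the data set analysed during
    the original run. Under ``fixed_full_data`` the shared full data are
    regenerated from the per-DGM record first, then the repetition's
    missingness draw is replayed.
    """
    spec = _spec_for(plan, dgm_label)
    gen_token = _token_for(states, rep_id, dgm_label, "state_token")
    if plan.fixed_full_data:
        full_token = _token_for(states, FIXED_FULL_DATA_REP, dgm_label, "state_token")
        full = replace(generate_full(spec, _restored_rng(full_token)), rep_id=rep_id)
        return apply_missingness(full, spec, _restored_rng(gen_token))
    rng = _restored_rng(gen_token)
    full = generate_full(spec, rng, rep_id=rep_id)
    return apply_missingness(full, spec, rng)


def recreate_analysis_rng(
    states: pd.DataFrame, rep_id: int, dgm_label: str
) -> np.random.Generator:
    """Generator positioned as it was before the repetition's first
    stochastic analysis — replaying MI with it reproduces the stored result."""
    token = _token_for(states, rep_id, dgm_label, "analysis_state_token")
    if not token:
        raise KeyError(
            f"no analysis state stored for rep {rep_id}, dgm {dgm_label!r}"
        )
    return _restored_rng(token)


@dataclass
class DistinctnessReport:
    ok: bool
    duplicate_pairs: list[tuple[str, str, int, int]]  # (dgm, method, rep_a, rep_b)

    def summary(self) -> str:
        if self.ok:
            return "repetitions are distinct: no two reps share (estimate, se)"
        lines = ["DUPLICATE repetitions found (possible re-seeding bug):"]
        for dgm, method, a, b in self.duplicate_pairs:
            lines.append(f"  {dgm}/{method}: reps {a} and {b} have identical (estimate, se)")
        return "\n".join(lines)


def verify_rep_distinctness(estimates: pd.DataFrame) -> DistinctnessReport:
    """Check that no two repetitions of the same dgm x method produced
    identical (estimate, se) — the signature of a loop that re-seeds the
    random stream each repetition."""
    if estimates["rep_id"].nunique() < 2:
        raise ValueError("need at least 2 repetitions to check distinctness")
    pairs: list[tuple[str, str, int, int]] = []
    ok_rows = estimates[estimates["status"] == "ok"]
    for (dgm, method), grp in ok_rows.groupby(["dgm", "method"], sort=False):
        dup = grp.groupby(["estimate", "se"], sort=False)["rep_id"].agg(list)
        for reps in dup:
            if len(reps) > 1:
                reps = sorted(reps)
                pairs.extend(
                    (str(dgm), str(method), int(reps[i]), int(reps[i + 1]))
                    for i in range(len(reps) - 1)
                )
    return DistinctnessReport(ok=not pairs, duplicate_pairs=pairs)
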