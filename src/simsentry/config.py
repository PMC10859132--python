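"""Run configuration: a single YAML (or JSON) document mirroring RunPlan.

Unknown keys are rejected outright — a silently ignored misspelt key is
exactly the kind of error this toolkit exists to prevent. The parsed
config is echoed verbatim into the run metadata.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dgm import DGMSpec, default_specs
from .engine import RunPlan
from .methods import MethodSettings, TriggerRules

__all__ = ["load_config", "plan_from_config", "plan_to_dict", "ConfigError"]

_TOP_KEYS = {
    "seed", "n_sim", "n_obs", "methods", "m_imputations", "alpha",
    "divergence_threshold", "fixed_full_data", "store_datasets", "verbose",
    "dgms", "triggers",
}
_DGM_KEYS = {
    "label", "n_obs", "mechanism", "alpha0", "alphaC", "beta0", "betaE",
    "betaC", "gamma0", "gammaE", "gammaD", "gammaC",
}
_TRIGGER_KEYS = {"on_separation", "max_abs_estimate", "max_se"}


class ConfigError(ValueError):
    pass


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    return doc


def plan_from_config(doc: dict, seed: int | None = None, n_sim: int | None = None) -> RunPlan:
    """Build a RunPlan from a parsed config; CLI flags may override seed/reps."""
    _reject_unknown(doc, _TOP_KEYS, "config")
    if seed is None:
        if "seed" not in doc:
            raise ConfigError("a seed is required (config key 'seed' or --seed)")
        seed = int(doc["seed"])
    n_obs = int(doc.get("n_obs", 500))
    if "dgms" in doc:
        specs = []
        for entry in doc["dgms"]:
            _reject_unknown(entry, _DGM_KEYS, f"dgm {entry.get('label', '?')!r}")
            entry = dict(entry)
            entry.setdefault("n_obs", n_obs)
            specs.append(DGMSpec(**entry))
    else:
        specs = default_specs(n_obs=n_obs)
    trig_doc = doc.get("triggers", {})
    _reject_unknown(trig_doc, _TRIGGER_KEYS, "triggers")
    settings = MethodSettings(
        m_imputations=int(doc.get("m_imputations", 20)),
        alpha=float(doc.get("alpha", 0.05)),
        divergence_threshold=float(doc.get("divergence_threshold", 10.0)),
        triggers=TriggerRules(**trig_doc),
    )
    return RunPlan(
        dgm_specs=specs,
        methods=tuple(doc.get("methods", ("full", "cca", "mi"))),
        n_sim=int(n_sim if n_sim is not None else doc.get("n_sim", 1000)),
        seed=seed,
        fixed_full_data=bool(doc.get("fixed_full_data", False)),
        store_datasets=bool(doc.get("store_datasets", False)),
        verbose=bool(doc.get("verbose", False)),
        settings=settings,
    )


def plan_to_dict(plan: RunPlan) -> dict:
    return {
        "seed": plan.seed,
        "n_sim": plan.n_sim,
        "methods": list(plan.methods),
        "fixed_full_data": plan.fixed_full_data,
        "store_datasets": plan.store_datasets,
        "m_imputations": plan.settings.m_imputations,
        "alpha": plan.settings.alpha,
        "divergence_threshold": plan.settings.divergence_threshold,
        "triggers": {
            "on_separation": plan.settings.triggers.on_separation,
            "max_abs_estimate": plan.settings.triggers.max_abs_estimate,
            "max_se": plan.settings.triggers.max_se,
        },
        "dgms": [s.to_dict() for s in plan.dgm_specs],
    }
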