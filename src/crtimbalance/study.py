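"""Factorial simulation study: grid construction, per-condition Monte Carlo
runs and grid-wide verification.

The default study crosses cluster size (5, 30, 50), intraclass correlation
(0.01, 0.05, 0.1), covariate effect size (0.2, 0.5, 0.8) and imbalance
quantile (0.025, 0.05, 0.1, 0.5, 0.9, 0.95, 0.975) — 189 conditions — with a
treatment effect of 0.5 outcome SDs, a two-sided 5 % test and an 80 % power
target.  For each condition the number of clusters is planned under assumed
covariate balance, replicate trials are generated from the adjusted model,
both models are fitted to every replicate, and the three evaluation criteria
are aggregated per model.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import (
    DEFAULT_MIN_N2,
    PlanningSpec,
    build_design,
    required_clusters,
)
from .fit import fit_cluster_means
from .metrics import (
    ConditionSummary,
    nominal_power_pct,
    summarize_model,
)
from .simulate import ModelParams, replicate_seed

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "SimulationCondition",
    "default_grid",
    "run_condition",
    "run_study",
    "verify_report",
    "planning_table",
]

#: Factor levels of the default study.
DEFAULT_FACTORS = {
    "n1": [5, 30, 50],
    "rho": [0.01, 0.05, 0.1],
    "beta2": [0.2, 0.5, 0.8],
    "q": [0.025, 0.05, 0.1, 0.5, 0.9, 0.95, 0.975],
}

#: Constants held fixed across the default grid.
DEFAULT_CONSTANTS = {"beta1": 0.5, "alpha": 0.05, "power_target": 0.8, "beta0": 0.0}

#: Acceptability thresholds for the two bias criteria (absolute percentages).
PARAM_BIAS_THRESHOLD = 10.0
SE_BIAS_THRESHOLD = 5.0


@dataclass(frozen=True)
class StudyConfig:
    """Factor levels, fixed constants and run settings of one study."""

    factor_levels: dict = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    constants: dict = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))
    reps: int = 5000
    seed: int = 1
    min_n2: int = DEFAULT_MIN_N2

    def __post_init__(self) -> None:
        for name in ("n1", "rho", "beta2", "q"):
            levels = self.factor_levels.get(name)
            if not levels:
                raise ValueError(f"factor '{name}' has no levels configured")
        for name in ("beta1", "alpha", "power_target"):
            if name not in self.constants:
                raise ValueError(f"missing study constant '{name}'")

    @property
    def planning_spec(self) -> PlanningSpec:
        return PlanningSpec(
            alpha=self.constants["alpha"],
            power_target=self.constants["power_target"],
            beta1_target=self.constants["beta1"],
            rho_xz_assumed=0.0,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        factor_levels = dict(DEFAULT_FACTORS)
        factor_levels.update(raw.get("factor_levels", {}))
        constants = dict(DEFAULT_CONSTANTS)
        constants.update(raw.get("constants", {}))
        run = raw.get("run", {})
        return cls(
            factor_levels=factor_levels,
            constants=constants,
            reps=int(run.get("reps", 5000)),
            seed=int(run.get("seed", 1)),
            min_n2=int(run.get("min_n2", DEFAULT_MIN_N2)),
        )


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial grid.

    ``index`` is the condition's position in the sorted Cartesian product of
    factor levels; replicate seeds derive from it, so results do not depend
    on the order in which conditions are executed.
    """

    index: int
    n1: int
    rho: float
    beta2: float
    q: float


def default_grid(config: StudyConfig | None = None) -> list[SimulationCondition]:
    """Full factorial grid in deterministic (sorted-levels) order."""
    if config is None:
        config = StudyConfig()
    levels = config.factor_levels
    product = itertools.product(
        sorted(levels["n1"]),
        sorted(levels["rho"]),
        sorted(levels["beta2"]),
        sorted(levels["q"]),
    )
    return [
        SimulationCondition(index=i, n1=n1, rho=rho, beta2=beta2, q=q)
        for i, (n1, rho, beta2, q) in enumerate(product)
    ]


def _condition_sufficient_stats(design, params, reps, master_seed, condition_index):
    """Cluster means and within-cluster SS for every replicate.

    Draws replicate-by-replicate with the same seed derivation as
    :func:`crtimbalance.simulate.replicate_stream`, so per-trial fits of a
    streamed replicate match the stacked fits bitwise.
    """
    n2, n1 = design.n2, design.n1
    mean = params.beta0 + params.beta1 * design.x + params.beta2 * design.z
    su = np.sqrt(params.sigma_u2)
    se = np.sqrt(params.sigma_e2)
    means = np.empty((reps, n2))
    ssw = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng(replicate_seed(master_seed, condition_index, r))
        u = rng.normal(0.0, su, size=n2)
        e = rng.normal(0.0, se, size=(n2, n1))
        ebar = e.mean(axis=1)
        means[r] = mean + u + ebar
        ssw[r] = ((e - ebar[:, None]) ** 2).sum()
    return means, ssw


def run_condition(
    condition: SimulationCondition,
    reps: int,
    master_seed: int,
    *,
    constants: dict | None = None,
    min_n2: int = DEFAULT_MIN_N2,
) -> ConditionSummary:
    """Simulate one condition and aggregate the evaluation criteria.

    Deterministic given ``(condition, reps, master_seed)``: replicate seeds
    derive from the condition index, never from execution order.
    """
    if reps < 2:
        raise ValueError("need reps >= 2 to estimate the SD of the estimates")
    constants = dict(DEFAULT_CONSTANTS, **(constants or {}))
    beta1 = constants["beta1"]
    alpha = constants["alpha"]
    plan = PlanningSpec(
        alpha=alpha,
        power_target=constants["power_target"],
        beta1_target=beta1,
        rho_xz_assumed=0.0,
    )
    design = build_design(condition.n1, condition.rho, condition.q, plan, min_n2=min_n2)
    params = ModelParams.from_icc(
        condition.rho, beta1, condition.beta2, constants.get("beta0", 0.0)
    )
    means, ssw = _condition_sufficient_stats(
        design, params, reps, master_seed, condition.index
    )
    summaries = {}
    for adjusted, tag in ((True, "adjusted"), (False, "unadjusted")):
        res = fit_cluster_means(design, means, ssw, adjusted, alpha)
        summaries[tag] = summarize_model(
            tag, res["beta1_hat"], res["se_beta1"], res["reject"], beta1
        )
    return ConditionSummary(
        n1=condition.n1,
        rho=condition.rho,
        beta2=condition.beta2,
        q=condition.q,
        n2=design.n2,
        k=design.imbalance.k,
        rho_xz=design.imbalance.rho_xz,
        reps=reps,
        failures=0,
        nominal_power_pct=nominal_power_pct(
            condition.n1, design.n2, condition.rho, beta1, alpha
        ),
        adjusted=summaries["adjusted"],
        unadjusted=summaries["unadjusted"],
    )


def planning_table(config: StudyConfig | None = None) -> pd.DataFrame:
    """Planned designs for every (n1, rho, q) cell of the grid."""
    if config is None:
        config = StudyConfig()
    plan = config.planning_spec
    rows = []
    for n1 in sorted(config.factor_levels["n1"]):
        for rho in sorted(config.factor_levels["rho"]):
            raw, n2 = required_clusters(n1, rho, plan, min_n2=config.min_n2)
            for q in sorted(config.factor_levels["q"]):
                design = build_design(n1, rho, q, plan, min_n2=config.min_n2)
                rows.append(
                    {
                        "n1": n1,
                        "rho": rho,
                        "q": q,
                        "raw_n2": raw,
                        "n2": n2,
                        "k": design.imbalance.k,
                        "rho_xz": design.imbalance.rho_xz,
                    }
                )
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig | None = None,
    *,
    reps: int | None = None,
    master_seed: int | None = None,
    out: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the whole grid; one row per condition per model.

    When ``out`` is given, writes ``<out>`` as CSV plus a companion
    ``<out stem>_metadata.json`` recording the configuration, seed, package
    version and any conditions whose planned number of clusters was raised to
    the configured minimum.
    """
    if config is None:
        config = StudyConfig()
    reps = config.reps if reps is None else reps
    master_seed = config.seed if master_seed is None else master_seed
    grid = default_grid(config)
    plan = config.planning_spec

    iterator = grid
    if progress:
        from tqdm import tqdm

        iterator = tqdm(grid, desc="conditions", unit="cond")

    rows = []
    for cond in iterator:
        summary = run_condition(
            cond,
            reps,
            master_seed,
            constants=config.constants,
            min_n2=config.min_n2,
        )
        for row in summary.rows():
            row["condition_index"] = cond.index
            rows.append(row)
        logger.debug(
            "condition %d (n1=%d rho=%g beta2=%g q=%g) done", cond.index,
            cond.n1, cond.rho, cond.beta2, cond.q,
        )
    results = pd.DataFrame(rows)

    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        results.to_csv(out, index=False)
        clamped = []
        for n1 in sorted(config.factor_levels["n1"]):
            for rho in sorted(config.factor_levels["rho"]):
                raw, n2 = required_clusters(n1, rho, plan, min_n2=config.min_n2)
                if 4 * np.ceil(raw / 4.0) < config.min_n2:
                    clamped.append({"n1": n1, "rho": rho, "raw_n2": raw, "n2": n2})
        metadata = {
            "version": __version__,
            "seed": master_seed,
            "reps": reps,
            "min_n2": config.min_n2,
            "factor_levels": config.factor_levels,
            "constants": config.constants,
            "conditions": len(grid),
            "min_n2_deviations": clamped,
        }
        meta_path = out.with_name(out.stem + "_metadata.json")
        meta_path.write_text(json.dumps(metadata, indent=2))
        logger.info("results written to %s (metadata: %s)", out, meta_path)
    return results


def _signed_extreme(values: pd.Series) -> float:
    """The entry with the largest absolute magnitude, sign preserved."""
    values = values.to_numpy()
    return float(values[np.argmax(np.abs(values))])


REQUIRED_COLUMNS = {
    "model",
    "n1",
    "rho",
    "beta2",
    "q",
    "parameter_bias_pct",
    "se_bias_pct",
    "empirical_power_pct",
    "nominal_power_pct",
}


def verify_report(results: pd.DataFrame) -> dict:
    """Grid-wide extrema and acceptability flags.

    Flags conditions whose absolute parameter bias exceeds 10 % or whose
    absolute standard-error bias exceeds 5 %, per model, and reports the
    grid-wide extreme parameter bias, SE bias and power loss versus nominal.
    """
    if results is None or len(results) == 0 or not REQUIRED_COLUMNS <= set(
        results.columns
    ):
        raise ValueError(
            "results table is empty or lacks required columns "
            f"{sorted(REQUIRED_COLUMNS)}"
        )
    report: dict = {"models": {}}
    for model, sub in results.groupby("model"):
        power_loss = sub["nominal_power_pct"] - sub["empirical_power_pct"]
        flagged_param = sub[sub["parameter_bias_pct"].abs() > PARAM_BIAS_THRESHOLD]
        flagged_se = sub[sub["se_bias_pct"].abs() > SE_BIAS_THRESHOLD]
        report["models"][model] = {
            "extreme_parameter_bias_pct": _signed_extreme(sub["parameter_bias_pct"]),
            "extreme_se_bias_pct": _signed_extreme(sub["se_bias_pct"]),
            "max_power_loss_pct_points": float(power_loss.max()),
            "worst_power_loss_condition": {
                "n1": int(sub.loc[power_loss.idxmax(), "n1"]),
                "rho": float(sub.loc[power_loss.idxmax(), "rho"]),
                "beta2": float(sub.loc[power_loss.idxmax(), "beta2"]),
                "q": float(sub.loc[power_loss.idxmax(), "q"]),
            },
            "n_flagged_parameter_bias": int(len(flagged_param)),
            "n_flagged_se_bias": int(len(flagged_se)),
        }
    return report
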