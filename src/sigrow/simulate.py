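"""Synthetic growth series and parameter-recovery experiments.

Real crop biomass series are destructive field measurements; none of the
bundled crops' raw observations are publicly available.  This module stands
in for them: it evaluates a growth model on an observation grid and adds
seeded Gaussian observation noise (additive sigma in grams, or proportional
to the signal as a coefficient of variation).  Negative draws are floored at
zero, a slight truncation of the noise distribution consistent with dry
mass being non-negative.

:func:`recovery_experiment` closes the loop: simulate from known parameters,
refit, and summarise how well the estimates recover the truth.  It is the
package's validation harness for the fitting claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import BSGParameters, NSGParameters
from .exceptions import ParameterError
from .model import (
    BSGModel,
    FitSettings,
    NSGModel,
    compare_models,
    predict_biomass,
)
from .series import GrowthSeries

__all__ = [
    "NoiseModel",
    "simulate_series",
    "default_design_times",
    "RecoverySummary",
    "recovery_experiment",
    "model_selection_experiment",
]

#: observation count of the default synthetic design
DEFAULT_N_POINTS = 30
#: coefficient of variation of the default proportional observation noise
DEFAULT_CV = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian observation noise specification.

    kind
        ``"none"`` (deterministic trajectory), ``"additive"`` (sigma =
        ``scale`` grams) or ``"proportional"`` (sigma = ``scale`` x signal,
        i.e. ``scale`` is a coefficient of variation).
    scale
        Noise magnitude, >= 0.
    seed
        RNG seed; required for reproducibility when kind != "none".
    """

    kind: str = "none"
    scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive", "proportional"):
            raise ParameterError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ParameterError(f"noise scale must be >= 0, got {self.scale}")


def default_design_times(params, n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Even observation grid from t_b + 1 to t_e, the default synthetic design."""
    return np.linspace(params.t_b + 1.0, params.t_e, n_points)


def simulate_series(
    params: NSGParameters | BSGParameters,
    times=None,
    noise: NoiseModel | None = None,
    label: str = "",
) -> GrowthSeries:
    """Simulate one observed series from a growth model.

    ``biomass = model trajectory + noise``, floored at 0.  With
    ``noise.kind == "none"`` the output equals the deterministic forward
    model exactly.  Identical inputs (including ``noise.seed``) give
    identical series.
    """
    if noise is None:
        noise = NoiseModel()
    if times is None:
        times = default_design_times(params)
    times = np.asarray(times, dtype=float)
    w = np.asarray(predict_biomass(params, times), dtype=float)
    if noise.kind != "none" and noise.scale > 0:
        rng = np.random.default_rng(noise.seed)
        if noise.kind == "additive":
            sigma = noise.scale
        else:
            sigma = noise.scale * w
        w = w + rng.normal(0.0, 1.0, size=w.shape) * sigma
        w = np.maximum(w, 0.0)
    return GrowthSeries(times, w, label=label)


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate-level and aggregated results of a recovery experiment."""

    model_id: str
    true_params: NSGParameters | BSGParameters
    true_wmax: float
    n_replicates: int
    n_failures: int
    seed: int
    replicates: pd.DataFrame = field(repr=False)

    def _rel_errors(self, column: str) -> np.ndarray:
        return self.replicates[f"rel_err_{column}"].to_numpy()

    def bias(self, name: str) -> float:
        """Mean signed error of one quantity (parameter name or 'w_max')."""
        return float(self.replicates[f"err_{name}"].mean())

    def median_rel_err(self, name: str) -> float:
        """Median |relative error| of one quantity."""
        return float(np.median(np.abs(self._rel_errors(name))))

    def rmse(self, name: str) -> float:
        return float(np.sqrt(np.mean(self.replicates[f"err_{name}"] ** 2)))

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("c", "k", "t_b", "t_e") if self.model_id == "NSG" else (
            "c_m", "t_m", "t_b", "t_e")

    def summary(self) -> str:
        lines = [
            f"parameter recovery: {self.model_id}, "
            f"{self.n_replicates} replicate(s), seed {self.seed}",
            f"  failures: {self.n_failures}",
            f"  {'quantity':>8s} {'true':>12s} {'bias':>12s} "
            f"{'med|rel err|':>12s} {'RMSE':>12s}",
        ]
        truths = dict(zip(self.param_names, self.true_params.astuple()))
        truths["w_max"] = self.true_wmax
        for name, true in truths.items():
            lines.append(
                f"  {name:>8s} {true:12.3f} {self.bias(name):12.4g} "
                f"{self.median_rel_err(name):12.4%} {self.rmse(name):12.4g}"
            )
        return "\n".join(lines)


def recovery_experiment(
    params: NSGParameters | BSGParameters,
    n_points: int = DEFAULT_N_POINTS,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> RecoverySummary:
    """Simulate-from-known-parameters, refit, and summarise recovery.

    Each replicate draws its own noise realisation and fit seed, both
    derived deterministically from ``seed``.  Replicates whose fit raises
    are counted as failures rather than aborting the experiment.

    Note: with large ``k * (t_e - t_b)`` the NSG exponential shoulder is
    confined to a sliver below ``t_e`` and ``k`` is only weakly identified;
    ``w_max`` and ``t_e`` remain well determined.
    """
    if n_points < 5:
        raise ParameterError(f"n_points must be >= 5, got {n_points}")
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be >= 1, got {n_replicates}")
    if noise is None:
        noise = NoiseModel()
    model_id = "NSG" if isinstance(params, NSGParameters) else "BSG"
    model_cls = NSGModel if model_id == "NSG" else BSGModel
    true_wmax = float(predict_biomass(params, params.t_e))
    times = default_design_times(params, n_points)
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    )
    names = ("c", "k", "t_b", "t_e") if model_id == "NSG" else (
        "c_m", "t_m", "t_b", "t_e")
    truths = dict(zip(names, params.astuple()))
    truths["w_max"] = true_wmax

    rows, n_failures = [], 0
    for rep, child in enumerate(child_seeds):
        child = int(child)
        series = simulate_series(
            params, times,
            noise=NoiseModel(noise.kind, noise.scale, seed=child),
            label=f"replicate-{rep}",
        )
        try:
            res = model_cls(series).fit(seed=child, settings=settings)
        except Exception:
            n_failures += 1
            continue
        estimates = dict(zip(names, res.params.astuple()))
        estimates["w_max"] = res.wmax
        row = {"replicate": rep, "seed": child, "sse": res.sse,
               "r_squared": res.rsquared}
        for name in (*names, "w_max"):
            est, true = estimates[name], truths[name]
            row[f"est_{name}"] = est
            row[f"err_{name}"] = est - true
            row[f"rel_err_{name}"] = (est - true) / true if true != 0 else np.nan
        rows.append(row)

    return RecoverySummary(
        model_id=model_id,
        true_params=params,
        true_wmax=true_wmax,
        n_replicates=n_replicates,
        n_failures=n_failures,
        seed=int(seed),
        replicates=pd.DataFrame(rows),
    )


def model_selection_experiment(
    params: NSGParameters | BSGParameters,
    n_points: int = DEFAULT_N_POINTS,
    noise: NoiseModel | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    settings: FitSettings | None = None,
) -> dict[str, int]:
    """How often AIC picks each model on data simulated from ``params``.

    Each replicate simulates a noisy series from the generating model, fits
    both growth curves, and records the AIC-preferred one.  Returns
    ``{"NSG": count, "BSG": count}``.  Fully seeded: replicate noise and fit
    seeds derive deterministically from ``seed``.
    """
    if noise is None:
        noise = NoiseModel("proportional", DEFAULT_CV)
    times = default_design_times(params, n_points)
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    )
    wins = {"NSG": 0, "BSG": 0}
    for child in child_seeds:
        child = int(child)
        series = simulate_series(
            params, times,
            noise=NoiseModel(noise.kind, noise.scale, seed=child))
        report = compare_models(series, seed=child, settings=settings)
        wins[report.preferred] += 1
    return wins
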