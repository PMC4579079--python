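"""Uncertainty experiments: factorial designs, one-at-a-time sweeps,
perturbed-physics ensembles and stochastic cover perturbations.

The two-stage protocol mirrors the standard practice for this class of
model: stage 1 is a full factorial over the handful of most uncertain
parameters (six parameters at three levels each gives 729 members),
scored against an observed/synthetic-truth trend; stage 2 sweeps every
parameter one at a time around the stage-1 best member, optionally
combined with annually redrawn multiplicative parameter perturbations
(+-10% by default) and a stochastic perturbation of the tree-cover
matrix to widen the ensemble spread.

Seeding: a master seed spawns one substream per (member, year), so
ensemble members are statistically independent, order-insensitive and
bit-reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import RasterField
from .params import PHYSICAL_PARAMS, RiskParams

__all__ = [
    "FactorialDesign",
    "PerturbationConfig",
    "factorial_design",
    "oat_design",
    "ppe_perturb",
    "stochastic_cover_perturbation",
    "run_ensemble",
    "select_best",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FactorialDesign:
    """Enumerated full-factorial parameter sets."""

    names: tuple[str, ...]
    levels: tuple[tuple[float, ...], ...]
    members: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.members)


def factorial_design(levels: dict[str, list[float]]) -> FactorialDesign:
    """Full Cartesian product of per-parameter level lists.

    Member order is deterministic lexicographic in the given parameter
    order (last parameter varies fastest).
    """
    if not levels:
        raise ValueError("at least one parameter required")
    names = tuple(levels)
    level_lists = []
    for name in names:
        vals = list(levels[name])
        if not vals:
            raise ValueError(f"empty level list for parameter {name!r}")
        level_lists.append(tuple(vals))
    members = tuple(
        dict(zip(names, combo)) for combo in itertools.product(*level_lists)
    )
    return FactorialDesign(names, tuple(level_lists), members)


def oat_design(
    reference: RiskParams, sweeps: dict[str, list[float]]
) -> list[tuple[str, float, RiskParams]]:
    """One-at-a-time sweep around a reference parameter set.

    One member per (parameter, value) pair with all other parameters
    at the reference; an empty sweep yields the reference alone,
    labelled ``("reference", nan, reference)``.
    """
    members: list[tuple[str, float, RiskParams]] = []
    for name, values in sweeps.items():
        for v in values:
            members.append((name, float(v), reference.with_overrides(**{name: v})))
    if not members:
        members.append(("reference", float("nan"), reference))
    return members


@dataclass(frozen=True)
class PerturbationConfig:
    """Knobs of the stochastic machinery.

    ppe_amplitude
        Half-width of the uniform multiplicative parameter draws
        (0.10 = +-10%); 0 disables the PPE.
    stochastic_sigma
        Standard deviation of the multiplicative Gaussian cover
        perturbation; 0 disables it.
    seed, member_id
        Master seed and member index feeding the per-(member, year)
        substreams.
    """

    seed: int
    member_id: int = 0
    ppe_amplitude: float = 0.10
    stochastic_sigma: float = 0.0
    perturbed_names: tuple[str, ...] = PHYSICAL_PARAMS

    def __post_init__(self) -> None:
        if self.ppe_amplitude < 0 or self.stochastic_sigma < 0:
            raise ValueError("perturbation amplitudes must be >= 0")

    def _rng(self, year: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.seed), int(self.member_id), int(year), stream]
        )

    def perturb_params(self, params: RiskParams, year: int) -> RiskParams:
        return ppe_perturb(params, self, year, self.member_id)

    def perturb_cover(
        self, cover: RasterField, year: int, f_t: float
    ) -> RasterField:
        if self.stochastic_sigma == 0.0:
            return cover
        return stochastic_cover_perturbation(
            cover, self.stochastic_sigma, rng=self._rng(year, 1), f_t=f_t
        )


def ppe_perturb(
    params: RiskParams,
    config: PerturbationConfig,
    year: int,
    member_id: int | None = None,
) -> RiskParams:
    """Multiply each physical parameter by a uniform[1-a, 1+a] draw.

    Draws are redrawn every year and are deterministic in
    (seed, member, year).
    """
    a = config.ppe_amplitude
    if a == 0.0:
        return params
    member = config.member_id if member_id is None else member_id
    rng = np.random.default_rng([int(config.seed), int(member), int(year), 0])
    factors = rng.uniform(1.0 - a, 1.0 + a, size=len(config.perturbed_names))
    overrides = {
        name: getattr(params, name) * f
        for name, f in zip(config.perturbed_names, factors)
    }
    return params.with_overrides(**overrides)


def stochastic_cover_perturbation(
    cover: RasterField,
    sigma: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    f_t: float = 1.0,
) -> RasterField:
    """Multiplicative Gaussian noise on the tree-cover matrix.

    Each valid cell is scaled by (1 + N(0, sigma^2)) and the result is
    clamped to [0, f_t].  ``sigma = 0`` returns the field unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return cover
    if rng is None:
        if seed is None:
            raise ValueError("a seed or generator is required when sigma > 0")
        rng = np.random.default_rng(seed)
    noise = 1.0 + rng.normal(0.0, sigma, size=cover.grid.shape)
    out = np.clip(cover.values * noise, 0.0, f_t)
    out = np.where(cover.mask, cover.values, out)
    return cover.with_values(out)


def run_ensemble(
    design: FactorialDesign | list[dict],
    simulate_and_score,
    reference: RiskParams | None = None,
) -> pd.DataFrame:
    """Run one simulation + evaluation per design member.

    ``simulate_and_score(params) -> dict`` must return at least the
    metrics ``R``, ``RMSE`` and ``bias`` for one parameter set.  A
    member that raises is recorded with NaN metrics rather than
    aborting the ensemble.  Returns one row per member with its
    parameter overrides and metrics.
    """
    members = design.members if isinstance(design, FactorialDesign) else list(design)
    if not members:
        raise ValueError("empty design")
    ref = reference if reference is not None else RiskParams()
    rows = []
    for idx, overrides in enumerate(members):
        params = ref.with_overrides(**overrides)
        row: dict = {"member": idx, **overrides}
        try:
            row.update(simulate_and_score(params))
        except Exception as exc:  # member failure recorded, not fatal
            logger.warning("ensemble member %d failed: %s", idx, exc)
            row.update({"R": np.nan, "RMSE": np.nan, "bias": np.nan,
                        "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)


def select_best(results: pd.DataFrame, metric: str) -> pd.Series:
    """Pick the best member: argmax R, argmin RMSE or argmin |bias|."""
    if metric == "R":
        idx = results["R"].idxmax()
    elif metric == "RMSE":
        idx = results["RMSE"].idxmin()
    elif metric == "bias":
        idx = results["bias"].abs().idxmin()
    else:
        raise ValueError(f"unknown selection metric {metric!r}")
    return results.loc[idx]
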