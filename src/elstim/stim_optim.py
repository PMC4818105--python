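"""Fixed-power stimulation efficiency: ERF-proportional vs. equal-amplitude strategies.

With identical electrode geometries, fixing the total stimulation power is
equivalent to fixing the Euclidean norm of the stimulus vector.  Along a unit
direction u, the model's response is driven by the projection t (w+_hat . u),
so the half-saturation threshold scale is t = c+ / (w+_hat . u); by
Cauchy-Schwarz this is minimized exactly when u is parallel to w+.  The
comparison of interest is the ratio of the ERF-proportional threshold to the
best naive strategy (equal currents on the 1-3 electrodes nearest the cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, UnreachableThresholdError
from .nonlinearity import LNModel
from .subspace import ERFPair

__all__ = [
    "StimStrategy",
    "ThresholdComparison",
    "make_strategies",
    "threshold_at_fixed_power",
    "compare_strategies",
]


@dataclass
class StimStrategy:
    """Unit-norm stimulation direction over electrodes."""

    direction: np.ndarray
    label: str  # "naive-1", "naive-2", "naive-3", "erf"

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0):
            raise InvalidParameterError(f"strategy direction must be unit norm, got {n}")


@dataclass
class ThresholdComparison:
    thresholds: dict[str, float]  # uA scale per strategy
    best_naive: str
    ratio: float  # erf threshold / best naive threshold


def make_strategies(
    erf: ERFPair,
    electrode_positions: np.ndarray,
    cell_position: np.ndarray,
    max_naive: int = 3,
    signed: bool = False,
) -> list[StimStrategy]:
    """Naive-k strategies on the k nearest electrodes plus the ERF direction.

    Naive amplitudes are equal and positive (anodic-first) by default;
    ``signed=True`` instead matches the sign of w+ on each chosen electrode.
    Distance ties are broken by electrode index (lower first).
    """
    if erf.w_plus is None:
        raise InvalidParameterError("ERF-proportional strategy requires w_plus")
    pos = np.asarray(electrode_positions, dtype=float)
    cell = np.asarray(cell_position, dtype=float)
    d = np.linalg.norm(pos - cell, axis=1)
    order = np.lexsort((np.arange(d.size), d))  # stable: index breaks ties
    strategies = []
    for k in range(1, max_naive + 1):
        u = np.zeros(d.size)
        chosen = order[:k]
        amp = 1.0 / np.sqrt(k)
        if signed:
            signs = np.sign(erf.w_plus[chosen])
            signs[signs == 0] = 1.0
            u[chosen] = amp * signs
        else:
            u[chosen] = amp
        strategies.append(StimStrategy(direction=u, label=f"naive-{k}"))
    w = erf.w_plus
    strategies.append(StimStrategy(direction=w / np.linalg.norm(w), label="erf"))
    return strategies


def threshold_at_fixed_power(
    model: LNModel,
    strategy: StimStrategy,
    method: str = "analytic",
    t_max: float = 1e7,
) -> float:
    """Smallest scale t > 0 reaching half-saturation along the strategy direction.

    The threshold is where N+ along the ray t*u reaches a+/2, i.e. where the
    projection onto the normalized w+ equals c+.  For the pure rising-sigmoid
    form this is t = c+ / (w+_hat . u); ``method="bisect"`` solves the same
    condition numerically and is the hook for variants with baseline or
    off-side terms enabled.
    """
    if model.w_plus is None:
        raise InvalidParameterError("model has no positive ERF")
    w_hat = model.w_plus / np.linalg.norm(model.w_plus)
    cos = float(w_hat @ strategy.direction)
    if cos <= 0:
        raise UnreachableThresholdError(
            f"strategy {strategy.label} has non-positive alignment with w_plus ({cos:.3g})"
        )
    c = model.sigmoid.c_plus
    if method == "analytic":
        return c / cos
    if method == "bisect":
        a_half = model.sigmoid.a_plus / 2.0
        f = lambda t: float(model.sigmoid.n_plus(np.array([t * cos]))[0]) - a_half
        hi = max(10.0 * abs(c) / cos, 1.0)
        while f(hi) < 0 and hi < t_max:
            hi *= 2.0
        return float(brentq(f, 0.0 if f(0.0) < 0 else -hi, hi, xtol=1e-12, rtol=1e-14))
    raise InvalidParameterError(f"unknown method {method!r}")


def compare_strategies(
    model: LNModel,
    strategies: list[StimStrategy],
    method: str = "analytic",
) -> ThresholdComparison:
    """Threshold per strategy and the ERF-to-best-naive threshold ratio."""
    labels = [s.label for s in strategies]
    if "erf" not in labels or len(strategies) < 2:
        raise InvalidParameterError("need the erf strategy plus at least one naive strategy")
    thresholds: dict[str, float] = {}
    for s in strategies:
        try:
            thresholds[s.label] = threshold_at_fixed_power(model, s, method=method)
        except UnreachableThresholdError:
            thresholds[s.label] = np.inf
    naive = {k: v for k, v in thresholds.items() if k != "erf"}
    if all(np.isinf(v) for v in naive.values()):
        raise UnreachableThresholdError("every naive strategy is unreachable")
    best = min(naive, key=naive.get)
    return ThresholdComparison(
        thresholds=thresholds,
        best_naive=best,
        ratio=thresholds["erf"] / naive[best],
    )
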