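"""Truncated-Gaussian white-noise stimulus ensembles and per-cell sigma calibration.

Multi-electrode stimulation experiments drive every electrode simultaneously
with biphasic current pulses whose amplitudes are drawn i.i.d. from a zero-mean
Gaussian.  Amplitudes beyond the stimulator compliance limit are rejected and
redrawn, so the marginal distribution on each electrode is a truncated normal.
The noise amplitude ``sigma`` is chosen per cell so that the response
probability sits at half its saturating level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import CalibrationError, DegenerateDesignError, InvalidParameterError

__all__ = [
    "PulseParams",
    "StimulusEnsemble",
    "CalibrationResult",
    "sample_white_noise",
    "calibrate_sigma",
]


@dataclass(frozen=True)
class PulseParams:
    """Biphasic pulse timing metadata (no waveform synthesis is performed).

    Amplitude sign convention: positive = anodic-first, negative = cathodic-first.
    """

    phase_duration_us: float = 500.0
    interphase_gap_us: float = 50.0
    pulse_rate_hz: float = 10.0
    amplitude_limit_ua: float = 300.0

    def __post_init__(self) -> None:
        for name in ("phase_duration_us", "interphase_gap_us", "pulse_rate_hz", "amplitude_limit_ua"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def pulse_width_s(self) -> float:
        """Total biphasic pulse width (two phases plus gap), in seconds."""
        return (2 * self.phase_duration_us + self.interphase_gap_us) * 1e-6


@dataclass
class StimulusEnsemble:
    """White-noise stimulus ensemble: one amplitude (uA) per electrode per pulse.

    ``amplitudes`` has one row per *presentation*; each distinct stimulus is
    repeated ``repeats`` times consecutively, and ``stimulus_ids`` maps each
    presentation back to its distinct stimulus.
    """

    amplitudes: np.ndarray  # (n_presentations, n_electrodes), uA
    sigma: float
    repeats: int
    seed: int
    mask: np.ndarray  # bool, True = operational
    pulse: PulseParams = field(default_factory=PulseParams)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.amplitudes.ndim != 2:
            raise InvalidParameterError("amplitudes must be 2-D (presentations x electrodes)")
        if self.mask.shape != (self.amplitudes.shape[1],):
            raise InvalidParameterError("mask length must match electrode count")

    @property
    def n_presentations(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def n_distinct(self) -> int:
        return self.n_presentations // self.repeats

    @property
    def stimulus_ids(self) -> np.ndarray:
        """Distinct-stimulus index per presentation."""
        return np.arange(self.n_presentations) // self.repeats


@dataclass
class CalibrationResult:
    """Outcome of the sigma-versus-response-probability sigmoid fit."""

    sigma_grid: np.ndarray
    response_prob: np.ndarray
    sigmoid_params: tuple[float, float, float]  # (max, gain, midpoint)
    chosen_sigma: float
    target_prob: float
    extrapolated: bool


def sample_white_noise(
    n_stimuli: int,
    n_electrodes: int,
    sigma: float,
    limit: float = 300.0,
    mask: np.ndarray | None = None,
    repeats: int = 1,
    seed: int = 0,
    pulse: PulseParams | None = None,
) -> StimulusEnsemble:
    """Draw ``n_stimuli`` distinct truncated-Gaussian stimulus vectors.

    Each electrode amplitude is drawn N(0, sigma^2); draws with ``|a| > limit``
    are rejected and redrawn (rejection keeps the distribution a true truncated
    normal rather than a clipped one, preserving the Gaussian assumptions of
    the downstream covariance analysis).  Masked electrodes are held at zero.
    Each distinct stimulus is expanded into ``repeats`` consecutive
    presentations.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if limit <= 0:
        raise InvalidParameterError("limit must be strictly positive")
    if n_electrodes < 1 or n_stimuli < 0:
        raise InvalidParameterError("n_electrodes >= 1 and n_stimuli >= 0 required")
    if repeats < 1:
        raise InvalidParameterError("repeats must be >= 1")
    if mask is None:
        mask = np.ones(n_electrodes, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n_electrodes,):
        raise InvalidParameterError("mask length must equal n_electrodes")
    if not mask.any():
        raise DegenerateDesignError("mask excludes every electrode")

    rng = np.random.default_rng(seed)
    amps = np.zeros((n_stimuli, n_electrodes))
    if sigma > 0:
        n_on = int(mask.sum())
        block = rng.normal(0.0, sigma, size=(n_stimuli, n_on))
        bad = np.abs(block) > limit
        while bad.any():
            block[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
            bad = np.abs(block) > limit
        amps[:, mask] = block
    amps = np.repeat(amps, repeats, axis=0)
    return StimulusEnsemble(
        amplitudes=amps,
        sigma=float(sigma),
        repeats=repeats,
        seed=seed,
        mask=mask,
        pulse=pulse if pulse is not None else PulseParams(amplitude_limit_ua=limit),
    )


def _saturating_sigmoid(s: np.ndarray, pmax: float, gain: float, mid: float) -> np.ndarray:
    return pmax / (1.0 + np.exp(-gain * (s - mid)))


def calibrate_sigma(
    sigma_grid: np.ndarray,
    response_prob: np.ndarray,
    target_fraction: float = 0.5,
) -> CalibrationResult:
    """Choose the noise amplitude giving ``target_fraction`` of the saturating response.

    Fits ``p(sigma) = max / (1 + exp(-gain (sigma - mid)))`` by nonlinear least
    squares and solves for the sigma where the fitted curve equals
    ``target_fraction * max``.  With the default target of one half this is
    simply the fitted midpoint.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    response_prob = np.asarray(response_prob, dtype=float)
    if sigma_grid.shape != response_prob.shape or sigma_grid.size < 3:
        raise InvalidParameterError("sigma_grid and response_prob must match with length >= 3")
    if np.any((response_prob < 0) | (response_prob > 1)):
        raise InvalidParameterError("response probabilities must lie in [0, 1]")
    if not (0 < target_fraction < 1):
        raise InvalidParameterError("target_fraction must lie in (0, 1)")

    span = float(sigma_grid.max() - sigma_grid.min())
    p0 = (
        max(float(response_prob.max()), 1e-3),
        4.0 / span if span > 0 else 1.0,
        float(sigma_grid[np.argmin(np.abs(response_prob - response_prob.max() / 2))]),
    )
    try:
        popt, _ = curve_fit(
            _saturating_sigmoid,
            sigma_grid,
            response_prob,
            p0=p0,
            bounds=([1e-6, 1e-9, -np.inf], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise CalibrationError(
            f"sigmoid fit failed on grid {sigma_grid.tolist()} with probabilities "
            f"{response_prob.tolist()}: {exc}"
        ) from exc
    pmax, gain, mid = (float(v) for v in popt)
    # p = target_fraction * pmax  =>  sigma = mid - log(1/tf - 1)/gain
    chosen = mid - np.log(1.0 / target_fraction - 1.0) / gain
    extrapolated = not (sigma_grid.min() <= chosen <= sigma_grid.max())
    return CalibrationResult(
        sigma_grid=sigma_grid,
        response_prob=response_prob,
        sigmoid_params=(pmax, gain, mid),
        chosen_sigma=float(chosen),
        target_prob=float(target_fraction * pmax),
        extrapolated=extrapolated,
    )
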