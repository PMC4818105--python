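"""Ground-truth LN-cell simulator for parameter-recovery testing.

Every estimation stage of the toolkit is testable against this module: it
builds a 20-electrode array, places a cell with a known electrical receptive
field and double-sigmoid nonlinearity on it, and simulates per-presentation
short- and long-latency spiking with known latency statistics.  The forward
model is exactly the polarity-split LN predictor the estimator assumes
(P = N+(w+.s) + N-(w-.s) + p0), so correct-specification recovery is the
default; an asymmetric mode (c+ != |c-|) probes robustness to
polarity-dependent thresholds, and an optional suppressive second axis makes
the ground truth genuinely two-dimensional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nonlinearity import DoubleSigmoid, LNModel
from .spike_processing import ResponseVector
from .stimgen import StimulusEnsemble, sample_white_noise
from .errors import InvalidParameterError

__all__ = [
    "ElectrodeArray",
    "GroundTruthCell",
    "SimulatedRecording",
    "default_array",
    "make_cell",
    "simulate_responses",
    "calibration_run",
]


@dataclass
class ElectrodeArray:
    """Planar stimulating-electrode layout (positions in mm)."""

    positions: np.ndarray  # (n, 2) mm
    diameter: float = 0.4  # mm, exposed disc
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.positions.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    def distances_to(self, point: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.positions - np.asarray(point, dtype=float), axis=1)


@dataclass
class GroundTruthCell:
    """Simulator cell: true filters, nonlinearity, latency statistics, position."""

    w_true_plus: np.ndarray  # unit-norm current-direction vector
    w_true_minus: np.ndarray
    sigmoid: DoubleSigmoid
    position: np.ndarray  # (x, y) mm
    baseline: float = 0.0
    latency_short: tuple[float, float] = (1.75, 0.3)  # mean, SD in ms
    latency_long: tuple[float, float] = (11.0, 2.0)
    p_long: float = 0.1
    suppressive_axis: tuple[np.ndarray, float, float] | None = None  # (unit vector, strength, width uA)

    def model(self) -> LNModel:
        """The cell's own LN predictor (the generative probability, pre-suppression)."""
        return LNModel(
            w_plus=self.w_true_plus,
            w_minus=self.w_true_minus,
            sigmoid=self.sigmoid,
            v1=self.w_true_plus / np.linalg.norm(self.w_true_plus),
            baseline=self.baseline,
        )

    def spike_probability(self, stimuli: np.ndarray) -> np.ndarray:
        p = self.model().predict(stimuli)
        if self.suppressive_axis is not None:
            v2, strength, width = self.suppressive_axis
            x2 = np.atleast_2d(stimuli) @ np.asarray(v2, dtype=float)
            penalty = 1.0 - strength * (1.0 - np.exp(-(x2**2) / (2.0 * width**2)))
            p = np.clip(p * penalty, 0.0, 1.0)
        return p


@dataclass
class SimulatedRecording:
    ensemble: StimulusEnsemble
    responses: ResponseVector
    truth: GroundTruthCell
    seed: int
    probabilities: np.ndarray = field(repr=False, default=None)


def default_array() -> ElectrodeArray:
    """20-electrode staggered grid: 5 columns x 4 rows over ~3.5 x 3.5 mm.

    Vertical center-to-center pitch within a column is 1.0 mm; alternate
    columns are offset by half a pitch.  Electrode index runs column-major.
    """
    cols, rows = 5, 4
    xs = np.arange(cols) * 0.875
    positions = []
    for c in range(cols):
        for r in range(rows):
            positions.append((xs[c], r * 1.0 + (0.5 if c % 2 else 0.0)))
    return ElectrodeArray(positions=np.asarray(positions))


def make_cell(
    array: ElectrodeArray,
    position: np.ndarray,
    n_significant: int = 3,
    seed: int = 0,
    a: float = 0.9,
    b: float = 0.03,
    c: float = 150.0,
    c_minus: float | None = None,
    decay_mm: float = 2.0,
    jitter: float = 0.1,
) -> GroundTruthCell:
    """Place a ground-truth cell whose ERF loads the nearest electrodes.

    The true positive ERF puts weight on the ``n_significant`` operational
    electrodes nearest ``position``, decaying exponentially with distance
    (scale ``decay_mm``, chosen so neighbouring-electrode weights stay within
    the same order of magnitude as observed multi-electrode ERFs) with seeded
    multiplicative jitter; magnitudes are re-sorted so weight strictly
    decreases with distance.  The negative ERF is
    the exact negation (symmetric cell) unless ``c_minus`` is given to build
    an asymmetric-threshold variant.
    """
    if not (1 <= n_significant <= array.n_electrodes):
        raise InvalidParameterError("n_significant must be in [1, n_electrodes]")
    position = np.asarray(position, dtype=float)
    d = array.distances_to(position)
    d_op = np.where(array.mask, d, np.inf)
    order = np.lexsort((np.arange(d.size), d_op))
    chosen = order[:n_significant]
    hull_lo, hull_hi = array.positions.min(axis=0), array.positions.max(axis=0)
    if np.any(position < hull_lo) or np.any(position > hull_hi):
        warnings.warn("cell position lies outside the electrode-array hull", stacklevel=2)
    rng = np.random.default_rng(seed)
    mags = np.exp(-d[chosen] / decay_mm) * (1.0 + jitter * rng.standard_normal(n_significant))
    mags = np.abs(mags)
    # weight must decrease with distance regardless of jitter draw
    mags = np.sort(mags)[::-1]
    w = np.zeros(array.n_electrodes)
    w[chosen] = mags
    w = w / np.linalg.norm(w)
    cm = -c if c_minus is None else c_minus
    sig = DoubleSigmoid(a_plus=a, b_plus=b, c_plus=c, a_minus=a, b_minus=b, c_minus=cm, r2=np.nan)
    return GroundTruthCell(
        w_true_plus=w,
        w_true_minus=-w,
        sigmoid=sig,
        position=position,
    )


def calibration_run(
    cell: GroundTruthCell,
    sigma_grid: np.ndarray = (50.0, 100.0, 150.0, 200.0, 250.0),
    n_pulses: int = 1500,
    response_window_ms: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Response probability per candidate sigma, for noise-amplitude calibration.

    Emulates the calibration protocol: short white-noise trains at each sigma,
    counting presentations with a spike within ``response_window_ms`` of the
    stimulus.  Feed the result to :func:`elstim.calibrate_sigma`.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    probs = np.empty(sigma_grid.size)
    n_el = cell.w_true_plus.size
    for i, s in enumerate(sigma_grid):
        ens = sample_white_noise(n_pulses, n_el, s, repeats=1, seed=seed + i)
        rec = simulate_responses(cell, ens, seed=seed + 100 + i)
        hit = np.array(
            [np.any(np.asarray(l) <= response_window_ms) for l in rec.responses.latencies]
        )
        probs[i] = hit.mean()
    return probs


def simulate_responses(
    cell: GroundTruthCell,
    ensemble: StimulusEnsemble,
    seed: int = 0,
) -> SimulatedRecording:
    """Bernoulli spiking from the cell's LN probability, with latencies.

    Each presentation draws a short-latency (direct) response with the LN
    probability; a responding presentation gets a latency drawn from the
    cell's short-latency normal, truncated at zero.  Long-latency (network)
    responses are drawn independently with probability ``p_long`` and their
    own latency distribution — a phenomenological stand-in for synaptic
    activation, sufficient to exercise latency clustering and re-running the
    pipeline on long-latency labels.
    """
    S = ensemble.amplitudes
    if S.shape[1] != cell.w_true_plus.size:
        raise InvalidParameterError("ensemble and cell electrode counts differ")
    rng = np.random.default_rng(seed)
    p = cell.spike_probability(S)
    short = (rng.random(p.size) < p).astype(int)
    long = (rng.random(p.size) < cell.p_long).astype(int)
    mu_s, sd_s = cell.latency_short
    mu_l, sd_l = cell.latency_long
    latencies: list[np.ndarray] = []
    for i in range(p.size):
        lats = []
        if short[i]:
            t = rng.normal(mu_s, sd_s)
            while t <= 0:
                t = rng.normal(mu_s, sd_s)
            lats.append(t)
        if long[i]:
            t = rng.normal(mu_l, sd_l)
            while t <= 0:
                t = rng.normal(mu_l, sd_l)
            lats.append(t)
        latencies.append(np.asarray(lats))
    responses = ResponseVector(short=short, long=long, latencies=latencies)
    return SimulatedRecording(
        ensemble=ensemble, responses=responses, truth=cell, seed=seed, probabilities=p
    )
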