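"""Static nonlinearity of the LN cascade: binning, double-sigmoid fit, prediction.

The spike probability given a stimulus s is modelled as

    P(spike | s) = N+(w+_hat . s) + N-(w-_hat . s) + p0,

where w+_hat and w-_hat are the unit-normalized polarity-split ERFs, p0 is a
spontaneous-rate baseline (default 0), and the one-sided sigmoids are

    N+(x) = a+ / (1 + exp(-b+ (x - c+)))
    N-(x) = a- - a- / (1 + exp(-b- (x - c-))),

so c+ and c- are the half-saturation thresholds in uA (c+ > 0 > c- for a
typical cell).  Projection axes are oriented consistently with the first
principal component v1 so that net anodic-first stimuli always project
positively; this keeps c- negative as conventionally reported and makes the
summed form well behaved far from threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import curve_fit

from .errors import FitFailureError, InsufficientSupportError, InvalidParameterError
from .subspace import ERFPair, SpikeTriggeredEnsemble

__all__ = [
    "BinnedProbability",
    "DoubleSigmoid",
    "LNModel",
    "LNModel2D",
    "sigmoid_pos",
    "sigmoid_neg",
    "bin_projections",
    "fit_double_sigmoid",
    "fit_2d",
]


def sigmoid_pos(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Rising sigmoid N+ for net anodic-first projections."""
    return a / (1.0 + np.exp(-b * (x - c)))


def sigmoid_neg(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Falling sigmoid N- for net cathodic-first projections (rises as x -> -inf)."""
    return a - a / (1.0 + np.exp(-b * (x - c)))


def oriented_axis(w: np.ndarray, v1: np.ndarray) -> np.ndarray:
    """Unit vector along ``w``, oriented to have positive dot product with v1."""
    u = np.asarray(w, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise InvalidParameterError("cannot normalize a zero ERF")
    u = u / norm
    return u if u @ v1 >= 0 else -u


@dataclass
class BinnedProbability:
    """Equal-spike-count binning of projected stimuli on one polarity side."""

    bin_centers: np.ndarray  # uA, mean projection of all stimuli in the bin
    probabilities: np.ndarray
    n_stimuli: np.ndarray
    n_spikes: np.ndarray
    side: str  # "positive" | "negative"


@dataclass
class DoubleSigmoid:
    """Fitted parameters of the two one-sided sigmoids plus goodness of fit."""

    a_plus: float
    b_plus: float
    c_plus: float
    a_minus: float
    b_minus: float
    c_minus: float
    r2: float

    def n_plus(self, x: np.ndarray) -> np.ndarray:
        return sigmoid_pos(np.asarray(x, dtype=float), self.a_plus, self.b_plus, self.c_plus)

    def n_minus(self, x: np.ndarray) -> np.ndarray:
        return sigmoid_neg(np.asarray(x, dtype=float), self.a_minus, self.b_minus, self.c_minus)


@dataclass
class LNModel:
    """One-dimensional (polarity-split) linear-nonlinear model."""

    w_plus: np.ndarray | None
    w_minus: np.ndarray | None
    sigmoid: DoubleSigmoid
    v1: np.ndarray
    baseline: float = 0.0
    off_side: str = "summed"  # "summed" evaluates both terms as written; "piecewise" only the matching side

    def _axes(self) -> tuple[np.ndarray | None, np.ndarray | None]:
        u_p = oriented_axis(self.w_plus, self.v1) if self.w_plus is not None else None
        u_m = oriented_axis(self.w_minus, self.v1) if self.w_minus is not None else None
        return u_p, u_m

    def predict(self, stimuli: np.ndarray) -> np.ndarray:
        """Spike probability per stimulus row, clipped to [0, 1]."""
        S = np.atleast_2d(np.asarray(stimuli, dtype=float))
        u_p, u_m = self._axes()
        term_p = self.sigmoid.n_plus(S @ u_p) if u_p is not None else 0.0
        term_m = self.sigmoid.n_minus(S @ u_m) if u_m is not None else 0.0
        if self.off_side == "piecewise":
            side = S @ self.v1 >= 0
            p = np.where(side, term_p, term_m) + self.baseline
        else:
            p = term_p + term_m + self.baseline
        return np.clip(p, 0.0, 1.0)


@dataclass
class LNModel2D:
    """Two-dimensional nonlinearity over projections onto (v1, v2).

    The spike-probability surface is estimated on an equal-width grid and
    interpolated with a cubic spline; grid cells with fewer than ``min_count``
    training stimuli are unsupported, and predictions there fall back to the
    1-D model (flagged).
    """

    v1: np.ndarray
    v2: np.ndarray
    x1_edges: np.ndarray
    x2_edges: np.ndarray
    prob_grid: np.ndarray  # (n1, n2) at cell centers
    support: np.ndarray  # bool (n1, n2)
    min_count: int
    fallback: LNModel | None = None
    _spline: RectBivariateSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        c1 = 0.5 * (self.x1_edges[:-1] + self.x1_edges[1:])
        c2 = 0.5 * (self.x2_edges[:-1] + self.x2_edges[1:])
        kx = min(3, c1.size - 1)
        ky = min(3, c2.size - 1)
        self._spline = RectBivariateSpline(c1, c2, self.prob_grid, kx=kx, ky=ky, s=0)

    def predict(self, stimuli: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (probability, supported) per stimulus row."""
        S = np.atleast_2d(np.asarray(stimuli, dtype=float))
        x1 = S @ self.v1
        x2 = S @ self.v2
        i1 = np.clip(np.searchsorted(self.x1_edges, x1, side="right") - 1, 0, self.support.shape[0] - 1)
        i2 = np.clip(np.searchsorted(self.x2_edges, x2, side="right") - 1, 0, self.support.shape[1] - 1)
        inside = (
            (x1 >= self.x1_edges[0]) & (x1 <= self.x1_edges[-1])
            & (x2 >= self.x2_edges[0]) & (x2 <= self.x2_edges[-1])
        )
        supported = inside & self.support[i1, i2]
        p = np.clip(self._spline.ev(x1, x2), 0.0, 1.0)
        if self.fallback is not None:
            p = np.where(supported, p, self.fallback.predict(S))
        return p, supported


def bin_projections(
    ens: SpikeTriggeredEnsemble,
    erf: ERFPair,
    n_bins_per_side: int = 15,
) -> tuple[BinnedProbability | None, BinnedProbability | None]:
    """Equal-spike-count binning of projections on each polarity side.

    Stimuli are split by the sign of their projection onto v1; each side is
    projected onto its unit-normalized ERF (oriented with v1).  Bin edges are
    quantiles of the spike-eliciting projections chosen so every bin holds an
    equal number of spikes (within one); the outermost edges are widened to
    catch all non-spiking stimuli on that side.  The probability per bin is
    (spike-eliciting stimuli) / (all stimuli) in the bin.
    """
    if n_bins_per_side < 2:
        raise InvalidParameterError("n_bins_per_side must be >= 2")
    S = ens.S_T
    resp = ens.response.astype(bool)
    v1_proj = S @ erf.v1
    out: list[BinnedProbability | None] = []
    for side, w in (("positive", erf.w_plus), ("negative", erf.w_minus)):
        if w is None:
            out.append(None)
            continue
        sel = v1_proj >= 0 if side == "positive" else v1_proj < 0
        u = oriented_axis(w, erf.v1)
        x = S[sel] @ u
        r = resp[sel]
        x_spk = np.sort(x[r])
        n_spk = x_spk.size
        n_bins = n_bins_per_side
        if n_spk < n_bins:
            warnings.warn(
                f"{side} side has {n_spk} spikes < {n_bins} bins; reducing bin count",
                stacklevel=2,
            )
            n_bins = max(1, n_spk)
        if n_bins == 0 or n_spk == 0:
            out.append(None)
            continue
        # interior edges at equal-spike quantiles; outer edges widened to +-inf
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.concatenate(([-np.inf], np.quantile(x_spk, qs), [np.inf]))
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        centers = np.empty(n_bins)
        prob = np.empty(n_bins)
        n_stim = np.empty(n_bins, dtype=int)
        n_spike = np.empty(n_bins, dtype=int)
        for b in range(n_bins):
            in_bin = idx == b
            n_stim[b] = int(in_bin.sum())
            n_spike[b] = int(r[in_bin].sum())
            centers[b] = x[in_bin].mean() if n_stim[b] else np.nan
            prob[b] = n_spike[b] / n_stim[b] if n_stim[b] else np.nan
        keep = n_stim > 0
        out.append(
            BinnedProbability(
                bin_centers=centers[keep],
                probabilities=prob[keep],
                n_stimuli=n_stim[keep],
                n_spikes=n_spike[keep],
                side=side,
            )
        )
    return out[0], out[1]


def _fit_one_side(
    centers: np.ndarray,
    prob: np.ndarray,
    rising: bool,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[float, float, float, np.ndarray]:
    f = sigmoid_pos if rising else sigmoid_neg
    span = float(np.ptp(centers)) or 1.0
    a0 = max(float(prob.max()), 1e-3)
    c0 = float(centers[np.argmin(np.abs(prob - a0 / 2))])
    b0 = 4.0 * a0 / span
    rng = np.random.default_rng(seed)
    best = None
    best_sse = np.inf
    for i in range(n_starts):
        b_try = b0 * (1.0 if i == 0 else float(np.exp(rng.normal(0, 1))))
        try:
            popt, _ = curve_fit(
                f,
                centers,
                prob,
                p0=(a0, b_try, c0),
                bounds=([1e-6, 1e-9, -np.inf], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        pred = f(centers, *popt)
        sse = float(((pred - prob) ** 2).sum())
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise FitFailureError(
            f"sigmoid fit failed on {'rising' if rising else 'falling'} side; "
            f"centers={centers.tolist()}, prob={prob.tolist()}"
        )
    return float(best[0]), float(best[1]), float(best[2]), f(centers, *best)


def fit_double_sigmoid(
    binned: tuple[BinnedProbability | None, BinnedProbability | None],
    seed: int = 0,
) -> DoubleSigmoid:
    """Fit the one-sided sigmoids independently (their parameters never interact).

    r2 is the coefficient of determination pooled over all bins of both sides.
    An absent side keeps NaN parameters and contributes nothing at prediction
    time.
    """
    pos, neg = binned
    if pos is None and neg is None:
        raise InvalidParameterError("at least one side must be binned")
    for b in (pos, neg):
        if b is not None and b.bin_centers.size < 4:
            raise InvalidParameterError("need >= 4 bins per defined side")
    preds: list[np.ndarray] = []
    obs: list[np.ndarray] = []
    ap = bp = cp = am = bm = cm = np.nan
    if pos is not None:
        ap, bp, cp, pred = _fit_one_side(pos.bin_centers, pos.probabilities, rising=True, seed=seed)
        preds.append(pred)
        obs.append(pos.probabilities)
    if neg is not None:
        am, bm, cm, pred = _fit_one_side(neg.bin_centers, neg.probabilities, rising=False, seed=seed)
        preds.append(pred)
        obs.append(neg.probabilities)
    y = np.concatenate(obs)
    yhat = np.concatenate(preds)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DoubleSigmoid(a_plus=ap, b_plus=bp, c_plus=cp, a_minus=am, b_minus=bm, c_minus=cm, r2=r2)


def fit_2d(
    ens: SpikeTriggeredEnsemble,
    v1: np.ndarray,
    v2: np.ndarray,
    grid_resolution: int = 15,
    min_count: int = 20,
    fallback: LNModel | None = None,
) -> LNModel2D:
    """Estimate the 2-D nonlinearity N2(v1.s, v2.s) on an equal-width grid.

    The probability per grid cell is spikes/stimuli; cells with fewer than
    ``min_count`` stimuli are marked unsupported (their value is filled with
    the overall spike rate purely to condition the spline; predictions there
    are flagged and deferred to the 1-D fallback).
    """
    if grid_resolution < 5:
        raise InvalidParameterError("grid_resolution must be >= 5")
    S = ens.S_T
    resp = ens.response.astype(bool)
    x1 = S @ np.asarray(v1, dtype=float)
    x2 = S @ np.asarray(v2, dtype=float)
    e1 = np.linspace(x1.min(), x1.max(), grid_resolution + 1)
    e2 = np.linspace(x2.min(), x2.max(), grid_resolution + 1)
    counts, _, _ = np.histogram2d(x1, x2, bins=(e1, e2))
    spikes, _, _ = np.histogram2d(x1[resp], x2[resp], bins=(e1, e2))
    support = counts >= min_count
    if (support.any(axis=1).sum() < 2) or (support.any(axis=0).sum() < 2):
        raise InsufficientSupportError("fewer than 2 supported grid cells per axis")
    overall = float(resp.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(counts > 0, spikes / np.maximum(counts, 1), overall)
    prob = np.where(support, prob, overall)
    return LNModel2D(
        v1=np.asarray(v1, dtype=float),
        v2=np.asarray(v2, dtype=float),
        x1_edges=e1,
        x2_edges=e2,
        prob_grid=prob,
        support=support,
        min_count=min_count,
        fallback=fallback,
    )
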