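"""Spike-triggered covariance analysis of multi-electrode stimulation.

The electrical receptive field (ERF) of a neuron is the vector of
per-electrode weights describing how strongly each stimulating electrode
drives it.  Given a white-noise stimulus ensemble S_T and the subset S_D of
stimuli that elicited a short-latency spike, the significant stimulus
subspace is found by eigendecomposition of C_s = cov(S_D): eigenvalues above
(below) the raw-ensemble variance mark excitatory (suppressive) directions.
Significance is assessed against a null built by circularly time-shifting the
response vector relative to the stimulus sequence, which preserves both the
spike count and the stimulus statistics.  The polarity-split ERFs w+ and w-
are the means of the spike-triggered stimuli with positive and negative
projection onto the first significant component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateResponseError,
    InsufficientSpikesError,
    InvalidParameterError,
    UndefinedExtentError,
)

__all__ = [
    "SpikeTriggeredEnsemble",
    "EigenSpectrum",
    "SignificanceResult",
    "ERFPair",
    "spike_triggered_cov",
    "significance_test",
    "estimate_erfs",
    "electrode_significance",
    "erf_extent",
]


@dataclass
class SpikeTriggeredEnsemble:
    """All stimuli S_T with the binary response vector defining the subset S_D."""

    stimuli: np.ndarray  # (n_presentations, n_electrodes), uA
    response: np.ndarray  # binary, per presentation
    mask: np.ndarray | None = None  # bool, True = operational
    stimulus_ids: np.ndarray | None = None  # distinct-stimulus index per presentation

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.response = np.asarray(self.response, dtype=int)
        if self.stimuli.ndim != 2 or self.response.shape != (self.stimuli.shape[0],):
            raise InvalidParameterError("stimuli must be 2-D with one response per row")
        if self.mask is None:
            self.mask = np.ones(self.stimuli.shape[1], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stimulus_ids is not None:
            self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)

    @property
    def S_T(self) -> np.ndarray:
        return self.stimuli

    @property
    def S_D(self) -> np.ndarray:
        """Spike-triggered stimulus subset."""
        return self.stimuli[self.response.astype(bool)]

    @property
    def n_electrodes(self) -> int:
        return self.stimuli.shape[1]


@dataclass
class EigenSpectrum:
    """Eigendecomposition of the spike-triggered covariance matrix.

    Eigenvectors are full-length (masked electrodes carry zeros), stored as
    columns in the same order as ``eigenvalues`` (descending).  ``sigma2`` is
    the mean per-electrode variance of the raw ensemble over operational
    electrodes, the reference against which eigenvalues are compared.
    """

    eigenvalues: np.ndarray  # uA^2, descending
    eigenvectors: np.ndarray  # (n_electrodes, n_kept) columns, unit norm
    sigma2: float

    @property
    def normalized_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues / self.sigma2


@dataclass
class SignificanceResult:
    """Outcome of the iterative shuffle-null eigenvalue significance test."""

    significant: list[tuple[np.ndarray, float, str]]  # (axis, eigenvalue, label)
    null_mean: float  # mean of the full shuffle eigenvalue distribution, 1st iteration
    ci_low: list[float]  # per iteration, bound on the smallest eigenvalue
    ci_high: list[float]  # per iteration, bound on the largest eigenvalue
    n_shuffles: int
    n_sd: float
    seed: int
    G: float
    null_first_eigenvectors: np.ndarray = field(repr=False)  # (n_shuffles, n_electrodes)
    null_shifts: np.ndarray = field(repr=False)  # circular offsets, 1st iteration

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.significant]


@dataclass
class ERFPair:
    """Polarity-split electrical receptive fields and their statistics.

    ``w_plus``/``w_minus`` are the means of the spike-triggered stimuli with
    positive/negative projection onto the splitting axis ``v1`` (either may be
    None when one polarity never elicited spikes).  ``corr`` is the Pearson
    correlation between the two ERFs over operational electrodes: values near
    -1 mean the same electrodes drive the cell with both polarities.
    """

    v1: np.ndarray
    w_plus: np.ndarray | None
    w_minus: np.ndarray | None
    mask: np.ndarray
    corr: float | None = None
    n_plus: int = 0
    n_minus: int = 0
    sig_plus: np.ndarray | None = None
    sig_minus: np.ndarray | None = None
    rms_bound_plus: np.ndarray | None = None
    rms_bound_minus: np.ndarray | None = None
    d_plus: float | None = None
    d_minus: float | None = None


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(v)))
    return v if v[i] >= 0 else -v


def _embed(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.size)
    out[mask] = v
    return out


def spike_triggered_cov(ens: SpikeTriggeredEnsemble) -> EigenSpectrum:
    """Eigendecomposition of C_s = cov(S_D), restricted to operational electrodes.

    The covariance is taken about the spike-triggered mean (unbiased, n-1
    denominator); the mean itself is recovered separately as the
    polarity-split ERFs.  ``sigma2`` is the mean per-electrode variance of the
    full ensemble, approximately the white-noise sigma squared (up to
    truncation).
    """
    mask = ens.mask
    if int(mask.sum()) < 2:
        raise InvalidParameterError("need at least 2 operational electrodes")
    S_D = ens.S_D[:, mask]
    if S_D.shape[0] < 2:
        raise InsufficientSpikesError(
            f"need >= 2 spike-eliciting stimuli, got {S_D.shape[0]}"
        )
    C = np.cov(S_D, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    full = np.column_stack([_embed(_fix_sign(evecs[:, j]), mask) for j in range(evecs.shape[1])])
    sigma2 = float(ens.S_T[:, mask].var(axis=0, ddof=1).mean())
    return EigenSpectrum(eigenvalues=evals, eigenvectors=full, sigma2=sigma2)


def _extreme_eigs(S: np.ndarray, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of cov of spike rows."""
    C = np.cov(S[resp], rowvar=False, ddof=1)
    return np.linalg.eigh(C)


def significance_test(
    ens: SpikeTriggeredEnsemble,
    n_shuffles: int = 1000,
    n_sd: float = 2.0,
    seed: int = 0,
) -> SignificanceResult:
    """Iterative eigenvalue significance test with a circular time-shift null.

    Each shuffle circularly shifts the binary response vector by a uniform
    random offset in [1, n-1] and recomputes the extreme (largest and
    smallest) eigenvalues of the resulting spike-triggered covariance.  If the
    observed largest eigenvalue exceeds null mean + n_sd SD of the shuffled
    maxima, the axis is recorded as excitatory (symmetrically, suppressive for
    the smallest); the data are then projected onto the orthogonal complement,
    the null regenerated, and the test repeated until no extreme is outside
    its bound.

    The strength ratio G = |e1 - e_rnd| / |e2 - e_rnd| compares the separation
    of the most significant eigenvalue from the first-iteration null mean to
    that of the next most significant one; G >> 1 marks an effectively
    one-dimensional cell.
    """
    if n_shuffles < 100:
        raise InvalidParameterError("n_shuffles must be >= 100")
    if n_sd <= 0:
        raise InvalidParameterError("n_sd must be positive")
    resp = ens.response.astype(bool)
    n = resp.size
    if resp.all() or not resp.any():
        raise DegenerateResponseError("response vector is all-zero or all-one")
    if int(resp.sum()) < 2:
        raise InsufficientSpikesError("need >= 2 spike-eliciting stimuli")

    mask = ens.mask
    S = ens.stimuli[:, mask].copy()
    rng = np.random.default_rng(seed)

    significant: list[tuple[np.ndarray, float, str]] = []
    ci_low: list[float] = []
    ci_high: list[float] = []
    null_mean_first = np.nan
    null_vecs_first: np.ndarray | None = None
    null_shifts_first: np.ndarray | None = None
    G = np.nan
    basis = np.eye(int(mask.sum()))  # maps current-subspace vectors to electrode space

    first_iteration = True
    while True:
        evals_obs, evecs_obs = _extreme_eigs(S, resp)
        shifts = rng.integers(1, n, size=n_shuffles)
        maxima = np.empty(n_shuffles)
        minima = np.empty(n_shuffles)
        if first_iteration:
            all_null = np.empty((n_shuffles, evals_obs.size))
            first_vecs = np.empty((n_shuffles, S.shape[1]))
        for j, off in enumerate(shifts):
            r = np.roll(resp, off)
            if first_iteration:
                w, V = _extreme_eigs(S, r)
                all_null[j] = w
                first_vecs[j] = V[:, -1]
            else:
                w = np.linalg.eigvalsh(np.cov(S[r], rowvar=False, ddof=1))
            maxima[j] = w[-1]
            minima[j] = w[0]
        hi = float(maxima.mean() + n_sd * maxima.std(ddof=0))
        lo = float(minima.mean() - n_sd * minima.std(ddof=0))
        ci_high.append(hi)
        ci_low.append(lo)

        if first_iteration:
            null_mean_first = float(all_null.mean())
            null_vecs_first = first_vecs
            null_shifts_first = shifts
            dev = np.abs(evals_obs - null_mean_first)
            top2 = np.sort(dev)[::-1][:2]
            G = float(top2[0] / top2[1]) if top2.size > 1 and top2[1] > 0 else np.inf
            first_iteration = False

        z_hi = (evals_obs[-1] - maxima.mean()) / max(maxima.std(ddof=0), 1e-300)
        z_lo = (minima.mean() - evals_obs[0]) / max(minima.std(ddof=0), 1e-300)
        exc = evals_obs[-1] > hi
        sup = evals_obs[0] < lo
        if not exc and not sup:
            break
        take_exc = exc and (not sup or z_hi >= z_lo)
        if take_exc:
            axis_sub, eigval, label = evecs_obs[:, -1], float(evals_obs[-1]), "excitatory"
        else:
            axis_sub, eigval, label = evecs_obs[:, 0], float(evals_obs[0]), "suppressive"
        axis_el = basis @ axis_sub
        significant.append((_fix_sign(_embed(axis_el, mask)), eigval, label))
        # deflate: project stimuli onto the orthogonal complement of the axis,
        # dropping the dimension so the remaining eigenspectra stay full-rank
        m = axis_sub.size
        Q, _ = np.linalg.qr(np.column_stack([axis_sub, np.eye(m)]))
        keep = Q[:, 1:m]  # orthonormal complement of axis_sub
        S = S @ keep
        basis = basis @ keep
        if S.shape[1] < 2:
            break

    assert null_vecs_first is not None and null_shifts_first is not None
    null_vecs_full = np.column_stack(
        [_embed(null_vecs_first[j], mask) for j in range(n_shuffles)]
    ).T
    return SignificanceResult(
        significant=significant,
        null_mean=null_mean_first,
        ci_low=ci_low,
        ci_high=ci_high,
        n_shuffles=n_shuffles,
        n_sd=n_sd,
        seed=seed,
        G=G,
        null_first_eigenvectors=null_vecs_full,
        null_shifts=np.asarray(null_shifts_first),
    )


def strength_ratio(e1: float, e2: float, e_rnd: float) -> float:
    """G = |e1 - e_rnd| / |e2 - e_rnd| (relative dominance of the first axis)."""
    denom = abs(e2 - e_rnd)
    if denom == 0:
        return np.inf
    return abs(e1 - e_rnd) / denom


def estimate_erfs(ens: SpikeTriggeredEnsemble, v1: np.ndarray) -> ERFPair:
    """Polarity-split ERFs: means of spike-triggered stimuli by projection sign.

    Stimuli in S_D with non-negative projection onto ``v1`` form S_D+ (net
    anodic-first) and the rest S_D- (net cathodic-first); w+ and w- are their
    means, analogous to polarity-resolved spike-triggered averages.  A side
    with no spikes is reported absent, as seen in cells driven by only one
    pulse polarity.
    """
    v1 = np.asarray(v1, dtype=float)
    S_D = ens.S_D
    if S_D.shape[0] == 0:
        raise InsufficientSpikesError("no spike-eliciting stimuli")
    proj = S_D @ v1
    pos = proj >= 0  # zero projections count once, on the positive side
    S_p, S_m = S_D[pos], S_D[~pos]
    w_plus = S_p.mean(axis=0) if S_p.shape[0] else None
    w_minus = S_m.mean(axis=0) if S_m.shape[0] else None
    corr = None
    if w_plus is not None and w_minus is not None:
        m = ens.mask
        corr = float(stats.pearsonr(w_plus[m], w_minus[m])[0])
    return ERFPair(
        v1=v1,
        w_plus=w_plus,
        w_minus=w_minus,
        mask=ens.mask,
        corr=corr,
        n_plus=int(S_p.shape[0]),
        n_minus=int(S_m.shape[0]),
    )


def electrode_significance(
    ens: SpikeTriggeredEnsemble,
    sig: SignificanceResult,
    erf: ERFPair,
) -> ERFPair:
    """Flag electrodes whose ERF weight exceeds the shuffle RMS bound.

    For every shuffle of the significance test's first iteration, the ERFs are
    recomputed from the time-shifted response using that shuffle's first
    eigenvector as the splitting axis; the per-electrode RMS over shuffles is
    the null amplitude scale, and true weights larger in magnitude are flagged
    significant.
    """
    resp = ens.response.astype(bool)
    S = ens.stimuli
    n_el = S.shape[1]
    acc_p = np.zeros(n_el)
    acc_m = np.zeros(n_el)
    cnt_p = 0
    cnt_m = 0
    for off, v in zip(sig.null_shifts, sig.null_first_eigenvectors):
        r = np.roll(resp, off)
        S_D = S[r]
        proj = S_D @ v
        pos = proj >= 0
        if pos.any():
            acc_p += S_D[pos].mean(axis=0) ** 2
            cnt_p += 1
        if (~pos).any():
            acc_m += S_D[~pos].mean(axis=0) ** 2
            cnt_m += 1
    rms_p = np.sqrt(acc_p / cnt_p) if cnt_p else None
    rms_m = np.sqrt(acc_m / cnt_m) if cnt_m else None
    erf.rms_bound_plus = rms_p
    erf.rms_bound_minus = rms_m
    if erf.w_plus is not None and rms_p is not None:
        erf.sig_plus = (np.abs(erf.w_plus) > rms_p) & erf.mask
    if erf.w_minus is not None and rms_m is not None:
        erf.sig_minus = (np.abs(erf.w_minus) > rms_m) & erf.mask
    return erf


def erf_extent(weights: np.ndarray, distances: np.ndarray) -> float:
    """Weighted mean cell-to-electrode distance, using absolute ERF weights.

    Signed weights can make the weighted mean negative or unstable when they
    nearly cancel, so magnitudes are used: the extent is a spatial spread.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    d = np.asarray(distances, dtype=float)
    if w.shape != d.shape:
        raise InvalidParameterError("weights and distances must have equal length")
    if np.any(d < 0):
        raise InvalidParameterError("distances must be non-negative")
    tot = w.sum()
    if tot == 0:
        raise UndefinedExtentError("all ERF weights are zero")
    return float((w * d).sum() / tot)
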