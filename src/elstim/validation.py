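"""Held-out validation: 80/20 split and binned calibration error.

Test presentations are binned by predicted probability into B equal-width
segments of [0, 1]; the model error is the RMS difference between the mean
predicted and the empirical spike probability per retained (non-empty,
supported) bin:

    E_MS = (1/B) sum_i (Phat_i - P_i)^2,   E_RMS = sqrt(E_MS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, ValidationError
from .nonlinearity import LNModel, LNModel2D
from .subspace import SpikeTriggeredEnsemble

__all__ = ["ValidationReport", "split_data", "validation_error", "compare_1d_2d"]


@dataclass
class ValidationReport:
    B: int
    predicted: np.ndarray  # mean predicted probability per retained bin
    actual: np.ndarray  # empirical probability per retained bin
    counts: np.ndarray  # presentations per retained bin
    e_ms: float
    e_rms: float
    omitted_bins: int
    n_test: int
    n_unsupported: int = 0


def split_data(
    ens: SpikeTriggeredEnsemble, fraction: float = 0.8, seed: int = 0
) -> tuple[SpikeTriggeredEnsemble, SpikeTriggeredEnsemble]:
    """Random train/test split at the distinct-stimulus level.

    All repeats of one distinct stimulus land in the same partition, so
    statistically dependent presentations never leak across the split.
    """
    if not (0 < fraction < 1):
        raise InvalidParameterError("fraction must lie in (0, 1)")
    ids = ens.stimulus_ids
    if ids is None:
        ids = np.arange(ens.stimuli.shape[0])
    distinct = np.unique(ids)
    n_train = int(round(fraction * distinct.size))
    if n_train == 0 or n_train == distinct.size:
        raise InvalidParameterError(
            f"fraction {fraction} leaves an empty partition for {distinct.size} distinct stimuli"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(distinct)
    train_ids = set(perm[:n_train].tolist())
    in_train = np.array([i in train_ids for i in ids])

    def _sub(sel: np.ndarray) -> SpikeTriggeredEnsemble:
        return SpikeTriggeredEnsemble(
            stimuli=ens.stimuli[sel],
            response=ens.response[sel],
            mask=ens.mask,
            stimulus_ids=ids[sel],
        )

    return _sub(in_train), _sub(~in_train)


def validation_error(
    model: LNModel | LNModel2D,
    test: SpikeTriggeredEnsemble,
    B: int = 10,
) -> ValidationReport:
    """Binned calibration error of a fitted model on held-out data.

    For 2-D models, presentations falling in unsupported surface regions are
    omitted from the error, mirroring the omission of under-sampled regions.
    """
    if B < 2:
        raise InvalidParameterError("B must be >= 2")
    resp = test.response.astype(float)
    if isinstance(model, LNModel2D):
        p, supported = model.predict(test.stimuli)
        p, resp = p[supported], resp[supported]
        n_unsupported = int((~supported).sum())
    else:
        p = model.predict(test.stimuli)
        n_unsupported = 0
    if p.size == 0:
        raise ValidationError("no supported test presentations")
    edges = np.linspace(0.0, 1.0, B + 1)
    idx = np.clip(np.digitize(p, edges) - 1, 0, B - 1)
    pred, act, cnt = [], [], []
    omitted = 0
    for b in range(B):
        in_bin = idx == b
        n = int(in_bin.sum())
        if n == 0:
            omitted += 1
            continue
        pred.append(float(p[in_bin].mean()))
        act.append(float(resp[in_bin].mean()))
        cnt.append(n)
    if not pred:
        raise ValidationError("every probability bin is empty")
    pred_a, act_a = np.asarray(pred), np.asarray(act)
    e_ms = float(((pred_a - act_a) ** 2).mean())
    return ValidationReport(
        B=B,
        predicted=pred_a,
        actual=act_a,
        counts=np.asarray(cnt),
        e_ms=e_ms,
        e_rms=float(np.sqrt(e_ms)),
        omitted_bins=omitted,
        n_test=int(resp.size),
        n_unsupported=n_unsupported,
    )


def compare_1d_2d(report_1d: ValidationReport, report_2d: ValidationReport) -> dict:
    """Side-by-side E_RMS of the 1-D and 2-D models on the same test set."""
    if report_1d.n_test + report_1d.n_unsupported != report_2d.n_test + report_2d.n_unsupported:
        raise InvalidParameterError("reports were computed on different test sets")
    return {
        "e_rms_1d": report_1d.e_rms,
        "e_rms_2d": report_2d.e_rms,
        "difference": report_1d.e_rms - report_2d.e_rms,
    }
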