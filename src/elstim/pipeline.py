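"""End-to-end model estimation: subspace -> ERFs -> nonlinearity -> validation.

``run_pipeline`` composes the estimation stages in their natural order on a
loaded dataset and returns (and optionally writes) a result bundle containing
the eigenspectrum, the significance test, the polarity-split ERFs with
electrode significance, the fitted 1-D LN model, and the held-out validation
report.  Every stage logs its seeds and parameters into the bundle so a run
is reproducible from its own output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import Dataset
from .nonlinearity import DoubleSigmoid, LNModel, bin_projections, fit_double_sigmoid
from .subspace import (
    ERFPair,
    EigenSpectrum,
    SignificanceResult,
    SpikeTriggeredEnsemble,
    electrode_significance,
    erf_extent,
    estimate_erfs,
    spike_triggered_cov,
)
from .validation import ValidationReport, split_data, validation_error

logger = logging.getLogger("elstim")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "fit_ln_model", "save_bundle"]


@dataclass
class PipelineConfig:
    """Knobs of the standard estimation pipeline, with their defaults."""

    n_shuffles: int = 1000
    n_sd: float = 2.0
    n_bins_per_side: int = 15
    validation_bins: int = 10
    train_fraction: float = 0.8
    split_seed: int = 0
    shuffle_seed: int = 0
    fit_seed: int = 0
    baseline: float = 0.0
    use_long: bool = False  # re-run the pipeline on long-latency labels


@dataclass
class PipelineResult:
    spectrum: EigenSpectrum
    significance: SignificanceResult
    erf: ERFPair
    model: LNModel
    report: ValidationReport
    config: PipelineConfig
    log: list[str] = field(default_factory=list)


def fit_ln_model(
    train: SpikeTriggeredEnsemble,
    v1: np.ndarray,
    n_bins_per_side: int = 15,
    baseline: float = 0.0,
    fit_seed: int = 0,
) -> tuple[ERFPair, LNModel]:
    """ERFs + double-sigmoid fit on a training ensemble, given the first axis."""
    erf = estimate_erfs(train, v1)
    binned = bin_projections(train, erf, n_bins_per_side=n_bins_per_side)
    sigmoid = fit_double_sigmoid(binned, seed=fit_seed)
    model = LNModel(
        w_plus=erf.w_plus,
        w_minus=erf.w_minus,
        sigmoid=sigmoid,
        v1=v1,
        baseline=baseline,
    )
    return erf, model


def run_pipeline(dataset: Dataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full estimation chain on a dataset.

    Stages: (1) spike-triggered covariance and shuffle-null significance on
    the full data, (2) 80/20 distinct-stimulus split, (3) ERF estimation,
    electrode significance and double-sigmoid fit on the training partition,
    (4) binned calibration error on the held-out partition.
    """
    config = config or PipelineConfig()
    log: list[str] = []

    response = dataset.responses.long if config.use_long else dataset.responses.short
    ens = SpikeTriggeredEnsemble(
        stimuli=dataset.ensemble.amplitudes,
        response=response,
        mask=dataset.ensemble.mask,
        stimulus_ids=dataset.ensemble.stimulus_ids,
    )

    def _log(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    try:
        spectrum = spike_triggered_cov(ens)
        _log(f"subspace: {ens.S_D.shape[0]} spike-triggered stimuli, sigma2={spectrum.sigma2:.4g}")
        sig = significance = _significance(ens, config, _log)
        v1 = sig.significant[0][0] if sig.significant else spectrum.eigenvectors[:, 0]
        train, test = split_data(ens, fraction=config.train_fraction, seed=config.split_seed)
        _log(
            f"split: {train.stimuli.shape[0]} train / {test.stimuli.shape[0]} test "
            f"presentations (seed {config.split_seed})"
        )
        erf, model = _fit(train, v1, config, _log)
        erf = electrode_significance(ens, sig, erf)
        if dataset.geometry is not None:
            d = dataset.geometry.distances_to(_cell_position(dataset))
            if erf.w_plus is not None:
                erf.d_plus = erf_extent(erf.w_plus, d)
            if erf.w_minus is not None:
                erf.d_minus = erf_extent(erf.w_minus, d)
        report = validation_error(model, test, B=config.validation_bins)
        _log(f"validation: E_RMS={report.e_rms:.4f} over {report.B - report.omitted_bins} bins")
    except Exception as exc:
        raise type(exc)(f"[pipeline stage failed] {exc}") from exc
    return PipelineResult(
        spectrum=spectrum,
        significance=significance,
        erf=erf,
        model=model,
        report=report,
        config=config,
        log=log,
    )


def _significance(ens, config, _log):
    from .subspace import significance_test

    sig = significance_test(
        ens, n_shuffles=config.n_shuffles, n_sd=config.n_sd, seed=config.shuffle_seed
    )
    _log(
        f"significance: {sig.n_significant} component(s) {sig.labels}, "
        f"G={sig.G:.3g}, shuffles={sig.n_shuffles}, seed={sig.seed}"
    )
    return sig


def _fit(train, v1, config, _log):
    erf, model = fit_ln_model(
        train,
        v1,
        n_bins_per_side=config.n_bins_per_side,
        baseline=config.baseline,
        fit_seed=config.fit_seed,
    )
    s = model.sigmoid
    _log(
        f"nonlinearity: a+={s.a_plus:.3g} b+={s.b_plus:.3g} c+={s.c_plus:.4g} "
        f"a-={s.a_minus:.3g} b-={s.b_minus:.3g} c-={s.c_minus:.4g} r2={s.r2:.4f}"
    )
    return erf, model


def _cell_position(dataset: Dataset) -> np.ndarray:
    meta = dataset.metadata or {}
    if "cell_position_mm" in meta:
        return np.asarray(meta["cell_position_mm"], dtype=float)
    # fall back to the ERF-weighted electrode centroid? no: array centroid
    return dataset.geometry.positions.mean(axis=0)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_") and f.name not in ("null_first_eigenvectors",)
        }
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def save_bundle(result: PipelineResult, directory: str | Path) -> None:
    """Serialize a pipeline result to JSON files in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subspace_out = {
        "eigenvalues": result.spectrum.eigenvalues,
        "normalized_eigenvalues": result.spectrum.normalized_eigenvalues,
        "sigma2": result.spectrum.sigma2,
        "significant": [
            {"axis": ax, "eigenvalue": ev, "label": lab}
            for ax, ev, lab in result.significance.significant
        ],
        "G": result.significance.G,
        "null_mean": result.significance.null_mean,
        "n_shuffles": result.significance.n_shuffles,
        "shuffle_seed": result.significance.seed,
        "erf": result.erf,
    }
    (directory / "subspace.json").write_text(json.dumps(_jsonable(subspace_out), indent=1))
    model_out = {
        "w_plus": result.model.w_plus,
        "w_minus": result.model.w_minus,
        "v1": result.model.v1,
        "sigmoid": result.model.sigmoid,
        "baseline": result.model.baseline,
    }
    (directory / "model.json").write_text(json.dumps(_jsonable(model_out), indent=1))
    (directory / "validation.json").write_text(json.dumps(_jsonable(result.report), indent=1))
    (directory / "pipeline_log.json").write_text(
        json.dumps({"config": _jsonable(result.config), "log": result.log}, indent=1)
    )


def load_model(path: str | Path) -> LNModel:
    """Read a model.json written by :func:`save_bundle`."""
    d = json.loads(Path(path).read_text())
    sig = DoubleSigmoid(**{k: (np.nan if v is None else v) for k, v in d["sigmoid"].items()})
    return LNModel(
        w_plus=None if d["w_plus"] is None else np.asarray(d["w_plus"]),
        w_minus=None if d["w_minus"] is None else np.asarray(d["w_minus"]),
        sigmoid=sig,
        v1=np.asarray(d["v1"]),
        baseline=d.get("baseline", 0.0) or 0.0,
    )
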