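"""Dataset readers/writers: CSV tables plus JSON sidecars and model files.

On-disk layout of a dataset directory:

* ``stimuli.csv`` — header row of electrode IDs, one row per presentation, uA.
* ``stimuli.json`` — sidecar with sigma, seed, repeats, mask, pulse parameters.
* ``responses.csv`` — presentation index, short (0/1), long (0/1 or blank),
  semicolon-joined latency list in ms.
* ``geometry.csv`` (optional) — electrode x/y positions in mm and mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataLoadError
from .spike_processing import ResponseVector
from .stimgen import PulseParams, StimulusEnsemble
from .synthetic_rgc import ElectrodeArray

__all__ = [
    "Dataset",
    "write_ensemble",
    "read_ensemble",
    "write_responses",
    "read_responses",
    "write_geometry",
    "read_geometry",
    "write_dataset",
    "read_dataset",
]


@dataclass
class Dataset:
    """A loaded stimulation experiment: stimuli, responses, geometry, metadata."""

    ensemble: StimulusEnsemble
    responses: ResponseVector
    geometry: ElectrodeArray | None = None
    metadata: dict | None = None

    def __post_init__(self) -> None:
        n_e = self.ensemble.n_presentations
        n_r = self.responses.n_presentations
        if n_e != n_r:
            raise DataLoadError(
                f"length mismatch: {n_e} stimulus presentations vs {n_r} response rows"
            )
        if self.geometry is not None and self.geometry.n_electrodes != self.ensemble.n_electrodes:
            raise DataLoadError(
                f"geometry has {self.geometry.n_electrodes} electrodes, "
                f"stimuli have {self.ensemble.n_electrodes}"
            )


def write_ensemble(ens: StimulusEnsemble, path: str | Path) -> None:
    path = Path(path)
    cols = [f"e{i}" for i in range(ens.n_electrodes)]
    pd.DataFrame(ens.amplitudes, columns=cols).to_csv(path, index=False)
    sidecar = {
        "sigma": ens.sigma,
        "seed": ens.seed,
        "repeats": ens.repeats,
        "mask": ens.mask.astype(int).tolist(),
        "pulse": asdict(ens.pulse),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_ensemble(path: str | Path) -> StimulusEnsemble:
    path = Path(path)
    try:
        df = pd.read_csv(path)
        amps = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataLoadError(f"non-numeric amplitude in {path}: {exc}") from exc
    meta = json.loads(path.with_suffix(".json").read_text())
    pulse = PulseParams(**meta["pulse"])
    limit = pulse.amplitude_limit_ua
    if np.any(np.abs(amps) > limit):
        bad = np.argwhere(np.abs(amps) > limit)[0]
        raise DataLoadError(
            f"amplitude {amps[bad[0], bad[1]]:.6g} uA at row {bad[0]}, column "
            f"{df.columns[bad[1]]} exceeds the declared limit {limit} uA"
        )
    return StimulusEnsemble(
        amplitudes=amps,
        sigma=float(meta["sigma"]),
        repeats=int(meta["repeats"]),
        seed=int(meta["seed"]),
        mask=np.asarray(meta["mask"], dtype=bool),
        pulse=pulse,
    )


def write_responses(resp: ResponseVector, path: str | Path) -> None:
    rows = []
    for i in range(resp.n_presentations):
        lats = ";".join(f"{v:.6g}" for v in np.atleast_1d(resp.latencies[i]))
        rows.append(
            {
                "presentation": i,
                "short": int(resp.short[i]),
                "long": int(resp.long[i]) if resp.long is not None else "",
                "latencies_ms": lats,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_responses(path: str | Path) -> ResponseVector:
    df = pd.read_csv(Path(path), keep_default_na=False)
    required = {"presentation", "short", "long", "latencies_ms"}
    if not required.issubset(df.columns):
        raise DataLoadError(f"responses file missing columns {required - set(df.columns)}")
    try:
        short = df["short"].astype(int).to_numpy()
    except ValueError as exc:
        raise DataLoadError(f"non-binary short column in {path}: {exc}") from exc
    long_col = df["long"]
    has_long = not (long_col.astype(str) == "").all()
    long = long_col.astype(int).to_numpy() if has_long else None
    latencies = []
    for s in df["latencies_ms"].astype(str):
        latencies.append(
            np.asarray([float(v) for v in s.split(";") if v != ""], dtype=float)
        )
    return ResponseVector(short=short, long=long, latencies=latencies)


def write_geometry(array: ElectrodeArray, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_mm": array.positions[:, 0],
            "y_mm": array.positions[:, 1],
            "operational": array.mask.astype(int),
        }
    ).to_csv(path, index=False)


def read_geometry(path: str | Path, diameter: float = 0.4) -> ElectrodeArray:
    df = pd.read_csv(Path(path))
    return ElectrodeArray(
        positions=df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        diameter=diameter,
        mask=df["operational"].to_numpy(dtype=bool) if "operational" in df else None,
    )


def write_dataset(ds: Dataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ensemble(ds.ensemble, directory / "stimuli.csv")
    write_responses(ds.responses, directory / "responses.csv")
    if ds.geometry is not None:
        write_geometry(ds.geometry, directory / "geometry.csv")
    if ds.metadata:
        (directory / "metadata.json").write_text(json.dumps(ds.metadata, indent=1))


def read_dataset(directory: str | Path) -> Dataset:
    directory = Path(directory)
    stim_path = directory / "stimuli.csv"
    resp_path = directory / "responses.csv"
    for p in (stim_path, resp_path):
        if not p.exists():
            raise DataLoadError(f"missing dataset file {p}")
    geom_path = directory / "geometry.csv"
    meta_path = directory / "metadata.json"
    return Dataset(
        ensemble=read_ensemble(stim_path),
        responses=read_responses(resp_path),
        geometry=read_geometry(geom_path) if geom_path.exists() else None,
        metadata=json.loads(meta_path.read_text()) if meta_path.exists() else None,
    )
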