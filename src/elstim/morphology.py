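"""Dendritic stratification depth and ON/OFF/ON-OFF classification.

Retinal ganglion cell type correlates with where the dendrites stratify in
the inner plexiform layer (IPL).  Terminal-dendrite depths x (recorded in the
instrument frame) are converted to a percentage of IPL thickness,

    s(x) = 100 (L_s - x) / (L_s - L_e),

where L_s is the IPL-GCL border and L_e the IPL-INL border, so s = 0 at the
ganglion-cell side and s = 100 at the inner-nuclear side.  Cells whose strata
all sit at <= 40% are OFF, all >= 60% are ON, one stratum in each band is
ON-OFF, and anything else is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .spike_processing import choose_k, cluster_latencies

__all__ = [
    "StratificationProfile",
    "stratification_depth",
    "classify_cell",
    "split_strata",
]


@dataclass
class StratificationProfile:
    """Terminal-dendrite depths plus the two IPL border depths (same frame, um)."""

    terminal_depths: np.ndarray
    L_s: float  # IPL-GCL border
    L_e: float  # IPL-INL border

    def __post_init__(self) -> None:
        self.terminal_depths = np.asarray(self.terminal_depths, dtype=float)
        if self.L_s == self.L_e:
            raise InvalidParameterError("L_s and L_e must differ")


def stratification_depth(profile: StratificationProfile) -> np.ndarray:
    """Percentage IPL depth s(x) = 100 (L_s - x)/(L_s - L_e) per terminal."""
    return 100.0 * (profile.L_s - profile.terminal_depths) / (profile.L_s - profile.L_e)


def split_strata(depths: np.ndarray, seed: int = 0) -> list[np.ndarray]:
    """Split a possibly bimodal depth distribution into 1 or 2 strata.

    Uses the same 1-D k-means machinery as latency clustering, choosing
    k in {1, 2} by silhouette score.
    """
    depths = np.asarray(depths, dtype=float).ravel()
    if depths.size == 0:
        raise InvalidParameterError("depths must be nonempty")
    k = choose_k(depths, seed=seed) if depths.size > 1 else 1
    if k == 1:
        return [depths]
    clusters = cluster_latencies(depths, k=2, seed=seed)
    return [depths[clusters.assignments == c] for c in range(2)]


def classify_cell(
    depths: np.ndarray,
    off_band: float = 40.0,
    on_band: float = 60.0,
    seed: int = 0,
) -> str:
    """ON / OFF / ON-OFF / unclassified from mean stratum depths (percent IPL)."""
    strata = split_strata(depths, seed=seed)
    means = [float(s.mean()) for s in strata]
    if all(m <= off_band for m in means):
        return "OFF"
    if all(m >= on_band for m in means):
        return "ON"
    has_off = any(m <= off_band for m in means)
    has_on = any(m >= on_band for m in means)
    if has_off and has_on:
        return "ON-OFF"
    return "unclassified"
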