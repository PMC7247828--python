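"""Data-driven discovery of a coarse variable for synchronizing ensembles.

Pipeline: rotating-frame phase snapshots -> 200-bin phase densities (a
permutation-invariant featurization) -> diffusion map with Laplace-Beltrami
normalization -> local-linear-regression selection of the significant
eigenfunction phi_1 -> verification that phi_1 is one-to-one with the
Kuramoto order parameter R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .manifold import DiffusionMapResult, KernelConfig, dmap_with_llr
from .oscillator_models import Trajectory, order_parameter_series, phase_density

__all__ = [
    "DensityDataset",
    "build_density_dataset",
    "densities_from_snapshots",
    "discover_coarse_variable",
    "check_one_to_one",
]

N_BINS_DEFAULT = 200
SNAPSHOTS_PER_TRAJECTORY = 400


@dataclass
class DensityDataset:
    """Snapshot-density matrix with per-snapshot order-parameter labels.

    ``densities`` has one normalized 200-bin phase density per row;
    ``R`` holds the coherence computed from the raw phases of the same
    snapshot; ``provenance`` records (trajectory id, time) per row.
    """

    densities: np.ndarray
    R: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.densities.shape[0] != self.R.shape[0]:
            raise ValueError("one R label per density row required")


def densities_from_snapshots(phases: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Normalized phase densities, one row per snapshot of ``phases``."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[1] == 0:
        raise ValueError("snapshot with empty phase vector")
    return np.stack([phase_density(row, n_bins).normalized for row in phases])


def build_density_dataset(
    trajectories: list[Trajectory],
    n_bins: int = N_BINS_DEFAULT,
    stride: int = 1,
) -> DensityDataset:
    """Bin equidistant-in-time snapshots of rotating-frame trajectories.

    Trajectories are expected to be transient-free and in the rotating
    frame (so that R alone captures the dynamics). ``stride`` subsamples
    the stored snapshots.
    """
    blocks, labels, prov = [], [], []
    for tid, traj in enumerate(trajectories):
        phases = traj.phases[::stride]
        times = traj.times[::stride]
        blocks.append(densities_from_snapshots(phases, n_bins))
        series = order_parameter_series(
            Trajectory(times=times, phases=phases, frame=traj.frame)
        )
        labels.append(series.R)
        prov.append(pd.DataFrame({"trajectory": tid, "time": times}))
    return DensityDataset(
        densities=np.vstack(blocks),
        R=np.concatenate(labels),
        provenance=pd.concat(prov, ignore_index=True),
    )


def discover_coarse_variable(
    dataset: DensityDataset,
    config: KernelConfig | None = None,
    threshold: float = 0.5,
) -> DiffusionMapResult:
    """Diffusion map on the density rows with harmonic detection.

    The returned phi_1 is sign-fixed to correlate positively with R so that
    downstream plots and fits are deterministic.
    """
    result = dmap_with_llr(dataset.densities, config or KernelConfig(), threshold)
    r_centered = dataset.R - dataset.R.mean()
    for k in range(1, result.eigenfunctions.shape[1]):
        if float(r_centered @ result.eigenfunctions[:, k]) < 0:
            result.eigenfunctions[:, k] *= -1.0
    return result


def check_one_to_one(phi: np.ndarray, labels: np.ndarray, window: int = 21) -> dict:
    """Quantify whether a discovered coordinate is one-to-one with a label.

    Returns the Spearman rank correlation, the fraction of monotonicity
    violations of phi after sorting by the label, and the min/max local
    slope of a moving-average smoothed phi(label) fit (a bounded, nonzero
    slope operationalizes "monotone with derivative bounded away from zero
    and infinity").
    """
    phi = np.asarray(phi, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if phi.shape != labels.shape:
        raise ValueError("coordinate and label vectors must have equal length")
    if np.ptp(phi) == 0 or np.ptp(labels) == 0:
        raise ValueError("rank correlation undefined for a constant vector")

    rho = float(spearmanr(phi, labels).statistic)
    order = np.argsort(labels, kind="stable")
    phi_sorted = phi[order]
    steps = np.diff(phi_sorted)
    expected_sign = np.sign(rho) if rho != 0 else 1.0
    violations = float(np.mean(expected_sign * steps < 0))

    # Moving-average smoothing before differentiating tames snapshot noise.
    w = max(3, min(window, len(phi) // 4) | 1)
    kernel = np.ones(w) / w
    smooth_phi = np.convolve(phi_sorted, kernel, mode="valid")
    smooth_lab = np.convolve(labels[order], kernel, mode="valid")
    dlab = np.diff(smooth_lab)
    good = dlab > 1e-12
    slopes = np.diff(smooth_phi)[good] / dlab[good]
    return {
        "spearman": rho,
        "violation_fraction": violations,
        "min_slope": float(slopes.min()) if slopes.size else np.nan,
        "max_slope": float(slopes.max()) if slopes.size else np.nan,
    }
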