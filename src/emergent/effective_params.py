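"""Data-driven effective parameters from steady-state phases.

For completely synchronized Kuramoto-family ensembles, the steady-state
phase of each oscillator is a function of that oscillator's heterogeneities
(frequency, coupling strength, firing coefficient, network degree).
Applying a diffusion map with an *output-only informed kernel* — built
solely from the steady phases, embedded as unit complex numbers, ignoring
the heterogeneities — reveals the intrinsic dimensionality of that
dependence. When a single eigenfunction phi_1 is significant, it is a
data-driven effective parameter: a (possibly nonlinear) combination of the
original heterogeneities that alone determines the steady phase. Level
sets of phi_1 in the original parameter space are iso-phase sets,
extracted here by marching squares (2-D) or marching cubes (3-D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .manifold import (
    DiffusionMapResult,
    KernelConfig,
    dmap_with_llr,
    gh_extend,
    gh_fit,
)
from .oscillator_models import (
    OscillatorEnsemble,
    integrate_to_sync,
    make_chung_lu_network,
    order_parameter,
    wrap_phases,
)

__all__ = [
    "SteadyStateDataset",
    "LevelSetFamily",
    "steady_state_dataset",
    "output_only_effective_param",
    "analytic_effective_parameter",
    "heterogeneous_k_balance_residual",
    "firing_balance_residual",
    "phi_on_grid",
    "extract_level_sets",
    "extract_level_surfaces",
    "REFERENCE_BANDWIDTHS",
]

# Reference kernel bandwidths for the three case studies (complex-plane
# embedding units).
REFERENCE_BANDWIDTHS = {"hetero_k": 0.5, "firing": 0.9, "chung_lu": 2.3e-2}


@dataclass
class SteadyStateDataset:
    """Rotating-frame steady phases of one synchronized ensemble.

    ``embedding`` holds x_j = e^{i theta_j} as (cos, sin) rows — the
    output-only observable; ``heterogeneities`` tabulates each oscillator's
    parameters (omega, K, alpha, degree as applicable) for later
    interpretation of the discovered coordinate.
    """

    phases: np.ndarray
    embedding: np.ndarray
    heterogeneities: pd.DataFrame
    model: str
    coherence: float
    sync_time: float
    psi_inf: float = 0.0

    @property
    def stationary_phases(self) -> np.ndarray:
        """Steady phases in the stationary frame (rotated + psi_inf) —
        required by balances that are not rotation-invariant (firing)."""
        return self.phases + self.psi_inf

    def __post_init__(self) -> None:
        moduli = np.hypot(self.embedding[:, 0], self.embedding[:, 1])
        if not np.allclose(moduli, 1.0, atol=1e-12):
            raise ValueError("embedding rows must be unit complex numbers")


@dataclass
class LevelSetFamily:
    """Iso-phi contours on a parameter grid.

    ``contours[level]`` is a list of polylines in parameter coordinates;
    every contour vertex bilinearly interpolates the gridded phi to its
    level.
    """

    grid_axes: tuple[np.ndarray, ...]
    phi_grid: np.ndarray
    levels: np.ndarray
    contours: dict[float, list[np.ndarray]] = field(default_factory=dict)


def steady_state_dataset(
    variant: str,
    n_oscillators: int | None = None,
    seed: int | None = None,
    t_max: float | None = None,
    speed_tol: float | None = None,
    network_seed: int | None = None,
    coupling: float = 20.0,
) -> SteadyStateDataset:
    """Simulate one case study to complete synchronization.

    Variants (defaults follow the three reference case studies):

    - ``"hetero_k"``: N=1500, omega ~ U[-pi, pi], K_i ~ U[10, 100]
    - ``"firing"``: as above plus alpha_i ~ U[-2, 2]
    - ``"chung_lu"``: N=4000, omega ~ U[0, 1], scalar K=20 on a Chung-Lu
      adjacency with (p, q, r) = (0.5, 0.9, 0.5)

    Initial phases are uniform on [0, 2 pi). The ensemble is integrated
    until the largest rotating-frame phase speed drops below ``speed_tol``,
    then the snapshot is shifted so psi = 0 and embedded on the unit
    circle.

    The firing variant differs in two ways. Its term alpha_i sin(theta_i)
    breaks rotational symmetry, pinning the ensemble to the stationary
    frame, so its steady state is checked on the absolute phase
    velocities, and to a much tighter tolerance: the analytic balance
    divides by alpha_i, so oscillators with small |alpha_i| amplify any
    residual drift. It also relaxes far more slowly (a weakly damped
    collective mode; relaxation times of hundreds of time units), hence
    the larger horizon — and some heterogeneity draws never settle at all
    (the attractor is a small-amplitude collective limit cycle instead of
    a fixed point) and raise the incomplete-synchronization error.
    """
    if t_max is None:
        t_max = {"hetero_k": 100.0, "firing": 900.0, "chung_lu": 200.0}.get(
            variant, 200.0
        )
    if speed_tol is None:
        speed_tol = 3e-7 if variant == "firing" else 1e-4
    rng = np.random.default_rng(seed)
    if variant == "hetero_k":
        n = n_oscillators or 1500
        omega = rng.uniform(-np.pi, np.pi, n)
        k_i = rng.uniform(10.0, 100.0, n)
        ensemble = OscillatorEnsemble(
            phases=np.zeros(n), frequencies=omega, coupling=k_i
        )
        het = pd.DataFrame({"omega": omega, "K": k_i})
    elif variant == "firing":
        n = n_oscillators or 1500
        omega = rng.uniform(-np.pi, np.pi, n)
        k_i = rng.uniform(10.0, 100.0, n)
        alpha = rng.uniform(-2.0, 2.0, n)
        ensemble = OscillatorEnsemble(
            phases=np.zeros(n), frequencies=omega, coupling=k_i, alpha=alpha
        )
        het = pd.DataFrame({"omega": omega, "K": k_i, "alpha": alpha})
    elif variant == "chung_lu":
        n = n_oscillators or 4000
        omega = rng.uniform(0.0, 1.0, n)
        network = make_chung_lu_network(
            n, 0.5, 0.9, 0.5, seed=network_seed if network_seed is not None else seed
        )
        ensemble = OscillatorEnsemble(
            phases=np.zeros(n),
            frequencies=omega,
            coupling=coupling,
            adjacency=network.adjacency.astype(float),
        )
        het = pd.DataFrame({"omega": omega, "degree": network.degrees})
    else:
        raise ValueError(f"unknown variant {variant!r}")

    theta0 = rng.uniform(0.0, 2.0 * np.pi, n)
    firing = variant == "firing"
    theta_inf, t_sync = integrate_to_sync(
        ensemble,
        theta0,
        speed_tol=speed_tol,
        t_max=t_max,
        chunk=25.0 if firing else 5.0,
        atol=1e-12 if firing else 1e-10,
        rtol=1e-10 if firing else 1e-8,
        absolute=firing,
    )
    coherence, psi = order_parameter(theta_inf)
    rotated = wrap_phases(theta_inf - psi)
    embedding = np.column_stack([np.cos(rotated), np.sin(rotated)])
    return SteadyStateDataset(
        phases=rotated,
        embedding=embedding,
        heterogeneities=het,
        model=variant,
        coherence=coherence,
        sync_time=t_sync,
        psi_inf=psi,
    )


def output_only_effective_param(
    dataset: SteadyStateDataset,
    epsilon: float | None = None,
    alpha: float = 1.0,
    n_eig: int = 11,
    threshold: float = 0.5,
) -> DiffusionMapResult:
    """Output-only-informed diffusion map on the unit-circle embedding.

    The kernel sees only the steady phases (through x = e^{i theta}); the
    heterogeneities never enter. The significant eigenfunctions are the
    data-driven effective parameters; phi_1 is sign-fixed to correlate
    positively with the steady phase and attached to the heterogeneity
    table as a new column.
    """
    if epsilon is None:
        epsilon = REFERENCE_BANDWIDTHS.get(dataset.model)
    result = dmap_with_llr(
        dataset.embedding,
        KernelConfig(epsilon=epsilon, alpha=alpha, n_eig=n_eig),
        threshold,
    )
    ref = dataset.phases - dataset.phases.mean()
    for k in range(1, result.eigenfunctions.shape[1]):
        if float(ref @ result.eigenfunctions[:, k]) < 0:
            result.eigenfunctions[:, k] *= -1.0
    dataset.heterogeneities["phi1"] = result.phi(1)
    return result


def analytic_effective_parameter(omega, K, R: float, psi: float = 0.0):
    """Closed-form steady phase for per-oscillator coupling:
    ``theta_inf = psi + arcsin(omega / (R K))``.

    Valid only for phase-locked oscillators, i.e. |omega / (R K)| <= 1;
    a larger argument means the oscillator drifts and has no steady phase.
    """
    arg = np.asarray(omega, dtype=float) / (R * np.asarray(K, dtype=float))
    if np.any(np.abs(arg) > 1.0):
        raise ValueError(
            "|omega / (R K)| > 1 for some oscillator: it drifts and is not "
            "phase-locked"
        )
    out = psi + np.arcsin(arg)
    return float(out) if out.ndim == 0 else out


def heterogeneous_k_balance_residual(theta_inf, omega, K, R: float, psi: float = 0.0):
    """Steady-state balance ``sin(theta_inf - psi) - omega / (R K)`` for the
    per-oscillator-coupling model; vanishes at a true steady state."""
    return np.sin(np.asarray(theta_inf) - psi) - np.asarray(omega) / (
        R * np.asarray(K)
    )


def firing_balance_residual(theta_inf, omega, alpha, K, R: float, psi: float = 0.0):
    """Steady-state balance of the firing model,
    ``(R K / alpha) sin(theta - psi) - sin(theta) - omega / alpha``;
    vanishes at a true steady state and reduces to the familiar psi = 0
    form ``(R K/alpha - 1) sin(theta) - omega/alpha`` when psi = 0.

    ``theta_inf`` and ``psi`` must be in the same (stationary) frame: the
    firing term pins the ensemble's absolute phase, so unlike the plain
    model no rotating-frame choice can set psi to zero — the realized mean
    phase of the steady state enters the balance explicitly. Oscillators
    with alpha = 0 reduce to the plain model and are rejected here.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha == 0.0):
        raise ZeroDivisionError(
            "alpha = 0 oscillators have no firing term; use the plain "
            "steady-state balance for them"
        )
    theta = np.asarray(theta_inf, dtype=float)
    return (
        (R * np.asarray(K) / alpha) * np.sin(theta - psi)
        - np.sin(theta)
        - np.asarray(omega) / alpha
    )


# ---------------------------------------------------------------------------
# Level sets in parameter space
# ---------------------------------------------------------------------------

def phi_on_grid(
    dataset: SteadyStateDataset,
    columns: tuple[str, ...],
    grid_axes: tuple[np.ndarray, ...],
    epsilon: float | None = None,
    n_harmonics: int | None = None,
) -> np.ndarray:
    """Transfer the scattered phi_1 values onto a regular parameter grid by
    geometric-harmonics extension.

    Heterogeneity columns are standardized before the kernel is built so
    that parameters with different units contribute comparably.
    """
    if "phi1" not in dataset.heterogeneities:
        raise ValueError("run output_only_effective_param first")
    pts = dataset.heterogeneities[list(columns)].to_numpy(dtype=float)
    mean, std = pts.mean(axis=0), pts.std(axis=0)
    std[std == 0] = 1.0
    model = gh_fit(
        (pts - mean) / std,
        dataset.heterogeneities["phi1"].to_numpy(),
        epsilon=epsilon,
        n_harmonics=n_harmonics,
    )
    mesh = np.meshgrid(*grid_axes, indexing="ij")
    grid_pts = np.column_stack([m.ravel() for m in mesh])
    values = gh_extend(model, (grid_pts - mean) / std)
    return values.reshape(mesh[0].shape)


def extract_level_sets(
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    phi_grid: np.ndarray,
    levels: np.ndarray,
) -> LevelSetFamily:
    """Marching-squares contours of a gridded scalar on a 2-D parameter
    grid; vertex indices are mapped back to parameter coordinates. Levels
    outside the observed range yield empty contour lists."""
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    phi_grid = np.asarray(phi_grid, dtype=float)
    if phi_grid.shape != (grid_x.size, grid_y.size):
        raise ValueError("phi grid must be (len(grid_x), len(grid_y))")
    family = LevelSetFamily(
        grid_axes=(grid_x, grid_y), phi_grid=phi_grid, levels=np.asarray(levels, float)
    )
    dx = grid_x[1] - grid_x[0]
    dy = grid_y[1] - grid_y[0]
    for level in family.levels:
        polylines = []
        for contour in measure.find_contours(phi_grid, level):
            coords = np.column_stack(
                [grid_x[0] + contour[:, 0] * dx, grid_y[0] + contour[:, 1] * dy]
            )
            polylines.append(coords)
        family.contours[float(level)] = polylines
    return family


def extract_level_surfaces(
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    phi_grid: np.ndarray,
    levels: np.ndarray,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Marching-cubes iso-surfaces of a 3-D gridded scalar (the firing
    model's (omega, K, alpha) space); returns vertices in parameter
    coordinates and triangle faces per level."""
    spacing = tuple(float(ax[1] - ax[0]) for ax in grid_axes)
    origin = np.array([ax[0] for ax in grid_axes])
    surfaces = {}
    for level in np.asarray(levels, dtype=float):
        if not phi_grid.min() < level < phi_grid.max():
            surfaces[float(level)] = (np.empty((0, 3)), np.empty((0, 3), dtype=int))
            continue
        verts, faces, _, _ = measure.marching_cubes(phi_grid, level, spacing=spacing)
        surfaces[float(level)] = (verts + origin, faces)
    return surfaces


def save_surface_obj(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Persist a triangulated level surface as OBJ-style text."""
    with open(path, "w") as fh:
        for v in vertices:
            fh.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for f in faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
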