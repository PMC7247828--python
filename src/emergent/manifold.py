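"""Diffusion maps, harmonic detection, and geometric harmonics.

The diffusion map builds a Markov operator from a Gaussian kernel on the
data, with the alpha-normalization of Coifman & Lafon controlling how the
sampling density enters (alpha = 1 approximates the Laplace-Beltrami
operator, removing density influence). Eigenfunctions of that operator
parameterize the underlying manifold, but higher eigenfunctions can be
"harmonics" — smooth functions of earlier ones that add no new direction.
These are detected by a leave-one-out local linear regression: each
eigenfunction is locally regressed on its predecessors, and a normalized
cross-validation residual near one flags a genuinely new coordinate.

Geometric harmonics provide the companion Nystrom-type extension: a
function known on the samples is expanded in the eigenfunctions of a
symmetric kernel matrix and evaluated out of sample through the
cross-kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "KernelConfig",
    "DiffusionMapResult",
    "GeometricHarmonicsModel",
    "median_pairwise_distance",
    "gaussian_kernel",
    "dmap_embed",
    "llr_residuals",
    "select_significant",
    "dmap_with_llr",
    "gh_fit",
    "gh_extend",
]


@dataclass
class KernelConfig:
    """Diffusion-map kernel settings.

    epsilon
        Bandwidth of the Gaussian kernel ``exp(-d^2 / (2 eps^2))``, in data
        units. ``None`` selects the median of the pairwise distances.
    alpha
        Density-normalization exponent (0 = graph Laplacian, 0.5 =
        Fokker-Planck, 1 = Laplace-Beltrami).
    n_eig
        Number of eigenpairs to compute, including the trivial constant
        (default 11: constant + 10 nontrivial).
    """

    epsilon: float | None = None
    alpha: float = 1.0
    n_eig: int = 11

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("kernel bandwidth must be positive")
        if self.n_eig < 2:
            raise ValueError("need at least two eigenpairs")


@dataclass
class DiffusionMapResult:
    """Eigenpairs of the diffusion operator plus harmonic diagnostics.

    ``eigenvalues``/``eigenfunctions`` include the trivial constant pair at
    index 0; ``phi(k)`` indexes the nontrivial eigenfunctions starting at
    phi_1. ``residuals[k-1]`` is the local-linear-regression residual of
    phi_k (r_1 = 1 by convention); ``significant`` lists the 1-based indices
    flagged as new manifold directions.
    """

    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray
    epsilon: float
    alpha: float
    residuals: np.ndarray | None = None
    significant: list[int] | None = None

    def phi(self, k: int) -> np.ndarray:
        """k-th nontrivial eigenfunction (k >= 1)."""
        if k < 1:
            raise IndexError("nontrivial eigenfunctions are numbered from 1")
        return self.eigenfunctions[:, k]

    @property
    def nontrivial(self) -> np.ndarray:
        """All nontrivial eigenfunctions as columns, ordered by eigenvalue."""
        return self.eigenfunctions[:, 1:]


def median_pairwise_distance(data: np.ndarray) -> float:
    """Median Euclidean pairwise distance — the default bandwidth heuristic."""
    d = pdist(np.asarray(data, dtype=float))
    return float(np.median(d))


def gaussian_kernel(sq_dists: np.ndarray, epsilon: float) -> np.ndarray:
    """``exp(-d^2 / (2 eps^2))`` on a matrix of squared distances."""
    return np.exp(-sq_dists / (2.0 * epsilon**2))


def dmap_embed(data: np.ndarray, config: KernelConfig | None = None) -> DiffusionMapResult:
    """Diffusion-map embedding of the rows of ``data``.

    Builds the Gaussian kernel, applies the alpha-normalization
    ``K~ = D^-a K D^-a``, and diagonalizes the row-stochastic operator
    ``A = D~^-1 K~`` through its symmetric conjugate
    ``S = D~^-1/2 K~ D~^-1/2`` for numerical stability. Eigenfunctions are
    back-transformed, sorted by descending eigenvalue, scaled so the
    trivial pair is (1, constant 1), and sign-fixed against the first data
    coordinate.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D matrix of observations")
    cfg = config or KernelConfig()
    n = data.shape[0]
    if n < cfg.n_eig + 1:
        raise ValueError(f"need more than n_eig={cfg.n_eig} data points, got {n}")

    sq = squareform(pdist(data, metric="sqeuclidean"))
    eps = cfg.epsilon if cfg.epsilon is not None else float(np.median(np.sqrt(sq[np.triu_indices(n, 1)])))
    kernel = gaussian_kernel(sq, eps)
    off_diag_max = (kernel - np.eye(n)).max()
    if off_diag_max < 1e-14:
        raise ValueError(
            f"kernel bandwidth {eps:g} is so small the kernel matrix is "
            "numerically diagonal; increase epsilon"
        )

    d = kernel.sum(axis=1)
    if cfg.alpha != 0.0:
        inv_d_alpha = d ** (-cfg.alpha)
        kernel = kernel * np.outer(inv_d_alpha, inv_d_alpha)
    d_tilde = kernel.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_tilde)
    sym = kernel * np.outer(inv_sqrt, inv_sqrt)
    sym = 0.5 * (sym + sym.T)  # defend against round-off asymmetry

    if n <= 1500:
        vals, vecs = eigh(sym, subset_by_index=(n - cfg.n_eig, n - 1))
    else:
        vals, vecs = eigsh(sym, k=cfg.n_eig, which="LA")
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]

    # Back-transform to eigenfunctions of the row-stochastic operator and
    # rescale so the constant eigenfunction is identically 1.
    funcs = vecs * inv_sqrt[:, None]
    funcs /= np.linalg.norm(funcs, axis=0) / np.sqrt(n)
    if funcs[0, 0] < 0:
        funcs[:, 0] *= -1.0
    # Deterministic sign: correlate each nontrivial phi with the first data
    # coordinate (ties broken toward positive first entry).
    ref = data[:, 0] - data[:, 0].mean()
    for k in range(1, funcs.shape[1]):
        c = float(ref @ funcs[:, k])
        if c < 0 or (c == 0 and funcs[0, k] < 0):
            funcs[:, k] *= -1.0

    return DiffusionMapResult(
        eigenvalues=vals, eigenfunctions=funcs, epsilon=eps, alpha=cfg.alpha
    )


def _local_linear_residual(
    target: np.ndarray, predictors: np.ndarray, eps_reg: float | None
) -> float:
    """Normalized leave-one-out local-linear-regression residual.

    Fits ``target(i) ~ a(i) + b(i)^T predictors(i)`` with Gaussian weights
    centered at each point i (the point itself excluded) and returns
    ``sqrt(sum (target - pred)^2 / sum target^2)``.
    """
    n = target.shape[0]
    sq = squareform(pdist(predictors, metric="sqeuclidean"))
    if eps_reg is None:
        eps_reg = float(np.median(np.sqrt(sq[np.triu_indices(n, 1)]))) / 3.0
    if eps_reg <= 0:
        raise ValueError("regression kernel scale must be positive")
    w = gaussian_kernel(sq, eps_reg)
    np.fill_diagonal(w, 0.0)  # leave-one-out weighting
    # tiny uniform floor: a point isolated in predictor space otherwise has
    # an all-zero weight row and a singular local system; the floor turns
    # its fit into a global least squares without affecting other points
    w += 1e-12

    x = np.column_stack([np.ones(n), predictors])  # n x m design
    m = x.shape[1]
    # Batched weighted normal equations: G_i = sum_j w_ij x_j x_j^T.
    xx = (x[:, :, None] * x[:, None, :]).reshape(n, m * m)
    gram = (w @ xx).reshape(n, m, m)
    rhs = w @ (x * target[:, None])
    ridge = 1e-10 * np.trace(gram, axis1=1, axis2=2)
    gram[:, np.arange(m), np.arange(m)] += ridge[:, None]
    coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
    pred = np.einsum("ij,ij->i", x, coef)
    return float(np.sqrt(np.sum((target - pred) ** 2) / np.sum(target**2)))


def llr_residuals(eigenfunctions: np.ndarray, eps_reg: float | None = None) -> np.ndarray:
    """Residuals r_k for a matrix of nontrivial eigenfunctions (columns,
    ordered by descending eigenvalue, trivial constant excluded).

    r_1 = 1 by convention (no predecessors to regress on); for k >= 2 the
    k-th eigenfunction is locally regressed on phi_1 .. phi_{k-1}. The
    regression kernel scale defaults to one third of the median pairwise
    distance among the predecessor rows, recomputed for each k.
    """
    phi = np.asarray(eigenfunctions, dtype=float)
    if phi.ndim != 2:
        raise ValueError("eigenfunctions must be a 2-D matrix (columns = phi_k)")
    m = phi.shape[1]
    res = np.ones(m)
    for k in range(1, m):
        res[k] = _local_linear_residual(phi[:, k], phi[:, :k], eps_reg)
    return res


def select_significant(
    residuals: np.ndarray,
    threshold: float = 0.5,
    eigenvalues: np.ndarray | None = None,
    min_eigenvalue_ratio: float = 1e-3,
) -> list[int]:
    """1-based indices of eigenfunctions whose residual exceeds the
    threshold, in eigenvalue order.

    When ``eigenvalues`` (nontrivial, descending) are supplied, two guards
    exclude eigenfunctions the kernel has not actually resolved — at the
    bottom of the spectrum the eigenvectors are dominated by sampling
    noise and are not functions on the manifold at all, so their (high)
    residuals carry no significance:

    - eigenvalues below ``min_eigenvalue_ratio`` times the leading
      nontrivial eigenvalue;
    - a trailing noise *plateau*: two or more smallest eigenvalues
      clustered within a factor of 2 of the very smallest (a genuinely
      resolved spectrum keeps decaying; quasi-equal trailing values are
      the discretization noise floor); and
    - everything past a spectral *cliff*, a more than twenty-fold drop
      between consecutive eigenvalues: past such a collapse the remaining
      eigenvectors carry mostly discretization noise. (A true new
      direction in extremely anisotropic data could in principle hide
      behind a cliff; inspect the residual spectrum when in doubt.)
    """
    residuals = np.asarray(residuals)
    keep = np.ones(residuals.shape[0], dtype=bool)
    if eigenvalues is not None:
        lam = np.abs(np.asarray(eigenvalues)[: residuals.shape[0]])
        keep = lam > min_eigenvalue_ratio * lam[0]
        plateau = lam < 2.0 * lam[-1]
        if plateau.sum() >= 2:
            keep &= ~plateau
        with np.errstate(divide="ignore", invalid="ignore"):
            drop = lam[1:] / lam[:-1]
        cliffs = np.flatnonzero(drop < 0.05)
        if cliffs.size:
            keep[cliffs[0] + 1 :] = False
    return [k + 1 for k, r in enumerate(residuals) if keep[k] and r > threshold]


def dmap_with_llr(
    data: np.ndarray,
    config: KernelConfig | None = None,
    threshold: float = 0.5,
    eps_reg: float | None = None,
) -> DiffusionMapResult:
    """Diffusion map plus harmonic detection in one call."""
    result = dmap_embed(data, config)
    result.residuals = llr_residuals(result.nontrivial, eps_reg)
    result.significant = select_significant(
        result.residuals, threshold, eigenvalues=result.eigenvalues[1:]
    )
    return result


# ---------------------------------------------------------------------------
# Geometric harmonics
# ---------------------------------------------------------------------------

@dataclass
class GeometricHarmonicsModel:
    """Spectrum of a symmetric Gaussian kernel on the training points,
    used to extend sampled functions out of sample."""

    points: np.ndarray
    epsilon: float
    eigenvalues: np.ndarray  # retained lambda_l, descending
    eigenvectors: np.ndarray  # retained psi^(l) as columns
    values: np.ndarray  # training function values F
    coefficients: np.ndarray = field(init=False)  # Lambda^-1 Psi^T F

    def __post_init__(self) -> None:
        proj = self.eigenvectors.T @ self.values
        scale = self.eigenvalues if proj.ndim == 1 else self.eigenvalues[:, None]
        self.coefficients = proj / scale


def gh_fit(
    points: np.ndarray,
    values: np.ndarray,
    epsilon: float | None = None,
    n_harmonics: int | None = None,
    cutoff: float = 1e-8,
) -> GeometricHarmonicsModel:
    """Fit a geometric-harmonics extension model.

    Diagonalizes the symmetric Gaussian kernel on ``points`` and retains the
    leading ``n_harmonics`` eigenpairs (all of them by default), truncating
    any eigenvalue below ``cutoff`` times the largest to keep the inverse
    well conditioned.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and points.shape[1] > 1 and np.asarray(values).shape[0] == points.shape[1]:
        points = points.T
    values = np.asarray(values, dtype=float)
    n = points.shape[0]
    if values.shape[0] != n:
        raise ValueError("one function value per training point required")
    if n_harmonics is not None and n_harmonics > n:
        raise ValueError("cannot retain more harmonics than training points")

    if epsilon is None:
        epsilon = median_pairwise_distance(points)
    kernel = gaussian_kernel(squareform(pdist(points, metric="sqeuclidean")), epsilon)
    vals, vecs = eigh(kernel)
    order = np.argsort(np.abs(vals))[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = n if n_harmonics is None else n_harmonics
    mask = np.abs(vals[:keep]) > cutoff * np.abs(vals[0])
    if not mask.all():
        warnings.warn(
            f"truncated {int((~mask).sum())} geometric harmonics below the "
            f"conditioning cutoff {cutoff:g}",
            stacklevel=2,
        )
    vals, vecs = vals[:keep][mask], vecs[:, :keep][:, mask]
    return GeometricHarmonicsModel(
        points=points, epsilon=float(epsilon), eigenvalues=vals, eigenvectors=vecs, values=values
    )


def gh_extend(model: GeometricHarmonicsModel, new_points: np.ndarray) -> np.ndarray:
    """Evaluate the extension ``f = K_new Psi Lambda^-1 Psi^T F`` at new
    points (rows)."""
    new_points = np.atleast_2d(np.asarray(new_points, dtype=float))
    if new_points.shape[1] != model.points.shape[1]:
        new_points = new_points.reshape(-1, model.points.shape[1])
    cross = gaussian_kernel(
        cdist(new_points, model.points, metric="sqeuclidean"), model.epsilon
    )
    return cross @ (model.eigenvectors @ model.coefficients)
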