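"""Learning ODE right-hand sides from flow pairs with an RK4-templated net.

A small feedforward network f-hat is embedded inside one step of the
classical fourth-order Runge-Kutta scheme: the model's prediction for a
flow pair (y(t), y(t + dt)) is ``rk4_step(f_hat, y(t), dt)``, and the mean
squared error on y(t + dt) is minimized. Because the same sub-network is
evaluated at all four stages, the trained f-hat is an approximation of the
time derivative itself, evaluable at arbitrary states.

The module also provides the flow-pair generator for the all-to-all
Kuramoto ensemble (initialize at R ~ 0 or R = 1, pre-integrate to a target
coherence, then step exactly dt further), the analytic Ott-Antonsen
reduction used as the ground-truth oracle, and a forward-Euler +
geometric-harmonics baseline estimator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .coarse_id import densities_from_snapshots
from .manifold import (
    GeometricHarmonicsModel,
    KernelConfig,
    dmap_with_llr,
    gh_extend,
    gh_fit,
)
from .oscillator_models import sample_cauchy_frequencies, wrap_phases

__all__ = [
    "FlowPairSet",
    "RK4NetConfig",
    "RHSModel",
    "PhiDynamicsResult",
    "ott_antonsen_rhs",
    "oa_fixed_point",
    "oa_flow",
    "oa_time_to_reach",
    "generate_flow_pairs",
    "rk4_step",
    "train_rhs_net",
    "integrate_learned",
    "baseline_euler_gh",
    "learn_phi_dynamics",
]


# ---------------------------------------------------------------------------
# Ott-Antonsen analytic oracle
# ---------------------------------------------------------------------------

def ott_antonsen_rhs(R, K: float = 2.0, gamma: float = 0.5):
    """Continuum-limit order-parameter ODE for Cauchy frequencies:
    ``dR/dt = -gamma R + (K/2) R (1 - R^2)`` (the mean phase is constant).
    """
    R = np.asarray(R, dtype=float)
    out = -gamma * R + 0.5 * K * R * (1.0 - R**2)
    return float(out) if out.ndim == 0 else out


def oa_fixed_point(K: float = 2.0, gamma: float = 0.5) -> float:
    """Stable coherence ``sqrt(1 - 2 gamma / K)`` (0 when K <= 2 gamma)."""
    if K <= 2.0 * gamma:
        return 0.0
    return float(np.sqrt(1.0 - 2.0 * gamma / K))


def _oa_ab(K: float, gamma: float) -> tuple[float, float]:
    return 0.5 * K - gamma, 0.5 * K


def oa_flow(r0, t, K: float = 2.0, gamma: float = 0.5):
    """Closed-form solution of the order-parameter ODE.

    The equation is a Bernoulli ODE ``dR/dt = a R - b R^3`` with
    ``a = K/2 - gamma``, ``b = K/2``; substituting u = R^-2 linearizes it,
    giving ``R(t)^2 = a u0 e^{2at} / (a + b u0 (e^{2at} - 1))`` with
    u0 = R(0)^2.
    """
    a, b = _oa_ab(K, gamma)
    r0 = np.asarray(r0, dtype=float)
    t = np.asarray(t, dtype=float)
    u0 = r0**2
    if a == 0:
        u = u0 / (1.0 + 2.0 * b * u0 * t)
    else:
        e = np.exp(2.0 * a * t)
        u = a * u0 * e / (a + b * u0 * (e - 1.0))
    out = np.sqrt(np.clip(u, 0.0, None))
    return float(out) if out.ndim == 0 else out


def oa_time_to_reach(r0, r_target, K: float = 2.0, gamma: float = 0.5):
    """Time for the analytic flow to move from r0 to r_target.

    Both coherences must lie strictly on the same side of the fixed point
    (the flow never crosses it); targets on the far side raise ValueError.
    """
    a, b = _oa_ab(K, gamma)
    if a <= 0:
        raise ValueError("inversion requires a supercritical coupling (K > 2 gamma)")
    u0 = np.asarray(r0, dtype=float) ** 2
    u = np.asarray(r_target, dtype=float) ** 2
    side0 = a - b * u0
    side1 = a - b * u
    if np.any(side0 * side1 <= 0):
        raise ValueError(
            "target coherence is beyond the attainable range: the analytic "
            "flow cannot cross its fixed point"
        )
    t = np.log(u * side0 / (u0 * side1)) / (2.0 * a)
    return float(t) if t.ndim == 0 else t


# ---------------------------------------------------------------------------
# Flow-pair generation
# ---------------------------------------------------------------------------

@dataclass
class FlowPairSet:
    """Matched observations (y(t), y(t + dt)) at a fixed reporting horizon.

    ``branch`` records which initialization produced each pair (0 = started
    near incoherence, 1 = started fully synchronized). When generated with
    ``retain_phases=True`` the raw phase snapshots at both ends are kept so
    the same flows can be re-expressed in a discovered coordinate.
    """

    y_start: np.ndarray
    y_end: np.ndarray
    dt: float
    variable: str = "R"
    branch: np.ndarray | None = None
    seed: int | None = None
    phases_start: np.ndarray | None = None
    phases_end: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y_start = np.asarray(self.y_start, dtype=float)
        self.y_end = np.asarray(self.y_end, dtype=float)
        if self.y_start.shape != self.y_end.shape:
            raise ValueError("start and end values must have equal length")
        if self.dt <= 0:
            raise ValueError("reporting horizon dt must be positive")
        if self.variable == "R" and (
            np.any(self.y_start < 0) or np.any(self.y_start > 1)
            or np.any(self.y_end < 0) or np.any(self.y_end > 1)
        ):
            raise ValueError("coherence values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.y_start.shape[0]


def _rotate_small(zr: np.ndarray, zi: np.ndarray, x: np.ndarray):
    """Multiply unit phasors (zr + i zi) by e^{ix} for small |x| via a
    degree-5 Taylor rotation (error O(x^6); the kick angle per substep is
    bounded by K R h ~ 2e-2)."""
    x2 = x * x
    c = 1.0 - x2 * (0.5 - x2 / 24.0)
    s = x * (1.0 - x2 * (1.0 / 6.0 - x2 / 120.0))
    return zr * c - zi * s, zr * s + zi * c


def _mean_field_kick(zr: np.ndarray, zi: np.ndarray, K: float, h: float):
    """Midpoint (RK2) substep for the pure coupling flow
    ``theta' = K R sin(psi - theta)`` on a batch of phasor rows.

    With z_j = e^{i theta_j} and Z = mean_j z_j = R e^{i psi}, the coupling
    velocity is ``K Im(Z conj(z_j))`` — pure complex arithmetic. Kept in
    numpy as the reference for the fused batch kernel below.
    """
    mzr = zr.mean(axis=1, keepdims=True)
    mzi = zi.mean(axis=1, keepdims=True)
    v1 = K * (zr * mzi - zi * mzr)
    mr, mi = _rotate_small(zr, zi, 0.5 * h * v1)
    m2r = mr.mean(axis=1, keepdims=True)
    m2i = mi.mean(axis=1, keepdims=True)
    v2 = K * (mr * m2i - mi * m2r)
    return _rotate_small(zr, zi, h * v2)


@numba.njit(cache=False, fastmath=True)
def _split_step_kernel(zr, zi, dr, di, coupling, h, out_means):  # pragma: no cover
    """One drift-kick-drift step, fused per row, in place.

    ``dr``/``di`` are the precomputed half-step free-rotation multipliers
    cos(omega h / 2), sin(omega h / 2). Writes the per-row mean phasor of
    the *advanced* state (the coherence monitor) into ``out_means``.
    """
    rows, n = zr.shape
    for r in range(rows):
        sr1 = 0.0
        si1 = 0.0
        for j in range(n):
            a = zr[r, j]
            b = zi[r, j]
            c = dr[r, j]
            s = di[r, j]
            na = a * c - b * s
            nb = a * s + b * c
            zr[r, j] = na
            zi[r, j] = nb
            sr1 += na
            si1 += nb
        mzr = sr1 / n
        mzi = si1 / n
        # midpoint state and its mean phasor
        sr2 = 0.0
        si2 = 0.0
        for j in range(n):
            a = zr[r, j]
            b = zi[r, j]
            x = 0.5 * h * coupling * (a * mzi - b * mzr)
            x2 = x * x
            cc = 1.0 - x2 * (0.5 - x2 / 24.0)
            ss = x * (1.0 - x2 * (1.0 / 6.0 - x2 / 120.0))
            sr2 += a * cc - b * ss
            si2 += a * ss + b * cc
        m2r = sr2 / n
        m2i = si2 / n
        sr3 = 0.0
        si3 = 0.0
        for j in range(n):
            a = zr[r, j]
            b = zi[r, j]
            # recompute the midpoint phasor, evaluate the midpoint velocity
            x = 0.5 * h * coupling * (a * mzi - b * mzr)
            x2 = x * x
            cc = 1.0 - x2 * (0.5 - x2 / 24.0)
            ss = x * (1.0 - x2 * (1.0 / 6.0 - x2 / 120.0))
            ma = a * cc - b * ss
            mb = a * ss + b * cc
            x = h * coupling * (ma * m2i - mb * m2r)
            x2 = x * x
            cc = 1.0 - x2 * (0.5 - x2 / 24.0)
            ss = x * (1.0 - x2 * (1.0 / 6.0 - x2 / 120.0))
            na = a * cc - b * ss
            nb = a * ss + b * cc
            # trailing half drift
            c = dr[r, j]
            s = di[r, j]
            fa = na * c - nb * s
            fb = na * s + nb * c
            zr[r, j] = fa
            zi[r, j] = fb
            sr3 += fa
            si3 += fb
        out_means[r, 0] = sr3 / n
        out_means[r, 1] = si3 / n


def generate_flow_pairs(
    n_pairs: int = 2000,
    dt: float = 0.01,
    n_oscillators: int = 8000,
    coupling: float = 2.0,
    gamma: float = 0.5,
    seed: int | None = None,
    retain_phases: bool = False,
    step: float = 0.01,
    r_lo: float = 0.02,
    r_hi: float = 1.0,
    margin: float = 0.02,
    r_switch: float = 0.2,
    arm_delay: float = 1.5,
) -> FlowPairSet:
    """Flow pairs (R(t), R(t + dt)) for the all-to-all Kuramoto ensemble.

    Every pair is a fresh ensemble: independently sampled Cauchy
    frequencies and its own initial phases, started either near incoherence
    (uniform random phases) or fully synchronized (identical phases). A
    jittered uniform grid of target coherences (allocated to the two
    branches in proportion to each branch's attainable span on its side of
    the stable fixed point) fixes where the recorded R(t) values should
    fall, so they cover [0, 1] approximately uniformly. Each ensemble is
    pre-integrated to its target and then integrated exactly ``dt``
    further.

    Pre-integration times are scheduled so the recorded slopes stay
    unbiased. Where the analytic flow predicts the trajectory well (the
    synchronized branch, and low-coherence targets before the incoherent
    branch's growth sets in), the time is fixed in advance by inverting
    the analytic flow from the ensemble's own initial coherence. Mid-range
    targets on the growth branch cannot be hit by any fixed schedule (the
    growth onset jitters between realizations), so those rows are
    snapshotted a fixed decorrelation delay AFTER first crossing a
    backshifted arming level: the crossing supplies realization-specific
    timing, while the delay (default 1.5 time units) lets the first-
    passage conditioning decay before the pair is recorded. Snapshots are
    never taken at the crossing itself — that would select on the noise
    history and bias the sampled slopes.

    Integration uses a symmetric drift-kick-drift splitting on unit
    phasors: the free rotation is an exact precomputed complex multiply
    and the coupling kick is a midpoint substep applied as small-angle
    rotations. All ensembles advance as one batch with step ``step``;
    ``dt`` must be an integer multiple of ``step``.
    """
    if dt <= 0 or step <= 0:
        raise ValueError("dt and step must be positive")
    n_sub = int(round(dt / step))
    if abs(n_sub * step - dt) > 1e-12 or n_sub < 1:
        raise ValueError("dt must be an integer multiple of the splitting step")
    r_star = oa_fixed_point(coupling, gamma)
    if not (r_lo < r_star - margin and r_star + margin < r_hi):
        raise ValueError(
            "requested coverage is not attainable: target range must bracket "
            f"the fixed point {r_star:.4f} with the margin excluded"
        )

    rng = np.random.default_rng(seed)
    span_lo = (r_star - margin) - r_lo
    span_hi = r_hi - (r_star + margin)
    n_low = int(round(n_pairs * span_lo / (span_lo + span_hi)))
    n_low = min(max(n_low, 1), n_pairs - 1)
    n_high = n_pairs - n_low

    def jittered_targets(lo: float, hi: float, m: int) -> np.ndarray:
        grid = np.linspace(lo, hi, m)
        half = 0.5 * (hi - lo) / max(m - 1, 1)
        return np.clip(grid + rng.uniform(-half, half, m), lo, hi)

    targets = np.concatenate(
        [
            jittered_targets(r_lo, r_star - margin, n_low),
            jittered_targets(r_star + margin, r_hi, n_high),
        ]
    )
    branch = np.concatenate([np.zeros(n_low, dtype=int), np.ones(n_high, dtype=int)])

    # Fresh ensembles: independently sampled Cauchy frequencies per pair,
    # drawn by a stratified quantile transform (one uniform draw per
    # equal-probability stratum). Stratification suppresses the sampling
    # noise of the empirical frequency distribution without truncating the
    # tails; the phasor integrator handles arbitrarily fast rotators
    # exactly in its drift factor, so no cap is needed here.
    u = (np.arange(n_oscillators) + rng.random((n_pairs, n_oscillators))) / n_oscillators
    omega = gamma * np.tan(np.pi * (u - 0.5))
    theta = np.where(
        branch[:, None] == 0,
        rng.uniform(0.0, 2.0 * np.pi, (n_pairs, n_oscillators)),
        np.pi,
    )
    zr, zi = np.cos(theta), np.sin(theta)
    r0 = np.maximum(np.hypot(zr.mean(axis=1), zi.mean(axis=1)), 1e-4)

    n_delay = int(round(arm_delay / step))
    armed = np.zeros(n_pairs, dtype=bool)
    arm_level = np.zeros(n_pairs)
    deadline = np.zeros(n_pairs, dtype=int)
    remaining = np.full(n_pairs, -1)
    finish_est = np.empty(n_pairs, dtype=int)

    for i in range(n_pairs):
        tgt = targets[i]
        if branch[i] == 1:
            t_fix = oa_time_to_reach(1.0, max(tgt, r_star + 1e-6), coupling, gamma)
            remaining[i] = int(round(t_fix / step)) + n_sub
        elif tgt <= r_switch:
            t_fix = (
                oa_time_to_reach(r0[i], tgt, coupling, gamma) if tgt > r0[i] else 0.0
            )
            remaining[i] = int(round(max(t_fix, 0.0) / step)) + n_sub
        else:
            armed[i] = True
            arm_level[i] = oa_flow(tgt, -arm_delay, coupling, gamma)
            t_est = oa_time_to_reach(
                r0[i], max(arm_level[i], r0[i] * (1 + 1e-9)), coupling, gamma
            )
            deadline[i] = int(np.ceil((1.5 * max(t_est, 0.0) + 2.0) / step))
            remaining[i] = deadline[i] + n_delay + n_sub  # worst case
        finish_est[i] = remaining[i]

    order = np.argsort(finish_est, kind="stable")
    zr, zi, omega = zr[order], zi[order], omega[order]
    branch, targets = branch[order], targets[order]
    armed, arm_level = armed[order], arm_level[order]
    deadline, remaining = deadline[order], remaining[order]

    # Exact free-rotation half-step multipliers.
    half = 0.5 * step * omega
    dr, di = np.cos(half), np.sin(half)

    y0 = np.empty(n_pairs)
    y1 = np.empty(n_pairs)
    phases0 = np.empty((n_pairs, n_oscillators)) if retain_phases else None
    phases1 = np.empty((n_pairs, n_oscillators)) if retain_phases else None
    done = np.zeros(n_pairs, dtype=bool)

    means = np.empty((n_pairs, 2))
    coherence_full = np.hypot(zr.mean(axis=1), zi.mean(axis=1))
    lo = 0
    current = 0
    while lo < n_pairs:
        act = slice(lo, n_pairs)
        coh = coherence_full[act]

        trigger = armed[act] & ((coh >= arm_level[act]) | (current >= deadline[act]))
        if trigger.any():
            idx = lo + np.flatnonzero(trigger)
            armed[idx] = False
            remaining[idx] = n_delay + n_sub

        snap = ~armed[act] & ~done[act] & (remaining[act] == n_sub)
        if snap.any():
            idx = lo + np.flatnonzero(snap)
            y0[idx] = coh[snap]
            if retain_phases:
                phases0[idx] = np.arctan2(zi[idx], zr[idx])

        finish = ~armed[act] & ~done[act] & (remaining[act] == 0)
        if finish.any():
            idx = lo + np.flatnonzero(finish)
            y1[idx] = coh[finish]
            if retain_phases:
                phases1[idx] = np.arctan2(zi[idx], zr[idx])
            done[idx] = True
            while lo < n_pairs and done[lo]:
                lo += 1
        if lo >= n_pairs:
            break

        act = slice(lo, n_pairs)
        _split_step_kernel(
            zr[act], zi[act], dr[act], di[act], coupling, step, means[act]
        )
        coherence_full[act] = np.hypot(means[act, 0], means[act, 1])
        if current % 256 == 255:
            norm = np.hypot(zr[act], zi[act])
            zr[act] /= norm
            zi[act] /= norm
        live = ~armed[act] & ~done[act]
        remaining[act][live] -= 1
        current += 1

    return FlowPairSet(
        y_start=y0,
        y_end=y1,
        dt=dt,
        variable="R",
        branch=branch,
        seed=seed,
        phases_start=phases0,
        phases_end=phases1,
    )


# ---------------------------------------------------------------------------
# RK4 template and the neural sub-network
# ---------------------------------------------------------------------------

def rk4_step(f, y, dt: float):
    """One classical fourth-order Runge-Kutta step with right-hand side f."""
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0


@dataclass
class RK4NetConfig:
    """Hyperparameters of the RK4-templated network.

    Defaults follow the reference training protocol: three tanh hidden
    layers of 24 units, Glorot-uniform kernels with zero biases, Adam at
    learning rate 1e-3 with full-batch updates, a 10% validation split, and
    10,000 epochs (coherence dynamics; the discovered-coordinate dynamics
    default to 50,000 via ``learn_phi_dynamics``).
    """

    hidden: tuple[int, ...] = (24, 24, 24)
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"
    lr_min: float = 1e-5
    epochs: int = 10000
    validation_fraction: float = 0.1
    seed: int = 0
    activation: str = "tanh"
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden):
            raise ValueError("hidden-layer widths must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation fraction must lie in [0, 1)")
        if self.activation != "tanh":
            raise ValueError("only the tanh activation is implemented")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


class _MLP:
    """Minimal feedforward net: tanh hidden layers, linear output,
    Glorot-uniform kernels, zero biases."""

    def __init__(self, widths: list[int], rng: np.random.Generator):
        self.widths = list(widths)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = x
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if li < len(self.weights) - 1:
                a = np.tanh(z)
            else:
                a = z
            if cache is not None:
                cache.append((h, a))
            h = a
        return h

    def backward(self, cache: list, grad_out: np.ndarray):
        """Gradients of a scalar loss wrt parameters and the input, given
        the forward cache and d(loss)/d(output)."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        g = grad_out
        for li in range(len(self.weights) - 1, -1, -1):
            h_in, a_out = cache[li]
            if li < len(self.weights) - 1:
                g = g * (1.0 - a_out**2)  # tanh'
            grads_w[li] = h_in.T @ g
            grads_b[li] = g.sum(axis=0)
            g = g @ self.weights[li].T
        return grads_w, grads_b, g

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases


def _rk4_loss_and_grads(net: _MLP, y: np.ndarray, target: np.ndarray, dt: float):
    """MSE on the RK4-stepped prediction, with gradients obtained by
    backpropagating through all four stages of the shared sub-network."""
    caches = []
    stages_in = []
    y_in = y
    ks = []
    for coeff in (0.0, 0.5 * dt, 0.5 * dt, dt):
        x = y_in if not ks else y_in + coeff * ks[-1]
        stages_in.append(x)
        cache: list = []
        ks.append(net.forward(x, cache))
        caches.append(cache)
    k1, k2, k3, k4 = ks
    y_next = y_in + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0

    n = y.shape[0]
    diff = y_next - target
    loss = float(np.mean(diff**2))
    g_next = 2.0 * diff / (n * diff.shape[1] if diff.ndim > 1 else n)

    stage_w = (dt / 6.0, dt / 3.0, dt / 3.0, dt / 6.0)
    feed = (0.0, 0.5 * dt, 0.5 * dt, dt)  # d(stage input)/d(previous k)
    total_w = [np.zeros_like(w) for w in net.weights]
    total_b = [np.zeros_like(b) for b in net.biases]
    adj = 0.0  # gradient flowing into the *next* stage's k from downstream
    for si in range(3, -1, -1):
        gk = stage_w[si] * g_next + adj
        gw, gb, gx = net.backward(caches[si], gk)
        for acc, g in zip(total_w, gw):
            acc += g
        for acc, g in zip(total_b, gb):
            acc += g
        adj = feed[si] * gx if si > 0 else 0.0
    return loss, total_w, total_b


@dataclass
class RHSModel:
    """Trained approximator of an ODE right-hand side.

    ``rhs`` evaluates the learned f-hat at arbitrary state values; the
    training report (loss curves, config, seed) is retained for audit.
    """

    net: _MLP
    dt: float
    config: RK4NetConfig
    variable: str = "R"
    train_loss: np.ndarray | None = None
    val_loss: np.ndarray | None = None

    def rhs(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        scalar = y.ndim == 0
        out = self.net.forward(np.atleast_1d(y).reshape(-1, 1)).ravel()
        return float(out[0]) if scalar else out

    def __call__(self, y):
        return self.rhs(y)

    def to_json(self) -> str:
        """Language-portable parameter dump (layer shapes + flat weights)."""
        payload = {
            "variable": self.variable,
            "dt": self.dt,
            "widths": self.net.widths,
            "weights": [w.ravel().tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "RHSModel":
        payload = json.loads(text)
        net = _MLP(payload["widths"], np.random.default_rng(0))
        net.weights = [
            np.asarray(w, dtype=float).reshape(i, o)
            for w, i, o in zip(
                payload["weights"], payload["widths"][:-1], payload["widths"][1:]
            )
        ]
        net.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        return cls(
            net=net,
            dt=payload["dt"],
            config=RK4NetConfig(),
            variable=payload["variable"],
        )


def train_rhs_net(pairs: FlowPairSet, config: RK4NetConfig | None = None) -> RHSModel:
    """Train the RK4-templated network on a flow-pair set.

    Full-batch Adam on the mean squared error of the RK4-stepped
    prediction against y(t + dt), with a seeded 90/10 train/validation
    shuffle and no early stopping (a fixed epoch count).
    """
    cfg = config or RK4NetConfig()
    n = len(pairs)
    if n < 50:
        raise ValueError("need at least 50 flow pairs to train")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = int(round(cfg.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train = pairs.y_start[train_idx].reshape(-1, 1)
    t_train = pairs.y_end[train_idx].reshape(-1, 1)
    x_val = pairs.y_start[val_idx].reshape(-1, 1)
    t_val = pairs.y_end[val_idx].reshape(-1, 1)

    net = _MLP([1, *cfg.hidden, 1], rng)
    params = net.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    train_curve = np.empty(cfg.epochs)
    val_curve = np.empty(cfg.epochs) if n_val else None

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            lr = cfg.lr_min + 0.5 * (cfg.learning_rate - cfg.lr_min) * (
                1.0 + np.cos(np.pi * frac)
            )
        else:
            lr = cfg.learning_rate
        loss, gw, gb = _rk4_loss_and_grads(net, x_train, t_train, pairs.dt)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: non-finite loss "
                f"(lr={cfg.learning_rate}, dt={pairs.dt})"
            )
        train_curve[epoch] = loss
        grads = gw + gb
        bc1 = 1.0 - cfg.beta1 ** (epoch + 1)
        bc2 = 1.0 - cfg.beta2 ** (epoch + 1)
        for p, g, mi, vi in zip(params, grads, m, v):
            mi *= cfg.beta1
            mi += (1.0 - cfg.beta1) * g
            vi *= cfg.beta2
            vi += (1.0 - cfg.beta2) * g**2
            p -= lr * (mi / bc1) / (np.sqrt(vi / bc2) + cfg.adam_eps)
        if n_val:
            pred = rk4_step(lambda z: net.forward(z), x_val, pairs.dt)
            val_curve[epoch] = float(np.mean((pred - t_val) ** 2))

    return RHSModel(
        net=net,
        dt=pairs.dt,
        config=cfg,
        variable=pairs.variable,
        train_loss=train_curve,
        val_loss=val_curve,
    )


def integrate_learned(
    model, y0: float, t_grid: np.ndarray, max_step: float | None = None
) -> np.ndarray:
    """Fixed-step RK4 rollout of a learned (or analytic) right-hand side.

    ``model`` may be an RHSModel or any callable f(y). Reports the state at
    every point of ``t_grid``; each interval is subdivided so no internal
    step exceeds ``max_step`` (default: the model's training dt, or the
    grid spacing for plain callables).
    """
    f = model.rhs if isinstance(model, RHSModel) else model
    t_grid = np.asarray(t_grid, dtype=float)
    if max_step is None:
        max_step = model.dt if isinstance(model, RHSModel) else float(np.diff(t_grid).min())
    out = np.empty_like(t_grid)
    y = float(y0)
    out[0] = y
    escaped = False
    for i in range(1, len(t_grid)):
        span = t_grid[i] - t_grid[i - 1]
        n_sub = max(1, int(np.ceil(span / max_step - 1e-12)))
        h = span / n_sub
        for _ in range(n_sub):
            y = float(rk4_step(lambda z: np.asarray(f(z)), y, h))
        out[i] = y
        if isinstance(model, RHSModel) and model.variable == "R" and not escaped:
            if y < -0.1 or y > 1.1:
                escaped = True
                warnings.warn(
                    f"learned trajectory left the coherence domain at t={t_grid[i]:g}",
                    stacklevel=2,
                )
    return out


# ---------------------------------------------------------------------------
# Baseline: forward Euler + geometric harmonics
# ---------------------------------------------------------------------------

@dataclass
class EulerGHBaseline:
    """Finite-difference derivative estimates smoothed by geometric
    harmonics; callable on arbitrary states in the sampled domain."""

    raw_states: np.ndarray
    raw_estimates: np.ndarray
    gh_model: GeometricHarmonicsModel

    def __call__(self, y) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y, dtype=float))
        return gh_extend(self.gh_model, y.reshape(-1, 1)).ravel()


def baseline_euler_gh(
    pairs: FlowPairSet, n_gh: int = 10, epsilon: float | None = None
) -> EulerGHBaseline:
    """Forward-Euler slope estimates ``(y(t+dt) - y(t)) / dt`` interpolated
    with ``n_gh`` geometric harmonics."""
    slopes = (pairs.y_end - pairs.y_start) / pairs.dt
    model = gh_fit(
        pairs.y_start.reshape(-1, 1), slopes, epsilon=epsilon, n_harmonics=n_gh
    )
    return EulerGHBaseline(
        raw_states=pairs.y_start.copy(), raw_estimates=slopes, gh_model=model
    )


# ---------------------------------------------------------------------------
# Dynamics of the discovered coordinate
# ---------------------------------------------------------------------------

class PipelineAssumptionError(RuntimeError):
    """The one-significant-eigenfunction assumption failed."""


@dataclass
class PhiDynamicsResult:
    """Learned dynamics of the discovered coarse coordinate phi_1, with the
    joint embedding and its correspondence diagnostics against R."""

    model: RHSModel
    embedding: object
    phi_pairs: FlowPairSet
    diagnostics: dict = field(default_factory=dict)


def learn_phi_dynamics(
    pairs: FlowPairSet,
    kernel_config: KernelConfig | None = None,
    net_config: RK4NetConfig | None = None,
    n_bins: int = 200,
    threshold: float = 0.5,
) -> PhiDynamicsResult:
    """Re-express the retained flow snapshots in the discovered coordinate
    and learn its evolution law.

    All snapshots (both ends of every pair) are binned into rotating-frame
    phase densities and embedded in ONE joint diffusion map, so that
    phi_1(t) and phi_1(t + dt) live on a common scale. The extracted
    (phi_1(t), phi_1(t + dt)) pairs then train the RK4-templated network,
    by default for 50,000 epochs (the nonuniform sampling in phi makes
    this a harder regression than the coherence itself).
    """
    if pairs.phases_start is None or pairs.phases_end is None:
        raise ValueError("flow pairs must retain phase snapshots (retain_phases=True)")
    n = len(pairs)
    snapshots = np.vstack([pairs.phases_start, pairs.phases_end])
    # Per-snapshot rotating frame: remove the mean phase before binning so
    # the density depends on clustering only.
    z = np.exp(1j * snapshots).mean(axis=1)
    rotated = wrap_phases(snapshots - np.angle(z)[:, None])
    densities = densities_from_snapshots(rotated, n_bins)

    embedding = dmap_with_llr(densities, kernel_config or KernelConfig(), threshold)
    if embedding.significant != [1]:
        raise PipelineAssumptionError(
            "expected exactly one significant eigenfunction, found "
            f"{embedding.significant} (residuals {np.round(embedding.residuals, 3)})"
        )
    r_all = np.concatenate([pairs.y_start, pairs.y_end])
    phi = embedding.phi(1)
    if float((r_all - r_all.mean()) @ phi) < 0:
        phi = -phi
        embedding.eigenfunctions[:, 1] = phi

    from scipy.stats import spearmanr

    rho = float(spearmanr(phi, r_all).statistic)
    phi_pairs = FlowPairSet(
        y_start=phi[:n],
        y_end=phi[n:],
        dt=pairs.dt,
        variable="phi1",
        branch=None if pairs.branch is None else pairs.branch.copy(),
        seed=pairs.seed,
    )
    cfg = net_config or RK4NetConfig(epochs=50000)
    model = train_rhs_net(phi_pairs, cfg)
    return PhiDynamicsResult(
        model=model,
        embedding=embedding,
        phi_pairs=phi_pairs,
        diagnostics={"spearman_phi_vs_R": rho},
    )
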