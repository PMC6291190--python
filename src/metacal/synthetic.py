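"""Desk-scale synthetic dynamics standing in for molecular simulations.

Overdamped (Brownian) Langevin dynamics on analytic multi-well potentials,
integrated with Euler-Maruyama, under three protocols: plain, ABMD-style
ratchet bias towards a target, and on-the-fly well-tempered metadynamics.
Everything is seeded and bit-reproducible.  Units are reduced: kB = 1, so
energies are in units of kT at temperature 1, and time is in units of the
diffusive time of the potential.

The four-well 2-D potential is built as the negative log of a Gaussian
mixture, so at kT = 1 its equilibrium basin populations equal the mixture
weights (up to small overlap corrections) and everything downstream - basin
populations, MFPT orderings - has an analytic or quadrature-checkable ground
truth.  The module also provides a grid-count reference MSM, a curved
contact-map trajectory generator for path-selection tests, and feature fields
with planted redundant/synergistic/noise structure for the co-information
scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    StabilityError,
)
from .metad_reweight import HillsLog

__all__ = [
    "SimConfig",
    "HarmonicPotential",
    "DoubleWell1D",
    "FourWell2D",
    "brownian_dynamics",
    "abmd_run",
    "metad_run",
    "ReferenceMSM",
    "reference_msm",
    "planted_information_field",
    "curved_contact_trajectory",
]

_GUARD = 50.0  # integrator divergence guard, in CV units


@dataclass(frozen=True)
class SimConfig:
    """Integrator settings: Euler-Maruyama overdamped Langevin."""

    dt: float = 0.005
    n_steps: int = 100_000
    kT: float = 1.0
    friction: float = 1.0
    seed: int = 0
    stride: int = 1

    def __post_init__(self):
        if not self.dt > 0:
            raise InvalidParameterError("dt must be positive")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.kT < 0:
            raise InvalidParameterError("kT must be >= 0")
        if not self.friction > 0:
            raise InvalidParameterError("friction must be positive")
        if self.stride < 1:
            raise InvalidParameterError("stride must be >= 1")


@dataclass(frozen=True)
class HarmonicPotential:
    """U = k/2 (x - x0)^2; Boltzmann variance kT / k."""

    k: float = 1.0
    x0: float = 0.0
    dim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * (x - self.x0) ** 2

    def grad(self, x: float) -> float:
        return self.k * (x - self.x0)

    @property
    def minima(self):
        return np.array([self.x0])


@dataclass(frozen=True)
class DoubleWell1D:
    """U = barrier * (x^2 - 1)^2: minima at +-1, barrier height at x = 0."""

    barrier: float = 8.0
    dim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.barrier * (x * x - 1.0) ** 2

    def grad(self, x: float) -> float:
        return 4.0 * self.barrier * x * (x * x - 1.0)

    @property
    def minima(self):
        return np.array([-1.0, 1.0])


@dataclass(frozen=True)
class FourWell2D:
    """Negative-log Gaussian-mixture potential with four unequal basins.

    U(x) = -ln sum_m w_m N(x; mu_m, sigma^2 I).  At kT = 1 the Boltzmann
    density is exactly the mixture, so basin populations equal the weights up
    to overlap, computable by quadrature.  Default minima sit at (+-1, +-1).
    """

    weights: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    sigma: float = 0.30
    minima_xy: tuple[tuple[float, float], ...] = (
        (1.0, 1.0), (-1.0, 1.0), (-1.0, -1.0), (1.0, -1.0),
    )
    dim: int = 2

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise InvalidParameterError("mixture weights must be positive")
        object.__setattr__(self, "weights", tuple(w / w.sum()))

    @property
    def minima(self):
        return np.asarray(self.minima_xy, dtype=float)

    def _mix(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu = self.minima
        w = np.asarray(self.weights)
        d2 = ((X[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
        return (w * np.exp(-d2 / (2.0 * self.sigma**2))).sum(axis=1)

    def energy(self, X):
        X = np.asarray(X, dtype=float)
        scalar = X.ndim == 1
        m = self._mix(X)
        U = -np.log(np.clip(m, 1e-300, None))
        return float(U[0]) if scalar else U

    def grad_xy(self, x: float, y: float) -> tuple[float, float]:
        s2 = self.sigma * self.sigma
        num_x = num_y = den = 0.0
        for wm, (mx, my) in zip(self.weights, self.minima_xy):
            dx, dy = x - mx, y - my
            g = wm * math.exp(-(dx * dx + dy * dy) / (2.0 * s2))
            den += g
            num_x += g * dx
            num_y += g * dy
        if den < 1e-300:
            den = 1e-300
        return num_x / (s2 * den), num_y / (s2 * den)


def _start_point(potential):
    m = np.atleast_2d(potential.minima)
    return np.asarray(m[0], dtype=float).ravel()


def _check_guard(x):
    if abs(x) > _GUARD:
        raise StabilityError(
            f"coordinate diverged beyond |x| = {_GUARD}; reduce dt"
        )


def brownian_dynamics(potential, config: SimConfig, x0=None) -> pd.DataFrame:
    """Unbiased overdamped Langevin trajectory.

    Returns a COLVAR-like DataFrame with columns ``time``, the CV(s) (``x``
    or ``x, y``) and a zero ``bias`` column; frames recorded every
    ``config.stride`` steps, starting with the initial point.
    """
    rng = np.random.default_rng(config.seed)
    dt, kT, fr = config.dt, config.kT, config.friction
    amp = math.sqrt(2.0 * kT * dt / fr)
    start = _start_point(potential) if x0 is None else np.atleast_1d(
        np.asarray(x0, dtype=float)
    )
    n_rec = config.n_steps // config.stride + 1
    if potential.dim == 1:
        noise = rng.standard_normal(config.n_steps)
        x = float(start[0])
        xs = np.empty(n_rec)
        xs[0] = x
        j = 1
        grad = potential.grad
        for i in range(config.n_steps):
            x += -grad(x) * dt / fr + amp * noise[i]
            if (i + 1) % config.stride == 0:
                _check_guard(x)
                xs[j] = x
                j += 1
        t = np.arange(n_rec) * dt * config.stride
        return pd.DataFrame({"time": t, "x": xs[:j], "bias": 0.0})
    # 2-D
    noise = rng.standard_normal((config.n_steps, 2))
    x, y = float(start[0]), float(start[1])
    xs = np.empty(n_rec)
    ys = np.empty(n_rec)
    xs[0], ys[0] = x, y
    j = 1
    grad = potential.grad_xy
    for i in range(config.n_steps):
        gx, gy = grad(x, y)
        x += -gx * dt / fr + amp * noise[i, 0]
        y += -gy * dt / fr + amp * noise[i, 1]
        if (i + 1) % config.stride == 0:
            _check_guard(x)
            _check_guard(y)
            xs[j], ys[j] = x, y
            j += 1
    t = np.arange(n_rec) * dt * config.stride
    return pd.DataFrame({"time": t, "x": xs[:j], "y": ys[:j], "bias": 0.0})


def abmd_run(potential, target_cv: float, force_constant, config: SimConfig,
             x0=None) -> pd.DataFrame:
    """Ratchet-biased (ABMD-style) 1-D run towards ``target_cv``.

    The elastic bias ``1/2 k (d - d_min)^2`` on the distance
    ``d = |x - target|`` acts only when d exceeds its running minimum
    ``d_min``; otherwise the system evolves freely, so progress towards the
    target is never undone but never forced.  ``force_constant`` may be a
    scalar or a schedule of values applied over equal step blocks
    (stepwise-increasing k, as in staged ratchet protocols).
    """
    if potential.dim != 1:
        raise InvalidParameterError("abmd_run drives a single CV")
    ks = np.atleast_1d(np.asarray(force_constant, dtype=float))
    if np.any(ks < 0):
        raise InvalidParameterError("force constants must be >= 0")
    block = max(1, math.ceil(config.n_steps / ks.size))
    rng = np.random.default_rng(config.seed)
    dt, kT, fr = config.dt, config.kT, config.friction
    amp = math.sqrt(2.0 * kT * dt / fr)
    start = _start_point(potential) if x0 is None else np.atleast_1d(
        np.asarray(x0, dtype=float)
    )
    x = float(start[0])
    d_min = abs(x - target_cv)
    noise = rng.standard_normal(config.n_steps)
    n_rec = config.n_steps // config.stride + 1
    xs = np.empty(n_rec)
    bs = np.empty(n_rec)
    dm = np.empty(n_rec)
    xs[0], bs[0], dm[0] = x, 0.0, d_min
    j = 1
    grad = potential.grad
    for i in range(config.n_steps):
        k = ks[min(i // block, ks.size - 1)]
        d = abs(x - target_cv)
        if d < d_min:
            d_min = d
        excess = d - d_min
        if excess > 0 and d > 0:
            fbias = k * excess * (1.0 if x > target_cv else -1.0)
            ebias = 0.5 * k * excess * excess
        else:
            fbias = 0.0
            ebias = 0.0
        x += -(grad(x) + fbias) * dt / fr + amp * noise[i]
        if (i + 1) % config.stride == 0:
            _check_guard(x)
            xs[j], bs[j], dm[j] = x, ebias, d_min
            j += 1
    t = np.arange(n_rec) * dt * config.stride
    return pd.DataFrame({"time": t, "x": xs[:j], "bias": bs[:j], "d_min": dm[:j]})


def metad_run(potential, config: SimConfig, height: float = 1.2,
              sigma: float = 0.15, deposit_stride: int = 500,
              bias_factor: float = 12.0, x0=None
              ) -> tuple[pd.DataFrame, HillsLog]:
    """Well-tempered metadynamics on a 1-D potential, hills on the coordinate.

    Every ``deposit_stride`` steps a Gaussian of width ``sigma`` is added at
    the current position with tempered height
    ``w * exp(-V(x, t) / (kB dT))``, dT = (gamma - 1) T.  Returns the
    trajectory (with the instantaneous bias at each recorded frame) and a
    :class:`HillsLog` consumable by the reweighting module (kB = 1 units).
    """
    if potential.dim != 1:
        raise InvalidParameterError("metad_run biases a single CV")
    if not bias_factor > 1:
        raise InvalidParameterError("bias factor gamma must exceed 1")
    rng = np.random.default_rng(config.seed)
    dt, kT, fr = config.dt, config.kT, config.friction
    delta_T = (bias_factor - 1.0) * kT  # kB = 1
    amp = math.sqrt(2.0 * kT * dt / fr)
    start = _start_point(potential) if x0 is None else np.atleast_1d(
        np.asarray(x0, dtype=float)
    )
    x = float(start[0])
    centers: list[float] = []
    heights: list[float] = []
    times: list[float] = []
    c_arr = np.empty(0)
    h_arr = np.empty(0)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    noise = rng.standard_normal(config.n_steps)
    n_rec = config.n_steps // config.stride + 1
    xs = np.empty(n_rec)
    vs = np.empty(n_rec)
    xs[0], vs[0] = x, 0.0
    j = 1
    grad = potential.grad

    def bias_and_force(xx):
        if c_arr.size == 0:
            return 0.0, 0.0
        d = xx - c_arr
        g = h_arr * np.exp(-d * d * inv2s2)
        V = float(g.sum())
        F = float((g * d).sum()) * 2.0 * inv2s2  # -dV/dx
        return V, F

    for i in range(config.n_steps):
        V, Fb = bias_and_force(x)
        x += (-grad(x) + Fb) * dt / fr + amp * noise[i]
        if (i + 1) % deposit_stride == 0:
            Vcur, _ = bias_and_force(x)
            h = height * math.exp(-Vcur / delta_T)
            centers.append(x)
            heights.append(h)
            times.append((i + 1) * dt)
            c_arr = np.asarray(centers)
            h_arr = np.asarray(heights)
        if (i + 1) % config.stride == 0:
            _check_guard(x)
            xs[j] = x
            vs[j], _ = bias_and_force(x)
            j += 1
    t = np.arange(n_rec) * dt * config.stride
    traj = pd.DataFrame({"time": t, "x": xs[:j], "bias": vs[:j]})
    hills = HillsLog(
        times=np.asarray(times), centers=np.asarray(centers)[:, None],
        sigmas=np.full((len(times), 1), sigma), heights=np.asarray(heights),
        bias_factor=bias_factor, temperature=kT,
        period=deposit_stride * dt, cv_names=("x",), kB=1.0,
    )
    return traj, hills


@dataclass
class ReferenceMSM:
    """Grid-count Markov state model of an unbiased trajectory."""

    pi: np.ndarray
    P: np.ndarray
    kappa: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    lag_time: float


def reference_msm(values, lag: int, edges, dt: float = 1.0) -> ReferenceMSM:
    """Count-matrix MSM on a regular grid of states at integer lag.

    States never visited are dropped; counts are row-normalized into P, pi is
    the total occupancy, and kappa = (P - I) / lag_time is the short-lag
    generator estimate.  Intended as the ground-truth reference against which
    MaxCal models are compared.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if lag < 1:
        raise InvalidParameterError("lag must be >= 1")
    if X.shape[0] <= lag:
        raise InsufficientDataError("trajectory not longer than the lag")
    edges = [np.asarray(e, dtype=float) for e in edges]
    if len(edges) != X.shape[1]:
        raise InvalidParameterError("one edge array per CV dimension required")
    nb = np.array([e.size - 1 for e in edges])
    idx = np.empty((X.shape[0], X.shape[1]), dtype=np.int64)
    for d, e in enumerate(edges):
        idx[:, d] = np.clip(np.searchsorted(e, X[:, d], side="right") - 1,
                            0, nb[d] - 1)
    strides = np.cumprod(np.concatenate(([1], nb[:-1])))
    flat = idx @ strides
    occupied, labels = np.unique(flat, return_inverse=True)
    n = occupied.size
    C = np.zeros((n, n))
    np.add.at(C, (labels[:-lag], labels[lag:]), 1.0)
    rows = C.sum(axis=1)
    keep = rows > 0
    if not keep.all():
        C = C[np.ix_(keep, keep)]
        remap = -np.ones(n, dtype=int)
        remap[keep] = np.arange(keep.sum())
        labels = remap[labels]
        occupied = occupied[keep]
        rows = C.sum(axis=1)
        n = keep.sum()
    P = C / rows[:, None]
    counts = np.bincount(labels[labels >= 0], minlength=n).astype(float)
    pi = counts / counts.sum()
    lag_time = lag * dt
    kappa = (P - np.eye(n)) / lag_time
    # grid-cell centres of the occupied states
    centers = np.empty((n, X.shape[1]))
    rem = occupied.copy()
    for d in range(X.shape[1]):
        cell = rem % nb[d]
        rem //= nb[d]
        mid = 0.5 * (edges[d][1:] + edges[d][:-1])
        centers[:, d] = mid[cell]
    return ReferenceMSM(pi=pi, P=P, kappa=kappa, centers=centers,
                        labels=labels, lag_time=lag_time)


def planted_information_field(latent, n_redundant: int = 3,
                              n_synergistic: int = 2, n_noise: int = 3,
                              loadings=(1.0, 0.8, 0.6), noise_sigma: float = 0.3,
                              seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Per-residue coordinate columns with controlled information structure.

    From a standardized latent activation series, emits pocket principal
    components and activation CVs (both latent-driven plus noise) and three
    residue classes of (x, y, z) columns: redundant residues follow the
    latent, synergistic residues mix the latent sign with an independent
    binary through a parity construction, and noise residues are independent
    Gaussians.  Returns the feature table and a {residue name: role} map.
    """
    if min(n_redundant, n_synergistic, n_noise) < 0:
        raise InvalidParameterError("residue counts must be >= 0")
    z = np.asarray(latent, dtype=float).ravel()
    z = (z - z.mean()) / (z.std() or 1.0)
    n = z.size
    rng = np.random.default_rng(seed)
    cols = {
        "PC1": z + noise_sigma * rng.standard_normal(n),
        "PC2": rng.standard_normal(n),
        "act1": z + noise_sigma * rng.standard_normal(n),
        "act2": 0.8 * z + noise_sigma * rng.standard_normal(n),
    }
    labels = {}
    loadings = np.resize(np.asarray(loadings, dtype=float), max(n_redundant, 1))
    r = 0
    for i in range(n_redundant):
        name = f"res{r:03d}"
        for ax in "xyz":
            cols[f"{name}_{ax}"] = (
                loadings[i] * z + noise_sigma * rng.standard_normal(n)
            )
        labels[name] = "redundant"
        r += 1
    for _ in range(n_synergistic):
        name = f"res{r:03d}"
        aux = rng.choice([-1.0, 1.0], size=n)
        parity = np.sign(z) * aux
        cols[f"{name}_x"] = parity + noise_sigma * rng.standard_normal(n)
        cols[f"{name}_y"] = aux + noise_sigma * rng.standard_normal(n)
        cols[f"{name}_z"] = noise_sigma * rng.standard_normal(n)
        labels[name] = "synergistic"
        r += 1
    for _ in range(n_noise):
        name = f"res{r:03d}"
        for ax in "xyz":
            cols[f"{name}_{ax}"] = rng.standard_normal(n)
        labels[name] = "noise"
        r += 1
    return pd.DataFrame(cols), labels


def curved_contact_trajectory(n_frames: int = 200, n_contacts: int = 8,
                              endpoint_separation: float = 2.0,
                              curvature: float = 0.25, noise: float = 0.04,
                              seed: int = 0) -> np.ndarray:
    """Noisy frames along a curved transition in contact-map space.

    A scalar progress variable u in [0, 1], sampled from a three-component
    Beta mixture (two endpoint basins and a midpoint shoulder, mimicking
    metastability along an activation transition), is mapped onto a planar
    arc embedded in the n_contacts-dimensional unit cube; the two extreme
    frames are ``endpoint_separation`` apart in Euclidean contact-map norm.
    Per-contact Gaussian noise of width ``noise`` is added and values are
    clipped to [0, 1].
    """
    if n_frames < 4:
        raise InsufficientDataError("need at least 4 frames")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n_frames, p=[0.35, 0.35, 0.30])
    u = np.where(
        comp == 0, rng.beta(1.5, 8.0, n_frames),
        np.where(comp == 1, rng.beta(8.0, 1.5, n_frames),
                 rng.beta(8.0, 8.0, n_frames)),
    )
    u[np.argmin(u)] = 0.0
    u[np.argmax(u)] = 1.0
    # orthonormal plane in contact space
    e1 = np.ones(n_contacts)
    e1[1::2] = -1.0
    e1 /= np.linalg.norm(e1)
    e2 = np.zeros(n_contacts)
    e2[: n_contacts // 2] = 1.0
    e2 -= (e2 @ e1) * e1
    e2 /= np.linalg.norm(e2)
    base = 0.5
    X = (
        base
        + endpoint_separation * np.outer(u - 0.5, e1)
        + endpoint_separation * curvature * np.outer(np.sin(np.pi * u), e2)
    )
    X += noise * rng.standard_normal(X.shape)
    return np.clip(X, 0.0, 1.0)
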