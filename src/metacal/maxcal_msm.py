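"""Maximum-Caliber Markov state models and first-passage analysis.

Given a stationary distribution pi over microstates and a small set of
dynamical constraints - the mean jump rate <N> and path-ensemble averages of
CV displacements <R_q> = sum_ij pi_i p_ij R_ij(q) - the Maximum Caliber
principle (maximum path entropy) yields transition weights of the form

    W_ij = e^{-a} exp(-sum_q b_q R_ij(q)),

which, with detailed balance imposed, gives the rate matrix

    kappa_ij = mu * sqrt(pi_j / pi_i) * exp(-sum_q b_q R_ij(q)),   i != j,

with diagonal set by zero row sums and p = exp(lag * kappa).  The multipliers
(mu, b_q) are fixed so the model reproduces the target jump rate N0 and the
target displacement averages R0(q) * lag.  Because the mean jump rate is
linear in mu at fixed b, mu is eliminated in closed form and only the b_q
require root finding.  Mean first passage times follow from the first-step
linear system on kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.cluster import KMeans

from .errors import (
    AmbiguousRegionError,
    ConvergenceError,
    DimensionError,
    EmptyRegionError,
    InfeasibleConstraintError,
    InsufficientDataError,
    InvalidParameterError,
    UnreachableTargetError,
)

__all__ = [
    "MicrostateModel",
    "ConstraintSpec",
    "MaxCalModel",
    "RegionSpec",
    "cluster_microstates",
    "estimate_dynamical_constraints",
    "maxcal_solve",
    "mean_jump_rate",
    "mfpt",
    "mfpt_from_transition_matrix",
    "assign_regions",
    "region_populations",
    "region_mfpt_matrix",
]


@dataclass
class MicrostateModel:
    """k-means microstates with occupation statistics of a weighted sample."""

    centers: np.ndarray
    pi: np.ndarray
    q_means: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        self.q_means = np.atleast_2d(np.asarray(self.q_means, dtype=float))
        if np.any(self.pi <= 0):
            raise InvalidParameterError("stationary probabilities must be > 0")
        if not np.isclose(self.pi.sum(), 1.0):
            raise InvalidParameterError("stationary probabilities must sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.size


def cluster_microstates(samples, weights=None, n_states: int = 20,
                        seed: int = 0) -> MicrostateModel:
    """Weighted k-means microstates of CV samples.

    pi_i is the normalized total member weight of state i and q_means its
    weighted member mean in CV space.  Seeded k-means++ initialization makes
    the result reproducible.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n_states < 1:
        raise InvalidParameterError("n_states must be >= 1")
    if n < n_states:
        raise InvalidParameterError(
            f"n_states ({n_states}) exceeds number of samples ({n})"
        )
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    km = KMeans(n_clusters=n_states, init="k-means++", n_init=10,
                random_state=seed)
    labels = km.fit_predict(X, sample_weight=w)
    pi = np.zeros(n_states)
    qm = np.zeros((n_states, X.shape[1]))
    for i in range(n_states):
        m = labels == i
        wi = w[m].sum()
        pi[i] = wi
        qm[i] = (w[m, None] * X[m]).sum(axis=0) / wi if wi > 0 else km.cluster_centers_[i]
    keep = pi > 0
    if not keep.all():
        # drop empty states so the stationary distribution stays strictly positive
        remap = -np.ones(n_states, dtype=int)
        remap[keep] = np.arange(keep.sum())
        labels = remap[labels]
        pi, qm = pi[keep], qm[keep]
        centers = km.cluster_centers_[keep]
    else:
        centers = km.cluster_centers_
    return MicrostateModel(centers=centers, pi=pi / pi.sum(), q_means=qm,
                           labels=labels)


@dataclass(frozen=True)
class ConstraintSpec:
    """One dynamical constraint: pairwise CV displacements and their target.

    ``R[i, j] = |qbar_i - qbar_j|`` (symmetric, zero diagonal) and ``target``
    is the wanted path-ensemble average displacement per unit time, R0(q).
    """

    name: str
    R: np.ndarray
    target: float

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise DimensionError("R must be a square matrix")
        if not np.allclose(R, R.T) or np.any(np.diag(R) != 0) or np.any(R < 0):
            raise InvalidParameterError(
                "R must be symmetric, non-negative, with zero diagonal"
            )
        object.__setattr__(self, "R", R)

    @classmethod
    def from_state_means(cls, name: str, q_means, target: float) -> "ConstraintSpec":
        q = np.asarray(q_means, dtype=float).ravel()
        return cls(name=name, R=np.abs(q[:, None] - q[None, :]), target=target)


@dataclass
class MaxCalModel:
    """Solved Maximum-Caliber kinetic model."""

    pi: np.ndarray
    kappa: np.ndarray
    lag: float
    mu: float
    b: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def transition_matrix(self) -> np.ndarray:
        return _expm_db(self.kappa, self.pi, self.lag)


def _rate_matrix(pi, mu, b_vec, R_list) -> np.ndarray:
    """kappa_ij = mu sqrt(pi_j/pi_i) exp(-sum_q b_q R_ij), zero row sums."""
    n = pi.size
    expo = np.zeros((n, n))
    for bq, R in zip(b_vec, R_list):
        expo -= bq * R
    K = mu * np.sqrt(pi[None, :] / pi[:, None]) * np.exp(expo)
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def _expm_db(kappa, pi, lag) -> np.ndarray:
    """exp(lag*kappa) via the symmetrized generator (real spectrum under DB)."""
    s = np.sqrt(pi)
    S = (s[:, None] * kappa) / s[None, :]
    S = 0.5 * (S + S.T)  # symmetric up to round-off under detailed balance
    evals, U = np.linalg.eigh(S)
    E = U @ (np.exp(lag * evals)[:, None] * U.T)
    P = (E / s[:, None]) * s[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def mean_jump_rate(model_or_kappa, pi=None) -> float:
    """<N> = sum_i pi_i sum_{j != i} kappa_ij, jumps per unit time."""
    if isinstance(model_or_kappa, MaxCalModel):
        K, pi = model_or_kappa.kappa, model_or_kappa.pi
    else:
        K = np.asarray(model_or_kappa, dtype=float)
        pi = np.asarray(pi, dtype=float)
    off = K - np.diag(np.diag(K))
    return float(pi @ off.sum(axis=1))


def _constraint_averages(pi, mu, b_vec, R_list, lag):
    K = _rate_matrix(pi, mu, b_vec, R_list)
    P = _expm_db(K, pi, lag)
    flux = pi[:, None] * P
    return np.array([float((flux * R).sum()) for R in R_list]), K, P


def maxcal_solve(pi, constraints=(), N0: float = 1.0, lag: float = 1.0,
                 tol: float = 1e-10, max_iter: int = 500) -> MaxCalModel:
    """Solve for the MaxCal rate matrix matching N0 and the R0(q) targets.

    The mean jump rate is linear in mu for fixed b, so mu = N0 / A(b) with
    A(b) = sum_{i != j} sqrt(pi_i pi_j) e^{-sum_q b_q R_ij}; the remaining
    root problem in the b_q (one per constraint) is solved with a hybrid
    Powell method.  Each constraint average must match R0(q) * lag to 1e-8
    relative; failure raises :class:`ConvergenceError` carrying the residuals,
    and targets outside the achievable range raise
    :class:`InfeasibleConstraintError`.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
        raise InvalidParameterError("pi must be strictly positive and sum to 1")
    if not N0 > 0:
        raise InvalidParameterError("mean jump rate N0 must be positive")
    if not lag > 0:
        raise InvalidParameterError("lag must be positive")
    constraints = list(constraints)
    R_list = [c.R for c in constraints]
    targets = np.array([c.target * lag for c in constraints])
    sqrt_outer = np.sqrt(np.outer(pi, pi))
    off_mask = ~np.eye(pi.size, dtype=bool)

    def mu_of(b_vec):
        expo = np.zeros_like(sqrt_outer)
        for bq, R in zip(b_vec, R_list):
            expo -= bq * R
        A = float((sqrt_outer * np.exp(expo))[off_mask].sum())
        return N0 / A

    if not constraints:
        mu = mu_of([])
        K = _rate_matrix(pi, mu, [], [])
        return MaxCalModel(pi=pi, kappa=K, lag=lag, mu=mu,
                           residuals={"N": 0.0})

    if np.any(targets <= 0):
        raise InfeasibleConstraintError(
            "constraint targets must be positive (zero/negative displacement "
            "averages cannot be matched by the exponential family)"
        )
    scale = np.where(targets > 0, targets, 1.0)

    def residual(b_vec):
        avgs, _, _ = _constraint_averages(pi, mu_of(b_vec), b_vec, R_list, lag)
        return (avgs - targets) / scale

    sol = optimize.root(residual, x0=np.zeros(len(constraints)), method="hybr",
                        options={"xtol": 1e-13, "maxfev": max_iter * (len(constraints) + 1)})
    res = residual(sol.x)
    if np.max(np.abs(res)) > 1e-8:
        # classify: is any target outside the achievable monotone range?
        Rmax = max(float(R.max()) for R in R_list)
        bprobe = 50.0 / max(Rmax, 1e-12)
        for sgn in (+1.0, -1.0):
            probe = residual(sgn * bprobe * np.ones(len(constraints)))
            if np.all(sgn * probe >= -1e-8):
                raise InfeasibleConstraintError(
                    f"constraint targets {targets.tolist()} outside achievable "
                    f"range; residuals at probe: {probe.tolist()}"
                )
        raise ConvergenceError(
            "MaxCal multiplier solve did not reach tolerance",
            residuals={c.name: float(r) for c, r in zip(constraints, res)},
        )
    mu = mu_of(sol.x)
    avgs, K, P = _constraint_averages(pi, mu, sol.x, R_list, lag)
    return MaxCalModel(
        pi=pi, kappa=K, lag=lag, mu=mu,
        b={c.name: float(bq) for c, bq in zip(constraints, sol.x)},
        residuals={c.name: float(r) for c, r in zip(constraints, res)},
    )


def estimate_dynamical_constraints(labels, q_means, lag_steps: int, dt: float):
    """Empirical (N0, R0 per CV) from a microstate label sequence.

    N0 is the fraction of (t, t + lag) pairs whose state changed, per unit
    time; R0(q) is the mean absolute difference of state-mean CV values over
    the same pairs, per unit time - the same path-ensemble functionals the
    MaxCal model constrains.
    """
    lab = np.asarray(labels)
    if lab.size <= lag_steps:
        raise InsufficientDataError("label sequence not longer than the lag")
    qm = np.atleast_2d(np.asarray(q_means, dtype=float))
    a, b = lab[:-lag_steps], lab[lag_steps:]
    lag_time = lag_steps * dt
    N0 = float(np.mean(a != b)) / lag_time
    R0 = [float(np.mean(np.abs(qm[b, q] - qm[a, q]))) / lag_time
          for q in range(qm.shape[1])]
    return N0, np.array(R0)


def maxcal_from_weighted_trajectory(samples, weights=None, lag_steps: int = 20,
                                    dt: float = 1.0, n_states: int = 20,
                                    seed: int = 0,
                                    lag_time: float | None = None):
    """End-to-end MaxCal model from a (possibly reweighted) CV trajectory.

    Clusters the samples into weighted k-means microstates, estimates pi from
    member weights, estimates the mean jump rate and per-CV displacement
    targets from start-frame-weighted (t, t + lag) pairs of microstate
    labels, and solves the MaxCal model at the (optionally rescaled) lag
    time.  With ``weights=None`` the trajectory is treated as unbiased; for
    metadynamics data pass the unbiasing frame weights and the median
    rescaled lag as ``lag_time``.

    Returns ``(model, microstates)``.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ms = cluster_microstates(X, weights=weights, n_states=n_states, seed=seed)
    lab = ms.labels
    if lab.size <= lag_steps:
        raise InsufficientDataError("trajectory not longer than the lag")
    if lag_time is None:
        lag_time = lag_steps * dt
    w = (np.ones(lab.size) if weights is None
         else np.asarray(weights, dtype=float))[: lab.size - lag_steps]
    a, b = lab[:-lag_steps], lab[lag_steps:]
    wsum = w.sum()
    N0 = float((w * (a != b)).sum() / wsum) / lag_time
    constraints = []
    for q in range(ms.q_means.shape[1]):
        disp = np.abs(ms.q_means[b, q] - ms.q_means[a, q])
        target = float((w * disp).sum() / wsum) / lag_time
        if target > 0:
            constraints.append(
                ConstraintSpec.from_state_means(f"q{q}", ms.q_means[:, q], target)
            )
    model = maxcal_solve(ms.pi, constraints, N0=N0, lag=lag_time)
    return model, ms


def mfpt(model, source, target) -> float:
    """Mean first passage time from a source set to a target set.

    First-step analysis on the rate matrix: solve
    ``sum_j kappa_ij m_j = -1`` for all i outside the target with ``m = 0``
    on the target, then return the pi-weighted average of m over the source
    states (pi renormalized within the source).
    """
    K, pi = model.kappa, model.pi
    n = pi.size
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if target.size == 0:
        raise InvalidParameterError("target set must be non-empty")
    if np.intersect1d(source, target).size:
        raise InvalidParameterError("source and target sets must be disjoint")
    mask = np.ones(n, dtype=bool)
    mask[target] = False
    Q = K[np.ix_(mask, mask)]
    try:
        m_free = np.linalg.solve(Q, -np.ones(mask.sum()))
    except np.linalg.LinAlgError as exc:
        raise UnreachableTargetError(
            "target unreachable: first-passage system is singular"
        ) from exc
    if np.any(m_free < -1e-9) or np.any(~np.isfinite(m_free)):
        raise UnreachableTargetError("target unreachable from some source state")
    m = np.zeros(n)
    m[mask] = m_free
    w = pi[source]
    return float(np.sum(w * m[source]) / w.sum())


def mfpt_from_transition_matrix(P, pi, source, target, lag_time: float = 1.0) -> float:
    """MFPT of a discrete-time chain, in time units of ``lag_time`` per step.

    Solves ``(I - P_QQ) m = 1`` with m = 0 on the target; used for
    count-matrix reference models where only P is available.
    """
    P = np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = pi.size
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if target.size == 0:
        raise InvalidParameterError("target set must be non-empty")
    if np.intersect1d(source, target).size:
        raise InvalidParameterError("source and target sets must be disjoint")
    mask = np.ones(n, dtype=bool)
    mask[target] = False
    A = np.eye(mask.sum()) - P[np.ix_(mask, mask)]
    try:
        m_free = np.linalg.solve(A, np.ones(mask.sum()))
    except np.linalg.LinAlgError as exc:
        raise UnreachableTargetError(
            "target unreachable: first-passage system is singular"
        ) from exc
    if np.any(m_free < -1e-9) or np.any(~np.isfinite(m_free)):
        raise UnreachableTargetError("target unreachable from some source state")
    m = np.zeros(n)
    m[mask] = m_free
    w = pi[source]
    return float(lag_time * np.sum(w * m[source]) / w.sum())


@dataclass(frozen=True)
class RegionSpec:
    """Named axis-aligned boxes in CV space.

    ``boxes`` maps region name -> (lower, upper) corner arrays.  States whose
    center falls in no box are labelled ``"unassigned"``; a state in more than
    one box is an error.
    """

    boxes: dict

    def __post_init__(self):
        clean = {}
        for name, (lo, hi) in self.boxes.items():
            lo = np.atleast_1d(np.asarray(lo, dtype=float))
            hi = np.atleast_1d(np.asarray(hi, dtype=float))
            if np.any(hi <= lo):
                raise InvalidParameterError(f"region {name!r} box is empty")
            clean[name] = (lo, hi)
        object.__setattr__(self, "boxes", clean)

    @property
    def names(self):
        return list(self.boxes.keys())


def assign_regions(centers, regions: RegionSpec) -> np.ndarray:
    """Region label of each microstate center (``"unassigned"`` if none)."""
    X = np.atleast_2d(np.asarray(centers, dtype=float))
    labels = np.array(["unassigned"] * X.shape[0], dtype=object)
    for name, (lo, hi) in regions.boxes.items():
        inside = np.all((X >= lo) & (X <= hi), axis=1)
        clash = inside & (labels != "unassigned")
        if np.any(clash):
            raise AmbiguousRegionError(
                f"states {np.flatnonzero(clash).tolist()} fall in both "
                f"{labels[clash][0]!r} and {name!r}"
            )
        labels[inside] = name
    return labels


def region_populations(pi, labels, regions: RegionSpec) -> dict:
    """Total stationary probability per region (unassigned mass excluded)."""
    pi = np.asarray(pi, dtype=float)
    labels = np.asarray(labels, dtype=object)
    return {name: float(pi[labels == name].sum()) for name in regions.names}


def region_mfpt_matrix(model, regions: RegionSpec, labels=None,
                       region_names=None) -> "pd.DataFrame":
    """MFPT between every ordered pair of regions; diagonal zero."""
    import pandas as pd

    if labels is None:
        labels = assign_regions(model_centers_or_qmeans(model), regions)
    labels = np.asarray(labels, dtype=object)
    names = list(region_names) if region_names is not None else [
        n for n in regions.names if np.any(labels == n)
    ]
    if len(names) < 2:
        raise EmptyRegionError("need at least 2 non-empty regions")
    for n in names:
        if not np.any(labels == n):
            raise EmptyRegionError(f"region {n!r} has no assigned microstates")
    M = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, t in enumerate(names):
            if i == j:
                continue
            M[i, j] = mfpt(model, np.flatnonzero(labels == a),
                           np.flatnonzero(labels == t))
    return pd.DataFrame(M, index=names, columns=names)


def model_centers_or_qmeans(model):
    if hasattr(model, "q_means"):
        return model.q_means
    raise DimensionError(
        "pass explicit labels: this model does not expose state CV means"
    )
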