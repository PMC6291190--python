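"""Contact-map conformational space and low-free-energy path selection.

A conformation is represented by a vector of smooth contact activations
``R_i = s(r_i)``, one per selected residue-residue contact, where ``s`` is a
rational switching function of the inter-residue distance.  Distances between
conformations are Euclidean norms in this contact space.  A transition path is
an ordered sequence of N reference contact maps chosen from a trajectory by
simulated annealing so that (a) nodes sit in densely sampled regions, (b) the
edges have similar lengths and (c) the total path is short.  The resulting
node sequence defines the smooth path collective variables S (progress along
the path, in [1, N]) and Z (distance from the path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .errors import (
    DimensionError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    InvalidPathError,
)

__all__ = [
    "Contact",
    "ContactSelection",
    "ContactMapFrame",
    "PathModel",
    "AnnealConfig",
    "switching_value",
    "select_activation_contacts",
    "contact_map_distance",
    "find_endpoints",
    "local_density",
    "path_objective",
    "anneal_path",
    "path_cvs",
]

CONTACT_TYPES = ("polar", "sidechain")
#: conventional cutoffs, in Angstrom, for the two contact classes
DEFAULT_R0 = {"polar": 4.5, "sidechain": 6.5}


@dataclass(frozen=True)
class Contact:
    """One residue-residue (or atom-atom) contact definition."""

    id_a: str
    id_b: str
    type: str = "polar"
    r0: float = 4.5

    def __post_init__(self):
        if self.type not in CONTACT_TYPES:
            raise InvalidParameterError(
                f"contact type must be one of {CONTACT_TYPES}, got {self.type!r}"
            )
        if not self.r0 > 0:
            raise InvalidParameterError(f"r0 must be positive, got {self.r0}")


@dataclass(frozen=True)
class ContactSelection:
    """An ordered set of activation-relevant contacts.

    Parameters
    ----------
    contacts
        Unique contact definitions; their order fixes the contact-map vector
        layout.
    threshold
        Switching-value difference cutoff used when the selection was made
        from active/inactive reference structures.  Must lie in (0, 1).
    """

    contacts: tuple[Contact, ...]
    threshold: float = 0.65

    def __post_init__(self):
        object.__setattr__(self, "contacts", tuple(self.contacts))
        if not 0 < self.threshold < 1:
            raise InvalidParameterError(
                f"threshold must be in (0, 1), got {self.threshold}"
            )
        pairs = [(c.id_a, c.id_b) for c in self.contacts]
        if len(set(pairs)) != len(pairs):
            raise InvalidParameterError("contact pairs must be unique")

    def __len__(self):
        return len(self.contacts)

    @property
    def r0(self) -> np.ndarray:
        return np.array([c.r0 for c in self.contacts])


@dataclass(frozen=True)
class ContactMapFrame:
    """Contact-map vector of one trajectory frame."""

    values: np.ndarray
    time: float = 0.0
    selection: ContactSelection | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise DimensionError("contact map values must be a 1-D vector")
        if np.any(v < 0) or np.any(v > 1):
            raise InvalidInputError("switching values must lie in [0, 1]")
        if self.selection is not None and len(self.selection) != v.size:
            raise DimensionError(
                f"frame has {v.size} values but selection defines "
                f"{len(self.selection)} contacts"
            )
        object.__setattr__(self, "values", v)


def _pow_sum(x: float | np.ndarray, n: int) -> float | np.ndarray:
    """sum_{j=0}^{n-1} x**j, evaluated by Horner (overflow-safe for |x|<=1)."""
    acc = np.ones_like(np.asarray(x, dtype=float))
    for _ in range(n - 1):
        acc = acc * x + 1.0
    return acc


def switching_value(r, r0):
    """Rational switching function ``s(r) = (1 - (r/r0)^6) / (1 - (r/r0)^10)``.

    Maps a contact distance to a smooth activation in [0, 1]; s(0) = 1,
    s(r0) = 3/5 (the removable singularity), s -> 0 as r -> inf, strictly
    decreasing.  Evaluated through the exact factored form
    ``(sum_{j<6} x^j) / (sum_{j<10} x^j)`` so no special-casing is needed at
    r = r0; for x > 1 the reciprocal-power form is used to avoid overflow.

    Parameters
    ----------
    r : float or array_like
        Distance(s), same length unit as ``r0``; must be >= 0.
    r0 : float
        Reference distance of the contact, > 0.

    Returns
    -------
    float or ndarray
        Switching value(s) in [0, 1].
    """
    r = np.asarray(r, dtype=float)
    if not np.isscalar(r0) or isinstance(r0, np.ndarray):
        r0 = float(r0)
    if r0 <= 0:
        raise InvalidParameterError(f"r0 must be positive, got {r0}")
    if np.any(r < 0):
        raise InvalidInputError("distances must be non-negative")
    x = r / r0
    small = x <= 1.0
    out = np.empty_like(x)
    # x <= 1: s = (1 + x + ... + x^5) / (1 + x + ... + x^9)
    xs = np.where(small, x, 0.0)
    out_small = _pow_sum(xs, 6) / _pow_sum(xs, 10)
    # x > 1: multiply num and den by x^-9 -> sums of inverse powers
    with np.errstate(divide="ignore"):
        xi = np.where(small, 1.0, 1.0 / x)
    num = xi**4 * _pow_sum(xi, 6)
    den = _pow_sum(xi, 10)
    out = np.where(small, out_small, num / den)
    if out.ndim == 0:
        return float(out)
    return out


def select_activation_contacts(s_active, s_inactive, threshold=0.65):
    """Mask of contacts whose activation change exceeds ``threshold``.

    A contact is retained when ``|s_active - s_inactive| > threshold``: both
    contacts formed and contacts broken on activation carry the signal, so the
    absolute difference is used.

    Returns
    -------
    ndarray of bool
        True for contacts to include in the activation contact map.
    """
    sa = np.asarray(s_active, dtype=float)
    si = np.asarray(s_inactive, dtype=float)
    if sa.shape != si.shape:
        raise DimensionError(
            f"active/inactive vectors differ in shape: {sa.shape} vs {si.shape}"
        )
    if not 0 < threshold < 1:
        raise InvalidParameterError(f"threshold must be in (0, 1), got {threshold}")
    return np.abs(sa - si) > threshold


def _frame_values(frame) -> np.ndarray:
    if isinstance(frame, ContactMapFrame):
        return frame.values
    return np.asarray(frame, dtype=float)


def _frames_matrix(frames) -> np.ndarray:
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        return np.asarray(frames, dtype=float)
    rows = [_frame_values(f) for f in frames]
    if not rows:
        return np.empty((0, 0))
    n = rows[0].size
    if any(r.size != n for r in rows):
        raise DimensionError("frames have inconsistent contact-map lengths")
    return np.vstack(rows)


def contact_map_distance(R1, R2) -> float:
    """Euclidean norm of the difference of two contact maps."""
    v1, v2 = _frame_values(R1), _frame_values(R2)
    if v1.shape != v2.shape:
        raise DimensionError(
            f"contact maps differ in length: {v1.shape} vs {v2.shape}"
        )
    if (
        isinstance(R1, ContactMapFrame)
        and isinstance(R2, ContactMapFrame)
        and R1.selection is not None
        and R2.selection is not None
        and R1.selection is not R2.selection
        and R1.selection != R2.selection
    ):
        raise DimensionError("frames belong to different contact selections")
    return float(np.linalg.norm(v1 - v2))


def pairwise_distances(frames) -> np.ndarray:
    """Full matrix of contact-map distances between all frame pairs."""
    X = _frames_matrix(frames)
    return cdist(X, X)


def find_endpoints(frames) -> tuple[int, int]:
    """Indices of the mutually furthest pair of frames.

    Ties are broken by the lexicographically smallest (i, j) with i < j, so
    the result is deterministic.
    """
    X = _frames_matrix(frames)
    n = X.shape[0]
    if n < 2:
        raise InsufficientDataError("need at least 2 frames to find endpoints")
    D = cdist(X, X)
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    best = np.max(vals)
    # lexicographic tie-break: triu_indices already enumerates (i, j) in
    # row-major order, so the first argmax is the smallest pair
    k = int(np.argmax(vals == best))
    return int(iu[0][k]), int(iu[1][k])


def median_nn_distance(D: np.ndarray) -> float:
    """Median over frames of the nearest-neighbour distance (self excluded)."""
    D = np.asarray(D, dtype=float)
    masked = D + np.diag(np.full(D.shape[0], np.inf))
    return float(np.median(masked.min(axis=1)))


def local_density(frames, radius: float | None = None,
                  radius_factor: float = 3.0) -> np.ndarray:
    """Number of other frames within ``radius`` of each frame.

    The frame itself is excluded from its own count.  When ``radius`` is None
    it defaults to ``radius_factor`` times the median nearest-neighbour
    distance of the set.
    """
    X = _frames_matrix(frames)
    D = cdist(X, X)
    if radius is None:
        radius = radius_factor * median_nn_distance(D)
    if not radius > 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    within = D <= radius
    return within.sum(axis=1) - 1  # remove self


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing settings for path selection.

    ``k_schedule`` is the decreasing sequence of effective temperatures; each
    value both weights the edge-length-variance term of the objective and
    serves as the Metropolis temperature at that level.
    """

    n_nodes: int = 10
    k_schedule: tuple[float, ...] = field(
        default_factory=lambda: tuple(1.0 * 0.95**i for i in range(40))
    )
    n_iters: int = 200
    density_radius_factor: float = 3.0
    objective_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    objective_form: str = "ratio"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 3:
            raise InvalidParameterError("n_nodes must be >= 3")
        ks = np.asarray(self.k_schedule, dtype=float)
        if ks.size == 0 or np.any(ks <= 0):
            raise InvalidParameterError("k_schedule must be strictly positive")
        if np.any(np.diff(ks) > 0):
            raise InvalidParameterError("k_schedule must be non-increasing")


@dataclass(frozen=True)
class PathModel:
    """Ordered reference nodes defining the path CVs S and Z.

    Attributes
    ----------
    nodes
        (N, n_contacts) array of reference contact maps, in path order.
    lam
        Smoothing parameter lambda (inverse contact-map-norm units).
    node_indices
        Indices of the nodes in the source frame set, in path order.
    endpoint_indices
        (j0, jN) of the mutually furthest source frames.
    """

    nodes: np.ndarray
    lam: float = 2.0
    node_indices: tuple[int, ...] | None = None
    endpoint_indices: tuple[int, int] | None = None
    objective: float | None = None
    seed: int | None = None

    def __post_init__(self):
        nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if nodes.shape[0] < 2:
            raise InvalidPathError("a path needs at least 2 nodes")
        if self.node_indices is not None and len(set(self.node_indices)) != len(
            self.node_indices
        ):
            raise InvalidPathError("path node indices must be distinct")
        if not self.lam > 0:
            raise InvalidParameterError("lambda must be positive")
        object.__setattr__(self, "nodes", nodes)

    def __len__(self):
        return self.nodes.shape[0]

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    @classmethod
    def with_auto_lambda(cls, nodes, **kw):
        """Build a path with lambda = 2.3 / (mean edge length)."""
        nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
        mean_edge = float(
            np.mean(np.linalg.norm(np.diff(nodes, axis=0), axis=1))
        )
        if mean_edge <= 0:
            raise InvalidPathError("degenerate path: zero mean edge length")
        return cls(nodes=nodes, lam=2.3 / mean_edge, **kw)


def path_objective_terms(path_indices, distance_matrix, densities) -> dict:
    """The three raw ingredients of the path objective.

    ``variance`` = (1/2) sum_i (d_i - dbar)^2 over edge lengths d_i,
    ``length`` = sum_i d_i, ``density`` = sum_j rho_j over path nodes.
    """
    idx = np.asarray(path_indices, dtype=int)
    if len(set(idx.tolist())) != idx.size:
        raise InvalidPathError("path contains a repeated node")
    D = np.asarray(distance_matrix, dtype=float)
    rho = np.asarray(densities, dtype=float)
    d = D[idx[:-1], idx[1:]]
    return {
        "variance": float(0.5 * np.sum((d - d.mean()) ** 2)),
        "length": float(np.sum(d)),
        "density": float(np.sum(rho[idx])),
    }


def path_objective(path_indices, distance_matrix, densities, k=1.0,
                   weights=(1.0, 1.0, 1.0), form: str = "ratio") -> float:
    """Annealing objective for a candidate path; lower is better.

    The default ``ratio`` form is

        ``W = (k/2) * sum_i (d_i - dbar)^2 * sum_i d_i / sum_j rho_j``

    with ``d_i`` the edge lengths along the path and ``rho_j`` the local
    sample densities at its nodes: minimizing it simultaneously favours equal
    edges, a short path, and nodes in densely sampled (low-free-energy)
    regions, and - being a ratio - is insensitive to the absolute scale of
    the density counts.  The ``composite`` form is the weighted sum
    ``w_var*(k/2)*sum(d_i-dbar)^2 + w_len*sum d_i - w_dens*sum rho_j``; with
    raw neighbour counts its density term tends to dominate, so it is not the
    default.
    """
    if not k > 0:
        raise InvalidParameterError("effective temperature k must be positive")
    t = path_objective_terms(path_indices, distance_matrix, densities)
    if form == "ratio":
        return float(k * t["variance"] * t["length"] / max(t["density"], 0.5))
    if form == "composite":
        w_var, w_len, w_dens = weights
        return float(
            w_var * k * t["variance"] + w_len * t["length"]
            - w_dens * t["density"]
        )
    raise InvalidParameterError(f"unknown objective form {form!r}")


def _anneal_initial(rng, n_frames, j0, jN, n_interior, D):
    pool = [i for i in range(n_frames) if i not in (j0, jN)]
    interior = list(rng.choice(pool, size=n_interior, replace=False))
    # order the random selection by distance from the start so the initial
    # path is not hopelessly tangled
    interior.sort(key=lambda i: D[j0, i])
    return [j0, *interior, jN]


def anneal_path(frames, config: AnnealConfig | None = None,
                lam: float = 2.0) -> PathModel:
    """Select an N-node transition path by Metropolis simulated annealing.

    Endpoints are pinned to the mutually furthest pair of frames; the
    N - 2 interior nodes start as a random selection and are refined with two
    move types (replace an interior node by an unused frame; swap adjacent
    interior nodes) under a geometric cooling schedule.  The state energy is
    :func:`path_objective` at the current schedule temperature; the returned
    path is the best state visited as measured at the final (coldest)
    temperature, making results comparable with exhaustive search.
    Deterministic for a fixed config seed.
    """
    if config is None:
        config = AnnealConfig()
    X = _frames_matrix(frames)
    n = X.shape[0]
    if n < config.n_nodes:
        raise InsufficientDataError(
            f"need at least as many frames ({n}) as path nodes ({config.n_nodes})"
        )
    D = cdist(X, X)
    rho = local_density(X, radius_factor=config.density_radius_factor).astype(float)
    j0, jN = find_endpoints(X)
    rng = np.random.default_rng(config.seed)

    n_interior = config.n_nodes - 2
    path = _anneal_initial(rng, n, j0, jN, n_interior, D)
    k_final = config.k_schedule[-1]
    w = config.objective_weights
    form = config.objective_form

    def energy(p, k):
        return path_objective(p, D, rho, k, w, form=form)

    best_path = list(path)
    best_final = energy(path, k_final)
    current = energy(path, k_final)
    # Metropolis temperature in units of the initial objective magnitude, so
    # the geometric k schedule cools at the problem's own energy scale
    t_scale = 0.1 * max(abs(best_final), 1e-300)

    for k in config.k_schedule:
        temp = k * t_scale
        for _ in range(config.n_iters):
            for _ in range(max(n_interior, 1)):
                move = rng.random()
                trial = list(path)
                if move < 0.5 or n_interior < 2:
                    pos = 1 + int(rng.integers(n_interior))
                    used = set(path)
                    cand = int(rng.integers(n))
                    if cand in used:
                        continue
                    trial[pos] = cand
                else:
                    pos = 1 + int(rng.integers(n_interior - 1))
                    trial[pos], trial[pos + 1] = trial[pos + 1], trial[pos]
                e_trial = energy(trial, k_final)
                dE = e_trial - current
                if dE <= 0 or rng.random() < math.exp(-dE / temp):
                    path = trial
                    current = e_trial
                    if e_trial < best_final:
                        best_final = e_trial
                        best_path = list(path)

    return PathModel(
        nodes=X[best_path],
        lam=lam,
        node_indices=tuple(best_path),
        endpoint_indices=(j0, jN),
        objective=best_final,
        seed=config.seed,
    )


def path_cvs(R, path: PathModel) -> tuple[float, float]:
    """Evaluate the path collective variables (S, Z) for one contact map.

    ``S = sum_k k e^{-lam d_k} / sum_k e^{-lam d_k}`` locates the frame along
    the path (in [1, N]); ``Z = -lam^{-1} log sum_k e^{-lam d_k}`` measures
    its distance from the path.  Computed with a shifted log-sum-exp so large
    ``lam * d`` never overflows.
    """
    if len(path) == 0:
        raise InvalidPathError("empty path")
    v = _frame_values(R)
    if v.size != path.nodes.shape[1]:
        raise DimensionError(
            f"frame has {v.size} contacts, path nodes have {path.nodes.shape[1]}"
        )
    d = np.linalg.norm(path.nodes - v[None, :], axis=1)
    a = -path.lam * d
    lse = logsumexp(a)
    wts = np.exp(a - lse)
    ks = np.arange(1, len(path) + 1)
    S = float(np.sum(ks * wts))
    Z = float(-lse / path.lam)
    return S, Z


def path_cvs_table(frames, path: PathModel) -> np.ndarray:
    """(n_frames, 2) array of (S, Z) for every frame."""
    X = _frames_matrix(frames)
    d = cdist(X, path.nodes)
    a = -path.lam * d
    lse = logsumexp(a, axis=1)
    wts = np.exp(a - lse[:, None])
    ks = np.arange(1, len(path) + 1)
    S = wts @ ks
    Z = -lse / path.lam
    return np.column_stack([S, Z])
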