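"""n-body information theory on weighted histograms.

Shannon entropy, mutual information (MI), conditional MI and the three-body
co-information (CI) are estimated from weighted multidimensional histograms of
trajectory features.  For three variable blocks X, Y, Z,

    CI(X, Y, Z) = MI(X, Y) - MI(X, Y | Z)
                = MI(X, Z) + MI(Y, Z) - MI(X u Y, Z)

is fully symmetric under permutations of the blocks.  Positive CI means X and
Y carry redundant information about Z (a common-cause structure); negative CI
means they are synergistic - jointly they say more about Z than separately.
The per-residue scan ranks each residue's Cartesian block Z by the CI it forms
with the ligand-pocket block X and the activation-CV block Y; a more negative
value marks a stronger conduit of information between the two ends of the
receptor.  All joint distributions are accumulated sparsely over occupied
bins, so high-dimensional joints (up to 7-D here) cost memory proportional to
the number of occupied cells only.  Histogram bin edges must be shared across
residues for the ranking to be meaningful; the scan enforces this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DimensionError,
    InsufficientDataError,
    InvalidBlockError,
    InvalidInputError,
    NormalizationError,
)

__all__ = [
    "HistogramND",
    "VariableBlock",
    "weighted_histogram",
    "entropy",
    "make_edges",
    "digitize_table",
    "joint_entropy",
    "mutual_information",
    "conditional_mi",
    "co_information",
    "residue_scan",
    "pocket_pca",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class HistogramND:
    """Normalized weighted histogram on fixed bin edges."""

    edges: tuple[np.ndarray, ...]
    probs: np.ndarray
    total_weight: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise InvalidInputError("histogram probabilities must be >= 0")
        object.__setattr__(self, "probs", p)
        object.__setattr__(
            self, "edges", tuple(np.asarray(e, dtype=float) for e in self.edges)
        )

    @property
    def ndim(self):
        return len(self.edges)


def weighted_histogram(values, weights=None, edges=None, bins=12) -> HistogramND:
    """Dense normalized histogram of (n_samples, n_dims) values.

    Out-of-range samples are dropped with a warning (``numpy.histogramdd``
    clips edge-exact values into the last bin, as usual).
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and edges is not None and len(edges) == 1:
        X = X.T
    if X.ndim != 2:
        raise DimensionError("values must be (n_samples, n_dims)")
    if X.shape[1] > X.shape[0] and X.shape[0] <= 2:
        X = X.T
    n = X.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise DimensionError("weights length must match number of samples")
    if edges is None:
        edges = [
            np.linspace(X[:, d].min(), X[:, d].max(), bins + 1)
            for d in range(X.shape[1])
        ]
    inside = np.ones(n, dtype=bool)
    for d, e in enumerate(edges):
        inside &= (X[:, d] >= e[0]) & (X[:, d] <= e[-1])
    if not inside.all():
        warnings.warn(
            f"dropping {int((~inside).sum())} out-of-range samples", stacklevel=2
        )
    H, edges = np.histogramdd(X[inside], bins=edges, weights=w[inside])
    total = H.sum()
    if total <= 0:
        raise InvalidInputError("histogram has zero total weight")
    return HistogramND(edges=tuple(edges), probs=H / total, total_weight=float(total))


def _entropy_from_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def entropy(hist, bits: bool = False) -> float:
    """Shannon entropy -sum p ln p of a normalized histogram.

    Accepts a :class:`HistogramND` or a raw probability array; nats by
    default, bits with ``bits=True``.
    """
    p = hist.probs if isinstance(hist, HistogramND) else np.asarray(hist, dtype=float)
    if np.any(p < 0):
        raise InvalidInputError("probabilities must be >= 0")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-8):
        raise NormalizationError(f"histogram sums to {s}, expected 1")
    H = _entropy_from_probs(p / s)
    return H / LN2 if bits else H


@dataclass(frozen=True)
class VariableBlock:
    """A named group of feature columns playing one role (X, Y or Z)."""

    name: str
    columns: tuple

    def __post_init__(self):
        object.__setattr__(self, "columns", tuple(self.columns))


def _columns_of(block) -> tuple:
    if isinstance(block, VariableBlock):
        return block.columns
    if isinstance(block, (str, int)):
        return (block,)
    return tuple(block)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise DimensionError("data must be 2-D (frames x features)")
    return pd.DataFrame(arr)


def make_edges(data, columns, bins: int = 12) -> dict:
    """Uniform per-column bin edges spanning each column's global range."""
    df = _as_frame(data)
    out = {}
    for c in columns:
        col = df[c].to_numpy(dtype=float)
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            hi = lo + 1e-12
        out[c] = np.linspace(lo, hi, bins + 1)
    return out


def digitize_table(data, edges: Mapping) -> tuple[np.ndarray, list, np.ndarray]:
    """Map each feature column to integer bin indices.

    Returns ``(idx, columns, nbins)`` where ``idx`` is (n_samples, n_cols)
    int64, columns lists the column order, and ``nbins`` the bin count per
    column.  Values at or past the outer edges are clipped into the boundary
    bins, matching dense-histogram conventions.
    """
    df = _as_frame(data)
    cols = list(edges.keys())
    n = len(df)
    idx = np.empty((n, len(cols)), dtype=np.int64)
    nbins = np.empty(len(cols), dtype=np.int64)
    for j, c in enumerate(cols):
        e = np.asarray(edges[c], dtype=float)
        k = e.size - 1
        b = np.searchsorted(e, df[c].to_numpy(dtype=float), side="right") - 1
        idx[:, j] = np.clip(b, 0, k - 1)
        nbins[j] = k
    return idx, cols, nbins


class DigitizedTable:
    """Pre-binned feature table for repeated entropy queries.

    Caches joint entropies keyed by the (sorted) column subset so the Eq-by-Eq
    identities reuse, rather than recompute, shared marginals.
    """

    def __init__(self, data, edges: Mapping, weights=None,
                 miller_madow: bool = False):
        self.idx, self.columns, self.nbins = digitize_table(data, edges)
        self.col_pos = {c: j for j, c in enumerate(self.columns)}
        n = self.idx.shape[0]
        if weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (n,):
                raise DimensionError("weights length must match table length")
            if np.any(~np.isfinite(w)) or np.any(w < 0):
                raise InvalidInputError("weights must be finite and >= 0")
            self.weights = w / w.sum()
        self.miller_madow = miller_madow
        # Kish effective sample size governs the Miller-Madow bias term
        self.n_eff = float(1.0 / np.sum(self.weights**2))
        self._cache: dict[tuple, float] = {}

    def joint_entropy(self, columns) -> float:
        cols = tuple(columns)
        key = tuple(sorted(map(str, cols)))
        if key in self._cache:
            return self._cache[key]
        pos = [self.col_pos[c] for c in cols]
        sub = self.idx[:, pos]
        strides = np.cumprod(np.concatenate(([1], self.nbins[pos][:-1])))
        keys = sub @ strides
        order = np.argsort(keys, kind="stable")
        ks = keys[order]
        ws = self.weights[order]
        boundaries = np.flatnonzero(np.diff(ks)) + 1
        p = np.add.reduceat(ws, np.concatenate(([0], boundaries)))
        H = _entropy_from_probs(p)
        if self.miller_madow:
            H += (np.count_nonzero(p) - 1) / (2.0 * self.n_eff)
        self._cache[key] = H
        return H


def _table(data, weights, edges, miller_madow=False) -> DigitizedTable:
    if isinstance(data, DigitizedTable):
        return data
    return DigitizedTable(data, edges, weights, miller_madow=miller_madow)


def _check_disjoint(*blocks):
    cols = [set(map(str, _columns_of(b))) for b in blocks]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i] & cols[j]:
                raise InvalidBlockError(
                    f"variable blocks overlap on {sorted(cols[i] & cols[j])}"
                )


def joint_entropy(data, weights, block, edges=None, bits=False,
                  miller_madow=False) -> float:
    t = _table(data, weights, edges, miller_madow)
    H = t.joint_entropy(_columns_of(block))
    return H / LN2 if bits else H


def mutual_information(data, weights, block_x, block_y, edges=None,
                       bits=False, miller_madow=False) -> float:
    """MI(X, Y) = H(X) + H(Y) - H(X, Y); clipped at the -1e-12 rounding floor."""
    _check_disjoint(block_x, block_y)
    t = _table(data, weights, edges, miller_madow)
    cx, cy = _columns_of(block_x), _columns_of(block_y)
    mi = t.joint_entropy(cx) + t.joint_entropy(cy) - t.joint_entropy(cx + cy)
    if mi < -1e-12:
        warnings.warn(f"MI estimate {mi} below rounding floor", stacklevel=2)
    mi = max(mi, 0.0)
    return mi / LN2 if bits else mi


def conditional_mi(data, weights, block_x, block_y, block_z, edges=None,
                   bits=False, miller_madow=False) -> float:
    """MI(X, Y | Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)."""
    _check_disjoint(block_x, block_y, block_z)
    t = _table(data, weights, edges, miller_madow)
    cx, cy, cz = (_columns_of(b) for b in (block_x, block_y, block_z))
    cmi = (
        t.joint_entropy(cx + cz)
        + t.joint_entropy(cy + cz)
        - t.joint_entropy(cx + cy + cz)
        - t.joint_entropy(cz)
    )
    return cmi / LN2 if bits else cmi


def co_information(data, weights, block_x, block_y, block_z, edges=None,
                   route: str = "eq8", bits=False,
                   miller_madow=False) -> float:
    """Three-body co-information of blocks X, Y, Z.

    ``route='eq8'`` computes MI(X,Y) - MI(X,Y|Z); ``route='eq9'`` computes
    MI(X,Z) + MI(Y,Z) - MI(X u Y, Z).  On identical histograms the two routes
    agree to floating-point error.  Positive = redundancy, negative = synergy.
    """
    _check_disjoint(block_x, block_y, block_z)
    t = _table(data, weights, edges, miller_madow)
    cx, cy, cz = (_columns_of(b) for b in (block_x, block_y, block_z))
    H = t.joint_entropy
    if route == "eq8":
        mi_xy = H(cx) + H(cy) - H(cx + cy)
        cmi = H(cx + cz) + H(cy + cz) - H(cx + cy + cz) - H(cz)
        ci = mi_xy - cmi
    elif route == "eq9":
        mi_xz = H(cx) + H(cz) - H(cx + cz)
        mi_yz = H(cy) + H(cz) - H(cy + cz)
        mi_xy_z = H(cx + cy) + H(cz) - H(cx + cy + cz)
        ci = mi_xz + mi_yz - mi_xy_z
    else:
        raise InvalidInputError(f"unknown route {route!r}; use 'eq8' or 'eq9'")
    return ci / LN2 if bits else ci


def residue_scan(data, weights, pocket_block, activation_block, residue_blocks,
                 bins: int = 12, edges=None, bits=False,
                 miller_madow=False) -> pd.DataFrame:
    """Co-information of every residue block with the pocket/activation pair.

    All residue coordinate columns are binned on one shared set of edges per
    coordinate axis (global min/max over all residues), which the CI ranking
    requires: changing bins between residues silently reshuffles the ranking.

    Returns a DataFrame with columns ``residue``, ``ci`` and ``ci_normalized``
    (ci divided by the maximum absolute ci across residues).
    """
    df = _as_frame(data)
    pocket = VariableBlock("pocket", _columns_of(pocket_block))
    activation = VariableBlock("activation", _columns_of(activation_block))
    residues = {}
    for b in residue_blocks:
        if isinstance(b, VariableBlock):
            residues[b.name] = b.columns
        else:
            name, cols = b
            residues[name] = tuple(cols)
    if not residues:
        raise InsufficientDataError("no residue blocks given")
    n_coords = {len(c) for c in residues.values()}
    if len(n_coords) != 1:
        raise InvalidBlockError("residue blocks must all have the same arity")
    (n_axis,) = n_coords

    if edges is None:
        edges = make_edges(df, pocket.columns + activation.columns, bins=bins)
        # shared residue-axis edges: pool the k-th coordinate of every residue
        for ax in range(n_axis):
            pooled = np.concatenate(
                [df[cols[ax]].to_numpy(dtype=float) for cols in residues.values()]
            )
            lo, hi = float(pooled.min()), float(pooled.max())
            if hi <= lo:
                hi = lo + 1e-12
            shared = np.linspace(lo, hi, bins + 1)
            for cols in residues.values():
                edges[cols[ax]] = shared
    else:
        for ax in range(n_axis):
            ref = None
            for cols in residues.values():
                e = np.asarray(edges[cols[ax]], dtype=float)
                if ref is None:
                    ref = e
                elif e.shape != ref.shape or not np.allclose(e, ref):
                    raise InvalidBlockError(
                        "residue blocks must share identical bin edges per axis"
                    )

    table = DigitizedTable(df, edges, weights, miller_madow=miller_madow)
    rows = []
    for name, cols in residues.items():
        ci = co_information(
            table, None, pocket, activation, VariableBlock(name, cols),
            route="eq8", bits=bits,
        )
        rows.append((name, ci))
    out = pd.DataFrame(rows, columns=["residue", "ci"])
    scale = out["ci"].abs().max()
    out["ci_normalized"] = out["ci"] / scale if scale > 0 else 0.0
    return out


def pocket_pca(coords, weights=None, n_components: int = 2):
    """Weighted principal components of binding-pocket coordinates.

    Eigen-decomposition of the weighted covariance; components are ordered by
    explained variance and each component's sign is fixed so its
    largest-magnitude loading is positive.

    Returns
    -------
    projections : (n_frames, n_components) ndarray
    loadings : (n_components, n_features) ndarray
    explained_variance_ratio : (n_components,) ndarray
    """
    X = np.asarray(coords, dtype=float)
    if isinstance(coords, pd.DataFrame):
        X = coords.to_numpy(dtype=float)
    if X.ndim != 2:
        raise DimensionError("coords must be (n_frames, n_features)")
    n = X.shape[0]
    if n < 3:
        raise InsufficientDataError("need at least 3 frames for PCA")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = w @ X
    Xc = X - mu
    cov = (Xc * w[:, None]).T @ Xc
    tot = np.trace(cov)
    if tot <= 0:
        raise DegenerateInputError("zero-variance input")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Xc @ comps.T, comps, evals / tot
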