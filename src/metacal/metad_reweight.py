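"""Well-tempered metadynamics bias evaluation and unbiased-ensemble recovery.

Well-tempered MetaD deposits Gaussian hills of decaying height on a set of
collective variables; the accumulated bias V(s, t) converges (up to a
constant) to -(1 - 1/gamma) F(s), so the free energy is recovered as
F = -(gamma / (gamma - 1)) V.  Static and dynamical unbiased averages are
recovered from the biased trajectory with per-frame weights
exp((V_t - c_t) / kB T), where the time-dependent correction c(t) is the
Tiwary-Parrinello running estimate of the reversible-work offset of the bias.
The same weights give the acceleration factor of the biased clock, so a
dynamical observable evaluated at a biased lag dt' corresponds to the unbiased
lag  dt = Dt * sum_{s in segment} exp((V_s - c_s)/kB T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (
    DimensionError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from .nbit import HistogramND

__all__ = [
    "KB_KJ_MOL_K",
    "HillsLog",
    "WeightedTrajectory",
    "FreeEnergySurface",
    "bias_value",
    "bias_at_frames",
    "well_tempered_height",
    "free_energy_from_bias",
    "CorrectionSeries",
    "bias_correction_series",
    "frame_weights",
    "reweighted_histogram",
    "rescaled_lag",
    "median_rescaled_lag",
    "dynamical_average",
    "reweight_trajectory",
]

#: Boltzmann constant in kJ/mol/K; pass kB=1.0 to work in units of kT.
KB_KJ_MOL_K = 0.0083144621


@dataclass(frozen=True)
class HillsLog:
    """Record of deposited Gaussians from a well-tempered MetaD run.

    Attributes
    ----------
    times : (n_hills,) deposition times, strictly increasing.
    centers : (n_hills, n_cv) CV values at deposition.
    sigmas : (n_hills, n_cv) Gaussian widths per CV.
    heights : (n_hills,) deposited (already tempered) heights, > 0.
    bias_factor : gamma = (T + dT)/T > 1.
    temperature : simulation temperature T.
    period : deposition period tau.
    """

    times: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    heights: np.ndarray
    bias_factor: float = 12.0
    temperature: float = 300.0
    period: float | None = None
    cv_names: tuple[str, ...] | None = None
    kB: float = KB_KJ_MOL_K

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.shape[0] != t.size:
            c = c.reshape(t.size, -1)
        s = np.asarray(self.sigmas, dtype=float)
        if s.ndim == 1 and s.size == c.shape[1]:
            s = np.broadcast_to(s, c.shape).copy()
        s = np.atleast_2d(s).reshape(t.size, -1) if t.size else np.atleast_2d(s)
        h = np.asarray(self.heights, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidInputError("hill times must be strictly increasing")
        if np.any(s <= 0):
            raise InvalidParameterError("hill sigmas must be positive")
        if np.any(h <= 0):
            raise InvalidParameterError("hill heights must be positive")
        if not self.bias_factor > 1:
            raise InvalidParameterError("bias factor gamma must exceed 1")
        for name, val in (("times", t), ("centers", c), ("sigmas", s), ("heights", h)):
            object.__setattr__(self, name, val)

    def __len__(self):
        return self.times.size

    @property
    def n_cv(self) -> int:
        return self.centers.shape[1]

    @property
    def delta_T(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature


def bias_value(hills: HillsLog, s_point, t: float) -> float:
    """Total bias V(s, t): sum of the Gaussians deposited up to time t."""
    if t < 0:
        raise InvalidInputError("time must be >= 0")
    s = np.atleast_1d(np.asarray(s_point, dtype=float))
    if len(hills) == 0:
        return 0.0
    if s.size != hills.n_cv:
        raise DimensionError(
            f"point has {s.size} CVs, hills have {hills.n_cv}"
        )
    m = hills.times <= t
    if not m.any():
        return 0.0
    d2 = (s[None, :] - hills.centers[m]) ** 2 / (2.0 * hills.sigmas[m] ** 2)
    return float(np.sum(hills.heights[m] * np.exp(-d2.sum(axis=1))))


def bias_at_frames(hills: HillsLog, points, times) -> np.ndarray:
    """Vectorized V(s_t, t) for a trajectory of frames.

    Frames must be in non-decreasing time order; each hill contributes to all
    frames at or after its deposition time, accumulated hill-by-hill over
    suffix slices.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] == 1 and P.shape[1] > 1 and hills.n_cv == 1:
        P = P.T
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise InvalidInputError("frame times must be non-decreasing")
    V = np.zeros(t.size)
    if len(hills) == 0:
        return V
    if P.shape[1] != hills.n_cv:
        raise DimensionError("frame CV dimensionality does not match hills")
    starts = np.searchsorted(t, hills.times, side="left")
    for k in range(len(hills)):
        i = starts[k]
        if i >= t.size:
            break
        d2 = (P[i:] - hills.centers[k]) ** 2 / (2.0 * hills.sigmas[k] ** 2)
        V[i:] += hills.heights[k] * np.exp(-d2.sum(axis=1))
    return V


def well_tempered_height(w: float, V_current: float, delta_T: float,
                         kB: float = KB_KJ_MOL_K) -> float:
    """Tempered hill height ``w * exp(-V_current / (kB dT))``."""
    if not w > 0:
        raise InvalidParameterError("initial height must be positive")
    if not delta_T > 0:
        raise InvalidParameterError("delta_T must be positive")
    return float(w * np.exp(-V_current / (kB * delta_T)))


@dataclass(frozen=True)
class FreeEnergySurface:
    """Free energy on a grid; minimum over sampled bins shifted to zero."""

    edges: tuple[np.ndarray, ...]
    F: np.ndarray
    sampled: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "edges", tuple(np.asarray(e, dtype=float) for e in self.edges)
        )
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        if self.sampled is None:
            object.__setattr__(self, "sampled", np.isfinite(F))

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


def free_energy_from_bias(V_grid, temperature: float, delta_T: float,
                          edges=None) -> FreeEnergySurface:
    """F = -((T + dT)/dT) V, shifted so the minimum is zero.

    With bias factor gamma = (T + dT)/T the prefactor is gamma/(gamma - 1).
    """
    if not delta_T > 0:
        raise InvalidParameterError("delta_T must be positive")
    V = np.asarray(V_grid, dtype=float)
    F = -((temperature + delta_T) / delta_T) * V
    F = F - np.nanmin(F)
    if edges is None:
        edges = (np.arange(V.shape[0] + 1, dtype=float),)
    return FreeEnergySurface(edges=tuple(edges), F=F)


class CorrectionSeries:
    """Time series of the reweighting correction c(t).

    Piecewise-linear in time between deposition instants, c(0) = 0 before the
    first hill, constant after the last.
    """

    def __init__(self, times, c):
        self.times = np.asarray(times, dtype=float)
        self.c = np.asarray(c, dtype=float)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, np.concatenate(([0.0], self.times)),
                        np.concatenate(([0.0], self.c)))
        return float(out) if out.ndim == 0 else out


def _hills_grid(hills: HillsLog, bins: int = 200):
    """Per-CV uniform grid covering the hill centers +- 3 * max sigma."""
    axes = []
    for d in range(hills.n_cv):
        pad = 3.0 * hills.sigmas[:, d].max()
        lo = hills.centers[:, d].min() - pad
        hi = hills.centers[:, d].max() + pad
        axes.append(np.linspace(lo, hi, bins))
    return axes


def bias_correction_series(hills: HillsLog, cv_grid=None, temperature=None,
                           bins: int = 200, kB: float | None = None
                           ) -> CorrectionSeries:
    """Tiwary-Parrinello correction c(t) evaluated at each deposition time.

    On a CV grid covering the sampled range,

        c(t) = kBT * [ ln sum_s e^{g/(g-1) beta V(s,t)}
                       - ln sum_s e^{1/(g-1) beta V(s,t)} ],

    which is zero for zero bias and equals V(t) for a spatially constant bias
    (so weights stay bias-independent in that degenerate case), and tends to
    the irreversible work performed on the system.
    """
    T = hills.temperature if temperature is None else temperature
    kB = hills.kB if kB is None else kB
    beta = 1.0 / (kB * T)
    g = hills.bias_factor
    if len(hills) == 0:
        return CorrectionSeries(np.array([0.0]), np.array([0.0]))
    if cv_grid is None:
        cv_grid = _hills_grid(hills, bins=bins)
    else:
        cv_grid = [np.asarray(a, dtype=float) for a in cv_grid]
        if any(a.size == 0 for a in cv_grid) or len(cv_grid) == 0:
            raise InvalidParameterError("cv grid must be non-empty per dimension")
    mesh = np.meshgrid(*cv_grid, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    V = np.zeros(pts.shape[0])
    c = np.empty(len(hills))
    for k in range(len(hills)):
        d2 = (pts - hills.centers[k]) ** 2 / (2.0 * hills.sigmas[k] ** 2)
        V += hills.heights[k] * np.exp(-d2.sum(axis=1))
        a = beta * V
        c[k] = (logsumexp(g / (g - 1.0) * a) - logsumexp(1.0 / (g - 1.0) * a)) / beta
    return CorrectionSeries(hills.times, c)


def frame_weights(V_t, c_t, temperature: float, kB: float = KB_KJ_MOL_K,
                  normalize: bool = False) -> np.ndarray:
    """Unbiasing weights ``exp((V_t - c_t) / kB T)``.

    A common additive shift of (V - c) only rescales all weights, so any
    normalized reweighted average is shift-invariant.  Raw (unnormalized)
    weights double as the instantaneous time-acceleration factor used for lag
    rescaling.
    """
    V = np.asarray(V_t, dtype=float)
    c = np.asarray(c_t, dtype=float)
    if V.shape != c.shape:
        raise DimensionError("V_t and c_t must have the same length")
    if np.any(~np.isfinite(V)) or np.any(~np.isfinite(c)):
        raise InvalidInputError("non-finite bias or correction values")
    w = np.exp((V - c) / (kB * temperature))
    if normalize:
        w = w / w.sum()
    return w


def reweighted_histogram(values, weights, bin_edges, temperature: float = 300.0,
                         kB: float = KB_KJ_MOL_K
                         ) -> tuple[HistogramND, FreeEnergySurface]:
    """Weighted histogram of observables and its free-energy surface.

    F = -kB T ln p, shifted so the sampled minimum is zero; unsampled bins are
    NaN in F and excluded from the ``sampled`` mask.
    """
    from .nbit import weighted_histogram

    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(bin_edges, np.ndarray) and bin_edges.ndim == 1:
        bin_edges = [bin_edges]
    hist = weighted_histogram(X, weights=weights, edges=list(bin_edges))
    with np.errstate(divide="ignore"):
        F = -kB * temperature * np.log(hist.probs)
    sampled = hist.probs > 0
    F[~sampled] = np.nan
    F = F - np.nanmin(F)
    return hist, FreeEnergySurface(edges=hist.edges, F=F, sampled=sampled)


def rescaled_lag(weights_segment, dt: float) -> float:
    """Unbiased lag ``dt * sum(weights)`` spanned by a biased segment."""
    w = np.asarray(weights_segment, dtype=float)
    if w.size == 0:
        raise InvalidInputError("empty weight segment")
    return float(dt * w.sum())


def median_rescaled_lag(weights, lag_steps: int, dt: float) -> float:
    """Median over sliding windows of the rescaled lag (robust to spikes)."""
    w = np.asarray(weights, dtype=float)
    if lag_steps < 1 or w.size <= lag_steps:
        raise InsufficientDataError("trajectory shorter than the lag")
    cs = np.concatenate(([0.0], np.cumsum(w)))
    # one window per valid (t, t + lag) frame pair
    seg = (cs[lag_steps:] - cs[:-lag_steps])[:-1]
    return float(dt * np.median(seg))


def dynamical_average(values, lag_steps: int, weights=None,
                      mode: str = "unbiased") -> float:
    """Mean absolute CV displacement over a lag.

    Unbiased mode: ``mean_t |r_t - r_{t+lag}|`` over all valid pairs.  MetaD
    mode: the same displacement averaged with the unbiasing weight of the
    starting frame, ``sum_t w_t |r_t - r_{t+lag}| / sum_t w_t`` (numerator and
    denominator over the identical valid-pair index set); with uniform
    weights this reduces exactly to the unbiased mode.
    """
    r = np.asarray(values, dtype=float)
    if lag_steps < 1:
        raise InvalidParameterError("lag must be >= 1 step")
    if r.size <= lag_steps:
        raise InsufficientDataError("trajectory not longer than the lag")
    disp = np.abs(r[lag_steps:] - r[:-lag_steps])
    if mode == "unbiased":
        return float(disp.mean())
    if mode == "metad":
        if weights is None:
            raise InvalidInputError("metad mode requires weights")
        w = np.asarray(weights, dtype=float)[: r.size - lag_steps]
        if w.size != disp.size:
            raise DimensionError("weights do not cover the valid-pair set")
        return float(np.sum(w * disp) / np.sum(w))
    raise InvalidParameterError(f"unknown mode {mode!r}")


@dataclass
class WeightedTrajectory:
    """Biased trajectory frames with bias, correction and unbiasing weights."""

    data: pd.DataFrame
    cv_cols: tuple[str, ...]
    bias: np.ndarray
    correction: np.ndarray
    temperature: float = 300.0
    kB: float = KB_KJ_MOL_K

    def __post_init__(self):
        n = len(self.data)
        self.bias = np.asarray(self.bias, dtype=float)
        self.correction = np.asarray(self.correction, dtype=float)
        if self.bias.shape != (n,) or self.correction.shape != (n,):
            raise DimensionError("bias/correction length must match frames")

    @property
    def weights(self) -> np.ndarray:
        return frame_weights(self.bias, self.correction, self.temperature, self.kB)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def dt(self) -> float:
        t = self.times
        return float(t[1] - t[0]) if t.size > 1 else 1.0


def reweight_trajectory(colvar: pd.DataFrame, hills: HillsLog, cv_cols,
                        temperature: float | None = None, bias_col=None,
                        grid_bins: int = 200,
                        kB: float | None = None) -> WeightedTrajectory:
    """Attach Tiwary-Parrinello unbiasing weights to a biased COLVAR table.

    The per-frame bias is taken from ``bias_col`` when the run logged it, and
    re-evaluated from the hills otherwise; c(t) is computed on a grid and
    interpolated at frame times.
    """
    T = hills.temperature if temperature is None else temperature
    kB = hills.kB if kB is None else kB
    cv_cols = tuple(cv_cols)
    t = colvar["time"].to_numpy(dtype=float)
    if bias_col is not None and bias_col in colvar:
        V = colvar[bias_col].to_numpy(dtype=float)
    else:
        pts = colvar[list(cv_cols)].to_numpy(dtype=float)
        V = bias_at_frames(hills, pts, t)
    corr = bias_correction_series(hills, temperature=T, bins=grid_bins, kB=kB)
    c = corr(t)
    return WeightedTrajectory(
        data=colvar, cv_cols=cv_cols, bias=V, correction=c,
        temperature=T, kB=kB,
    )
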