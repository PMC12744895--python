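"""Percent signal enhancement and empirical enhancement-model fitting.

The early postcontrast enhancement of a voxel or region is summarized as
percent signal enhancement (PSE) relative to the mean precontrast signal:

    PSE(t) = 100 * (S(t) - Spre) / Spre

Enhancement curves are fit with an empirical model of contrast uptake.
At the voxel level a two-parameter form is used to avoid over-fitting
noisy single-voxel data:

    PSE(t) = A * alpha * t^2 / (1 + alpha * t^2)

with A the saturation amplitude (percent) and alpha (1/min) the initial
uptake rate; the product A*alpha is the maximum enhancement-rate proxy used
for clustering. Cluster-averaged curves have enough SNR for a third
parameter, the washout rate beta (1/min, may be negative for persistently
enhancing tissue):

    PSE_c(t) = A * alpha * t^2 / (1 + alpha * t^2) * exp(-beta * t)

The secondary parameter AUC30 integrates the three-parameter curve over the
first 30 s (t30 = 0.5 min).

The fit time origin is the last precontrast frame: the model forces
PSE(0) = 0, so t = 0 must sit at the bolus-adjacent frame. Only
postcontrast frames enter the fits.

The two-parameter fit is solved by variable projection: for fixed alpha the
amplitude A enters linearly and has a closed-form least-squares solution, so
the fit reduces to a 1D search over alpha (coarse log-grid bracketing plus
bounded Brent refinement). This is deterministic and fast enough to run on
every voxel of a volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .io_core import DataError, DynamicSeries, RegionLabels

logger = logging.getLogger(__name__)

A_BOUNDS = (0.0, 1000.0)        # percent
ALPHA_BOUNDS = (0.0, 100.0)     # 1/min
BETA_BOUNDS = (-2.0, 10.0)      # 1/min
LOW_ENHANCEMENT_PSE = 5.0       # percent; below this a voxel is flagged

T30 = 0.5  # minutes; upper limit of the early-enhancement integral


@dataclass(frozen=True)
class PseCurve:
    """Enhancement time course of a voxel, region or cluster.

    ``times`` are minutes relative to the fit origin (last precontrast
    frame), so precontrast frames have t <= 0; ``baseline`` is the mean
    precontrast signal the PSE was normalized by; ``n_voxels`` counts the
    voxels averaged into the curve (1 for a single voxel).
    """

    times: np.ndarray
    pse: np.ndarray
    baseline: float
    n_voxels: int = 1

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pse, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pse", p)
        if t.shape != p.shape:
            raise DataError("times and pse must have equal length")
        if not self.baseline > 0:
            raise DataError("baseline must be positive")

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.times > 0]

    @property
    def post_pse(self) -> np.ndarray:
        return self.pse[self.times > 0]


@dataclass(frozen=True)
class EmmTwoFit:
    A: float
    alpha: float
    rss: float
    converged: bool
    low_enhancement: bool = False

    @property
    def a_alpha(self) -> float:
        return self.A * self.alpha


@dataclass(frozen=True)
class EmmThreeFit:
    A: float
    alpha: float
    beta: float
    auc30: float
    rss: float
    converged: bool
    low_enhancement: bool = False

    @property
    def a_alpha(self) -> float:
        return self.A * self.alpha


def fit_times(series: DynamicSeries, origin_offset: float = 0.0) -> np.ndarray:
    """Frame times (minutes) shifted so t=0 is the last precontrast frame,
    optionally moved by ``origin_offset`` minutes (bolus-arrival shift)."""
    origin = series.frame_times[series.n_precontrast - 1] + origin_offset
    return series.frame_times - origin


def compute_pse(series: DynamicSeries, selector) -> PseCurve:
    """PSE curve of a single voxel (index triple) or a region (boolean mask).

    For a mask the raw signal is averaged across voxels first and the PSE
    computed from the averaged curve with its own mean precontrast baseline
    (averaging raw signal, not per-voxel PSE).
    """
    if isinstance(selector, tuple):
        sig = series.voxels[selector]
        n_vox = 1
    else:
        mask = np.asarray(selector, dtype=bool)
        if mask.shape != series.shape:
            raise DataError("selector mask does not match series grid")
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise DataError("empty selector mask")
        sig = series.voxels[mask].mean(axis=0)
    baseline = float(sig[: series.n_precontrast].mean())
    if baseline <= 0:
        raise DataError("non-positive precontrast baseline")
    pse = 100.0 * (sig - baseline) / baseline
    return PseCurve(times=fit_times(series), pse=pse, baseline=baseline,
                    n_voxels=n_vox)


def emm2_eval(A: float, alpha: float, t) -> np.ndarray:
    """Two-parameter uptake model A*alpha*t^2/(1+alpha*t^2); 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    tt = np.clip(t, 0.0, None) ** 2
    return A * alpha * tt / (1.0 + alpha * tt)


def emm3_eval(A: float, alpha: float, beta: float, t) -> np.ndarray:
    """Three-parameter model with exponential washout; 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = emm2_eval(A, alpha, t) * np.exp(-beta * np.clip(t, 0.0, None))
    return out


def auc30(A: float, alpha: float, beta: float = 0.0, t30: float = T30) -> float:
    """Integral of the three-parameter enhancement curve over [0, t30] min.

    For beta = 0 this has the closed form A*(t30 - arctan(sqrt(alpha)*t30)
    / sqrt(alpha)), used directly; otherwise adaptive quadrature at absolute
    tolerance 1e-8. Units: percent * min.
    """
    if A == 0.0 or alpha == 0.0:
        return 0.0
    if beta == 0.0:
        ra = np.sqrt(alpha)
        return float(A * (t30 - np.arctan(ra * t30) / ra))
    val, _ = integrate.quad(lambda t: emm3_eval(A, alpha, beta, t),
                            0.0, t30, epsabs=1e-8, epsrel=1e-10)
    return float(val)


# ---------------------------------------------------------------------------
# two-parameter fit (variable projection over alpha)

def _proj_amplitude(y: np.ndarray, f: np.ndarray) -> float:
    denom = float(f @ f)
    if denom <= 0.0:
        return 0.0
    return float(np.clip((y @ f) / denom, *A_BOUNDS))

def _vp_rss(alpha: float, t2: np.ndarray, y: np.ndarray) -> float:
    f = alpha * t2 / (1.0 + alpha * t2)
    a = _proj_amplitude(y, f)
    r = y - a * f
    return float(r @ r)


def fit_emm2_curve(curve: PseCurve) -> EmmTwoFit:
    """Least-squares two-parameter fit of a single PSE curve."""
    t = curve.post_times
    y = curve.post_pse
    if t.size < 4:
        raise DataError("need >= 4 postcontrast frames for the 2-param fit")
    return _fit_emm2_arrays(t, y)


def _fit_emm2_arrays(t: np.ndarray, y: np.ndarray) -> EmmTwoFit:
    t2 = t * t
    peak = float(np.max(y)) if y.size else 0.0
    if peak < LOW_ENHANCEMENT_PSE:
        # still fit, but flag: these voxels carry little kinetic information
        low = True
    else:
        low = False
    # coarse log-grid bracket, then Brent refinement inside the bracket
    grid = np.concatenate(([0.0], np.geomspace(1e-3, ALPHA_BOUNDS[1], 60)))
    rss_grid = np.array([_vp_rss(a, t2, y) for a in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:
        alpha = float(lo)
    else:
        res = optimize.minimize_scalar(
            _vp_rss, bounds=(lo, hi), args=(t2, y), method="bounded",
            options={"xatol": 1e-12, "maxiter": 500},
        )
        alpha = float(res.x)
        if _vp_rss(alpha, t2, y) > rss_grid[i]:
            alpha = float(grid[i])
    f = alpha * t2 / (1.0 + alpha * t2)
    A = _proj_amplitude(y, f)
    rss = float(np.sum((y - A * f) ** 2))
    if A == 0.0:
        alpha = 0.0
    return EmmTwoFit(A=A, alpha=alpha, rss=rss, converged=True,
                     low_enhancement=low)


def fit_emm2_voxelwise(
    series: DynamicSeries,
    labels: RegionLabels,
    region: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-voxel two-parameter fits over one region (or all foreground).

    Returns 3D maps ``A``, ``alpha``, ``a_alpha``, ``rss`` (NaN outside the
    region and at invalid voxels) plus boolean ``valid`` and
    ``low_enhancement`` masks. Voxels with non-positive baseline are invalid
    and excluded downstream.
    """
    if labels.labels.shape != series.shape:
        raise DataError("label grid does not match series grid")
    if region is None:
        mask = np.isin(labels.labels, (1, 2, 3))
    else:
        mask = labels.mask(region)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise DataError(f"region {region}: no voxels to fit")

    t_all = fit_times(series)
    post = t_all > 0
    t = t_all[post]
    if t.size < 4:
        raise DataError("need >= 4 postcontrast frames")
    npre = series.n_precontrast

    shape = series.shape
    A = np.full(shape, np.nan)
    alpha = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    low = np.zeros(shape, dtype=bool)

    sig = series.voxels[mask]              # (n_vox, n_frames)
    baselines = sig[:, :npre].mean(axis=1)
    good = baselines > 0
    n_bad = int((~good).sum())

    # vectorized variable-projection scan: for each candidate alpha the
    # best A is closed-form, so the coarse bracketing runs as one matmul
    t2 = t * t
    grid = np.geomspace(1e-3, ALPHA_BOUNDS[1], 60)
    F = grid[:, None] * t2 / (1.0 + grid[:, None] * t2)   # (n_alpha, n_t)
    denom = (F * F).sum(axis=1)                           # (n_alpha,)

    Y = 100.0 * (sig[good][:, post] - baselines[good, None]) / baselines[good, None]
    num = Y @ F.T                                         # (n_vox, n_alpha)
    Astar = np.clip(num / denom, *A_BOUNDS)
    yy = (Y * Y).sum(axis=1)
    rss_grid = yy[:, None] - 2.0 * Astar * num + Astar ** 2 * denom
    best = np.argmin(rss_grid, axis=1)

    gidx = idx[good]
    for row in range(Y.shape[0]):
        y = Y[row]
        i_g = best[row]
        lo = grid[max(i_g - 1, 0)]
        hi = grid[min(i_g + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            _vp_rss, bounds=(lo, hi), args=(t2, y), method="bounded",
            options={"xatol": 1e-12, "maxiter": 500})
        al = float(res.x)
        rss_al = _vp_rss(al, t2, y)
        # a flat (zero-enhancement) voxel is best served by alpha = A = 0
        if yy[row] <= rss_al:
            al, a_, r_ = 0.0, 0.0, float(yy[row])
        else:
            f = al * t2 / (1.0 + al * t2)
            a_ = _proj_amplitude(y, f)
            r_ = float(np.sum((y - a_ * f) ** 2))
            if a_ == 0.0:
                al = 0.0
        i, j, k = gidx[row]
        A[i, j, k] = a_
        alpha[i, j, k] = al
        rss[i, j, k] = r_
        valid[i, j, k] = True
        low[i, j, k] = float(np.max(y)) < LOW_ENHANCEMENT_PSE
    if n_bad:
        logger.warning("%d voxels with non-positive baseline excluded", n_bad)
    if not valid.any():
        raise DataError("all voxel fits failed in region")
    return {"A": A, "alpha": alpha, "a_alpha": A * alpha, "rss": rss,
            "valid": valid, "low_enhancement": low}


# ---------------------------------------------------------------------------
# three-parameter cluster-curve fit

def fit_emm3_curve(curve: PseCurve) -> EmmThreeFit:
    """Bounded least-squares three-parameter fit of a cluster-mean curve.

    Initialized from the two-parameter fit with beta = 0; AUC30 is attached
    by quadrature. Non-convergence flags the fit instead of discarding it.
    """
    t = curve.post_times
    y = curve.post_pse
    if t.size < 5:
        raise DataError("need >= 5 postcontrast frames for the 3-param fit")
    init2 = _fit_emm2_arrays(t, y)
    x0 = np.array([max(init2.A, 1e-3), max(init2.alpha, 1e-3), 0.0])

    def resid(p):
        return emm3_eval(p[0], p[1], p[2], t) - y

    lb = [A_BOUNDS[0], ALPHA_BOUNDS[0], BETA_BOUNDS[0]]
    ub = [A_BOUNDS[1], ALPHA_BOUNDS[1], BETA_BOUNDS[1]]
    x0 = np.clip(x0, lb, ub)
    sol = optimize.least_squares(resid, x0, bounds=(lb, ub),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                 max_nfev=500 * 3)
    A_, al, be = (float(v) for v in sol.x)
    converged = bool(sol.success)
    if not converged:
        logger.warning("3-parameter fit did not converge: %s", sol.message)
    lowflag = float(np.max(y)) < LOW_ENHANCEMENT_PSE if y.size else True
    return EmmThreeFit(A=A_, alpha=al, beta=be,
                       auc30=auc30(A_, al, be),
                       rss=float(2 * sol.cost), converged=converged,
                       low_enhancement=lowflag)
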