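"""Concentration conversion, population AIF and extended Tofts model.

Cluster-mean enhancement curves are converted to tissue contrast-agent
concentration C(t) and fit with the extended Tofts model (ETM)

    C(t) = vp * Cp(t) + Ktrans * int_0^t Cp(tau) exp(-(Ktrans/ve)(t - tau)) dtau

where Ktrans (1/min) is the volume transfer constant, ve the extravascular
extracellular fraction, vp the plasma fraction and Cp(t) the arterial input
function. The rate constant Kep = Ktrans/ve is derived after the fit and the
identity Kep*ve = Ktrans holds exactly in every emitted fit.

Signal-to-concentration conversion inverts the spoiled gradient echo (SPGR)
steady-state signal equation using the tissue's precontrast T1 (``spgr``
mode), or uses the small-enhancement linear approximation
C = PSE / (100 * r1 * T10) (``linear`` mode). Which mode produced a result
is recorded with the result.

The default Cp(t) is the widely used population AIF composed of two
Gaussian bolus terms plus an exponential body washout modulated by a
sigmoid, with its published parameter vector (in mM and minutes). The
functional form is pluggable: any parameter vector of the same family, or a
user-supplied callable, can be configured instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io_core import DataError
from .kinetics import PseCurve

logger = logging.getLogger(__name__)

KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-3, 1.0)
VP_BOUNDS = (0.0, 0.2)

# deterministic multistart points (ktrans, ve, vp)
_STARTS = (
    (0.1, 0.3, 0.01),
    (0.5, 0.6, 0.002),
    (0.02, 0.1, 0.05),
)

#: Bi-Gaussian + sigmoid-modulated exponential population AIF parameters:
#: A_n [mmol*min], T_n [min], sigma_n [min] for the two Gaussians;
#: alpha [mM], beta [1/min], s [1/min], tau [min] for the washout term.
PARKER_PARAMS = {
    "A1": 0.809, "A2": 0.330,
    "T1": 0.17046, "T2": 0.365,
    "sigma1": 0.0563, "sigma2": 0.132,
    "alpha": 1.050, "beta": 0.1685,
    "s": 38.078, "tau": 0.483,
}


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tissue concentration (mM) on the fit time axis (minutes)."""

    times: np.ndarray
    conc: np.ndarray
    mode: str = "spgr"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.shape != c.shape:
            raise DataError("times and conc must have equal length")
        if not np.all(np.isfinite(c)):
            raise DataError("non-finite concentration values")


@dataclass(frozen=True)
class PopulationAif:
    """Population arterial input function Cp(t) in mM, t in minutes.

    Cp is zero before ``bolus_arrival`` and the whole curve is shifted by
    it. The default parameters are the published population values for the
    bi-Gaussian + sigmoidal-exponential form.
    """

    params: dict = field(default_factory=lambda: dict(PARKER_PARAMS))
    bolus_arrival: float = 0.0
    form: str = "parker"

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ts = t - self.bolus_arrival
        p = self.params
        out = np.zeros_like(ts)
        pos = ts > 0
        u = ts[pos]
        g1 = p["A1"] / (p["sigma1"] * np.sqrt(2 * np.pi)) * np.exp(
            -((u - p["T1"]) ** 2) / (2 * p["sigma1"] ** 2))
        g2 = p["A2"] / (p["sigma2"] * np.sqrt(2 * np.pi)) * np.exp(
            -((u - p["T2"]) ** 2) / (2 * p["sigma2"] ** 2))
        wash = p["alpha"] * np.exp(-p["beta"] * u) / (
            1.0 + np.exp(-p["s"] * (u - p["tau"])))
        out[pos] = g1 + g2 + wash
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class ToftsFit:
    ktrans: float
    ve: float
    vp: float
    rss: float
    converged: bool

    @property
    def kep(self) -> float:
        """Reverse rate constant, Ktrans/ve (1/min)."""
        return self.ktrans / self.ve


# ---------------------------------------------------------------------------
# signal <-> concentration

def _spgr_rel(E1: np.ndarray, cos_fa: float) -> np.ndarray:
    """SPGR signal up to the M0*sin(fa) factor."""
    return (1.0 - E1) / (1.0 - cos_fa * E1)


def spgr_signal_ratio(conc, t10_s: float, relaxivity: float, tr_s: float,
                      flip_deg: float) -> np.ndarray:
    """Forward model: S(t)/S0 for tissue concentration ``conc`` (mM)."""
    conc = np.asarray(conc, dtype=float)
    cos_fa = np.cos(np.deg2rad(flip_deg))
    r10 = 1.0 / t10_s
    r1 = r10 + relaxivity * conc
    e1 = np.exp(-tr_s * r1)
    e10 = np.exp(-tr_s * r10)
    return _spgr_rel(e1, cos_fa) / _spgr_rel(e10, cos_fa)


def pse_to_concentration(
    curve: PseCurve,
    t10_s: float = 1.4,
    relaxivity: float = 5.0,
    tr_s: float = 0.004,
    flip_deg: float = 10.0,
    mode: str = "spgr",
) -> ConcentrationCurve:
    """Convert a PSE curve to tissue concentration (mM).

    ``spgr`` inverts the spoiled-gradient-echo signal equation (the signal
    ratio S/S0 = 1 + PSE/100 determines R1(t), then
    C = (R1 - 1/T10)/r1); ``linear`` applies the small-enhancement
    approximation. Frames whose signal ratio falls outside the invertible
    range of the SPGR equation are clipped to the boundary and logged.
    """
    if min(t10_s, relaxivity, tr_s) <= 0 or not (0 < flip_deg < 90):
        raise DataError("conversion constants out of range")
    pse = np.clip(curve.pse, None, None)
    if mode == "linear":
        conc = (pse / 100.0) / (relaxivity * t10_s)
        conc = np.where(curve.times <= 0, 0.0, conc)
        return ConcentrationCurve(times=curve.times, conc=conc, mode=mode)
    if mode != "spgr":
        raise ValueError(f"unknown conversion mode {mode!r}")

    cos_fa = np.cos(np.deg2rad(flip_deg))
    r10 = 1.0 / t10_s
    e10 = np.exp(-tr_s * r10)
    base_rel = _spgr_rel(np.array(e10), cos_fa)
    rel = (1.0 + pse / 100.0) * base_rel            # S(t)/(M0 sin(fa))
    # invert (1-E1)/(1-cos*E1) = rel  ->  E1 = (1-rel)/(1-rel*cos)
    e1 = (1.0 - rel) / (1.0 - rel * cos_fa)
    n_clip = int(np.sum((e1 <= 0) | (e1 >= 1)))
    if n_clip:
        logger.warning("%d frames outside SPGR invertible range; clipped",
                       n_clip)
    e1 = np.clip(e1, 1e-12, 1.0 - 1e-12)
    r1 = -np.log(e1) / tr_s
    conc = (r1 - r10) / relaxivity
    conc = np.where(curve.times <= 0, 0.0, conc)
    return ConcentrationCurve(times=curve.times, conc=conc, mode=mode)


def eval_population_aif(aif: PopulationAif, t) -> np.ndarray:
    return aif(t)


# ---------------------------------------------------------------------------
# extended Tofts forward model and fit

def _exp_conv_piecewise_linear(times: np.ndarray, cp: np.ndarray,
                               kep: float) -> np.ndarray:
    """Exact convolution int_0^t cp(tau) exp(-kep (t-tau)) dtau for a
    piecewise-linear cp on the (possibly non-uniform) grid ``times``.

    Each interval contributes g_j = c_j*phi1 + (c_{j+1}-c_j)*phi2 with the
    exact exponential-kernel weights; the running sum is evaluated with
    scaled cumulative sums in blocks sized so that no intermediate
    exponential overflows.
    """
    n = times.size
    out = np.zeros(n)
    if n < 2:
        return out
    h = np.diff(times)
    x = kep * h
    e = np.exp(-x)
    small = x < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        phi1 = np.where(small, h * (1 - x / 2 + x * x / 6), (1 - e) / kep)
        phi2 = np.where(small, h * (0.5 - x / 3 + x * x / 8),
                        (x - 1 + e) / np.where(small, 1.0, kep * kep * h))
    g = cp[:-1] * phi1 + np.diff(cp) * phi2       # interval contributions

    # blockwise scaled cumsum: within a block, I_n = exp(-kep (t_n - t_a))
    # * (acc + sum_j g_j exp(kep (t_{j+1} - t_a))); block span limited so
    # the positive exponent stays < 50
    max_span = 50.0 / kep if kep > 0 else np.inf
    acc = 0.0
    a = 0
    while a < n - 1:
        b = n - 1 if not np.isfinite(max_span) else min(
            n - 1, a + max(1, int(np.searchsorted(
                times, times[a] + max_span, side="right") - a)))
        t_a = times[a]
        w = g[a:b] * np.exp(kep * (times[a + 1:b + 1] - t_a))
        s = np.cumsum(w)
        out[a + 1:b + 1] = np.exp(-kep * (times[a + 1:b + 1] - t_a)) \
            * (acc + s)
        acc = out[b]
        a = b
    return out


def etm_forward(ktrans: float, ve: float, vp: float, aif: PopulationAif,
                times, refine: int = 100) -> ConcentrationCurve:
    """Extended Tofts forward model sampled at ``times`` (minutes).

    The convolution uses the exact exponential-kernel recursion for
    piecewise-linear Cp on a grid refined by ``refine`` relative to the
    frame spacing (the AIF bolus is much sharper than the frame interval;
    the default keeps the absolute error below 1e-5 mM).
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DataError("times must be strictly increasing")
    t_hi = times[-1]
    spacing = np.min(np.diff(times)) if times.size > 1 else times[-1]
    step = spacing / max(refine, 1)
    dense = np.arange(0.0, t_hi + step / 2, step)
    grid = np.union1d(dense, times[times >= 0])
    if grid[0] > 0:
        grid = np.concatenate(([0.0], grid))
    cp = aif(grid)
    kep = ktrans / ve if ve > 0 else 0.0
    conv = _exp_conv_piecewise_linear(grid, cp, kep)
    c_grid = vp * cp + ktrans * conv
    conc = np.interp(times, grid, c_grid)
    conc[times <= 0] = 0.0
    return ConcentrationCurve(times=times, conc=conc, mode="model")


def fit_etm(curve: ConcentrationCurve, aif: PopulationAif,
            refine: int = 100) -> ToftsFit:
    """Bounded least-squares ETM fit of a concentration curve.

    Three deterministic starting points guard against local minima; the
    lowest-RSS solution wins, ties to the first start.
    """
    post = curve.times > 0
    t = curve.times[post]
    y = curve.conc[post]
    if t.size < 6:
        raise DataError("need >= 6 postcontrast frames for the ETM fit")

    lb = [KTRANS_BOUNDS[0], VE_BOUNDS[0], VP_BOUNDS[0]]
    ub = [KTRANS_BOUNDS[1], VE_BOUNDS[1], VP_BOUNDS[1]]

    def resid(p):
        model = etm_forward(p[0], p[1], p[2], aif, t, refine=refine)
        return model.conc - y

    best = None
    for x0 in _STARTS:
        sol = optimize.least_squares(resid, np.clip(x0, lb, ub),
                                     bounds=(lb, ub), xtol=1e-12, ftol=1e-12,
                                     gtol=1e-12, max_nfev=2000)
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    kt, ve, vp = (float(v) for v in best.x)
    converged = bool(best.success)
    if not converged:
        logger.warning("ETM fit flagged: %s", best.message)
    if np.max(np.abs(y)) < 1e-12:
        # zero curve: parameters pinned at the lower boundary, flag it
        converged = False
    return ToftsFit(ktrans=kt, ve=ve, vp=vp, rss=float(2 * best.cost),
                    converged=converged)
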