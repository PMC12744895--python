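"""Synthetic bilateral-breast DCE phantom and cohort simulator.

No clinical cohort ships with this package, so every end-to-end test runs
on synthetic data with known ground truth, at two levels:

**Voxel level** (:func:`generate_phantom`): a rectangular bilateral volume
with two mirror-symmetric breast blocks, each holding a parenchyma slab
subdivided into five bands of increasing enhancement kinetics (so K = 5
clustering has genuine structure to find), an ellipsoidal tumor carved into
the ipsilateral slab (its mirror cavity is carved from the contralateral
slab too, keeping the parenchymal geometry bilaterally identical), and
optional vessel lines. Two generation modes cover the two model families
used downstream:

* ``signal`` mode — each voxel's noiseless enhancement follows the
  three-parameter empirical model directly, giving exact truth for the
  enhancement-model fitting stages;
* ``concentration`` mode — each voxel follows the extended Tofts model
  driven by the population AIF, mapped to signal through the SPGR forward
  equation, giving exact truth for the pharmacokinetic stage.

Bilateral asymmetry is imposed by multiplying the ipsilateral uptake rate
(alpha, or Ktrans in concentration mode) by the factor ``asymmetry_r``
relative to its mirrored contralateral counterpart, so the ground-truth
A*alpha (or Ktrans) I/C ratio equals ``asymmetry_r`` exactly. Within-band
heterogeneity is drawn per voxel from a mean-preserving log-normal; the
per-voxel draw is made on the contralateral side and mirrored, so with
``asymmetry_r = 1`` and zero noise the two breasts are voxelwise identical.

**Patient level** (:func:`generate_cohort`): per-patient kinetic feature
vectors for a pCR and a non-pCR group drawn from configurable group
distributions (defaults reproduce the published group means and SDs of the
bilateral-asymmetry and tumor-kinetics tables), plus clinical covariates
with realistic frequencies, truncated at physical bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .io_core import (DataError, DynamicSeries, RegionLabels,
                      IPSILATERAL_PARENCHYMA, CONTRALATERAL_PARENCHYMA,
                      TUMOR, VESSEL)
from .kinetics import emm3_eval
from .pharmacokinetics import PopulationAif, spgr_signal_ratio

# ---------------------------------------------------------------------------
# voxel-level phantom

#: default five-band kinetics, slowest to fastest (percent, 1/min, 1/min)
PARENCHYMA_BANDS = {
    "A": (15.0, 25.0, 35.0, 45.0, 60.0),
    "alpha": (0.5, 0.9, 1.4, 2.0, 2.8),
    "beta": (0.0, 0.01, 0.02, 0.03, 0.05),
}
TUMOR_BANDS = {
    "A": (80.0, 110.0, 140.0, 170.0, 200.0),
    "alpha": (4.0, 8.0, 12.0, 16.0, 20.0),
    "beta": (-0.04, -0.02, 0.0, 0.02, 0.04),
}
VESSEL_KINETICS = {"A": 250.0, "alpha": 30.0, "beta": 0.3}

#: default five-band extended-Tofts truth for concentration mode
PARENCHYMA_BANDS_ETM = {
    "ktrans": (0.02, 0.04, 0.06, 0.09, 0.13),
    "ve": (0.15, 0.20, 0.25, 0.30, 0.35),
    "vp": (0.002, 0.003, 0.004, 0.005, 0.006),
}
TUMOR_BANDS_ETM = {
    "ktrans": (0.05, 0.10, 0.21, 0.35, 0.50),
    "ve": (0.20, 0.25, 0.33, 0.45, 0.60),
    "vp": (0.001, 0.003, 0.006, 0.012, 0.020),
}


@dataclass
class PhantomSpec:
    """Geometry, kinetics, schedule and noise of one synthetic patient."""

    shape: tuple[int, int, int] = (32, 64, 8)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)
    laterality: str = "left"              # side holding the tumor
    n_precontrast: int = 5
    n_postcontrast: int = 18
    spacing_s: float = 5.0                # frame spacing, must sit in [3, 9]
    mode: str = "signal"                  # "signal" | "concentration"
    s0: float = 500.0                     # tissue baseline signal
    background_s0: float = 25.0
    noise: str = "none"                   # "none" | "gaussian" | "rician"
    noise_sd_frac: float = 0.0            # SD as fraction of s0
    asymmetry_r: float = 1.0              # ipsi/contra uptake-rate factor
    dispersion_sigma: float = 0.15        # log-normal sigma within a band
    seed: int = 0
    include_vessels: bool = True
    parenchyma_bands: dict = field(default_factory=lambda: dict(PARENCHYMA_BANDS))
    tumor_bands: dict = field(default_factory=lambda: dict(TUMOR_BANDS))
    parenchyma_bands_etm: dict = field(default_factory=lambda: dict(PARENCHYMA_BANDS_ETM))
    tumor_bands_etm: dict = field(default_factory=lambda: dict(TUMOR_BANDS_ETM))
    # SPGR constants for concentration mode
    tr_s: float = 0.004
    flip_deg: float = 10.0
    t10_s: float = 1.4
    relaxivity: float = 5.0
    aif: PopulationAif = field(default_factory=PopulationAif)

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    def validate(self) -> None:
        if self.asymmetry_r <= 0:
            raise DataError("asymmetry_r must be > 0")
        if self.noise_sd_frac < 0:
            raise DataError("noise amplitude must be >= 0")
        if not (3.0 <= self.spacing_s <= 9.0):
            raise DataError("frame spacing must lie in [3, 9] s")
        if self.mode not in ("signal", "concentration"):
            raise DataError(f"unknown phantom mode {self.mode!r}")
        if self.noise not in ("none", "gaussian", "rician"):
            raise DataError(f"unknown noise model {self.noise!r}")
        if min(self.shape) < 8 or self.shape[0] < 16:
            raise DataError("grid too small for the bilateral geometry")


@dataclass
class PhantomTruth:
    """Ground truth: region/band table plus per-voxel parameter maps."""

    table: pd.DataFrame
    voxel_maps: dict[str, np.ndarray]
    mode: str
    asymmetry_r: float


def _geometry(spec: PhantomSpec):
    """Region masks. Axis 0 is left-right; the tumor-bearing (ipsilateral)
    side is ``spec.laterality``. Returns masks + band index map (0..4 inside
    parenchyma/tumor, -1 elsewhere)."""
    nx, ny, nz = spec.shape
    half = nx // 2
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]

    left = x < half
    ips_side = left if spec.laterality == "left" else ~left

    # parenchyma slab, mirror-symmetric in x
    mx = (x >= 2) & (x <= half - 3) | (x >= nx - half + 2) & (x <= nx - 3)
    y_lo, y_hi = max(2, ny // 8), ny - max(2, ny // 8) - 1
    z_lo, z_hi = 1, nz - 2
    slab = mx & (y >= y_lo) & (y <= y_hi) & (z >= z_lo) & (z <= z_hi)
    slab = np.broadcast_to(slab, spec.shape).copy()

    # five kinetic bands along y
    band = np.full(spec.shape, -1, dtype=np.int8)
    edges = np.linspace(y_lo, y_hi + 1, 6).astype(int)
    for b in range(5):
        in_band = slab & (y >= edges[b]) & (y < edges[b + 1])
        band[np.broadcast_to(in_band, spec.shape)] = b

    # ellipsoidal tumor inside the ipsilateral slab; mirror cavity on the
    # contralateral side keeps the parenchymal geometry bilaterally equal
    cx_l = (2 + half - 3) / 2.0
    cx = cx_l if spec.laterality == "left" else nx - 1 - cx_l
    cy, cz = (y_lo + y_hi) / 2.0, (z_lo + z_hi) / 2.0
    rx, ry, rz = (half - 5) / 2.0, (y_hi - y_lo) / 5.0, max((nz - 3) / 2.0, 1.5)
    d2 = (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)
    d2 = np.broadcast_to(d2, spec.shape)
    tumor = (d2 <= 1.0) & slab
    if not tumor.any():
        raise DataError("degenerate geometry: empty tumor")
    ips3 = np.broadcast_to(ips_side, spec.shape)
    if not np.all(ips3[tumor]):
        raise DataError("tumor crosses the midline")
    cavity = tumor | tumor[::-1, :, :]   # tumor plus its mirror image

    parenchyma = slab & ~cavity
    ips_par = parenchyma & np.broadcast_to(ips_side, spec.shape)
    con_par = parenchyma & ~np.broadcast_to(ips_side, spec.shape)

    vessel = np.zeros(spec.shape, dtype=bool)
    if spec.include_vessels:
        vy = slice(ny // 3, 2 * ny // 3)
        vessel[half - 2, vy, z_lo] = True
        vessel[nx - half + 1, vy, z_lo] = True
        vessel &= ~cavity

    # tumor radial quintile bands (equal-count shells, innermost = band 4,
    # i.e. the fastest kinetics sit at the core)
    t_idx = np.argwhere(tumor)
    radii = d2[tumor]
    order = np.argsort(radii, kind="stable")
    shells = np.array_split(order, 5)
    tumor_band = np.full(spec.shape, -1, dtype=np.int8)
    for b, shell in enumerate(shells):
        for row in t_idx[shell]:
            tumor_band[tuple(row)] = 4 - b
    return ips_par, con_par, tumor, vessel, band, tumor_band


def _mirror(arr: np.ndarray) -> np.ndarray:
    return arr[::-1, :, :]


def _lognormal_field(rng: np.random.Generator, shape, sigma: float
                     ) -> np.ndarray:
    """Mean-1 log-normal multiplier field."""
    if sigma == 0:
        return np.ones(shape)
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=shape)


def _etm_conc_many(times: np.ndarray, cp: np.ndarray, ktrans: np.ndarray,
                   kep: np.ndarray, vp: np.ndarray) -> np.ndarray:
    """Extended-Tofts curves for many voxels at once (exact exponential
    recursion for piecewise-linear Cp), times already refined."""
    n_vox = ktrans.size
    out = np.zeros((n_vox, times.size))
    acc = np.zeros(n_vox)
    for j in range(times.size - 1):
        h = times[j + 1] - times[j]
        x = kep * h
        e = np.exp(-x)
        small = x < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            phi1 = np.where(small, h * (1 - x / 2 + x * x / 6), (1 - e) / kep)
            phi2 = np.where(small, h * (0.5 - x / 3 + x * x / 8),
                            (x - 1 + e) / (kep * kep * h))
        acc = acc * e + cp[j] * phi1 + (cp[j + 1] - cp[j]) * phi2
        out[:, j + 1] = acc
    return vp[:, None] * cp[None, :] + ktrans[:, None] * out


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[DynamicSeries, RegionLabels, PhantomTruth]:
    """Build the synthetic series, label map and ground-truth tables."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ips_par, con_par, tumor, vessel, band, tumor_band = _geometry(spec)
    shape = spec.shape

    n_frames = spec.n_precontrast + spec.n_postcontrast
    times_min = np.arange(n_frames) * spec.spacing_s / 60.0
    t_rel = times_min - times_min[spec.n_precontrast - 1]   # 0 at last pre

    labels = np.zeros(shape, dtype=np.int16)
    labels[ips_par] = IPSILATERAL_PARENCHYMA
    labels[con_par] = CONTRALATERAL_PARENCHYMA
    labels[tumor] = TUMOR
    labels[vessel] = VESSEL

    if spec.mode == "signal":
        names = ("A", "alpha", "beta")
        par_bands, tum_bands = spec.parenchyma_bands, spec.tumor_bands
        scaled = "alpha"          # rate scaled by the asymmetry factor
    else:
        names = ("ktrans", "ve", "vp")
        par_bands, tum_bands = spec.parenchyma_bands_etm, spec.tumor_bands_etm
        scaled = "ktrans"

    maps = {n: np.full(shape, np.nan) for n in names}

    # contralateral parenchyma first; per-voxel dispersion drawn there and
    # mirrored so that asymmetry_r = 1 gives voxelwise identical breasts
    rows = []
    for b in range(5):
        m_con = con_par & (band == b)
        if not m_con.any():
            raise DataError("degenerate geometry: empty parenchyma band")
        vals = {}
        for n in names:
            base = par_bands[n][b]
            disp = _lognormal_field(rng, int(m_con.sum()), spec.dispersion_sigma)
            vals[n] = base * disp if n in ("A", "alpha", "ktrans") else \
                np.clip(base * disp, None, 1.0) if n == "ve" else base * disp
            maps[n][m_con] = vals[n]
        rows.append({"region": "contralateral_parenchyma", "band": b + 1,
                     "n_voxels": int(m_con.sum()),
                     **{n: par_bands[n][b] for n in names}})
    for n in names:
        mirrored = _mirror(maps[n])
        factor = spec.asymmetry_r if n == scaled else 1.0
        maps[n][ips_par] = factor * mirrored[ips_par]
    for b in range(5):
        rows.append({"region": "ipsilateral_parenchyma", "band": b + 1,
                     "n_voxels": int((ips_par & (band == b)).sum()),
                     **{n: par_bands[n][b] * (spec.asymmetry_r if n == scaled else 1.0)
                        for n in names}})

    for b in range(5):
        m_t = tumor & (tumor_band == b)
        for n in names:
            base = tum_bands[n][b]
            disp = _lognormal_field(rng, int(m_t.sum()), spec.dispersion_sigma)
            v = base * disp if n in ("A", "alpha", "ktrans") else base * disp
            if n == "ve":
                v = np.clip(v, None, 1.0)
            maps[n][m_t] = v
        rows.append({"region": "tumor", "band": b + 1,
                     "n_voxels": int(m_t.sum()),
                     **{n: tum_bands[n][b] for n in names}})

    # build the 4D signal
    signal = np.full(shape + (n_frames,), spec.background_s0)
    tissue = ips_par | con_par | tumor | vessel
    t_post = np.clip(t_rel, 0.0, None)

    if spec.mode == "signal":
        A = maps["A"][tissue]
        al = maps["alpha"][tissue]
        be = maps["beta"][tissue]
        if vessel.any():
            vk = VESSEL_KINETICS
            vm = vessel[tissue]
            A = np.where(vm, vk["A"], np.where(np.isnan(A), 0.0, A))
            al = np.where(vm, vk["alpha"], np.where(np.isnan(al), 0.0, al))
            be = np.where(vm, vk["beta"], np.where(np.isnan(be), 0.0, be))
        tt = t_post[None, :] ** 2
        pse = (A[:, None] * al[:, None] * tt / (1.0 + al[:, None] * tt)
               * np.exp(-be[:, None] * t_post[None, :]))
        signal[tissue] = spec.s0 * (1.0 + pse / 100.0)
    else:
        kt = np.where(np.isnan(maps["ktrans"][tissue]), 0.0, maps["ktrans"][tissue])
        ve = np.where(np.isnan(maps["ve"][tissue]), 0.5, maps["ve"][tissue])
        vp = np.where(np.isnan(maps["vp"][tissue]), 0.0, maps["vp"][tissue])
        if vessel.any():
            vm = vessel[tissue]
            kt = np.where(vm, 0.0, kt)
            vp = np.where(vm, 0.6, vp)   # vessels carry near-blood signal
        step = spec.spacing_s / 60.0 / 10.0
        dense = np.union1d(np.arange(0.0, t_post[-1] + step / 2, step), t_post)
        cp = spec.aif(dense)
        kep = np.where(ve > 0, kt / ve, 0.0)
        conc_dense = _etm_conc_many(dense, cp, kt, kep, vp)
        cols = np.searchsorted(dense, t_post)
        conc = conc_dense[:, cols]
        conc[:, t_rel <= 0] = 0.0
        ratio = spgr_signal_ratio(conc, spec.t10_s, spec.relaxivity,
                                  spec.tr_s, spec.flip_deg)
        signal[tissue] = spec.s0 * ratio

    if spec.noise != "none" and spec.noise_sd_frac > 0:
        sd = spec.noise_sd_frac * spec.s0
        if spec.noise == "gaussian":
            signal = np.clip(signal + rng.normal(0, sd, signal.shape), 0, None)
        else:  # Rician: magnitude of a complex Gaussian perturbation
            n1 = rng.normal(0, sd, signal.shape)
            n2 = rng.normal(0, sd, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    series = DynamicSeries(voxels=signal, frame_times=times_min,
                           n_precontrast=spec.n_precontrast,
                           voxel_size=spec.voxel_size)
    region_labels = RegionLabels(labels=labels, laterality=spec.laterality)
    if spec.mode == "signal":
        maps["a_alpha"] = maps["A"] * maps["alpha"]
    truth = PhantomTruth(table=pd.DataFrame(rows), voxel_maps=maps,
                         mode=spec.mode, asymmetry_r=spec.asymmetry_r)
    return series, region_labels, truth


# ---------------------------------------------------------------------------
# patient-level cohort simulator

#: published group distributions (mean, SD) — non-pCR then pCR — for the
#: bilateral parenchymal asymmetry (I/C) and tumor kinetic features
DEFAULT_FEATURES = {
    "kBPE_A_IC": (1.21, 0.44, 1.19, 0.59),
    "kBPE_alpha_IC": (1.47, 0.93, 1.02, 0.36),
    "kBPE_A_alpha_IC": (1.66, 0.86, 1.07, 0.26),
    "kBPE_beta_IC": (2.06, 9.97, 5.57, 24.53),
    "kBPE_AUC30_IC": (1.79, 1.29, 1.05, 0.31),
    "kBPE_Ktrans_IC": (1.45, 0.56, 1.03, 0.12),
    "kBPE_ve_IC": (0.88, 0.79, 1.05, 0.24),
    "kBPE_Kep_IC": (5.00, 8.13, 1.06, 0.42),
    "kBPE_vp_IC": (3.08, 3.88, 1.44, 0.85),
    "kT_A": (1.49, 0.44, 1.52, 0.43),
    "kT_alpha": (13.7, 7.84, 12.0, 7.6),
    "kT_A_alpha": (21.1, 13.4, 19.5, 14.3),
    "kT_beta": (-0.04, 0.16, -0.05, 0.13),
    "kT_AUC30": (0.56, 0.20, 0.55, 0.20),
    "kT_Ktrans": (0.21, 0.11, 0.18, 0.09),
    "kT_ve": (0.33, 0.17, 0.33, 0.19),
    "kT_Kep": (0.74, 0.32, 0.67, 0.26),
    "kT_vp": (0.0062, 0.0067, 0.0060, 0.0059),
}

#: physical truncation bounds applied during sampling
DEFAULT_BOUNDS = {
    **{k: (1e-3, np.inf) for k in DEFAULT_FEATURES if k.endswith("_IC")
       and "beta" not in k},
    "kT_A": (0.0, np.inf), "kT_alpha": (0.0, np.inf),
    "kT_A_alpha": (0.0, np.inf), "kT_AUC30": (0.0, np.inf),
    "kT_Ktrans": (0.0, np.inf), "kT_Kep": (0.0, np.inf),
    "kT_ve": (1e-3, 1.0), "kT_vp": (0.0, 0.2),
}

#: binary clinical covariates: P(positive) in non-pCR / pCR groups
DEFAULT_CLINICAL = {
    "postmenopausal": (15 / 30, 11 / 26),
    "ER": (18 / 30, 15 / 26),
    "PR": (13 / 30, 8 / 26),
    "HER2": (17 / 30, 14 / 26),
    "grade3": (26 / 30, 25 / 26),
}


@dataclass
class CohortSpec:
    n_nonpcr: int = 30
    n_pcr: int = 26
    features: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    clinical: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL))
    age: tuple = (51.0, 12.0, 24.0, 74.0)   # mean, SD, lo, hi
    family: str = "normal"                   # "normal" | "lognormal"
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_nonpcr, self.n_pcr) < 1:
            raise DataError("group sizes must be >= 1")
        for name, (m0, s0_, m1, s1) in self.features.items():
            if s0_ < 0 or s1 < 0:
                raise DataError(f"{name}: negative SD")
        if self.family not in ("normal", "lognormal"):
            raise DataError(f"unknown distribution family {self.family!r}")


def _sample_truncated(rng, mean, sd, lo, hi, n, family="normal"):
    if sd == 0:
        return np.full(n, np.clip(mean, lo, hi))
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        if family == "lognormal" and mean > 0:
            s2 = np.log1p((sd / mean) ** 2)
            draw = rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), todo.size)
        else:
            draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    if todo.size:
        out[todo] = np.clip(rng.normal(mean, sd, todo.size), lo, hi)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table with group-structured kinetic features,
    clinical covariates and the binary pCR outcome."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nonpcr + spec.n_pcr
    outcome = np.concatenate([np.zeros(spec.n_nonpcr, dtype=int),
                              np.ones(spec.n_pcr, dtype=int)])
    data = {"patient_id": [f"P{i:03d}" for i in range(n)],
            "outcome": outcome}

    m_age, s_age, lo_age, hi_age = spec.age
    data["age"] = np.round(_sample_truncated(
        rng, m_age, s_age, lo_age, hi_age, n), 0)
    for name, (p0, p1) in spec.clinical.items():
        p = np.where(outcome == 1, p1, p0)
        data[name] = (rng.random(n) < p).astype(int)

    for name, (m0, s0_, m1, s1) in spec.features.items():
        lo, hi = spec.bounds.get(name, (-np.inf, np.inf))
        v0 = _sample_truncated(rng, m0, s0_, lo, hi, spec.n_nonpcr, spec.family)
        v1 = _sample_truncated(rng, m1, s1, lo, hi, spec.n_pcr, spec.family)
        data[name] = np.concatenate([v0, v1])

    return pd.DataFrame(data)


def default_pools(cohort: pd.DataFrame) -> dict[str, list[str]]:
    """Candidate-feature pools for the model-family search."""
    return {
        "clinical": [c for c in ("age", "postmenopausal", "ER", "PR",
                                 "HER2", "grade3") if c in cohort.columns],
        "kT": [c for c in cohort.columns if c.startswith("kT_")],
        "kBPE_IC": [c for c in cohort.columns if c.startswith("kBPE_")],
    }
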