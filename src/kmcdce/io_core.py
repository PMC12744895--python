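"""Core domain containers and file I/O for ultrafast breast DCE-MRI analysis.

The package works on three kinds of input:

* a 4D dynamic series (x, y, z, t) of signal intensities with per-frame
  acquisition times (a handful of precontrast frames followed by a rapid
  postcontrast train at 3-9 s spacing),
* a co-registered 3D label map marking ipsilateral/contralateral normal
  parenchyma, tumor and vessels,
* a per-patient clinical covariate table with the binary treatment outcome
  (pathologic complete response, pCR, versus residual disease).

Series and labels are exchanged as NIfTI; frame timing travels in a JSON
sidecar because the NIfTI time-step header cannot express variable frame
spacing. All times are converted to minutes at read time and stay in minutes
everywhere downstream (uptake/washout rates and Ktrans/Kep are per-minute).
Voxel coordinates are plain 0-based array indices: the series and its masks
must share a grid, and no world-coordinate resampling is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region codes used in every label map.
BACKGROUND = 0
IPSILATERAL_PARENCHYMA = 1
CONTRALATERAL_PARENCHYMA = 2
TUMOR = 3
VESSEL = 4

VALID_LABEL_CODES = frozenset(
    {BACKGROUND, IPSILATERAL_PARENCHYMA, CONTRALATERAL_PARENCHYMA, TUMOR, VESSEL}
)

REGION_NAMES = {
    IPSILATERAL_PARENCHYMA: "ipsilateral_parenchyma",
    CONTRALATERAL_PARENCHYMA: "contralateral_parenchyma",
    TUMOR: "tumor",
}


class DataError(ValueError):
    """An input violates a structural contract (shape, timing, codes)."""


@dataclass(frozen=True)
class DynamicSeries:
    """A 4D DCE-MRI acquisition.

    Attributes
    ----------
    voxels : ndarray, shape (x, y, z, t)
        Signal intensity, arbitrary units, finite and non-negative.
    frame_times : ndarray, shape (t,)
        Acquisition time of each frame in minutes, strictly increasing.
    n_precontrast : int
        Number of leading frames acquired before contrast arrival.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    """

    voxels: np.ndarray
    frame_times: np.ndarray
    n_precontrast: int
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "frame_times", times)
        if vox.ndim != 4:
            raise DataError(f"series must be 4D, got {vox.ndim}D")
        if times.ndim != 1 or times.size != vox.shape[3]:
            raise DataError(
                f"{times.size} frame times for {vox.shape[3]} frames"
            )
        if np.any(np.diff(times) <= 0):
            raise DataError("frame times must be strictly increasing")
        if not (1 <= self.n_precontrast < vox.shape[3]):
            raise DataError(
                f"n_precontrast={self.n_precontrast} out of range for "
                f"{vox.shape[3]} frames"
            )
        if not np.all(np.isfinite(vox)) or np.any(vox < 0):
            raise DataError("voxel values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]

    @property
    def postcontrast_times(self) -> np.ndarray:
        """Times of the postcontrast frames, minutes."""
        return self.frame_times[self.n_precontrast:]


@dataclass(frozen=True)
class RegionLabels:
    """3D region label map on the same grid as a :class:`DynamicSeries`.

    ``laterality`` records which anatomical side carries the tumor
    ("left" or "right"); tumor and vessel voxels never carry a parenchyma
    code (the exclusion is applied upstream, before clustering).
    """

    labels: np.ndarray
    laterality: str = "left"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise DataError("label map must be integer-valued")
            lab = lab.astype(np.int16)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 3:
            raise DataError(f"label map must be 3D, got {lab.ndim}D")
        codes = set(np.unique(lab).tolist())
        unknown = codes - VALID_LABEL_CODES
        if unknown:
            raise DataError(f"unknown label codes {sorted(unknown)}")
        if self.laterality not in ("left", "right"):
            raise DataError(f"laterality must be 'left' or 'right'")

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def check_tumor_side(self) -> bool:
        """Warn (do not fail) if the tumor centroid sits on the side opposite
        the declared laterality. The left half of axis 0 is 'left'."""
        idx = np.argwhere(self.labels == TUMOR)
        if idx.size == 0:
            return True
        mid = self.labels.shape[0] / 2.0
        centroid_x = idx[:, 0].mean()
        on_left = centroid_x < mid
        ok = bool((self.laterality == "left") == on_left)
        if not ok:
            logger.warning(
                "tumor centroid (x=%.1f) is on the %s half but laterality=%s",
                centroid_x, "left" if on_left else "right", self.laterality,
            )
        return ok


def read_dynamic_series(
    path: str | Path,
    timing: str | Path | Mapping | None = None,
    n_precontrast: int | None = None,
) -> DynamicSeries:
    """Read a 4D NIfTI series plus its timing sidecar.

    ``timing`` is a JSON file (or pre-parsed mapping) with keys
    ``frame_times`` (one per frame), ``unit`` ("s" or "min") and
    ``n_precontrast``. Defaults to ``<path minus extensions>.timing.json``.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataError(f"{path.name}: expected 4D NIfTI, got {data.ndim}D")

    if timing is None:
        timing = path.with_name(path.name.split(".")[0] + ".timing.json")
    if isinstance(timing, (str, Path)):
        timing_path = Path(timing)
        if not timing_path.exists():
            raise DataError(f"timing sidecar not found: {timing_path}")
        meta = json.loads(timing_path.read_text())
    else:
        meta = dict(timing)

    times = np.asarray(meta["frame_times"], dtype=float)
    unit = meta.get("unit", "min")
    if unit in ("s", "sec", "seconds"):
        times = times / 60.0
    elif unit not in ("min", "minutes"):
        raise DataError(f"unknown time unit {unit!r}")
    npre = n_precontrast if n_precontrast is not None else int(meta["n_precontrast"])

    zooms = img.header.get_zooms()[:3]
    return DynamicSeries(
        voxels=data,
        frame_times=times,
        n_precontrast=npre,
        voxel_size=tuple(float(z) for z in zooms),
    )


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write series as 4D NIfTI plus the JSON timing sidecar (minutes)."""
    path = Path(path)
    affine = np.diag(list(series.voxel_size) + [1.0])
    img = nib.Nifti1Image(series.voxels.astype(np.float64), affine)
    img.header.set_zooms(series.voxel_size + (1.0,))
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + ".timing.json")
    sidecar.write_text(json.dumps({
        "frame_times": series.frame_times.tolist(),
        "unit": "min",
        "n_precontrast": series.n_precontrast,
    }, indent=1))
    return path


def read_region_labels(
    path: str | Path,
    laterality: str = "left",
    grid_shape: tuple[int, int, int] | None = None,
) -> RegionLabels:
    """Read and validate a 3D integer label map."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"label map must be 3D, got {data.ndim}D")
    if grid_shape is not None and tuple(data.shape) != tuple(grid_shape):
        raise DataError(
            f"label grid {data.shape} does not match series grid {grid_shape}"
        )
    labels = RegionLabels(labels=np.rint(data).astype(np.int16),
                          laterality=laterality)
    labels.check_tumor_side()
    return labels


def write_region_labels(labels: RegionLabels, path: str | Path,
                        voxel_size: Sequence[float] = (1.5, 1.5, 3.0)) -> Path:
    path = Path(path)
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), str(path))
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-patient covariate/feature table; validates the outcome."""
    df = pd.read_csv(path)
    return validate_cohort_table(df)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    if "outcome" not in df.columns:
        raise DataError("cohort table must have an 'outcome' column")
    vals = set(pd.unique(df["outcome"].dropna()))
    if not vals <= {0, 1, "pCR", "nonpCR"}:
        raise DataError(f"outcome must be binary (0/1 or pCR/nonpCR), got {vals}")
    if vals & {"pCR", "nonpCR"}:
        df = df.copy()
        df["outcome"] = (df["outcome"] == "pCR").astype(int)
    return df


def write_summary_tables(
    summaries: Iterable, path: str | Path, overwrite: bool = False
) -> Path:
    """Write patient summaries to ``<path>/patient_summaries.csv``.

    One row per patient; columns are the flattened kinetic summary
    (``<param>_<ips_ave|con_ave|IC|kT>``) plus covariates. Values survive a
    write/read round trip to 10 significant digits.
    """
    rows = [s.to_row() if hasattr(s, "to_row") else dict(s) for s in summaries]
    if not rows:
        raise DataError("empty summary collection")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = path / "patient_summaries.csv"
    if out.exists() and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.12g")
    return out
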