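"""Weighted cluster averages, bilateral asymmetry ratios and tumor summaries.

Per-cluster kinetic parameters are collapsed to patient-level biomarkers:

* normal parenchyma, each breast: weighted average of clusters 2, 3, 4 with
  weights 2, 3, 4 (sum 9). The extreme clusters are excluded — cluster 1 is
  dominated by barely-enhancing voxels and cluster 5 by outliers.
* bilateral asymmetry: I/C = ipsilateral / contralateral weighted average.
  I/C > 1 means the parenchyma on the tumor side enhances faster/stronger.
* tumor: weighted average of clusters 3, 4, 5 with weights 3, 4, 5
  (sum 12); the lowest two clusters are excluded for low SNR and the
  strongest-enhancing cluster carries the largest weight.

Averaging is applied to each derived parameter independently. Composite
identities (Kep = Ktrans/ve) are enforced per cluster, before averaging,
because weighted averaging does not commute with ratios; likewise A*alpha
is the per-cluster product of the fitted A and alpha. Missing cluster
values propagate to a missing patient value — there is no fallback
reweighting, which would silently change the estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import RegionLabels, TUMOR, DataError

logger = logging.getLogger(__name__)

#: kinetic parameters summarized per patient
PARAMETERS = ("A", "alpha", "A_alpha", "beta", "AUC30",
              "Ktrans", "ve", "Kep", "vp")

PARENCHYMA_CLUSTERS = (2, 3, 4)
PARENCHYMA_WEIGHTS = (2.0, 3.0, 4.0)
TUMOR_CLUSTERS = (3, 4, 5)
TUMOR_WEIGHTS = (3.0, 4.0, 5.0)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def weighted_parenchyma_average(c2, c3, c4) -> float:
    """(2*c2 + 3*c3 + 4*c4) / 9; missing inputs propagate."""
    if any(_is_missing(v) for v in (c2, c3, c4)):
        logger.info("parenchymal average missing: cluster value absent")
        return float("nan")
    return (2.0 * c2 + 3.0 * c3 + 4.0 * c4) / 9.0


def weighted_tumor_average(c3, c4, c5) -> float:
    """(3*c3 + 4*c4 + 5*c5) / 12; missing inputs propagate."""
    if any(_is_missing(v) for v in (c3, c4, c5)):
        logger.info("tumor average missing: cluster value absent")
        return float("nan")
    return (3.0 * c3 + 4.0 * c4 + 5.0 * c5) / 12.0


def ic_ratio(ips, con) -> float:
    """Ipsilateral / contralateral ratio; guarded against a zero denominator."""
    if _is_missing(ips) or _is_missing(con):
        return float("nan")
    if abs(con) < 1e-9:
        logger.warning("I/C undefined: contralateral average ~ 0")
        return float("nan")
    return ips / con


def tumor_volume(labels: RegionLabels, voxel_size_mm) -> float:
    """Tumor volume in cm^3: voxel count times voxel volume."""
    vs = tuple(float(v) for v in voxel_size_mm)
    if min(vs) <= 0:
        raise DataError("voxel size must be positive")
    n = int((labels.labels == TUMOR).sum())
    if n == 0:
        logger.warning("no tumor voxels; volume = 0")
    return n * vs[0] * vs[1] * vs[2] / 1000.0


@dataclass
class PatientSummary:
    """Patient-level kinetic summary plus covariates and outcome.

    ``values`` maps parameter -> {"ips_ave", "con_ave", "IC", "kT"}.
    """

    patient_id: str
    values: dict[str, dict[str, float]]
    tumor_volume_cm3: float = float("nan")
    covariates: dict = field(default_factory=dict)
    outcome: int | None = None

    def to_row(self) -> dict:
        row: dict = {"patient_id": self.patient_id}
        for p, d in self.values.items():
            for kind, v in d.items():
                row[f"{p}_{kind}"] = v
        row["tumor_volume_cm3"] = self.tumor_volume_cm3
        row.update(self.covariates)
        if self.outcome is not None:
            row["outcome"] = self.outcome
        return row


def summarize_patient(
    cluster_table: pd.DataFrame,
    labels: RegionLabels | None = None,
    voxel_size_mm=(1.5, 1.5, 3.0),
    covariates: Mapping | None = None,
    outcome: int | None = None,
    patient_id: str = "patient",
) -> PatientSummary:
    """Collapse a per-cluster parameter table to a PatientSummary.

    ``cluster_table`` needs columns ``region`` (ipsilateral_parenchyma /
    contralateral_parenchyma / tumor), ``cluster`` (1..5) and one column per
    parameter in :data:`PARAMETERS`. Missing required clusters make the
    affected parameter missing.
    """
    def cluster_value(region: str, cluster: int, param: str) -> float:
        rows = cluster_table[(cluster_table["region"] == region)
                             & (cluster_table["cluster"] == cluster)]
        if len(rows) != 1 or param not in rows.columns:
            return float("nan")
        return float(rows.iloc[0][param])

    values: dict[str, dict[str, float]] = {}
    for p in PARAMETERS:
        ips = weighted_parenchyma_average(
            *(cluster_value("ipsilateral_parenchyma", c, p)
              for c in PARENCHYMA_CLUSTERS))
        con = weighted_parenchyma_average(
            *(cluster_value("contralateral_parenchyma", c, p)
              for c in PARENCHYMA_CLUSTERS))
        kt = weighted_tumor_average(
            *(cluster_value("tumor", c, p) for c in TUMOR_CLUSTERS))
        values[p] = {
            "ips_ave": ips,
            "con_ave": con,
            "IC": ic_ratio(ips, con),
            "kT": kt,
        }

    vol = tumor_volume(labels, voxel_size_mm) if labels is not None else float("nan")
    return PatientSummary(
        patient_id=patient_id,
        values=values,
        tumor_volume_cm3=vol,
        covariates=dict(covariates or {}),
        outcome=outcome,
    )
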