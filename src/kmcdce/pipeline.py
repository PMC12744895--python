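"""Per-patient and cohort-level orchestration.

The patient pipeline follows the analysis flow end to end: percent signal
enhancement -> per-voxel two-parameter enhancement fits -> K = 5 k-means
clustering of the A*alpha map (tumor, ipsilateral parenchyma and
contralateral parenchyma clustered separately) -> cluster-mean curves ->
three-parameter fits with AUC30 -> concentration conversion -> extended
Tofts fits -> weighted cluster averages, bilateral I/C ratios and tumor
summaries. Every intermediate can be written to disk, together with a run
manifest (config echo, seeds, config hash) so a run is exactly replayable.

Cohort-level analysis takes a table of per-patient summaries (or a
simulated cohort) and produces the group-comparison table and the
exhaustive-search logistic model reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, kinetics, pharmacokinetics as pk, stats, summary
from .io_core import (DataError, DynamicSeries, RegionLabels, REGION_NAMES,
                      read_dynamic_series, read_region_labels)
from .phantom import default_pools

logger = logging.getLogger(__name__)

REGION_CODES = {1: "ipsilateral_parenchyma", 2: "contralateral_parenchyma",
                3: "tumor"}


@dataclass
class PipelineConfig:
    """Tunable options of the per-patient pipeline."""

    # clustering
    k: int = 5
    cluster_init: str = "quantile"
    seed: int = 0
    # kinetics
    origin_offset: float = 0.0            # minutes, bolus-arrival shift
    # concentration conversion / ETM
    conversion_mode: str = "spgr"         # "spgr" | "linear"
    t10_parenchyma_s: float = 1.4
    t10_tumor_s: float = 1.5
    relaxivity: float = 5.0               # L/(mmol s)
    tr_s: float = 0.004
    flip_deg: float = 10.0
    aif_params: dict = field(
        default_factory=lambda: dict(pk.PARKER_PARAMS))
    bolus_arrival: float = 0.0
    # cohort statistics
    n_boot: int = 1000
    stratified_bootstrap: bool = False
    families: tuple[str, ...] = tuple(stats.FAMILIES)

    def aif(self) -> pk.PopulationAif:
        return pk.PopulationAif(params=dict(self.aif_params),
                                bolus_arrival=self.bolus_arrival)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        cfg = cls(**raw)
        if cfg.k != 5:
            logger.warning("k = %d overrides the default of 5 clusters", cfg.k)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_patient(
    series: DynamicSeries,
    labels: RegionLabels,
    config: PipelineConfig | None = None,
    covariates=None,
    outcome=None,
    patient_id: str = "patient",
) -> tuple[summary.PatientSummary, dict]:
    """Run the full kinetic pipeline on one patient in memory.

    Returns the patient summary plus an intermediates dict with the voxel
    fit maps, the per-region cluster assignments and the per-cluster
    parameter table.
    """
    config = config or PipelineConfig()
    if labels.labels.shape != series.shape:
        raise DataError("stage voxel_fit: label grid mismatch")

    maps = kinetics.fit_emm2_voxelwise(series, labels)
    aif = config.aif()

    assignments: dict[str, clustering.ClusterAssignment] = {}
    cluster_rows = []
    for code, region in REGION_CODES.items():
        mask = labels.mask(code) & maps["valid"]
        try:
            asg = clustering.kmeans_cluster(
                maps["a_alpha"], mask, k=config.k, seed=config.seed,
                init=config.cluster_init, region=region)
        except DataError as exc:
            raise DataError(f"stage clustering[{region}]: {exc}") from exc
        assignments[region] = asg
        curves = clustering.cluster_mean_curves(series, asg)
        t10 = config.t10_tumor_s if region == "tumor" else config.t10_parenchyma_s
        for c, curve in curves.items():
            row = {"region": region, "cluster": c,
                   "n_voxels": int(asg.counts[c - 1]),
                   "mean_a_alpha": float(asg.means[c - 1])}
            try:
                f3 = kinetics.fit_emm3_curve(curve)
                row.update(A=f3.A, alpha=f3.alpha, A_alpha=f3.a_alpha,
                           beta=f3.beta, AUC30=f3.auc30, emm3_rss=f3.rss,
                           emm3_converged=f3.converged)
            except DataError as exc:
                logger.warning("%s cluster %d: EMM3 fit failed (%s)",
                               region, c, exc)
            try:
                conc = pk.pse_to_concentration(
                    curve, t10_s=t10, relaxivity=config.relaxivity,
                    tr_s=config.tr_s, flip_deg=config.flip_deg,
                    mode=config.conversion_mode)
                tf = pk.fit_etm(conc, aif)
                row.update(Ktrans=tf.ktrans, ve=tf.ve, vp=tf.vp, Kep=tf.kep,
                           etm_rss=tf.rss, etm_converged=tf.converged)
            except DataError as exc:
                logger.warning("%s cluster %d: ETM fit failed (%s)",
                               region, c, exc)
            cluster_rows.append(row)

    cluster_table = pd.DataFrame(cluster_rows)
    patient = summary.summarize_patient(
        cluster_table, labels=labels, voxel_size_mm=series.voxel_size,
        covariates=covariates, outcome=outcome, patient_id=patient_id)
    intermediates = {"voxel_maps": maps, "assignments": assignments,
                     "cluster_table": cluster_table}
    return patient, intermediates


def run_patient(
    series_path, labels_path, out_dir, config: PipelineConfig | None = None,
    laterality: str = "left", patient_id: str = "patient",
) -> summary.PatientSummary:
    """Disk-to-disk variant of :func:`analyze_patient`."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = read_dynamic_series(series_path)
    labels = read_region_labels(labels_path, laterality=laterality,
                                grid_shape=series.shape)
    patient, inter = analyze_patient(series, labels, config,
                                     patient_id=patient_id)

    inter["cluster_table"].to_csv(out / "cluster_fits.csv", index=False,
                                  float_format="%.12g")
    pd.DataFrame([patient.to_row()]).to_csv(out / "patient_summary.csv",
                                            index=False, float_format="%.12g")
    import nibabel as nib
    affine = np.diag(list(series.voxel_size) + [1.0])
    for name in ("A", "alpha", "a_alpha"):
        nib.save(nib.Nifti1Image(inter["voxel_maps"][name], affine),
                 str(out / f"map_{name}.nii.gz"))
    for region, asg in inter["assignments"].items():
        nib.save(nib.Nifti1Image(asg.label_map.astype(np.int16), affine),
                 str(out / f"clusters_{region}.nii.gz"))
    manifest = {"config": config.to_dict(),
                "config_hash": config.config_hash(),
                "patient_id": patient_id,
                "series": str(series_path), "labels": str(labels_path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return patient


def run_cohort(
    cohort: pd.DataFrame,
    n_boot: int | None = None,
    seed: int | None = None,
    families=None,
    config: PipelineConfig | None = None,
) -> tuple[list[stats.GroupComparison], dict[str, stats.ModelReport]]:
    """Group comparisons plus exhaustive model search on a cohort table."""
    config = config or PipelineConfig()
    n_boot = config.n_boot if n_boot is None else n_boot
    seed = config.seed if seed is None else seed
    families = config.families if families is None else families

    y = cohort["outcome"]
    if y.nunique() < 2 or y.value_counts().min() < 2:
        raise DataError("need >= 2 patients in each outcome group")

    pools = default_pools(cohort)
    skip = {"patient_id", "outcome"}
    comparisons = []
    for col in cohort.columns:
        if col in skip:
            continue
        try:
            comparisons.append(stats.compare_groups(
                cohort, col, n_boot=n_boot, seed=seed))
        except DataError as exc:
            logger.warning("comparison %s skipped: %s", col, exc)

    reports: dict[str, stats.ModelReport] = {}
    for fam in families:
        reports[fam] = stats.exhaustive_model_search(
            cohort, pools, fam, n_boot=n_boot, seed=seed)
    return comparisons, reports


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "feature": c.feature, "kind": c.kind, "test": c.test,
            "nonpCR_mean": c.mean_nonpcr, "nonpCR_sd": c.sd_nonpcr,
            "pCR_mean": c.mean_pcr, "pCR_sd": c.sd_pcr,
            "p_value": c.p_value, "auc": c.auc,
            "auc_ci_low": c.auc_ci[0], "auc_ci_high": c.auc_ci[1],
        })
    return pd.DataFrame(rows)


def reports_to_dict(reports: dict[str, stats.ModelReport]) -> dict:
    out = {}
    for fam, r in reports.items():
        out[fam] = {
            "features": list(r.features),
            "coefficients": r.coefficients,
            "auc": r.auc,
            "auc_ci": list(r.auc_ci),
            "sensitivity": r.sensitivity,
            "specificity": r.specificity,
            "accuracy": r.accuracy,
            "youden_threshold": r.threshold,
            "n_bootstrap": r.n_bootstrap,
        }
    return out
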