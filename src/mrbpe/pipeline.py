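"""Cohort pipeline: mask -> bias-correct -> segment -> density -> BPE -> stats.

``analyse_subject_volumes`` runs the whole per-subject chain on in-memory
volumes; ``run_subject`` is its file-backed wrapper and ``run_cohort``
iterates a manifest with a skip-and-log failure policy, then assembles the
statistics report (group comparison on right-breast metrics, Bland–Altman
right/left agreement, and repeatability CVs when replicate runs are
present).  All randomness is routed through one seed per subject derived
from the cohort seed and the subject id, so results are independent of
cohort ordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import bpe as bpe_mod
from .bias import correct_bias
from .fcm import compute_density, segment_fgt
from .grids import DceSeries, VolumeGrid, read_series, read_volume
from .masking import (auto_seeds, auto_tolerance, erode_mask, region_grow,
                      split_laterality)

log = logging.getLogger(__name__)

BPE_METRICS = ("bpe_median_pct", "bpe_q1_pct", "bpe_q3_pct", "bpe_iqr_pct",
               "bpe_skewness", "bpe_kurtosis")
DENSITY_METRICS = ("fgt_volume_cc", "mrbd_pct")


@dataclass
class RunConfig:
    """Stage parameters for a cohort run (defaults from the stage modules)."""

    # masking
    seeds: list | None = None          # None -> automatic per-half seeding
    tolerance: float | None = None     # None -> robust-range fraction
    erode_radius_vox: int = 2
    fill_holes: bool = True
    # bias correction
    bias_order: int = 2
    # segmentation
    n_clusters: int = 7
    fcm_m: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    fgt_selection: object = "gap"        # T2w: parenchyma is dark
    parenchyma_selection: object = "gap-high"  # pre-contrast FS: bright
    # BPE
    denominator_floor_fraction: float = 0.01
    # cohort
    rng_seed: int = 0
    group_labels: tuple[str, str] = ("high_risk", "population_risk")

    def subject_seed(self, subject_id) -> int:
        return zlib.crc32(f"{self.rng_seed}:{subject_id}".encode()) & 0x7FFFFFFF


def analyse_subject_volumes(
    t2w: VolumeGrid,
    dce: DceSeries | None,
    cfg: RunConfig | None = None,
    subject_id="subject",
    exclusion: np.ndarray | None = None,
) -> list[dict]:
    """Run the full per-breast analysis chain on one subject's volumes.

    Returns one record per laterality with density metrics, BPE
    distribution metrics, and QC fields.  If ``dce`` is None the BPE fields
    are NaN and flagged absent.
    """
    cfg = cfg or RunConfig()
    seed = cfg.subject_seed(subject_id)

    seeds = cfg.seeds if cfg.seeds is not None else auto_seeds(t2w)
    tol = cfg.tolerance if cfg.tolerance is not None else auto_tolerance(t2w)
    grown = region_grow(t2w, seeds, tol)
    if cfg.fill_holes:
        grown = dataclasses.replace(
            grown, values=ndimage.binary_fill_holes(grown.values))
    eroded = erode_mask(grown, cfg.erode_radius_vox)
    left, right = split_laterality(eroded)

    bias_res = correct_bias(t2w, eroded, max_order=cfg.bias_order)

    records = []
    for breast in (left, right):
        rec = {
            "subject": subject_id,
            "laterality": breast.laterality,
            "rng_seed": seed,
            "breast_voxels": breast.n_voxels,
            "bias_converged": bias_res.converged,
            "bpe_available": False,
        }
        for m in DENSITY_METRICS + BPE_METRICS:
            rec[m] = float("nan")
        rec["mtp_index"] = -1
        rec["bpe_dropped_voxels"] = 0
        if breast.n_voxels == 0:
            rec["error"] = "empty breast mask after laterality split"
            records.append(rec)
            continue

        seg = segment_fgt(
            bias_res.corrected, breast,
            n_clusters=cfg.n_clusters, m=cfg.fcm_m,
            assignment=cfg.fgt_selection,
            tol=cfg.fcm_tol, max_iter=cfg.fcm_max_iter, rng_seed=seed,
        )
        dens = compute_density(seg, breast, t2w.voxel_volume_mm3)
        rec["fgt_volume_cc"] = dens.fgt_volume_cc
        rec["mrbd_pct"] = dens.mrbd_pct
        rec["breast_volume_cc"] = dens.breast_volume_cc
        rec["fcm_converged_t2w"] = seg.model.converged_

        if dce is not None:
            breast_on_dce = breast.resample_to(dce.frame(0))
            par = bpe_mod.segment_parenchyma_precontrast(
                dce, breast_on_dce, exclusion=exclusion,
                n_clusters=cfg.n_clusters,
                assignment=cfg.parenchyma_selection,
                m=cfg.fcm_m, tol=cfg.fcm_tol,
                max_iter=cfg.fcm_max_iter, rng_seed=seed,
            )
            mtp = bpe_mod.select_mtp(dce, par)
            res = bpe_mod.compute_bpe_map(
                dce, par, mtp,
                denominator_floor_fraction=cfg.denominator_floor_fraction,
            )
            rec.update({
                "bpe_available": True,
                "mtp_index": res.mtp_index,
                "bpe_median_pct": res.median_pct,
                "bpe_q1_pct": res.q1_pct,
                "bpe_q3_pct": res.q3_pct,
                "bpe_iqr_pct": res.iqr_pct,
                "bpe_skewness": res.skewness,
                "bpe_kurtosis": res.kurtosis,
                "bpe_n_voxels": res.n_voxels,
                "bpe_dropped_voxels": res.n_dropped_low_denominator,
                "fcm_converged_dce": par.model.converged_,
            })
        records.append(rec)
    return records


def run_subject(cfg: RunConfig, subject: dict) -> list[dict]:
    """File-backed subject run.

    ``subject`` holds ``id`` and file paths (``t2w``, optional ``dce`` +
    ``times``, optional ``exclusion``) plus passthrough covariates
    (``group``, ``age``, ``weight``, ``replicate``).
    """
    t2w = read_volume(subject["t2w"])
    dce = None
    if subject.get("dce"):
        p = Path(subject["dce"])
        if p.exists():
            dce = read_series(p, subject.get("times"))
        else:
            log.warning("subject %s: DCE file missing, BPE fields flagged absent",
                        subject["id"])
    exclusion = None
    if subject.get("exclusion"):
        exclusion = read_volume(subject["exclusion"]).values.astype(bool)
    records = analyse_subject_volumes(
        t2w, dce, cfg, subject_id=subject["id"], exclusion=exclusion)
    for rec in records:
        for key in ("group", "age", "weight", "replicate"):
            if key in subject:
                rec[key] = subject[key]
    return records


def run_cohort(cfg: RunConfig, manifest: list[dict]
               ) -> tuple[pd.DataFrame, dict]:
    """Run every manifest subject and assemble the statistics report.

    Failed subjects are skipped and logged (recorded in the report), so one
    bad case cannot abort a cohort run.
    """
    from . import statistics as st

    if not manifest:
        raise ValueError("manifest is empty")
    all_records, failures = [], []
    for subject in manifest:
        try:
            all_records.extend(run_subject(cfg, subject))
        except Exception as exc:  # noqa: BLE001 — skip-and-log policy
            log.error("subject %s failed: %s", subject.get("id"), exc)
            failures.append({"subject": subject.get("id"), "error": str(exc)})
    table = pd.DataFrame(all_records)
    report: dict = {"failures": failures}
    if table.empty:
        return table, report

    if "replicate" in table.columns:
        primary = table[table["replicate"].fillna(0) == 0]
    else:
        primary = table

    # group comparison on right-breast metrics only
    right = primary[primary["laterality"] == "right"]
    if "group" in right.columns and right["group"].nunique() == 2:
        metrics = [m for m in DENSITY_METRICS + BPE_METRICS
                   if m in right.columns]
        cmp_table = st.cohort_compare(right, metrics,
                                      group_labels=cfg.group_labels)
        report["group_comparison"] = cmp_table

    # right/left agreement
    agreement = {}
    wide = primary.pivot_table(index="subject", columns="laterality",
                               values=list(DENSITY_METRICS + ("bpe_median_pct",)),
                               aggfunc="first")
    for metric in DENSITY_METRICS + ("bpe_median_pct",):
        if (metric, "right") not in wide.columns:
            continue
        sub = wide[metric].dropna(subset=["right", "left"])
        if len(sub) >= 2:
            agreement[metric] = st.bland_altman(
                np.column_stack([sub["right"], sub["left"]]))
    if agreement:
        report["bland_altman"] = agreement

    # repeatability CVs across replicate runs, per metric
    if "replicate" in table.columns and table["replicate"].nunique() > 1:
        cv_section = {}
        for metric in DENSITY_METRICS + ("bpe_median_pct",):
            reps = []
            for (_subj, _lat), grp in table.groupby(["subject", "laterality"]):
                vals = grp[metric].dropna().to_numpy(float)
                if vals.size >= 2:
                    reps.append(vals)
            if reps:
                cv_section[metric] = st.coefficient_of_variation(reps)
        if cv_section:
            report["repeatability_cv"] = cv_section
    return table, report


def report_to_json(report: dict) -> dict:
    """Flatten a run_cohort report into JSON-serialisable form."""
    out: dict = {"failures": report.get("failures", [])}
    if "group_comparison" in report:
        out["group_comparison"] = json.loads(
            report["group_comparison"].to_json(orient="records"))
    if "bland_altman" in report:
        out["bland_altman"] = {
            k: {"bias": v.bias, "sd_diff": v.sd_diff, "rpc": v.rpc,
                "loa_low": v.loa_low, "loa_high": v.loa_high,
                "n_pairs": v.n_pairs}
            for k, v in report["bland_altman"].items()}
    if "repeatability_cv" in report:
        out["repeatability_cv"] = {
            k: {"cv_pct": v.cv_pct, "n_subjects": v.n_subjects,
                "per_subject_cv_pct": v.per_subject_cv_pct}
            for k, v in report["repeatability_cv"].items()}
    return out
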