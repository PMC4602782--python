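"""End-to-end orchestration of the DMN connectivity study.

Stage order mirrors the study design: per-subject preprocessing (motion
screen, discard, smooth, nuisance regression, band-pass) -> per-seed z maps
-> healthy-control conjunction DMN mask -> subject mean z maps -> voxelwise
ANOVA with age/gender covariates -> Monte-Carlo cluster correction -> post
hoc pairwise t within significant clusters -> per-subject ROI means ->
MHE diagnosis (when groups are undiagnosed) -> score correlations -> ROC.

:func:`analyze_subjects` works on in-memory objects; :func:`analyze` wraps
it with manifest/NIfTI loading and result-table writing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .connectivity import (
    ConjunctionResult,
    SeedSpec,
    build_conjunction,
    default_seeds,
    mean_seed_zmap,
    subject_seed_zmaps,
)
from .diagnostics import (
    NormativeReference,
    diagnose_mhe,
    pearson_with_scores,
    prevalence,
    roc_curve,
)
from .errors import DmnfcError
from .inference import (
    Cluster,
    ClusterCorrection,
    DesignInfo,
    alphasim_min_extent,
    estimate_smoothness,
    extract_clusters,
    posthoc_t,
    roi_mean,
    voxelwise_anova,
)
from .preprocess import PreprocessConfig, preprocess_subject
from .types import BinaryMask, BoldSeries, MotionTrace, SubjectRecord, VolumeMap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis parameters for one run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seeds: list[SeedSpec] = field(default_factory=default_seeds)
    conjunction_q: float = 0.05
    correction: ClusterCorrection = field(default_factory=ClusterCorrection)
    roc_orientation: str = "lower"
    norm_sd_multiplier: float = 2.0
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectData:
    """One subject's loaded inputs."""

    record: SubjectRecord
    bold: BoldSeries
    trace: MotionTrace


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one cohort."""

    retained: list[SubjectRecord]
    excluded: list[tuple[str, str]]  # (subject_id, reason)
    conjunction: ConjunctionResult
    f_map: VolumeMap
    p_map: VolumeMap
    correction: ClusterCorrection
    smoothness_fwhm_mm: tuple[float, float, float]
    clusters: list[Cluster]
    cluster_table: pd.DataFrame
    roi_values: pd.DataFrame  # rows: subjects, columns: cluster labels
    posthoc_tables: dict[str, pd.DataFrame]
    correlation_table: pd.DataFrame
    roc_table: pd.DataFrame
    mhe_prevalence: tuple[int, int, float] | None


def _design_from_records(records: list[SubjectRecord]) -> DesignInfo:
    return DesignInfo(
        groups=[r.group for r in records],
        age_years=np.array([r.age_years for r in records]),
        gender=np.array([0.0 if r.gender == "M" else 1.0 for r in records]),
    )


def _model_residual_maps(
    subject_maps: list[VolumeMap], design: DesignInfo, mask: BinaryMask
) -> list[VolumeMap]:
    """Residuals of the full group+covariate model, for smoothness estimation."""
    from .inference import _group_design, _stack_maps

    X, _ = _group_design(design.groups, design)
    Y, flat_mask = _stack_maps(subject_maps, mask)
    valid = np.isfinite(Y).all(axis=0)
    resid = np.full_like(Y, np.nan)
    if valid.any():
        Q, _ = np.linalg.qr(X)
        Yv = Y[:, valid]
        resid[:, valid] = Yv - Q @ (Q.T @ Yv)
    shape = mask.data.shape
    out = []
    for i, m in enumerate(subject_maps):
        data = np.full(int(np.prod(shape)), np.nan)
        data[flat_mask] = resid[i]
        out.append(VolumeMap(data.reshape(shape), m.affine, "z"))
    return out


def analyze_subjects(
    subjects: list[SubjectData],
    csf_mask: BinaryMask | None,
    wm_mask: BinaryMask | None,
    brain_mask: BinaryMask | None,
    config: RunConfig,
    analysis_mask: BinaryMask | None = None,
) -> AnalysisResult:
    """Run the full analysis on loaded subjects.

    ``analysis_mask`` overrides the conjunction DMN mask as the voxel domain
    of the group statistics (used for calibration studies); by default the
    healthy-control conjunction mask gates the ANOVA.
    """
    t0 = time.time()
    excluded: list[tuple[str, str]] = []
    retained: list[SubjectRecord] = []
    per_seed_hc: dict[str, list[VolumeMap]] = {s.name: [] for s in config.seeds}
    mean_maps: list[VolumeMap] = []

    for sub in subjects:
        processed, verdict = preprocess_subject(
            sub.bold, sub.trace, csf_mask, wm_mask, brain_mask, config.preprocess
        )
        if processed is None:
            excluded.append((sub.record.subject_id, verdict.reason))
            logger.info("excluded %s: %s", sub.record.subject_id, verdict.reason)
            continue
        zmaps = subject_seed_zmaps(processed, config.seeds)
        if sub.record.group == "HC":
            for name, zm in zmaps.items():
                per_seed_hc[name].append(zm)
        mean_maps.append(mean_seed_zmap(list(zmaps.values())))
        retained.append(sub.record)
        logger.debug(
            "subject %s processed in %.2f s", sub.record.subject_id, time.time() - t0
        )

    if not retained:
        raise DmnfcError("no subjects survived motion screening")

    # diagnosis of undiagnosed cirrhotic patients from HC norms
    if any(r.group == "cirrhotic-undiagnosed" for r in retained):
        norms = NormativeReference.from_controls(
            retained, sd_multiplier=config.norm_sd_multiplier
        )
        retained = [
            r.relabel(diagnose_mhe(r, norms))
            if r.group == "cirrhotic-undiagnosed"
            else r
            for r in retained
        ]

    conj = build_conjunction(per_seed_hc, mean_maps, q=config.conjunction_q)
    stat_mask = analysis_mask if analysis_mask is not None else conj.dmn_mask

    design = _design_from_records(retained)
    f_map, p_map = voxelwise_anova(mean_maps, design, stat_mask)

    voxel = tuple(float(np.linalg.norm(stat_mask.affine[:3, j])) for j in range(3))
    resid_maps = _model_residual_maps(mean_maps, design, stat_mask)
    smoothness = estimate_smoothness(resid_maps, stat_mask, voxel)
    correction = ClusterCorrection(
        cluster_forming_p=config.correction.cluster_forming_p,
        alpha=config.correction.alpha,
        n_iterations=config.correction.n_iterations,
        connectivity=config.correction.connectivity,
        smoothness_fwhm_mm=smoothness,
    )
    correction = alphasim_min_extent(correction, stat_mask, rng_seed=config.master_seed)
    clusters = extract_clusters(
        f_map,
        p_map,
        correction.cluster_forming_p,
        correction.min_extent_k or 1,
        correction.connectivity,
    )

    labels = [f"cluster_{i + 1:02d}" for i in range(len(clusters))]
    roi_values = pd.DataFrame(
        {
            lab: [roi_mean(m, cl) for m in mean_maps]
            for lab, cl in zip(labels, clusters)
        },
        index=[r.subject_id for r in retained],
    )

    groups = np.array([r.group for r in retained])
    cluster_rows = []
    for lab, cl in zip(labels, clusters):
        row = {
            "label": lab,
            "size": cl.size,
            "peak_x_mm": cl.peak_mni_mm[0],
            "peak_y_mm": cl.peak_mni_mm[1],
            "peak_z_mm": cl.peak_mni_mm[2],
            "peak_stat": cl.peak_stat,
        }
        for g in ("HC", "nonHE", "MHE"):
            sel = groups == g
            row[f"mean_z_{g}"] = (
                float(roi_values[lab].to_numpy()[sel].mean()) if sel.any() else np.nan
            )
        cluster_rows.append(row)
    cluster_table = pd.DataFrame(cluster_rows)

    # post hoc pairwise t tests within the significant ANOVA regions
    posthoc_tables: dict[str, pd.DataFrame] = {}
    if clusters:
        sig_mask = np.zeros(stat_mask.data.shape, bool)
        for cl in clusters:
            sig_mask[tuple(cl.voxel_indices.T)] = True
        sig_mask = BinaryMask(sig_mask, stat_mask.affine)
        for a, b in (("nonHE", "HC"), ("MHE", "HC"), ("MHE", "nonHE")):
            keep = (groups == a) | (groups == b)
            if groups[keep].size and len(set(groups[keep])) == 2:
                sub_maps = [m for m, k in zip(mean_maps, keep) if k]
                t_map, tp_map = posthoc_t(sub_maps, design.subset(keep), sig_mask)
                rows = []
                for lab, cl in zip(labels, clusters):
                    tv = t_map.data[tuple(cl.voxel_indices.T)]
                    tv = tv[np.isfinite(tv)]
                    pv = tp_map.data[tuple(cl.voxel_indices.T)]
                    pv = pv[np.isfinite(pv)]
                    rows.append(
                        {
                            "label": lab,
                            "peak_t": float(tv[np.argmax(np.abs(tv))]) if tv.size else np.nan,
                            "min_p": float(pv.min()) if pv.size else np.nan,
                        }
                    )
                posthoc_tables[f"{a}_vs_{b}"] = pd.DataFrame(rows)

    # correlations with neuropsych scores over all patients (MHE + nonHE)
    is_patient = np.isin(groups, ("MHE", "nonHE"))
    corr_rows = []
    for lab in labels:
        vals = roi_values[lab].to_numpy()[is_patient]
        for test, scores in (
            ("nct_a", np.array([r.nct_a_seconds for r in retained])[is_patient]),
            ("dst", np.array([float(r.dst_score) for r in retained])[is_patient]),
        ):
            if vals.size >= 3 and np.ptp(vals) > 0 and np.ptp(scores) > 0:
                r_val, p_val = pearson_with_scores(vals, scores)
            else:
                r_val, p_val = np.nan, np.nan
            corr_rows.append({"label": lab, "test": test, "r": r_val, "p": p_val})
    correlation_table = pd.DataFrame(corr_rows)

    # ROC: MHE vs nonHE per significant region
    roc_rows = []
    patient_labels = [g for g in groups[is_patient]]
    for lab in labels:
        vals = roi_values[lab].to_numpy()[is_patient]
        if "MHE" in patient_labels and "nonHE" in patient_labels:
            roc = roc_curve(vals, patient_labels, orientation=config.roc_orientation)
            roc_rows.append(
                {
                    "label": lab,
                    "auc": roc.auc,
                    "cutoff": roc.optimal_cutoff,
                    "sensitivity": roc.sens_at_cutoff,
                    "specificity": roc.spec_at_cutoff,
                }
            )
    roc_table = pd.DataFrame(roc_rows)

    prev = None
    if is_patient.any():
        prev = prevalence(patient_labels)

    logger.info(
        "analysis complete: %d retained, %d excluded, %d clusters, %.1f s",
        len(retained),
        len(excluded),
        len(clusters),
        time.time() - t0,
    )
    return AnalysisResult(
        retained=retained,
        excluded=excluded,
        conjunction=conj,
        f_map=f_map,
        p_map=p_map,
        correction=correction,
        smoothness_fwhm_mm=smoothness,
        clusters=clusters,
        cluster_table=cluster_table,
        roi_values=roi_values,
        posthoc_tables=posthoc_tables,
        correlation_table=correlation_table,
        roc_table=roc_table,
        mhe_prevalence=prev,
    )


def load_subject(record: SubjectRecord, n_discard: int) -> SubjectData:
    bold = dio.read_bold(record.bold_path, n_discard=n_discard)
    trace = dio.read_motion(record.motion_path, n_volumes=bold.params.n_volumes)
    return SubjectData(record=record, bold=bold, trace=trace)


def _find_mask(manifest_path: Path, name: str) -> BinaryMask | None:
    p = manifest_path.parent / f"mask_{name}.nii.gz"
    if not p.is_file():
        p = manifest_path.parent / f"mask_{name}.nii"
    return dio.read_mask(p) if p.is_file() else None


def analyze(
    manifest_path: str | Path, config: RunConfig, out_dir: str | Path
) -> AnalysisResult:
    """Load a cohort from its manifest, run the analysis, write result files.

    Tissue masks are looked up as ``mask_{csf,wm,brain}.nii.gz`` next to the
    manifest. Outputs: statistical maps (NIfTI), the conjunction mask, the
    cluster / correlation / ROC tables (TSV), per-subject ROI means,
    exclusion list, and a run-metadata JSON echoing every parameter.
    """
    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = dio.read_manifest(manifest_path)
    subjects = []
    for rec in records:
        subjects.append(load_subject(rec, config.preprocess.n_discard))
    result = analyze_subjects(
        subjects,
        csf_mask=_find_mask(manifest_path, "csf"),
        wm_mask=_find_mask(manifest_path, "wm"),
        brain_mask=_find_mask(manifest_path, "brain"),
        config=config,
    )
    write_results(result, config, out)
    return result


def write_results(result: AnalysisResult, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    dio.write_map(result.f_map, out / "anova_F.nii.gz")
    dio.write_map(result.p_map, out / "anova_p.nii.gz")
    dio.write_mask(result.conjunction.dmn_mask, out / "dmn_mask.nii.gz")
    for name, m in result.conjunction.seed_masks.items():
        dio.write_mask(m, out / f"seed_mask_{name}.nii.gz")
    result.cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
    result.roi_values.to_csv(out / "roi_values.tsv", sep="\t")
    result.correlation_table.to_csv(out / "correlations.tsv", sep="\t", index=False)
    result.roc_table.to_csv(out / "roc.tsv", sep="\t", index=False)
    for pair, table in result.posthoc_tables.items():
        table.to_csv(out / f"posthoc_{pair}.tsv", sep="\t", index=False)
    pd.DataFrame(result.excluded, columns=["subject_id", "reason"]).to_csv(
        out / "excluded.tsv", sep="\t", index=False
    )
    seed_sizes = pd.DataFrame(
        [
            {"seed": name, "mask_voxels": m.n_voxels}
            for name, m in result.conjunction.seed_masks.items()
        ]
    )
    seed_sizes.to_csv(out / "seed_mask_sizes.tsv", sep="\t", index=False)
    meta = {
        "config": config.to_dict(),
        "smoothness_fwhm_mm": list(result.smoothness_fwhm_mm),
        "min_extent_k": result.correction.min_extent_k,
        "n_retained": len(result.retained),
        "n_excluded": len(result.excluded),
        "n_clusters": len(result.clusters),
        "mhe_prevalence": result.mhe_prevalence,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
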