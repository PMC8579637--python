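"""Stage orchestration: simulate -> fit -> stats.

Ties the synthetic cohort, voxel-wise fitting, ROI summarisation and
the statistics layer into reproducible filesystem stages.  Every stage
is deterministic given (config, seed); ``simulate`` writes a manifest
with the seed and a config hash so reruns are verifiable.

The in-memory helpers (:func:`fit_rendered_patient`,
:func:`fitted_cohort_frame`, :func:`response_report`) are the actual
workhorses; the ``run_*`` functions wrap them with NIfTI/CSV/JSON I/O
for the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .map_fitting import (
    ParameterMap,
    SignalVolume,
    fit_adc,
    fit_dki,
    fit_ivim_segmented,
    fit_tofts,
)
from .roi_metrics import PatientRecord, recist_classify, roi_summary, volume_from_mask
from .synthetic_cohort import CohortConfig, cohort_to_frame, generate_cohort, render_patient_images

__all__ = [
    "config_to_yaml",
    "config_from_yaml",
    "run_simulate",
    "run_fit",
    "run_stats",
    "fit_rendered_patient",
    "fitted_cohort_frame",
    "response_report",
    "MODEL_MARKERS",
]

#: fitting model -> markers it produces
MODEL_MARKERS = {
    "adc": ("ADC",),
    "dki": ("MD", "MK"),
    "ivim": ("Dslow", "Dfast", "PF"),
    "tofts": ("Ktrans", "Kep", "Ve"),
}


# ---------------------------------------------------------------- config I/O

def config_to_yaml(config: CohortConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

def config_from_yaml(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    field_names = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dwi_b", "dki_b", "ivim_b", "grid_shape", "spacing_mm",
                "pre_diameter_cm", "diameter_range_cm"):
        if key in data:
            data[key] = tuple(data[key])
    for key in ("diameter_delta_pct", "volume_delta_pct"):
        if key in data:
            data[key] = {g: tuple(v) for g, v in data[key].items()}
    for key in ("pre_distributions", "delta_pct"):
        if key in data:
            data[key] = {m: {g: tuple(v) for g, v in per.items()}
                         for m, per in data[key].items()}
    return CohortConfig(**data)


def _config_hash(config: CohortConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ------------------------------------------------------------------ fitting

def fit_rendered_patient(images: dict, config: CohortConfig,
                         models=("adc", "dki", "ivim", "tofts"),
                         roi_only: bool = True) -> dict:
    """Fit the requested models on one patient's rendered images.

    Returns ``{marker: RoiStats}`` over the analysis ROI (the largest
    axial lesion slice, the standard single-slice convention).  With
    ``roi_only`` fitting is restricted to the ROI, which is all the
    downstream statistics consume.
    """
    roi = images["roi"]
    fit_mask = roi if roi_only else images["mask"]
    out = {}
    if "adc" in models:
        adc, _ = fit_adc(images["dwi"], mask=fit_mask)
        out["ADC"] = roi_summary(adc, roi)
    if "dki" in models:
        md, mk, _ = fit_dki(images["dki"], mask=fit_mask)
        out["MD"] = roi_summary(md, roi)
        out["MK"] = roi_summary(mk, roi)
    if "ivim" in models:
        dslow, dfast, pf, _ = fit_ivim_segmented(images["ivim"], mask=fit_mask)
        out["Dslow"] = roi_summary(dslow, roi)
        out["Dfast"] = roi_summary(dfast, roi)
        out["PF"] = roi_summary(pf, roi)
    if "tofts" in models:
        kt, kep, ve = fit_tofts(images["dce"], config.aif(), mask=fit_mask)
        out["Ktrans"] = roi_summary(kt, roi)
        out["Kep"] = roi_summary(kep, roi)
        out["Ve"] = roi_summary(ve, roi)
    return out


def _mask_diameter_cm(mask: np.ndarray, spacing_mm) -> float:
    """Largest in-plane extent of the lesion on its largest axial slice."""
    counts = mask.sum(axis=(0, 1))
    z = int(np.argmax(counts))
    sl = mask[:, :, z]
    if not sl.any():
        return 0.0
    xs, ys = np.nonzero(sl)
    ext_x = (xs.max() - xs.min() + 1) * spacing_mm[0]
    ext_y = (ys.max() - ys.min() + 1) * spacing_mm[1]
    return max(ext_x, ext_y) / 10.0


def fitted_cohort_frame(records: list[PatientRecord], config: CohortConfig,
                        models=("adc", "dki", "ivim", "tofts"),
                        timepoints=("pre", "post")) -> pd.DataFrame:
    """Render and fit every patient; return the long cohort table.

    Sizes (diameter, volume) are measured from the rendered lesion
    masks, so the table contains only quantities the imaging pipeline
    itself produced.
    """
    rows = []
    for rec in records:
        for tp in timepoints:
            images = render_patient_images(rec, config, tp)
            stats = fit_rendered_patient(images, config, models)
            d_cm = _mask_diameter_cm(images["mask"], config.spacing_mm)
            v_cm3 = volume_from_mask(images["mask"], config.spacing_mm,
                                     config.slice_gap_mm)
            for name, st in stats.items():
                rows.append({
                    "patient_id": rec.patient_id, "timepoint": tp,
                    "parameter": name, "mean": st.mean, "median": st.median,
                    "iqr": st.iqr, "diameter_cm": d_cm, "volume_cm3": v_cm3,
                    "group": rec.group, "recist": rec.recist,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- reporting

def _comparison_row(gc: cs.GroupComparison) -> dict:
    return {"variable": gc.variable, "test": gc.test,
            "statistic": gc.statistic, "p": gc.p_value,
            "summary_1": json.dumps(gc.summary_1),
            "summary_2": json.dumps(gc.summary_2)}


def response_report(frame: pd.DataFrame, alpha: float = 0.05) -> dict:
    """The full statistics bundle from a long cohort table.

    Produces analogues of a response-prediction paper's tables: paired
    pre/post marker comparisons, RG-vs-NRG comparisons of sizes,
    markers and their changes, and ROC rows (each significant
    pre-treatment marker plus the logistic PRE combination) with the
    Youden cutoff, likelihood ratios and predictive values.
    """
    wide = frame.pivot_table(index=["patient_id", "group"],
                             columns=["parameter", "timepoint"],
                             values="mean", sort=False)
    size = frame.drop_duplicates(["patient_id", "timepoint"]).pivot_table(
        index=["patient_id", "group"], columns="timepoint",
        values=["diameter_cm", "volume_cm3"], sort=False)
    wide = wide.join(size)
    groups = wide.index.get_level_values("group").to_numpy()
    y = groups == "RG"
    if y.all() or not y.any():
        raise ValueError("both responder and non-responder patients required")
    markers = sorted({p for p, tp in wide.columns if tp in ("pre", "post")
                      and p not in ("diameter_cm", "volume_cm3")})

    paired = []
    for m in markers:
        if (m, "pre") in wide.columns and (m, "post") in wide.columns:
            paired.append(_comparison_row(cs.compare_paired(
                wide[(m, "pre")], wide[(m, "post")], alpha, variable=m)))

    unpaired = []
    candidates: dict[str, np.ndarray] = {}
    for m in markers:
        for tp in ("pre", "post"):
            vals = wide[(m, tp)].to_numpy()
            unpaired.append(_comparison_row(cs.compare_unpaired(
                vals[y], vals[~y], alpha, variable=f"{m}-{tp}")))
            if tp == "pre":
                candidates[m] = vals
        delta = wide[(m, "post")] - wide[(m, "pre")]
        delta_pct = 100.0 * delta / wide[(m, "pre")]
        for name, vals in ((f"d{m}", delta.to_numpy()), (f"d{m}%", delta_pct.to_numpy())):
            unpaired.append(_comparison_row(cs.compare_unpaired(
                vals[y], vals[~y], alpha, variable=name)))
    for label, col in (("D-post", ("diameter_cm", "post")),
                       ("V-post", ("volume_cm3", "post"))):
        vals = wide[col].to_numpy()
        unpaired.append(_comparison_row(cs.compare_unpaired(
            vals[y], vals[~y], alpha, variable=label)))
    for label, col in (("dD%", "diameter_cm"), ("dV%", "volume_cm3")):
        vals = (100.0 * (wide[(col, "post")] - wide[(col, "pre")])
                / wide[(col, "pre")]).to_numpy()
        unpaired.append(_comparison_row(cs.compare_unpaired(
            vals[y], vals[~y], alpha, variable=label)))

    unpaired_df = pd.DataFrame(unpaired)
    sig_pre = [m for m in candidates
               if float(unpaired_df.loc[unpaired_df.variable == f"{m}-pre", "p"].iloc[0]) < alpha]

    roc_rows = []
    for m in sig_pre:
        roc_rows.append(cs.roc_analysis(candidates[m], y, marker=f"{m}-pre"))
    combo = None
    if len(sig_pre) >= 1:
        X = np.column_stack([candidates[m] for m in sig_pre])
        combo = cs.logistic_combine(X, y.astype(int), feature_names=tuple(sig_pre))
        roc_rows.append(cs.roc_analysis(combo.scores, y, marker="PRE"))

    roc_df = pd.DataFrame([dataclasses.asdict(r) for r in roc_rows])
    pairwise = []
    for i in range(len(roc_rows)):
        for j in range(i + 1, len(roc_rows)):
            si = candidates.get(roc_rows[i].marker.removesuffix("-pre"),
                                combo.scores if combo is not None else None)
            sj = candidates.get(roc_rows[j].marker.removesuffix("-pre"),
                                combo.scores if combo is not None else None)
            diff, z, p = cs.delong_compare(si, sj, y)
            pairwise.append({"marker_1": roc_rows[i].marker,
                             "marker_2": roc_rows[j].marker,
                             "auc_diff": diff, "z": z, "p": p})
    return {
        "n_responders": int(y.sum()),
        "n_nonresponders": int((~y).sum()),
        "paired_pre_post": pd.DataFrame(paired),
        "group_comparisons": unpaired_df,
        "roc": roc_df,
        "roc_pairwise": pd.DataFrame(pairwise),
        "pre_combination": combo,
        "significant_pre_markers": sig_pre,
    }


# ------------------------------------------------------------- file stages

def run_simulate(config: CohortConfig, out_dir: str | Path,
                 write_images: bool = True) -> Path:
    """Generate a cohort fixture directory (images, truth table, manifest)."""
    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"output location {out.parent} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(config)
    frame = cohort_to_frame(records)
    frame.to_csv(out / "cohort_truth.csv", index=False)
    config_to_yaml(config, out / "config.yaml")
    if write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for rec in records:
            pdir = img_dir / rec.patient_id
            pdir.mkdir(exist_ok=True)
            for tp in ("pre", "post"):
                images = render_patient_images(rec, config, tp)
                for key in ("dwi", "dki", "ivim", "dce"):
                    images[key].to_nifti(pdir / f"{tp}_{key}.nii")
                for key in ("mask", "roi"):
                    arr = images[key].astype(np.uint8)
                    affine = np.diag(list(config.spacing_mm) + [1.0])
                    nib.save(nib.Nifti1Image(arr, affine), str(pdir / f"{tp}_{key}.nii"))
    manifest = {"seed": config.seed, "config_hash": _config_hash(config),
                "n_patients": len(records), "images": bool(write_images)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def run_fit(in_dir: str | Path, out_dir: str | Path,
            models=("adc", "dki", "ivim", "tofts")) -> Path:
    """Fit parameter maps for every patient/timepoint in a fixture dir."""
    in_dir, out = Path(in_dir), Path(out_dir)
    config = config_from_yaml(in_dir / "config.yaml")
    truth = pd.read_csv(in_dir / "cohort_truth.csv")
    out.mkdir(parents=True, exist_ok=True)
    acqs = {"dwi": config.dwi_acq, "dki": config.dki_acq,
            "ivim": config.ivim_acq, "dce": config.dce_acq}
    rows = []
    for pdir in sorted((in_dir / "images").iterdir()):
        pid = pdir.name
        meta = truth[truth.patient_id == pid].iloc[0]
        for tp in ("pre", "post"):
            mask = np.asarray(nib.load(str(pdir / f"{tp}_mask.nii")).dataobj) > 0
            roi = np.asarray(nib.load(str(pdir / f"{tp}_roi.nii")).dataobj) > 0
            if not roi.any():
                import warnings
                warnings.warn(f"empty ROI for {pid} {tp}; skipped", stacklevel=2)
                continue
            images = {"mask": mask, "roi": roi}
            for key in ("dwi", "dki", "ivim", "dce"):
                path = pdir / f"{tp}_{key}.nii"
                try:
                    images[key] = SignalVolume.from_nifti(path, acqs[key])
                except Exception as exc:
                    raise RuntimeError(f"cannot read {path}: {exc}") from exc
            stats = fit_rendered_patient(images, config, models)
            mdir = out / "maps" / pid
            mdir.mkdir(parents=True, exist_ok=True)
            d_cm = _mask_diameter_cm(mask, config.spacing_mm)
            v_cm3 = volume_from_mask(mask, config.spacing_mm, config.slice_gap_mm)
            for name, st in stats.items():
                rows.append({"patient_id": pid, "timepoint": tp,
                             "parameter": name, "mean": st.mean,
                             "median": st.median, "iqr": st.iqr,
                             "diameter_cm": d_cm, "volume_cm3": v_cm3,
                             "group": meta.group, "recist": meta.recist})
    pd.DataFrame(rows).to_csv(out / "cohort_fitted.csv", index=False)
    return out


def run_stats(cohort_csv: str | Path, out_dir: str | Path,
              alpha: float = 0.05) -> Path:
    """Statistics bundle (CSV tables + JSON) from a long cohort table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.read_csv(cohort_csv)
    report = response_report(frame, alpha=alpha)
    for key in ("paired_pre_post", "group_comparisons", "roc", "roc_pairwise"):
        report[key].to_csv(out / f"{key}.csv", index=False)
    combo = report["pre_combination"]
    bundle = {
        "n_responders": report["n_responders"],
        "n_nonresponders": report["n_nonresponders"],
        "significant_pre_markers": report["significant_pre_markers"],
        "roc": report["roc"].to_dict(orient="records"),
        "roc_pairwise": report["roc_pairwise"].to_dict(orient="records"),
        "pre_logistic": None if combo is None else {
            "features": list(combo.feature_names),
            "coefficients": combo.coefficients.tolist(),
            "intercept": combo.intercept,
            "separation": combo.separation,
        },
    }
    (out / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    return out
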