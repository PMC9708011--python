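"""Reading and writing cohorts: NIfTI image stacks, landmark and clinical
CSV tables, and the ground-truth JSON sidecar for synthetic cohorts."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import CineStudy, SyntheticConfig, LANDMARK_LABELS


def write_cohort(studies: list[CineStudy], out_dir, config: SyntheticConfig | None = None):
    """Write per-subject NIfTI per view plus landmarks/clinical CSVs.

    Layout: ``<out>/images/<subject>_<view>.nii``, ``<out>/landmarks.csv``,
    ``<out>/clinical.csv`` and, for synthetic cohorts, ``<out>/truth.json``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    lm_rows, clin = [], {}
    for st in studies:
        img = nib.Nifti1Image(np.asarray(st.tensor, dtype=np.float32), affine=np.eye(4))
        nib.save(img, out / "images" / f"{st.subject_id}_{st.view}.nii")
        for label, (r, c) in st.landmarks.items():
            lm_rows.append({"subject_id": st.subject_id, "view": st.view,
                            "label": label, "x": r, "y": c})
        row = clin.setdefault(st.subject_id, {
            "subject_id": st.subject_id,
            "survival_time_years": st.survival_time,
            "event": int(st.event),
        })
        row.update(st.covariates)
        if st.latent_risk is not None:
            row["latent_risk"] = st.latent_risk
    pd.DataFrame(lm_rows).to_csv(out / "landmarks.csv", index=False)
    pd.DataFrame(list(clin.values())).to_csv(out / "clinical.csv", index=False)
    if config is not None:
        cfg = asdict(config)
        cfg["views"] = list(cfg["views"])
        if cfg.get("signal_region"):
            cfg["signal_region"] = {
                v: [np.asarray(a).tolist() for a in reg]
                for v, reg in cfg["signal_region"].items()
            }
        (out / "truth.json").write_text(json.dumps(cfg, indent=2))
    return out


def read_cohort(in_dir, view: str | None = None) -> list[CineStudy]:
    """Load a cohort written by :func:`write_cohort`."""
    root = Path(in_dir)
    lms = pd.read_csv(root / "landmarks.csv")
    clin = pd.read_csv(root / "clinical.csv").set_index("subject_id")
    studies = []
    for path in sorted((root / "images").glob("*.nii*")):
        stem = path.name.split(".nii")[0]
        subject_id, v = stem.rsplit("_", 1)
        if view is not None and v != view:
            continue
        tensor = np.asarray(nib.load(path).dataobj, dtype=float)
        sub = lms[(lms.subject_id == subject_id) & (lms.view == v)]
        landmarks = {row.label: (row.x, row.y) for row in sub.itertuples()}
        row = clin.loc[subject_id]
        covs = {c: float(row[c]) for c in clin.columns
                if c not in ("survival_time_years", "event", "latent_risk")}
        studies.append(CineStudy(
            subject_id=subject_id, view=v, tensor=tensor, landmarks=landmarks,
            covariates=covs, survival_time=float(row["survival_time_years"]),
            event=bool(row["event"]),
            latent_risk=float(row["latent_risk"]) if "latent_risk" in clin.columns else None,
        ))
    return studies


def write_landmark_reference(ref, path):
    np.savez(path, view=ref.view, landmarks=ref.reference_landmarks,
             mask_center=ref.mask_center, mask_semi_axes=ref.mask_semi_axes,
             mask_angle=ref.mask_angle)


def read_dicom_series(series_dir) -> np.ndarray:
    """Load a directory of single-frame DICOM files as an H x W x T stack.

    Frames are ordered by InstanceNumber when present, else by filename.
    """
    import pydicom

    paths = sorted(p for p in Path(series_dir).iterdir() if p.suffix.lower() in
                   (".dcm", ".ima", ""))
    if not paths:
        raise ValueError(f"no DICOM files in {series_dir}")
    frames = []
    for p in paths:
        ds = pydicom.dcmread(p)
        order = getattr(ds, "InstanceNumber", None)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        frames.append((order if order is not None else p.name, slope * arr + intercept))
    frames.sort(key=lambda kv: kv[0])
    stack = np.stack([f for _, f in frames], axis=-1)
    if stack.ndim != 3:
        raise ValueError("expected single-frame 2D DICOM images")
    return stack


def save_mpca_model(model, path):
    """One-file archive: mean tensor, per-mode bases, variances, config."""
    np.savez_compressed(
        path,
        mean_tensor=model.mean_tensor,
        basis_mode1=model.mode_bases[0],
        basis_mode2=model.mode_bases[1],
        basis_mode3=model.mode_bases[2],
        feature_variances=model.feature_variances,
        feature_order=model.feature_order,
        variance_kept=model.variance_kept,
        n_iterations=model.n_iterations,
    )


def load_mpca_model(path):
    from .mpca import MPCAModel

    with np.load(path) as z:
        return MPCAModel(
            mean_tensor=z["mean_tensor"],
            mode_bases=[z["basis_mode1"], z["basis_mode2"], z["basis_mode3"]],
            feature_variances=z["feature_variances"],
            feature_order=z["feature_order"],
            variance_kept=float(z["variance_kept"]),
            n_iterations=int(z["n_iterations"]),
        )


def save_prognostic_model(model, path):
    """Classifier archive: selection, weights, calibration, provenance."""
    np.savez_compressed(
        path,
        view=model.view,
        indices=model.selected.indices,
        fisher_scores=model.selected.fisher_scores,
        tuning_metric=model.selected.tuning_metric,
        weight_vector=model.weight_vector,
        bias=model.bias,
        calibration_slope=model.calibration_slope,
        calibration_intercept=model.calibration_intercept,
        feature_contrast=(model.feature_contrast
                          if model.feature_contrast is not None else np.array([])),
        provenance=json.dumps(model.provenance, default=str),
    )


def load_prognostic_model(path):
    from .selection import SelectedFeatureSet, TrainedPrognosticModel

    with np.load(path) as z:
        contrast = z["feature_contrast"]
        return TrainedPrognosticModel(
            view=str(z["view"]),
            selected=SelectedFeatureSet(
                indices=z["indices"],
                fisher_scores=z["fisher_scores"],
                tuning_metric=float(z["tuning_metric"]),
            ),
            weight_vector=z["weight_vector"],
            bias=float(z["bias"]),
            calibration_slope=float(z["calibration_slope"]),
            calibration_intercept=float(z["calibration_intercept"]),
            feature_contrast=contrast if contrast.size else None,
            provenance=json.loads(str(z["provenance"])),
        )


def read_region_masks(path) -> dict:
    """Region masks from a NIfTI label image (1=RV, 2=LV, 3=septum)."""
    lab = np.asarray(nib.load(path).dataobj)
    names = {1: "RV", 2: "LV", 3: "septum"}
    return {name: lab == code for code, name in names.items() if (lab == code).any()}
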