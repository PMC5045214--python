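"""Readers and writers for the formats the pipeline touches.

Volumes travel as NIfTI-1, cohorts as a manifest CSV pointing at the
per-subject files, feature tables as CSV (one file per channel), and
models / cross-validation reports as JSON.  Configuration files may be
YAML or JSON.
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

from .atlas import AtlasParcellation
from .evaluation import CVReport
from .features import FeatureTable
from .synthetic import CHANNELS, Cohort, CohortConfig, EffectSpec, Subject

_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])  # synthetic grids use 3 mm voxels


def write_nifti(path: Path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _AFFINE), str(path))


def read_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def write_atlas(path: Path, atlas: AtlasParcellation) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), _AFFINE), str(path))


def read_atlas(path: Path) -> AtlasParcellation:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int64)
    ids = tuple(int(i) for i in np.unique(labels) if i > 0)
    return AtlasParcellation(labels=labels, roi_ids=ids)


def write_cohort(cohort: Cohort, out_dir: Path) -> Path:
    """Write per-subject volumes, the atlas, and a manifest CSV.

    Returns the manifest path.  Layout: ``atlas.nii.gz``, one
    ``<subject_id>_func.nii.gz`` / ``<subject_id>_anat.nii.gz`` pair per
    subject, and ``manifest.csv`` with subject_id, label and file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(out_dir / "atlas.nii.gz", cohort.atlas)
    rows = []
    for s in cohort.subjects:
        fpath = out_dir / f"{s.subject_id}_func.nii.gz"
        apath = out_dir / f"{s.subject_id}_anat.nii.gz"
        write_nifti(fpath, s.functional)
        write_nifti(apath, s.structural)
        rows.append({"subject_id": s.subject_id, "label": s.label,
                     "functional": fpath.name, "structural": apath.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: Path, atlas: AtlasParcellation | None = None,
                config: CohortConfig | None = None) -> Cohort:
    """Load a cohort from a manifest CSV written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "label", "functional", "structural"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(df.columns))}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in manifest: {dup}")
    if atlas is None:
        atlas_path = base / "atlas.nii.gz"
        if not atlas_path.exists():
            raise FileNotFoundError(f"no atlas found at {atlas_path}")
        atlas = read_atlas(atlas_path)
    subjects = []
    shapes = set()
    for _, row in df.iterrows():
        label = str(row["label"]).lower()
        if label not in ("patient", "control"):
            raise ValueError(f"subject {row['subject_id']}: unknown label {row['label']!r}")
        fpath, apath = base / row["functional"], base / row["structural"]
        for p in (fpath, apath):
            if not p.exists():
                raise FileNotFoundError(f"subject {row['subject_id']}: missing {p}")
        func = read_nifti(fpath)
        struct = read_nifti(apath)
        if func.shape[:3] != atlas.shape or struct.shape != atlas.shape:
            raise ValueError(f"subject {row['subject_id']}: grid mismatch with atlas")
        shapes.add(func.shape)
        subjects.append(Subject(subject_id=str(row["subject_id"]), label=label,
                                functional=func, structural=struct))
    if len(shapes) > 1:
        raise ValueError("subjects disagree on volume shape or time points")
    labels = {s.label for s in subjects}
    if labels != {"patient", "control"}:
        raise ValueError("cohort must contain both patients and controls")
    shape = subjects[0].functional.shape
    if config is None:
        npat = sum(s.label == "patient" for s in subjects)
        config = CohortConfig(n_patients=max(npat, 2),
                              n_controls=max(len(subjects) - npat, 2),
                              n_timepoints=shape[3], volume_shape=shape[:3],
                              n_rois=atlas.n_rois)
    return Cohort(subjects=tuple(subjects), atlas=atlas, config=config,
                  resolved_effects=())


def write_feature_tables(tables: dict[str, FeatureTable], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ch, tab in tables.items():
        df = pd.DataFrame(tab.matrix, columns=[f"roi_{r}" for r in tab.roi_ids])
        df.insert(0, "subject_id", tab.subject_ids)
        df.insert(1, "label", tab.labels)
        df.to_csv(out_dir / f"features_{ch}.csv", index=False)


def read_feature_tables(in_dir: Path,
                        channels: tuple[str, ...] = CHANNELS) -> dict[str, FeatureTable]:
    in_dir = Path(in_dir)
    tables = {}
    for ch in channels:
        path = in_dir / f"features_{ch}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing feature table {path}")
        df = pd.read_csv(path)
        roi_cols = [c for c in df.columns if c.startswith("roi_")]
        tables[ch] = FeatureTable(
            matrix=df[roi_cols].to_numpy(dtype=float), channel=ch,
            roi_ids=tuple(int(c.split("_", 1)[1]) for c in roi_cols),
            subject_ids=tuple(df["subject_id"].astype(str)),
            labels=tuple(df["label"].astype(str)))
    return tables


def _selection_record_dict(rec) -> dict:
    return {"channel": rec.channel, "fold_index": rec.fold_index,
            "ttest_survivors": list(rec.ttest_survivors),
            "rfe_ranking": list(rec.rfe_ranking),
            "final_subset": list(rec.final_subset), "empty": rec.empty}


def cv_report_to_dict(report: CVReport) -> dict:
    return {
        "metrics": {
            "accuracy": report.metrics.accuracy,
            "sensitivity": report.metrics.sensitivity,
            "specificity": report.metrics.specificity,
            "auc": report.metrics.auc,
            "counts": dataclasses.asdict(report.metrics.counts),
        },
        "folds": [{
            "fold_index": f.fold_index, "test_subject": f.test_subject,
            "true_label": f.true_label, "score": f.score,
            "prediction": f.prediction, "beta": f.beta,
            "selections": {ch: _selection_record_dict(r)
                           for ch, r in f.selections.items()},
        } for f in report.folds],
        "feature_counts": {ch: {str(k): v for k, v in cnt.items()}
                           for ch, cnt in report.feature_counts.items()},
    }


def write_cv_report(report: CVReport, path: Path,
                    extra: dict | None = None) -> None:
    payload = cv_report_to_dict(report)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def model_to_dict(model) -> dict:
    return {"beta": model.beta.tolist(),
            "alpha_signed": model.alpha_signed.tolist(),
            "bias": model.bias, "support": model.support.tolist(),
            "y": model.y.tolist(), "C": model.C,
            "channel_names": list(model.channel_names),
            "norm_constants": list(model.norm_constants),
            "objective": model.objective, "converged": model.converged}


def load_config_file(path: Path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def effects_from_config(items: list[dict]) -> tuple[EffectSpec, ...]:
    return tuple(EffectSpec(roi_id=int(e["roi_id"]), channel=str(e["channel"]),
                            effect_size=float(e["effect_size"]),
                            partners=tuple(e["partners"]) if e.get("partners") else None)
                 for e in items)


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]
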