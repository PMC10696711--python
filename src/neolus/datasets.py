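"""Dataset manifests: writing, loading, validation and summaries.

A dataset on disk is a directory of 8-bit grayscale PNG frames plus a
``manifest.csv`` with one row per frame (subject, video, frame index,
path, class label, lung region, clinical covariates).  Synthetic
cohorts additionally carry a provenance JSON (seed, generator version)
so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantom import CLASS_LABELS, LUNG_REGIONS, SampleMeta

MANIFEST_COLUMNS = ("subject_id", "video_id", "frame_index", "path",
                    "class_label", "lung_region", "ga_weeks", "cgats_weeks",
                    "dol_days")


def save_cohort(images: list[np.ndarray], metas: list[SampleMeta],
                out_dir: str | Path,
                provenance: dict | None = None) -> Path:
    """Write frames as PNG plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for img, meta in zip(images, metas):
        fname = f"frames/{meta.video_id}_f{meta.frame_index:02d}.png"
        iio.imwrite(out_dir / fname,
                    np.clip(np.rint(img), 0, 255).astype(np.uint8))
        rows.append({"subject_id": meta.subject_id, "video_id": meta.video_id,
                     "frame_index": meta.frame_index, "path": fname,
                     "class_label": meta.class_label,
                     "lung_region": meta.lung_region,
                     "ga_weeks": meta.ga_weeks,
                     "cgats_weeks": meta.cgats_weeks,
                     "dol_days": meta.dol_days})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, index=False)
    if provenance is not None:
        (out_dir / "provenance.json").write_text(
            json.dumps(provenance, indent=2))
    return manifest


def load_dataset(manifest_path: str | Path,
                 ) -> tuple[list[np.ndarray], list[SampleMeta]]:
    """Load images and metadata; schema violations name the failing row."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "video_id", "frame_index"])
    if dup.any():
        raise ValueError("duplicate subject/video/frame keys at rows "
                         f"{list(df.index[dup])}")
    base = manifest_path.parent
    images, metas = [], []
    for i, row in df.iterrows():
        meta = SampleMeta(
            subject_id=str(row["subject_id"]), video_id=str(row["video_id"]),
            frame_index=int(row["frame_index"]),
            class_label=str(row["class_label"]),
            lung_region=str(row["lung_region"]),
            ga_weeks=float(row["ga_weeks"]),
            cgats_weeks=float(row["cgats_weeks"]),
            dol_days=float(row["dol_days"]))
        try:
            meta.validate()
        except ValueError as err:
            raise ValueError(f"manifest row {i}: {err}") from err
        path = base / str(row["path"])
        if not path.exists():
            raise FileNotFoundError(f"manifest row {i}: missing image {path}")
        images.append(np.asarray(iio.imread(path), dtype=float))
        metas.append(meta)
    return images, metas


def summarize_dataset(metas: list[SampleMeta]) -> pd.DataFrame:
    """Per-class distinct subjects/videos and image counts, plus totals."""
    if not metas:
        raise ValueError("no samples to summarize")
    df = pd.DataFrame([{"class_label": m.class_label,
                        "subject_id": m.subject_id,
                        "video_id": m.video_id} for m in metas])
    rows = []
    for label in [c for c in CLASS_LABELS
                  if c in set(df["class_label"])]:
        sub = df[df["class_label"] == label]
        rows.append({"class_label": label,
                     "patients": sub["subject_id"].nunique(),
                     "videos": sub["video_id"].nunique(),
                     "images": len(sub)})
    out = pd.DataFrame(rows)
    total = {"class_label": "Total",
             "patients": df["subject_id"].nunique(),
             "videos": df["video_id"].nunique(),
             "images": len(df)}
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
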