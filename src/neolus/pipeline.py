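"""End-to-end convenience: images -> preprocessed -> DTCWT -> feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dtcwt import dtcwt_forward
from .features import CLINICAL_NAMES, FeatureConfig, extract_features
from .modeling import FeatureTable
from .phantom import SampleMeta, generate_cohort
from .preprocess import NORMALIZED_SHAPE, RoiRect, preprocess_image


def build_feature_table(images: list[np.ndarray], metas: list[SampleMeta],
                        rois_by_video: dict[str, list[RoiRect]] | None = None,
                        levels: int = 5,
                        config: FeatureConfig | None = None) -> FeatureTable:
    """Preprocess, decompose and featurize a set of frames.

    Frames already at the canonical 500x400 size skip renormalization.
    """
    config = config or FeatureConfig()
    names: list[str] | None = None
    rows = []
    for img, meta in zip(images, metas):
        rois = (rois_by_video or {}).get(meta.video_id)
        if rois or img.shape != NORMALIZED_SHAPE:
            img = preprocess_image(img, rois)
        fv = extract_features(dtcwt_forward(img, levels=levels), meta, config)
        if names is None:
            names = fv.names
        rows.append(fv.values)
    if names is None:
        raise ValueError("no images given")
    matrix = np.vstack(rows)
    clinical_mask = np.array([n in CLINICAL_NAMES for n in names])
    return FeatureTable(matrix, names,
                        np.array([m.class_label for m in metas]),
                        np.array([m.subject_id for m in metas]),
                        clinical_mask)


def phantom_feature_table(n_subjects_per_class: int = 4,
                          videos_per_subject: int = 6,
                          frames_per_video: int = 5,
                          seed: int = 0,
                          levels: int = 5,
                          config: FeatureConfig | None = None,
                          ) -> FeatureTable:
    """Balanced phantom cohort straight to a feature table."""
    images, metas = generate_cohort(n_subjects_per_class, videos_per_subject,
                                    frames_per_video, seed)
    return build_feature_table(images, metas, levels=levels, config=config)


def feature_table_to_csv(t: FeatureTable, metas: list[SampleMeta],
                         path: str) -> None:
    df = pd.DataFrame(t.matrix, columns=t.names)
    meta_df = pd.DataFrame([{
        "subject_id": m.subject_id, "video_id": m.video_id,
        "frame_index": m.frame_index, "class_label": m.class_label,
        "lung_region": m.lung_region} for m in metas])
    pd.concat([meta_df, df], axis=1).to_csv(path, index=False)
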