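"""End-to-end helpers chaining generation, preprocessing, feature extraction,
selection and the network grid."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureConfig, extract_features
from .preprocess import PreprocessConfig, extract_segment, preprocess_recording
from .selection import build_design_matrix, select_features
from .synth import CohortConfig, generate_cohort


def extract_cohort_features(
    recordings,
    pre_cfg: PreprocessConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Preprocess and extract features for a list of (wake, sleep) recording
    pairs; returns the stacked tidy feature table."""
    feat_cfg = feat_cfg or FeatureConfig()
    tables = []
    for pair in recordings:
        for rec in pair:
            cfg = pre_cfg or PreprocessConfig(segment_s=min(60.0, rec.duration))
            clean = extract_segment(preprocess_recording(rec, cfg), cfg)
            tables.append(extract_features(clean, feat_cfg))
    return pd.concat(tables, ignore_index=True)


def run_selection_study(config: CohortConfig, alpha: float = 0.05,
                        pre_cfg: PreprocessConfig | None = None,
                        feat_cfg: FeatureConfig | None = None):
    """Generate a cohort, extract channel-averaged features and run the
    logistic screen.  Returns (selected names, LR results frame, table,
    labels)."""
    recordings, labels = generate_cohort(config)
    if pre_cfg is None:
        pre_cfg = PreprocessConfig(segment_s=config.duration)
    table = extract_cohort_features(recordings, pre_cfg, feat_cfg)
    label_series = pd.Series(
        labels, index=[pair[0].subject_id for pair in recordings]
    )
    selected, frame = select_features(table, label_series, alpha=alpha)
    return selected, frame, table, label_series


def build_all_designs(table: pd.DataFrame, labels, alpha: float = 0.05):
    """SET 1 / SET 2 / SET 3 design matrices from one feature table."""
    selected, _ = select_features(table, labels, alpha=alpha)
    designs = {
        1: build_design_matrix(table, labels, 1),
        2: build_design_matrix(table, labels, 2),
        3: build_design_matrix(table, labels, 3, selected_features=selected),
    }
    return designs, selected


def labels_series(recordings, labels) -> pd.Series:
    return pd.Series(np.asarray(labels),
                     index=[pair[0].subject_id for pair in recordings])
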