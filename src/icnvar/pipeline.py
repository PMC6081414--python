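"""Glue between cohort generation, feature extraction and classification."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import assemble_feature_vector, pairwise_features
from .preprocess import bandpass
from .synthetic import Cohort


def cohort_feature_matrix(
    cohort: Cohort,
    metric: str = "VAR",
    apply_bandpass: bool = True,
    include_iq: bool = True,
    include_age: bool = True,
    include_motion: bool = True,
    **metric_kwargs,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Predictor matrix X, labels y and feature names for a cohort.

    Time-courses are band-pass filtered into 0.01-0.1 Hz before phase
    estimation by default (``apply_bandpass=False`` uses the raw series).
    """
    rows, names = [], None
    for record, tc in zip(cohort.records, cohort.timecourses):
        data = bandpass(tc.data, tc.tr_seconds) if apply_bandpass else tc.data
        tc_f = type(tc)(data=data, tr_seconds=tc.tr_seconds, labels=tc.labels)
        pairs = pairwise_features(tc_f, metric=metric, **metric_kwargs)
        vec, names = assemble_feature_vector(
            pairs,
            record,
            include_iq=include_iq,
            include_age=include_age,
            include_motion=include_motion,
        )
        rows.append(vec)
    return np.vstack(rows), cohort.labels, names


def features_to_frame(
    X: np.ndarray, y: np.ndarray, names: tuple[str, ...], subject_ids=None
) -> pd.DataFrame:
    """Features as a tidy table (one row per subject) for CSV round-trips."""
    df = pd.DataFrame(X, columns=list(names))
    df.insert(0, "group_label", y)
    if subject_ids is not None:
        df.insert(0, "subject_id", list(subject_ids))
    return df
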