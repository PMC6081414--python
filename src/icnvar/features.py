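"""Pairwise dynamic-connectivity metrics and predictor assembly.

Three metrics are computed for every unordered pair of network
time-courses:

* **VAR** (inter-network phase variability, the quantity of interest): the
  variance over frames of the instantaneous phase difference between the
  two series.  The instantaneous phase of each series is the angle of its
  analytic signal (series + i * Hilbert transform); the difference is
  wrapped to (-pi, pi] before the variance is taken.  A pair of networks
  that stays phase-locked has VAR near 0; a pair whose phase relation
  wanders has large VAR, approaching pi^2/3 when the wrapped difference is
  uniform on the circle.
* **FC**: Pearson correlation of the raw series (static functional
  connectivity).
* **PS**: the phase-locking value |mean_t exp(i * dphi(t))| (static phase
  synchrony).

For N networks the metrics are assembled in row-major upper-triangle
order, N(N-1)/2 values (45 for N = 10); this canonical order fixes feature
identity for weight reporting.  The full predictor vector of the
diagnostic model appends verbal/performance/full IQ, sex (male = 1), age
and mean framewise displacement to the 45 pairwise values.

Notes on estimator choices.  "Variance" is the ordinary sample variance
(denominator T - 1) of the wrapped differences; when the mean difference
sits near +/-pi, wrapping splits the sample across the branch cut and
inflates this estimator, so a circular variance (1 - R) alternative is
available via ``estimator="circular"``.  The discrete analytic signal is
unreliable near the series ends, so by default ceil(5% T) frames are
trimmed from each end before the variance or PLV is taken
(``trim_frac=0`` reproduces the full-series computation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .records import SubjectRecord
from .timecourses import TimeSeriesMatrix

METRICS = ("VAR", "FC", "PS")

#: Covariate block appended after the pairwise features, in model order.
COVARIATE_NAMES = ("viq", "piq", "fiq", "sex", "age", "mean_fd")


@dataclass(frozen=True)
class PairFeatureVector:
    """Metric values for all unordered component pairs, canonical order."""

    values: np.ndarray
    pair_labels: tuple[str, ...]
    metric: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.pair_labels):
            raise ValueError("values and pair labels disagree in length")


def wrap_phase(delta):
    """Wrap angles to the half-open interval (-pi, pi]; -pi maps to +pi."""
    delta = np.asarray(delta, dtype=float)
    if not np.isfinite(delta).all():
        raise ValueError("cannot wrap non-finite phase values")
    return np.pi - np.mod(np.pi - delta, 2.0 * np.pi)


def analytic_phase(series: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) of the discrete analytic signal."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("expected a 1D series")
    if series.size < 8:
        raise ValueError("series too short for a meaningful analytic signal")
    if np.ptp(series) == 0:
        raise ValueError("constant series: instantaneous phase undefined")
    return np.angle(hilbert(series))


def _trim(x: np.ndarray, trim_frac: float) -> np.ndarray:
    if trim_frac < 0 or trim_frac >= 0.5:
        raise ValueError("trim_frac must lie in [0, 0.5)")
    k = int(np.ceil(trim_frac * len(x)))
    return x[k: len(x) - k] if k else x


def phase_difference_variance(dphi: np.ndarray, ddof: int = 1, estimator: str = "wrapped") -> float:
    """Variance of phase differences after wrapping to (-pi, pi].

    ``estimator="wrapped"`` is the ordinary sample variance of the wrapped
    values; ``"circular"`` returns 1 - R (circular variance), bounded in
    [0, 1] and immune to branch-cut inflation.
    """
    w = wrap_phase(dphi)
    if estimator == "wrapped":
        return float(np.var(w, ddof=ddof))
    if estimator == "circular":
        return float(1.0 - np.abs(np.mean(np.exp(1j * w))))
    raise ValueError(f"unknown estimator {estimator!r}")


def inter_icn_variability(
    x: np.ndarray,
    y: np.ndarray,
    trim_frac: float = 0.05,
    ddof: int = 1,
    estimator: str = "wrapped",
) -> float:
    """Temporal variance of the wrapped instantaneous phase difference.

    Symmetric in (x, y), invariant to positive rescaling of either input
    and to a constant phase offset between them (up to analytic-signal
    edge effects).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    dphi = analytic_phase(x) - analytic_phase(y)
    return phase_difference_variance(_trim(dphi, trim_frac), ddof=ddof, estimator=estimator)


def functional_connectivity(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of the two series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def phase_synchrony(x: np.ndarray, y: np.ndarray, trim_frac: float = 0.05) -> float:
    """Phase-locking value of the instantaneous phase difference, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    dphi = _trim(analytic_phase(x) - analytic_phase(y), trim_frac)
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def pair_labels(labels) -> tuple[str, ...]:
    """Canonical pair labels: row-major upper triangle over component order."""
    labels = list(labels)
    return tuple(
        f"{labels[i]}-{labels[j]}"
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    )


def pairwise_features(tc: TimeSeriesMatrix, metric: str = "VAR", **metric_kwargs) -> PairFeatureVector:
    """One metric value per unordered component pair; N(N-1)/2 features."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    n = tc.n_components
    if n < 2:
        raise ValueError("need at least 2 components for pairwise features")
    fn = {
        "VAR": inter_icn_variability,
        "FC": functional_connectivity,
        "PS": phase_synchrony,
    }[metric]
    labels = pair_labels(tc.labels)
    values = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[k] = fn(tc.data[:, i], tc.data[:, j], **metric_kwargs)
            except ValueError as err:
                raise ValueError(f"pair {labels[k]}: {err}") from err
            k += 1
    return PairFeatureVector(values=values, pair_labels=labels, metric=metric)


def assemble_feature_vector(
    pairs: PairFeatureVector,
    record: SubjectRecord,
    include_iq: bool = True,
    include_age: bool = True,
    include_motion: bool = True,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Concatenate pairwise metrics with the covariate block of the model.

    Full order: [pair metrics..., viq, piq, fiq, sex, age, mean_fd]
    (51 predictors for 10 components).  The ablation flags drop the IQ,
    age or head-motion blocks, mirroring the reduced model variants.
    """
    values = list(pairs.values)
    names = [f"{pairs.metric}_{p}" for p in pairs.pair_labels]
    if include_iq:
        for key in ("viq", "piq", "fiq"):
            v = getattr(record, key)
            if v is None or not np.isfinite(v):
                raise ValueError(f"subject {record.subject_id}: missing covariate {key}")
            values.append(float(v))
            names.append(key)
    values.append(float(record.sex_code))
    names.append("sex")
    if include_age:
        if record.age is None or not np.isfinite(record.age):
            raise ValueError(f"subject {record.subject_id}: missing covariate age")
        values.append(float(record.age))
        names.append("age")
    if include_motion:
        if record.mean_fd is None or not np.isfinite(record.mean_fd):
            raise ValueError(f"subject {record.subject_id}: missing covariate mean_fd")
        values.append(float(record.mean_fd))
        names.append("mean_fd")
    return np.asarray(values, dtype=float), tuple(names)
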