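"""Pattern-recognition benchmark: Hudgins time-domain features, a 3^J
class linear discriminant classifier, and motion-normalized proportional
speed scalars derived from calibration MAV statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import CLASS_ENCODINGS, RawEmgRecording, StimulusEncoding

WINDOW_SAMPLES = 32
INCREMENT_SAMPLES = 3


def td_features(window: np.ndarray, zc_threshold: float = 0.0,
                ssc_threshold: float = 0.0) -> tuple[float, int, int, float]:
    """Mean absolute value, zero crossings, slope-sign changes, waveform
    length of one single-channel window."""
    x = np.asarray(window, float)
    if x.size < 2:
        raise ValueError("window too short for time-domain features")
    mav = float(np.abs(x).mean())
    prod = x[:-1] * x[1:]
    zc = int(np.count_nonzero((prod < 0) & (np.abs(x[:-1] - x[1:]) >= zc_threshold)))
    if x.size >= 3:
        d1 = x[1:-1] - x[:-2]
        d2 = x[1:-1] - x[2:]
        ssc = int(np.count_nonzero(d1 * d2 > ssc_threshold))
    else:
        ssc = 0
    wl = float(np.abs(np.diff(x)).sum())
    return mav, zc, ssc, wl


def feature_vector(window_block: np.ndarray, zc_threshold: float = 0.0,
                   ssc_threshold: float = 0.0) -> np.ndarray:
    """Flatten the per-channel feature quadruples of an (I, n) block."""
    feats = []
    for ch in window_block:
        feats.extend(td_features(ch, zc_threshold, ssc_threshold))
    return np.asarray(feats, float)


def window_count(n_samples: int, window: int = WINDOW_SAMPLES,
                 increment: int = INCREMENT_SAMPLES) -> int:
    if n_samples < window:
        raise ValueError("recording shorter than one feature window")
    return (n_samples - window) // increment + 1


def window_stream(recording: RawEmgRecording,
                  stimulus: StimulusEncoding | None = None,
                  window: int = WINDOW_SAMPLES,
                  increment: int = INCREMENT_SAMPLES):
    """Sliding-window features with optional majority-vote class labels.

    Yields ``(start_index, feature_vector, label)``; label is ``None``
    when no stimulus is given.  Majority ties resolve to the lowest
    class index.
    """
    n = recording.n_samples
    n_windows = window_count(n, window, increment)
    class_ids = stimulus.class_ids() if stimulus is not None else None
    for k in range(n_windows):
        start = k * increment
        block = recording.voltages[:, start:start + window]
        label = None
        if class_ids is not None:
            counts = np.bincount(class_ids[start:start + window], minlength=9)
            label = int(np.argmax(counts))
        yield start, feature_vector(block), label


@dataclass(frozen=True)
class ProportionalityTables:
    """Class-mean calibration MAVs S (I x M) and their column sums C."""

    S: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.C, self.S.sum(axis=0)):
            raise ValueError("C must equal the column sums of S")


@dataclass
class LdaModel:
    """Linear discriminant classifier with a shared covariance and a
    per-feature standard scaler fitted on calibration windows."""

    classes: np.ndarray
    means: np.ndarray        # (M, n_features), scaled space
    cov_inv: np.ndarray      # shared within-class covariance inverse
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def scale(self, features: np.ndarray) -> np.ndarray:
        return (features - self.scaler_mean) / self.scaler_sd


def fit_proportionality(mav: np.ndarray, labels: np.ndarray,
                        n_classes: int = 9) -> ProportionalityTables:
    """Class-mean calibration MAV table S (one column per class) and its
    channel sums C, from unscaled per-window MAV vectors."""
    mav = np.atleast_2d(np.asarray(mav, float))
    labels = np.asarray(labels, int)
    for m in range(n_classes):
        if np.count_nonzero(labels == m) < 1:
            raise ValueError(f"calibration lacks coverage of class {m}")
    S = np.stack(
        [mav[labels == m].mean(axis=0) for m in range(n_classes)], axis=1
    )  # (I, M)
    return ProportionalityTables(S=S, C=S.sum(axis=0))


def fit(features: np.ndarray, labels: np.ndarray,
        n_classes: int = 9, ridge: float = 1e-6
        ) -> tuple[LdaModel, ProportionalityTables]:
    """Calibrate the classifier and proportionality tables.

    ``features`` is (n_windows, 4*I) with MAVs at columns 0, 4, 8, ...;
    S and C are computed from the unscaled MAV columns; the classifier
    uses standardized features and uniform priors.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels, int)
    for m in range(n_classes):
        if np.count_nonzero(labels == m) < 2:
            raise ValueError(f"calibration lacks coverage of class {m}")

    tables = fit_proportionality(features[:, 0::4], labels, n_classes)

    scaler_mean = features.mean(axis=0)
    scaler_sd = features.std(axis=0)
    scaler_sd = np.where(scaler_sd == 0, 1.0, scaler_sd)
    Z = (features - scaler_mean) / scaler_sd

    means = np.stack([Z[labels == m].mean(axis=0) for m in range(n_classes)])
    # pooled within-class covariance
    resid = Z - means[labels]
    cov = resid.T @ resid / (Z.shape[0] - n_classes)
    dim = cov.shape[0]
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        cov = cov + (ridge * np.trace(cov) / dim) * np.eye(dim)
    cov_inv = np.linalg.inv(cov)

    model = LdaModel(
        classes=np.arange(n_classes),
        means=means,
        cov_inv=cov_inv,
        scaler_mean=scaler_mean,
        scaler_sd=scaler_sd,
    )
    return model, tables


def discriminants(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """Gaussian discriminant scores (uniform priors) per class."""
    z = model.scale(np.atleast_2d(features))
    scores = z @ model.cov_inv @ model.means.T - 0.5 * np.einsum(
        "mi,ij,mj->m", model.means, model.cov_inv, model.means
    )
    return scores


def classify(model: LdaModel, features: np.ndarray) -> int:
    """Most likely class; ties resolve to the lowest class index."""
    scores = discriminants(model, features)
    return int(np.argmax(scores, axis=-1)[0] if scores.ndim > 1 else np.argmax(scores))


def proportionality(mav_vector: np.ndarray, m: int,
                    tables: ProportionalityTables) -> float:
    """Motion-normalized proportional speed scalar for class ``m``:
    the S-weighted, C-normalized MAV sum, squared."""
    if m < 1 or m >= tables.S.shape[1]:
        raise ValueError(f"class {m} has no proportionality scalar")
    c = tables.C[m]
    if c <= 0:
        raise ValueError(f"degenerate class {m}: zero calibration MAV sum")
    weighted = float(tables.S[:, m] @ np.asarray(mav_vector, float)) / c
    return weighted ** 2


def mvc_magnitude(recording: RawEmgRecording, window_seconds: float = 0.5) -> float:
    """Maximum over sliding windows of the channel-summed MAV."""
    w = int(round(window_seconds * recording.sampling_rate))
    if recording.n_samples < w:
        raise ValueError("recording shorter than the MAV window")
    rect = np.abs(recording.voltages)
    windows = np.lib.stride_tricks.sliding_window_view(rect, w, axis=1)
    summed = windows.mean(axis=-1).sum(axis=0)  # channel-summed MAV per position
    return float(summed.max())


def calibrate_from_session(recording: RawEmgRecording,
                           stimulus: StimulusEncoding,
                           zc_threshold: float = 0.0,
                           ssc_threshold: float = 0.0
                           ) -> tuple[LdaModel, ProportionalityTables]:
    """Windowing + feature extraction + fit, straight from a session."""
    starts, feats, labels = [], [], []
    for start, vec, label in window_stream(recording, stimulus):
        starts.append(start)
        feats.append(vec)
        labels.append(label)
    return fit(np.asarray(feats), np.asarray(labels))
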