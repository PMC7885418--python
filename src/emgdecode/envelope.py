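"""Envelope extraction and normalization of raw sEMG.

Pipeline: full-wave rectification, causal moving-average FIR filtering
(growing window during warm-up), per-channel rescaling by calibration
1st/99th percentiles, clipping to [0, 1] and an element-wise square
root.  A streaming variant reproduces the batch pipeline sample by
sample, bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synth import RawEmgRecording


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel 1st and 99th percentile of the raw envelope."""

    p1: np.ndarray
    p99: np.ndarray

    def __post_init__(self):
        if np.any(self.p99 <= self.p1):
            bad = int(np.flatnonzero(self.p99 <= self.p1)[0])
            raise ValueError(f"degenerate channel {bad}: p99 <= p1")

    def to_json(self) -> str:
        return json.dumps({"p1": self.p1.tolist(), "p99": self.p99.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        d = json.loads(text)
        return cls(p1=np.asarray(d["p1"], float), p99=np.asarray(d["p99"], float))


@dataclass(frozen=True)
class EnvelopeSet:
    """I x T envelope matrix tagged with its processing stage."""

    values: np.ndarray
    stage: str  # "raw" (unbounded) or "normalized" (in [0, 1])
    filter_length: int


def filter_length_samples(window_seconds: float, sampling_rate: float) -> int:
    return int(round(window_seconds * sampling_rate))


def group_delay_seconds(window_seconds: float, sampling_rate: float) -> float:
    """FIR moving-average lag (W - 1) / (2 Fs)."""
    w = filter_length_samples(window_seconds, sampling_rate)
    return (w - 1) / (2.0 * sampling_rate)


def extract_envelope(raw: RawEmgRecording, window_seconds: float = 0.5) -> EnvelopeSet:
    """Rectify and causally moving-average filter a recording.

    Output column t is the mean of |x| over the trailing ``W`` samples;
    for t < W - 1 the mean runs over the t + 1 available samples.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    if raw.n_samples == 0:
        raise ValueError("empty recording")
    w = filter_length_samples(window_seconds, raw.sampling_rate)
    if w < 1:
        raise ValueError("filter length rounds to zero samples")
    rect = np.abs(raw.voltages)  # (I, T)
    T = rect.shape[1]
    env = np.empty_like(rect, dtype=float)
    # warm-up: growing-window means (same element order as streaming buffer)
    for t in range(min(w - 1, T)):
        env[:, t] = rect[:, : t + 1].mean(axis=1)
    if T >= w:
        windows = np.lib.stride_tricks.sliding_window_view(rect, w, axis=1)
        env[:, w - 1:] = windows.mean(axis=-1)
    return EnvelopeSet(values=env, stage="raw", filter_length=w)


def fit_normalization(env: EnvelopeSet) -> NormalizationStats:
    """Per-channel 1st/99th envelope percentiles (linear interpolation)."""
    if env.stage != "raw":
        raise ValueError("normalization statistics are fitted on raw envelopes")
    if env.values.shape[1] < 100:
        raise ValueError("need at least 100 samples for stable percentiles")
    p1 = np.percentile(env.values, 1.0, axis=1)
    p99 = np.percentile(env.values, 99.0, axis=1)
    return NormalizationStats(p1=p1, p99=p99)


def apply_normalization(env: EnvelopeSet, stats: NormalizationStats) -> EnvelopeSet:
    """Rescale by (p1, p99), clip to [0, 1] and take the square root."""
    if env.values.shape[0] != stats.p1.shape[0]:
        raise ValueError(
            f"channel mismatch: envelope has {env.values.shape[0]}, "
            f"stats have {stats.p1.shape[0]}"
        )
    scaled = (env.values - stats.p1[:, None]) / (stats.p99 - stats.p1)[:, None]
    return EnvelopeSet(
        values=np.sqrt(np.clip(scaled, 0.0, 1.0)),
        stage="normalized",
        filter_length=env.filter_length,
    )


def preprocess(raw: RawEmgRecording, window_seconds: float = 0.5
               ) -> tuple[EnvelopeSet, NormalizationStats]:
    """Full batch pipeline: envelope, percentile fit, normalization."""
    env = extract_envelope(raw, window_seconds)
    stats = fit_normalization(env)
    return apply_normalization(env, stats), stats


class StreamingEnvelope:
    """Sample-by-sample replica of the batch preprocessing pipeline.

    After ``t`` calls the output equals column ``t`` of the batch result
    exactly (identical arithmetic, identical summation order).
    """

    def __init__(self, stats: NormalizationStats, filter_length: int,
                 n_channels: int | None = None):
        if filter_length < 1:
            raise ValueError("filter_length must be >= 1")
        self.stats = stats
        self.w = int(filter_length)
        self.n_channels = int(n_channels if n_channels is not None else stats.p1.shape[0])
        # (I, W) layout keeps the reduction axis contiguous, so the mean
        # uses the same pairwise summation order as the batch pipeline
        self._buf = np.zeros((self.n_channels, self.w))
        self._count = 0

    def reset(self) -> None:
        self._buf[:] = 0.0
        self._count = 0

    def step(self, sample: np.ndarray) -> np.ndarray:
        """Consume one raw voltage vector, return the normalized envelope."""
        sample = np.asarray(sample, dtype=float)
        if sample.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} channel values")
        self._buf[:, :-1] = self._buf[:, 1:]
        self._buf[:, -1] = np.abs(sample)
        self._count += 1
        n = min(self._count, self.w)
        env = self._buf[:, self.w - n:].mean(axis=1)
        scaled = (env - self.stats.p1) / (self.stats.p99 - self.stats.p1)
        return np.sqrt(np.clip(scaled, 0.0, 1.0))
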