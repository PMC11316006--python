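"""EMG signal processing: causal filtering, 100 ms RMS bins, lag stacking.

The chain mirrors a streaming-capable myoelectric front end: a 60 Hz IIR
notch followed by a 10th-order Butterworth bandpass (20-400 Hz), applied
causally (forward-only) so that the same filters can run sample-by-sample
in the simulated real-time loop.  RMS is extracted over non-overlapping
100 ms bins; the current bin is concatenated with the 4 preceding bins
(oldest first) to give the models short-term temporal context; features
are z-scored with statistics learned from the training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, FittingError
from .simdata import EMGRecording

log = logging.getLogger(__name__)

DEFAULT_BIN_MS = 100.0
DEFAULT_N_LAGS = 5
SCALER_EPS = 1e-8


@dataclass(frozen=True)
class FilterSpec:
    """Notch + bandpass design.

    ``order`` is the overall Butterworth bandpass order (an even number;
    the design uses order/2 pole pairs per band edge).  ``notch_q`` is the
    notch quality factor.
    """

    notch_hz: float = 60.0
    bandpass_hz: tuple[float, float] = (20.0, 400.0)
    order: int = 10
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not (0 < lo < hi):
            raise ConfigurationError("band edges must satisfy 0 < lo < hi")
        if self.order <= 0 or self.order % 2:
            raise ConfigurationError("order must be even and positive")

    def design_sos(self, fs_hz: float) -> np.ndarray:
        """Cascaded second-order sections: notch first, then bandpass."""
        lo, hi = self.bandpass_hz
        if fs_hz <= 2 * hi:
            raise ConfigurationError(
                f"fs={fs_hz} too low for band edge {hi} Hz (need fs > {2 * hi})"
            )
        b, a = sps.iirnotch(self.notch_hz, self.notch_q, fs=fs_hz)
        notch_sos = sps.tf2sos(b, a)
        bp_sos = sps.butter(
            self.order // 2, (lo, hi), btype="bandpass", fs=fs_hz, output="sos"
        )
        return np.vstack([notch_sos, bp_sos])


def filter_emg(rec: EMGRecording, spec: FilterSpec | None = None) -> EMGRecording:
    """Apply notch then bandpass causally (forward-only) per channel."""
    spec = spec or FilterSpec()
    sos = spec.design_sos(rec.fs_hz)
    # float64 so chunked streaming with persisted state reproduces this exactly
    out = sps.sosfilt(sos, rec.signal.astype(np.float64), axis=1)
    return replace(rec, signal=out)


def compute_rms_bins(
    rec: EMGRecording, bin_ms: float = DEFAULT_BIN_MS
) -> tuple[np.ndarray, np.ndarray]:
    """RMS per channel over consecutive non-overlapping bins.

    Returns (bins x channels matrix, per-bin end times in seconds).  The
    trailing partial bin is dropped.  At 3000 Hz and 100 ms each bin spans
    300 samples.
    """
    samples_per_bin = rec.fs_hz * bin_ms / 1000.0
    n = int(round(samples_per_bin))
    if abs(samples_per_bin - n) > 1e-9 or n < 1:
        raise ConfigurationError(
            f"bin of {bin_ms} ms is not an integer sample count at fs={rec.fs_hz}"
        )
    n_bins = rec.signal.shape[1] // n
    if n_bins == 0:
        log.warning("recording shorter than one bin; returning empty RMS matrix")
        return np.empty((0, rec.layout.n_channels)), np.empty(0)
    x = rec.signal[:, : n_bins * n].astype(np.float64)
    rms = np.sqrt(np.mean(x.reshape(x.shape[0], n_bins, n) ** 2, axis=2)).T
    bin_times = rec.t0 + (np.arange(1, n_bins + 1) * n) / rec.fs_hz
    return rms, bin_times


@dataclass
class Scaler:
    """Per-feature (mean, sd) learned from the training split."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class FeatureMatrix:
    """Per-bin lagged-RMS feature rows on the 10 Hz bin clock.

    Row t concatenates the channel blocks of bins [t-4 .. t], oldest
    first, so the column count is n_channels * n_lags.
    """

    values: np.ndarray
    bin_times_s: np.ndarray
    n_channels: int
    n_lags: int = DEFAULT_N_LAGS
    bin_ms: float = DEFAULT_BIN_MS
    standardized: bool = False
    scaler: Scaler | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.n_channels * self.n_lags:
            raise ConfigurationError(
                "feature width must equal n_channels * n_lags: "
                f"{self.values.shape[1]} != {self.n_channels}*{self.n_lags}"
            )
        if self.values.shape[0] != len(self.bin_times_s):
            raise ConfigurationError("one bin time per feature row required")


def stack_lags(
    rms: np.ndarray,
    bin_times_s: np.ndarray,
    n_lags: int = DEFAULT_N_LAGS,
    bin_ms: float = DEFAULT_BIN_MS,
) -> FeatureMatrix:
    """Concatenate each bin with its preceding ``n_lags - 1`` bins.

    Missing history at the start is causally padded by replicating the
    earliest available bin, preserving the row <-> label alignment and
    matching the warm-up behaviour of the streaming loop.
    """
    if n_lags < 1:
        raise ConfigurationError("n_lags must be >= 1")
    rms = np.asarray(rms, dtype=np.float64)
    n_bins, n_ch = rms.shape
    padded = np.vstack([np.repeat(rms[:1], n_lags - 1, axis=0), rms]) if n_bins else rms
    blocks = [padded[lag : lag + n_bins] for lag in range(n_lags)]  # oldest first
    values = np.concatenate(blocks, axis=1) if n_bins else rms.reshape(0, n_ch * n_lags)
    return FeatureMatrix(
        values=values,
        bin_times_s=np.asarray(bin_times_s, dtype=float),
        n_channels=n_ch,
        n_lags=n_lags,
        bin_ms=bin_ms,
    )


def fit_scaler(features: FeatureMatrix, train_mask: np.ndarray) -> Scaler:
    """Learn per-feature z-scoring statistics from the masked (training) rows.

    Zero-variance features are guarded with sd + 1e-8 so constant columns
    standardize to zero rather than NaN.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape[0] != features.values.shape[0]:
        raise FittingError("train_mask length must match feature rows")
    if train_mask.sum() < 2:
        raise FittingError("training mask must select at least 2 bins")
    x = features.values[train_mask]
    return Scaler(mean=x.mean(axis=0), sd=x.std(axis=0))


def apply_scaler(features: FeatureMatrix, scaler: Scaler) -> FeatureMatrix:
    """Return a standardized copy of ``features`` using training statistics."""
    z = (features.values - scaler.mean) / (scaler.sd + SCALER_EPS)
    return replace(features, values=z, standardized=True, scaler=scaler)
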