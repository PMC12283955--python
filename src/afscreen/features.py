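"""R-peak detection, R-R interval computation, per-patient mean normalization,
and the minimum-peak admission filters.

The pipeline keeps exactly one feature per patient: the collection of
normalized R-R intervals

    x_i = delta_i / mean_j(delta_j),   delta_i = t_{i+1} - t_i,

so every feature vector has mean 1 and no units.  Because the normalization is
scale-invariant, it is immaterial whether intervals are measured in sample
indices or seconds.

Peak detection is a pluggable registry.  One simple built-in detector ships
with the package (band-passed squared-derivative energy with an adaptive
threshold, in the Pan-Tompkins tradition); published detectors such as XQRS
are registered as lazy adapters that require their backend package at call
time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import InsufficientPeaksError
from .io import Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakIndices:
    """Sample positions of detected R-peaks (strictly increasing)."""

    indices: np.ndarray
    fs: float
    detector_name: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.indices.size and self.indices[0] < 0:
            raise ValueError("peak indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class RRiVector:
    """One patient's mean-normalized R-R interval samples (unitless, mean 1)."""

    values: np.ndarray
    patient_id: str = ""
    binary_label: int | None = None
    raw_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"RRiVector {self.patient_id!r}: needs at least one interval")
        if np.any(self.values <= 0):
            raise ValueError(f"RRiVector {self.patient_id!r}: intervals must be positive")
        if abs(self.values.mean() - 1.0) > 1e-9:
            raise ValueError(f"RRiVector {self.patient_id!r}: mean must be 1 "
                             f"(got {self.values.mean():.12g}); call normalize() first")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def id(self) -> str:  # uniform access alongside Recording.id
        return self.patient_id


# ---------------------------------------------------------------------------
# Detector registry
# ---------------------------------------------------------------------------

_DETECTORS: dict[str, Callable] = {}


def register_detector(name: str):
    """Decorator registering ``fn(samples, fs) -> indices`` under ``name``."""

    def deco(fn):
        _DETECTORS[name] = fn
        return fn

    return deco


def available_detectors() -> list:
    return sorted(_DETECTORS)


@register_detector("threshold")
def _threshold_detector(samples: np.ndarray, fs: float) -> np.ndarray:
    """Built-in detector: band-pass, square, integrate, adaptive threshold.

    The QRS energy envelope is the 150 ms moving average of the squared
    band-passed signal (5-15 Hz where the sampling rate allows).  Regions
    above 30% of the peak envelope, separated by a 200 ms refractory period,
    each contribute one peak placed at the local maximum of the raw trace.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return np.empty(0, dtype=np.int64)
    if fs > 40:
        b, a = sps.butter(2, [5.0 / (fs / 2), min(15.0 / (fs / 2), 0.99)], btype="band")
        bp = sps.filtfilt(b, a, x)
    else:
        bp = x - np.median(x)
    energy = bp ** 2
    win = max(1, int(round(0.150 * fs)))
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    if env.max() <= 0:
        return np.empty(0, dtype=np.int64)
    above = env > 0.3 * env.max()
    refractory = max(1, int(round(0.200 * fs)))
    peaks = []
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j < n and (above[j] or (j - i) < 1):
                if not above[j]:
                    break
                j += 1
            # widen slightly so the raw maximum is inside the window
            lo = max(0, i - win // 2)
            hi = min(n, j + win // 2)
            peak = lo + int(np.argmax(x[lo:hi]))
            if not peaks or peak - peaks[-1] >= refractory:
                peaks.append(peak)
            i = j + refractory
        else:
            i += 1
    return np.array(sorted(set(peaks)), dtype=np.int64)


def _lazy_adapter(name: str, module: str, hint: str):
    @register_detector(name)
    def adapter(samples, fs, _module=module, _hint=hint, _name=name):
        try:
            __import__(_module)
        except ImportError as err:
            raise ImportError(
                f"detector {_name!r} requires the optional package {_module!r} "
                f"({_hint}); install it or use the built-in 'threshold' detector"
            ) from err
        return _dispatch_external(_name, samples, fs)

    return adapter


def _dispatch_external(name: str, samples, fs):
    if name == "xqrs":
        from wfdb import processing as wp

        xqrs = wp.XQRS(sig=np.asarray(samples, float), fs=fs)
        xqrs.detect(verbose=False)
        return np.asarray(xqrs.qrs_inds, dtype=np.int64)
    import neurokit2 as nk

    method = {"pantompkins": "pantompkins1985", "hamilton": "hamilton2002",
              "christov": "christov2004", "elgendi": "elgendi2010",
              "rodrigues": "rodrigues2021", "zong": "zong2003",
              "makowski": "neurokit"}[name]
    _, info = nk.ecg_peaks(np.asarray(samples, float), sampling_rate=fs, method=method)
    return np.asarray(info["ECG_R_Peaks"], dtype=np.int64)


_lazy_adapter("xqrs", "wfdb", "PhysioNet's XQRS detector")
for _nm in ("pantompkins", "hamilton", "christov", "elgendi", "rodrigues", "zong", "makowski"):
    _lazy_adapter(_nm, "neurokit2", f"the published {_nm} detector")


def detect_peaks(recording: Recording, detector: str = "threshold") -> PeakIndices:
    """Run the named detector backend on a recording.

    Coincident duplicate indices from a backend are removed with a logged
    warning, guaranteeing strictly increasing output (hence strictly positive
    intervals downstream).  An empty result is allowed; the minimum-peak
    filter discards such recordings later.
    """
    if detector not in _DETECTORS:
        raise KeyError(f"unknown detector {detector!r}; registered backends: "
                       f"{available_detectors()}")
    raw = np.asarray(_DETECTORS[detector](recording.samples, recording.fs), dtype=np.int64)
    uniq = np.unique(raw)  # sorts and deduplicates
    if uniq.size != raw.size:
        logger.warning("detector %s returned %d duplicate indices on %s; removed",
                       detector, raw.size - uniq.size, recording.id)
    if uniq.size and (uniq[0] < 0 or uniq[-1] >= recording.samples.size):
        raise ValueError(f"detector {detector!r} returned out-of-range indices on "
                         f"{recording.id!r}")
    return PeakIndices(indices=uniq, fs=recording.fs, detector_name=detector)


# ---------------------------------------------------------------------------
# Intervals and normalization
# ---------------------------------------------------------------------------

def compute_intervals(peaks: PeakIndices) -> np.ndarray:
    """Successive R-R intervals in seconds: ``(t_{i+1} - t_i) / fs``."""
    if len(peaks) < 2:
        raise InsufficientPeaksError(
            f"need at least 2 peaks to form an interval, got {len(peaks)}")
    return np.diff(peaks.indices).astype(float) / peaks.fs


def normalize(intervals: Sequence[float], patient_id: str = "",
              binary_label: int | None = None, raw_label: str = "") -> RRiVector:
    """Divide intervals by their mean, yielding a unitless vector of mean 1.

    Scale-invariant: ``normalize(c * delta) == normalize(delta)`` for any
    ``c > 0``, so sample-index and seconds units are interchangeable upstream.
    """
    delta = np.asarray(intervals, dtype=float)
    if delta.size == 0:
        raise InsufficientPeaksError("cannot normalize an empty interval sequence")
    if np.any(delta <= 0):
        raise ValueError("non-positive interval encountered; this signals a "
                         "peak-detection artifact upstream")
    return RRiVector(values=delta / delta.mean(), patient_id=patient_id,
                     binary_label=binary_label, raw_label=raw_label)


#: Minimum peak counts per source corpus; overridable everywhere.
MIN_PEAKS_BY_SOURCE = {"sph": 8, "diagnostick": 51, "cinc": 20, "synthetic": 2}


def filter_min_peaks(items: Sequence, min_peaks: int):
    """Retain ``(recording, peaks)`` pairs with at least ``min_peaks`` peaks.

    Returns ``(retained, report)`` where the report lists every discarded id
    with its peak count.  Filtering is total: retained + discarded equals the
    input count.
    """
    if min_peaks < 2:
        raise ValueError(f"min_peaks must be >= 2, got {min_peaks}")
    retained, report = [], []
    for rec, peaks in items:
        if len(peaks) >= min_peaks:
            retained.append((rec, peaks))
        else:
            report.append({"id": rec.id, "peak_count": len(peaks),
                           "reason": f"fewer than {min_peaks} peaks"})
    return retained, report


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

class RRIntervalExtractor(TransformerMixin, BaseEstimator):
    """Transform ECG recordings into normalized R-R interval vectors.

    Parameters
    ----------
    detector : str, default="threshold"
        Name of a registered peak-detection backend.
    min_peaks : int, default=2
        Recordings with fewer detected peaks are discarded (reported in
        ``discard_report_`` after :meth:`transform`).

    Attributes
    ----------
    discard_report_ : list of dict
        Ids and peak counts of recordings dropped by the minimum-peak filter
        during the most recent :meth:`transform`.
    """

    def __init__(self, detector: str = "threshold", min_peaks: int = 2):
        self.detector = detector
        self.min_peaks = min_peaks

    def fit(self, X=None, y=None):
        if self.detector not in _DETECTORS:
            raise KeyError(f"unknown detector {self.detector!r}; registered: "
                           f"{available_detectors()}")
        if self.min_peaks < 2:
            raise ValueError(f"min_peaks must be >= 2, got {self.min_peaks}")
        return self

    def transform(self, X: Sequence[Recording]) -> list:
        """Detect peaks, filter, and return one :class:`RRiVector` per retained recording."""
        self.fit()
        pairs = [(rec, detect_peaks(rec, self.detector)) for rec in X]
        retained, report = filter_min_peaks(pairs, self.min_peaks)
        self.discard_report_ = report
        out = []
        for rec, peaks in retained:
            out.append(normalize(compute_intervals(peaks), patient_id=rec.id,
                                 raw_label=rec.raw_label,
                                 binary_label=getattr(rec, "binary_label", None)))
        return out


def extract_rri(recordings: Sequence[Recording], detector: str = "threshold",
                min_peaks: int = 2):
    """Functional wrapper over :class:`RRIntervalExtractor`; returns (vectors, discard report)."""
    tf = RRIntervalExtractor(detector=detector, min_peaks=min_peaks)
    vectors = tf.transform(recordings)
    return vectors, tf.discard_report_
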