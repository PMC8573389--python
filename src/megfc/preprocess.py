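"""Band decomposition and segment extraction for multichannel MEG-like recordings.

The analysis decomposes each recording into seven canonical neurophysiological
frequency bands (delta through fast ripple) and, around each spike-and-wave
seizure, extracts three period segments: a 3-s ictal segment starting at seizure
onset, a 3-s termination segment ending at seizure offset, and a 30-s interictal
segment placed at least 10 s away from the seizure.

Filters are zero-phase (forward-backward second-order sections), so band-limited
features are not shifted in time.  Segments are filtered after extraction with
1 s of context taken from the recording where available (reflection padding
otherwise) to keep filter transients out of the analysed window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import SegmentUnavailableError

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")

PERIOD_ICTAL = "ictal"
PERIOD_TERMINATION = "termination"
PERIOD_INTERICTAL = "interictal"
PERIODS = (PERIOD_ICTAL, PERIOD_TERMINATION, PERIOD_INTERICTAL)

#: Minimum seizure duration (s) so that the two 3-s windows cannot overlap.
MIN_EVENT_DURATION_S = 6.0


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    @property
    def bandwidth(self) -> float:
        return self.f_hi - self.f_lo


_DEFAULT_BANDS = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 80.0),
    BandSpec("ripple", 80.0, 250.0),
    BandSpec("fast ripple", 250.0, 500.0),
)


def default_bands() -> list[BandSpec]:
    """The seven analysis bands: delta (1–4 Hz), theta (4–8), alpha (8–12),
    beta (12–30), gamma (30–80), ripple (80–250) and fast ripple (250–500)."""
    return list(_DEFAULT_BANDS)


def band_by_name(name: str) -> BandSpec:
    for b in _DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


@dataclass
class Recording:
    """A channels x samples multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in arbitrary field units.
    fs : float
        Sampling rate in samples/second.
    channel_labels : list of str
        Unique channel names.
    region_of : dict
        Maps each channel label to one of ``REGIONS``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    region_of: dict[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        missing = [c for c in self.channel_labels if c not in self.region_of]
        if missing:
            raise ValueError(f"channels without region assignment: {missing}")
        bad = {c: r for c, r in self.region_of.items() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {bad}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def regions(self) -> list[str]:
        """Region label per channel, in channel order."""
        return [self.region_of[c] for c in self.channel_labels]

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.channel_labels), dict(self.region_of)
        )


@dataclass(frozen=True)
class SeizureEvent:
    """One spike-and-wave discharge: onset = first spike, offset = last slow wave."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.offset_s - self.onset_s < MIN_EVENT_DURATION_S - 1e-9:
            raise ValueError(
                f"seizure must last >= {MIN_EVENT_DURATION_S} s so the ictal and "
                f"termination windows are disjoint; got "
                f"{self.offset_s - self.onset_s:.3f} s"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SegmentWindow:
    """A raw (unfiltered) period window plus filtering context.

    ``data`` holds the window with ``pad_left``/``pad_right`` context samples on
    either side; ``core`` strips the context.
    """

    period: str
    start_s: float
    stop_s: float
    data: np.ndarray
    pad_left: int
    pad_right: int
    fs: float
    channel_labels: list[str]
    region_of: dict[str, str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1] - self.pad_left - self.pad_right

    @property
    def core(self) -> np.ndarray:
        stop = self.data.shape[1] - self.pad_right
        return self.data[:, self.pad_left : stop]


@dataclass
class AnalysisSegment:
    """A period-labeled, band-filtered slice of a recording."""

    period: str
    band: BandSpec
    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    region_of: dict[str, str] = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _notch_sos(fs: float, base_hz: float, max_hz: float | None, q: float) -> np.ndarray:
    nyq = fs / 2.0
    if base_hz >= nyq:
        raise ValueError(f"notch base {base_hz} Hz must lie below Nyquist ({nyq} Hz)")
    top = nyq if max_hz is None else min(max_hz, nyq)
    sections = []
    f = base_hz
    while f < top:
        b, a = signal.iirnotch(f, q, fs=fs)
        sections.append(signal.tf2sos(b, a))
        f += base_hz
    return np.vstack(sections)


def notch_array(
    x: np.ndarray, fs: float, base_hz: float = 50.0, max_hz: float | None = None, q: float = 30.0
) -> np.ndarray:
    """Zero-phase comb of band-stop filters at ``base_hz`` and its harmonics."""
    sos = _notch_sos(fs, base_hz, max_hz, q)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def notch(
    recording: Recording,
    base_hz: float = 50.0,
    max_hz: float | None = None,
    q: float = 30.0,
) -> Recording:
    """Remove power-line interference at ``base_hz`` and all harmonics below Nyquist."""
    out = recording.copy()
    out.data = notch_array(recording.data, recording.fs, base_hz, max_hz, q)
    return out


@lru_cache(maxsize=256)
def _band_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    if band.f_hi >= fs / 2.0:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_hi} Hz must lie below "
            f"Nyquist ({fs / 2.0} Hz)"
        )
    return signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``x`` along its last axis."""
    sos = _band_sos(band, fs, order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def bandpass(recording: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Band-limit a recording to ``band`` with a zero-phase Butterworth filter."""
    out = recording.copy()
    out.data = bandpass_array(recording.data, band, recording.fs, order)
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _window_with_context(
    recording: Recording, start_s: float, stop_s: float, pad_s: float, period: str
) -> SegmentWindow:
    fs = recording.fs
    i0 = int(np.floor(start_s * fs))
    i1 = int(np.floor(stop_s * fs))
    pad = int(round(pad_s * fs))
    lo = max(0, i0 - pad)
    hi = min(recording.n_samples, i1 + pad)
    chunk = recording.data[:, lo:hi]
    left_have = i0 - lo
    right_have = hi - i1
    # Reflect to make up any context the recording could not provide.
    left_missing = pad - left_have
    right_missing = pad - right_have
    if left_missing > 0 or right_missing > 0:
        chunk = np.pad(
            chunk,
            ((0, 0), (max(0, left_missing), max(0, right_missing))),
            mode="reflect",
        )
    return SegmentWindow(
        period=period,
        start_s=start_s,
        stop_s=stop_s,
        data=chunk,
        pad_left=pad,
        pad_right=pad,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        region_of=dict(recording.region_of),
    )


def extract_segments(
    recording: Recording,
    event: SeizureEvent,
    interictal_gap_s: float = 10.0,
    ictal_len_s: float = 3.0,
    interictal_len_s: float = 30.0,
    pad_s: float = 1.0,
    periods: tuple[str, ...] = PERIODS,
) -> dict[str, SegmentWindow]:
    """Extract the raw period windows around one seizure.

    ictal = [onset, onset + 3 s); termination = [offset − 3 s, offset);
    interictal = the earliest 30-s window starting at least ``interictal_gap_s``
    after offset, or failing that the latest 30-s window ending at least that far
    before onset.

    Raises
    ------
    SegmentUnavailableError
        If the recording cannot host a requested window, naming the shortfall.
    """
    out: dict[str, SegmentWindow] = {}
    dur = recording.duration_s

    if PERIOD_ICTAL in periods:
        stop = event.onset_s + ictal_len_s
        if stop > dur:
            raise SegmentUnavailableError(
                f"ictal window [{event.onset_s}, {stop}) s exceeds recording "
                f"duration {dur:.3f} s by {stop - dur:.3f} s"
            )
        out[PERIOD_ICTAL] = _window_with_context(
            recording, event.onset_s, stop, pad_s, PERIOD_ICTAL
        )

    if PERIOD_TERMINATION in periods:
        start = event.offset_s - ictal_len_s
        if event.offset_s > dur:
            raise SegmentUnavailableError(
                f"termination window ends at {event.offset_s} s but recording "
                f"lasts {dur:.3f} s"
            )
        out[PERIOD_TERMINATION] = _window_with_context(
            recording, start, event.offset_s, pad_s, PERIOD_TERMINATION
        )

    if PERIOD_INTERICTAL in periods:
        after_start = event.offset_s + interictal_gap_s
        before_start = event.onset_s - interictal_gap_s - interictal_len_s
        if after_start + interictal_len_s <= dur:
            start = after_start
        elif before_start >= 0:
            start = before_start
        else:
            need_after = after_start + interictal_len_s - dur
            raise SegmentUnavailableError(
                f"no {interictal_len_s:.0f}-s interictal window fits "
                f">= {interictal_gap_s:.0f} s from the seizure: recording is "
                f"{need_after:.3f} s too short after offset and the pre-onset "
                f"window would start at {before_start:.3f} s"
            )
        out[PERIOD_INTERICTAL] = _window_with_context(
            recording, start, start + interictal_len_s, pad_s, PERIOD_INTERICTAL
        )

    return out


def filter_segment(
    window: SegmentWindow,
    band: BandSpec,
    notch_base: float | None = 50.0,
    order: int = 4,
) -> AnalysisSegment:
    """Notch + band-pass one raw window, then strip the filtering context."""
    x = window.data
    if notch_base is not None:
        x = notch_array(x, window.fs, notch_base)
    x = bandpass_array(x, band, window.fs, order)
    stop = x.shape[1] - window.pad_right
    return AnalysisSegment(
        period=window.period,
        band=band,
        data=x[:, window.pad_left : stop],
        fs=window.fs,
        channel_labels=list(window.channel_labels),
        region_of=dict(window.region_of),
    )
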