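"""Band-pass filtering, epoch segmentation and the eight-window scheme.

The decoding problem is framed around a cue-paced calibration run: a fixation
cross appears at t = 0 s of each trial cycle, the imagery cue spans 2-6 s, and
a break follows.  Epochs are therefore cut from 2 to 6 s after each event so
that a 4-s epoch covers exactly the imagery (or rest) interval.  Within that
epoch, eight non-overlapping analysis windows tile the four canonical
durations: four of 0.5 s, two of 1 s, one of 2 s and one of 4 s, all anchored
at the epoch start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: epoch extent relative to the cue-cycle origin (fixation cross), seconds
EPOCH_START_S = 2.0
EPOCH_END_S = 6.0
EPOCH_LEN_S = EPOCH_END_S - EPOCH_START_S

#: mu/beta band and filter defaults
DEFAULT_BAND = (8.0, 30.0)
DEFAULT_FILTER_ORDER = 2


@dataclass
class RawRecording:
    """Continuous multichannel EEG with a cue event list.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered 10-20 electrode names, one per row of ``samples``.
    events : list of (int, str)
        ``(sample_index, category)`` pairs; the index marks the cue-cycle
        origin the epoch is cut relative to.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x times array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.samples.shape[1]
        for t, lab in self.events:
            if not (0 <= t < n):
                raise ValueError(f"event at sample {t} outside recording of {n} samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


@dataclass
class EpochSet:
    """Segmented trials: ``data`` is trials x channels x samples."""

    data: np.ndarray
    labels: np.ndarray
    t0: float
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis interval ``[start, start + duration)`` within an epoch.

    ``start`` is in seconds from the epoch start; ``index_within_duration``
    orders the windows that share a duration.
    """

    start: float
    duration: float
    index_within_duration: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.duration <= 0:
            raise ValueError("window duration must be positive")

    @property
    def name(self) -> str:
        return f"{self.duration:g}s_w{self.index_within_duration}"


def bandpass(
    raw: RawRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = False,
) -> RawRecording:
    """Apply a Butterworth band-pass to every channel.

    The default is the causal (forward-only) 2nd-order 8-30 Hz filter, matching
    a real-time decoding chain; ``zero_phase=True`` switches to forward-backward
    filtering for offline analysis (doubling the effective order).
    """
    nyq = raw.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=raw.fs, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, raw.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, raw.samples, axis=1)
    return replace(raw, samples=np.ascontiguousarray(filtered))


def butter_bandpass_gain(
    freqs: np.ndarray | float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
    fs: float = 256.0,
) -> np.ndarray:
    """Magnitude response |H(f)| of the band-pass design at given frequencies."""
    b, a = signal.butter(order, [low, high], btype="bandpass", fs=fs)
    _, h = signal.freqz(b, a, worN=2 * np.pi * np.atleast_1d(freqs) / fs)
    return np.abs(h)


def segment(
    raw: RawRecording,
    start_s: float = EPOCH_START_S,
    end_s: float = EPOCH_END_S,
) -> EpochSet:
    """Cut one fixed-length epoch per event, ``[start_s, end_s)`` after its onset.

    Trailing events without enough signal left are dropped with a warning; an
    empty event list is an error because nothing downstream can run.
    """
    if not raw.events:
        raise ValueError("no trials: recording has an empty event list")
    i0 = int(round(start_s * raw.fs))
    i1 = int(round(end_s * raw.fs))
    n_samp = i1 - i0
    trials, labels = [], []
    n_dropped = 0
    for onset, label in raw.events:
        lo, hi = onset + i0, onset + i1
        if hi > raw.n_times:
            n_dropped += 1
            continue
        trials.append(raw.samples[:, lo:hi])
        labels.append(label)
    if n_dropped:
        logger.warning("dropped %d truncated trailing trial(s)", n_dropped)
    if not trials:
        raise ValueError("no trials: every event was truncated")
    data = np.stack(trials, axis=0)
    assert data.shape[2] == n_samp
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        t0=start_s,
        fs=raw.fs,
        channel_labels=list(raw.channel_labels),
    )


def window_scheme() -> list[WindowSpec]:
    """The eight-window tiling of the 4-s epoch.

    Four 0.5-s windows at 0, 0.5, 1, 1.5 s; two 1-s windows at 0 and 1 s; one
    2-s window and one 4-s window, both at 0 s.  Windows of equal duration are
    pairwise disjoint; the short families sit at the start of the epoch where
    the earliest imagery-related desynchronization is expected.
    """
    windows = []
    for k, start in enumerate((0.0, 0.5, 1.0, 1.5)):
        windows.append(WindowSpec(start, 0.5, k))
    for k, start in enumerate((0.0, 1.0)):
        windows.append(WindowSpec(start, 1.0, k))
    windows.append(WindowSpec(0.0, 2.0, 0))
    windows.append(WindowSpec(0.0, 4.0, 0))
    return windows


def slice_epochs(epochs: EpochSet, w: WindowSpec) -> EpochSet:
    """Restrict every trial to one analysis window (half-open, in samples)."""
    i0 = int(np.floor(w.start * epochs.fs))
    i1 = i0 + int(np.floor(w.duration * epochs.fs))
    if i1 > epochs.n_samples:
        raise ValueError(
            f"window [{w.start}, {w.start + w.duration}) s exceeds epoch of "
            f"{epochs.n_samples / epochs.fs:g} s"
        )
    return EpochSet(
        data=epochs.data[:, :, i0:i1],
        labels=epochs.labels,
        t0=epochs.t0 + w.start,
        fs=epochs.fs,
        channel_labels=list(epochs.channel_labels),
    )


def read_gdf_session(path: str, picks: list[str] | None = None) -> RawRecording:
    """Optional reader for BCI Competition IV-2a calibration files (A01T-A09T).

    Maps the competition's cue annotations (event codes 769/770, left/right
    hand) onto the container used throughout this package.  Requires ``mne``;
    the synthetic-data path never touches this function.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    if picks is not None:
        raw.pick(picks)
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_to_label = {}
    for key, code in event_id.items():
        if key.endswith("769"):
            code_to_label[code] = "left"
        elif key.endswith("770"):
            code_to_label[code] = "right"
    ev = [
        (int(sample), code_to_label[code])
        for sample, _, code in events
        if code in code_to_label
    ]
    return RawRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=ev,
    )
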