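"""Seeded simulation of cue-paced motor-imagery EEG sessions.

The generator emulates a calibration run on a small sensorimotor montage:
two cortical sources of band-limited mu (8-13 Hz) and beta (13-30 Hz)
oscillatory activity, one centred under C3 (left motor cortex) and one under
C4 (right motor cortex), mixed into 11 channels through fixed unit-norm
scalp topographies, on top of 1/f^gamma background noise and a white sensor
noise floor.

Motor imagery of one hand attenuates the mu/beta power of the *contralateral*
source (event-related desynchronization, ERD) by a configurable fractional
depth while the cue is on screen, optionally with an ipsilateral gain
(event-related synchronization, ERS).  Each trial cycle is 10 s long: fixation
cross at 0 s, imagery cue from 2 to 6 s, break from 6 to 10 s, then the next
cycle.  Two task modes are supported:

``mi_vs_rest``
    every cycle carries a hand-imagery cue; a matching "rest" epoch is taken
    from each cycle's break interval (marked by an event 4 s after the cross,
    so the standard 2-6 s segmentation lands on the 6-10 s break).
``left_vs_right``
    cycles alternate (in seeded random order) between left- and right-hand
    cues, balanced per class.

The oscillatory sources are amplitude-modulated band-passed white noise, not
sinusoids, so per-trial channel covariances are full rank — a prerequisite
for the spatial-filtering stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .preprocess import RawRecording

logger = logging.getLogger(__name__)

MU_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)

#: default montage; the sensorimotor strip plus fronto/centro-parietal neighbours
DEFAULT_CHANNELS = (
    "FC3", "FC4", "C3", "C4", "CP3", "CP4", "CPz", "C1", "C2", "C5", "C6",
)

# Approximate 2-D 10-20 coordinates (x: left-negative lateral, y: anterior),
# head radius normalized to 1.
_ELECTRODE_XY = {
    "FC3": (-0.40, 0.25), "FC4": (0.40, 0.25),
    "C5": (-0.60, 0.0), "C3": (-0.40, 0.0), "C1": (-0.20, 0.0),
    "Cz": (0.0, 0.0), "C2": (0.20, 0.0), "C4": (0.40, 0.0), "C6": (0.60, 0.0),
    "CP3": (-0.40, -0.25), "CPz": (0.0, -0.25), "CP4": (0.40, -0.25),
}

TASK_MODES = ("mi_vs_rest", "left_vs_right")

#: trial-cycle timing in seconds: fixation cross, cue on, cue off / break end
CYCLE_CROSS_S = 0.0
CYCLE_CUE_ON_S = 2.0
CYCLE_CUE_OFF_S = 6.0
CYCLE_LEN_S = 10.0


@dataclass
class SimulationConfig:
    """All knobs of one simulated session.

    ``erd_depth`` is the fractional mu/beta power attenuation of the
    contralateral source during imagery (0 = no modulation, i.e. no signal);
    ``snr_db`` scales the total scalp-projected power of each oscillatory
    source relative to the per-channel broadband background power;
    ``sensor_noise_db`` sets the white noise floor on the same scale.
    """

    n_trials_per_class: int = 35
    fs: float = 256.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    task_mode: str = "mi_vs_rest"
    erd_depth: float = 0.5
    ers_gain: float = 1.0
    snr_db: float = 5.0
    background_exponent: float = 1.0
    sensor_noise_db: float = -10.0
    seed: int = 0
    mu_beta_power_ratio: float = 2.0
    envelope_ramp_s: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth < 1.0):
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.ers_gain < 1.0:
            raise ValueError("ers_gain must be >= 1")
        if self.fs <= 2 * BETA_BAND[1]:
            raise ValueError(
                f"fs={self.fs} Hz cannot represent the beta band "
                f"(need fs > {2 * BETA_BAND[1]:g} Hz)"
            )
        if self.n_trials_per_class < 2:
            raise ValueError("need at least 2 trials per class")
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"task_mode must be one of {TASK_MODES}")

    @property
    def n_cycles(self) -> int:
        """Cue cycles in the session: one per trial (both hands in LR mode)."""
        if self.task_mode == "left_vs_right":
            return 2 * self.n_trials_per_class
        return self.n_trials_per_class


@dataclass
class SourceModel:
    """Fixed forward model: two unit-norm scalp topographies and class gains.

    ``class_gain[label]`` maps each category to per-source *power* multipliers
    applied while the cue is on; for "rest" all gains are 1.
    """

    topographies: np.ndarray  # n_channels x 2, columns = (left-cortex, right-cortex)
    class_gain: dict[str, tuple[float, float]]
    mu_band: tuple[float, float] = MU_BAND
    beta_band: tuple[float, float] = BETA_BAND

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.topographies, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("topographies must have unit Euclidean norm")
        if np.linalg.matrix_rank(self.topographies) < 2:
            raise ValueError("the two topographies must be linearly independent")


def gaussian_topography(
    center: str, channels: tuple[str, ...] = DEFAULT_CHANNELS, width: float = 0.35
) -> np.ndarray:
    """Unit-norm Gaussian scalp bump centred on a 10-20 electrode position."""
    cx, cy = _ELECTRODE_XY[center]
    w = np.array(
        [
            np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
            for x, y in (_ELECTRODE_XY[ch] for ch in channels)
        ]
    )
    return w / np.linalg.norm(w)


def default_source_model(config: SimulationConfig) -> SourceModel:
    """Two Gaussian-bump sources at C3/C4 with the configured ERD/ERS gains.

    Imagining one hand attenuates the contralateral source's power by
    ``1 - erd_depth`` and scales the ipsilateral source by ``ers_gain``.  In
    ``mi_vs_rest`` mode the cued imagery is right-hand by convention, so the
    left-cortex (C3) source carries the ERD.
    """
    topo = np.column_stack(
        [
            gaussian_topography("C3", config.channel_labels),
            gaussian_topography("C4", config.channel_labels),
        ]
    )
    att = 1.0 - config.erd_depth
    ers = config.ers_gain
    if config.task_mode == "mi_vs_rest":
        gains = {"mi": (att, ers), "rest": (1.0, 1.0)}
    else:
        # (left-cortex gain, right-cortex gain)
        gains = {"left": (ers, att), "right": (att, ers)}
    return SourceModel(topographies=topo, class_gain=gains)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance white noise band-passed to ``band`` (zero-phase, order 4)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n: int, exponent: float
) -> np.ndarray:
    """Per-channel unit-variance noise with power spectrum 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0)  # d cancels in the normalization
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _cue_envelope(
    n: int, fs: float, onsets: np.ndarray, amp_gain: float, ramp_s: float
) -> np.ndarray:
    """Amplitude envelope: 1 at rest, ``amp_gain`` inside each cue interval.

    Raised-cosine ramps of ``ramp_s`` sit just inside the cue interval so the
    full modulation never leaks outside [cue_on, cue_off).
    """
    env = np.ones(n)
    n_ramp = int(round(ramp_s * fs))
    n_cue = int(round((CYCLE_CUE_OFF_S - CYCLE_CUE_ON_S) * fs))
    profile = np.full(n_cue, amp_gain)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        profile[:n_ramp] = 1.0 + (amp_gain - 1.0) * ramp
        profile[n_cue - n_ramp:] = 1.0 + (amp_gain - 1.0) * ramp[::-1]
    for onset in onsets:
        lo = onset + int(round(CYCLE_CUE_ON_S * fs))
        env[lo : lo + n_cue] = profile
    return env


def generate_session(config: SimulationConfig) -> RawRecording:
    """Simulate one calibration session.

    Returns a continuous recording of ``n_cycles`` 10-s trial cycles whose
    event list marks each fixation-cross onset with its trial category (plus,
    in ``mi_vs_rest`` mode, one "rest" marker per cycle placed 4 s after the
    cross so standard segmentation lands on the break interval).  Identical
    config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    model = default_source_model(config)
    fs = config.fs
    n_cycles = config.n_cycles
    n = int(round(n_cycles * CYCLE_LEN_S * fs))
    cycle_n = int(round(CYCLE_LEN_S * fs))
    onsets = np.arange(n_cycles) * cycle_n

    # trial categories per cycle
    if config.task_mode == "left_vs_right":
        cats = np.array(["left", "right"]).repeat(config.n_trials_per_class)
        cats = rng.permutation(cats)
        events = [(int(o), str(c)) for o, c in zip(onsets, cats)]
    else:
        cats = np.array(["mi"] * n_cycles)
        events = [(int(o), "mi") for o in onsets]
        rest_offset = int(round(4.0 * fs))
        events += [(int(o + rest_offset), "rest") for o in onsets]
        events.sort()

    # two oscillatory sources: mu + beta band-limited noise, unit total variance
    mu_w = np.sqrt(
        config.mu_beta_power_ratio / (1.0 + config.mu_beta_power_ratio)
    )
    beta_w = np.sqrt(1.0 / (1.0 + config.mu_beta_power_ratio))
    sources = np.stack(
        [
            mu_w * _bandlimited_noise(rng, n, fs, MU_BAND)
            + beta_w * _bandlimited_noise(rng, n, fs, BETA_BAND)
            for _ in range(2)
        ]
    )

    # class-dependent amplitude envelopes (power gain -> sqrt for amplitude)
    for src_idx in range(2):
        env = np.ones(n)
        for onset, cat in zip(onsets, cats):
            g = model.class_gain[str(cat)][src_idx]
            if g != 1.0:
                env *= _cue_envelope(
                    n, fs, np.array([onset]), np.sqrt(g), config.envelope_ramp_s
                )
        sources[src_idx] *= env

    # scale sources to the configured SNR re: per-channel background power
    src_amp = 0.0 if np.isneginf(config.snr_db) else 10.0 ** (config.snr_db / 20.0)
    sensor_amp = (
        0.0
        if np.isneginf(config.sensor_noise_db)
        else 10.0 ** (config.sensor_noise_db / 20.0)
    )
    n_ch = len(config.channel_labels)
    x = src_amp * (model.topographies @ sources)
    x += _one_over_f_noise(rng, n_ch, n, config.background_exponent)
    x += sensor_amp * rng.standard_normal((n_ch, n))

    return RawRecording(
        samples=x,
        fs=fs,
        channel_labels=list(config.channel_labels),
        events=events,
    )


def generate_cohort(configs: list[SimulationConfig]) -> list[RawRecording]:
    """One session per config; duplicate seeds are flagged (identical subjects)."""
    if not configs:
        raise ValueError("cohort needs at least one simulation config")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) < len(seeds):
        logger.warning("duplicate seeds in cohort configs: %s", seeds)
    return [generate_session(c) for c in configs]


def save_session(path: str | Path, raw: RawRecording, config: SimulationConfig) -> None:
    """Persist a session to a .npz container (samples, events, config echo)."""
    path = Path(path)
    event_samples = np.array([t for t, _ in raw.events], dtype=np.int64)
    event_labels = np.array([lab for _, lab in raw.events])
    np.savez_compressed(
        path,
        samples=raw.samples,
        fs=np.float64(raw.fs),
        channel_labels=np.array(raw.channel_labels),
        event_samples=event_samples,
        event_labels=event_labels,
        config_json=np.str_(json.dumps(asdict(config))),
    )


def load_session(path: str | Path) -> tuple[RawRecording, SimulationConfig]:
    """Inverse of :func:`save_session`."""
    with np.load(path, allow_pickle=False) as z:
        raw = RawRecording(
            samples=z["samples"],
            fs=float(z["fs"]),
            channel_labels=[str(c) for c in z["channel_labels"]],
            events=[
                (int(t), str(lab))
                for t, lab in zip(z["event_samples"], z["event_labels"])
            ],
        )
        cfg_dict = json.loads(str(z["config_json"]))
        cfg_dict["channel_labels"] = tuple(cfg_dict["channel_labels"])
        config = SimulationConfig(**cfg_dict)
    return raw, config
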