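"""Synthetic single-channel EEG with stage-typical spectral structure.

Each sleep stage is described by a :class:`StageSpec`: a mixture of
band-limited noise components (center frequency, bandwidth, RMS amplitude
in microvolts) plus transient events (sleep spindles, K-complexes) at a
given rate per 30-s epoch.  Defaults encode the classical staging
criteria: dominant alpha (8–13 Hz) in wake, theta (4–7 Hz) in N1 and REM,
spindles and K-complexes in N2, and high-voltage (>75 µV) slow (<2 Hz)
activity in N3.

Hypnograms are generated from a first-order Markov chain over the five
stages; the default transition matrix has strong self-transitions so that
the fraction of transitional epochs lands in the 10–30 % range seen in
overnight recordings.

Band-limited components are realized by band-pass filtering white noise
(not pure sinusoids), so that correlation and autocorrelation features
downstream are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import EPOCH_S, STAGES

__all__ = [
    "Component",
    "Transient",
    "StageSpec",
    "SyntheticRecording",
    "default_stage_specs",
    "default_transition_matrix",
    "generate_stage_signal",
    "generate_hypnogram",
    "generate_recording",
    "save_recording",
]


@dataclass(frozen=True)
class Component:
    """Band-limited noise component of a stage's EEG mixture.

    Parameters
    ----------
    center_freq : float
        Center frequency in Hz.
    bandwidth : float
        Full bandwidth in Hz (the component occupies
        ``center_freq ± bandwidth / 2``).
    amplitude : float
        Target RMS amplitude in microvolts.
    """

    center_freq: float
    bandwidth: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError(f"center_freq must be > 0, got {self.center_freq}")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class Transient:
    """Transient EEG event (sleep spindle or K-complex).

    ``kind`` is ``"spindle"`` (a Hann-windowed sinusoidal burst at
    ``freq``) or ``"k_complex"`` (a single tapered biphasic pulse whose
    shape is set by ``duration``; ``freq`` is ignored).  ``rate`` is the
    expected number of events per 30-s epoch.
    """

    kind: str
    rate: float
    duration: float
    freq: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("spindle", "k_complex"):
            raise ValueError(f"unknown transient kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.duration <= 0 or self.amplitude <= 0:
            raise ValueError("duration and amplitude must be > 0")


@dataclass(frozen=True)
class StageSpec:
    """Generative description of one sleep stage's EEG."""

    stage: str
    components: tuple[Component, ...] = ()
    transients: tuple[Transient, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")


@dataclass
class SyntheticRecording:
    """One synthetic night: samples (µV), per-epoch stages, lights-out."""

    samples: np.ndarray
    stages: list[str]
    fs: float
    lights_out_epoch: int
    seed: int

    @property
    def n_epochs(self) -> int:
        return len(self.stages)


def default_stage_specs() -> dict[str, StageSpec]:
    """Stage specs encoding the classical per-stage EEG criteria.

    Amplitudes are RMS microvolts.  Wake is alpha-dominated, N1 is
    low-amplitude theta, N2 adds spindles and K-complexes on a theta
    background, N3 is high-voltage slow-wave activity, and REM mixes
    theta with sawtooth-range and faster activity.
    """
    return {
        "W": StageSpec(
            "W",
            components=(Component(10.0, 2.5, 30.0), Component(4.5, 2.5, 10.0)),
        ),
        "N1": StageSpec(
            "N1",
            components=(Component(5.0, 2.0, 25.0), Component(10.0, 2.0, 8.0)),
        ),
        "N2": StageSpec(
            "N2",
            components=(Component(5.0, 2.0, 20.0), Component(1.5, 1.0, 15.0)),
            transients=(
                Transient("spindle", rate=4.0, duration=1.0, freq=13.5, amplitude=30.0),
                Transient("k_complex", rate=1.5, duration=0.7, freq=1.5, amplitude=80.0),
            ),
        ),
        "N3": StageSpec(
            "N3",
            components=(Component(1.0, 0.8, 80.0), Component(5.0, 2.0, 10.0)),
        ),
        "R": StageSpec(
            "R",
            components=(
                Component(5.0, 2.0, 20.0),
                Component(3.0, 1.0, 10.0),
                Component(20.0, 4.0, 12.0),
            ),
        ),
    }


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic stage transition matrix in canonical order.

    Self-transitions around 0.8 reproduce the 10–30 % transitional-epoch
    fraction typical of overnight hypnograms.
    """
    # rows/cols: N1, N2, N3, R, W
    return np.array(
        [
            [0.70, 0.14, 0.00, 0.08, 0.08],
            [0.05, 0.82, 0.07, 0.04, 0.02],
            [0.00, 0.10, 0.88, 0.00, 0.02],
            [0.05, 0.05, 0.00, 0.86, 0.04],
            [0.12, 0.05, 0.00, 0.03, 0.80],
        ]
    )


def _bandlimited_noise(
    rng: np.random.Generator, comp: Component, n: int, fs: float
) -> np.ndarray:
    lo = max(comp.center_freq - comp.bandwidth / 2.0, 0.01)
    hi = min(comp.center_freq + comp.bandwidth / 2.0, fs / 2.0 * 0.999)
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0:
        x = x * (comp.amplitude / rms)
    return x


def _transient_waveform(tr: Transient, fs: float) -> np.ndarray:
    n = max(int(round(tr.duration * fs)), 2)
    t = np.arange(n) / fs
    win = np.hanning(n)
    if tr.kind == "spindle":
        return tr.amplitude * np.sin(2 * np.pi * tr.freq * t) * win
    # K-complex: one tapered full cycle -> biphasic sharp-wave-then-rebound
    return tr.amplitude * np.sin(2 * np.pi * t / tr.duration) * win


def generate_stage_signal(
    spec: StageSpec, duration: float, fs: float, seed: int
) -> np.ndarray:
    """Generate ``duration`` seconds of stage-typical EEG at ``fs`` Hz.

    The signal is the sum of the spec's band-limited noise components
    (each scaled to its RMS amplitude) and Poisson-placed transients.
    Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If a component frequency reaches the Nyquist frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    for comp in spec.components:
        if comp.center_freq >= fs / 2:
            raise ValueError(
                f"component frequency {comp.center_freq} Hz is at or above "
                f"Nyquist ({fs / 2} Hz)"
            )
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for comp in spec.components:
        x += _bandlimited_noise(rng, comp, n, fs)
    for tr in spec.transients:
        count = rng.poisson(tr.rate * duration / EPOCH_S)
        wave = _transient_waveform(tr, fs)
        for _ in range(count):
            max_start = n - len(wave)
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            x[start : start + len(wave)] += wave
    return x


def generate_hypnogram(
    n_epochs: int, transition_matrix: np.ndarray, seed: int
) -> list[str]:
    """Markov-chain stage sequence of length ``n_epochs``, starting at W.

    ``transition_matrix`` is 5×5 row-stochastic in canonical stage order
    (N1, N2, N3, R, W); rows must sum to 1 within 1e-9.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.shape != (5, 5):
        raise ValueError(f"transition matrix must be 5x5, got {tm.shape}")
    if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    state = STAGES.index("W")
    out = [STAGES[state]]
    for _ in range(n_epochs - 1):
        state = int(rng.choice(5, p=tm[state]))
        out.append(STAGES[state])
    return out


def generate_recording(
    n_epochs: int,
    specs: dict[str, StageSpec] | None = None,
    transition_matrix: np.ndarray | None = None,
    fs: float = 100.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Generate a full stage-labelled synthetic recording.

    A hypnogram is drawn from the Markov chain and one epoch of signal is
    generated per stage label and concatenated.  ``lights_out_epoch`` is
    0: the synthetic subject is in bed from the start.
    """
    if specs is None:
        specs = default_stage_specs()
    missing = [s for s in STAGES if s not in specs]
    if missing:
        raise ValueError(f"missing StageSpec for stages: {missing}")
    if transition_matrix is None:
        transition_matrix = default_transition_matrix()
    rng = np.random.default_rng(seed)
    hyp_seed = int(rng.integers(0, 2**31))
    stages = generate_hypnogram(n_epochs, transition_matrix, hyp_seed)
    pieces = []
    for stage in stages:
        epoch_seed = int(rng.integers(0, 2**31))
        pieces.append(generate_stage_signal(specs[stage], EPOCH_S, fs, epoch_seed))
    samples = np.concatenate(pieces)
    return SyntheticRecording(
        samples=samples, stages=stages, fs=fs, lights_out_epoch=0, seed=seed
    )


def save_recording(
    rec: SyntheticRecording,
    edf_path,
    hypnogram_path,
    channel: str = "Fpz-Cz",
) -> None:
    """Write the recording as an EDF file plus a plain-text hypnogram."""
    from .data_io import write_edf, write_hypnogram

    write_edf(edf_path, rec.samples, rec.fs, channel=channel)
    write_hypnogram(hypnogram_path, rec.stages, lights_out=rec.lights_out_epoch)
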