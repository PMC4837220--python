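"""Morlet-wavelet time-frequency features for 30-s EEG epochs.

A complex Morlet wavelet is a complex exponential at a peak frequency f
under a Gaussian envelope of width ``sigma = n_cycles / (2*pi*f)``; the
cycle count trades temporal precision (few cycles) against frequency
precision (many cycles).  Convolving the signal with the wavelet and
taking the squared magnitude yields a time-resolved band-power series
per band.

Per epoch the feature vector contains, in fixed layout order:

====================  =====================================================
block                 size (B bands, W windows, L lags)
====================  =====================================================
epoch band power      B       mean squared band power over the epoch
window band power     B * W   same over sliding windows (band-major)
epoch signal power    1       mean squared time-domain signal
window signal power   W       same over sliding windows
band correlations     B(B-1)/2  Pearson r between band-power series pairs
autocorrelation       L       normalized autocorrelation at lags 1..L
====================  =====================================================

With the default 22-band table, 11 windows (5 s, step 2.5 s) and 50
sample lags the total is 557 features; stacking the two preceding and
two succeeding epochs' features gives 5 x 557 = 2785.

Powers are log-transformed and autocorrelations squared
(:func:`transform_features`), then every feature is min-max mapped to
[0, 1] separately per recording (:func:`scale_per_recording`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from . import EPOCH_S

__all__ = [
    "BandConfig",
    "FeatureLayout",
    "default_band_table",
    "load_band_table",
    "save_band_table",
    "morlet_kernel",
    "band_power_series",
    "sliding_windows",
    "epoch_features",
    "extract_recording_features",
    "transform_features",
    "scale_per_recording",
    "add_context",
    "N_AUTOCORR_LAGS",
]

N_AUTOCORR_LAGS = 50  # 0.5 s at 100 Hz


@dataclass(frozen=True)
class BandConfig:
    """One analysis band: label, peak frequency (Hz), wavelet cycle count."""

    label: str
    peak_freq: float
    n_cycles: float

    def __post_init__(self) -> None:
        if self.peak_freq <= 0:
            raise ValueError("peak_freq must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def sigma(self) -> float:
        """Gaussian time SD of the wavelet envelope, in seconds."""
        return self.n_cycles / (2 * np.pi * self.peak_freq)


def default_band_table() -> list[BandConfig]:
    """The default 22-band analysis table.

    Bands target the stage-discriminative rhythms: the slow band (four
    low rows plus its 0.5 Hz lower edge) for N3 slow waves, K-complex
    frequencies for N2, delta/theta for N1/R/W, alpha for W and N1,
    spindle frequencies for N2/N3, beta for arousals and wake, and a
    gamma band.  Few cycles favor temporal precision (transients), many
    cycles frequency precision (sustained rhythms).
    """
    rows = [
        ("slow_0.5", 0.5, 3),
        ("slow_0.7", 0.7, 3),
        ("slow_1.0", 1.0, 3),
        ("slow_1.5", 1.5, 3),
        ("slow_2.0", 2.0, 3),
        ("kcomplex_2.0", 2.0, 3),
        ("kcomplex_3.2", 3.2, 3),
        ("theta_3", 3.0, 5),
        ("theta_4", 4.0, 5),
        ("theta_5", 5.0, 5),
        ("theta_6", 6.0, 5),
        ("alpha_8", 8.0, 10),
        ("alpha_10", 10.0, 10),
        ("alpha_12", 12.0, 10),
        ("spindle_12", 12.0, 3),
        ("spindle_13", 13.0, 3),
        ("spindle_14", 14.0, 3),
        ("spindle_15", 15.0, 3),
        ("beta_16", 16.0, 3),
        ("beta_18", 18.0, 3),
        ("beta_20", 20.0, 5),
        ("gamma_40", 40.0, 5),
    ]
    return [BandConfig(label, f, c) for label, f, c in rows]


def load_band_table(path) -> list[BandConfig]:
    """Read a band table: one ``label peak_freq n_cycles`` line per band.

    Blank lines and ``#`` comments are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"band table file not found: {path}")
    bands = []
    for ln in path.read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"band table line {ln!r}: expected 'label freq cycles'")
        bands.append(BandConfig(parts[0], float(parts[1]), float(parts[2])))
    if not bands:
        raise ValueError(f"band table {path} is empty")
    return bands


def save_band_table(path, bands: list[BandConfig]) -> None:
    with open(path, "w") as fh:
        fh.write("# label peak_freq_hz n_cycles\n")
        for b in bands:
            fh.write(f"{b.label} {b.peak_freq} {b.n_cycles}\n")


@dataclass(frozen=True)
class FeatureLayout:
    """Named block layout of the per-epoch feature vector."""

    n_bands: int
    n_windows: int
    n_lags: int = N_AUTOCORR_LAGS

    @property
    def n_band_corr(self) -> int:
        return self.n_bands * (self.n_bands - 1) // 2

    @property
    def total(self) -> int:
        b, w = self.n_bands, self.n_windows
        return b + w * b + 1 + w + self.n_band_corr + self.n_lags

    def slices(self) -> dict[str, slice]:
        """Block name → column slice, in layout order."""
        sizes = [
            ("epoch_band_power", self.n_bands),
            ("window_band_power", self.n_bands * self.n_windows),
            ("epoch_signal_power", 1),
            ("window_signal_power", self.n_windows),
            ("band_corr", self.n_band_corr),
            ("autocorr", self.n_lags),
        ]
        out, start = {}, 0
        for name, size in sizes:
            out[name] = slice(start, start + size)
            start += size
        return out

    def column_names(self, bands: list[BandConfig] | None = None) -> list[str]:
        blab = (
            [b.label for b in bands]
            if bands is not None
            else [f"band{i}" for i in range(self.n_bands)]
        )
        names: list[str] = [f"epoch_power[{b}]" for b in blab]
        for b in blab:
            names += [f"win_power[{b}][w{w}]" for w in range(self.n_windows)]
        names.append("epoch_power[signal]")
        names += [f"win_power[signal][w{w}]" for w in range(self.n_windows)]
        for i in range(self.n_bands):
            for j in range(i + 1, self.n_bands):
                names.append(f"corr[{blab[i]},{blab[j]}]")
        names += [f"autocorr[lag{k}]" for k in range(1, self.n_lags + 1)]
        assert len(names) == self.total
        return names


# ---------------------------------------------------------------------------
# Wavelets and band power


def morlet_kernel(peak_freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, unit energy, support ±4 sigma.

    ``sigma = n_cycles / (2*pi*peak_freq)``; the kernel is
    ``exp(2j*pi*f*t) * exp(-t^2 / (2*sigma^2))`` sampled at ``fs`` and
    normalized so that ``sum(|w|^2) / fs == 1``.
    """
    if peak_freq >= fs / 2:
        raise ValueError(
            f"peak frequency {peak_freq} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    sigma = n_cycles / (2 * np.pi * peak_freq)
    half = int(np.ceil(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * peak_freq * t) * np.exp(-(t**2) / (2 * sigma**2))
    energy = np.sum(np.abs(w) ** 2) / fs
    return w / np.sqrt(energy)


def band_power_series(
    samples: np.ndarray, band: BandConfig, fs: float
) -> np.ndarray:
    """Time-resolved band power: |signal * Morlet kernel|^2, same length.

    The convolution is centered on the input; signal ends are implicitly
    zero-padded.
    """
    samples = np.asarray(samples, dtype=float)
    kernel = morlet_kernel(band.peak_freq, band.n_cycles, fs)
    if len(kernel) > len(samples):
        raise ValueError(
            f"wavelet for band {band.label!r} spans {len(kernel)} samples but the "
            f"signal has only {len(samples)}; provide a longer segment"
        )
    conv = _signal.fftconvolve(samples, kernel, mode="same")
    return np.abs(conv) ** 2


def sliding_windows(
    epoch_s: float = EPOCH_S, win_s: float = 5.0, step_s: float = 2.5
) -> list[tuple[float, float]]:
    """Fully contained ``(start_s, end_s)`` windows within one epoch.

    Count is ``floor((epoch_s - win_s) / step_s) + 1``; the defaults
    (30 s epoch, 5 s window, 2.5 s step) give 11 windows.
    """
    if win_s > epoch_s:
        raise ValueError("window longer than epoch")
    if win_s <= 0 or step_s <= 0:
        raise ValueError("win_s and step_s must be > 0")
    n = int(np.floor((epoch_s - win_s) / step_s + 1e-9)) + 1
    return [(i * step_s, i * step_s + win_s) for i in range(n)]


def _mean_square(x: np.ndarray) -> float:
    return float(np.mean(np.asarray(x) ** 2))


def _pairwise_pearson(series: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations; zero-variance pairs give 0."""
    b = series.shape[0]
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1))
    out = []
    for i in range(b):
        for j in range(i + 1, b):
            denom = norms[i] * norms[j]
            if denom == 0:
                out.append(0.0)
            else:
                out.append(float(np.dot(centered[i], centered[j]) / denom))
    return np.array(out)


def _autocorr(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Normalized autocorrelation at lags 1..n_lags (0 for a zero signal)."""
    x = np.asarray(x, dtype=float)
    denom = float(np.dot(x, x))
    out = np.zeros(n_lags)
    if denom == 0:
        return out
    for k in range(1, n_lags + 1):
        if k < len(x):
            out[k - 1] = float(np.dot(x[:-k], x[k:])) / denom
    return out


def epoch_features(
    epoch_samples: np.ndarray,
    band_powers: np.ndarray,
    layout: FeatureLayout,
    fs: float,
    win_s: float = 5.0,
    step_s: float = 2.5,
    band_power_stat: str = "mean_square",
) -> np.ndarray:
    """Raw feature vector for one epoch.

    Parameters
    ----------
    epoch_samples : array of shape (n,)
        Time-domain signal of the epoch.
    band_powers : array of shape (n_bands, n)
        Band-power series segments covering the same epoch.
    band_power_stat : {"mean_square", "mean"}
        How the "power of the band-power series" is summarized: the
        signal power of that series (default, scales as amplitude^4) or
        its plain mean (scales as amplitude^2, like the signal-power
        blocks).  Time-domain power blocks always use mean square.
    """
    x = np.asarray(epoch_samples, dtype=float)
    bp = np.asarray(band_powers, dtype=float)
    if bp.shape[0] != layout.n_bands:
        raise ValueError(
            f"{bp.shape[0]} band-power series but layout expects {layout.n_bands}"
        )
    if bp.shape[1] != len(x):
        raise ValueError("band-power series must cover the full epoch")
    epoch_s = len(x) / fs
    windows = sliding_windows(epoch_s, win_s, step_s)
    if len(windows) != layout.n_windows:
        raise ValueError(
            f"{len(windows)} windows from ({epoch_s}, {win_s}, {step_s}) but "
            f"layout expects {layout.n_windows}"
        )
    win_idx = [(int(round(a * fs)), int(round(b * fs))) for a, b in windows]
    if band_power_stat == "mean_square":
        bstat = _mean_square
    elif band_power_stat == "mean":
        bstat = lambda v: float(np.mean(v))  # noqa: E731
    else:
        raise ValueError(f"unknown band_power_stat {band_power_stat!r}")

    parts = [np.array([bstat(row) for row in bp])]
    wbp = np.empty((layout.n_bands, len(windows)))
    for bi in range(layout.n_bands):
        for wi, (a, b) in enumerate(win_idx):
            wbp[bi, wi] = bstat(bp[bi, a:b])
    parts.append(wbp.ravel())  # band-major
    parts.append(np.array([_mean_square(x)]))
    parts.append(np.array([_mean_square(x[a:b]) for a, b in win_idx]))
    parts.append(_pairwise_pearson(bp))
    parts.append(_autocorr(x, layout.n_lags))
    vec = np.concatenate(parts)
    assert vec.shape[0] == layout.total
    return vec


def extract_recording_features(
    samples: np.ndarray,
    fs: float,
    bands: list[BandConfig] | None = None,
    epoch_s: float = EPOCH_S,
    win_s: float = 5.0,
    step_s: float = 2.5,
    band_power_stat: str = "mean_square",
) -> tuple[np.ndarray, FeatureLayout]:
    """Raw feature matrix (n_epochs × total) for one recording.

    Band-power series are computed by convolving the *whole* signal once
    per band (zero-padded at the ends) and then segmented into epochs,
    avoiding per-epoch convolution edge artifacts.
    """
    if bands is None:
        bands = default_band_table()
    samples = np.asarray(samples, dtype=float)
    n_per_epoch = int(round(fs * epoch_s))
    n_epochs = len(samples) // n_per_epoch
    if n_epochs == 0:
        raise ValueError("signal shorter than one epoch")
    layout = FeatureLayout(
        n_bands=len(bands), n_windows=len(sliding_windows(epoch_s, win_s, step_s))
    )
    bp_full = np.stack([band_power_series(samples, b, fs) for b in bands])
    rows = np.empty((n_epochs, layout.total))
    for e in range(n_epochs):
        sl = slice(e * n_per_epoch, (e + 1) * n_per_epoch)
        rows[e] = epoch_features(
            samples[sl], bp_full[:, sl], layout, fs, win_s, step_s,
            band_power_stat=band_power_stat,
        )
    return rows, layout


# ---------------------------------------------------------------------------
# Transforms, scaling, context


def transform_features(
    raw: np.ndarray, layout: FeatureLayout, log_floor: float = 1e-12
) -> np.ndarray:
    """Center feature distributions: log powers, square autocorrelations.

    Power blocks get ``log(max(x, log_floor))`` (the floor guards exact
    zeros from synthetic inputs); the autocorrelation block is squared;
    correlations pass through unchanged.  Negative powers indicate an
    upstream bug and raise.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    out = raw.copy()
    sl = layout.slices()
    for block in (
        "epoch_band_power",
        "window_band_power",
        "epoch_signal_power",
        "window_signal_power",
    ):
        vals = raw[:, sl[block]]
        if np.any(vals < 0):
            raise ValueError(f"negative power values in block {block!r}")
        out[:, sl[block]] = np.log(np.maximum(vals, log_floor))
    out[:, sl["autocorr"]] = raw[:, sl["autocorr"]] ** 2
    return out


def scale_per_recording(
    transformed: np.ndarray, recording_ids: np.ndarray
) -> np.ndarray:
    """Min-max map each feature to [0, 1] separately per recording.

    Features that are constant within a recording map to 0.5.  Every
    recording must contribute at least 2 epochs.
    """
    x = np.atleast_2d(np.asarray(transformed, dtype=float))
    rids = np.asarray(recording_ids)
    if len(rids) != x.shape[0]:
        raise ValueError("recording_ids length must match row count")
    out = np.empty_like(x)
    for rid in _unique_in_order(rids):
        mask = rids == rid
        if int(mask.sum()) < 2:
            raise ValueError(
                f"recording {rid!r} has a single epoch; per-recording scaling "
                "needs at least 2"
            )
        block = x[mask]
        lo, hi = block.min(axis=0), block.max(axis=0)
        span = hi - lo
        scaled = np.where(span > 0, (block - lo) / np.where(span > 0, span, 1.0), 0.5)
        out[mask] = scaled
    return out


def add_context(
    scaled: np.ndarray, recording_ids: np.ndarray, width: int = 2
) -> np.ndarray:
    """Stack each epoch with its ±``width`` neighbors' features.

    Row e becomes ``concat(e-width, ..., e, ..., e+width)``; boundaries
    use replication padding and the context never crosses recording
    boundaries.  Rows of one recording must be contiguous and in time
    order.
    """
    x = np.atleast_2d(np.asarray(scaled, dtype=float))
    rids = np.asarray(recording_ids)
    if len(rids) != x.shape[0]:
        raise ValueError("recording_ids length must match row count")
    seen: set = set()
    prev = None
    for rid in rids:
        if rid != prev:
            if rid in seen:
                raise ValueError(
                    "rows of each recording must be contiguous and time-ordered"
                )
            seen.add(rid)
            prev = rid
    blocks = []
    for rid in _unique_in_order(rids):
        block = x[rids == rid]
        n = block.shape[0]
        idx = np.arange(n)
        cols = [
            block[np.clip(idx + off, 0, n - 1)]
            for off in range(-width, width + 1)
        ]
        blocks.append(np.hstack(cols))
    return np.vstack(blocks)


def _unique_in_order(values: np.ndarray) -> list:
    out, seen = [], set()
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
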