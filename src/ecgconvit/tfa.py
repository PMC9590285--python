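"""Gaussian-window STFT, time reassignment and the TSST spectrogram image.

The short-time Fourier transform of a signal :math:`x` with Gaussian window
:math:`g` is

.. math:: F_x^g(t,\\omega) = \\int x(\\tau)\\, g^*(t-\\tau)\\, e^{-j\\omega\\tau}\\, d\\tau

(the phase referenced to absolute time :math:`\\tau`).  Impulsive events
smear over the window support in :math:`|F|^2`.  Time reassignment sharpens
them: the group-delay estimate

.. math:: \\hat t_x(t,\\omega) = \\Re\\left(t - F_x^{\\tau g}/F_x^g\\right),
          \\qquad \\tau g(t) = t\\, g(t)

gives, for each coefficient, the time at which its energy actually arrived,
and the time-reassigned synchrosqueezing transform (TSST) scatter-adds each
complex STFT coefficient into the time bin nearest :math:`\\hat t` while
leaving its frequency untouched.  For a pure impulse at :math:`n_0` the
identity :math:`F^{\\tau g}/F^g = t - n_0` makes the reassignment exact, so
all the energy in every frequency row lands in one column — the property
that makes TSST a good front end for R-peak-centred ECG beats.

The squared magnitude of the reassigned grid, optionally log-compressed and
min-max scaled, is resampled to a 160x160 raster that the ConViT classifier
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

IMAGE_SIZE = 160


@dataclass(frozen=True)
class STFTConfig:
    """Discretization of the Gaussian-window STFT.

    window_sd
        Gaussian sigma in samples.
    window_len
        odd truncation length of the window (support ±window_len//2).
    hop
        frame step in samples.
    n_freq
        one-sided frequency bins spanning [0, fs/2]; the FFT length is
        2*(n_freq-1).
    fs
        sampling rate in Hz (sets the frequency axis only).

    Defaults suit 300-sample beats at 360 Hz: sigma 8, length 65, hop 1 and
    160 bins, so the raster needs minimal resampling.
    """

    window_sd: float = 8.0
    window_len: int = 65
    hop: int = 1
    n_freq: int = 160
    fs: float = 360.0

    def __post_init__(self) -> None:
        if self.window_len % 2 == 0 or self.window_len < 3:
            raise ValueError("window_len must be odd and >= 3")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.n_freq < 2:
            raise ValueError("n_freq must be >= 2")
        if self.window_sd <= 0 or self.fs <= 0:
            raise ValueError("window_sd and fs must be positive")

    @property
    def half(self) -> int:
        return self.window_len // 2

    @property
    def n_fft(self) -> int:
        return 2 * (self.n_freq - 1)

    def window(self) -> np.ndarray:
        """g(m) = exp(-m^2 / 2 sigma^2) / (sigma sqrt(2 pi)) on m = -h..h."""
        m = np.arange(-self.half, self.half + 1, dtype=float)
        return np.exp(-0.5 * (m / self.window_sd) ** 2) / (self.window_sd * np.sqrt(2 * np.pi))

    def time_window(self) -> np.ndarray:
        """tau*g: the window multiplied by the time offset from its centre."""
        m = np.arange(-self.half, self.half + 1, dtype=float)
        return m * self.window()


@dataclass
class TFGrid:
    """Complex time-frequency coefficients with their axes."""

    values: np.ndarray        # (n_time, n_freq) complex
    time_axis: np.ndarray     # sample indices
    freq_axis: np.ndarray     # Hz, spanning [0, fs/2]
    config: STFTConfig
    kind: str                 # "stft" | "tsst"

    def spectrogram(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def to_npz(self, path: str | Path) -> None:
        np.savez(path, values=self.values, time_axis=self.time_axis,
                 freq_axis=self.freq_axis, kind=self.kind)


@dataclass
class GroupDelayMap:
    """Reassignment targets t-hat (sample index) with a validity mask."""

    values: np.ndarray      # (n_time, n_freq) real
    valid_mask: np.ndarray  # bool, True where |F| exceeded the threshold
    time_axis: np.ndarray


@dataclass
class SpectrogramImage:
    """160x160 raster in [0, 1] fed to the classifier."""

    pixels: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"expected {IMAGE_SIZE}x{IMAGE_SIZE} pixels, "
                             f"got {self.pixels.shape}")

    def to_png(self, path: str | Path) -> None:
        from PIL import Image
        arr = np.rint(255 * np.clip(self.pixels, 0.0, 1.0)).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(Path(path))


def _frames(x: np.ndarray, cfg: STFTConfig) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded analysis frames: row t holds x[t-h .. t+h]."""
    h = cfg.half
    xp = np.concatenate([np.zeros(h), x, np.zeros(h)])
    times = np.arange(0, len(x), cfg.hop)
    idx = times[:, None] + np.arange(cfg.window_len)[None, :]
    return xp[idx], times


def _windowed_stft(x: np.ndarray, cfg: STFTConfig, window: np.ndarray) -> np.ndarray:
    """F[t, w] = sum_tau x(tau) w(t - tau) e^{-j w tau} on the discrete grid."""
    frames, times = _frames(x, cfg)
    # frame sample k corresponds to absolute time tau = t + (k - h); the
    # window argument is t - tau = h - k, so an even window is applied as-is
    # and the odd tau*g window must be flipped.
    tapered = frames * window[::-1][None, :]
    spec = np.fft.rfft(tapered, n=cfg.n_fft, axis=1)[:, : cfg.n_freq]
    k = np.arange(cfg.n_freq)
    # undo the FFT's frame-local time origin: bin phase references tau = t - h
    phase = np.exp(-2j * np.pi * k[None, :] * (times[:, None] - cfg.half) / cfg.n_fft)
    return spec * phase


def stft(x: np.ndarray, cfg: STFTConfig | None = None) -> TFGrid:
    """Gaussian-window STFT of a real signal.

    Linear in ``x``; matches the direct summation definition to numerical
    precision (the FFT is just a fast path).
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < cfg.window_len:
        raise ValueError(f"signal length {len(x)} shorter than window_len {cfg.window_len}")
    values = _windowed_stft(x, cfg, cfg.window())
    times = np.arange(0, len(x), cfg.hop)
    freqs = np.arange(cfg.n_freq) * cfg.fs / cfg.n_fft
    return TFGrid(values, times, freqs, cfg, "stft")


def _default_eps(F: np.ndarray) -> float:
    m = np.abs(F).max()
    return 1e-8 * m if m > 0 else np.inf


def group_delay(x: np.ndarray, cfg: STFTConfig | None = None,
                eps: float | None = None) -> GroupDelayMap:
    """Group-delay (time-reassignment) map t-hat = Re(t - F^{tg}/F^{g}).

    Cells where |F^g| <= eps are masked (their ratio is numerically
    meaningless); ``eps`` defaults to 1e-8 * max|F|.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(x, dtype=float)
    Fg = stft(x, cfg).values
    if eps is None:
        eps = _default_eps(Fg)
    elif eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    Ftg = _windowed_stft(x, cfg, cfg.time_window())
    times = np.arange(0, len(x), cfg.hop)
    mask = np.abs(Fg) > eps
    that = np.full(Fg.shape, np.nan)
    t_grid = np.broadcast_to(times[:, None].astype(float), Fg.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mask, Ftg, 0.0) / np.where(mask, Fg, 1.0)
    that[mask] = (t_grid - ratio.real)[mask]
    return GroupDelayMap(that, mask, times)


def tsst(x: np.ndarray, cfg: STFTConfig | None = None,
         eps: float | None = None) -> TFGrid:
    """Time-reassigned synchrosqueezing transform.

    Each complex STFT coefficient is accumulated into the time bin nearest
    its group delay (clipped to the grid); coefficients below the magnitude
    threshold stay at their original time.  The complex sum over each
    frequency row is therefore conserved exactly.
    """
    cfg = cfg or STFTConfig()
    grid = stft(x, cfg)
    gd = group_delay(x, cfg, eps)
    F = grid.values
    n_time, n_freq = F.shape
    # target time-bin per cell: round(t-hat / hop), clipped to the grid
    bins = np.broadcast_to(np.arange(n_time)[:, None], F.shape).copy()
    reassigned = np.clip(np.rint(gd.values[gd.valid_mask] / cfg.hop), 0, n_time - 1)
    bins[gd.valid_mask] = reassigned.astype(int)
    S = np.zeros_like(F)
    cols = np.broadcast_to(np.arange(n_freq)[None, :], F.shape)
    np.add.at(S, (bins.ravel(), cols.ravel()), F.ravel())
    return TFGrid(S, grid.time_axis, grid.freq_axis, cfg, "tsst")


def rasterize(grid: TFGrid, mode: str = "log", log_k: float = 1000.0) -> SpectrogramImage:
    """Turn |values|^2 into the 160x160 classifier input.

    The energy grid (rows = frequency ascending, columns = time) is
    optionally log-compressed as ``log(1 + k p / p_max)``, min-max scaled to
    [0, 1], and bilinearly resampled to 160x160.  All-zero grids map to
    all-zero images.
    """
    if grid.values.size == 0:
        raise ValueError("cannot rasterize an empty grid")
    if mode not in ("linear", "log"):
        raise ValueError(f"unknown rasterization mode {mode!r}")
    power = grid.spectrogram().T  # (n_freq, n_time)
    pmax = power.max()
    if pmax > 0 and mode == "log":
        power = np.log1p(log_k * power / pmax)
    rows = np.linspace(0, power.shape[0] - 1, IMAGE_SIZE)
    cols = np.linspace(0, power.shape[1] - 1, IMAGE_SIZE)
    coords = np.meshgrid(rows, cols, indexing="ij")
    pixels = ndimage.map_coordinates(power, coords, order=1, mode="nearest")
    # min-max scale after resampling so the [0, 1] contract holds exactly
    span = pixels.max() - pixels.min()
    if span > 0:
        pixels = (pixels - pixels.min()) / span
    return SpectrogramImage(pixels, {"kind": grid.kind, "mode": mode})


def beat_to_image(beat: np.ndarray, cfg: STFTConfig | None = None,
                  transform: str = "tsst", mode: str = "log") -> SpectrogramImage:
    """One-call front end: beat -> (TSST or STFT) -> 160x160 image."""
    if transform == "tsst":
        grid = tsst(beat, cfg)
    elif transform == "stft":
        grid = stft(beat, cfg)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return rasterize(grid, mode=mode)


class TSSTImageTransformer:
    """sklearn-style transformer: (n, 300) beats -> (n, 160, 160) images.

    Parameters mirror :class:`STFTConfig` plus the transform kind
    (``"tsst"`` default, ``"stft"`` for the baseline) and rasterization mode.
    Stateless: ``fit`` only validates input.
    """

    def __init__(self, window_sd: float = 8.0, window_len: int = 65, hop: int = 1,
                 n_freq: int = 160, fs: float = 360.0, transform_kind: str = "tsst",
                 raster_mode: str = "log"):
        self.window_sd = window_sd
        self.window_len = window_len
        self.hop = hop
        self.n_freq = n_freq
        self.fs = fs
        self.transform_kind = transform_kind
        self.raster_mode = raster_mode

    def _config(self) -> STFTConfig:
        return STFTConfig(self.window_sd, self.window_len, self.hop,
                          self.n_freq, self.fs)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("window_sd", "window_len", "hop", "n_freq", "fs",
                 "transform_kind", "raster_mode")}

    def set_params(self, **params) -> "TSSTImageTransformer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "TSSTImageTransformer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < self.window_len:
            raise ValueError("X must be (n_beats, n_samples) with n_samples >= window_len")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_beats, n_samples)")
        cfg = self._config()
        return np.stack([
            beat_to_image(row, cfg, self.transform_kind, self.raster_mode).pixels
            for row in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
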