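"""Cross-wavelet synchrony extraction.

Morlet continuous wavelet transform (CWT) and cross-wavelet transform (XWT)
of uniformly resampled interbeat-interval series (tachograms), following the
Torrence & Compo formulation: frequency-domain convolution with the analytic
Morlet wavelet, Fourier period ``lambda(s) = 4*pi*s / (w0 + sqrt(2 + w0^2))``,
cone of influence at the ``sqrt(2)*s`` e-folding time, and pointwise
significance of cross power against the product of the two series' theoretical
AR(1) (red-noise) spectra.

The synchrony measure is cross-wavelet *power* ``|W_xy| = |W_x * conj(W_y)|``
(not normalized coherence).  HRV frequency bands split the standard HF
(0.15-0.40 Hz) and LF (0.04-0.15 Hz) ranges at their geometric midpoints into
UHF/LHF and ULF/LLF; analysis focuses on LHF+UHF, whose period edge is
1/0.15 Hz = 6.67 s.  Band power is summarized as the mean in-band, in-cone
cross power over 10-s intervals nested in the four analysis minutes of the
lying segment, then log-z-scored within a normalization stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.special import k1

from .preprocess import RRSeries
from .synthetic import SegmentTimeline

DYAD_NAMES = {
    ("horse", "participant"): "horse-participant",
    ("therapist", "participant"): "therapist-participant",
    ("horse", "therapist"): "horse-therapist",
}


# ---------------------------------------------------------------------------
# tachogram


@dataclass
class Tachogram:
    """Interbeat intervals resampled onto a uniform grid."""

    t: np.ndarray    # seconds
    ibi: np.ndarray  # milliseconds
    fs: float        # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.t.size != self.ibi.size:
            raise ValueError("t and ibi must have equal length")

    @property
    def n(self) -> int:
        return self.t.size

    def ar1(self) -> float:
        """Lag-1 sample autocorrelation (red-noise persistence estimate)."""
        x = self.ibi - self.ibi.mean()
        denom = float(np.dot(x, x))
        if denom == 0:
            return 0.0
        return float(np.dot(x[1:], x[:-1]) / denom)


def resample_ibi(
    series: RRSeries,
    fs: float = 4.0,
    window: tuple[float, float] | None = None,
    max_gap_s: float | None = None,
) -> Tachogram:
    """Cubic-spline resampling of the RR series onto a uniform ``fs`` grid.

    The window is half-open ``[start, end)`` (240 s at 4 Hz gives exactly 960
    samples).  Grid points beyond the first/last beat are filled by linear
    extension of the edge values.  A between-beat span larger than
    ``max_gap_s`` inside the window means the cleaned series does not cover it
    and is an error; the default adapts to the species' beat spacing
    (``max(2 s, 2.5 x median interval)``).
    """
    if window is None:
        window = (float(series.beat_time[0]), float(series.beat_time[-1]))
    start, end = window
    tb = series.beat_time
    rr = series.rr
    if tb.size < 4:
        raise ValueError("too few beats in window for spline resampling")
    if max_gap_s is None:
        max_gap_s = max(2.0, 2.5 * float(np.median(rr)) / 1000.0)
    core = (tb >= start) & (tb <= end)
    spans = np.diff(tb[core])
    if spans.size and spans.max() > max_gap_s:
        raise ValueError(
            f"coverage gap of {spans.max():.2f} s inside window exceeds {max_gap_s} s"
        )
    grid = start + np.arange(int(round((end - start) * fs))) / fs
    spline = CubicSpline(tb, rr)
    out = spline(grid)
    # linear (constant-slope-free) fallback outside the beat support
    out = np.where(grid < tb[0], rr[0], out)
    out = np.where(grid > tb[-1], rr[-1], out)
    return Tachogram(t=grid, ibi=out, fs=fs)


# ---------------------------------------------------------------------------
# continuous wavelet transform


@dataclass(frozen=True)
class CWTConfig:
    """Morlet CWT parameters (Torrence & Compo conventions)."""

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    s_min: float | None = None  # default 2/fs
    n_scales: int | None = None  # default: periods up to segment_length/4

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for practical admissibility")
        if self.dj <= 0:
            raise ValueError("dj must be positive")

    @property
    def fourier_factor(self) -> float:
        """Fourier period per unit scale: 4*pi / (w0 + sqrt(2 + w0^2))."""
        return 4.0 * np.pi / (self.omega0 + np.sqrt(2.0 + self.omega0**2))


@dataclass
class CWTResult:
    """Complex Morlet coefficients of one (standardized) tachogram."""

    W: np.ndarray        # (n_scales, n_times) complex
    time: np.ndarray     # seconds
    scale: np.ndarray    # wavelet scales
    period: np.ndarray   # Fourier periods, seconds
    coi: np.ndarray      # per-time maximum valid period, seconds
    fs: float
    ar1: float           # lag-1 autocorrelation of the input tachogram
    config: CWTConfig


def cwt_morlet(x: Tachogram, config: CWTConfig | None = None) -> CWTResult:
    """Morlet CWT via FFT, with the input mean-removed and unit-variance.

    The daughter wavelets are normalized so white noise of unit variance has
    expected power 1 at every scale, which is the normalization the red-noise
    significance test assumes.
    """
    config = config or CWTConfig()
    n = x.n
    dt = 1.0 / x.fs
    sd = x.ibi.std()
    if sd == 0:
        xn = np.zeros(n)
    else:
        xn = (x.ibi - x.ibi.mean()) / sd

    s0 = config.s_min if config.s_min is not None else 2.0 * dt
    if config.n_scales is None:
        max_period = n * dt / 4.0
        s_max = max_period / config.fourier_factor
        J = int(np.floor(np.log2(s_max / s0) / config.dj))
    else:
        J = config.n_scales - 1
    scales = s0 * 2.0 ** (config.dj * np.arange(J + 1))
    periods = config.fourier_factor * scales

    # series must be at least 2 e-folding times of the smallest scale
    if n * dt < 2.0 * np.sqrt(2.0) * s0:
        raise ValueError("series shorter than two e-folding times at s_min")

    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(xn, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)

    W = np.empty((scales.size, n), dtype=complex)
    norm_const = np.pi**-0.25
    for j, s in enumerate(scales):
        psi_hat = norm_const * np.sqrt(2.0 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega - config.omega0) ** 2
        ) * (omega > 0)
        # ifft carries the 1/N that the normalized-DFT convention expects
        W[j] = np.fft.ifft(xhat * psi_hat)[:n]

    t = x.t
    edge = np.minimum(t - t[0], t[-1] - t)
    coi = config.fourier_factor * edge / np.sqrt(2.0)
    return CWTResult(
        W=W, time=t, scale=scales, period=periods, coi=coi, fs=x.fs, ar1=x.ar1(), config=config
    )


# ---------------------------------------------------------------------------
# cross-wavelet


@dataclass
class XWTResult:
    """Cross-wavelet transform of two tachograms on a common grid."""

    time: np.ndarray
    period: np.ndarray
    power: np.ndarray    # |W_xy|, cross-wavelet power (modulus)
    phase: np.ndarray    # radians in (-pi, pi]
    coi: np.ndarray      # per-time maximum valid period (stricter of the two)
    ar1_x: float
    ar1_y: float
    fs: float
    config: CWTConfig
    sig_mask: np.ndarray | None = None
    alpha: float | None = None
    Wxy: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def in_coi(self) -> np.ndarray:
        """Boolean grid, True where the cell is inside the cone of influence
        (i.e. *valid*, period < coi(t))."""
        return self.period[:, None] < self.coi[None, :]


def cross_wavelet(wx: CWTResult, wy: CWTResult) -> XWTResult:
    """Cross-wavelet transform ``W_xy = W_x * conj(W_y)``.

    Power is the modulus ``|W_xy|``; phase is its argument (positive when x
    leads y); the cone of influence is the stricter (elementwise minimum) of
    the two inputs' cones.
    """
    if wx.W.shape != wy.W.shape or not np.allclose(wx.period, wy.period) or not np.allclose(
        wx.time, wy.time
    ):
        raise ValueError("cross_wavelet requires identical time/scale grids")
    Wxy = wx.W * np.conj(wy.W)
    # |Wx||Wy| == |Wx * conj(Wy)| mathematically, and is floating-point
    # identical to wavelet power |W|^2 for the self-cross case
    return XWTResult(
        time=wx.time,
        period=wx.period,
        power=np.abs(wx.W) * np.abs(wy.W),
        phase=np.angle(Wxy),
        coi=np.minimum(wx.coi, wy.coi),
        ar1_x=wx.ar1,
        ar1_y=wy.ar1,
        fs=wx.fs,
        config=wx.config,
        Wxy=Wxy,
    )


# ---------------------------------------------------------------------------
# significance


def _ar1_spectrum(freq_dt: np.ndarray, a: float) -> np.ndarray:
    """Normalized theoretical AR(1) spectrum at frequency*dt (cycles/sample)."""
    return (1.0 - a**2) / (1.0 + a**2 - 2.0 * a * np.cos(2.0 * np.pi * freq_dt))


def xwt_quantile(alpha: float) -> float:
    """Quantile Z of sqrt(chi2_2 * chi2_2') with P(Z > z) = z*K1(z) = alpha.

    Torrence & Compo tabulate Z(5%) = 3.999 for the cross-wavelet
    distribution with nu = 2; this solves the same tail equation for any
    level.
    """
    if alpha >= 1.0:
        return 0.0
    f = lambda z: z * k1(z) - alpha
    return float(brentq(f, 1e-12, 60.0))


def pointwise_significance(
    result: XWTResult,
    alpha: float = 0.05,
    method: str = "analytic",
    n_surrogates: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Pointwise red-noise significance mask for cross-wavelet power.

    ``analytic``: the background is ``sqrt(P_x(f) * P_y(f)) * Z(alpha) / 2``
    per scale, with ``P`` the theoretical AR(1) spectra at the two estimated
    lag-1 autocorrelations and ``Z`` the quantile of the square root of the
    product of two chi-squared(2) powers.  ``montecarlo``: per-scale quantile
    of |W_xy| over AR(1) surrogate pairs matched to ``ar1_x``/``ar1_y``.

    The mask is True where power exceeds the background; it is stored on the
    result (with ``alpha``) and returned.
    """
    for a in (result.ar1_x, result.ar1_y):
        if abs(a) >= 1.0:
            raise ValueError(f"|ar1| must be < 1, got {a}")
    dt = 1.0 / result.fs
    freq_dt = dt / result.period  # frequency * dt per scale
    if method == "analytic":
        px = _ar1_spectrum(freq_dt, result.ar1_x)
        py = _ar1_spectrum(freq_dt, result.ar1_y)
        crit = np.sqrt(px * py) * xwt_quantile(alpha) / 2.0
        mask = result.power > crit[:, None]
    elif method == "montecarlo":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n = result.time.size
        samples: list[np.ndarray] = []
        for _ in range(n_surrogates):
            sx = _ar1_series(rng, n, result.ar1_x)
            sy = _ar1_series(rng, n, result.ar1_y)
            wx = cwt_morlet(Tachogram(result.time, sx, result.fs), result.config)
            wy = cwt_morlet(Tachogram(result.time, sy, result.fs), result.config)
            samples.append(np.abs(wx.W) * np.abs(wy.W))
        stack = np.concatenate(samples, axis=1)  # (n_scales, n_surr*n)
        if alpha <= 0:
            # "never exceeded under the null": global max over all surrogate
            # cells at every scale
            crit = np.full(result.period.size, stack.max())
        else:
            crit = np.quantile(stack, 1.0 - alpha, axis=1)
        mask = result.power > crit[:, None]
    else:
        raise ValueError(f"unknown significance method {method!r}")
    result.sig_mask = mask
    result.alpha = alpha
    return mask


def _ar1_series(rng: np.random.Generator, n: int, a: float) -> np.ndarray:
    """Stationary AR(1) sample of length n with lag-1 autocorrelation a."""
    x = np.empty(n)
    x[0] = rng.standard_normal() / np.sqrt(max(1.0 - a**2, 1e-12))
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i]
    return x


# ---------------------------------------------------------------------------
# frequency bands


@dataclass(frozen=True)
class FrequencyBands:
    """HRV band edges in Hz; HF and LF split at geometric midpoints.

    Only the HF lower edge (0.15 Hz, i.e. a 6.67 s period) is anchored in
    standard HRV practice; the UHF/LHF and ULF/LLF splits are this package's
    sub-partition of the standard bands.
    """

    lf_low: float = 0.04
    lf_split: float = 0.0775
    hf_low: float = 0.15
    hf_split: float = 0.245
    hf_high: float = 0.40

    def __post_init__(self) -> None:
        if not self.lf_low < self.lf_split < self.hf_low < self.hf_split < self.hf_high:
            raise ValueError("band edges must be strictly increasing")

    @property
    def hf_edge_period_s(self) -> float:
        """Period of the HF lower edge (0.15 Hz -> 6.67 s)."""
        return 1.0 / self.hf_low


def band_partition(periods: np.ndarray, bands: FrequencyBands | None = None) -> np.ndarray:
    """Label each scale's Fourier period with its band.

    Frequency = 1/period, half-open convention [low, high); frequencies
    outside [lf_low, hf_high) are labeled ``out``.
    """
    bands = bands or FrequencyBands()
    freq = 1.0 / np.asarray(periods, dtype=float)
    labels = np.full(freq.shape, "out", dtype=object)
    labels[(freq >= bands.lf_low) & (freq < bands.lf_split)] = "LLF"
    labels[(freq >= bands.lf_split) & (freq < bands.hf_low)] = "ULF"
    labels[(freq >= bands.hf_low) & (freq < bands.hf_split)] = "LHF"
    labels[(freq >= bands.hf_split) & (freq < bands.hf_high)] = "UHF"
    return labels


# ---------------------------------------------------------------------------
# interval extraction


def extract_interval_power(
    result: XWTResult,
    timeline: SegmentTimeline,
    bands: FrequencyBands | None = None,
    band_subset: tuple[str, ...] = ("LHF", "UHF"),
    use_coi: bool = True,
) -> pd.DataFrame:
    """Mean cross power per 10-s interval of the lying segment's first 240 s.

    Four one-minute blocks, each split into six 10-s intervals (half-open),
    per band in ``band_subset``.  Cells outside the cone of influence are
    excluded from the mean (unless ``use_coi=False``); rows with more than
    50% of their cells excluded are flagged ``coi_flag``.
    """
    bands = bands or FrequencyBands()
    lying = timeline.window("lying")
    if lying[1] - lying[0] < 240.0:
        raise ValueError("lying segment shorter than 240 s")
    start = lying[0]
    labels = band_partition(result.period, bands)
    valid = result.in_coi() if use_coi else np.ones_like(result.power, dtype=bool)

    rows = []
    for minute in range(1, 5):
        for interval in range(1, 7):
            t0 = start + (minute - 1) * 60.0 + (interval - 1) * 10.0
            t1 = t0 + 10.0
            tsel = (result.time >= t0) & (result.time < t1)
            for band in band_subset:
                ssel = labels == band
                cells = result.power[np.ix_(ssel, tsel)]
                ok = valid[np.ix_(ssel, tsel)]
                n_cells = cells.size
                n_ok = int(ok.sum())
                mean_p = float(cells[ok].mean()) if n_ok else np.nan
                rows.append(
                    {
                        "minute": minute,
                        "interval": interval,
                        "band": band,
                        "power": mean_p,
                        "n_cells": n_cells,
                        "n_used": n_ok,
                        "coi_flag": bool(n_ok < 0.5 * n_cells),
                    }
                )
    return pd.DataFrame(rows)


def ztransform_power(
    table: pd.DataFrame,
    stratum: str | list[str] = "dyad",
    power_col: str = "power",
) -> pd.DataFrame:
    """Log-z-score cross power within a normalization stratum.

    ``cwp_z = (log(power) - mean) / sd`` with the *sample* sd (ddof=1),
    computed within each group defined by ``stratum`` (a column name, list of
    column names, or the shorthand ``"dyad"`` / ``"dyad_session"``).  A
    zero-sd stratum gets ``cwp_z = 0``.  Non-positive power is an error
    (cross power is a modulus; zero occurs only for degenerate input).
    """
    if isinstance(stratum, str):
        stratum_cols = {
            "dyad": ["dyad"],
            "dyad_session": ["dyad", "session_id"],
        }.get(stratum, [stratum])
    else:
        stratum_cols = list(stratum)
    out = table.copy()
    if (out[power_col] <= 0).any():
        raise ValueError("non-positive cross power; cannot log-transform")
    out["log_power"] = np.log(out[power_col])

    def _z(g: pd.Series) -> pd.Series:
        if g.size < 2:
            raise ValueError("z-transform stratum needs >= 2 rows")
        sd = g.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return pd.Series(np.zeros(g.size), index=g.index)
        return (g - g.mean()) / sd

    cols = [c for c in stratum_cols if c in out.columns]
    if cols:
        out["cwp_z"] = out.groupby(cols, group_keys=False)["log_power"].apply(_z)
    else:
        out["cwp_z"] = _z(out["log_power"])
    return out


def phase_stats(
    result: XWTResult,
    band: str,
    window: tuple[float, float],
    bands: FrequencyBands | None = None,
) -> tuple[float, float]:
    """Circular mean phase and concentration over a band/time selection.

    Returns ``(mean_angle, R)`` where ``R`` in [0, 1] is the resultant length
    of the unit phase vectors over in-cone cells; R = 1 means a perfectly
    consistent phase relation (e.g. 0 for in-phase, pi for anti-phase).
    """
    labels = band_partition(result.period, bands or FrequencyBands())
    ssel = labels == band
    tsel = (result.time >= window[0]) & (result.time < window[1])
    valid = result.in_coi()[np.ix_(ssel, tsel)]
    ph = result.phase[np.ix_(ssel, tsel)][valid]
    if ph.size == 0:
        raise ValueError("empty band/window selection for phase statistics")
    z = np.exp(1j * ph).mean()
    return float(np.angle(z)), float(np.abs(z))


# ---------------------------------------------------------------------------
# plotting


def plot_xwt(result: XWTResult, ax=None, arrow_density: tuple[int, int] = (16, 8)):
    """Cross-wavelet power map: log2-period axis, coi shading, significance
    contour, and phase arrows (rightward = in-phase, leftward = anti-phase)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    T, P = np.meshgrid(result.time, result.period)
    mesh = ax.pcolormesh(T, P, result.power, cmap="jet", shading="auto")
    ax.set_yscale("log", base=2)
    ax.invert_yaxis()
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Period (s)")
    plt.colorbar(mesh, ax=ax, label="cross-wavelet power")
    ax.plot(result.time, result.coi, "w--", lw=1)
    ax.fill_between(
        result.time, result.coi, result.period.max(), color="white", alpha=0.35, hatch="x"
    )
    if result.sig_mask is not None and result.sig_mask.any():
        ax.contour(T, P, result.sig_mask.astype(float), levels=[0.5], colors="white", linewidths=1.5)
    it = max(1, result.time.size // arrow_density[0])
    ip = max(1, result.period.size // arrow_density[1])
    sl = (slice(None, None, ip), slice(None, None, it))
    ax.quiver(
        T[sl], P[sl], np.cos(result.phase)[sl], np.sin(result.phase)[sl],
        pivot="mid", scale=40, width=0.002, color="black",
    )
    ax.set_ylim(result.period.max(), result.period.min())
    return ax
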