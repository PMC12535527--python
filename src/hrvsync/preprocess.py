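"""RR-interval cleaning.

Beat-to-beat (RR) recordings from chest-belt sensors contain duplicated rows,
ectopic/artifact beats and dropped-beat gaps; equine recordings are markedly
worse than human ones.  This module implements the cleaning chain used before
any spectral analysis:

    remove_duplicates -> detect_outliers -> interpolate_gaps

plus an iterative variant (:func:`clean_equine`) for horse recordings, and the
baseline vagal-tone index RMSSD.

Conventions
-----------
* Outliers are flagged when the *relative* deviation from a running median of
  neighbouring beats strictly exceeds a threshold in [0.20, 0.50] (default
  0.30), or when the interval falls outside species-specific absolute bounds
  (humans 300-2000 ms, horses 500-4000 ms).
* Gaps no longer than ``short_gap_max_s`` (default 2 s) are bridged by beats
  whose RR interpolates linearly between the flanking intervals; longer gaps
  use a linear trend fitted to 10 s of real data on each side.
* Cleaning an already-clean series is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("hrvsync")

FLAG_OK = "ok"
FLAG_OUTLIER = "outlier"
FLAG_INTERPOLATED = "interpolated"
FLAG_DUPLICATE = "duplicate_removed"

#: absolute physiological RR bounds in ms, by role
PHYSIO_BOUNDS_MS = {
    "participant": (300.0, 2000.0),
    "therapist": (300.0, 2000.0),
    "horse": (500.0, 4000.0),
}


class UnusableRecordingError(RuntimeError):
    """Raised when a recording is too corrupted to clean (>50% flagged)."""


@dataclass
class RRSeries:
    """One subject's beat-to-beat record.

    Parameters
    ----------
    beat_time : array of float
        Beat timestamps in seconds from session start, strictly increasing.
    rr : array of float
        Interbeat intervals in milliseconds; ``rr[k]`` is the interval that
        *ends* at ``beat_time[k]``.
    flag : array of str
        Per-beat quality mark (``ok``, ``outlier``, ``interpolated``,
        ``duplicate_removed``).
    role : str
        ``participant``, ``therapist`` or ``horse``.
    """

    beat_time: np.ndarray
    rr: np.ndarray
    role: str = "participant"
    subject_id: str = ""
    session_id: str = ""
    flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.flag is None:
            self.flag = np.full(self.beat_time.size, FLAG_OK, dtype=object)
        else:
            self.flag = np.asarray(self.flag, dtype=object)
        if self.beat_time.shape != self.rr.shape:
            raise ValueError("beat_time and rr must have equal length")

    def __len__(self) -> int:
        return self.beat_time.size

    @property
    def duration_s(self) -> float:
        return float(self.beat_time[-1] - self.beat_time[0]) if len(self) else 0.0

    def copy(self) -> "RRSeries":
        return replace(
            self,
            beat_time=self.beat_time.copy(),
            rr=self.rr.copy(),
            flag=self.flag.copy(),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.beat_time, "rr_ms": self.rr, "flag": self.flag}
        )


@dataclass(frozen=True)
class CleaningConfig:
    """Parameters of the cleaning chain."""

    outlier_threshold: float = 0.30  # relative deviation, strict inequality
    short_gap_max_s: float = 2.0
    median_window: int = 11  # beats, odd
    max_passes: int = 5
    flank_s: float = 10.0  # real-data context used for long-gap trends

    def __post_init__(self) -> None:
        if not 0.20 <= self.outlier_threshold <= 0.50:
            raise ValueError(
                f"outlier_threshold must be in [0.20, 0.50], got {self.outlier_threshold}"
            )
        if self.short_gap_max_s <= 0:
            raise ValueError("short_gap_max_s must be positive")


# ---------------------------------------------------------------------------
# duplicates


def remove_duplicates(series: RRSeries) -> RRSeries:
    """Collapse rows with identical timestamps, keeping the first.

    Returns a new series; the number of removed rows is logged.  Ordering is
    preserved and surviving flags are untouched.
    """
    t = series.beat_time
    keep = np.ones(t.size, dtype=bool)
    keep[1:] = np.diff(t) > 0.0
    n_removed = int((~keep).sum())
    if n_removed:
        logger.debug("remove_duplicates: dropped %d rows", n_removed)
    out = replace(
        series,
        beat_time=t[keep],
        rr=series.rr[keep],
        flag=series.flag[keep],
    )
    return out


# ---------------------------------------------------------------------------
# outliers


def _running_median(rr: np.ndarray, window: int) -> np.ndarray:
    """Running median over a ``window``-beat neighbourhood of each beat.

    A median filter tolerates up to window//2 contaminated beats in any
    neighbourhood, so isolated spikes cannot mask themselves.
    """
    from scipy.ndimage import median_filter

    return median_filter(rr, size=window, mode="nearest")


def detect_outliers(series: RRSeries, config: CleaningConfig | None = None) -> np.ndarray:
    """Boolean mask of artifact beats.

    A beat is flagged iff its relative deviation from the running median of
    neighbouring intervals *strictly* exceeds ``outlier_threshold``, or iff it
    lies outside the absolute physiological bounds for the subject's species.
    """
    config = config or CleaningConfig()
    n = len(series)
    if config.median_window > n:
        raise ValueError(
            f"median_window={config.median_window} larger than series ({n} beats)"
        )
    med = _running_median(series.rr, config.median_window)
    rel = np.abs(series.rr - med) / med
    mask = rel > config.outlier_threshold
    lo, hi = PHYSIO_BOUNDS_MS.get(series.role, PHYSIO_BOUNDS_MS["participant"])
    mask |= (series.rr < lo) | (series.rr > hi)
    return mask


def drop_beats(series: RRSeries, mask: np.ndarray) -> RRSeries:
    """Delete masked beats (they become gaps for :func:`interpolate_gaps`)."""
    keep = ~np.asarray(mask, dtype=bool)
    return replace(
        series,
        beat_time=series.beat_time[keep],
        rr=series.rr[keep],
        flag=series.flag[keep],
    )


# ---------------------------------------------------------------------------
# gaps


def _find_gaps(series: RRSeries, factor: float = 1.8) -> list[int]:
    """Indices k such that the span (beat k, beat k+1) is a gap.

    A gap is a between-beat span exceeding ``factor`` times the local median
    interval — i.e. at least one beat is missing inside it.
    """
    t = series.beat_time
    if t.size < 3:
        return []
    spans = np.diff(t) * 1000.0  # ms
    med = np.median(series.rr[1:])
    return [int(k) for k in np.nonzero(spans > factor * med)[0]]


def _bridge_short(rr_before: float, rr_after: float, gap_ms: float) -> np.ndarray:
    """RR values bridging a short gap: linear between the flanking intervals."""
    mean_flank = 0.5 * (rr_before + rr_after)
    n = max(1, int(round(gap_ms / mean_flank)))
    # midpoints of n equal subdivisions of the flank-to-flank ramp
    fracs = (np.arange(n) + 0.5) / n
    return rr_before + (rr_after - rr_before) * fracs


def _bridge_long(series: RRSeries, k: int, gap_s: float, flank_s: float) -> np.ndarray:
    """RR values for a long gap: linear trend over ``flank_s`` of context."""
    t, rr = series.beat_time, series.rr
    t0, t1 = t[k], t[k + 1]
    pre = (t >= t0 - flank_s) & (t <= t0)
    post = (t >= t1) & (t <= t1 + flank_s)
    sel = pre | post
    # exclude rr values that are themselves gap-spans
    good = sel.copy()
    good[k + 1] = False
    if good.sum() < 2:
        raise ValueError("insufficient flanking data for long-gap trend")
    coef = np.polyfit(t[good], rr[good], 1)
    trend = np.poly1d(coef)
    rrs = []
    pos = t0
    while True:
        nxt = trend(pos + trend(pos) / 2000.0)  # RR at the midpoint of the step
        nxt = max(nxt, 200.0)  # guard against runaway trends
        if pos + nxt / 1000.0 >= t1 - 0.5 * nxt / 1000.0:
            break
        rrs.append(nxt)
        pos += nxt / 1000.0
    rrs.append((t1 - pos) * 1000.0)  # final interval lands on the gap-end beat
    return np.asarray(rrs)


def interpolate_gaps(series: RRSeries, config: CleaningConfig | None = None) -> RRSeries:
    """Fill dropped-beat gaps with interpolated beats.

    Short gaps (<= ``short_gap_max_s``) are bridged by beats whose RR runs
    linearly between the flanking intervals.  Longer gaps follow a linear trend
    fitted to ``flank_s`` seconds of real data before and after the gap.  Gaps
    at the very start or end of the recording have no flanking data and are
    left unfilled (reported via the log).
    """
    config = config or CleaningConfig()
    gaps = _find_gaps(series)
    if not gaps:
        return series.copy()

    t_parts: list[np.ndarray] = []
    rr_parts: list[np.ndarray] = []
    fl_parts: list[np.ndarray] = []
    prev = 0
    for k in gaps:
        gap_s = series.beat_time[k + 1] - series.beat_time[k]
        # the gap-end beat's own rr is unreliable (it may span the gap);
        # the after-flank is the first interval following it
        rr_after = series.rr[k + 2] if k + 2 < len(series) else series.rr[k]
        try:
            if gap_s <= config.short_gap_max_s:
                rr_new = _bridge_short(series.rr[k], rr_after, gap_s * 1000.0)
            else:
                rr_new = _bridge_long(series, k, gap_s, config.flank_s)
        except ValueError:
            logger.warning("gap at %.1f s left unfilled: no flanking data", series.beat_time[k])
            continue
        # interior beats at cumulative interval positions; the existing
        # gap-end beat takes the final bridged interval as its RR
        t_new = series.beat_time[k] + np.cumsum(rr_new[:-1]) / 1000.0
        t_parts.append(series.beat_time[prev : k + 1])
        rr_parts.append(series.rr[prev : k + 1])
        fl_parts.append(series.flag[prev : k + 1])
        t_parts.append(t_new)
        rr_parts.append(rr_new[:-1])
        fl_parts.append(np.full(t_new.size, FLAG_INTERPOLATED, dtype=object))
        # patch the gap-end beat's RR (it currently spans the whole gap)
        series = series.copy()
        series.rr[k + 1] = rr_new[-1]
        prev = k + 1
    t_parts.append(series.beat_time[prev:])
    rr_parts.append(series.rr[prev:])
    fl_parts.append(series.flag[prev:])
    return replace(
        series,
        beat_time=np.concatenate(t_parts),
        rr=np.concatenate(rr_parts),
        flag=np.concatenate(fl_parts),
    )


# ---------------------------------------------------------------------------
# full chains


def clean_series(series: RRSeries, config: CleaningConfig | None = None) -> RRSeries:
    """Standard (human) cleaning chain: duplicates -> outliers -> gaps."""
    config = config or CleaningConfig()
    out = remove_duplicates(series)
    mask = detect_outliers(out, config)
    out = drop_beats(out, mask)
    return interpolate_gaps(out, config)


def clean_equine(
    series: RRSeries, config: CleaningConfig | None = None
) -> tuple[RRSeries, list[dict]]:
    """Iterative artifact pass for horse recordings.

    Repeats detect -> delete -> interpolate until a pass flags nothing or
    ``max_passes`` is reached.  Returns the cleaned series and a per-pass audit
    log of flagged/inserted counts.

    Raises
    ------
    UnusableRecordingError
        If any single pass flags more than 50% of the beats.
    """
    config = config or CleaningConfig()
    out = remove_duplicates(series)
    audit: list[dict] = []
    for p in range(config.max_passes):
        mask = detect_outliers(out, config)
        n_flagged = int(mask.sum())
        if n_flagged > 0.5 * len(out):
            raise UnusableRecordingError(
                f"unusable recording: pass {p + 1} flagged {n_flagged}/{len(out)} beats"
            )
        if n_flagged == 0:
            audit.append({"pass": p + 1, "flagged": 0, "inserted": 0})
            break
        before = len(out)
        out = drop_beats(out, mask)
        out = interpolate_gaps(out, config)
        audit.append(
            {"pass": p + 1, "flagged": n_flagged, "inserted": len(out) - (before - n_flagged)}
        )
    return out, audit


# ---------------------------------------------------------------------------
# summary statistics


def rmssd(series: RRSeries, window: tuple[float, float] | None = None) -> float:
    """Root mean square of successive RR differences, in ms.

    Interpolated beats are included.  ``window`` is ``(start_s, end_s)``,
    half-open; default is the whole series.
    """
    rr = series.rr
    if window is not None:
        sel = (series.beat_time >= window[0]) & (series.beat_time < window[1])
        rr = rr[sel]
    if rr.size < 3:
        raise ValueError(f"rmssd needs >= 3 beats in window, got {rr.size}")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d**2)))
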