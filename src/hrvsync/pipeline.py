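"""End-to-end orchestration: sessions -> band-power table -> model ladder.

Ties the stages together with one seed: clean each role's series (iterative
pass for horses), resample the lying window to a uniform tachogram, run the
three dyadic cross-wavelet transforms, extract the 10-s interval HF power
grid, z-score it, and hand the long table to the hierarchical models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import models, preprocess, spectral, synthetic

logger = logging.getLogger("hrvsync")

#: analysis window inside the lying segment (first four minutes)
ANALYSIS_S = 240.0
#: tachogram margin on each side of the analysis window, so that the cone of
#: influence at HF periods clears the extracted intervals
EDGE_MARGIN_S = 30.0


def clean_recording(
    rec: synthetic.SessionRecording, config: preprocess.CleaningConfig | None = None
) -> dict[str, preprocess.RRSeries]:
    """Clean each role's series (equine iterative pass for the horse)."""
    config = config or preprocess.CleaningConfig()
    out = {}
    for role, series in rec.series.items():
        if role == "horse":
            out[role], _ = preprocess.clean_equine(series, config)
        else:
            out[role] = preprocess.clean_series(series, config)
    return out


def session_band_power(
    rec: synthetic.SessionRecording,
    cleaning: preprocess.CleaningConfig | None = None,
    cwt_config: spectral.CWTConfig | None = None,
    bands: spectral.FrequencyBands | None = None,
    fs: float = 4.0,
    use_coi: bool = True,
    clean: bool = True,
    cleaned: dict[str, preprocess.RRSeries] | None = None,
) -> pd.DataFrame:
    """Unnormalized 10-s HF interval cross power for the session's 3 dyads.

    The tachogram window is the analysis window plus an edge margin on each
    side, so the cone of influence at HF periods does not intrude on the
    extracted intervals.  ``cleaned`` short-circuits the cleaning stage when
    the caller already holds cleaned series.
    """
    cwt_config = cwt_config or spectral.CWTConfig()
    bands = bands or spectral.FrequencyBands()
    lying = rec.timeline.window("lying")
    t0 = max(lying[0] - EDGE_MARGIN_S, 0.0)
    t1 = lying[0] + ANALYSIS_S + EDGE_MARGIN_S

    if cleaned is not None:
        series = cleaned
    else:
        series = clean_recording(rec, cleaning) if clean else rec.series
    cwts = {}
    for role, s in series.items():
        tach = spectral.resample_ibi(s, fs=fs, window=(t0, t1))
        cwts[role] = spectral.cwt_morlet(tach, cwt_config)

    frames = []
    for (a, b), dyad_name in spectral.DYAD_NAMES.items():
        xwt = spectral.cross_wavelet(cwts[a], cwts[b])
        rows = spectral.extract_interval_power(xwt, rec.timeline, bands, use_coi=use_coi)
        rows.insert(0, "dyad", dyad_name)
        for key in (
            "participant_id", "therapist_id", "horse_id", "session_id",
            "session_index", "group", "favorite_horse", "ctq_total",
        ):
            if key in rec.meta:
                rows[key] = rec.meta[key]
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)


def add_baseline_rmssd(
    table: pd.DataFrame,
    rec: synthetic.SessionRecording,
    cleaned: dict[str, preprocess.RRSeries],
) -> pd.DataFrame:
    """Attach each human's baseline RMSSD over the 4-minute analysis window."""
    lying = rec.timeline.window("lying")
    win = (lying[0], lying[0] + ANALYSIS_S)
    for role, col in (("participant", "rmssd_participant"), ("therapist", "rmssd_therapist")):
        try:
            table[col] = preprocess.rmssd(cleaned[role], win)
        except ValueError:
            table[col] = np.nan
    return table


def cohort_band_power(
    table: pd.DataFrame,
    sessions: list[synthetic.SessionRecording],
    z_stratum: str = "dyad",
    clean: bool = True,
    fs: float = 4.0,
    cleaning: preprocess.CleaningConfig | None = None,
    cwt_config: spectral.CWTConfig | None = None,
    bands: spectral.FrequencyBands | None = None,
) -> pd.DataFrame:
    """Z-scored long-format band-power table for a whole simulated cohort."""
    frames = []
    for rec in sessions:
        cleaned = clean_recording(rec, cleaning) if clean else rec.series
        rows = session_band_power(
            rec, cwt_config=cwt_config, bands=bands, fs=fs, cleaned=cleaned
        )
        rows = add_baseline_rmssd(rows, rec, cleaned)
        frames.append(rows)
    long = pd.concat(frames, ignore_index=True)
    # carry cohort metadata columns (CTQ subscales) onto every row
    meta_cols = [c for c in table.columns if c.startswith("ctq_")]
    meta = table[["session_id"] + meta_cols].drop_duplicates("session_id")
    long = long.merge(meta, on="session_id", how="left", suffixes=("", "_cohort"))
    return spectral.ztransform_power(long, stratum=z_stratum)


def ctq_ladder(
    band_table: pd.DataFrame,
    response_dyad: str,
    ctq_col: str = "ctq_total",
    alpha: float = 0.05,
) -> tuple[models.LadderResult, float, float]:
    """Null -> design -> CTQ ladder for one dyad response.

    Returns the ladder plus the CTQ term's estimate and Wald p-value in the
    CTQ-augmented model.  The CTQ total enters rescaled to (total - 25) / 100
    so its coefficient is the shift across the full questionnaire range.
    """
    data = models.build_design(band_table, response_dyad)
    data = data[~data["power"].isna()].copy()
    data["ctq_scaled"] = (data[ctq_col] - 25.0) / 100.0
    base = models.ModelSpec(
        response="cwp_z",
        fixed=("C(minute)", "C(band)"),
        groups="participant_id",
        re_formula="1",
        name="design",
    )
    ladder = [
        models.ModelSpec(response="cwp_z", groups="participant_id", name="intercept-only"),
        base,
        base.with_terms("ctq_scaled", name="design+ctq"),
    ]
    result = models.model_ladder(data, ladder, alpha=alpha)
    full = result.fits[-1]
    row = full.estimates.set_index("term").loc["ctq_scaled"]
    return result, float(row["estimate"]), float(row["p"])
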