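"""Synthetic triad generator.

Ground-truth RR-interval sessions for the participant / riding-therapist /
therapy-horse triad, with *known, tunable* heart-rate-variability coupling.

The cardiac model is integral pulse frequency modulation (IPFM): a beat is
emitted whenever the integral of the instantaneous rate crosses the next
integer.  The rate is ``(mean_hr / 60) * m(t)`` where ``m(t)`` is a positive
modulating signal around 1 built from

* a *shared* narrowband high-frequency (HF, respiratory) oscillation per dyad,
  weighted by ``sqrt(kappa)`` in both members — ``kappa`` in [0, 1] is the
  variance share of the HF modulator that the dyad has in common and is the
  generator's ground-truth synchrony dial;
* an *own* narrowband HF oscillation at the species' respiratory frequency,
  weighted so total HF modulation depth stays ``hf_amp`` regardless of kappa;
* an own low-frequency (LF, baroreflex-range) oscillation; and
* white observation noise.

Cohorts mirror the study design: controls receive one session, patients four,
childhood-trauma (CTQ) scores span 25-125, and the true dyad kappas are linear
in the CTQ total so that downstream model ladders have a known target.

All randomness flows from a single seed through a hierarchical
``numpy.random.SeedSequence`` spawn tree, so identical seeds give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import FLAG_OK, RRSeries

ROLES = ("participant", "therapist", "horse")
DYADS = (
    ("horse", "participant"),
    ("therapist", "participant"),
    ("horse", "therapist"),
)

#: species-level resting defaults: mean heart rate (bpm), own HF and LF
#: modulator centre frequencies (Hz)
SPECIES_DEFAULTS = {
    "participant": {"mean_hr": 70.0, "hf_freq": 0.25, "lf_freq": 0.10},
    "therapist": {"mean_hr": 65.0, "hf_freq": 0.25, "lf_freq": 0.10},
    "horse": {"mean_hr": 38.0, "hf_freq": 0.10, "lf_freq": 0.05},
}

#: HF frequency at which dyads couple; inside the human HF analysis band
COUPLING_HF_FREQ = 0.25


@dataclass(frozen=True)
class CouplingConfig:
    """One dyad's generator settings."""

    duration_s: float = 300.0
    mean_hr: float = 70.0  # bpm (per member; triads override per species)
    hf_freq: float = 0.25  # Hz, respiratory modulator
    lf_freq: float = 0.10  # Hz
    # modulation depths give a resting RR coefficient of variation ~6%,
    # comfortably inside the 20-50% artifact-detection corridor
    hf_amp: float = 0.05   # modulation depth (dimensionless)
    lf_amp: float = 0.025
    kappa: float = 0.5     # shared HF variance fraction, in [0, 1]
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        if not self.hf_freq > self.lf_freq > 0:
            raise ValueError("need hf_freq > lf_freq > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level design: group sizes and true effect slopes.

    ``ctq_effect_*`` are slopes of the dyad kappa on the rescaled CTQ total
    ``(total - 25) / 100`` (so a slope of -0.3 moves kappa by -0.3 across the
    full 25-125 CTQ range); ``favorite_effect`` shifts the horse-therapist
    kappa when the therapist works her favorite horse.
    """

    n_control: int = 56
    n_patient: int = 36
    # base kappas keep each subject's shared-variance budget <= 1 even with
    # the lying boost (participant: 0.35 + 0.2 + 0.35 = 0.9)
    base_kappa_hp: float = 0.35  # horse-participant
    base_kappa_tp: float = 0.35  # therapist-participant
    base_kappa_ht: float = 0.30  # horse-therapist
    ctq_effect_therapist: float = 0.0
    ctq_effect_horse: float = 0.0
    favorite_effect: float = 0.0
    lying_boost: float = 0.2     # proximity boost on horse-participant kappa
    n_therapists: int = 3
    n_horses: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_patient < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass(frozen=True)
class CTQScores:
    """Childhood Trauma Questionnaire: five subscales, each scored 5-25."""

    emotional_abuse: int
    physical_abuse: int
    sexual_abuse: int
    emotional_neglect: int
    physical_neglect: int

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 5 <= v <= 25:
                raise ValueError(f"CTQ subscale {name}={v} outside [5, 25]")

    def as_dict(self) -> dict[str, int]:
        return {
            "emotional_abuse": self.emotional_abuse,
            "physical_abuse": self.physical_abuse,
            "sexual_abuse": self.sexual_abuse,
            "emotional_neglect": self.emotional_neglect,
            "physical_neglect": self.physical_neglect,
        }

    @property
    def total(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class SegmentTimeline:
    """Ordered, non-overlapping session segments in seconds."""

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, start, end in self.segments:
            if end <= start:
                raise ValueError(f"segment {name} has non-positive duration")
            if start < prev_end:
                raise ValueError(f"segment {name} overlaps its predecessor")
            prev_end = end
        lying = [s for s in self.segments if s[0] == "lying"]
        if lying and lying[0][2] - lying[0][1] < 240.0:
            raise ValueError("lying segment must last >= 240 s")

    def window(self, name: str) -> tuple[float, float]:
        for seg, start, end in self.segments:
            if seg == name:
                return (start, end)
        raise KeyError(f"no segment named {name!r}")

    @property
    def duration_s(self) -> float:
        return self.segments[-1][2]

    @classmethod
    def default(cls) -> "SegmentTimeline":
        """The study schedule: 10 min questionnaires flanking 5/5/15/5 min
        contact, grooming, riding and lying blocks."""
        mins = [
            ("questionnaire", 0, 10),
            ("contact", 10, 15),
            ("grooming", 15, 20),
            ("riding", 20, 35),
            ("lying", 35, 40),
            ("farewell", 40, 45),
            ("questionnaire2", 45, 55),
        ]
        return cls(tuple((n, a * 60.0, b * 60.0) for n, a, b in mins))

    @classmethod
    def compact(cls) -> "SegmentTimeline":
        """Desk-scale schedule with the full 300 s lying block but trimmed
        surrounding segments; used in simulations and tests."""
        secs = [
            ("questionnaire", 0, 30),
            ("contact", 30, 60),
            ("grooming", 60, 90),
            ("riding", 90, 150),
            ("lying", 150, 450),
            ("farewell", 450, 480),
            ("questionnaire2", 480, 510),
        ]
        return cls(tuple((n, float(a), float(b)) for n, a, b in secs))


# ---------------------------------------------------------------------------
# oscillators and modulators


def narrowband(
    rng: np.random.Generator, n: int, fs: float, f0: float, rel_bw: float = 0.2
) -> np.ndarray:
    """Unit-variance narrowband Gaussian oscillation centred at ``f0`` Hz.

    White Gaussian noise is shaped in the frequency domain by a Gaussian
    window of width ``rel_bw * f0``; the envelope therefore fluctuates on a
    ~``1/(2*pi*rel_bw*f0)`` timescale, as respiratory sinus arrhythmia does.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = rel_bw * f0
    spec *= np.exp(-0.5 * ((freqs - f0) / sigma) ** 2)
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def narrowband_rhythmic(
    rng: np.random.Generator, n: int, fs: float, f0: float, rel_bw: float = 0.2
) -> np.ndarray:
    """Unit-variance constant-envelope oscillation with narrowband phase drift.

    The *shared* (dyadic) respiratory modulator: breathing that drives two
    coupled hearts is rhythmic, so its amplitude is steady while its phase
    wanders like a narrowband process.  Implemented by taking the phase of a
    narrowband Gaussian process's analytic signal at constant amplitude
    ``sqrt(2)`` (unit variance).
    """
    from scipy.signal import hilbert

    z = narrowband(rng, n, fs, f0, rel_bw)
    za = hilbert(z)
    mag = np.abs(za)
    mag[mag == 0] = 1.0
    return np.sqrt(2.0) * np.real(za / mag)


def generate_modulators(
    config: CouplingConfig, sample_rate: float = 8.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Two coupled heart-rate modulators for one dyad.

    Returns ``(t, m1, m2, parts)`` where ``parts`` holds the HF components
    (``hf1``, ``hf2``) for verification.  Each member's HF component is
    ``sqrt(kappa) * shared + sqrt(1 - kappa) * own``, so the two HF components
    correlate at exactly ``kappa`` in expectation.
    """
    if sample_rate < 4.0:
        raise ValueError("sample_rate must be >= 4 Hz")
    n = int(round(config.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    shared = narrowband_rhythmic(rng, n, sample_rate, config.hf_freq)
    own1 = narrowband(rng, n, sample_rate, config.hf_freq)
    own2 = narrowband(rng, n, sample_rate, config.hf_freq)
    lf1 = narrowband(rng, n, sample_rate, config.lf_freq)
    lf2 = narrowband(rng, n, sample_rate, config.lf_freq)
    wk, wo = np.sqrt(config.kappa), np.sqrt(1.0 - config.kappa)
    hf1 = wk * shared + wo * own1
    hf2 = wk * shared + wo * own2
    m1 = 1.0 + config.hf_amp * hf1 + config.lf_amp * lf1 + config.noise_sd * rng.standard_normal(n)
    m2 = 1.0 + config.hf_amp * hf2 + config.lf_amp * lf2 + config.noise_sd * rng.standard_normal(n)
    return t, np.clip(m1, 0.2, None), np.clip(m2, 0.2, None), {"hf1": hf1, "hf2": hf2}


# ---------------------------------------------------------------------------
# IPFM cardiac model


def ipfm_beats(
    t: np.ndarray,
    modulator: np.ndarray,
    mean_hr: float,
    role: str = "participant",
    subject_id: str = "",
    session_id: str = "",
) -> RRSeries:
    """Emit beats by integral pulse frequency modulation.

    Beat ``k`` occurs when ``integral_0^t (mean_hr / 60) * m(tau) dtau``
    crosses the integer ``k``; RR intervals are successive beat-time
    differences in ms.  The first beat's RR is set equal to the second's
    (the interval preceding the record is unobserved).
    """
    if mean_hr <= 0:
        raise ValueError("mean_hr must be positive")
    m = np.asarray(modulator, dtype=float)
    if np.any(m <= 0):
        raise ValueError("modulator must be strictly positive")
    rate = (mean_hr / 60.0) * m
    dt = np.diff(t)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
    n_beats = int(np.floor(integral[-1]))
    ks = np.arange(1, n_beats + 1, dtype=float)
    beat_t = np.interp(ks, integral, t)
    if beat_t.size < 2:
        raise ValueError("recording too short: fewer than two beats")
    rr = np.empty_like(beat_t)
    rr[1:] = np.diff(beat_t) * 1000.0
    rr[0] = rr[1]
    return RRSeries(
        beat_time=beat_t + t[0] - t[0],
        rr=rr,
        role=role,
        subject_id=subject_id,
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# artifact injection


def inject_artifacts(
    series: RRSeries,
    spike_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    gap_spec: list[tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[RRSeries, dict]:
    """Corrupt a series the way chest-belt recordings fail.

    * *spikes*: RR scaled by a factor near 0.5 (false trigger) or 2.0 (missed
      beat), drawn at ``spike_rate`` per minute;
    * *duplicates*: exact duplicate rows inserted at ``duplicate_rate`` per
      minute;
    * *gaps*: all beats inside each ``(start_s, length_s)`` window removed.

    Returns the corrupted copy and a ground-truth mask dict with the spiked
    beat times, duplicated times, and gap windows.
    """
    if spike_rate < 0 or duplicate_rate < 0:
        raise ValueError("rates must be >= 0")
    gap_spec = gap_spec or []
    t0, t1 = series.beat_time[0], series.beat_time[-1]
    for start, length in gap_spec:
        if start < t0 or start + length > t1:
            raise ValueError(f"gap ({start}, {length}) outside recording [{t0}, {t1}]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = series.copy()
    minutes = series.duration_s / 60.0

    n_spike = rng.poisson(spike_rate * minutes)
    spike_idx = np.array([], dtype=int)
    if n_spike > 0:
        spike_idx = rng.choice(len(out), size=min(n_spike, len(out)), replace=False)
        factors = rng.choice([0.5, 2.0], size=spike_idx.size)
        factors *= 1.0 + 0.05 * rng.standard_normal(spike_idx.size)
        out.rr[spike_idx] = out.rr[spike_idx] * factors
    spiked_times = series.beat_time[np.sort(spike_idx)]

    n_dup = rng.poisson(duplicate_rate * minutes)
    dup_times = np.array([])
    if n_dup > 0:
        dup_idx = np.sort(rng.choice(len(out), size=min(n_dup, len(out)), replace=False))
        dup_times = out.beat_time[dup_idx]
        t_new = np.insert(out.beat_time, dup_idx + 1, out.beat_time[dup_idx])
        rr_new = np.insert(out.rr, dup_idx + 1, out.rr[dup_idx])
        fl_new = np.insert(out.flag, dup_idx + 1, out.flag[dup_idx])
        out = RRSeries(t_new, rr_new, out.role, out.subject_id, out.session_id, fl_new)

    keep = np.ones(len(out), dtype=bool)
    for start, length in gap_spec:
        keep &= ~((out.beat_time > start) & (out.beat_time <= start + length))
    out = RRSeries(
        out.beat_time[keep], out.rr[keep], out.role, out.subject_id, out.session_id, out.flag[keep]
    )
    mask = {
        "spiked_times": spiked_times,
        "duplicated_times": dup_times,
        "gap_windows": list(gap_spec),
        "n_spiked": int(spike_idx.size),
        "n_duplicated": int(dup_times.size),
    }
    return out, mask


# ---------------------------------------------------------------------------
# triad sessions


@dataclass
class SessionRecording:
    """A triad of RR series plus the session's timeline and metadata."""

    series: dict[str, RRSeries]
    timeline: SegmentTimeline
    meta: dict = field(default_factory=dict)


def _dyads_of(role: str) -> list[tuple[str, str]]:
    return [d for d in DYADS if role in d]


def generate_triad_session(
    meta: dict,
    timeline: SegmentTimeline,
    kappas: dict[tuple[str, str], float],
    lying_boost: float = 0.2,
    hf_amp: float = 0.05,
    lf_amp: float = 0.025,
    noise_sd: float = 0.01,
    sample_rate: float = 8.0,
    seed: int = 0,
    member_kappa: dict[tuple[tuple[str, str], str], float] | None = None,
) -> SessionRecording:
    """Generate the three coupled RR series of one session.

    ``kappas`` maps each dyad in :data:`DYADS` to its shared-HF variance
    fraction.  Coupling lives at :data:`COUPLING_HF_FREQ` (inside the human HF
    band) via one shared oscillator per dyad; each subject adds an own
    respiratory oscillator at its species frequency.  During the lying
    segment the horse-participant kappa is raised by ``lying_boost``
    (physical proximity intensifies synchrony); per-subject kappa sums are
    renormalized if they would exceed 1.

    ``member_kappa`` optionally overrides one member's weight in a dyad
    (key ``(dyad, role)``): the two partners then load the shared oscillator
    with sqrt of their own weights and their HF correlation is the geometric
    mean of the two.  This expresses one-sided attunement — e.g. a therapist
    who couples less strongly to a particular participant — without touching
    the other member's overall HF composition.
    """
    member_kappa = member_kappa or {}
    for d in DYADS:
        if d not in kappas:
            raise KeyError(f"missing coupling config for dyad {d}")
    n = int(round(timeline.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    ss = np.random.SeedSequence(seed)
    child = {name: s for name, s in zip(
        ["shared_hp", "shared_tp", "shared_ht", "participant", "therapist", "horse"],
        ss.spawn(6),
    )}

    shared = {
        d: narrowband_rhythmic(
            np.random.default_rng(child[f"shared_{d[0][0]}{d[1][0]}"]),
            n, sample_rate, COUPLING_HF_FREQ,
        )
        for d in DYADS
    }

    lying = timeline.window("lying")
    in_lying = (t >= lying[0]) & (t < lying[1])

    series: dict[str, RRSeries] = {}
    true_kappa = {}
    for role in ROLES:
        sp = SPECIES_DEFAULTS[role]
        rng = np.random.default_rng(child[role])
        own_hf = narrowband(rng, n, sample_rate, sp["hf_freq"])
        own_lf = narrowband(rng, n, sample_rate, sp["lf_freq"])
        noise = rng.standard_normal(n)

        k_t = {}
        for d in _dyads_of(role):
            w = member_kappa.get((d, role), kappas[d])
            k = np.full(n, float(np.clip(w, 0.0, 1.0)))
            if d == ("horse", "participant") and lying_boost:
                k[in_lying] = np.clip(k[in_lying] + lying_boost, 0.0, 1.0)
            k_t[d] = k
        total = sum(k_t.values())
        over = total > 1.0
        if np.any(over):
            for d in k_t:
                k_t[d][over] /= total[over]
            total = np.minimum(total, 1.0)

        hf = sum(np.sqrt(k_t[d]) * shared[d] for d in k_t)
        hf = hf + np.sqrt(np.clip(1.0 - total, 0.0, None)) * own_hf
        m = 1.0 + hf_amp * hf + lf_amp * own_lf + noise_sd * noise
        series[role] = ipfm_beats(
            t,
            np.clip(m, 0.2, None),
            sp["mean_hr"],
            role=role,
            subject_id=str(meta.get(f"{role}_id", role)),
            session_id=str(meta.get("session_id", "")),
        )
        true_kappa[role] = {d: (float(k_t[d].mean())) for d in k_t}

    out_meta = dict(meta)
    out_meta["true_kappa"] = {f"{a}-{b}": float(kappas[(a, b)]) for a, b in DYADS}
    out_meta["lying_boost"] = lying_boost
    return SessionRecording(series=series, timeline=timeline, meta=out_meta)


# ---------------------------------------------------------------------------
# cohorts


def _draw_ctq(rng: np.random.Generator, group: str) -> CTQScores:
    """Draw one participant's CTQ subscales.

    A participant-level severity in (0, 1) is shared across subscales (trauma
    forms co-occur) with per-subscale jitter.  Patient severities are spread
    nearly uniformly so cohort totals cover the full 25-125 range of the
    study's illustrative bins; controls skew low.
    """
    sev = rng.beta(1.2, 3.0) if group == "control" else rng.uniform(0.02, 0.95)
    scores = {}
    for name in (
        "emotional_abuse",
        "physical_abuse",
        "sexual_abuse",
        "emotional_neglect",
        "physical_neglect",
    ):
        p = np.clip(sev + 0.1 * rng.standard_normal(), 0.0, 1.0)
        scores[name] = int(5 + rng.binomial(20, p))
    return CTQScores(**scores)


def generate_cohort(
    config: CohortConfig,
    timeline: SegmentTimeline | None = None,
    make_sessions: bool = True,
) -> tuple[pd.DataFrame, list[SessionRecording]]:
    """Simulate a full cohort: metadata table plus (optionally) RR sessions.

    The returned table has one row per session with the ground-truth kappas:
    ``kappa_tp = base + ctq_effect_therapist * (ctq_total - 25) / 100`` and
    analogously for the horse dyad, both clipped to [0, 1]; the
    horse-therapist kappa gains ``favorite_effect`` when the session's horse
    is the therapist's favorite.  Controls get 1 session, patients 4.
    """
    timeline = timeline or SegmentTimeline.default()
    ss = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])

    therapists = [f"RT{i + 1}" for i in range(config.n_therapists)]
    horses = [f"TH{i + 1}" for i in range(config.n_horses)]
    favorite = {th: horses[i % len(horses)] for i, th in enumerate(therapists)}

    rows = []
    participants = [("control", i) for i in range(config.n_control)] + [
        ("patient", i) for i in range(config.n_patient)
    ]
    session_seeds = ss.spawn(len(participants) * 4)
    seed_iter = iter(session_seeds)
    k = 0
    for group, i in participants:
        pid = f"{'C' if group == 'control' else 'P'}{i + 1:03d}"
        ctq = _draw_ctq(meta_rng, group)
        ctq_scaled = (ctq.total - 25) / 100.0
        kappa_tp = float(np.clip(config.base_kappa_tp + config.ctq_effect_therapist * ctq_scaled, 0, 1))
        kappa_hp = float(np.clip(config.base_kappa_hp + config.ctq_effect_horse * ctq_scaled, 0, 1))
        n_sessions = 1 if group == "control" else 4
        for s in range(n_sessions):
            th = therapists[int(meta_rng.integers(len(therapists)))]
            ho = horses[int(meta_rng.integers(len(horses)))]
            fav = int(favorite[th] == ho)
            kappa_ht = float(np.clip(config.base_kappa_ht + config.favorite_effect * fav, 0, 1))
            sess_seed = next(seed_iter)
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "session_index": s + 1,
                    "session_id": f"{pid}_s{s + 1}",
                    "therapist_id": th,
                    "horse_id": ho,
                    "favorite_horse": fav,
                    **{f"ctq_{kk}": v for kk, v in ctq.as_dict().items()},
                    "ctq_total": ctq.total,
                    "kappa_hp": kappa_hp,
                    "kappa_tp": kappa_tp,
                    "kappa_ht": kappa_ht,
                    "_seed": int(sess_seed.generate_state(1)[0] % (2**31)),
                }
            )
            k += 1
    table = pd.DataFrame(rows)

    sessions: list[SessionRecording] = []
    if make_sessions:
        for _, row in table.iterrows():
            # CTQ-linked attenuation acts on the *partner's* attunement to
            # the participant (therapist / horse side); the participant's own
            # HF composition stays fixed, so each dyad's extracted synchrony
            # reflects only its own kappa
            kappas = {
                ("horse", "participant"): config.base_kappa_hp,
                ("therapist", "participant"): config.base_kappa_tp,
                ("horse", "therapist"): row["kappa_ht"],
            }
            member_kappa = {
                (("therapist", "participant"), "therapist"): row["kappa_tp"],
                (("horse", "participant"), "horse"): row["kappa_hp"],
            }
            meta = {
                "participant_id": row["participant_id"],
                "therapist_id": row["therapist_id"],
                "horse_id": row["horse_id"],
                "session_id": row["session_id"],
                "session_index": int(row["session_index"]),
                "group": row["group"],
                "favorite_horse": int(row["favorite_horse"]),
                "ctq_total": int(row["ctq_total"]),
            }
            sessions.append(
                generate_triad_session(
                    meta,
                    timeline,
                    kappas,
                    lying_boost=config.lying_boost,
                    seed=int(row["_seed"]),
                    member_kappa=member_kappa,
                )
            )
    return table, sessions
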