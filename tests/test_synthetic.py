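"""Triad generator: coupled modulators, IPFM beats, artifacts, cohorts."""

import numpy as np
import pytest
from scipy import signal

from hrvsync import preprocess, synthetic
from hrvsync.synthetic import CohortConfig, CouplingConfig, SegmentTimeline


class TestGenerateModulators:
    def test_full_sharing_gives_identical_hf_components(self):
        cfg = CouplingConfig(kappa=1.0, noise_sd=0.0, seed=1)
        _, _, _, parts = synthetic.generate_modulators(cfg)
        np.testing.assert_allclose(parts["hf1"], parts["hf2"])

    def test_no_sharing_gives_near_zero_correlation(self):
        # sample correlation -> 0 as duration grows
        rs = []
        for seed in range(10):
            cfg = CouplingConfig(duration_s=1800.0, kappa=0.0, seed=seed)
            _, _, _, parts = synthetic.generate_modulators(cfg)
            rs.append(np.corrcoef(parts["hf1"], parts["hf2"])[0, 1])
        assert abs(np.mean(rs)) < 0.05
        assert np.max(np.abs(rs)) < 0.25

    def test_half_sharing_matches_monte_carlo_oracle(self):
        # independent Monte-Carlo estimate of the expected HF correlation at
        # kappa = 0.5, averaged over 50 seeds
        rs = []
        for seed in range(50):
            cfg = CouplingConfig(duration_s=600.0, kappa=0.5, seed=seed)
            _, _, _, parts = synthetic.generate_modulators(cfg)
            rs.append(np.corrcoef(parts["hf1"], parts["hf2"])[0, 1])
        mc = np.mean(rs)
        assert mc == pytest.approx(0.5, abs=0.05)  # variance-share construction
        cfg = CouplingConfig(duration_s=600.0, kappa=0.5, seed=123)
        _, _, _, parts = synthetic.generate_modulators(cfg)
        r = np.corrcoef(parts["hf1"], parts["hf2"])[0, 1]
        assert r == pytest.approx(mc, abs=0.1)

    def test_deterministic_under_fixed_seed(self):
        cfg = CouplingConfig(seed=7)
        _, m1a, m2a, _ = synthetic.generate_modulators(cfg)
        _, m1b, m2b, _ = synthetic.generate_modulators(cfg)
        np.testing.assert_array_equal(m1a, m1b)
        np.testing.assert_array_equal(m2a, m2b)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            CouplingConfig(kappa=1.2)

    def test_tachogram_spectral_peak_at_hf_freq(self):
        # hf only: the resampled tachogram's average spectrum peaks at hf_freq
        # (single narrowband realizations scatter; average 10 seeds)
        spectra = []
        for seed in range(10):
            cfg = CouplingConfig(
                duration_s=600.0, kappa=0.0, lf_amp=1e-9, noise_sd=0.0, seed=seed
            )
            t, m1, _, _ = synthetic.generate_modulators(cfg)
            s = synthetic.ipfm_beats(t, m1, 70.0)
            grid = np.arange(5.0, 595.0, 0.25)
            ibi = np.interp(grid, s.beat_time, s.rr)
            f, p = signal.welch(ibi - ibi.mean(), fs=4.0, nperseg=512)
            spectra.append(p)
        peak = f[np.argmax(np.mean(spectra, axis=0))]
        assert peak == pytest.approx(0.25, abs=f[1] - f[0])


class TestIpfmBeats:
    @pytest.mark.parametrize("hr,expected_rr", [(60.0, 1000.0), (40.0, 1500.0)])
    def test_constant_modulator_gives_exact_spacing(self, hr, expected_rr):
        t = np.arange(0, 300, 0.125)
        s = synthetic.ipfm_beats(t, np.ones(t.size), hr)
        np.testing.assert_allclose(np.diff(s.beat_time), expected_rr / 1000.0, atol=1e-9)
        np.testing.assert_allclose(s.rr, expected_rr, atol=1e-6)

    def test_beat_count_matches_integration_oracle(self):
        # oracle: closed-form integral of (hr/60)*(1 + 0.1 sin(2 pi 0.25 t))
        t = np.arange(0, 300, 0.125)
        m = 1.0 + 0.1 * np.sin(2 * np.pi * 0.25 * t)
        s = synthetic.ipfm_beats(t, m, 60.0)
        T = t[-1]
        integral = T + 0.1 * (1 - np.cos(2 * np.pi * 0.25 * T)) / (2 * np.pi * 0.25)
        assert abs(len(s) - np.floor(integral)) <= 1

    def test_mean_rr_within_two_percent(self):
        for role, hr in (("participant", 70.0), ("horse", 38.0)):
            cfg = CouplingConfig(duration_s=300.0, mean_hr=hr, seed=5)
            t, m1, _, _ = synthetic.generate_modulators(cfg)
            s = synthetic.ipfm_beats(t, m1, hr, role=role)
            assert np.mean(s.rr) == pytest.approx(60000.0 / hr, rel=0.02)

    def test_rejects_bad_inputs(self):
        t = np.arange(0, 10, 0.125)
        with pytest.raises(ValueError, match="mean_hr"):
            synthetic.ipfm_beats(t, np.ones(t.size), -5.0)
        with pytest.raises(ValueError, match="positive"):
            synthetic.ipfm_beats(t, np.zeros(t.size), 60.0)


class TestInjectArtifacts:
    def test_no_corruption_is_identity(self, human_series):
        out, mask = synthetic.inject_artifacts(human_series)
        np.testing.assert_array_equal(out.rr, human_series.rr)
        assert mask["n_spiked"] == 0 and mask["n_duplicated"] == 0

    def test_gap_removes_all_beats_in_window(self, human_series):
        out, mask = synthetic.inject_artifacts(human_series, gap_spec=[(100.0, 1.5)])
        assert not np.any((out.beat_time > 100.0) & (out.beat_time <= 101.5))
        assert mask["gap_windows"] == [(100.0, 1.5)]

    def test_spike_count_matches_generator_replay(self, human_series):
        out, mask = synthetic.inject_artifacts(human_series, spike_rate=2.0, seed=42)
        # independent replay of the same generator protocol
        rng = np.random.default_rng(np.random.SeedSequence(42))
        expected = rng.poisson(2.0 * human_series.duration_s / 60.0)
        assert mask["n_spiked"] == min(expected, len(human_series))
        changed = np.sum(out.rr != human_series.rr)
        assert changed == mask["n_spiked"]

    def test_gap_outside_recording_errors(self, human_series):
        with pytest.raises(ValueError, match="outside recording"):
            synthetic.inject_artifacts(human_series, gap_spec=[(1e4, 1.0)])


class TestSegmentTimeline:
    def test_default_matches_session_schedule(self):
        tl = SegmentTimeline.default()
        lying = tl.window("lying")
        assert lying == (2100.0, 2400.0)
        assert tl.duration_s == 3300.0

    def test_overlap_and_short_lying_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            SegmentTimeline((("a", 0.0, 10.0), ("b", 5.0, 20.0)))
        with pytest.raises(ValueError, match="lying"):
            SegmentTimeline((("lying", 0.0, 100.0),))


class TestGenerateTriadSession:
    def test_three_roles_span_timeline(self, compact_timeline):
        rec = synthetic.generate_triad_session(
            {"session_id": "s"},
            compact_timeline,
            {d: 0.3 for d in synthetic.DYADS},
            seed=3,
        )
        assert set(rec.series) == set(synthetic.ROLES)
        for role, s in rec.series.items():
            assert s.beat_time[-1] > compact_timeline.duration_s - 5.0
        # horse beats much sparser than human
        assert len(rec.series["horse"]) < 0.65 * len(rec.series["participant"])

    def test_missing_dyad_config_errors(self, compact_timeline):
        with pytest.raises(KeyError, match="missing coupling config"):
            synthetic.generate_triad_session(
                {}, compact_timeline, {("horse", "participant"): 0.5}
            )

    def test_metadata_records_true_kappas(self, compact_timeline):
        kappas = {
            ("horse", "participant"): 0.4,
            ("therapist", "participant"): 0.2,
            ("horse", "therapist"): 0.1,
        }
        rec = synthetic.generate_triad_session({}, compact_timeline, kappas, seed=1)
        assert rec.meta["true_kappa"]["horse-participant"] == 0.4
        assert rec.meta["lying_boost"] == 0.2


class TestGenerateCohort:
    def test_session_counts_by_group(self):
        cfg = CohortConfig(n_control=3, n_patient=2, seed=1)
        table, sessions = synthetic.generate_cohort(
            cfg, SegmentTimeline.compact(), make_sessions=False
        )
        counts = table.groupby(["participant_id", "group"]).size().reset_index(name="n")
        assert (counts.loc[counts["group"] == "control", "n"] == 1).all()
        assert (counts.loc[counts["group"] == "patient", "n"] == 4).all()
        assert len(table) == 3 * 1 + 2 * 4

    def test_ctq_scores_valid_and_kappas_deterministic_in_ctq(self):
        cfg = CohortConfig(
            n_control=20, n_patient=20, ctq_effect_therapist=-0.3, seed=5
        )
        table, _ = synthetic.generate_cohort(cfg, make_sessions=False)
        sub = table.drop_duplicates("participant_id")
        ctq_cols = [c for c in table.columns if c.startswith("ctq_") and c != "ctq_total"]
        assert ((table[ctq_cols] >= 5) & (table[ctq_cols] <= 25)).all().all()
        assert (table["ctq_total"] == table[ctq_cols].sum(axis=1)).all()
        # OLS of true kappa on rescaled CTQ recovers the slope exactly
        x = (sub["ctq_total"] - 25) / 100.0
        unclipped = ~((sub["kappa_tp"] <= 0) | (sub["kappa_tp"] >= 1))
        slope = np.polyfit(x[unclipped], sub["kappa_tp"][unclipped], 1)[0]
        assert slope == pytest.approx(-0.3, abs=1e-10)

    def test_null_ctq_effect_gives_zero_slope(self):
        cfg = CohortConfig(n_control=10, n_patient=5, ctq_effect_therapist=0.0, seed=2)
        table, _ = synthetic.generate_cohort(cfg, make_sessions=False)
        assert table["kappa_tp"].nunique() == 1

    def test_identical_seeds_give_identical_cohorts(self):
        cfg = CohortConfig(n_control=2, n_patient=1, seed=9)
        tl = SegmentTimeline.compact()
        t1, s1 = synthetic.generate_cohort(cfg, tl)
        t2, s2 = synthetic.generate_cohort(cfg, tl)
        assert t1.equals(t2)
        for a, b in zip(s1, s2):
            for role in synthetic.ROLES:
                np.testing.assert_array_equal(
                    a.series[role].beat_time, b.series[role].beat_time
                )

    def test_favorite_effect_shifts_horse_therapist_kappa(self):
        cfg = CohortConfig(n_control=30, n_patient=0, favorite_effect=0.2, seed=3)
        table, _ = synthetic.generate_cohort(cfg, make_sessions=False)
        fav = table[table["favorite_horse"] == 1]["kappa_ht"]
        other = table[table["favorite_horse"] == 0]["kappa_ht"]
        assert fav.nunique() == 1 and other.nunique() == 1
        assert fav.iloc[0] - other.iloc[0] == pytest.approx(0.2)
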