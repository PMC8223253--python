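import numpy as np
import pandas as pd
import pytest

from scalphfo.core import BANDS, Segment
from scalphfo.energy import (
    TFMap,
    average_band_energy,
    band_energy,
    band_freq_grid,
    channel_band_energies,
    morlet_tfr,
    responsible_leads,
)
from scalphfo.synth import CohortConfig, generate_background, generate_cohort, inject_burst

FS = 1000.0


def _tone(freq, dur=4.0, amp=1.0):
    t = np.arange(0, dur, 1 / FS)
    return amp * np.sin(2 * np.pi * freq * t)


class TestMorletTFR:
    def test_localizes_tone(self):
        grid = np.arange(40, 80, 2.0)
        tf = morlet_tfr(_tone(60), FS, grid)
        mid = len(tf.times) // 2
        assert abs(grid[tf.power[:, mid].argmax()] - 60) <= 2.0

    def test_normalization_frequency_independent(self):
        # unit sinusoid -> peak power 1 at its own frequency, any frequency
        for f0 in (45.0, 90.0, 150.0, 250.0):
            tf = morlet_tfr(_tone(f0), FS, np.array([f0]))
            mid = len(tf.times) // 2
            assert tf.power[0, mid] == pytest.approx(1.0, rel=0.05)

    def test_zero_signal(self):
        tf = morlet_tfr(np.zeros(2000), FS, np.arange(40, 80, 5.0))
        assert np.allclose(tf.power, 0.0)

    def test_quadratic_amplitude_scaling(self):
        tf1 = morlet_tfr(_tone(60), FS, np.array([60.0]))
        tf3 = morlet_tfr(_tone(60, amp=3.0), FS, np.array([60.0]))
        mid = len(tf1.times) // 2
        assert tf3.power[0, mid] / tf1.power[0, mid] == pytest.approx(9.0, rel=0.02)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(_tone(60), FS, np.array([600.0]))

    def test_omega0_floor(self):
        with pytest.raises(ValueError):
            morlet_tfr(_tone(60), FS, np.array([60.0]), omega0=3.0)

    def test_tfmap_grid_validation(self):
        with pytest.raises(ValueError):
            TFMap(np.array([80.0, 40.0]), np.arange(3.0), np.zeros((2, 3)), np.zeros(2))


class TestAverageBandEnergy:
    def test_quadratic_scaling(self):
        e1 = band_energy(_tone(60), FS, "gamma")
        e2 = band_energy(_tone(60, amp=2.0), FS, "gamma")
        assert e2 / e1 == pytest.approx(4.0, rel=0.01)

    def test_cross_band_leakage_small(self):
        x = _tone(60)
        assert band_energy(x, FS, "ripple") < 0.05 * band_energy(x, FS, "gamma")

    def test_white_noise_stability_across_seeds(self):
        energies = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=int(4 * FS))
            energies.append(band_energy(x, FS, "gamma"))
        energies = np.array(energies)
        assert np.all(np.abs(energies - energies.mean()) / energies.mean() < 0.15)

    def test_time_shift_invariance(self):
        base = np.zeros(int(6 * FS))
        from scalphfo.core import EEGRecording

        vals = []
        for t0 in (2.0, 3.0):
            rec = EEGRecording(["x"], FS, base[None, :].copy())
            inject_burst(rec, "x", t0, 60.0, 10, 30.0)
            vals.append(band_energy(rec.data[0], FS, "gamma"))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.02

    def test_empty_selection_rejected(self):
        tf = morlet_tfr(_tone(60, dur=4.0), FS, np.arange(40, 80, 2.0))
        with pytest.raises(ValueError):
            average_band_energy(tf, BANDS["fast_ripple"])


class TestChannelBandEnergies:
    def _cohort_segments(self):
        cfg = CohortConfig(
            n_subjects_per_group=1,
            channels=("C3", "C4"),
            interictal_duration_s=3.0,
            states_per_group={"NC": ("wake", "sleep"), "IS": ("wake", "sleep")},
            seed=60,
        )
        return generate_cohort(cfg)[0]

    def test_row_count(self):
        segs = [s for s in self._cohort_segments() if s.group == "NC"]
        table = channel_band_energies(segs)
        # 2 channels x 2 states x 3 bands x 1 subject
        assert len(table) == 12
        assert set(table.columns) == {"subject", "group", "channel", "state", "band", "avg_energy"}

    def test_missing_metadata_rejected(self, background_10s):
        seg = Segment(background_10s, state="wake", onset=0.0)
        with pytest.raises(ValueError):
            channel_band_energies([seg])

    def test_empty_input(self):
        assert channel_band_energies([]).empty

    def test_configured_direction_recovered(self):
        # two channels: a single-channel record is annulled by average reference
        cfg = CohortConfig(
            n_subjects_per_group=3,
            channels=("C3", "O1"),
            interictal_duration_s=3.0,
            states_per_group={"NC": ("wake", "sleep"), "IS": ("wake", "sleep")},
            band_effects={
                (g, "wake", b): 2.0 for g in ("IS", "NC") for b in BANDS
            },
            seed=61,
        )
        segs, _ = generate_cohort(cfg)
        table = channel_band_energies(segs)
        med = table.groupby(["state", "band"])["avg_energy"].median()
        for band in BANDS:
            assert med["sleep", band] < med["wake", band]


class TestResponsibleLeads:
    def _table(self, energies: dict) -> pd.DataFrame:
        rows = []
        for (subject, channel), e in energies.items():
            rows.append(
                dict(subject=subject, group="IS", channel=channel, state="wake",
                     band="gamma", avg_energy=e)
            )
        return pd.DataFrame(rows)

    def test_top_channel_wins(self):
        table = self._table({("s1", "T3"): 9.0, ("s1", "C3"): 1.0, ("s1", "O1"): 2.0})
        summary = responsible_leads(table)
        assert summary.per_subject["s1"] == [("T3", "temporal")]
        assert summary.lobe_counts == {"temporal": 1}

    def test_tie_flagged_canonical_order(self):
        table = self._table({("s1", "C4"): 5.0, ("s1", "C3"): 5.0})
        summary = responsible_leads(table)
        assert summary.per_subject["s1"][0][0] == "C3"  # canonical order
        assert "s1" in summary.ties

    def test_counts_sum_to_total(self):
        table = self._table(
            {("s1", "T3"): 3.0, ("s1", "F3"): 1.0, ("s2", "Fp1"): 8.0, ("s2", "O2"): 1.0}
        )
        summary = responsible_leads(table, top_k=1)
        assert sum(summary.lobe_counts.values()) == 2

    def test_injected_lead_recovered(self):
        rec = generate_background(4.0, FS, ["T3", "C3", "O1"], 20.0, seed=62)
        for t0 in (0.8, 1.8, 2.8):
            inject_burst(rec, "T3", t0, 60.0, 8, 60.0)
        seg = Segment(rec, state="wake", onset=0.0, subject="s1", group="IS")
        table = channel_band_energies([seg], [BANDS["gamma"]])
        summary = responsible_leads(table)
        assert summary.per_subject["s1"][0][0] == "T3"

    def test_temporal_weighted_cohort(self):
        # bursts concentrated on temporal electrodes -> temporal plurality
        rng = np.random.default_rng(63)
        segs = []
        for i in range(6):
            rec = generate_background(3.0, FS, ["F7", "T3", "C3", "O1"], 20.0, seed=70 + i)
            target = "T3" if i % 2 else "F7"
            for t0 in (0.7, 1.5, 2.2):
                inject_burst(rec, target, t0 + rng.uniform(0, 0.1), 60.0, 8, 60.0)
            segs.append(Segment(rec, state="wake", onset=0.0, subject=f"s{i}", group="IS"))
        table = channel_band_energies(segs, [BANDS["gamma"]])
        summary = responsible_leads(table)
        assert summary.lobe_counts["temporal"] == 6

    def test_bad_top_k(self):
        with pytest.raises(ValueError):
            responsible_leads(self._table({("s1", "C3"): 1.0}), top_k=0)

    def test_empty_table(self):
        with pytest.raises(ValueError):
            responsible_leads(pd.DataFrame(columns=["subject", "channel", "avg_energy"]))
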