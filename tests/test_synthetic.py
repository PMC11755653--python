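"""Surrogate generator: determinism, spectral content, coupling behavior."""

import numpy as np
import pytest
from scipy.signal import periodogram

from wbsync import AnalysisConfig
from wbsync.errors import DomainError, ValidationError
from wbsync.experiments import pair_analysis, single_band_config
from wbsync.recordings import CANONICAL_CHANNELS
from wbsync.stats import correlate_with_ahi
from wbsync.synthetic import (CouplingScheme, default_scheme,
                              generate_cohort, generate_coupled_pair,
                              generate_recording)


class TestCoupledPair:
    def test_same_seed_reproduces_bitwise(self):
        a1, a2 = generate_coupled_pair(6.0, 2.0, 0.5, 30, 100.0, seed=3)
        b1, b2 = generate_coupled_pair(6.0, 2.0, 0.5, 30, 100.0, seed=3)
        c1, _ = generate_coupled_pair(6.0, 2.0, 0.5, 30, 100.0, seed=4)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)
        assert not np.array_equal(a1, c1)

    def test_full_coupling_is_fully_synchronous(self):
        cfg = single_band_config(AnalysisConfig(), "theta", points=5)
        x1, x2 = generate_coupled_pair(6.0, 2.0, 1.0, 120, 100.0, seed=11,
                                       noise_sd=0.0)
        _, _, series = pair_analysis(x1, x2, 100.0, cfg)
        assert series["theta"].mean_wb >= 0.99

    def test_invalid_band_rejected(self):
        with pytest.raises(DomainError):
            generate_coupled_pair(49.0, 6.0, 0.5, 10, 100.0, seed=0)
        with pytest.raises(DomainError):
            generate_coupled_pair(0.2, 0.6, 0.5, 10, 100.0, seed=0)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(DomainError):
            generate_coupled_pair(6.0, 2.0, 1.5, 10, 100.0, seed=0)

    def test_spectral_power_concentrated_in_band(self):
        x1, _ = generate_coupled_pair(6.0, 2.0, 0.7, 120, 100.0, seed=21)
        f, pxx = periodogram(x1, fs=100.0)
        in_band = (f >= 3.5) & (f <= 8.5)
        assert pxx[in_band].sum() / pxx.sum() >= 0.8


class TestRecording:
    def test_sample_count_arithmetic(self):
        rec = generate_recording(default_scheme(), duration=600, fs=100, seed=0,
                                 channels=("C3", "C4"))
        assert rec.n_samples == 60000 and rec.n_channels == 2

    def test_channel_subset_is_exact_restriction(self):
        scheme = default_scheme()
        full = generate_recording(scheme, duration=5, fs=100, seed=9)
        sub = generate_recording(scheme, duration=5, fs=100, seed=9,
                                 channels=("C3", "Pz"))
        for ch in ("C3", "Pz"):
            assert np.array_equal(sub.signals[sub.channel_labels.index(ch)],
                                  full.signals[full.channel_labels.index(ch)])

    def test_channels_power_concentrated_in_configured_bands(self):
        rec = generate_recording(default_scheme(), duration=120, fs=100,
                                 seed=13, channels=("C3", "Fz"))
        union = [(0.25, 1), (1, 4), (4, 8), (8, 12), (12, 20), (20, 30)]
        for row in rec.signals:
            f, pxx = periodogram(row, fs=rec.fs)
            margin = 0.5
            in_band = np.zeros_like(f, bool)
            for lo, hi in union:
                in_band |= (f >= lo - margin) & (f <= hi + margin)
            assert pxx[in_band].sum() / pxx.sum() >= 0.8

    def test_nondisjoint_pairs_rejected(self):
        with pytest.raises(ValidationError):
            CouplingScheme(coupling={"delta": {("C3", "C4"): 0.5,
                                               ("C4", "Cz"): 0.5}})

    def test_targeted_pair_dominates_recovered_matrix(self):
        # couple only (C3, C4) in delta; every other delta cell is background
        scheme = CouplingScheme(
            coupling={"delta": {("C3", "C4"): 0.9}}, noise_sd=0.3)
        cfg = single_band_config(AnalysisConfig(), "delta", points=5)
        hits = 0
        channels = ("C3", "C4", "O1", "Fz")
        for seed in range(3):
            rec = generate_recording(scheme, duration=300, fs=100,
                                     seed=(31, seed), channels=channels)
            means = {}
            for i in range(len(channels)):
                for j in range(i + 1, len(channels)):
                    _, _, s = pair_analysis(rec.signals[i], rec.signals[j],
                                            rec.fs, cfg)
                    means[(channels[i], channels[j])] = s["delta"].mean_wb
            if max(means, key=means.get) == ("C3", "C4"):
                hits += 1
        assert hits == 3


class TestCohort:
    def test_group_sizes_and_ahi_ranges(self):
        cohort = generate_cohort(4, 5, default_scheme(), seed=2, duration=5,
                                 channels=("C3", "C4"))
        groups = [s.group for s in cohort.subjects]
        assert groups.count("control") == 4 and groups.count("main") == 5
        for s in cohort.subjects:
            if s.group == "control":
                assert 0 <= s.ahi <= 15
            else:
                assert 15 < s.ahi <= 120

    def test_determinism_and_ground_truth(self):
        a = generate_cohort(2, 2, default_scheme(), seed=5, duration=4,
                            channels=("C3", "C4"))
        b = generate_cohort(2, 2, default_scheme(), seed=5, duration=4,
                            channels=("C3", "C4"))
        assert a.ground_truth() == b.ground_truth()
        assert np.array_equal(a.subjects[0].recording.signals,
                              b.subjects[0].recording.signals)

    def test_coupling_declines_with_ahi(self):
        cohort = generate_cohort(6, 6, default_scheme(coupling_jitter_sd=0.0),
                                 seed=8, duration=4, channels=("C3", "C4"))
        ahis = np.array([s.ahi for s in cohort.subjects])
        eps = np.array([s.true_coupling.coupling["delta"][("C3", "C4")]
                        for s in cohort.subjects])
        order = np.argsort(ahis)
        assert np.all(np.diff(eps[order]) <= 1e-12)

    def test_degenerate_two_subject_cohort(self):
        cohort = generate_cohort(1, 1, default_scheme(), seed=3, duration=4,
                                 channels=("C3", "C4"))
        assert len(cohort.manifest()) == 2
        res = correlate_with_ahi(np.array([0.5, 0.4]),
                                 np.array([s.ahi for s in cohort.subjects]))
        assert not res.defined

    def test_edf_export_round_trip(self, tmp_path):
        from wbsync.recordings import read_manifest, read_recording

        cohort = generate_cohort(1, 1, default_scheme(), seed=6, duration=4)
        manifest = cohort.to_edf(tmp_path)
        assert len(manifest) == 2
        df = read_manifest(tmp_path / "manifest.csv")
        rec = read_recording(df.iloc[0]["path"])
        assert rec.n_channels == 19
        assert (tmp_path / "ground_truth.json").stat().st_size > 0
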