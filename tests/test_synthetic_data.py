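import math

import numpy as np
import pytest
from scipy import stats

from bivalink import (
    CLASSES,
    MARKS,
    ConfigError,
    PromoterWindow,
    SimulationConfig,
    generate_dataset,
    promoter_mean_signal,
    read_bedgraph,
    read_peaks_bed,
    read_tss_annotation,
    scenario_two_waves,
)
from bivalink.synthetic_data import TWO_WAVE_STAGES, TWO_WAVE_TRAJECTORIES


def small_config(**overrides):
    defaults = dict(n_genes=200, stages=("s1", "s2"), seed=7)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum"):
            small_config(class_fractions={"bivalent": 0.5, "k4_only": 0.2,
                                          "k27_only": 0.1, "silent": 0.1})

    def test_depth_must_be_positive(self):
        with pytest.raises(ConfigError, match="depth"):
            small_config(depth={"s1": 0.0, "s2": 1.0})

    def test_label_plan_shape_checked(self):
        with pytest.raises(ConfigError, match="label_plan"):
            small_config(label_plan=np.full((5, 2), "bivalent", dtype=object))


class TestGenerateDataset:
    def test_same_seed_is_byte_identical_on_disk(self, tmp_path):
        d1 = generate_dataset(small_config())
        d2 = generate_dataset(small_config())
        m1 = d1.write(tmp_path / "a")
        m2 = d2.write(tmp_path / "b")
        for key in m1:
            with open(m1[key], "rb") as f1, open(m2[key], "rb") as f2:
                assert f1.read() == f2.read(), key

    def test_different_seed_differs(self):
        d1 = generate_dataset(small_config())
        d2 = generate_dataset(small_config(seed=8))
        s = d1.tracks["s1"]["H3K4me3"].data["chr1"]
        assert not np.array_equal(s, d2.tracks["s1"]["H3K4me3"].data["chr1"])

    def test_depth_multiplier_scales_tracks_exactly(self):
        base = generate_dataset(small_config(depth={"s1": 1.0, "s2": 1.0}))
        deep = generate_dataset(small_config(depth={"s1": 1.0, "s2": 10.0}))
        for mark in MARKS:
            np.testing.assert_array_equal(
                deep.tracks["s1"][mark].data["chr1"], base.tracks["s1"][mark].data["chr1"]
            )
            np.testing.assert_array_equal(
                deep.tracks["s2"][mark].data["chr1"],
                base.tracks["s2"][mark].data["chr1"] * 10.0,
            )

    def test_degenerate_config_paints_exact_class_means(self):
        config = small_config(
            class_fractions={"bivalent": 1.0, "k4_only": 0.0, "k27_only": 0.0, "silent": 0.0},
            signal_log_sd=0.0,
            background_level=0.0,
            multi_tss_fraction=0.0,
        )
        ds = generate_dataset(config)
        win = PromoterWindow(1000, 1000)
        for mark in MARKS:
            expected = math.exp(config.class_log_means["bivalent"][mark])
            vals = promoter_mean_signal(ds.tracks["s1"][mark], ds.annotation, win)
            np.testing.assert_allclose(vals.values, expected, rtol=1e-12)

    def test_outputs_pass_format_readers(self, tmp_path):
        ds = generate_dataset(small_config(multi_tss_fraction=0.3))
        manifest = ds.write(tmp_path)
        ann = read_tss_annotation(manifest["annotation"])
        assert ann.n_genes == 200 and len(ann) > 200  # multi-TSS genes present
        track = read_bedgraph(manifest["track:s1:H3K4me3"], bin_size=100)
        np.testing.assert_allclose(
            track.data["chr1"], ds.tracks["s1"]["H3K4me3"].data["chr1"], rtol=1e-12
        )
        peaks = read_peaks_bed(manifest["peaks:s1"])
        assert len(peaks) == len(ds.peaks["s1"])

    def test_peaks_cover_k4_positive_genes_only(self):
        ds = generate_dataset(small_config(multi_tss_fraction=0.0, background_level=0.0))
        for stage in ("s1", "s2"):
            k4_on = {
                g
                for g in ds.truth.labels.index
                if ds.truth.labels.loc[g, stage] in ("bivalent", "k4_only")
            }
            named = set(ds.peaks[stage].intervals["name"])
            assert named == k4_on

    def test_class_fractions_within_binomial_ci(self):
        fractions = {"bivalent": 0.1, "k4_only": 0.2, "k27_only": 0.15, "silent": 0.55}
        ds = generate_dataset(
            SimulationConfig(n_genes=5000, stages=("s1",), class_fractions=fractions, seed=11)
        )
        labels = ds.truth.labels["s1"]
        for cls, frac in fractions.items():
            observed = int((labels == cls).sum())
            lo, hi = stats.binom.interval(0.99, 5000, frac)
            assert lo <= observed <= hi, cls

    def test_class_log_means_recovered(self):
        config = SimulationConfig(
            n_genes=5000, stages=("s1",), seed=13, multi_tss_fraction=0.0,
            background_level=0.0,
        )
        ds = generate_dataset(config)
        win = PromoterWindow(1000, 1000)
        vals = promoter_mean_signal(ds.tracks["s1"]["H3K27me3"], ds.annotation, win)
        labels = ds.truth.labels["s1"]
        sd = config.signal_log_sd
        for cls in CLASSES:
            sel = labels == cls
            n = int(sel.sum())
            logs = np.log(vals[labels.index[sel]])
            mu = config.class_log_means[cls]["H3K27me3"]
            assert abs(logs.mean() - mu) < 3 * sd / math.sqrt(n)


class TestTwoWaveScenario:
    def test_planted_counts_are_exact_quotas(self, two_wave_dataset):
        truth = two_wave_dataset.truth
        n = len(truth.labels)
        expected_s3 = sum(
            round(frac * n)
            for _, frac, classes in TWO_WAVE_TRAJECTORIES
            if classes[2] == "bivalent"
        )
        assert len(truth.bivalent_genes("S3")) == expected_s3

    def test_newly_bivalent_at_s4_all_carry_prior_k27(self, two_wave_dataset):
        truth = two_wave_dataset.truth
        gained = truth.bivalent_genes("S4") - truth.bivalent_genes("S3")
        assert gained  # wave 2 exists
        prior = set(truth.labels.loc[sorted(gained), "S3"])
        assert prior == {"k27_only"}

    def test_newly_bivalent_at_s3_gain_both_marks(self, two_wave_dataset):
        truth = two_wave_dataset.truth
        gained = truth.bivalent_genes("S3") - truth.bivalent_genes("S2")
        prior = set(truth.labels.loc[sorted(gained), "S2"])
        assert prior == {"silent"}

    def test_stage_names_and_plan_shape(self):
        config = scenario_two_waves(n_genes=100, seed=0)
        assert config.stages == TWO_WAVE_STAGES
        assert config.label_plan.shape == (100, 4)
        assert len(config.trajectory_names) == 100
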