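import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bivalink import (
    ConfigError,
    PromoterWindow,
    build_matrix,
    generate_dataset,
    promoter_mean_signal,
    SimulationConfig,
)

from conftest import make_annotation, make_track
from oracles import per_basepair_gene_signal

WIN = PromoterWindow(upstream=1000, downstream=500)


class TestWindow:
    def test_plus_strand_bounds(self):
        assert WIN.bounds(5000, "+") == (4000, 5500)

    def test_minus_strand_bounds_follow_transcription(self):
        # upstream lies 3'-ward in genomic coordinates for minus-strand genes
        assert WIN.bounds(5000, "-") == (4500, 6000)

    def test_strand_naive_reading(self):
        win = PromoterWindow(1000, 500, strand_aware=False)
        assert win.bounds(5000, "-") == (4000, 5500)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ConfigError):
            PromoterWindow(0, 0)


class TestPromoterMeanSignal:
    def test_all_zero_track(self):
        ann = make_annotation([("A", "chr1", 2000, "+"), ("B", "chr1", 5000, "-")])
        track = make_track({"chr1": np.zeros(100)})
        assert promoter_mean_signal(track, ann, WIN).tolist() == [0.0, 0.0]

    def test_constant_track_gives_the_constant(self):
        ann = make_annotation([("A", "chr1", 5000, "+")])
        track = make_track({"chr1": np.full(100, 4.0)})
        for win in (WIN, PromoterWindow(1000, 1000), PromoterWindow(10, 20)):
            assert promoter_mean_signal(track, ann, win)["A"] == 4.0

    def test_max_over_tss_rule(self):
        # two promoters of one gene with constant signal 2.0 and 5.0
        ann = make_annotation([("A", "chr1", 1000, "+"), ("A", "chr1", 7000, "+")])
        arr = np.zeros(120)
        arr[0:30] = 2.0
        arr[60:90] = 5.0
        track = make_track({"chr1": arr})
        assert promoter_mean_signal(track, ann, WIN)["A"] == 5.0

    def test_hand_length_weighted_mean(self):
        # bins [1.0, 3.0]; window [50, 200) = last 50 bp of bin 0 plus all of bin 1
        ann = make_annotation([("A", "chr1", 50, "+")])
        track = make_track({"chr1": [1.0, 3.0]})
        got = promoter_mean_signal(track, ann, PromoterWindow(upstream=0, downstream=150))
        assert got["A"] == pytest.approx((1 * 50 + 3 * 100) / 150, rel=1e-12)

    def test_window_truncated_at_chromosome_start_renormalizes(self):
        ann = make_annotation([("A", "chr1", 100, "+")])
        track = make_track({"chr1": [6.0, 6.0, 0.0]})
        # nominal window [-900, 600): usable [0, 600) -> (6*200 + 0*400)/600
        got = promoter_mean_signal(track, ann, WIN)
        assert got["A"] == pytest.approx((6.0 * 200) / 600, rel=1e-12)

    def test_tss_on_absent_chromosome_scores_zero(self):
        ann = make_annotation([("A", "chrX", 5000, "+")])
        track = make_track({"chr1": np.ones(100)})
        assert promoter_mean_signal(track, ann, WIN)["A"] == 0.0

    def test_zero_usable_window_names_gene(self):
        ann = make_annotation([("A", "chr1", 0, "+")])
        track = make_track({"chr1": np.ones(10)})
        with pytest.raises(ValueError, match="gene A"):
            promoter_mean_signal(track, ann, PromoterWindow(upstream=100, downstream=0))

    @given(st.floats(0.1, 100.0), st.integers(0, 1000))
    def test_linearity_in_track_scale(self, c, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random(60) * 10
        ann = make_annotation([("A", "chr1", 2500, "+"), ("B", "chr1", 4100, "-")])
        track = make_track({"chr1": arr})
        base = promoter_mean_signal(track, ann, WIN)
        scaled = promoter_mean_signal(track.scaled(c), ann, WIN)
        assert np.allclose(scaled.values, base.values * c, rtol=1e-9)

    def test_adding_a_tss_never_decreases_value(self):
        rng = np.random.default_rng(7)
        arr = rng.random(80) * 5
        track = make_track({"chr1": arr})
        base = promoter_mean_signal(
            track, make_annotation([("A", "chr1", 3000, "+")]), WIN
        )["A"]
        more = promoter_mean_signal(
            track, make_annotation([("A", "chr1", 3000, "+"), ("A", "chr1", 6200, "-")]), WIN
        )["A"]
        assert more >= base

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_basepair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bin_size = int(rng.integers(10, 120))
        arrs = {c: rng.random(int(rng.integers(5, 60))) * 8 for c in ("chr1", "chr2")}
        track = make_track(arrs, bin_size=bin_size)
        records = []
        for g in range(12):
            chrom = "chr1" if g % 2 else "chr2"
            tss = int(rng.integers(150, bin_size * 60))
            records.append((f"g{g:02d}", chrom, tss, "+" if g % 3 else "-"))
        ann = make_annotation(records)
        win = PromoterWindow(upstream=int(rng.integers(1, 400)), downstream=int(rng.integers(1, 400)))
        got = promoter_mean_signal(track, ann, win)
        expected = per_basepair_gene_signal(arrs, bin_size, records, win.upstream, win.downstream)
        for gene, val in expected.items():
            assert got[gene] == pytest.approx(val, rel=1e-9, abs=1e-12)


class TestBuildMatrix:
    def test_shape_and_column_order(self):
        ann = make_annotation([("A", "chr1", 500, "+"), ("B", "chr1", 2500, "+"),
                               ("C", "chr1", 4500, "-")])
        t1 = make_track({"chr1": np.ones(60)}, stage="s1")
        t2 = make_track({"chr1": np.full(60, 2.0)}, stage="s2")
        mat = build_matrix([("s2", t2), ("s1", t1)], ann, WIN, mark="H3K4me3")
        assert mat.values.shape == (3, 2)
        assert mat.stages == ["s2", "s1"]
        assert not mat.normalized

    def test_duplicate_stage_names_rejected(self):
        ann = make_annotation([("A", "chr1", 500, "+")])
        t = make_track({"chr1": np.ones(10)})
        with pytest.raises(ConfigError, match="duplicate"):
            build_matrix([("s1", t), ("s1", t)], ann, WIN)

    def test_mixed_marks_rejected(self):
        ann = make_annotation([("A", "chr1", 500, "+")])
        with pytest.raises(ConfigError, match="mix"):
            build_matrix(
                [("s1", make_track({"chr1": np.ones(10)}, mark="H3K4me3")),
                 ("s2", make_track({"chr1": np.ones(10)}, mark="H3K27me3"))],
                ann, WIN,
            )

    def test_zero_noise_synthetic_recovers_class_mean_times_depth(self):
        config = SimulationConfig(
            n_genes=40,
            stages=("s1", "s2"),
            class_fractions={"bivalent": 1.0, "k4_only": 0.0, "k27_only": 0.0, "silent": 0.0},
            signal_log_sd=0.0,
            background_level=0.0,
            multi_tss_fraction=0.0,
            depth={"s1": 1.0, "s2": 4.0},
            seed=3,
        )
        ds = generate_dataset(config)
        expected = np.exp(config.class_log_means["bivalent"]["H3K4me3"])
        mat = build_matrix(
            [(s, ds.tracks[s]["H3K4me3"]) for s in config.stages],
            ds.annotation, PromoterWindow(1000, 1000), mark="H3K4me3",
        )
        np.testing.assert_allclose(mat.values["s1"], expected, rtol=1e-12)
        np.testing.assert_allclose(mat.values["s2"], expected * 4.0, rtol=1e-12)
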