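"""Copy-number windows, ratios, segmentation and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from chordax import cnv, synth
from chordax.models import GeneModel, Segment


def _profile_from_values(values, chrom="chr1", sample="s"):
    n = len(values)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 100 + 1,
            "end": (np.arange(n) + 1) * 100,
            "tumor": 100.0,
            "ref": 100.0,
            "log2": np.asarray(values, dtype=float),
        }
    )
    return cnv.CopyRatioProfile(sample_id=sample, windows=df)


class TestMakeWindows:
    def test_uniform_reads_equal_windows(self):
        starts = {"chr1": np.arange(1, 1001)}
        w = cnv.make_windows(starts, reads_per_window=100,
                             chrom_lengths={"chr1": 1000})
        assert len(w) == 10
        assert w["n_reads"].tolist() == [100] * 10

    def test_nonuniform_depth_equal_counts_cumulative_oracle(self):
        rng = np.random.default_rng(0)
        # heavy left tail: windows must be narrow there, wide on the right
        starts = np.sort(
            np.concatenate(
                [rng.integers(1, 2000, 800), rng.integers(2000, 50_000, 200)]
            )
        )
        w = cnv.make_windows({"chr1": starts}, reads_per_window=100,
                             chrom_lengths={"chr1": 50_000})
        # oracle: count reads falling in each reported window
        for row in w.itertuples():
            n = ((starts >= row.start) & (starts <= row.end)).sum()
            assert n == row.n_reads
        # exactly the target count except where boundary ties force more
        assert w["n_reads"].iloc[:-1].ge(100).all()
        assert (w["n_reads"].iloc[:-1] - 100).max() <= 5
        widths = w["end"] - w["start"]
        assert widths.iloc[-1] > widths.iloc[0]

    def test_windows_never_cross_chromosomes(self):
        starts = {
            "chr1": np.arange(1, 201), "chr2": np.arange(1, 201),
        }
        w = cnv.make_windows(starts, reads_per_window=100,
                             chrom_lengths={"chr1": 200, "chr2": 200})
        assert set(w["chrom"]) == {"chr1", "chr2"}
        assert len(w) == 4

    def test_underpopulated_chromosome_single_window(self):
        with pytest.warns(UserWarning, match="fewer"):
            w = cnv.make_windows(
                {"chr1": np.arange(1, 31)}, reads_per_window=100,
                chrom_lengths={"chr1": 5000},
            )
        assert len(w) == 1 and w["end"].iloc[0] == 5000

    def test_small_reads_per_window_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            cnv.make_windows({"chr1": [1]}, reads_per_window=10)


class TestPseudoNormal:
    def test_single_normal_identity(self):
        counts = np.array([10.0, 20.0, 30.0])
        assert np.allclose(cnv.build_pseudo_normal([counts]), counts)

    def test_three_identical_normals_unchanged(self):
        c = np.array([5.0, 15.0, 25.0])
        assert np.allclose(cnv.build_pseudo_normal([c, c, c]), c)

    def test_median_across_equal_libraries(self):
        a = np.array([10.0, 50.0, 40.0])  # all libraries total 100
        b = np.array([20.0, 50.0, 30.0])
        c = np.array([90.0, 8.0, 2.0])
        pseudo = cnv.build_pseudo_normal([a, b, c])
        assert pseudo[0] == 20.0  # median of {10, 20, 90}

    def test_mismatched_windows_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            cnv.build_pseudo_normal([np.ones(3), np.ones(4)])


class TestLog2Ratio:
    WINDOWS = pd.DataFrame(
        {
            "chrom": ["chr1"] * 10,
            "start": np.arange(10) * 10 + 1,
            "end": (np.arange(10) + 1) * 10,
        }
    )

    def test_equal_counts_all_zero(self):
        t = np.full(10, 50.0)
        p = cnv.compute_log2_ratio(t, t, self.WINDOWS)
        assert np.allclose(p.windows["log2"], 0.0)

    def test_doubled_arm_closed_form(self):
        ref = np.full(10, 100.0)
        tumor = ref.copy()
        tumor[:3] *= 2  # minority of windows doubled
        p = cnv.compute_log2_ratio(tumor, ref, self.WINDOWS)
        c = cnv.FLOOR_OFFSET
        expected = np.log2((200 + c) / (100 + c)) - 0.0  # median is 0
        assert np.allclose(p.windows["log2"][:3], expected)
        assert np.allclose(p.windows["log2"][3:], 0.0)

    def test_library_scale_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.integers(50, 150, 10).astype(float)
        r = rng.integers(50, 150, 10).astype(float)
        p1 = cnv.compute_log2_ratio(t, r, self.WINDOWS, floor_offset=0.0)
        p2 = cnv.compute_log2_ratio(2 * t, 2 * r, self.WINDOWS,
                                    floor_offset=0.0)
        assert np.allclose(p1.windows["log2"], p2.windows["log2"])

    def test_all_zero_tumor_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cnv.compute_log2_ratio(
                np.zeros(10), np.full(10, 5.0), self.WINDOWS
            )


class TestSegmentation:
    def test_flat_profile_one_segment_per_chromosome(self):
        n = 40
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * n + ["chr2"] * n,
                "start": list(range(n)) * 2,
                "end": list(range(1, n + 1)) * 2,
                "tumor": 100.0,
                "ref": 100.0,
                "log2": 0.0,
            }
        )
        segs = cnv.segment_profile(
            cnv.CopyRatioProfile(sample_id="s", windows=df)
        )
        assert len(segs) == 2
        assert all(s.call == "neutral" for s in segs)

    def test_noiseless_step_boundary_matches_exhaustive_oracle(self):
        values = np.array([0.0] * 30 + [1.0] * 30)
        # oracle: exhaustive split maximizing mean difference
        diffs = [
            abs(values[:i].mean() - values[i:].mean())
            for i in range(1, len(values))
        ]
        oracle_split = int(np.argmax(diffs)) + 1
        segs = cnv.segment_profile(_profile_from_values(values))
        assert len(segs) == 2
        assert segs[0].n_windows == oracle_split == 30
        assert segs[0].mean_log2 == 0.0 and segs[1].mean_log2 == 1.0
        assert segs[1].call == "gain"

    def test_segment_means_reconstruct_window_means(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0, 0.1, 50), rng.normal(-1, 0.1, 40),
             rng.normal(0, 0.1, 60)]
        )
        profile = _profile_from_values(values)
        segs = cnv.segment_profile(profile)
        for seg in segs:
            w = profile.windows
            member = w[(w["start"] >= seg.start) & (w["end"] <= seg.end)]
            assert seg.mean_log2 == pytest.approx(member["log2"].mean())
            assert seg.n_windows == len(member)
        # segments tile the chromosome without overlap
        assert sum(s.n_windows for s in segs) == len(values)

    def test_injected_arm_loss_recovered(self):
        arms = {"chr1": ("loss", "neutral")}
        df = synth.simulate_depth_profiles(
            arms, n_windows=200, mean_depth=200, noise=0.05, seed=8
        )
        profile = cnv.compute_log2_ratio(df["tumor"], df["normal"], df)
        segs = cnv.segment_profile(profile)
        wc = cnv.window_calls(profile, segs)
        affected = wc[df["state"] == "loss"]
        assert (affected["call"] == "loss").mean() >= 0.9


class TestGeneCalls:
    SEGS = [
        Segment("chr1", 1, 1000, 10, mean_log2=1.0, call="gain"),
        Segment("chr1", 1001, 2000, 10, mean_log2=0.0, call="neutral"),
    ]

    def test_gene_inside_gain_segment(self):
        g = GeneModel("g", "chr1", "+", ((100, 300),))
        assert cnv.call_gene_copy_number(self.SEGS, [g])["g"] == "gain"

    def test_zero_mean_neutral(self):
        g = GeneModel("g", "chr1", "+", ((1200, 1400),))
        assert cnv.call_gene_copy_number(self.SEGS, [g])["g"] == "neutral"

    def test_boundary_spanning_gene_weighted_mean(self):
        # 50/50 split across +1 and 0 segments: weighted mean 0.5 -> gain
        g = GeneModel("g", "chr1", "+", ((501, 1500),))
        assert cnv.call_gene_copy_number(self.SEGS, [g])["g"] == "gain"

    def test_gene_outside_segments_rejected(self):
        g = GeneModel("g", "chr2", "+", ((10, 20),))
        with pytest.raises(ValueError, match="outside"):
            cnv.call_gene_copy_number(self.SEGS, [g])


class TestCohortFrequency:
    def test_counts(self):
        calls = {
            f"s{i}": {"locusA": "gain" if i < 5 else "neutral",
                      "locusB": "loss"}
            for i in range(8)
        }
        freq = cnv.cohort_frequency(calls)
        assert freq.loc["locusA", "n_gain"] == 5
        assert freq.loc["locusB", "n_loss"] == 8
        assert (freq["n_total"] == 8).all()

    def test_missing_locus_zero_counts(self):
        freq = cnv.cohort_frequency(
            {"s1": {"a": "gain"}, "s2": {"b": "loss"}}
        )
        assert freq.loc["b", "n_gain"] == 0
        assert freq.loc["b", "n_total"] == 2

    def test_synthetic_cohort_reproduces_arm_pattern(self, cohort_spec):
        """Losses concentrate on the 1p/10/13 analogues, gains on the
        7/17q analogues, when every sample carries the default events."""
        sample_calls = {}
        for i in range(4):
            df = synth.simulate_depth_profiles(
                cohort_spec.cna_arms, n_windows=100, mean_depth=200,
                noise=0.05, seed=20 + i,
            )
            profile = cnv.compute_log2_ratio(df["tumor"], df["normal"], df)
            segs = cnv.segment_profile(profile)
            wc = cnv.window_calls(profile, segs)
            sample_calls[f"s{i}"] = {
                f"{r.chrom}:{r.arm}:{r.start}": r.call
                for r in wc.join(df["arm"]).itertuples()
            }
        freq = cnv.cohort_frequency(sample_calls)
        arm = freq.index.str.split(":").str[:2].str.join(":")
        loss_rate = freq.groupby(arm)["n_loss"].sum() / (freq.groupby(arm)[
            "n_total"].sum())
        gain_rate = freq.groupby(arm)["n_gain"].sum() / (freq.groupby(arm)[
            "n_total"].sum())
        assert loss_rate["chr1:p"] > 0.8 and loss_rate["chr4:q"] > 0.8
        assert gain_rate["chr2:p"] > 0.8 and gain_rate["chr5:q"] > 0.8
        assert loss_rate["chr5:q"] < 0.1 and gain_rate["chr1:p"] < 0.1
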