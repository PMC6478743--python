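import math

import numpy as np
import pandas as pd
import pytest

from mmsv import cna
from mmsv.model import Interval, TranslocationCall, ValidationError


def seg(chrom, start, end, log2, sample="S1"):
    return {"sample": sample, "chrom": chrom, "start": start, "end": end, "log2": log2}


def per_base_bin_oracle(seg_df, bin_bp, length):
    """Independent per-base averaging for a single chromosome."""
    values = np.full(length, np.nan)
    for _, row in seg_df.iterrows():
        values[int(row["start"]) : int(row["end"])] = row["log2"]
    out = []
    for start in range(0, length, bin_bp):
        chunk = values[start : start + bin_bp]
        covered = ~np.isnan(chunk)
        out.append(float(np.mean(chunk[covered])) if covered.any() else np.nan)
    return np.array(out)


def random_segmentation(rng, length, sample="S1"):
    cuts = np.sort(rng.choice(np.arange(1, length), size=rng.integers(3, 12), replace=False))
    edges = np.concatenate([[0], cuts, [length]])
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        if rng.random() < 0.15:
            continue  # leave an uncovered gap
        rows.append(seg("c", int(lo), int(hi), float(rng.normal(0, 0.4)), sample))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "log2"])


class TestBinning:
    def test_full_bin_single_segment(self):
        df = pd.DataFrame([seg("c", 0, 100_000, 0.30)])
        out = cna.bin_cna(df, 100_000, {"c": 100_000})
        assert out["log2"].tolist() == [0.30]

    def test_weighted_mean_of_half_bins(self):
        df = pd.DataFrame([seg("c", 0, 50_000, 0.2), seg("c", 50_000, 100_000, 0.4)])
        out = cna.bin_cna(df, 100_000, {"c": 100_000})
        assert out["log2"].iloc[0] == pytest.approx(0.30)

    def test_uncovered_bin_is_missing(self):
        df = pd.DataFrame([seg("c", 0, 1_000, 0.2)])
        out = cna.bin_cna(df, 1_000, {"c": 3_000})
        assert math.isnan(out["log2"].iloc[2])

    def test_matches_per_base_oracle(self, rng):
        length, bin_bp = 50_000, 1_000
        for _ in range(20):
            df = random_segmentation(rng, length)
            got = cna.bin_cna(df, bin_bp, {"c": length})["log2"].to_numpy()
            want = per_base_bin_oracle(df, bin_bp, length)
            np.testing.assert_allclose(got, want, atol=1e-12, equal_nan=True)


class TestRegionCalls:
    REGION = Interval("c", 0, 10_000, "r")

    @pytest.mark.parametrize(
        "log2,expected",
        [(0.2, "gain"), (0.19, "neutral"), (-0.19, "neutral"), (-0.2, "loss"), (-0.25, "loss")],
    )
    def test_threshold_boundaries(self, log2, expected):
        df = pd.DataFrame([seg("c", 0, 10_000, log2)])
        assert cna.call_region(df, self.REGION) == expected

    def test_uncovered_region_neutral_with_warning(self):
        df = pd.DataFrame([seg("other", 0, 10_000, 1.0)])
        with pytest.warns(UserWarning, match="no segment coverage"):
            assert cna.call_region(df, self.REGION) == "neutral"


def hyperdiploidy_rule_oracle(gains16: np.ndarray) -> bool:
    """Concordant-gain rule stated directly on a 16-vector (8 chrom pairs)."""
    pairs = gains16.reshape(8, 2)
    return int(np.sum(pairs.all(axis=1))) >= 4


class TestHyperdiploidy:
    def _calls(self, gains16):
        return {
            f"chr{i}": ["gain" if g else "neutral" for g in gains16[2 * i : 2 * i + 2]]
            for i in range(8)
        }

    def test_four_concordant_chromosomes_is_hyperdiploid(self):
        gains = np.zeros(16, dtype=bool)
        gains[[0, 1, 2, 3, 6, 7, 10, 11]] = True  # chroms 0,1,3,5 fully gained
        assert cna.classify_hyperdiploidy(self._calls(gains)) is True

    def test_three_concordant_is_not(self):
        gains = np.zeros(16, dtype=bool)
        gains[[0, 1, 2, 3, 6, 7]] = True
        assert cna.classify_hyperdiploidy(self._calls(gains)) is False

    def test_discordant_gains_never_count(self):
        gains = np.array([True, False] * 8)  # one region on all 8, never both
        assert cna.classify_hyperdiploidy(self._calls(gains)) is False

    def test_matches_rule_on_sampled_vectors(self, rng):
        for _ in range(2_000):
            gains = rng.random(16) < rng.uniform(0.2, 0.8)
            assert cna.classify_hyperdiploidy(self._calls(gains)) == (
                hyperdiploidy_rule_oracle(gains)
            )

    def test_monotone_in_gains(self, rng):
        for _ in range(200):
            gains = rng.random(16) < 0.5
            before = cna.classify_hyperdiploidy(self._calls(gains))
            flip = rng.integers(0, 16)
            gains2 = gains.copy()
            gains2[flip] = True
            after = cna.classify_hyperdiploidy(self._calls(gains2))
            assert after >= before  # adding a gain never loses HD

    def test_wrong_region_count_rejected(self):
        with pytest.raises(ValidationError):
            cna.classify_hyperdiploidy({"chr1": ["gain"]})


class TestCommonCNA:
    PANEL = [
        Interval("c1", 0, 10_000, "del(1p)"),
        Interval("c1", 20_000, 30_000, "amp(1q)"),
        Interval("c2", 0, 10_000, "del(13)"),
        Interval("c3", 0, 10_000, "del(17p)"),
    ] + [
        Interval(f"h{i}", s, s + 5_000, "HD")
        for i in range(8)
        for s in (0, 50_000)
    ]

    def _flat(self, value=0.0):
        rows = [seg(c, 0, 100_000, value) for c in
                ["c1", "c2", "c3"] + [f"h{i}" for i in range(8)]]
        return pd.DataFrame(rows)

    def test_all_neutral_profile(self):
        summary = cna.classify_common_cna(self._flat(0.0), self.PANEL)
        assert not any(
            [summary.hyperdiploid, summary.del_1p, summary.amp_1q,
             summary.del_13, summary.del_17p]
        )

    def test_isolated_amp1q(self):
        df = self._flat(0.0)
        df.loc[(df["chrom"] == "c1"), "log2"] = 0.0
        extra = pd.DataFrame([seg("c1", 20_000, 30_000, 0.5)])
        df = pd.concat(
            [df[df["chrom"] != "c1"],
             pd.DataFrame([seg("c1", 0, 20_000, 0.0), seg("c1", 30_000, 100_000, 0.0)]),
             extra],
            ignore_index=True,
        )
        summary = cna.classify_common_cna(df, self.PANEL)
        assert summary.amp_1q and not summary.del_1p and not summary.hyperdiploid

    def test_generator_truth_roundtrip(self, cohort):
        """HD and focal-panel calls recover the planted truth exactly at the
        generator's noise level."""
        mismatches = 0
        for s in cohort.truth["samples"]:
            summary = cna.classify_common_cna(
                cohort.segments.for_sample(s["sample"]), cohort.spec.table1,
                sample=s["sample"],
            )
            got = (summary.hyperdiploid, summary.del_1p, summary.amp_1q,
                   summary.del_13, summary.del_17p)
            want = (s["hd"], s["del_1p"], s["amp_1q"], s["del_13"], s["del_17p"])
            mismatches += got != want
        assert mismatches == 0


class TestBoundaryProximity:
    SEGS = pd.DataFrame(
        [seg("cA", 0, 1_000_000, 0.0), seg("cA", 1_000_000, 1_500_000, 0.5),
         seg("cA", 1_500_000, 3_000_000, 0.0), seg("cB", 0, 3_000_000, 0.05)]
    )

    def _call(self, pos, chrom="cA"):
        return TranslocationCall(
            sample="S", chrom_a=chrom, pos_a=pos, chrom_b="cB", pos_b=2_000_000
        )

    @pytest.mark.parametrize(
        "pos,within,dist",
        [(990_000, True, 10_000), (989_999, False, 10_001),
         (1_200_000, False, 200_000)],  # inside the gain, nearest edge
    )
    def test_distance_to_state_change(self, pos, within, dist):
        got_within, got_dist = cna.breakpoint_boundary_proximity(
            self._call(pos), self.SEGS, end="A"
        )
        assert got_within is within
        assert got_dist == dist

    def test_no_state_change_infinite(self):
        flat = pd.DataFrame([seg("cA", 0, 3_000_000, 0.05)])
        within, dist = cna.breakpoint_boundary_proximity(self._call(1_000), flat, end="A")
        assert within is False and math.isinf(dist)

    def test_focality_cap_excludes_broad_segments(self):
        within, _ = cna.breakpoint_boundary_proximity(
            self._call(999_000), self.SEGS, end="A", max_segment_span=100_000
        )
        assert within is False  # the 500 kb gain is broader than the cap

    def test_min_over_both_ends(self):
        call = TranslocationCall(
            sample="S", chrom_a="cB", pos_a=2_000_000, chrom_b="cA", pos_b=1_495_000
        )
        within, dist = cna.breakpoint_boundary_proximity(call, self.SEGS, end="both")
        assert within is True and dist == 5_000


class TestCooccurrence:
    def test_identical_annotations_extreme(self, rng):
        a = rng.random(24) < 0.5
        table, odds, p = cna.cooccurrence_test(a, a)
        assert p < 1e-4 and odds > 1

    def test_independent_annotations_calibrated(self, rng):
        """Fisher's exact test is valid (conservative) under independence."""
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.random(40) < 0.4
            b = rng.random(40) < 0.4
            _, _, p = cna.cooccurrence_test(a, b)
            rejections += p < 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert rate <= 0.05 + 2 * se

    def test_fdr_monotone_and_bounded(self, rng):
        p = rng.random(50) ** 2
        q = cna.fdr_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all()
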