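import numpy as np
import pytest

from mmsv import qc
from mmsv.model import (
    AnnotationSet,
    GenomeAssembly,
    Interval,
    MappabilityTrack,
    TranslocationCall,
    ValidationError,
)
from mmsv.simulate import generate_homology_fixtures, plant_identity_pair


def window_identity_oracle(seq_a: str, seq_b: str, window: int = 100) -> float:
    """Independent all-offset window scan via one-hot matrix products."""
    def onehot(seq):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        return np.stack([(arr == ord(c)).astype(np.float32) for c in "ACGT"])

    def windows(mat, w):
        n = mat.shape[1] - w + 1
        return np.stack([mat[:, i : i + w] for i in range(n)])  # (n, 4, w)

    wa = windows(onehot(seq_a), window)
    wb = windows(onehot(seq_b), window)
    best = 0.0
    for i in range(wa.shape[0]):
        matches = np.einsum("cw,ncw->n", wa[i], wb)
        best = max(best, float(matches.max()))
    return best / window


def _mkcall(pos_a, pos_b, chrom_a="chrA", chrom_b="chrB", **kw):
    kw.setdefault("spanning_reads", 10)
    kw.setdefault("total_reads", 40)
    return TranslocationCall(
        sample="S1", chrom_a=chrom_a, pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b, **kw
    )


class TestVAF:
    @pytest.mark.parametrize(
        "spanning,total,expected", [(10, 40, 0.25), (0, 30, 0.0), (40, 40, 1.0)]
    )
    def test_ratio(self, spanning, total, expected):
        assert qc.compute_vaf(spanning, total) == expected

    def test_zero_total_is_undefined(self):
        with pytest.raises(qc.UndefinedVAFError):
            qc.compute_vaf(0, 0)

    def test_spanning_above_total_rejected(self):
        with pytest.raises(ValidationError):
            qc.compute_vaf(41, 40)

    def test_clonal_binomial_cohort_median_near_half(self, rng):
        """Clonal heterozygous events at purity 1, depth 40: read sampling is
        binomial, so the cohort median VAF stays near 0.5."""
        totals = rng.poisson(40, size=300).clip(min=1)
        spanning = rng.binomial(totals, 0.5)
        vafs = [qc.compute_vaf(s, t) for s, t in zip(spanning, totals)]
        assert 0.45 <= float(np.median(vafs)) <= 0.55


class TestHomology:
    def _genome_with_copy(self, rng, identity_matches=100):
        a, b = plant_identity_pair(rng, identity_matches, flank_bp=1000)
        pad_a = "".join(rng.choice(list("ACGT"), size=2000))
        pad_b = "".join(rng.choice(list("ACGT"), size=2000))
        # breakpoints sit immediately after each planted flank
        return GenomeAssembly({"chrA": a + pad_a, "chrB": b + pad_b}), 1000, 1000

    def test_exact_copy_flagged(self, rng):
        genome, pa, pb = self._genome_with_copy(rng, 100)
        assert qc.homology_flag(_mkcall(pa, pb), genome) is True

    def test_random_flanks_not_flagged_and_match_oracle(self, rng):
        for fx in generate_homology_fixtures(seed=5, planted=(), n_random=8):
            impl = qc.max_window_identity(fx["seq_a"], fx["seq_b"])
            assert impl == window_identity_oracle(fx["seq_a"], fx["seq_b"])
            assert impl < 0.80

    @pytest.mark.parametrize("matches,expected_flag", [(79, False), (80, True)])
    def test_identity_boundary(self, rng, matches, expected_flag):
        """80/100 matches in the best window crosses the threshold; 79 does not."""
        genome, pa, pb = self._genome_with_copy(rng, matches)
        assert qc.homology_flag(_mkcall(pa, pb), genome) is expected_flag

    def test_planted_identity_exact_against_oracle(self, rng):
        for matches in (70, 79, 80, 92):
            a, b = plant_identity_pair(rng, matches)
            impl = qc.max_window_identity(a, b)
            assert impl == pytest.approx(matches / 100)
            assert impl == window_identity_oracle(a, b)

    def test_symmetric_in_sides(self, rng):
        genome, pa, pb = self._genome_with_copy(rng, 85)
        fwd = _mkcall(pa, pb)
        rev = _mkcall(pb, pa, chrom_a="chrB", chrom_b="chrA")
        assert qc.homology_flag(fwd, genome) == qc.homology_flag(rev, genome)

    def test_invariant_under_reverse_complement_of_one_side(self, rng):
        genome, pa, pb = self._genome_with_copy(rng, 85)
        flipped = GenomeAssembly(
            {
                "chrA": genome.sequences["chrA"],
                "chrB": qc.reverse_complement(genome.sequences["chrB"]),
            }
        )
        pb_flipped = flipped.lengths["chrB"] - pb
        assert qc.homology_flag(_mkcall(pa, pb), genome) == qc.homology_flag(
            _mkcall(pa, pb_flipped), flipped
        )

    def test_short_flank_unevaluable(self):
        genome = GenomeAssembly({"chrA": "ACGT" * 500, "chrB": "ACGT" * 10})
        with pytest.raises(ValidationError):
            qc.homology_flag(_mkcall(1000, 20), genome)


class TestMappability:
    def _track(self, value, L=10_000):
        return MappabilityTrack(
            {c: (np.array([0]), np.array([L]), np.array([float(value)]))
             for c in ("chrA", "chrB")}
        )

    def test_fully_mappable_not_flagged(self):
        assert qc.mappability_flag(_mkcall(5000, 5000), self._track(1.0)) is False

    def test_unmappable_flagged(self):
        assert qc.mappability_flag(_mkcall(5000, 5000), self._track(0.0)) is True

    def test_mean_exactly_threshold_not_flagged(self):
        """The filter is strictly 'less than 20%'."""
        assert qc.mappability_flag(_mkcall(5000, 5000), self._track(0.2)) is False

    def test_per_end_evaluation(self):
        track = MappabilityTrack(
            {
                "chrA": (np.array([0]), np.array([10_000]), np.array([1.0])),
                "chrB": (np.array([0]), np.array([10_000]), np.array([0.05])),
            }
        )
        assert qc.mappability_flag(_mkcall(5000, 5000), track) is True


class TestApplyQC:
    def test_no_filters_triggered_keeps_everything(self):
        calls = [_mkcall(5000, 6000)]
        res = qc.apply_qc(calls)  # no genome/track/blacklist supplied
        assert res.kept == calls and res.removed == []

    def test_blacklisted_breakpoint_removed_with_reason(self):
        ann = AnnotationSet().add_category(
            "blacklist", [Interval("chrA", 4000, 6000, "bl")]
        )
        res = qc.apply_qc([_mkcall(5000, 6000), _mkcall(9000, 6000)], blacklist=ann)
        assert len(res.kept) == 1 and len(res.removed) == 1
        assert res.removed[0].filter_flags == {"blacklist"}
        assert list(res.reasons["reasons"]) == ["blacklist"]

    def test_planted_artifacts_exactly_removed(self, small_cohort_qc):
        cohort, result = small_cohort_qc
        planted = {
            a["call_name"] for s in cohort.truth["samples"] for a in s["artifacts"]
        }
        assert {c.name for c in result.removed} == planted

    def test_partition_and_idempotence(self, small_cohort_qc):
        cohort, result = small_cohort_qc
        assert len(result.kept) + len(result.removed) == len(cohort.calls)
        again = qc.apply_qc(
            result.kept, cohort.genome, cohort.mappability, cohort.annotations
        )
        assert {c.name for c in again.kept} == {c.name for c in result.kept}


class TestClassifyBreakpoint:
    @pytest.fixture()
    def annotation(self):
        ann = AnnotationSet()
        ann.add_category("csr", [Interval("chr1", 50_000, 52_000, "S_M")])
        ann.add_category("vd", [Interval("chr1", 10_000, 40_000, "VD")])
        return ann

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (50_000 - 2_499, "CSR"),   # just inside the upstream window
            (50_000 - 2_500, "CSR"),   # window edge
            (52_000 + 2_499, "CSR"),
            (20_000, "VD"),
            (52_000 + 2_501, "extragenic"),
            (5_000, "extragenic"),
        ],
    )
    def test_classes(self, annotation, pos, expected):
        assert qc.classify_breakpoint("chr1", pos, annotation) == expected

    def test_csr_takes_precedence_over_vd(self):
        ann = AnnotationSet()
        ann.add_category("csr", [Interval("chr1", 41_000, 43_000, "S")])
        ann.add_category("vd", [Interval("chr1", 10_000, 40_000, "VD")])
        # position inside VD but within 2.5 kb of the switch region
        assert qc.classify_breakpoint("chr1", 39_000, ann) == "CSR"

    def test_every_position_classified(self, annotation, rng):
        for pos in rng.integers(0, 100_000, size=200):
            assert qc.classify_breakpoint("chr1", int(pos), annotation) in {
                "CSR", "VD", "extragenic",
            }


def fisher_p_oracle(table) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    from scipy.stats import hypergeom

    a, b, c, d = np.asarray(table).ravel()
    n, K, N = a + b + c + d, a + b, a + c
    amin, amax = max(0, K + N - n), min(K, N)
    probs = hypergeom.pmf(np.arange(amin, amax + 1), n, K, N)
    p_obs = hypergeom.pmf(a, n, K, N)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestOddsRatio:
    def test_symmetric_table(self):
        odds, p = qc.breakpoint_bias_odds_ratio([[10, 10], [10, 10]])
        assert odds == 1.0 and p == 1.0

    def test_against_enumeration_oracle(self):
        odds, p = qc.breakpoint_bias_odds_ratio([[8, 2], [2, 8]])
        assert odds == pytest.approx(16.0)
        assert p == pytest.approx(fisher_p_oracle([[8, 2], [2, 8]]), rel=1e-9)

    def test_zero_cell_corrected_finite(self):
        odds, p = qc.breakpoint_bias_odds_ratio([[5, 0], [3, 7]])
        assert np.isfinite(odds) and odds > 1

    def test_rejects_negative_counts(self):
        with pytest.raises(ValidationError):
            qc.breakpoint_bias_odds_ratio([[1, -1], [2, 2]])
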