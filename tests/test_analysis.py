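"""Pileup analytics: frequencies, spectrum, MAF, contexts, windows, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circmut import analysis
from circmut.analysis import (
    BASES,
    MixtureSpec,
    Pileup,
    build_pileup,
    classify_pyrimidine_context,
    ct_frequency_by_context,
    fold_change,
    maf_distribution,
    mixture_expected_af,
    overall_mutation_frequency,
    site_maf,
    spectrum_by_type,
    subsample_curve,
    t_test_two_sample,
    tsma_per_base,
    tsma_region,
    window_frequencies,
)
from circmut.seqio import ReferenceSeq

from conftest import make_hit, random_seq


def pileup_from_counts(ref: ReferenceSeq, counts: np.ndarray) -> Pileup:
    p = Pileup(ref)
    p.counts = np.asarray(counts, dtype=np.int64)
    return p


def random_pileup(rng, length=80) -> tuple[ReferenceSeq, Pileup]:
    ref = ReferenceSeq("r", random_seq(rng, length))
    counts = rng.integers(0, 30, size=(length, 4))
    return ref, pileup_from_counts(ref, counts)


class TestBuildPileup:
    def test_single_clean_read(self, small_ref):
        hit = make_hit(small_ref, 20, small_ref.bases[20:80])
        p = build_pileup([hit], small_ref)
        assert (p.coverage[20:80] == 1).all()
        assert p.coverage.sum() == 60
        assert p.total_mismatches() == 0

    def test_quality_zero_site_contributes_nothing(self, small_ref):
        quals = np.full(60, 60)
        quals[10] = 0
        hit = make_hit(small_ref, 20, small_ref.bases[20:80], quals=quals)
        p = build_pileup([hit], small_ref)
        assert p.coverage[30] == 0 and p.coverage.sum() == 59

    def test_junction_masked_positions_skipped(self, small_ref):
        hit = make_hit(small_ref, 0, small_ref.bases[0:60], masked={0, 59})
        p = build_pileup([hit], small_ref)
        assert p.coverage[0] == 0 and p.coverage[59] == 0

    def test_tiling_coverage_matches_brute_force(self, small_ref, rng):
        starts = rng.integers(0, 300, size=10)
        hits = [
            make_hit(small_ref, int(s), (small_ref.bases * 2)[s : s + 60])
            for s in starts
        ]
        p = build_pileup(hits, small_ref)
        expected = np.zeros(300, dtype=int)
        for s in starts:
            for i in range(60):
                expected[(s + i) % 300] += 1
        assert (p.coverage == expected).all()

    def test_out_of_range_hit_rejected(self, small_ref):
        hit = make_hit(small_ref, 10, small_ref.bases[10:40])
        hit.ref_pos = 400
        with pytest.raises(ValueError):
            build_pileup([hit], small_ref)


class TestOverallFrequency:
    def test_one_in_ten_thousand(self):
        ref = ReferenceSeq("r", "A" * 100)
        counts = np.zeros((100, 4), dtype=int)
        counts[:, 0] = 100  # A coverage
        counts[0, 0] -= 1
        counts[0, 3] += 1  # one A->T
        p = pileup_from_counts(ref, counts)
        assert overall_mutation_frequency(p) == pytest.approx(1e-4)

    def test_zero_mismatches(self, small_ref):
        hit = make_hit(small_ref, 0, small_ref.bases[0:60])
        assert overall_mutation_frequency(build_pileup([hit], small_ref)) == 0.0

    def test_exclusions_match_brute_recount(self, rng):
        ref, p = random_pileup(rng)
        excl = {("C", "G"), ("G", "C")}
        got = overall_mutation_frequency(p, exclude_types=excl)
        # oracle: enumerate every (position, allele) cell
        numer = 0
        denom = 0
        for i, rb in enumerate(ref.bases):
            for j, ab in enumerate(BASES):
                denom += p.counts[i, j]
                if ab != rb and (rb, ab) not in excl:
                    numer += p.counts[i, j]
        assert got == pytest.approx(numer / denom)

    def test_zero_coverage_rejected(self):
        ref = ReferenceSeq("r", "ACGT")
        with pytest.raises(ValueError):
            overall_mutation_frequency(pileup_from_counts(ref, np.zeros((4, 4))))


class TestSpectrum:
    def test_single_event(self):
        ref = ReferenceSeq("r", "A" * 50 + "C" * 50)
        counts = np.zeros((100, 4), dtype=int)
        counts[:50, 0] = 20  # 1000 covered A's
        counts[0, 0] -= 1
        counts[0, 3] += 1
        df = spectrum_by_type(pileup_from_counts(ref, counts))
        at = df[(df["from"] == "A") & (df["to"] == "T")].iloc[0]
        assert at["frequency"] == pytest.approx(1e-3)
        assert at["denominator"] == 1000
        # C types undefined (zero coverage), remaining A types zero
        cg = df[(df["from"] == "C") & (df["to"] == "G")].iloc[0]
        assert np.isnan(cg["frequency"])
        ag = df[(df["from"] == "A") & (df["to"] == "G")].iloc[0]
        assert ag["frequency"] == 0.0

    def test_matches_exhaustive_tally(self, rng):
        ref, p = random_pileup(rng)
        df = spectrum_by_type(p).set_index(["from", "to"])
        tally: dict = {}
        denom: dict = {}
        for i, rb in enumerate(ref.bases):
            denom[rb] = denom.get(rb, 0) + int(p.counts[i].sum())
            for j, ab in enumerate(BASES):
                if ab != rb:
                    tally[(rb, ab)] = tally.get((rb, ab), 0) + int(p.counts[i, j])
        for (frm, to), count in tally.items():
            row = df.loc[(frm, to)]
            assert row["count"] == count
            assert row["denominator"] == denom[frm]
        assert df["count"].sum() == p.total_mismatches()


class TestMafDistribution:
    def test_single_site_binning(self):
        ref = ReferenceSeq("r", "A" * 10)
        counts = np.zeros((10, 4), dtype=int)
        counts[:, 0] = 40_000
        counts[3, 2] = 2  # MAF 5e-05
        p = pileup_from_counts(ref, counts)
        maf = site_maf(p)
        assert len(maf) == 1
        assert maf.iloc[0]["maf"] == pytest.approx(2 / 40_002)
        assert 1e-5 <= maf.iloc[0]["maf"] < 1e-4

    def test_no_variant_sites(self, small_ref):
        hits = [make_hit(small_ref, 0, small_ref.bases[0:60])]
        df = maf_distribution(hits, small_ref, n_reads_sample=1)
        assert (df["proportion"] == 0).all()
        assert df.attrs["n_variant_sites"] == 0

    def test_proportions_match_per_site_recount(self, small_ref, rng):
        hits = []
        for s in rng.integers(0, 300, size=30):
            bases = list((small_ref.bases * 2)[s : s + 50])
            if rng.random() < 0.5:  # inject a variant
                i = int(rng.integers(0, 50))
                bases[i] = "ACGT"[(BASES.index(bases[i]) + 1) % 4]
            hits.append(make_hit(small_ref, int(s), "".join(bases)))
        df = maf_distribution(hits, small_ref, n_reads_sample=len(hits), bins=[0, 1e-2, 0.5, 1])
        maf = site_maf(build_pileup(hits, small_ref))["maf"].to_numpy()
        for _, row in df.iterrows():
            expected = ((maf >= row["maf_lo"]) & (maf < row["maf_hi"])).sum()
            assert row["n_sites"] == expected
        if len(maf):
            assert df["proportion"].sum() == pytest.approx(1.0)

    def test_subsampling_is_seeded(self, small_ref, rng):
        hits = [
            make_hit(small_ref, int(s), (small_ref.bases * 2)[s : s + 50])
            for s in rng.integers(0, 300, size=20)
        ]
        a = maf_distribution(hits, small_ref, n_reads_sample=10, seed=4)
        b = maf_distribution(hits, small_ref, n_reads_sample=10, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_oversampling_warns(self, small_ref):
        hits = [make_hit(small_ref, 0, small_ref.bases[0:60])]
        with pytest.warns(UserWarning, match="using all"):
            maf_distribution(hits, small_ref, n_reads_sample=10)


class TestPyrimidineContext:
    def _ref(self, s):
        return ReferenceSeq("r", s)

    def test_mono_di_poly(self):
        ref = self._ref("AACAAACTAATCCAAA")
        assert classify_pyrimidine_context(ref, 2) == "mono"  # A A C A A
        assert classify_pyrimidine_context(ref, 6) == "di"  # A C T A
        assert classify_pyrimidine_context(ref, 12) == "poly"  # T C C
        assert classify_pyrimidine_context(ref, 11, "+") == "poly"  # same T-C-C run
        # position 11 is T: asking for a C there is an error
        with pytest.raises(ValueError):
            classify_pyrimidine_context(ref, 0)

    def test_minus_strand_g_as_c(self):
        # '-' strand pyrimidine run = G/A run on '+': G at 1 flanked by A's -> GAA... run
        ref = self._ref("TGACTTTTTTTTTTTT")
        assert classify_pyrimidine_context(ref, 1, "-") == "di"  # run G,A on '+'
        with pytest.raises(ValueError):
            classify_pyrimidine_context(ref, 0, "-")

    def test_circular_run_wraps_origin(self):
        ref = self._ref("CAAAAAAAAAAAAAT")  # run T..C wraps around the origin
        assert classify_pyrimidine_context(ref, 0) == "di"


def test_classify_errors_on_non_c():
    ref = ReferenceSeq("r", "AAAA")
    with pytest.raises(ValueError):
        classify_pyrimidine_context(ref, 1, "+")


class TestCtByContext:
    def test_counts_both_strands(self):
        #        0123456789
        ref = ReferenceSeq("r", "ACAAAGAAAA")
        counts = np.zeros((10, 4), dtype=int)
        counts[[0, 2, 3, 4, 7, 8, 9], 0] = 10
        counts[1, 1] = 8
        counts[1, 3] = 2  # C->T events on '+', mono context
        counts[5, 2] = 6
        counts[5, 0] = 1  # G->A event = C->T on '-' (G flanked by A's: poly run)
        df = ct_frequency_by_context(pileup_from_counts(ref, counts), ref).set_index(
            "context"
        )
        assert df.loc["mono", "events"] == 2
        assert df.loc["mono", "frequency"] == pytest.approx(2 / 10)
        assert df.loc["poly", "events"] == 1
        assert df.loc["poly", "frequency"] == pytest.approx(1 / 7)
        assert np.isnan(df.loc["di", "frequency"])

    def test_symmetric_classes_equal_frequencies(self):
        ref = ReferenceSeq("r", "ACAAACTAAA")  # one mono C, one di C
        counts = np.zeros((10, 4), dtype=int)
        counts[[1, 5], 1] = 9
        counts[[1, 5], 3] = 1
        df = ct_frequency_by_context(pileup_from_counts(ref, counts), ref).set_index(
            "context"
        )
        assert df.loc["mono", "frequency"] == df.loc["di", "frequency"]


class TestWindows:
    def test_5kb_gives_50_windows(self, rng):
        ref = ReferenceSeq("r", random_seq(rng, 5000))
        counts = np.zeros((5000, 4), dtype=int)
        counts[:, 0] = 1
        df = window_frequencies(pileup_from_counts(ref, counts), 100)
        assert len(df) == 50
        assert not df["short"].any()

    def test_conservation_and_short_flag(self, rng):
        ref, p = random_pileup(rng, length=250)
        df = window_frequencies(p, 100)
        assert len(df) == 3
        assert df.iloc[-1]["short"]
        assert df["mismatches"].sum() == p.total_mismatches()
        assert df["coverage"].sum() == p.coverage.sum()

    def test_hot_window_flagged_as_maximum(self):
        ref = ReferenceSeq("r", "A" * 300)
        counts = np.zeros((300, 4), dtype=int)
        counts[:, 0] = 1000
        counts[150, 2] = 100  # 10x hot window
        counts[10, 2] = 10
        df = window_frequencies(pileup_from_counts(ref, counts), 100)
        assert df["frequency"].idxmax() == 1

    def test_invalid_window(self, rng):
        _, p = random_pileup(rng)
        with pytest.raises(ValueError):
            window_frequencies(p, 0)


class _FakeRead:
    """Stand-in read carrying a value; only its length matters to the sampler."""

    def __init__(self, value: float, length: int = 50):
        self.value = value
        self._length = length

    def __len__(self) -> int:
        return self._length


class TestSubsampleCurve:
    @staticmethod
    def _freq(pairs):
        return float(np.mean([r1.value for r1, _ in pairs]))

    @staticmethod
    def _pairs(rng, n):
        return [(_FakeRead(float(rng.random())), _FakeRead(0.0)) for _ in range(n)]

    def test_deterministic_under_seed(self, rng):
        pairs = self._pairs(rng, 40)
        a = subsample_curve(pairs, [500, 1000], self._freq, seed=3)
        b = subsample_curve(pairs, [500, 1000], self._freq, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_full_size_mean_equals_full_frequency(self, rng):
        pairs = self._pairs(rng, 40)
        total = sum(len(a) + len(b) for a, b in pairs)
        df = subsample_curve(pairs, [total], self._freq, seed=3)
        assert df.iloc[0]["mean"] == pytest.approx(self._freq(pairs))
        assert df.iloc[0]["sd"] == 0.0

    def test_sd_shrinks_with_size(self, rng):
        pairs = self._pairs(rng, 400)
        df = subsample_curve(pairs, [1000, 15000], self._freq, replicates=8, seed=5)
        assert df.iloc[1]["sd"] < df.iloc[0]["sd"]


class TestFoldChangeAndTTest:
    def test_fold_change(self):
        assert fold_change(2e-4, 1e-4) == pytest.approx(2.0)
        assert fold_change(1e-4, 1e-4) == 1.0
        assert fold_change(0, 1e-4) == 0.0
        with pytest.raises(ValueError):
            fold_change(1e-4, 0)

    def test_identical_groups(self):
        t, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        # pooled s^2 = 1, se = sqrt(2/3), t = -10 / 0.816497 = -12.2474
        t, p = t_test_two_sample([1, 2, 3], [11, 12, 13])
        assert t == pytest.approx(-12.24745, abs=1e-4)
        assert p < 0.05

    def test_separated_groups_significant(self):
        _, p = t_test_two_sample([1.0, 1.1, 0.9], [5.0, 5.1, 4.9])
        assert p < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [1.0, 2.0])


class TestTsmaModel:
    def test_zero_maps_to_zero(self):
        assert tsma_per_base(0.0, 95) == 0.0
        assert tsma_region(0.0, 95) == 0.0

    def test_small_alpha_linear_limit(self):
        alpha = 1e-7
        assert tsma_region(alpha, 95) == pytest.approx(alpha * 95, rel=1e-4)

    def test_forward_evaluation(self):
        assert tsma_region(1.64422e-4, 95) == pytest.approx(1.55e-2, rel=1e-4)

    @given(st.floats(min_value=0.0, max_value=0.5))
    def test_round_trip(self, e_l):
        assert tsma_region(tsma_per_base(e_l, 95), 95) == pytest.approx(
            e_l, abs=1e-12, rel=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tsma_per_base(1.0, 95)
        with pytest.raises(ValueError):
            tsma_region(-0.1, 95)


class TestMixture:
    def test_identical_strains_unchanged(self):
        af = {100: {"A": 0.3, "G": 0.7}}
        spec = MixtureSpec(af, af, (1, 1))
        assert mixture_expected_af(spec, 100) == pytest.approx({"A": 0.3, "G": 0.7})

    def test_weighted_average(self):
        spec = MixtureSpec(
            {5: {"A": 1.0, "G": 0.0}}, {5: {"A": 0.0, "G": 1.0}}, (3, 1)
        )
        out = mixture_expected_af(spec, 5)
        assert out["A"] == pytest.approx(0.75) and out["G"] == pytest.approx(0.25)

    def test_absent_site_rejected(self):
        spec = MixtureSpec({1: {"A": 1.0}}, {1: {"A": 1.0}}, (1, 1))
        with pytest.raises(ValueError):
            mixture_expected_af(spec, 2)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec({1: {"A": 0.5, "G": 0.4}}, {1: {"A": 1.0}}, (1, 1))
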