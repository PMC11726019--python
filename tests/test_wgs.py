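"""WGS caller: interleaving, the three tests, criteria engine, amp flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shattercall.io import DetectorParams, SVJunction
from shattercall.wgs import (
    RegionStats,
    breakpoint_exponential_test,
    call_wgs,
    chromosomal_enrichment_test,
    cluster_regions,
    count_interleaved,
    evaluate_criteria,
    flag_amplified_segments,
    fragment_joins_test,
)

from conftest import make_segments


def J(p1, p2, s1="+", s2="-", chrom="1"):
    return SVJunction(chrom, p1, s1, chrom, p2, s2).normalized()


# ---------------------------------------------------------------------------
# interleave counting


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def oracle_interleaved(junctions):
    """O(n^2) pairwise predicate + union-find; independent of the package."""
    js = [j for j in junctions if j.chrom1 == j.chrom2]
    n = len(js)
    uf = UnionFind(n)
    linked = [False] * n
    for i in range(n):
        for k in range(i + 1, n):
            a, b = js[i], js[k]
            if (a.pos1 < b.pos1 < a.pos2 < b.pos2) or (
                b.pos1 < a.pos1 < b.pos2 < a.pos2
            ):
                uf.union(i, k)
                linked[i] = linked[k] = True
    sizes = {}
    for i in range(n):
        if linked[i]:
            sizes[uf.find(i)] = sizes.get(uf.find(i), 0) + 1
    return max(sizes.values(), default=0)


class TestInterleaved:
    def test_two_overlapping_junctions(self):
        assert count_interleaved([J(10, 50), J(30, 80)]) == 2

    def test_nested_junctions_do_not_interleave(self):
        assert count_interleaved([J(10, 100), J(30, 60)]) == 0

    def test_chain_forms_one_component(self):
        assert count_interleaved([J(10, 40), J(30, 70), J(60, 90)]) == 3

    def test_interchromosomal_ignored(self):
        j = SVJunction("1", 10, "+", "2", 50, "-")
        assert count_interleaved([j, J(10, 50), J(30, 80)]) == 2

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=200),
                st.integers(min_value=1, max_value=200),
            ).filter(lambda t: t[0] != t[1]),
            min_size=0,
            max_size=50,
        )
    )
    def test_matches_union_find_oracle(self, pairs):
        js = [J(min(a, b), max(a, b)) for a, b in pairs]
        assert count_interleaved(js) == oracle_interleaved(js)


# ---------------------------------------------------------------------------
# fragment joins test


def _junctions_with_counts(counts):
    strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
    out = []
    pos = 100
    for (s1, s2), k in zip(strands, counts):
        for _ in range(k):
            out.append(SVJunction("1", pos, s1, "1", pos + 50, s2))
            pos += 200
    return out


def oracle_exact_multinomial(counts):
    """Full enumeration of all outcomes of n draws into 4 equiprobable cells."""
    n = sum(counts)
    def prob(cs):
        coef = math.factorial(n)
        for c in cs:
            coef //= math.factorial(c)
        return coef * 0.25**n

    p_obs = prob(counts)
    total = 0.0
    for c1 in range(n + 1):
        for c2 in range(n - c1 + 1):
            for c3 in range(n - c1 - c2 + 1):
                cs = (c1, c2, c3, n - c1 - c2 - c3)
                if prob(cs) <= p_obs + 1e-12:
                    total += prob(cs)
    return total


class TestFragmentJoins:
    def test_perfect_uniformity(self):
        assert fragment_joins_test(_junctions_with_counts([10, 10, 10, 10])) == 1.0

    def test_all_one_class_rejected(self):
        # chi-square statistic 3*n*... = (40-10)^2/10 * ... = 90+3*10 = 120 on 3 df
        p = fragment_joins_test(_junctions_with_counts([40, 0, 0, 0]))
        assert p < 1e-15

    @pytest.mark.parametrize("counts", [(2, 1, 1, 0), (4, 0, 0, 0), (3, 3, 2, 1)])
    def test_exact_path_matches_enumeration_oracle(self, counts):
        p = fragment_joins_test(_junctions_with_counts(list(counts)))
        assert p == pytest.approx(oracle_exact_multinomial(list(counts)), abs=1e-9)

    def test_zero_junctions_rejected(self):
        with pytest.raises(ValueError):
            fragment_joins_test([])

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 under uniform orientations, n=40."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            counts = rng.multinomial(40, [0.25] * 4)
            p = fragment_joins_test(_junctions_with_counts(list(counts)))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------------------
# breakpoint exponential test


class TestBreakpointExponential:
    def test_uniform_quantiles_near_one(self):
        region = (1, 1_000_000)
        pos = [int(1 + (k + 0.5) / 20 * 999_999) for k in range(20)]
        assert breakpoint_exponential_test(pos, region) > 0.5

    def test_extreme_clustering_rejected(self):
        region = (1, 1_000_000)
        pos = list(range(2000, 10_001, 2000))  # all in the first 1%
        assert breakpoint_exponential_test(pos, region) < 1e-6

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError, match=">= 5 distinct"):
            breakpoint_exponential_test([1, 2, 3, 4], (1, 100))

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        region = (1, 10_000_000)
        rejections = 0
        reps = 400
        for _ in range(reps):
            pos = rng.integers(region[0], region[1], size=30)
            rejections += breakpoint_exponential_test(list(pos), region) < 0.05
        assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------------------
# chromosomal enrichment test


def oracle_binom_tail(k, n, p):
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestEnrichment:
    def test_strong_enrichment(self):
        assert chromosomal_enrichment_test(50, 8, 60, 100) < 1e-10

    def test_proportional_is_not_enriched(self):
        p = chromosomal_enrichment_test(5, 8, 60, 100)
        assert p == pytest.approx(oracle_binom_tail(5, 60, 0.08), rel=1e-9)
        assert p > 0.3

    def test_all_breakends_on_tiny_chromosome(self):
        p = chromosomal_enrichment_test(60, 1, 60, 100)
        assert p == pytest.approx(0.01**60, rel=1e-6)

    def test_zero_genome_breakends_rejected(self):
        with pytest.raises(ValueError):
            chromosomal_enrichment_test(0, 8, 0, 100)


# ---------------------------------------------------------------------------
# criteria engine


def oracle_criteria(rs, p):
    """Independent truth table transcribed from the combined criteria."""
    joins = not math.isnan(rs.p_joins) and rs.p_joins >= p.alpha_joins
    expo = not math.isnan(rs.p_exp) and rs.p_exp >= p.alpha_exp
    enr = not math.isnan(rs.p_enrich) and rs.p_enrich <= p.alpha_enrich
    dist = enr or expo
    crits = set()
    if rs.n_intra_interleaved >= 6 and rs.max_osc2 >= 7 and joins and dist:
        crits.add("i")
    if rs.n_intra_interleaved >= 3 and rs.n_inter >= 4 and rs.max_osc2 >= 7 and joins:
        crits.add("ii")
    if rs.n_intra_interleaved >= 40 and joins:
        crits.add("iii")
    if rs.n_sv_total >= 100 and rs.max_osc2 >= 5:
        crits.add("iv")
    if rs.n_intra_interleaved >= 6 and 4 <= rs.max_osc2 <= 6 and joins and dist:
        crits.add("v")
    if crits & {"i", "ii", "iii", "iv"}:
        verdict = "positive"
    elif crits == {"v"}:
        verdict = "low_density"
    else:
        verdict = "negative"
    return crits, verdict


class TestEvaluateCriteria:
    P = DetectorParams()

    def _rs(self, intra=0, inter=0, total=None, osc=0, pj=1.0, pen=1.0, pex=1.0):
        return RegionStats(
            n_intra_interleaved=intra,
            n_inter=inter,
            n_sv_total=total if total is not None else intra + inter,
            max_osc2=osc,
            p_joins=pj,
            p_enrich=pen,
            p_exp=pex,
        )

    def test_canonical_positive(self):
        rs = self._rs(intra=6, osc=7, pj=0.5, pex=0.5, pen=1.0)
        call = evaluate_criteria((1, 100), rs, self.P)
        assert "i" in call.criteria_passed and call.verdict == "positive"

    def test_low_density_band(self):
        rs = self._rs(intra=6, osc=5, pj=0.5, pen=0.01, pex=0.01)
        call = evaluate_criteria((1, 100), rs, self.P)
        assert call.criteria_passed == ("v",)
        assert call.verdict == "low_density"

    def test_below_every_criterion(self):
        rs = self._rs(intra=5, inter=0, osc=7, pj=0.5, pex=0.5, pen=1.0)
        call = evaluate_criteria((1, 100), rs, self.P)
        assert call.criteria_passed == () and call.verdict == "negative"

    def test_nan_pvalue_fails_the_test(self):
        rs = self._rs(intra=6, osc=7, pj=float("nan"), pex=0.5)
        call = evaluate_criteria((1, 100), rs, self.P)
        assert call.verdict == "negative"

    def test_matches_truth_table_oracle_on_random_tuples(self):
        rng = np.random.default_rng(23)
        for _ in range(10_000):
            rs = self._rs(
                intra=int(rng.integers(0, 120)),
                inter=int(rng.integers(0, 10)),
                total=int(rng.integers(0, 200)),
                osc=int(rng.integers(0, 12)),
                pj=float(rng.choice([0.001, 0.04, 0.05, 0.3, float("nan")])),
                pen=float(rng.choice([0.001, 0.05, 0.06, 0.7, float("nan")])),
                pex=float(rng.choice([0.001, 0.04, 0.06, 0.9, float("nan")])),
            )
            call = evaluate_criteria((1, 100), rs, self.P)
            want_crits, want_verdict = oracle_criteria(rs, self.P)
            assert set(call.criteria_passed) == want_crits
            assert call.verdict == want_verdict

    def test_determinism(self):
        rs = self._rs(intra=6, osc=7, pj=0.5, pex=0.5)
        a = evaluate_criteria((1, 100), rs, self.P)
        b = evaluate_criteria((1, 100), rs, self.P)
        assert a == b


# ---------------------------------------------------------------------------
# clustering, amplification flags, driver


class TestClusterRegions:
    def test_single_cluster(self):
        js = [J(30_000_000 + i * 3_000_000, 33_000_000 + i * 3_000_000) for i in range(10)]
        regions = cluster_regions(js, "1", 200_000_000)
        assert (30_000_000, 60_000_000) in regions
        assert (1, 200_000_000) in regions

    def test_two_distant_groups(self):
        js = [J(10_000_000, 12_000_000), J(11_000_000, 13_000_000),
              J(150_000_000, 152_000_000), J(151_000_000, 153_000_000)]
        regions = cluster_regions(js, "1", 200_000_000)
        assert len(regions) == 3  # two clusters + whole chromosome

    def test_no_junctions_only_whole_chromosome(self):
        assert cluster_regions([], "1", 200_000_000) == [(1, 200_000_000)]


class TestAmplificationFlags:
    def test_boundary_is_strict(self):
        segs = make_segments([2, 11, 2, 10, 2], lengths=[10**7, 10**5, 10**7, 10**5, 10**7])
        flagged, baseline = flag_amplified_segments(segs)
        assert baseline == 2
        assert [s.total_cn for s in flagged] == [11]  # 10 is not > 5*2

    def test_constant_genome_none_flagged(self):
        flagged, baseline = flag_amplified_segments(make_segments([2, 2, 2]))
        assert flagged == [] and baseline == 2

    def test_baseline_is_length_weighted(self):
        segs = make_segments([4, 4, 2], lengths=[10**6, 10**6, 10**8])
        _, baseline = flag_amplified_segments(segs)
        assert baseline == 2


class TestCallWgs:
    def test_no_junctions_is_negative(self):
        segs = {"1": make_segments([2, 1, 2, 1, 2, 1, 2, 1])}
        calls = call_wgs(segs, [])
        assert all(c.verdict == "negative" for c in calls)

    def test_verdict_invariant_holds(self):
        rng = np.random.default_rng(3)
        js = [J(int(a), int(a) + int(b)) for a, b in
              zip(rng.integers(1, 50_000_000, 30), rng.integers(1, 20_000_000, 30))]
        segs = {"1": make_segments([2, 1] * 6)}
        for c in call_wgs(segs, js):
            crits = set(c.criteria_passed)
            if crits & {"i", "ii", "iii", "iv"}:
                assert c.verdict == "positive"
            elif crits == {"v"}:
                assert c.verdict == "low_density"
            else:
                assert c.verdict == "negative"
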