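"""WGS chromothripsis calling: SV cluster statistics plus CN oscillation.

A region is called chromothripsis when one or more of five combined
criteria hold:

  (i)   >= 6 interleaved intrachromosomal SVs, >= 7 contiguous segments
        oscillating between two CN states, the fragment joins test, and
        either the chromosomal enrichment or the breakpoint exponential
        test;
  (ii)  >= 3 interleaved intrachromosomal SVs and >= 4 interchromosomal
        SVs, >= 7 oscillating segments, and the fragment joins test;
  (iii) >= 40 interleaved intrachromosomal SVs and the fragment joins test;
  (iv)  >= 100 SVs (intra + inter) and >= 5 oscillating segments;
  (v)   >= 6 interleaved intrachromosomal SVs, 4-6 oscillating segments,
        the fragment joins test, and either the enrichment or the
        exponential test.

A region passing only criterion (v) is reported as "low density".  The
fragment joins test checks that the four junction orientation classes occur
in equal proportions (expected under random re-ligation of shattered
fragments) and passes when NOT rejected; the exponential test checks
breakpoint uniformity over the region (KS) and passes when NOT rejected;
the enrichment test (length-adjusted binomial tail) passes when rejected
toward an excess of breakends on the chromosome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io import (
    INTRA_CLASSES,
    ChromSegment,
    ChromothripsisCall,
    DetectorParams,
    SVJunction,
)
from .oscillation import find_oscillation_runs, max_oscillating_segments

__all__ = [
    "cluster_regions",
    "count_interleaved",
    "fragment_joins_test",
    "breakpoint_exponential_test",
    "chromosomal_enrichment_test",
    "evaluate_criteria",
    "flag_amplified_segments",
    "call_wgs",
]


# ---------------------------------------------------------------------------
# region finding


def cluster_regions(
    junctions: Sequence[SVJunction],
    chrom: str,
    chrom_length: int,
    gap_bp: int = 10_000_000,
) -> list[tuple[int, int]]:
    """Candidate regions on one chromosome from breakend density.

    Consecutive intrachromosomal breakends <= ``gap_bp`` apart form a
    cluster; each cluster region is extended to cover both ends of its
    member junctions.  The whole chromosome is always an additional
    candidate.
    """
    intra = [
        j.normalized()
        for j in junctions
        if j.intrachromosomal and j.chrom1 == chrom
    ]
    regions: list[tuple[int, int]] = []
    ends = sorted(
        pos for j in intra for pos in (j.pos1, j.pos2)
    )
    if ends:
        clusters: list[list[int]] = [[ends[0]]]
        for p in ends[1:]:
            if p - clusters[-1][-1] <= gap_bp:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            lo, hi = cl[0], cl[-1]
            # pull in the full span of any junction with a breakend inside
            for j in intra:
                if lo <= j.pos1 <= hi or lo <= j.pos2 <= hi:
                    lo, hi = min(lo, j.pos1), max(hi, j.pos2)
            regions.append((lo, hi))
    whole = (1, chrom_length)
    if whole not in regions:
        regions.append(whole)
    return regions


# ---------------------------------------------------------------------------
# interleaving


def _interleaves(a: SVJunction, b: SVJunction) -> bool:
    """Spans overlap without nesting: a1 < b1 < a2 < b2 (either order)."""
    return (a.pos1 < b.pos1 < a.pos2 < b.pos2) or (b.pos1 < a.pos1 < b.pos2 < a.pos2)


def count_interleaved(junctions: Sequence[SVJunction]) -> int:
    """Size of the largest connected component of the interleave graph.

    Two intrachromosomal junctions interleave when their spans overlap
    without either nesting inside the other — the topological signature of
    random fragment re-ligation.  A junction with no interleaving partner
    is not counted (an isolated vertex is not a cluster), so the result is
    0 or >= 2.
    """
    js = [j.normalized() for j in junctions if j.intrachromosomal]
    n = len(js)
    if n < 2:
        return 0
    # sweep: adjacency via the pairwise predicate, components via BFS
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, k in itertools.combinations(range(n), 2):
        if _interleaves(js[i], js[k]):
            adj[i].append(k)
            adj[k].append(i)
    seen = [False] * n
    best = 0
    for start in range(n):
        if seen[start] or not adj[start]:
            continue
        size = 0
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        best = max(best, size)
    return best


# ---------------------------------------------------------------------------
# statistical tests

_EXACT_MAX_N = 19  # below this, full multinomial enumeration


def fragment_joins_test(junctions: Sequence[SVJunction]) -> float:
    """Equal-proportion test over the four junction orientation classes.

    Under random ligation each intrachromosomal orientation class occurs
    with probability 1/4.  Chi-square with 3 df when the total count is at
    least 20; otherwise the exact multinomial goodness-of-fit p-value
    (sum of probabilities of all outcomes no more probable than observed).
    """
    counts = _orientation_counts(junctions)
    n = int(sum(counts))
    if n == 0:
        raise ValueError("fragment joins test requires at least one intrachromosomal junction")
    if n > _EXACT_MAX_N:
        return float(stats.chisquare(counts).pvalue)
    return _exact_multinomial_p(counts)


def _orientation_counts(junctions: Iterable[SVJunction]) -> list[int]:
    counts = dict.fromkeys(INTRA_CLASSES, 0)
    for j in junctions:
        if j.intrachromosomal:
            counts[j.normalized().orientation_class] += 1
    return [counts[c] for c in INTRA_CLASSES]


def _exact_multinomial_p(counts: Sequence[int]) -> float:
    n = sum(counts)
    p_obs = math.exp(stats.multinomial.logpmf(list(counts), n, [0.25] * 4))
    total = 0.0
    for c1 in range(n + 1):
        for c2 in range(n - c1 + 1):
            for c3 in range(n - c1 - c2 + 1):
                c4 = n - c1 - c2 - c3
                p = math.exp(stats.multinomial.logpmf([c1, c2, c3, c4], n, [0.25] * 4))
                if p <= p_obs * (1 + 1e-12):
                    total += p
    return min(1.0, total)


def breakpoint_exponential_test(
    positions: Sequence[int], region: tuple[int, int], collapse_bp: int = 1000
) -> float:
    """One-sample KS p-value for uniformity of breakpoints over the region.

    Uniform positions have exponential spacings; clustering far beyond the
    uniform expectation rejects.  The test examines breakpoint *loci*:
    breakends within ``collapse_bp`` of each other (the two ligated sides
    of one cut, or caller jitter) collapse to a single position, since
    coincident duplicates would fail the KS distinct-points assumption and
    mimic clustering.  Requires >= 5 loci after collapsing.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("region length must be positive")
    pos = sorted(set(positions))
    loci: list[int] = []
    for p in pos:
        if not loci or p - loci[-1] > collapse_bp:
            loci.append(p)
    if len(loci) < 5:
        raise ValueError("breakpoint exponential test requires >= 5 distinct positions")
    scaled = [(p - lo) / (hi - lo) for p in loci]
    return float(stats.kstest(scaled, "uniform").pvalue)


def chromosomal_enrichment_test(
    n_chrom: int, chrom_length: int, n_genome: int, genome_length: int
) -> float:
    """One-sided binomial tail P[X >= n_chrom], X ~ Bin(n_genome, len frac).

    Small p-values mean the chromosome carries more breakends than its
    share of the genome would predict.
    """
    if n_genome <= 0:
        raise ValueError("enrichment test requires at least one genome-wide breakend")
    if n_chrom > n_genome:
        raise ValueError("chromosome breakend count exceeds genome-wide count")
    frac = chrom_length / genome_length
    return float(stats.binom.sf(n_chrom - 1, n_genome, frac))


# ---------------------------------------------------------------------------
# criteria engine


@dataclass(frozen=True)
class RegionStats:
    """Inputs to the criteria engine for one candidate region."""

    n_intra_interleaved: int
    n_inter: int
    n_sv_total: int
    max_osc2: int
    p_joins: float  # nan when not computable
    p_enrich: float
    p_exp: float


def evaluate_criteria(
    region: tuple[int, int],
    rs: RegionStats,
    params: DetectorParams | None = None,
    sample: str = "",
    chrom: str = "",
    ccf_assumed: bool = False,
) -> ChromothripsisCall:
    """Evaluate the five combined criteria and map them to a verdict.

    ``positive`` when any of criteria i-iv holds; ``low_density`` when only
    criterion v holds; ``negative`` otherwise.  A test whose p-value is NaN
    (precondition unmet, e.g. no junctions) fails in the pass direction.
    """
    p = params or DetectorParams()
    joins_pass = not math.isnan(rs.p_joins) and rs.p_joins >= p.alpha_joins
    exp_pass = not math.isnan(rs.p_exp) and rs.p_exp >= p.alpha_exp
    enrich_pass = not math.isnan(rs.p_enrich) and rs.p_enrich <= p.alpha_enrich
    dist_pass = enrich_pass or exp_pass

    passed: list[str] = []
    if (
        rs.n_intra_interleaved >= p.min_intra_i
        and rs.max_osc2 >= p.min_osc_i
        and joins_pass
        and dist_pass
    ):
        passed.append("i")
    if (
        rs.n_intra_interleaved >= p.min_intra_ii
        and rs.n_inter >= p.min_inter_ii
        and rs.max_osc2 >= p.min_osc_i
        and joins_pass
    ):
        passed.append("ii")
    if rs.n_intra_interleaved >= p.min_intra_iii and joins_pass:
        passed.append("iii")
    if rs.n_sv_total >= p.min_total_iv and rs.max_osc2 >= p.min_osc_iv:
        passed.append("iv")
    if (
        rs.n_intra_interleaved >= p.min_intra_i
        and p.osc_low_min <= rs.max_osc2 <= p.osc_low_max
        and joins_pass
        and dist_pass
    ):
        passed.append("v")

    if any(c in passed for c in ("i", "ii", "iii", "iv")):
        verdict = "positive"
    elif passed == ["v"]:
        verdict = "low_density"
    else:
        verdict = "negative"
    return ChromothripsisCall(
        sample=sample,
        chrom=chrom,
        start=region[0],
        end=region[1],
        n_intra_interleaved=rs.n_intra_interleaved,
        n_inter=rs.n_inter,
        n_sv_total=rs.n_sv_total,
        max_osc2=rs.max_osc2,
        p_joins=rs.p_joins,
        p_enrich=rs.p_enrich,
        p_exp=rs.p_exp,
        criteria_passed=tuple(passed),
        verdict=verdict,
        ccf_assumed=ccf_assumed,
    )


# ---------------------------------------------------------------------------
# amplification flags


def flag_amplified_segments(
    segments: Sequence[ChromSegment], params: DetectorParams | None = None
) -> tuple[list[ChromSegment], int]:
    """Segments whose CN exceeds ``amp_baseline_factor`` x chromosome baseline.

    The baseline is the length-weighted mode of the integer total CN over
    the chromosome; the comparison is strict (> factor x baseline).
    Returns ``(flagged_segments, baseline)``.
    """
    p = params or DetectorParams()
    if not segments:
        return [], 0
    weights: dict[int, int] = {}
    for s in segments:
        weights[s.total_cn] = weights.get(s.total_cn, 0) + s.length
    baseline = max(sorted(weights), key=lambda cn: weights[cn])
    flagged = [s for s in segments if s.total_cn > p.amp_baseline_factor * baseline]
    return flagged, baseline


# ---------------------------------------------------------------------------
# driver


def call_wgs(
    segments_by_chrom: Mapping[str, Sequence[ChromSegment]],
    junctions: Sequence[SVJunction],
    params: DetectorParams | None = None,
    sample: str = "",
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ChromothripsisCall]:
    """Chromosome-level chromothripsis calls from segments plus junctions.

    Each chromosome's candidate regions (breakend clusters plus the whole
    chromosome) are scored independently; the chromosome reports its most
    confident region (positive > low_density > negative, then SV count).
    Chromosome/genome lengths default to the observed extent of the input.
    """
    p = params or DetectorParams()
    junctions = [j.normalized() for j in junctions]
    lengths = dict(chrom_lengths or {})
    chroms = set(segments_by_chrom) | {j.chrom1 for j in junctions} | {
        j.chrom2 for j in junctions
    }
    for c in chroms:
        observed = [s.end for s in segments_by_chrom.get(c, ())]
        observed += [j.pos1 for j in junctions if j.chrom1 == c]
        observed += [j.pos2 for j in junctions if j.chrom2 == c]
        lengths.setdefault(c, max(observed, default=1))
    genome_length = sum(lengths.values())
    genome_breakends = sum(
        (2 if j.intrachromosomal else 1) + (0 if j.intrachromosomal else 1)
        for j in junctions
    )

    calls: list[ChromothripsisCall] = []
    rank = {"positive": 0, "low_density": 1, "negative": 2}
    for chrom in sorted(chroms):
        segs = list(segments_by_chrom.get(chrom, ()))
        amp_flagged, _ = flag_amplified_segments(segs, p)
        amp_set = set(id(s) for s in amp_flagged)
        osc_segs = [s for s in segs if id(s) not in amp_set]
        chrom_breakends = sum(
            (1 if j.chrom1 == chrom else 0) + (1 if j.chrom2 == chrom else 0)
            for j in junctions
        )
        best: ChromothripsisCall | None = None
        for region in cluster_regions(junctions, chrom, lengths[chrom], p.cluster_gap_bp):
            lo, hi = region
            intra_in = [
                j
                for j in junctions
                if j.intrachromosomal
                and j.chrom1 == chrom
                and lo <= j.pos1
                and j.pos2 <= hi
            ]
            inter_in = [
                j
                for j in junctions
                if not j.intrachromosomal
                and (
                    (j.chrom1 == chrom and lo <= j.pos1 <= hi)
                    or (j.chrom2 == chrom and lo <= j.pos2 <= hi)
                )
            ]
            region_segs = [s for s in osc_segs if s.end >= lo and s.start <= hi]
            runs = find_oscillation_runs(region_segs, p)
            positions = [pos for j in intra_in for pos in (j.pos1, j.pos2)]
            p_joins = p_exp = float("nan")
            if intra_in:
                p_joins = fragment_joins_test(intra_in)
            if len(set(positions)) >= 5 and hi > lo:
                p_exp = breakpoint_exponential_test(positions, region)
            p_enrich = float("nan")
            if genome_breakends > 0 and chrom_breakends <= genome_breakends:
                p_enrich = chromosomal_enrichment_test(
                    chrom_breakends, lengths[chrom], genome_breakends, genome_length
                )
            rs = RegionStats(
                n_intra_interleaved=count_interleaved(intra_in),
                n_inter=len(inter_in),
                n_sv_total=len(intra_in) + len(inter_in),
                max_osc2=max_oscillating_segments(runs),
                p_joins=p_joins,
                p_enrich=p_enrich,
                p_exp=p_exp,
            )
            call = evaluate_criteria(
                region,
                rs,
                p,
                sample=sample,
                chrom=chrom,
                ccf_assumed=any(s.cell_fraction is None for s in region_segs),
            )
            if best is None or (
                (rank[call.verdict], -call.n_sv_total, call.start)
                < (rank[best.verdict], -best.n_sv_total, best.start)
            ):
                best = call
        if best is not None:
            calls.append(best)
    return calls
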