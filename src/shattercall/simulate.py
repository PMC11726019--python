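"""Generative model of chromothripsis and of non-chromothriptic controls.

The chromothripsis generator follows the micronucleation mechanism: one
homolog of a chromosome (or a sub-region) is shattered at K uniformly
placed breakpoints; each of the K+1 fragments survives with probability r;
survivors are re-ligated in uniformly random order and orientation into a
derivative chromosome, so junction orientation classes are uniform over the
four intrachromosomal types.  Optionally a subset of surviving fragments
instead circularizes into an ecDNA element amplified to A copies (a
fragment that underwent an early duplication inside the circle reaches 2A).

Copy-number bookkeeping on a diploid baseline: lost fragments keep only the
intact homolog (CN 1), retained fragments CN 2, ecDNA fragments CN
2 - 1 + A (one chromosomal copy lost into the circle, A extrachromosomal
copies), and a duplicated ecDNA fragment CN 2 - 1 + 2A.

Controls scatter a handful of isolated simple events (deletions and tandem
duplications, alternating, widely spaced) — enough rearrangement to be a
genome worth screening, but below every chromothripsis criterion.

Rendering converts the ground truth into the two assay readouts: WGS
(segments + junctions, log-ratio noise, <=100 bp junction jitter) and a
targeted panel (CN observed only at gene-footprint targets, junctions
dropped) whose sparse sampling degrades long oscillation runs — the
mechanism behind the panel's reduced sensitivity relative to WGS.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import ChromSegment, SVJunction

__all__ = [
    "GRCH37_CHROM_LENGTHS",
    "ShatterSimConfig",
    "Fragment",
    "ShatterTruth",
    "PanelDesign",
    "simulate_chromothripsis",
    "simulate_control",
    "simulate_control_genome",
    "render_wgs",
    "render_panel",
    "default_panel",
]

#: GRCh37 chromosome lengths (bp) used as the default genome context
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
}


@dataclass
class ShatterSimConfig:
    """Generative parameters: K breakpoints, retention r, ecDNA copies A."""

    chrom: str = "11"
    chrom_length: int = GRCH37_CHROM_LENGTHS["11"]
    region: tuple[int, int] | None = None  # None = whole chromosome
    n_breakpoints: int = 300
    retention_prob: float = 0.5
    purity: float = 0.8
    ecdna: bool = False
    ecdna_fragments: int = 3
    ecdna_copies: int = 60
    oncogene_duplicated: bool = False
    noise_sd: float = 0.1
    n_control_events: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breakpoints < 2:
            raise ValueError("n_breakpoints must be >= 2")
        if not (0.0 < self.retention_prob <= 1.0):
            raise ValueError("retention_prob must lie in (0, 1]")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.ecdna and self.ecdna_copies < 6:
            raise ValueError("ecdna_copies must be >= 6 (amplification regime)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.region is not None and not (
            1 <= self.region[0] < self.region[1] <= self.chrom_length
        ):
            raise ValueError("region must satisfy 1 <= start < end <= chrom_length")

    @property
    def span(self) -> tuple[int, int]:
        return self.region if self.region is not None else (1, self.chrom_length)


@dataclass(frozen=True)
class Fragment:
    start: int
    end: int
    retained: bool
    ecdna: bool = False
    duplicated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ShatterTruth:
    """Ground truth: fragments, junctions, per-bp CN profile, label."""

    chrom: str
    config: ShatterSimConfig
    fragments: list[Fragment]
    junctions: list[SVJunction]
    cn_segments: list[tuple[int, int, int]]  # (start, end, total_cn), merged
    label: bool  # chromothripsis present on this chromosome

    def cn_at(self, pos: int) -> int:
        for s, e, cn in self.cn_segments:
            if s <= pos <= e:
                return cn
        raise ValueError(f"position {pos} outside the simulated chromosome")

    def expected_cn_profile(self) -> list[tuple[int, int, int]]:
        """Recompute the CN step function from fragment bookkeeping alone."""
        cfg = self.config
        lo, hi = cfg.span
        pieces: list[tuple[int, int, int]] = []
        if lo > 1:
            pieces.append((1, lo - 1, 2))
        A = cfg.ecdna_copies
        for f in self.fragments:
            if f.ecdna:
                cn = 2 - 1 + (2 * A if f.duplicated else A)
            elif f.retained:
                cn = 2
            else:
                cn = 1
            pieces.append((f.start, f.end, cn))
        if hi < cfg.chrom_length:
            pieces.append((hi + 1, cfg.chrom_length, 2))
        return _merge_cn(pieces)


def _merge_cn(pieces: Sequence[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    merged: list[tuple[int, int, int]] = []
    for s, e, cn in sorted(pieces):
        if merged and merged[-1][2] == cn and s == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e, cn)
        else:
            merged.append((s, e, cn))
    return merged


def _ligation_junction(
    chrom: str,
    frag_a: Fragment,
    flip_a: bool,
    frag_b: Fragment,
    flip_b: bool,
    jid: str,
    n_support: int,
) -> SVJunction:
    # the 3' end of A in derivative orientation joins the 5' end of B;
    # strand + = reference sequence left of the breakend is retained
    pos_a, strand_a = (frag_a.end, "+") if not flip_a else (frag_a.start, "-")
    pos_b, strand_b = (frag_b.start, "-") if not flip_b else (frag_b.end, "+")
    return SVJunction(
        chrom1=chrom,
        pos1=pos_a,
        strand1=strand_a,
        chrom2=chrom,
        pos2=pos_b,
        strand2=strand_b,
        n_support=n_support,
        id=jid,
    ).normalized()


def simulate_chromothripsis(config: ShatterSimConfig) -> ShatterTruth:
    """Shatter -> stochastic retention -> random re-ligation -> optional ecDNA."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.span
    K = cfg.n_breakpoints
    # K distinct interior breakpoints, uniform on the region
    bps: set[int] = set()
    while len(bps) < K:
        bps.update(
            int(x) for x in rng.integers(lo + 1, hi, size=K - len(bps))
        )
    cuts = sorted(bps)
    bounds = [lo] + cuts + [hi + 1]
    retained_flags = rng.random(K + 1) < cfg.retention_prob
    frags = [
        Fragment(start=bounds[i], end=bounds[i + 1] - 1, retained=bool(retained_flags[i]))
        for i in range(K + 1)
    ]

    retained_idx = [i for i, f in enumerate(frags) if f.retained]
    circle_idx: list[int] = []
    if cfg.ecdna:
        if cfg.ecdna_fragments > len(retained_idx):
            raise ValueError(
                f"ecdna_fragments={cfg.ecdna_fragments} exceeds the "
                f"{len(retained_idx)} retained fragments"
            )
        circle_idx = sorted(
            int(i)
            for i in rng.choice(retained_idx, size=cfg.ecdna_fragments, replace=False)
        )
        dup_i = int(rng.choice(circle_idx)) if cfg.oncogene_duplicated else None
        for i in circle_idx:
            frags[i] = dataclasses.replace(frags[i], ecdna=True, duplicated=(i == dup_i))

    derivative_idx = [i for i in retained_idx if i not in set(circle_idx)]
    junctions: list[SVJunction] = []
    # derivative chromosome: uniform permutation, each fragment flipped w.p. 1/2
    order = [derivative_idx[k] for k in rng.permutation(len(derivative_idx))]
    flips = rng.random(len(order)) < 0.5
    for k in range(len(order) - 1):
        junctions.append(
            _ligation_junction(
                cfg.chrom,
                frags[order[k]],
                bool(flips[k]),
                frags[order[k + 1]],
                bool(flips[k + 1]),
                jid=f"der{k}",
                n_support=int(rng.poisson(30)),
            )
        )
    # ecDNA circle: permuted, flipped ring; k fragments emit k junctions
    if circle_idx:
        ring = [circle_idx[k] for k in rng.permutation(len(circle_idx))]
        ring_flips = rng.random(len(ring)) < 0.5
        A = cfg.ecdna_copies
        for k in range(len(ring)):
            nxt = (k + 1) % len(ring)
            junctions.append(
                _ligation_junction(
                    cfg.chrom,
                    frags[ring[k]],
                    bool(ring_flips[k]),
                    frags[ring[nxt]],
                    bool(ring_flips[nxt]) if nxt != k else bool(ring_flips[k]),
                    jid=f"ec{k}",
                    n_support=int(rng.poisson(30 * A / 2)),
                )
            )

    truth = ShatterTruth(
        chrom=cfg.chrom,
        config=cfg,
        fragments=frags,
        junctions=junctions,
        cn_segments=[],
        label=True,
    )
    truth.cn_segments = truth.expected_cn_profile()
    return truth


def simulate_control(config: ShatterSimConfig) -> ShatterTruth:
    """Scattered isolated simple events: the negative class for benchmarking.

    Deletions (CN 1) and tandem duplications (CN 3) alternate along the
    chromosome with wide spacing, so no four contiguous segments oscillate
    between two states; the construction is checked and resampled if a
    draw ever violates it.
    """
    cfg = config
    m = cfg.n_control_events
    lo, hi = cfg.span
    for attempt in range(100):
        rng = np.random.default_rng((cfg.seed, 7, attempt))
        frags: list[Fragment] = []
        junctions: list[SVJunction] = []
        pieces: list[tuple[int, int, int]] = []
        if m > 0:
            sizes = rng.integers(500_000, 3_000_000, size=m)
            gap_min = 5_000_000
            usable = (hi - lo) - int(sizes.sum()) - gap_min * (m + 1)
            if usable < 0:
                raise ValueError("chromosome too short for the requested control events")
            offsets = np.sort(rng.random(m)) * usable
            start_type = int(rng.integers(0, 2))
            for k in range(m):
                s = int(lo + gap_min * (k + 1) + offsets[k] + sizes[:k].sum())
                e = s + int(sizes[k]) - 1
                is_del = (k + start_type) % 2 == 0
                cn = 1 if is_del else 3
                pieces.append((s, e, cn))
                frags.append(Fragment(start=s, end=e, retained=not is_del))
                if is_del:
                    j = SVJunction(cfg.chrom, s - 1, "+", cfg.chrom, e + 1, "-",
                                   n_support=int(rng.poisson(30)), id=f"del{k}")
                else:
                    j = SVJunction(cfg.chrom, s, "-", cfg.chrom, e, "+",
                                   n_support=int(rng.poisson(30)), id=f"dup{k}")
                junctions.append(j.normalized())
        # fill the remainder of the chromosome with baseline CN 2
        profile: list[tuple[int, int, int]] = []
        cursor = 1
        for s, e, cn in sorted(pieces):
            if s > cursor:
                profile.append((cursor, s - 1, 2))
            profile.append((s, e, cn))
            cursor = e + 1
        if cursor <= cfg.chrom_length:
            profile.append((cursor, cfg.chrom_length, 2))
        profile = _merge_cn(profile)
        if _max_alternating(profile) < 4:
            return ShatterTruth(
                chrom=cfg.chrom,
                config=cfg,
                fragments=frags,
                junctions=junctions,
                cn_segments=profile,
                label=False,
            )
    raise RuntimeError("control construction check failed after 100 resamples")


def simulate_control_genome(
    config: ShatterSimConfig, genome: Mapping[str, int] | None = None
) -> list[ShatterTruth]:
    """Scatter ``n_control_events`` simple events across a whole genome.

    Real scattered rearrangements distribute over many chromosomes rather
    than piling onto one; events are allocated to chromosomes in proportion
    to length and each affected chromosome is built by
    :func:`simulate_control`.  Returns one truth per affected chromosome
    (unaffected chromosomes are flat diploid and are omitted).
    """
    genome = dict(genome or GRCH37_CHROM_LENGTHS)
    rng = np.random.default_rng((config.seed, 29))
    chroms = sorted(genome)
    total = sum(genome.values())
    alloc = rng.multinomial(config.n_control_events, [genome[c] / total for c in chroms])
    truths: list[ShatterTruth] = []
    for i, (chrom, k) in enumerate(zip(chroms, alloc)):
        if k == 0:
            continue
        sub = dataclasses.replace(
            config,
            chrom=chrom,
            chrom_length=genome[chrom],
            region=None,
            n_control_events=int(k),
            seed=(config.seed * 97 + i) % (2**31),
        )
        truths.append(simulate_control(sub))
    return truths


def _max_alternating(profile: Sequence[tuple[int, int, int]]) -> int:
    """Longest strictly alternating two-state stretch of the CN profile."""
    cns = [cn for _, _, cn in profile]
    best = 1 if cns else 0
    for i in range(len(cns)):
        for j in range(i + 1, len(cns)):
            sub = cns[i : j + 1]
            if len(set(sub)) == 2 and all(a != b for a, b in zip(sub, sub[1:])):
                best = max(best, len(sub))
    return best


# ---------------------------------------------------------------------------
# rendering


def _mixture_log_ratio(cn: int, purity: float) -> float:
    return math.log2((purity * cn + 2.0 * (1.0 - purity)) / 2.0)


def _minor_cn(cn: int) -> int:
    # intact homolog contributes one copy everywhere; the derivative and
    # ecDNA copies all come from the shattered homolog
    return 0 if cn < 2 else 1


def _log_odds(cn: int, purity: float) -> float:
    # full LOH in a pure tumor has unbounded allelic imbalance; cap the
    # denominator the way a finite-coverage assay would
    minor = _minor_cn(cn)
    major = cn - minor
    num = purity * major + (1.0 - purity)
    den = max(purity * minor + (1.0 - purity), 0.01)
    return math.log(max(num, 0.01) / den)


def render_wgs(
    truth: ShatterTruth, config: ShatterSimConfig | None = None
) -> tuple[dict[str, list[ChromSegment]], list[SVJunction]]:
    """Render ground truth as a WGS readout: segments plus jittered junctions."""
    cfg = config or truth.config
    rng = np.random.default_rng((cfg.seed, 11))
    segs: list[ChromSegment] = []
    for s, e, cn in truth.cn_segments:
        noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
        segs.append(
            ChromSegment(
                chrom=truth.chrom,
                start=s,
                end=e,
                n_marks=max(1, (e - s + 1) // 100_000),
                log_ratio=_mixture_log_ratio(cn, cfg.purity) + noise,
                log_odds=_log_odds(cn, cfg.purity),
                total_cn=cn,
                minor_cn=_minor_cn(cn),
                cell_fraction=1.0,
            )
        )
    jittered: list[SVJunction] = []
    for j in truth.junctions:
        d1, d2 = (int(x) for x in rng.integers(-100, 101, size=2))
        jittered.append(
            dataclasses.replace(
                j, pos1=max(1, j.pos1 + d1), pos2=max(1, j.pos2 + d2)
            ).normalized()
        )
    return {truth.chrom: segs}, jittered


@dataclass
class PanelDesign:
    """Target intervals (1-based inclusive) per chromosome, sorted."""

    targets: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.targets.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping panel targets on chromosome {chrom}")

    @property
    def n_targets(self) -> int:
        return sum(len(v) for v in self.targets.values())


def default_panel(
    n_targets: int = 505,
    genome: Mapping[str, int] | None = None,
    seed: int = 0,
) -> PanelDesign:
    """A synthetic gene-panel footprint: ``n_targets`` intervals of 10-100 kb.

    Targets are allocated to chromosomes in proportion to length and placed
    with mild clustering (a third of targets land near an earlier one, the
    way gene families cluster).  Deterministic given the seed.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    genome = dict(genome or GRCH37_CHROM_LENGTHS)
    rng = np.random.default_rng((seed, 13))
    chroms = sorted(genome)
    total = sum(genome.values())
    alloc = rng.multinomial(n_targets, [genome[c] / total for c in chroms])
    targets: dict[str, list[tuple[int, int]]] = {}
    for chrom, k in zip(chroms, alloc):
        if k == 0:
            continue
        ivs: list[tuple[int, int]] = []
        guard = 0
        while len(ivs) < k and guard < 10_000:
            guard += 1
            size = int(rng.integers(10_000, 100_001))
            if ivs and rng.random() < 0.33:
                anchor = ivs[int(rng.integers(0, len(ivs)))][0]
                start = anchor + int(rng.integers(-1_000_000, 1_000_001))
            else:
                start = int(rng.integers(1, max(2, genome[chrom] - size)))
            start = min(max(1, start), max(1, genome[chrom] - size))
            end = start + size - 1
            if all(e < start or end < s for s, e in ivs):
                ivs.append((start, end))
        targets[chrom] = sorted(ivs)
    return PanelDesign(targets=targets)


def render_panel(
    truth: ShatterTruth,
    panel: PanelDesign,
    config: ShatterSimConfig | None = None,
) -> dict[str, list[ChromSegment]]:
    """Render ground truth at panel resolution: CN at targets only, no SVs.

    Each target observes the integer CN at its midpoint; consecutive
    targets with equal CN merge into one segment with ``n_marks`` = number
    of targets merged.  Like a real segmentation of marker-level data, the
    rendered segments tile the covered extent of the chromosome: the
    boundary between adjacent segments falls midway between the last
    target of one and the first target of the next.
    """
    cfg = config or truth.config
    if panel.n_targets == 0:
        raise ValueError("panel has no targets")
    rng = np.random.default_rng((cfg.seed, 17))
    targets = panel.targets.get(truth.chrom, [])
    groups: list[tuple[int, int, int, int]] = []  # first/last target, cn, n_marks
    for s, e in targets:
        mid = (s + e) // 2
        if mid > truth.config.chrom_length:
            continue
        cn = truth.cn_at(mid)
        if groups and groups[-1][2] == cn:
            gs, _, gcn, gn = groups[-1]
            groups[-1] = (gs, e, gcn, gn + 1)
        else:
            groups.append((s, e, cn, 1))
    # tile: segment bounds at midpoints between neighbouring target groups
    tiled: list[tuple[int, int, int, int]] = []
    for i, (s, e, cn, n) in enumerate(groups):
        lo = s if i == 0 else (groups[i - 1][1] + s) // 2 + 1
        hi = e if i == len(groups) - 1 else (e + groups[i + 1][0]) // 2
        tiled.append((lo, hi, cn, n))
    segs: list[ChromSegment] = []
    for s, e, cn, n in tiled:
        noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
        segs.append(
            ChromSegment(
                chrom=truth.chrom,
                start=s,
                end=e,
                n_marks=n,
                log_ratio=_mixture_log_ratio(cn, cfg.purity) + noise,
                log_odds=_log_odds(cn, cfg.purity),
                total_cn=cn,
                minor_cn=_minor_cn(cn),
                cell_fraction=1.0,
            )
        )
    return {truth.chrom: segs}
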