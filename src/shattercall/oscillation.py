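"""Runs of segments oscillating between two copy-number states.

The oscillating pattern — consecutive segments alternating between two
integer total-CN values, reflecting alternately retained and lost shattered
fragments — is the shared core of both the targeted-panel and the WGS
caller.  A *run* is a maximal stretch whose total CNs alternate between two
states s1 != s2: directly adjacent segments in the stretch differ, and
optionally up to ``max_deviations`` interior segments whose CN lies outside
{s1, s2} may be bridged (excluded from the count) without breaking the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import ChromSegment, DetectorParams

__all__ = [
    "OscillationRun",
    "find_oscillation_runs",
    "max_oscillating_segments",
    "track_concordance",
]


@dataclass(frozen=True)
class OscillationRun:
    """A maximal two-state alternating stretch of segments.

    ``first_index``/``last_index`` index into the chromosome's sorted
    segment list; ``member_indices`` are the conforming segments (interior
    bridged deviations excluded), so ``run_length == len(member_indices)``.
    """

    chrom: str
    first_index: int
    last_index: int
    states: frozenset[int]
    run_length: int
    size_ratio: float
    min_cell_fraction: float
    track_concordant: bool
    tracks_checked: frozenset[str]
    member_indices: tuple[int, ...]
    ccf_assumed: bool = False

    def __post_init__(self) -> None:
        if self.run_length != len(self.member_indices):
            raise ValueError("run_length must equal the number of member segments")
        if self.size_ratio < 1.0:
            raise ValueError("size_ratio must be >= 1")


def track_concordance(
    segments: Sequence[ChromSegment],
) -> tuple[bool, frozenset[str]]:
    """Check that CN tracks change in consistent directions along a run.

    At every internal boundary the sign of the log-ratio change must match
    the sign of the integer total-CN change; where the allelic log-odds and
    minor CN are present on both sides, the sign of the log-odds change must
    be consistent with the change in allelic imbalance (total - 2*minor).
    Missing tracks are skipped; returns ``(concordant, tracks_checked)``.
    """
    checked: set[str] = set()
    ok = True
    for a, b in zip(segments, segments[1:]):
        d_cn = b.total_cn - a.total_cn
        if d_cn == 0:
            continue
        checked.add("log_ratio")
        if _sign(b.log_ratio - a.log_ratio) != _sign(d_cn):
            ok = False
        if (
            a.log_odds is not None
            and b.log_odds is not None
            and a.minor_cn is not None
            and b.minor_cn is not None
        ):
            d_imb = (b.total_cn - 2 * b.minor_cn) - (a.total_cn - 2 * a.minor_cn)
            if d_imb != 0:
                checked.add("log_odds")
                if _sign(b.log_odds - a.log_odds) != _sign(d_imb):
                    ok = False
    return ok, frozenset(checked)


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _candidate_windows(cns: Sequence[int], d: int) -> list[tuple[int, ...]]:
    """All maximal alternating stretches, each as its tuple of member indices.

    For every unordered pair of distinct CN values present, scan forward:
    a window accepts pair values (which must differ from a directly
    preceding conforming neighbour) and bridges at most ``d`` out-of-pair
    deviations; endpoints must conform and both pair values must occur.
    Contained windows (member subset of an equal-or-longer window) are
    pruned.
    """
    n = len(cns)
    values = sorted(set(cns))
    raw: set[tuple[int, ...]] = set()
    for ai in range(len(values)):
        for bi in range(ai + 1, len(values)):
            pair = {values[ai], values[bi]}
            i = 0
            while i < n:
                if cns[i] not in pair:
                    i += 1
                    continue
                members = [i]
                n_dev = 0  # bridged interior deviants
                j = i + 1
                while j < n:
                    x = cns[j]
                    gap = j - members[-1] - 1  # deviants pending a bridge
                    if x in pair:
                        if gap == 0 and x == cns[members[-1]]:
                            break  # adjacent equal states: alternation break
                        if n_dev + gap > d:
                            break
                        n_dev += gap
                        members.append(j)
                    elif n_dev + gap + 1 > d:
                        break  # this deviant could never be bridged
                    j += 1
                if len(members) >= 2 and len({cns[k] for k in members}) == 2:
                    raw.add(tuple(members))
                i = members[1] if len(members) >= 2 else i + 1
    # prune windows whose members are a subset of an equal-or-longer window
    windows = sorted(raw, key=lambda m: (-len(m), m[0]))
    kept: list[tuple[int, ...]] = []
    for w in windows:
        ws = set(w)
        if any(ws < set(k) or (ws <= set(k) and w != k) for k in kept):
            continue
        kept.append(w)
    return kept


def find_oscillation_runs(
    segments: Sequence[ChromSegment],
    params: DetectorParams | None = None,
) -> list[OscillationRun]:
    """Find maximal two-state oscillation runs in one chromosome's segments.

    Segments must be sorted and non-overlapping.  Returns non-overlapping
    runs selected greedily by (run length desc, leftmost); annotations
    (size ratio, minimum cell fraction, track concordance) are filled from
    the conforming member segments.
    """
    params = params or DetectorParams()
    if not segments:
        return []
    cns = [s.total_cn for s in segments]
    windows = _candidate_windows(cns, params.max_deviations)
    windows.sort(key=lambda m: (-len(m), m[0]))
    chosen: list[tuple[int, ...]] = []
    for w in windows:
        if all(w[-1] < c[0] or c[-1] < w[0] for c in chosen):
            chosen.append(w)
    chosen.sort(key=lambda m: m[0])
    return [_annotate(segments, members) for members in chosen]


def _annotate(
    segments: Sequence[ChromSegment], members: tuple[int, ...]
) -> OscillationRun:
    member_segs = [segments[k] for k in members]
    lengths = [s.length for s in member_segs]
    concordant, checked = track_concordance(member_segs)
    return OscillationRun(
        chrom=segments[0].chrom,
        first_index=members[0],
        last_index=members[-1],
        states=frozenset(s.total_cn for s in member_segs),
        run_length=len(members),
        size_ratio=max(lengths) / min(lengths),
        min_cell_fraction=min(s.effective_cell_fraction for s in member_segs),
        track_concordant=concordant,
        tracks_checked=checked,
        member_indices=members,
        ccf_assumed=any(s.cell_fraction is None for s in member_segs),
    )


def max_oscillating_segments(runs: Sequence[OscillationRun]) -> int:
    """Longest run length among the given runs (0 if none)."""
    return max((r.run_length for r in runs), default=0)
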