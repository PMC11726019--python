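"""Targeted-panel (tNGS) chromothripsis caller: copy-number segments only.

A chromosome is *suggestive of chromothripsis* when it carries a window of
at least ``min_panel_run`` (default 5) consecutive oscillating segments
that are uniformly sized (max/min length ratio within bound), each present
in at least ``min_segment_ccf`` of cancer cells, and whose log-ratio and
integer-CN tracks move concordantly.  The original modality was manual
inspection of per-chromosome CN plots; this caller fixes the rule as a
deterministic procedure with the same thresholds as defaults.

High-level amplification spikes (CN above ``amp_baseline_factor`` x the
chromosome baseline, the ecDNA regime) sit inside chromothriptic regions
and would break the alternation, so they are bridged out before the rule
is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .io import ChromSegment, DetectorParams, PanelCall
from .oscillation import OscillationRun, find_oscillation_runs, track_concordance

__all__ = ["call_panel", "concordance_vs_truth", "ConcordanceResult"]

_FILTER_LABELS = ("run_too_short", "low_ccf", "nonuniform_sizes", "discordant_tracks")


def _window_failures(
    segments: Sequence[ChromSegment], members: Sequence[int], params: DetectorParams
) -> list[str]:
    segs = [segments[k] for k in members]
    reasons = []
    if len(segs) < params.min_panel_run:
        reasons.append("run_too_short")
    if min(s.effective_cell_fraction for s in segs) < params.min_segment_ccf:
        reasons.append("low_ccf")
    lengths = [s.length for s in segs]
    if max(lengths) / min(lengths) > params.uniformity_max_ratio:
        reasons.append("nonuniform_sizes")
    if not track_concordance(segs)[0]:
        reasons.append("discordant_tracks")
    return reasons


def _qualifying_window(
    segments: Sequence[ChromSegment], run: OscillationRun, params: DetectorParams
) -> tuple[int, ...] | None:
    """Longest window of run members that passes every panel filter.

    The rule is a window property ("a minimum of five consecutive ...
    uniformly sized ..."), so sub-windows of a maximal run are searched;
    the longest qualifying window wins, leftmost on ties.
    """
    m = run.member_indices
    best: tuple[int, ...] | None = None
    for w in range(len(m), params.min_panel_run - 1, -1):
        for i in range(0, len(m) - w + 1):
            window = m[i : i + w]
            if not _window_failures(segments, window, params):
                return window
    return best


def call_panel(
    segments_by_chrom: Mapping[str, Sequence[ChromSegment]],
    params: DetectorParams | None = None,
    sample: str = "",
) -> list[PanelCall]:
    """Per-chromosome panel verdicts for one sample's segment set.

    ``suggestive_positive`` when a qualifying oscillation window exists;
    otherwise ``negative`` with ``reasons`` naming the filters that
    eliminated the longest run.
    """
    from .wgs import flag_amplified_segments  # amp spikes bridged before the rule

    p = params or DetectorParams()
    calls: list[PanelCall] = []
    for chrom in sorted(segments_by_chrom):
        segs = list(segments_by_chrom[chrom])
        flagged, _ = flag_amplified_segments(segs, p)
        amp_ids = {id(s) for s in flagged}
        osc_segs = [s for s in segs if id(s) not in amp_ids]
        runs = find_oscillation_runs(osc_segs, p)
        ccf_assumed = any(s.cell_fraction is None for s in segs)
        best_window: tuple[int, ...] | None = None
        for run in sorted(runs, key=lambda r: (-r.run_length, r.first_index)):
            window = _qualifying_window(osc_segs, run, p)
            if window is not None and (
                best_window is None or len(window) > len(best_window)
            ):
                best_window = window
        if best_window is not None:
            segs_in = [osc_segs[k] for k in best_window]
            lengths = [s.length for s in segs_in]
            calls.append(
                PanelCall(
                    sample=sample,
                    chrom=chrom,
                    start=segs_in[0].start,
                    end=segs_in[-1].end,
                    verdict="suggestive_positive",
                    run_length=len(best_window),
                    size_ratio=max(lengths) / min(lengths),
                    min_cell_fraction=min(
                        s.effective_cell_fraction for s in segs_in
                    ),
                    reasons=(),
                    ccf_assumed=ccf_assumed,
                )
            )
            continue
        # negative: report why the longest run fails
        reasons: tuple[str, ...] = ("run_too_short",)
        start = segs[0].start if segs else 0
        end = segs[-1].end if segs else 0
        run_length = 0
        size_ratio = 1.0
        min_cf = 1.0
        if runs:
            longest = min(runs, key=lambda r: (-r.run_length, r.first_index))
            reasons = tuple(
                _window_failures(osc_segs, longest.member_indices, p)
            ) or ("run_too_short",)
            segs_in = [osc_segs[k] for k in longest.member_indices]
            start, end = segs_in[0].start, segs_in[-1].end
            run_length = longest.run_length
            size_ratio = longest.size_ratio
            min_cf = longest.min_cell_fraction
        calls.append(
            PanelCall(
                sample=sample,
                chrom=chrom,
                start=start,
                end=end,
                verdict="negative",
                run_length=run_length,
                size_ratio=size_ratio,
                min_cell_fraction=min_cf,
                reasons=reasons,
                ccf_assumed=ccf_assumed,
            )
        )
    return calls


@dataclass(frozen=True)
class ConcordanceResult:
    """Chromosome-level confusion table with exact binomial 95% intervals."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    per_chrom: dict[str, str]


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return (float(ci.low), float(ci.high))


def concordance_vs_truth(
    calls: Sequence[PanelCall], truth: Mapping[str, bool]
) -> ConcordanceResult:
    """Sensitivity/specificity of calls against per-chromosome truth labels.

    Truth maps chromosome -> chromothripsis present.  Labels must cover
    every chromosome with a call; a truth class with no members reports its
    rate as missing (None) rather than 0/0.
    """
    missing = [c.chrom for c in calls if c.chrom not in truth]
    if missing:
        raise ValueError(f"truth labels missing for chromosome(s): {sorted(set(missing))}")
    tp = fn = tn = fp = 0
    per_chrom: dict[str, str] = {}
    for c in calls:
        positive = c.verdict == "suggestive_positive"
        if truth[c.chrom]:
            if positive:
                tp += 1
                per_chrom[c.chrom] = "TP"
            else:
                fn += 1
                per_chrom[c.chrom] = "FN"
        else:
            if positive:
                fp += 1
                per_chrom[c.chrom] = "FP"
            else:
                tn += 1
                per_chrom[c.chrom] = "TN"
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return ConcordanceResult(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        sensitivity_ci=_binom_ci(tp, tp + fn) if sens is not None else None,
        specificity=spec,
        specificity_ci=_binom_ci(tn, tn + fp) if spec is not None else None,
        per_chrom=per_chrom,
    )
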