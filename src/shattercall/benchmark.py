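"""Benchmark harness: simulator -> both detectors -> operating characteristics.

Re-creates, on simulated genomes, the targeted-panel versus WGS concordance
experiment: for each seed a chromothriptic genome and a control genome are
generated, rendered both as WGS and at panel resolution, and run through
the corresponding caller.  Sensitivity and specificity per mode carry
exact (Clopper-Pearson) binomial 95% intervals.  Deterministic given the
base seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import DetectorParams
from .panel import call_panel
from .simulate import (
    GRCH37_CHROM_LENGTHS,
    PanelDesign,
    ShatterSimConfig,
    default_panel,
    render_panel,
    render_wgs,
    simulate_chromothripsis,
    simulate_control_genome,
)
from .wgs import call_wgs

__all__ = ["run_benchmark", "BenchmarkResult"]


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    n: int
    seed: int

    def rate(self, mode: str, metric: str) -> float:
        row = self.table[self.table["mode"] == mode].iloc[0]
        return float(row[metric])


def _ci(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def run_benchmark(
    n: int,
    seed: int = 0,
    sim_config: ShatterSimConfig | None = None,
    params: DetectorParams | None = None,
    panel: PanelDesign | None = None,
) -> BenchmarkResult:
    """Paired operating characteristics of the WGS and panel callers.

    For each of ``n`` replicate seeds, one chromothriptic genome (one
    shattered chromosome) and one control genome (simple events scattered
    across all chromosomes) are simulated and rendered for both assays.
    Detection means a non-negative WGS verdict (positive or low-density)
    or a suggestive-positive panel verdict on any chromosome; on control
    genomes any such call is a false positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = sim_config or ShatterSimConfig()
    params = params or DetectorParams()
    panel = panel or default_panel(seed=seed)
    counts = {
        ("wgs", "tp"): 0,
        ("wgs", "fn"): 0,
        ("wgs", "tn"): 0,
        ("wgs", "fp"): 0,
        ("panel", "tp"): 0,
        ("panel", "fn"): 0,
        ("panel", "tn"): 0,
        ("panel", "fp"): 0,
    }
    for i in range(n):
        cfg = dataclasses.replace(base, seed=(seed * 100_003 + i) % (2**31))
        for truths, is_pos in (
            ([simulate_chromothripsis(cfg)], True),
            (simulate_control_genome(cfg), False),
        ):
            segs: dict = {}
            junctions: list = []
            panel_segs: dict = {}
            for truth, t_cfg in (
                (t, t.config) for t in truths
            ):
                s, j = render_wgs(truth, t_cfg)
                segs.update(s)
                junctions.extend(j)
                panel_segs.update(render_panel(truth, panel, t_cfg))
            wgs_calls = call_wgs(
                segs, junctions, params, chrom_lengths=GRCH37_CHROM_LENGTHS
            )
            # detection on any simulated chromosome counts: a positive call
            # anywhere on a control genome is a false positive
            wgs_hit = any(c.verdict != "negative" for c in wgs_calls)
            panel_calls = call_panel(panel_segs, params)
            panel_hit = any(c.verdict == "suggestive_positive" for c in panel_calls)
            for mode, hit in (("wgs", wgs_hit), ("panel", panel_hit)):
                if is_pos:
                    counts[(mode, "tp" if hit else "fn")] += 1
                else:
                    counts[(mode, "fp" if hit else "tn")] += 1

    rows = []
    for mode in ("wgs", "panel"):
        tp, fn = counts[(mode, "tp")], counts[(mode, "fn")]
        tn, fp = counts[(mode, "tn")], counts[(mode, "fp")]
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        s_lo, s_hi = _ci(tp, tp + fn)
        p_lo, p_hi = _ci(tn, tn + fp)
        rows.append(
            {
                "mode": mode,
                "n_pos": tp + fn,
                "n_neg": tn + fp,
                "tp": tp,
                "fn": fn,
                "tn": tn,
                "fp": fp,
                "sensitivity": sens,
                "sensitivity_ci_low": s_lo,
                "sensitivity_ci_high": s_hi,
                "specificity": spec,
                "specificity_ci_low": p_lo,
                "specificity_ci_high": p_hi,
            }
        )
    return BenchmarkResult(table=pd.DataFrame(rows), n=n, seed=seed)
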