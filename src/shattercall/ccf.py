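"""Cancer-cell-fraction estimation from read counts, purity and local CN.

The expected variant allele frequency of a mutation carried by a fraction
CCF of tumor cells in a sample of purity p is

    VAF(CCF) = p * CCF / (CN_diploid * (1 - p) + CN_mut * p)

where CN_diploid is the copy number in normal cells (2 at autosomal loci)
and CN_mut the expected number of copies carrying the mutation in tumor
cells.  The CCF point estimate maximizes the binomial likelihood of the
observed alt-read count over a grid on [0, 1] (step 0.01); the grid
likelihoods, normalized under a uniform prior, give a posterior from which
a central 95% interval is read off.  A CCF of >= 0.8 is regarded as clonal
or near-clonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import DetectorParams, MutationObservation

__all__ = ["CcfEstimate", "expected_vaf", "estimate_ccf", "annotate_mutation_table"]

CLONAL = "clonal_or_near_clonal"
SUBCLONAL = "subclonal"

GRID_STEP = 0.01


@dataclass(frozen=True)
class CcfEstimate:
    ccf_point: float
    ccf_low: float
    ccf_high: float
    clonality_class: str
    capped: bool = False  # the likelihood wanted CCF > 1 (clamped to the grid)

    def __post_init__(self) -> None:
        if not (self.ccf_low <= self.ccf_point <= self.ccf_high):
            raise ValueError("interval must contain the point estimate")


def expected_vaf(purity: float, ccf: float, cn_mut: int, cn_diploid: int = 2) -> float:
    """Expected VAF of a mutation at the given CCF, purity and CN context."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if not (0.0 <= ccf <= 1.0):
        raise ValueError("ccf must lie in [0, 1]")
    denom = cn_diploid * (1.0 - purity) + cn_mut * purity
    if denom <= 0:
        raise ValueError("copy-number denominator must be positive")
    return purity * ccf / denom


def estimate_ccf(
    obs: MutationObservation, params: DetectorParams | None = None
) -> CcfEstimate:
    """Grid maximum-likelihood CCF with a central 95% posterior interval.

    The posterior uses a uniform prior over the CCF grid.  Ties in the
    likelihood resolve to the smallest CCF.  Estimates that would exceed a
    CCF of 1 pile up at the upper grid edge and are flagged ``capped``.
    """
    params = params or DetectorParams()
    if obs.depth < 1:
        raise ValueError("depth must be >= 1")
    grid = np.round(np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP), 10)
    vafs = np.array(
        [expected_vaf(obs.purity, c, obs.cn_mut, obs.cn_diploid) for c in grid]
    )
    loglik = stats.binom.logpmf(obs.alt_reads, obs.depth, vafs)
    if np.all(np.isneginf(loglik)):
        raise ValueError(
            "degenerate input: expected VAF is impossible for the observed reads "
            "at every CCF on the grid"
        )
    best = int(np.argmax(loglik))
    point = float(grid[best])
    post = np.exp(loglik - np.max(loglik))
    post /= post.sum()
    cdf = np.cumsum(post)
    low = float(grid[int(np.searchsorted(cdf, 0.025))])
    high = float(grid[int(np.searchsorted(cdf, 0.975))])
    low, high = min(low, point), max(high, point)
    # an MLE at the upper edge with the naive inversion wanting more is capped
    naive = (
        (obs.alt_reads / obs.depth)
        * (obs.cn_diploid * (1 - obs.purity) + obs.cn_mut * obs.purity)
        / obs.purity
    )
    capped = bool(point >= 1.0 and naive > 1.0 + GRID_STEP / 2)
    clonality = CLONAL if point >= params.clonal_ccf_cutoff else SUBCLONAL
    return CcfEstimate(point, low, high, clonality, capped)


def mutant_copies_default(cn_total: int) -> int:
    """Fallback mutant multiplicity when phasing is unknown: the local total CN."""
    return max(1, int(cn_total))


def annotate_mutation_table(
    path_in: str | Path,
    path_out: str | Path,
    params: DetectorParams | None = None,
) -> pd.DataFrame:
    """Annotate a tab-separated mutation table with CCF columns.

    Expects columns sample, chrom, pos, alt_reads, depth, purity, cn_mut
    (optional cn_diploid); appends ccf_point, ccf_low, ccf_high, clonality.
    """
    params = params or DetectorParams()
    df = pd.read_csv(path_in, sep="\t")
    required = ["sample", "chrom", "pos", "alt_reads", "depth", "purity", "cn_mut"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path_in}: missing column(s): {', '.join(missing)}")
    points, lows, highs, classes = [], [], [], []
    for _, row in df.iterrows():
        obs = MutationObservation(
            alt_reads=int(row["alt_reads"]),
            depth=int(row["depth"]),
            purity=float(row["purity"]),
            cn_mut=int(row["cn_mut"]),
            cn_diploid=int(row.get("cn_diploid", 2) or 2),
        )
        est = estimate_ccf(obs, params)
        points.append(est.ccf_point)
        lows.append(est.ccf_low)
        highs.append(est.ccf_high)
        classes.append(est.clonality_class)
    df["ccf_point"] = points
    df["ccf_low"] = lows
    df["ccf_high"] = highs
    df["clonality"] = classes
    df.to_csv(path_out, sep="\t", index=False, lineterminator="\n")
    return df
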