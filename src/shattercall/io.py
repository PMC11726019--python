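"""Domain types and file I/O for segment tables, BEDPE junctions, and call reports.

Internal coordinates are 1-based inclusive everywhere.  BEDPE input
(0-based, half-open) is converted at the boundary: each breakend interval is
collapsed to its midpoint (rounded down).  Chromosome label dialects
("chr11" vs "11") are unified by stripping the ``chr`` prefix.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ChromSegment",
    "SVJunction",
    "MutationObservation",
    "DetectorParams",
    "ChromothripsisCall",
    "PanelCall",
    "orientation_class",
    "normalize_chrom",
    "read_segments",
    "read_bedpe",
    "write_report",
    "read_report_json",
]

#: the four intrachromosomal junction orientation classes plus translocations
DELETION_LIKE = "deletion-like"
DUPLICATION_LIKE = "duplication-like"
HEAD_TO_HEAD = "head-to-head-inversion"
TAIL_TO_TAIL = "tail-to-tail-inversion"
INTERCHROMOSOMAL = "interchromosomal"

INTRA_CLASSES = (DELETION_LIKE, DUPLICATION_LIKE, HEAD_TO_HEAD, TAIL_TO_TAIL)


def normalize_chrom(label: object) -> str:
    """Strip a leading ``chr`` prefix so mixed-dialect inputs agree."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def orientation_class(same_chrom: bool, strand1: str, strand2: str) -> str:
    """Classify a junction from its breakend strands.

    Strand ``+`` means the ligated end retains the reference sequence to the
    *left* of the breakend; ``-`` retains the right side.  For an
    intrachromosomal junction normalized to pos1 < pos2, the four strand
    pairs map onto the canonical rearrangement types: (+,-) deletion-like,
    (-,+) duplication-like, (+,+) head-to-head inversion, (-,-) tail-to-tail
    inversion.  Any interchromosomal junction is its own class.
    """
    if not same_chrom:
        return INTERCHROMOSOMAL
    pair = (strand1, strand2)
    table = {
        ("+", "-"): DELETION_LIKE,
        ("-", "+"): DUPLICATION_LIKE,
        ("+", "+"): HEAD_TO_HEAD,
        ("-", "-"): TAIL_TO_TAIL,
    }
    try:
        return table[pair]
    except KeyError:
        raise ValueError(f"invalid strand pair {pair!r}") from None


@dataclass(frozen=True)
class ChromSegment:
    """One allele-specific copy-number segment (FACETS-style).

    ``log_ratio`` is the log2 tumor/normal coverage ratio, ``log_odds`` the
    allelic-imbalance log-odds, ``total_cn``/``minor_cn`` the integer fit and
    ``cell_fraction`` the fraction of cancer cells carrying the state.
    ``log_odds``, ``minor_cn`` and ``cell_fraction`` may be missing (None).
    """

    chrom: str
    start: int
    end: int
    n_marks: int
    log_ratio: float
    log_odds: float | None = None
    total_cn: int = 2
    minor_cn: int | None = None
    cell_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.n_marks < 1:
            raise ValueError("n_marks must be >= 1")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValueError("minor_cn must be >= 0")
            if self.minor_cn > self.total_cn - self.minor_cn:
                raise ValueError(
                    "minor_cn exceeds major allele copy number "
                    f"({self.minor_cn} of total {self.total_cn})"
                )
        if self.cell_fraction is not None and not (0.0 <= self.cell_fraction <= 1.0):
            raise ValueError("cell_fraction must lie in [0, 1]")

    @property
    def length(self) -> int:
        """Segment length in bp (1-based inclusive)."""
        return self.end - self.start + 1

    @property
    def effective_cell_fraction(self) -> float:
        """cell_fraction, with missing values treated as 1.0 (disclosed in calls)."""
        return 1.0 if self.cell_fraction is None else self.cell_fraction


@dataclass(frozen=True)
class SVJunction:
    """One structural-variant junction: two breakends with strands."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    n_support: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")
        if self.n_support < 0:
            raise ValueError("n_support must be >= 0")

    @property
    def intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def orientation_class(self) -> str:
        return orientation_class(self.intrachromosomal, self.strand1, self.strand2)

    def normalized(self) -> "SVJunction":
        """Canonical form: intrachromosomal junctions ordered pos1 < pos2.

        Swapping breakends swaps the strands with them; re-normalizing a
        normalized junction changes nothing.
        """
        if self.intrachromosomal and self.pos2 < self.pos1:
            return dataclasses.replace(
                self,
                pos1=self.pos2,
                strand1=self.strand2,
                pos2=self.pos1,
                strand2=self.strand1,
            )
        return self


@dataclass(frozen=True)
class MutationObservation:
    """Read counts plus the sample context needed to map VAF to CCF."""

    alt_reads: int
    depth: int
    purity: float
    cn_mut: int
    cn_diploid: int = 2

    def __post_init__(self) -> None:
        if self.alt_reads < 0:
            raise ValueError("alt_reads must be >= 0")
        if self.depth < self.alt_reads:
            raise ValueError("depth must be >= alt_reads")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")
        if self.cn_mut < 1:
            raise ValueError("cn_mut must be >= 1")


@dataclass
class DetectorParams:
    """Every numeric threshold used by the panel and WGS callers.

    Panel rule: ``min_panel_run`` consecutive oscillating segments (default
    5), each with cell fraction >= ``min_segment_ccf`` (default 0.5),
    uniformly sized (max/min length ratio <= ``uniformity_max_ratio``) and
    with concordant log-ratio / integer-CN tracks.  WGS criteria thresholds
    default to the combined-criteria values (6 interleaved intrachromosomal
    SVs + 7 oscillating segments; 3 intra + 4 inter + 7 oscillating; 40
    intra; 100 total SVs + 5 oscillating; low-density band 4-6 oscillating).
    """

    # panel rule
    min_panel_run: int = 5
    min_segment_ccf: float = 0.5
    uniformity_max_ratio: float = 10.0
    # clonality
    clonal_ccf_cutoff: float = 0.8
    # statistical test levels
    alpha_joins: float = 0.05
    alpha_enrich: float = 0.05
    alpha_exp: float = 0.05
    # WGS criteria thresholds
    min_intra_i: int = 6
    min_intra_ii: int = 3
    min_inter_ii: int = 4
    min_intra_iii: int = 40
    min_total_iv: int = 100
    min_osc_i: int = 7
    min_osc_iv: int = 5
    osc_low_min: int = 4
    osc_low_max: int = 6
    # amplification flag and oscillation tolerance
    amp_baseline_factor: float = 5.0
    max_deviations: int = 0
    # region clustering
    cluster_gap_bp: int = 10_000_000

    def __post_init__(self) -> None:
        for name in (
            "min_panel_run",
            "min_intra_i",
            "min_intra_ii",
            "min_inter_ii",
            "min_intra_iii",
            "min_total_iv",
            "min_osc_i",
            "min_osc_iv",
            "osc_low_min",
            "osc_low_max",
            "cluster_gap_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_joins", "alpha_enrich", "alpha_exp"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.uniformity_max_ratio < 1.0:
            raise ValueError("uniformity_max_ratio must be >= 1")
        if self.amp_baseline_factor <= 0:
            raise ValueError("amp_baseline_factor must be positive")
        if self.max_deviations < 0:
            raise ValueError("max_deviations must be >= 0")


# ---------------------------------------------------------------------------
# call records

CRITERIA = ("i", "ii", "iii", "iv", "v")


@dataclass
class ChromothripsisCall:
    """Per-region WGS verdict with counts, test p-values and criterion flags."""

    sample: str
    chrom: str
    start: int
    end: int
    n_intra_interleaved: int
    n_inter: int
    n_sv_total: int
    max_osc2: int
    p_joins: float
    p_enrich: float
    p_exp: float
    criteria_passed: tuple[str, ...]
    verdict: str  # positive | low_density | negative
    ccf_assumed: bool = False  # cell_fraction missing somewhere, treated as 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria_passed"] = list(self.criteria_passed)
        d["kind"] = "wgs"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChromothripsisCall":
        d = {k: v for k, v in d.items() if k != "kind"}
        d["criteria_passed"] = tuple(d["criteria_passed"])
        return cls(**d)


@dataclass
class PanelCall:
    """Per-chromosome targeted-panel verdict based on CN oscillation alone."""

    sample: str
    chrom: str
    start: int
    end: int
    verdict: str  # suggestive_positive | negative
    run_length: int
    size_ratio: float
    min_cell_fraction: float
    reasons: tuple[str, ...] = ()
    ccf_assumed: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reasons"] = list(self.reasons)
        d["kind"] = "panel"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelCall":
        d = {k: v for k, v in d.items() if k != "kind"}
        d["reasons"] = tuple(d["reasons"])
        return cls(**d)


# ---------------------------------------------------------------------------
# segment tables

#: canonical column -> accepted aliases (FACETS hisens/purity dialects included)
SEGMENT_ALIASES: dict[str, tuple[str, ...]] = {
    "chrom": ("chrom", "chromosome", "chr"),
    "start": ("start", "loc.start"),
    "end": ("end", "loc.end"),
    "num_mark": ("num_mark", "num.mark", "nmark"),
    "cnlr": ("cnlr", "cnlr.median", "log_ratio", "seg.mean"),
    "logOR": ("logor", "mafr", "log_odds"),
    "tcn": ("tcn", "tcn.em", "total_cn"),
    "lcn": ("lcn", "lcn.em", "minor_cn"),
    "cf": ("cf", "cf.em", "cell_fraction", "ccf"),
}

_REQUIRED = ("chrom", "start", "end", "cnlr", "tcn")


def _map_columns(columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lowered = {c.lower(): c for c in columns}
    out: dict[str, str] = {}
    for canon, names in aliases.items():
        for name in names:
            if name.lower() in lowered:
                out[canon] = lowered[name.lower()]
                break
    return out


def read_segments(
    path: str | Path,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[dict[str, list[ChromSegment]], dict[str, int]]:
    """Read a tab-separated allele-specific segment table.

    Returns ``(segments_by_chrom, stats)`` where ``segments_by_chrom`` maps
    chromosome label (``chr`` prefix stripped) to segments sorted by start,
    and ``stats`` counts rows read and rows dropped (missing integer CN).

    Raises ``ValueError`` naming the offending 1-based file line for
    malformed rows and for overlapping segments (the input is expected to be
    a segmentation, not an interval list).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    colmap = _map_columns(df.columns, aliases or SEGMENT_ALIASES)
    missing = [c for c in _REQUIRED if c not in colmap]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    by_chrom: dict[str, list[tuple[int, ChromSegment]]] = {}
    n_read = 0
    n_dropped = 0
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        n_read += 1

        def val(canon: str) -> str | None:
            col = colmap.get(canon)
            if col is None:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            v = str(v).strip()
            return v if v not in ("", "NA", "nan", "None") else None

        tcn_raw = val("tcn")
        if tcn_raw is None:
            n_dropped += 1
            continue
        try:
            chrom = normalize_chrom(val("chrom"))
            start = int(float(val("start")))
            end = int(float(val("end")))
            n_marks_raw = val("num_mark")
            lcn_raw = val("lcn")
            cf_raw = val("cf")
            logor_raw = val("logOR")
            seg = ChromSegment(
                chrom=chrom,
                start=start,
                end=end,
                n_marks=int(float(n_marks_raw)) if n_marks_raw is not None else 1,
                log_ratio=float(val("cnlr")),
                log_odds=float(logor_raw) if logor_raw is not None else None,
                total_cn=int(float(tcn_raw)),
                minor_cn=int(float(lcn_raw)) if lcn_raw is not None else None,
                cell_fraction=float(cf_raw) if cf_raw is not None else None,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed segment row at line {line}: {exc}") from exc
        by_chrom.setdefault(chrom, []).append((line, seg))

    out: dict[str, list[ChromSegment]] = {}
    for chrom, entries in by_chrom.items():
        entries.sort(key=lambda e: (e[1].start, e[1].end))
        prev_line = None
        prev: ChromSegment | None = None
        for line, seg in entries:
            if prev is not None and seg.start <= prev.end:
                raise ValueError(
                    f"{path}: overlapping segments on chromosome {chrom} "
                    f"(lines {prev_line} and {line}): "
                    f"{prev.start}-{prev.end} vs {seg.start}-{seg.end}"
                )
            prev, prev_line = seg, line
        out[chrom] = [seg for _, seg in entries]
    return out, {"n_read": n_read, "n_dropped": n_dropped}


def write_segments(segments_by_chrom: Mapping[str, Sequence[ChromSegment]], path: str | Path) -> None:
    """Write segments back out in the canonical tab-separated layout."""
    rows = []
    for chrom in sorted(segments_by_chrom, key=_chrom_sort_key):
        for s in segments_by_chrom[chrom]:
            rows.append(
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "num_mark": s.n_marks,
                    "cnlr": s.log_ratio,
                    "logOR": s.log_odds,
                    "tcn": s.total_cn,
                    "lcn": s.minor_cn,
                    "cf": s.cell_fraction,
                }
            )
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "num_mark", "cnlr", "logOR", "tcn", "lcn", "cf"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# BEDPE

_BEDPE_COLS = 10  # chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2


def _midpoint_1based(start0: int, end0: int) -> int:
    # midpoint of a 0-based half-open interval, rounded down, as 1-based
    return (start0 + end0 - 1) // 2 + 1


def read_bedpe(path: str | Path) -> list[SVJunction]:
    """Read 10-column BEDPE into normalized :class:`SVJunction` records.

    Breakend intervals are collapsed to midpoints; intrachromosomal
    junctions are ordered pos1 < pos2 (strands travel with their breakends).
    """
    path = Path(path)
    out: list[SVJunction] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < _BEDPE_COLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_BEDPE_COLS} BEDPE columns "
                    f"(including strand1/strand2), found {len(fields)}"
                )
            c1, s1, e1, c2, s2, e2, name, score, st1, st2 = fields[:_BEDPE_COLS]
            if st1 not in "+-" or st2 not in "+-":
                raise ValueError(f"{path}: line {lineno}: missing or invalid strand columns")
            try:
                j = SVJunction(
                    chrom1=normalize_chrom(c1),
                    pos1=_midpoint_1based(int(s1), int(e1)),
                    strand1=st1,
                    chrom2=normalize_chrom(c2),
                    pos2=_midpoint_1based(int(s2), int(e2)),
                    strand2=st2,
                    n_support=int(float(score)) if score not in (".", "") else 0,
                    id=name if name != "." else f"sv{lineno}",
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append(j.normalized())
    return out


def write_bedpe(junctions: Iterable[SVJunction], path: str | Path) -> None:
    """Write junctions as 10-column BEDPE (0-based half-open point intervals)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom1,
                        j.pos1 - 1,
                        j.pos1,
                        j.chrom2,
                        j.pos2 - 1,
                        j.pos2,
                        j.id or ".",
                        j.n_support,
                        j.strand1,
                        j.strand2,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# reports


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


_REPORT_COLUMNS = [
    "kind",
    "sample",
    "chrom",
    "start",
    "end",
    "verdict",
    "criteria_passed",
    "n_intra_interleaved",
    "n_inter",
    "n_sv_total",
    "max_osc2",
    "p_joins",
    "p_enrich",
    "p_exp",
    "run_length",
    "size_ratio",
    "min_cell_fraction",
    "reasons",
    "ccf_assumed",
]


def write_report(
    calls: Sequence[ChromothripsisCall | PanelCall], prefix: str | Path
) -> tuple[Path, Path]:
    """Write calls as ``<prefix>.tsv`` + loss-less ``<prefix>.json`` sidecar.

    Rows are stably sorted by (sample, chromosome, start); an empty call
    list produces a header-only TSV and an empty JSON list.
    """
    ordered = sorted(
        calls, key=lambda c: (c.sample, _chrom_sort_key(c.chrom), c.start)
    )
    tsv_path = Path(f"{prefix}.tsv")
    json_path = Path(f"{prefix}.json")
    rows = []
    for c in ordered:
        d = c.to_dict()
        row = {col: d.get(col, "") for col in _REPORT_COLUMNS}
        if isinstance(row.get("criteria_passed"), list):
            row["criteria_passed"] = ",".join(row["criteria_passed"])
        if isinstance(row.get("reasons"), list):
            row["reasons"] = ",".join(row["reasons"])
        rows.append(row)
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False, lineterminator="\n"
    )
    with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump([c.to_dict() for c in ordered], fh, indent=1)
        fh.write("\n")
    return tsv_path, json_path


def read_report_json(path: str | Path) -> list[ChromothripsisCall | PanelCall]:
    """Reload the JSON sidecar written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out: list[ChromothripsisCall | PanelCall] = []
    for d in data:
        if d.get("kind") == "panel":
            out.append(PanelCall.from_dict(d))
        else:
            out.append(ChromothripsisCall.from_dict(d))
    return out
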