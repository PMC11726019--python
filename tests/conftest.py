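import pytest

from shattercall.io import ChromSegment, DetectorParams


def make_segments(
    cns,
    chrom="11",
    seg_len=10_000_000,
    cell_fraction=0.9,
    log_ratio_per_cn=0.5,
    lengths=None,
    minor=None,
):
    """Segments with the given total-CN sequence and self-consistent tracks.

    log_ratio is a monotone function of CN so the concordance check passes
    by construction unless the caller overrides it.
    """
    segs = []
    pos = 1
    for i, cn in enumerate(cns):
        ln = lengths[i] if lengths is not None else seg_len
        segs.append(
            ChromSegment(
                chrom=chrom,
                start=pos,
                end=pos + ln - 1,
                n_marks=5,
                log_ratio=log_ratio_per_cn * (cn - 2),
                log_odds=None if minor is None else abs(cn - 2 * minor[i]) * 0.3,
                total_cn=cn,
                minor_cn=None if minor is None else minor[i],
                cell_fraction=cell_fraction,
            )
        )
        pos += ln
    return segs


@pytest.fixture
def default_params():
    return DetectorParams()
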