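"""Repeat-element contribution to exons and coding sequence.

Quantifies what fraction of a genomic feature (an exon, or a spliced CDS
mapped to the genome through its gene model) is covered by annotated repeat
elements, optionally restricted to one repeat family such as Alu. Coverage is
computed per base on the merged union of repeat intervals, so overlapping
RepeatMasker hits are never double-counted.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence, Union

from .formats import GeneModel, GenomicInterval


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as disjoint, sorted intervals (labels dropped)."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    merged: list[GenomicInterval] = []
    cur_start, cur_end = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(ivs[0].chrom, cur_start, cur_end))
    return merged


def _family_matches(label: str, family: str) -> bool:
    """Match a family filter against a 'class/family' repeat label."""
    parts = [p.lower() for p in label.split("/")]
    return family.lower() in parts or label.lower() == family.lower()


def overlap_fraction(
    feature: Union[GenomicInterval, GeneModel, Sequence[GenomicInterval]],
    repeats: Iterable[GenomicInterval],
    family_filter: Optional[str] = None,
) -> float:
    """Fraction of a feature's bases covered by (merged) repeat intervals.

    ``feature`` may be a single interval, an explicit list of intervals, or a
    GeneModel, in which case the spliced CDS (the CDS restricted to exons) is
    scored. With ``family_filter`` set, only repeats whose class/family label
    contains that family are counted; a filter matching nothing yields 0.0
    with a warning.
    """
    if isinstance(feature, GeneModel):
        pieces = feature.spliced_cds_intervals()
    elif isinstance(feature, GenomicInterval):
        pieces = [feature]
    else:
        pieces = list(feature)
    total = sum(iv.length for iv in pieces)
    if total <= 0:
        raise ValueError("feature length must be > 0")
    repeats = list(repeats)
    if family_filter is not None:
        kept = [iv for iv in repeats if _family_matches(iv.label, family_filter)]
        if repeats and not kept:
            warnings.warn(
                f"family filter {family_filter!r} matched no repeat intervals",
                stacklevel=2,
            )
        repeats = kept
    if not repeats:
        return 0.0
    merged = merge_intervals(repeats)
    covered = 0
    for piece in pieces:
        for rep in merged:
            lo = max(piece.start, rep.start)
            hi = min(piece.end, rep.end)
            if hi > lo:
                covered += hi - lo
    return covered / total
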