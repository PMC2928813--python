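"""Genomic interval bookkeeping shared by both homozygosity scans.

Intervals are 1-based and closed at both ends throughout the package; BED
input (0-based, half-open) is converted on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genotypes import natural_chrom_key


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start_bp: int
    end_bp: int
    label: str | None = None

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"interval start {self.start_bp} > end {self.end_bp} on {self.chrom}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Closed-interval intersection test (shared boundary bp counts)."""
        return (
            str(self.chrom) == str(other.chrom)
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start_bp, other.start_bp),
            min(self.end_bp, other.end_bp),
        )


@dataclass(frozen=True)
class KnownLocus:
    """A named disease locus used for exclusion testing."""

    name: str
    interval: GenomicInterval

    def __post_init__(self):
        if not self.name:
            raise ValueError("locus name must be non-empty")


def merge_touching(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals that overlap or share a boundary coordinate.

    A 1-bp gap is *not* merged: intervals must actually share at least one bp.
    Output is sorted and pairwise disjoint.
    """
    ordered = sorted(intervals, key=lambda iv: (natural_chrom_key(iv.chrom), iv.start_bp))
    out: list[GenomicInterval] = []
    for iv in ordered:
        if out and str(out[-1].chrom) == str(iv.chrom) and iv.start_bp <= out[-1].end_bp:
            prev = out.pop()
            out.append(GenomicInterval(prev.chrom, prev.start_bp,
                                       max(prev.end_bp, iv.end_bp)))
        else:
            out.append(GenomicInterval(iv.chrom, iv.start_bp, iv.end_bp))
    return out


def span_mbp(interval: GenomicInterval, decimals: int = 2, *, inclusive: bool = False) -> float:
    """Interval span in Mbp, rounded half-up.

    The default is the simple coordinate difference (end - start); the
    inclusive variant (end - start + 1) is exposed because run sizes in bp use
    it — at 2 decimals on Mbp-scale spans the two agree.
    """
    diff = interval.end_bp - interval.start_bp + (1 if inclusive else 0)
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(diff) / Decimal(10**6)).quantize(q, rounding=ROUND_HALF_UP))


def consensus(
    hh_intervals: list[GenomicInterval], ibs_intervals: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Cross-method support: intersections labelled BOTH, the rest single-method.

    Regions flagged HH_ONLY mirror loci the haplotype scan suggests but the
    full-marker shared-IBS scan rejects (and vice versa for IBS_ONLY).
    """
    out: list[GenomicInterval] = []
    hh_hit = [False] * len(hh_intervals)
    ibs_hit = [False] * len(ibs_intervals)
    for i, a in enumerate(hh_intervals):
        for j, b in enumerate(ibs_intervals):
            x = a.intersect(b)
            if x is not None:
                out.append(GenomicInterval(x.chrom, x.start_bp, x.end_bp, "BOTH"))
                hh_hit[i] = ibs_hit[j] = True
    for i, a in enumerate(hh_intervals):
        if not hh_hit[i]:
            out.append(GenomicInterval(a.chrom, a.start_bp, a.end_bp, "HH_ONLY"))
    for j, b in enumerate(ibs_intervals):
        if not ibs_hit[j]:
            out.append(GenomicInterval(b.chrom, b.start_bp, b.end_bp, "IBS_ONLY"))
    out.sort(key=lambda iv: (natural_chrom_key(iv.chrom), iv.start_bp, iv.end_bp))
    return out


# ---------------------------------------------------------------------------
# BED I/O for known loci (0-based half-open on disk, 1-based closed in memory)
# ---------------------------------------------------------------------------

def read_known_loci_bed(path) -> list[KnownLocus]:
    loci: list[KnownLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path} line {lineno}: need chrom,start,end,name")
            chrom, start, end, name = fields[:4]
            loci.append(KnownLocus(name, GenomicInterval(chrom, int(start) + 1, int(end))))
    return loci


def write_known_loci_bed(loci: list[KnownLocus], path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{locus.name}\n")


def intervals_to_frame(intervals: list[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start_bp": [iv.start_bp for iv in intervals],
            "end_bp": [iv.end_bp for iv in intervals],
            "label": [iv.label or "" for iv in intervals],
        }
    )
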