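"""Shared identical-by-state runs of homozygosity across affected samples.

The workhorse scan: find every maximal run of consecutive SNPs at which all
affected individuals are homozygous *for the same allele*, keep runs of at
least ``min_run_snps`` markers, then bridge runs separated by isolated
heterozygous calls (presumed false-heterozygote genotyping errors — a single
interrupting marker carried by at most ``bridge_max_carriers`` samples).  An
opposite-homozygote conflict or a missing call never bridges: only the error
mode actually observed on arrays (true homozygote miscalled heterozygous) is
forgiven.

Sizes in bp use the inclusive convention end - start + 1.  Run reports are
sorted by descending SNP count, ties broken by (chromosome, start bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AA, AB, BB, MISSING, GenotypePanel, natural_chrom_key
from .regions import GenomicInterval


@dataclass
class ScanConfig:
    min_run_snps: int = 35          # report runs of at least this many SNPs
    bridge_max_gap_snps: int = 1    # bridge at most this many consecutive interrupting SNPs
    bridge_max_carriers: int = 1    # ... each heterozygous in at most this many samples
    contrast_match_frac: float = 0.95  # unaffected counts as "matching" above this

    def __post_init__(self):
        if self.min_run_snps < 1:
            raise ValueError("min_run_snps must be >= 1")
        if self.bridge_max_gap_snps < 0 or self.bridge_max_carriers < 0:
            raise ValueError("bridge limits must be >= 0")


@dataclass
class SharedRun:
    """A maximal run of consecutive SNPs homozygous and IBS in all affecteds."""

    chrom: str
    start_idx: int
    end_idx: int                   # inclusive marker row indices
    start_snp: str
    end_snp: str
    start_bp: int
    end_bp: int
    n_snps: int
    size_bp: int
    alleles: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp)


@dataclass
class MergedRegion:
    """Bridged union of shared runs; SNP count covers the whole span."""

    chrom: str
    start_idx: int
    end_idx: int
    start_snp: str
    end_snp: str
    start_bp: int
    end_bp: int
    n_snps: int
    size_bp: int
    n_component_runs: int
    bridged_indices: list[int] = field(default_factory=list)
    alleles: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    not_segregating: bool = False
    unaffected_match_frac: dict[str, float] = field(default_factory=dict)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp)


def run_size_bp(run) -> int:
    """Inclusive physical size of a run: end - start + 1."""
    return int(run.end_bp) - int(run.start_bp) + 1


def _sort_runs(runs):
    runs.sort(key=lambda r: (-r.n_snps, natural_chrom_key(r.chrom), r.start_bp))
    return runs


def shared_ibs_runs(
    panel: GenotypePanel, affected_ids: list[str], config: ScanConfig | None = None
) -> list[SharedRun]:
    """All maximal runs where every affected is homozygous for one shared allele.

    A marker conforms when every affected call is AA, or every affected call is
    BB; heterozygous and missing calls both break runs (missingness is not an
    error mode this scan forgives).  Runs shorter than ``min_run_snps`` are
    dropped; output is in descending SNP count.
    """
    config = config or ScanConfig()
    if not affected_ids:
        raise ValueError("need at least one affected sample")
    cols = [panel.sample_index(s) for s in affected_ids]
    calls = panel.calls[:, cols]
    all_aa = (calls == AA).all(axis=1)
    all_bb = (calls == BB).all(axis=1)
    conforming = all_aa | all_bb
    shared_allele = np.where(all_bb, BB, AA).astype(np.int8)

    ids = panel.markers["id"].to_numpy()
    pos = panel.markers["pos_bp"].to_numpy()

    runs: list[SharedRun] = []
    for chrom, lo, hi in panel.chrom_blocks():
        i = lo
        while i < hi:
            if not conforming[i]:
                i += 1
                continue
            j = i
            while j + 1 < hi and conforming[j + 1]:
                j += 1
            n = j - i + 1
            if n >= config.min_run_snps:
                runs.append(SharedRun(
                    chrom=chrom, start_idx=i, end_idx=j,
                    start_snp=str(ids[i]), end_snp=str(ids[j]),
                    start_bp=int(pos[i]), end_bp=int(pos[j]),
                    n_snps=n, size_bp=int(pos[j]) - int(pos[i]) + 1,
                    alleles=shared_allele[i:j + 1].copy(),
                ))
            i = j + 1
    return _sort_runs(runs)


def _bridgeable(panel: GenotypePanel, cols: list[int], idx: int, max_carriers: int) -> bool:
    """True when marker ``idx`` fails the run predicate only through scattered hets."""
    row = panel.calls[idx, cols]
    if (row == MISSING).any():
        return False
    hets = int((row == AB).sum())
    if hets == 0 or hets > max_carriers:
        return False
    homs = row[row != AB]
    return homs.size == 0 or bool((homs == homs[0]).all())


def bridge_runs(
    runs: list[SharedRun],
    panel: GenotypePanel,
    affected_ids: list[str],
    config: ScanConfig | None = None,
) -> list[MergedRegion]:
    """Merge runs separated by short stretches of presumed genotyping errors.

    Two same-chromosome runs merge when the markers between them number at
    most ``bridge_max_gap_snps`` and each is non-conforming solely because at
    most ``bridge_max_carriers`` samples are heterozygous there.  Merging is
    transitive.  The merged SNP count covers the whole span (bridged markers
    included); the shared-allele vector takes the majority homozygous call at
    bridged markers.
    """
    config = config or ScanConfig()
    cols = [panel.sample_index(s) for s in affected_ids]
    ids = panel.markers["id"].to_numpy()
    pos = panel.markers["pos_bp"].to_numpy()
    for r in runs:
        if (str(ids[r.start_idx]) != r.start_snp or str(ids[r.end_idx]) != r.end_snp
                or int(pos[r.start_idx]) != r.start_bp
                or int(pos[r.end_idx]) != r.end_bp):
            raise ValueError(
                f"run {r.start_snp}..{r.end_snp} does not match this panel's markers"
            )

    ordered = sorted(runs, key=lambda r: (natural_chrom_key(r.chrom), r.start_idx))
    groups: list[list[SharedRun]] = []
    bridged: list[list[int]] = []
    for r in ordered:
        if groups:
            prev = groups[-1][-1]
            gap = list(range(prev.end_idx + 1, r.start_idx))
            if (
                r.chrom == prev.chrom
                and 0 < len(gap) <= config.bridge_max_gap_snps
                and all(_bridgeable(panel, cols, g, config.bridge_max_carriers) for g in gap)
            ):
                groups[-1].append(r)
                bridged[-1].extend(gap)
                continue
        groups.append([r])
        bridged.append([])

    merged: list[MergedRegion] = []
    for members, gaps in zip(groups, bridged):
        first, last = members[0], members[-1]
        span = np.arange(first.start_idx, last.end_idx + 1)
        alleles = np.full(len(span), AA, dtype=np.int8)
        for m in members:
            alleles[m.start_idx - first.start_idx:m.end_idx - first.start_idx + 1] = m.alleles
        for g in gaps:
            row = panel.calls[g, cols]
            homs = row[(row == AA) | (row == BB)]
            alleles[g - first.start_idx] = (
                BB if homs.size and (homs == BB).sum() > (homs == AA).sum() else AA
            )
        merged.append(MergedRegion(
            chrom=first.chrom,
            start_idx=first.start_idx, end_idx=last.end_idx,
            start_snp=first.start_snp, end_snp=last.end_snp,
            start_bp=first.start_bp, end_bp=last.end_bp,
            n_snps=last.end_idx - first.start_idx + 1,
            size_bp=last.end_bp - first.start_bp + 1,
            n_component_runs=len(members),
            bridged_indices=gaps,
            alleles=alleles,
        ))
    return _sort_runs(merged)


def contrast_unaffected(
    regions: list[MergedRegion],
    panel: GenotypePanel,
    unaffected_ids: list[str],
    *,
    min_match_frac: float = 0.95,
) -> list[MergedRegion]:
    """Flag regions where an unaffected carries the affecteds' homozygous haplotype.

    For every unaffected sample, the fraction of region markers at which it is
    homozygous for the shared allele is recorded; a fraction of at least
    ``min_match_frac`` marks the region NOT_SEGREGATING — homozygosity there
    does not co-segregate with disease status.
    """
    for region in regions:
        region.unaffected_match_frac = {}
        region.not_segregating = False
        for sid in unaffected_ids:
            col = panel.calls[region.start_idx:region.end_idx + 1, panel.sample_index(sid)]
            frac = float((col == region.alleles).mean()) if len(col) else 0.0
            region.unaffected_match_frac[sid] = frac
            if frac >= min_match_frac:
                region.not_segregating = True
    return regions


def rank_candidates(regions: list[MergedRegion]) -> pd.DataFrame:
    """Rank by descending SNP count with the outlier diagnostic ratio.

    ``ratio_to_next`` is each region's SNP count divided by the next-ranked
    region's; with no successor the ratio is reported as infinity.
    """
    ordered = _sort_runs(list(regions))
    counts = [r.n_snps for r in ordered]
    ratios = [
        counts[i] / counts[i + 1] if i + 1 < len(counts) else float("inf")
        for i in range(len(counts))
    ]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "chrom": [r.chrom for r in ordered],
            "start_snp": [r.start_snp for r in ordered],
            "end_snp": [r.end_snp for r in ordered],
            "start_bp": [r.start_bp for r in ordered],
            "end_bp": [r.end_bp for r in ordered],
            "n_snps": counts,
            "size_bp": [r.size_bp for r in ordered],
            "ratio_to_next": ratios,
            "not_segregating": [r.not_segregating for r in ordered],
        }
    )


def runs_to_frame(runs: list[SharedRun]) -> pd.DataFrame:
    """Table-1-style layout: SNPs, Chr, StartSNP, EndSNP, Start(bp), End(bp), Size(bp)."""
    return pd.DataFrame(
        {
            "SNPs": [r.n_snps for r in runs],
            "Chr": [r.chrom for r in runs],
            "StartSNP": [r.start_snp for r in runs],
            "EndSNP": [r.end_snp for r in runs],
            "Start(bp)": [r.start_bp for r in runs],
            "End(bp)": [r.end_bp for r in runs],
            "Size(bp)": [r.size_bp for r in runs],
        }
    )
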