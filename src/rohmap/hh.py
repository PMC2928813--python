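"""Homozygous-haplotype (HH) linkage scan.

A rapid non-parametric screen for autosomal-recessive loci in consanguineous
pedigrees: each affected individual is reduced to its *homozygosity haplotype*
— the ordered subset of markers at which the call is completely homozygous
(AA or BB) — and candidate regions are the maximal stretches free of
*discordance points*, markers where two affecteds are homozygous for opposite
alleles.  Heterozygous and missing calls are simply absent from the haplotype
and can neither support nor break a region, which makes the screen robust on
dense array panels.

Regions are additionally split wherever two consecutive informative markers
are further apart than ``largegap_bp`` (centromere-style gap handling), and
only regions of genetic length >= ``cutoff_cm`` are reported.  Unaffected
samples play no role in this scan; they enter only the shared-IBS contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AA, BB, GenotypePanel, natural_chrom_key
from .regions import GenomicInterval, KnownLocus


class MapInvalidError(ValueError):
    """Raised when cM positions are unusable; repair them with genetic_map first."""


@dataclass
class HHConfig:
    cutoff_cm: float = 3.0          # minimum genetic length of a reported region
    largegap_bp: int = 400_000      # split regions across larger physical gaps
    min_informative_snps: int = 1   # optional extra floor on informative markers

    def __post_init__(self):
        if self.cutoff_cm <= 0 or self.largegap_bp <= 0:
            raise ValueError("cutoff_cm and largegap_bp must be positive")


@dataclass
class HomozygosityHaplotype:
    """Per-sample ordered list of completely homozygous markers."""

    sample_id: str
    indices: np.ndarray            # global marker row indices
    alleles: np.ndarray            # call codes at those markers: AA(0) or BB(2)


@dataclass
class RCHH:
    """Region of conserved homozygosity haplotype shared among affecteds."""

    chrom: str
    start_marker: str
    end_marker: str
    start_bp: int
    end_bp: int
    genetic_length_cm: float
    n_informative_snps: int
    supporting_samples: list[str] = field(default_factory=list)
    start_idx: int = -1
    end_idx: int = -1

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp)


def homozygous_subset(panel: GenotypePanel, sample_id: str) -> HomozygosityHaplotype:
    """The subset of completely homozygous markers for one sample."""
    col = panel.calls[:, panel.sample_index(sample_id)]
    hom = (col == AA) | (col == BB)
    idx = np.flatnonzero(hom)
    return HomozygosityHaplotype(sample_id, idx, col[idx].copy())


def find_discordance_points(haps: list[HomozygosityHaplotype]) -> np.ndarray:
    """Markers where two samples are homozygous for *different* alleles."""
    if len(haps) < 2:
        return np.empty(0, dtype=np.intp)
    has_a: set[int] = set()
    has_b: set[int] = set()
    for hap in haps:
        has_a.update(hap.indices[hap.alleles == AA].tolist())
        has_b.update(hap.indices[hap.alleles == BB].tolist())
    return np.array(sorted(has_a & has_b), dtype=np.intp)


def _require_valid_cm(panel: GenotypePanel) -> np.ndarray:
    cm = panel.markers["cm"].to_numpy(dtype=float)
    if np.isnan(cm).any():
        raise MapInvalidError(
            "panel has markers with missing cM positions; run genetic_map.repair_map first"
        )
    return cm


def shared_rcch(
    panel: GenotypePanel, affected_ids: list[str], config: HHConfig | None = None
) -> list[RCHH]:
    """Candidate regions shared by all affecteds' homozygosity haplotypes.

    Maximal stretches of informative markers (homozygous in at least one
    affected) free of discordance points, split across physical gaps larger
    than ``largegap_bp``; regions shorter than ``cutoff_cm`` are dropped.
    Region boundaries sit on the outermost concordant markers — discordance
    points are excluded from the regions they delimit.
    """
    config = config or HHConfig()
    if len(affected_ids) < 2:
        raise ValueError("HH scan needs at least two affected samples")
    cm = _require_valid_cm(panel)
    pos = panel.markers["pos_bp"].to_numpy()
    ids = panel.markers["id"].to_numpy()
    chroms = panel.markers["chrom"].to_numpy()

    cols = [panel.sample_index(s) for s in affected_ids]
    calls = panel.calls[:, cols]
    a_hom = (calls == AA).any(axis=1)
    b_hom = (calls == BB).any(axis=1)
    informative = a_hom | b_hom
    discordant = a_hom & b_hom

    out: list[RCHH] = []
    for chrom, lo, hi in panel.chrom_blocks():
        run: list[int] = []

        def close() -> None:
            if len(run) >= max(1, config.min_informative_snps):
                s, e = run[0], run[-1]
                length = float(cm[e] - cm[s])
                if length >= config.cutoff_cm:
                    out.append(RCHH(
                        chrom=str(chroms[s]),
                        start_marker=str(ids[s]), end_marker=str(ids[e]),
                        start_bp=int(pos[s]), end_bp=int(pos[e]),
                        genetic_length_cm=length,
                        n_informative_snps=len(run),
                        supporting_samples=sorted(affected_ids),
                        start_idx=s, end_idx=e,
                    ))
            run.clear()

        for i in range(lo, hi):
            if not informative[i]:
                continue
            if run and pos[i] - pos[run[-1]] > config.largegap_bp:
                close()
            if discordant[i]:
                close()
                continue
            run.append(i)
        close()

    out.sort(key=lambda r: (natural_chrom_key(r.chrom), r.start_bp))
    return out


def test_known_loci(rcchs: list[RCHH], loci: list[KnownLocus]) -> pd.DataFrame:
    """Exclusion report: OVERLAPPED if any candidate region intersects a locus.

    Intersection is on closed bp intervals; an empty candidate list excludes
    every locus.
    """
    rows = []
    for locus in loci:
        hit = None
        for r in rcchs:
            if r.interval().overlaps(locus.interval):
                hit = r
                break
        rows.append({
            "locus": locus.name,
            "chrom": locus.interval.chrom,
            "start_bp": locus.interval.start_bp,
            "end_bp": locus.interval.end_bp,
            "verdict": "OVERLAPPED" if hit else "EXCLUDED",
            "overlapping_region": (
                f"{hit.chrom}:{hit.start_bp}-{hit.end_bp}" if hit else ""
            ),
        })
    return pd.DataFrame(
        rows, columns=["locus", "chrom", "start_bp", "end_bp", "verdict",
                       "overlapping_region"],
    )


def rcchs_to_frame(rcchs: list[RCHH]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in rcchs],
            "start_snp": [r.start_marker for r in rcchs],
            "end_snp": [r.end_marker for r in rcchs],
            "start_bp": [r.start_bp for r in rcchs],
            "end_bp": [r.end_bp for r in rcchs],
            "cm_length": [round(r.genetic_length_cm, 6) for r in rcchs],
            "n_snps": [r.n_informative_snps for r in rcchs],
        }
    )
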