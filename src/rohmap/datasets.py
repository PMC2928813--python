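"""Built-in fixtures: published worked-example coordinates and synthetic data.

Three kinds of objects live here:

* the run table published by the AR-CMT2 homozygosity-mapping study whose
  analysis this package reimplements (boundary SNPs and bp coordinates are
  printed inputs and are used as such);
* programmatically built synthetic panels/transcripts that reconstruct the
  *structure* of that study's findings (a chromosome-9 candidate region
  interrupted by single-sample heterozygote calls; a splice-acceptor mutation
  whose cryptic rescue deletes two exonic bases);
* the default simulation scenario — a multiply consanguineous pedigree with
  six affecteds in three sibships and a dense SNP map.

Everything synthetic is generated at call time; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import AA, AB, BB, GenotypePanel, Sample
from .regions import GenomicInterval, KnownLocus
from .simulate import PedigreeSpec, SimConfig
from .splice import PointSubstitution, TranscriptModel

# ---------------------------------------------------------------------------
# Published shared-IBS run table (worked-example input)
# ---------------------------------------------------------------------------

# (SNPs, Chr, StartSNP, EndSNP, Start(bp), End(bp), Size(bp), contiguous-block member)
_REPORTED_RUNS = [
    (378, "9", "rs2479106", "rs10123453", 125_565_033, 127_899_007, 2_333_975, True),
    (337, "9", "rs9409287", "rs7039798", 128_044_215, 129_597_047, 1_552_833, True),
    (219, "9", "rs4837971", "rs10986087", 124_289_305, 125_482_561, 1_193_257, True),
    (177, "9", "rs1324475", "rs10760198", 122_423_730, 123_650_357, 1_226_628, True),
    (146, "9", "rs10760198", "rs4837971", 123_650_357, 124_289_305, 638_949, True),
    (67, "9", "rs10123453", "rs9409287", 127_899_007, 128_044_215, 145_209, True),
    (57, "18", "rs17240415", "rs3891810", 64_801_868, 64_929_306, 127_439, False),
    (49, "21", "rs8132309", "rs363568", 29_767_744, 29_954_834, 187_091, False),
    (46, "4", "rs17353301", "rs10517306", 33_489_284, 34_049_422, 560_139, False),
    (41, "7", "rs4646450", "rs2246709", 99_104_254, 99_203_655, 99_402, False),
    (40, "9", "rs7039798", "rs10987845", 129_597_047, 129_841_977, 244_931, True),
    (37, "1", "rs6660164", "rs4310401", 80_222_072, 80_428_702, 206_631, False),
    (36, "9", "rs11787664", "rs10118040", 116_821_477, 116_919_235, 97_759, False),
    (35, "4", "rs4696998", "rs7655220", 21_588_415, 21_746_131, 157_717, False),
]

CANDIDATE_REGION = GenomicInterval("9", 122_423_730, 129_841_977, "AR-CMT2 candidate")


def reported_runs() -> pd.DataFrame:
    """The published table of all runs of >= 35 consecutive shared-IBS homozygous
    SNPs among the six affected samples, in descending SNP-count order.

    The ``contiguous`` column marks the chromosome-9 block whose members chain
    via shared boundary SNPs into the single candidate region.
    """
    return pd.DataFrame(
        _REPORTED_RUNS,
        columns=["SNPs", "Chr", "StartSNP", "EndSNP", "Start(bp)", "End(bp)",
                 "Size(bp)", "contiguous"],
    )


# ---------------------------------------------------------------------------
# Chromosome-9 candidate-region reconstruction
# ---------------------------------------------------------------------------

_BOUNDARY_SNPS = {
    122_423_730: "rs1324475",
    123_650_357: "rs10760198",
    124_289_305: "rs4837971",
    125_482_561: "rs10986087",
    125_565_033: "rs2479106",
    127_899_007: "rs10123453",
    128_044_215: "rs9409287",
    129_597_047: "rs7039798",
    129_841_977: "rs10987845",
}


def _segment_positions(start: int, end: int, n: int) -> np.ndarray:
    pos = np.linspace(start, end, n).round().astype(np.int64)
    pos[0], pos[-1] = start, end
    if np.any(np.diff(pos) <= 0):
        raise ValueError("segment too dense for integer positions")
    return pos


def chr9_candidate_panel(n_affected: int = 6) -> tuple[GenotypePanel, GenomicInterval]:
    """Reconstruct the chromosome-9 candidate region as a synthetic panel.

    The contiguous reported runs chain via shared boundary SNPs with one real
    gap (125,482,561 → 125,565,033) attributed to isolated false-heterozygote
    calls.  The panel carries every segment's SNP count, one single-sample
    heterozygous marker in the gap, and discordant flanking markers, so a
    shared-IBS scan plus bridging recovers one region spanning the published
    candidate interval.  Returns (panel, expected merged interval).
    """
    chain1 = [(122_423_730, 123_650_357, 177),
              (123_650_357, 124_289_305, 146),
              (124_289_305, 125_482_561, 219)]
    chain2 = [(125_565_033, 127_899_007, 378),
              (127_899_007, 128_044_215, 67),
              (128_044_215, 129_597_047, 337),
              (129_597_047, 129_841_977, 40)]

    def chain_positions(segs):
        parts = [_segment_positions(*segs[0])]
        parts += [_segment_positions(*s)[1:] for s in segs[1:]]
        return np.concatenate(parts)

    left_flank = np.array([122_300_000, 122_350_000, 122_400_000], dtype=np.int64)
    gap_marker = np.array([125_523_000], dtype=np.int64)
    right_flank = np.array([129_900_000, 129_950_000, 130_000_000], dtype=np.int64)
    pos = np.concatenate([left_flank, chain_positions(chain1), gap_marker,
                          chain_positions(chain2), right_flank])

    ids = [
        _BOUNDARY_SNPS.get(int(p), f"sim9_{k:05d}") for k, p in enumerate(pos)
    ]
    markers = pd.DataFrame({
        "id": ids, "chrom": "9", "pos_bp": pos,
        "cm": pos / 1e6, "maf": 0.3,
    })
    samples = [Sample(id=f"aff{i + 1}", status="affected") for i in range(n_affected)]

    calls = np.full((len(pos), n_affected), AA, dtype=np.int8)
    flank_rows = np.concatenate([np.arange(3), np.arange(len(pos) - 3, len(pos))])
    calls[flank_rows, 0] = AA
    calls[flank_rows, 1] = BB          # opposite homozygote: a discordance point
    gap_row = 3 + len(chain_positions(chain1))
    assert pos[gap_row] == 125_523_000
    calls[gap_row, 0] = AB             # the lone presumed false heterozygote

    panel = GenotypePanel(markers, samples, calls)
    return panel, CANDIDATE_REGION


# ---------------------------------------------------------------------------
# Toy acceptor-mutation transcript (synthetic stand-in for the real gene models)
# ---------------------------------------------------------------------------

def toy_acceptor_transcript(strand: str = "+") -> tuple[TranscriptModel, PointSubstitution]:
    """A small synthetic 4-exon transcript mirroring the studied mutation class.

    The penultimate exon begins with AG, and the supplied substitution destroys
    the acceptor AG of the intron preceding it (AG→AA).  The nearest cryptic
    acceptor therefore removes two exonic bases — an obligatory frameshift.
    Synthetic sequence; not the real disease gene.
    """
    exon1 = "GGGATGGCTGCTAAAGAAGCTACT"        # 5'UTR GGG + 7 codons
    intron1 = "GTAAGTCTCTTTCTTTCTTTCCAG"
    exon2 = "GATCTTGGAATTCTTGCGGTT"           # 7 codons
    intron2 = "GTGAGTAAACTTTCTTTCCTTTCAG"
    exon3 = "AGGTTTGACGCTGCAGCAGTT"           # penultimate exon, begins AG; 7 codons
    intron3 = "GTAAGATTTTCTCTCTTTTACAG"
    exon4 = "GCTGCAGCTGTTTAATAGATAGATAGA"     # 4 codons + TAA stop + 3'UTR

    seq = exon1 + intron1 + exon2 + intron2 + exon3 + intron3 + exon4
    starts, exons = 1, []
    for part in (exon1, intron1, exon2, intron2, exon3, intron3, exon4):
        exons.append((starts, starts + len(part) - 1))
        starts += len(part)
    exon_ivs = [exons[0], exons[2], exons[4], exons[6]]
    cds_start = 4                                        # the A of ATG
    cds_end = exon_ivs[3][0] + 15 - 1                    # last base of the TAA stop
    mut_pos = exon_ivs[2][0] - 1                         # terminal G of intron 2

    if strand == "+":
        tx = TranscriptModel("toytx1", "toychr", "+", exon_ivs, cds_start, cds_end, seq)
        mut = PointSubstitution(mut_pos, "G", "A")
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        L = len(seq)
        rc = "".join(comp[b] for b in reversed(seq))
        flip = lambda s, e: (L - e + 1, L - s + 1)
        tx = TranscriptModel(
            "toytx1", "toychr", "-",
            [flip(s, e) for s, e in reversed(exon_ivs)],
            *sorted(flip(cds_start, cds_end)), rc,
        )
        mut = PointSubstitution(L - mut_pos + 1, "C", "T")
    return tx, mut


# ---------------------------------------------------------------------------
# Default simulation scenario
# ---------------------------------------------------------------------------

def demo_pedigree() -> PedigreeSpec:
    """A multiply consanguineous pedigree: one ancestral couple, three
    first-cousin matings, six affecteds in three sibships plus unaffected
    sibs and carrier parents — the structure homozygosity mapping exploits."""
    S = Sample
    members = [
        S("gf1", sex="male"), S("gm1", sex="female"),
        S("d1", sex="female"), S("d2", sex="male"), S("d3", sex="female"),
        S("c1", "gf1", "gm1", "male"), S("c2", "gf1", "gm1", "female"),
        S("c3", "gf1", "gm1", "male"),
        S("e1", "c1", "d1", "male", "unaffected"),
        S("e2", "c1", "d1", "male", "unaffected"),
        S("e3", "d2", "c2", "female", "unaffected"),
        S("e4", "d2", "c2", "female", "unaffected"),
        S("e5", "c3", "d3", "female", "unaffected"),
        S("e6", "c3", "d3", "male", "unaffected"),
        S("s1", "e1", "e3", "male", "affected"),
        S("s2", "e1", "e3", "female", "affected"),
        S("u1", "e1", "e3", "male", "unaffected"),
        S("s3", "e2", "e5", "male", "affected"),
        S("s4", "e2", "e5", "female", "affected"),
        S("u2", "e2", "e5", "female", "unaffected"),
        S("s5", "e6", "e4", "male", "affected"),
        S("s6", "e6", "e4", "female", "affected"),
        S("u3", "e6", "e4", "male", "unaffected"),
    ]
    return PedigreeSpec(members, ["s1", "s2", "s3", "s4", "s5", "s6"])


_PANEL_SEED = 424242   # fixes the marker panel itself (positions, frequencies)


def default_marker_map(
    n_chr9: int = 5000, n_other: int = 1500, chr9_cm: float = 100.0
) -> pd.DataFrame:
    """Dense SNP map: the causal chromosome plus two background chromosomes.

    Chromosome 9 carries ``n_chr9`` markers over ``chr9_cm`` cM (default
    0.02 cM spacing, array-like density at the scale run detection needs);
    per-marker B-allele frequencies are drawn once from U(0.05, 0.5) with a
    fixed internal seed so the panel is a constant of the scenario.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    frames = []
    for chrom, n, total_cm, bp0, step in [
        ("1", n_other, 75.0, 1_000_000, 20_000),
        ("2", n_other, 75.0, 1_000_000, 20_000),
        ("9", n_chr9, chr9_cm, 1_000_000, 25_000),
    ]:
        frames.append(pd.DataFrame({
            "id": [f"s{chrom}_{i:05d}" for i in range(n)],
            "chrom": chrom,
            "pos_bp": bp0 + step * np.arange(n, dtype=np.int64),
            "cm": np.linspace(0.0, total_cm, n),
            "maf": rng.uniform(0.05, 0.5, size=n).round(4),
        }))
    return pd.concat(frames, ignore_index=True)


def default_sim_config(seed: int, markers: pd.DataFrame | None = None,
                       **overrides) -> SimConfig:
    """The standard simulation scenario: causal locus mid-chromosome-9,
    shared tract of at least 300 markers, false-heterozygote rate 5e-4.

    The default error model emulates the mode actually reported on the study
    array — isolated false-heterozygote calls — so ``missing_rate`` is 0;
    raise it to probe robustness to no-calls (which break runs and are never
    bridged)."""
    markers = default_marker_map() if markers is None else markers
    kwargs = dict(
        seed=seed,
        markers=markers,
        founder_freqs=markers["maf"].to_numpy(),
        causal_chrom="9",
        causal_founder="gf1",
        target_region_snps=300,
        het_error_rate=5e-4,
        missing_rate=0.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def synthetic_known_loci() -> list[KnownLocus]:
    """23 synthetic placeholder disease loci for exclusion testing.

    Stand-ins for the known CMT subtype loci (real coordinates are genome-
    build-dependent and deliberately not shipped); names are placeholders.
    """
    loci = []
    spots = [
        ("1", 5), ("2", 5), ("9", 2),            # on simulated chromosomes
        ("3", 2), ("5", 2), ("7", 1), ("8", 1),  # off-panel: trivially excluded
        ("10", 1), ("11", 1), ("12", 1), ("16", 1), ("17", 1),
    ]
    k = 0
    for chrom, n in spots:
        for j in range(n):
            k += 1
            if chrom in ("1", "2"):
                start = 2_000_000 + j * 6_000_000
            elif chrom == "9":
                start = 2_000_000 if j == 0 else 110_000_000   # away from mid-chromosome
            else:
                start = 10_000_000 + j * 5_000_000
            loci.append(KnownLocus(
                f"LOCUS{k:02d}", GenomicInterval(chrom, start, start + 2_000_000)
            ))
    assert len(loci) == 23
    return loci
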