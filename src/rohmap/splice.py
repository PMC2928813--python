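"""Splice-acceptor mutation consequence annotation.

Models the canonical failure mode of an intronic acceptor-site point mutation:
the terminal AG of an intron is destroyed (e.g. AG→AA), the spliceosome falls
back to the nearest downstream AG (a cryptic acceptor, often only a few bases
into the exon), and the resulting junction deletes a handful of exonic bases
from the mature mRNA.  When the deletion length is not a multiple of three the
reading frame shifts and the protein truncates at the first downstream stop.

The model is deliberately minimal: the AG dinucleotide is the sole acceptor
determinant (no branch point, polypyrimidine tract, or splice-strength
scoring), and the nearest downstream AG wins.  Minus-strand transcripts are
reverse-complemented into a transcript-forward frame before analysis; all
offsets are reported in transcript coordinates.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

NO_CRYPTIC = "NO_CRYPTIC"


class SpliceInputError(ValueError):
    pass


@dataclass(frozen=True)
class PointSubstitution:
    """A genomic single-base substitution, plus-strand coordinates and bases."""

    pos: int        # 1-based genomic coordinate
    ref: str
    alt: str


@dataclass
class SpliceConsequence:
    disrupted_intron_index: int | None
    cryptic_offset_nt: int | None       # exonic bases removed by the aberrant junction
    deleted_nt: int
    is_frameshift: bool
    ref_protein_len_aa: int
    mut_protein_len_aa: int
    intact_prefix_aa: int
    stop_lost: bool = False
    status: str = "OK"                  # OK / NO_CRYPTIC / NO_DISRUPTION


@dataclass
class TranscriptModel:
    """Exon/CDS structure over a genomic sequence window.

    ``exons`` are 1-based closed genomic intervals in ascending genomic order;
    ``seq`` is the plus-strand genomic sequence starting at ``seq_start``.
    Transcript-forward views (attributes prefixed ``tf_``) are derived at
    construction so the splice logic is strand-agnostic.
    """

    tx_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    seq: str
    seq_start: int = 1

    tf_seq: str = field(init=False, repr=False)
    tf_exons: list[tuple[int, int]] = field(init=False, repr=False)
    tf_cds: tuple[int, int] = field(init=False, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise SpliceInputError(f"strand must be + or -, got {self.strand!r}")
        self.seq = self.seq.upper()
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise SpliceInputError("exons overlap or touch")
        span_end = self.seq_start + len(self.seq) - 1
        if self.exons[0][0] < self.seq_start or self.exons[-1][1] > span_end:
            raise SpliceInputError("exons fall outside the supplied sequence")
        self._build_tf()
        self._validate_reference()

    # -- coordinate transforms -------------------------------------------
    def _g2tf(self, g: int) -> int:
        if self.strand == "+":
            return g - self.seq_start
        return (self.seq_start + len(self.seq) - 1) - g

    def _build_tf(self) -> None:
        if self.strand == "+":
            self.tf_seq = self.seq
            self.tf_exons = [(s - self.seq_start, e - self.seq_start) for s, e in self.exons]
        else:
            self.tf_seq = str(Seq(self.seq).reverse_complement())
            self.tf_exons = [
                (self._g2tf(e), self._g2tf(s)) for s, e in reversed(self.exons)
            ]
        a, b = self._g2tf(self.cds_start), self._g2tf(self.cds_end)
        self.tf_cds = (min(a, b), max(a, b))

    # -- derived structure ------------------------------------------------
    @property
    def n_introns(self) -> int:
        return len(self.tf_exons) - 1

    def intron_acceptor_tf(self, i: int) -> tuple[int, int]:
        """Transcript-forward positions of intron i's terminal AG dinucleotide."""
        if not 0 <= i < self.n_introns:
            raise SpliceInputError(f"intron index {i} out of range")
        nxt = self.tf_exons[i + 1][0]
        return (nxt - 2, nxt - 1)

    def mrna(self) -> str:
        return "".join(self.tf_seq[s:e + 1] for s, e in self.tf_exons)

    def _mrna_offsets(self) -> list[int]:
        offs, total = [], 0
        for s, e in self.tf_exons:
            offs.append(total)
            total += e - s + 1
        return offs

    def tf_to_mrna(self, p: int) -> int:
        for (s, e), off in zip(self.tf_exons, self._mrna_offsets()):
            if s <= p <= e:
                return off + (p - s)
        raise SpliceInputError(f"transcript-forward position {p} is intronic")

    def cds_mrna_span(self) -> tuple[int, int]:
        return self.tf_to_mrna(self.tf_cds[0]), self.tf_to_mrna(self.tf_cds[1])

    def _validate_reference(self) -> None:
        for i in range(self.n_introns):
            a0, a1 = self.intron_acceptor_tf(i)
            if a0 < 0 or self.tf_seq[a0:a1 + 1] != "AG":
                raise SpliceInputError(
                    f"reference intron {i} of {self.tx_id} does not end in AG "
                    f"(found {self.tf_seq[a0:a1 + 1]!r})"
                )
        c0, c1 = self.cds_mrna_span()
        if (c1 - c0 + 1) % 3 != 0:
            raise SpliceInputError(f"reference CDS length of {self.tx_id} not divisible by 3")

    def ref_protein_len_aa(self) -> int:
        c0, c1 = self.cds_mrna_span()
        return (c1 - c0 + 1) // 3 - 1   # minus the stop codon


# ---------------------------------------------------------------------------
# The three analysis steps
# ---------------------------------------------------------------------------

def check_acceptor_disruption(tx: TranscriptModel, mut: PointSubstitution) -> int | None:
    """Index of the intron whose acceptor AG the mutation destroys, else None.

    Donor sites and exonic substitutions return None: only acceptor disruption
    is modelled.
    """
    span_end = tx.seq_start + len(tx.seq) - 1
    if not tx.seq_start <= mut.pos <= span_end:
        raise SpliceInputError(f"mutation position {mut.pos} outside transcript span")
    if tx.seq[mut.pos - tx.seq_start] != mut.ref.upper():
        raise SpliceInputError(
            f"ref mismatch at {tx.chrom}:{mut.pos}: sequence has "
            f"{tx.seq[mut.pos - tx.seq_start]!r}, substitution says {mut.ref.upper()!r}"
        )
    p = tx._g2tf(mut.pos)
    alt = mut.alt.upper() if tx.strand == "+" else str(Seq(mut.alt.upper()).complement())
    for i in range(tx.n_introns):
        a0, a1 = tx.intron_acceptor_tf(i)
        if p in (a0, a1):
            dinuc = list(tx.tf_seq[a0:a1 + 1])
            dinuc[p - a0] = alt
            if "".join(dinuc) != "AG":
                return i
    return None


def next_cryptic_acceptor(
    tx: TranscriptModel, intron_index: int, *, window_nt: int = 200
) -> int | None:
    """Exonic bases removed by falling back to the nearest downstream AG.

    Scans the exon following the disrupted intron for the first AG within
    ``window_nt``; the aberrant junction lands immediately 3' of that AG, so
    an exon beginning ``AG...`` gives offset 2.  Returns None (NO_CRYPTIC)
    when no AG exists in the window.
    """
    s, e = tx.tf_exons[intron_index + 1]
    exon_seq = tx.tf_seq[s:e + 1][:window_nt]
    p = exon_seq.find("AG")
    if p == -1:
        return None
    return p + 2


def apply_aberrant_splice(
    tx: TranscriptModel, intron_index: int, offset_nt: int
) -> SpliceConsequence:
    """Consequence of deleting ``offset_nt`` exonic bases at the given junction.

    Builds the mutant mature CDS, translates from the reference start codon to
    the first in-frame stop, and reports frame, truncation and the intact
    amino-acid prefix (codons fully 5' of the junction).
    """
    if offset_nt < 0:
        raise SpliceInputError("offset must be >= 0")
    s, e = tx.tf_exons[intron_index + 1]
    if offset_nt > e - s + 1:
        raise SpliceInputError(
            f"offset {offset_nt} exceeds exon length {e - s + 1}"
        )
    mrna = tx.mrna()
    junction = tx.tf_to_mrna(s)
    c0, c1 = tx.cds_mrna_span()
    if junction < c0:
        raise SpliceInputError("junction upstream of the start codon is not modelled")

    mutant = mrna[:junction] + mrna[junction + offset_nt:]
    coding = mutant[c0:]
    coding = coding[: len(coding) - len(coding) % 3]
    prot = str(Seq(coding).translate())
    stop_at = prot.find("*")
    stop_lost = stop_at == -1
    mut_len = len(prot) if stop_lost else stop_at

    ref_len = tx.ref_protein_len_aa()
    return SpliceConsequence(
        disrupted_intron_index=intron_index,
        cryptic_offset_nt=offset_nt,
        deleted_nt=offset_nt,
        is_frameshift=offset_nt % 3 != 0,
        ref_protein_len_aa=ref_len,
        mut_protein_len_aa=mut_len,
        intact_prefix_aa=min((junction - c0) // 3, mut_len),
        stop_lost=stop_lost,
        status="OK",
    )


def annotate_substitution(
    tx: TranscriptModel, mut: PointSubstitution, *, window_nt: int = 200
) -> SpliceConsequence:
    """Full pipeline: disruption check → cryptic acceptor → consequence."""
    i = check_acceptor_disruption(tx, mut)
    ref_len = tx.ref_protein_len_aa()
    if i is None:
        return SpliceConsequence(None, None, 0, False, ref_len, ref_len, ref_len,
                                 status="NO_DISRUPTION")
    offset = next_cryptic_acceptor(tx, i, window_nt=window_nt)
    if offset is None:
        return SpliceConsequence(i, None, 0, False, ref_len, ref_len, ref_len,
                                 status=NO_CRYPTIC)
    return apply_aberrant_splice(tx, i, offset)


# ---------------------------------------------------------------------------
# GFF3-lite + FASTA I/O
# ---------------------------------------------------------------------------

def read_transcript(gff_path, fasta_path, tx_id: str | None = None) -> TranscriptModel:
    """Load exon/CDS features (GFF3) and genomic sequence (FASTA) for one transcript."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", force=True,
        keep_order=True,
    )
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    chrom = strand = parent = None
    for feat in db.all_features(order_by="start"):
        fparent = feat.attributes.get("Parent", [feat.id])[0]
        if tx_id is not None and fparent != tx_id:
            continue
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if parent is None:
            parent, chrom, strand = fparent, feat.seqid, feat.strand
        elif fparent != parent:
            raise SpliceInputError(
                f"multiple transcripts in {gff_path}; pass tx_id explicitly"
            )
        (exons if feat.featuretype == "exon" else cds).append((feat.start, feat.end))
    if not exons or not cds:
        raise SpliceInputError(f"no exon/CDS features found for {tx_id or 'transcript'}")

    record = next(
        (r for r in SeqIO.parse(str(fasta_path), "fasta") if r.id == chrom), None
    )
    if record is None:
        raise SpliceInputError(f"sequence {chrom!r} not found in {fasta_path}")
    return TranscriptModel(
        tx_id=parent, chrom=chrom, strand=strand, exons=exons,
        cds_start=min(s for s, _ in cds), cds_end=max(e for _, e in cds),
        seq=str(record.seq), seq_start=1,
    )


def write_transcript(tx: TranscriptModel, gff_path, fasta_path) -> None:
    """Emit a transcript as GFF3-lite + FASTA (used for fixtures and the CLI)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, (s, e) in enumerate(tx.exons, start=1):
            fh.write(
                f"{tx.chrom}\ttoy\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID=exon{k};Parent={tx.tx_id}\n"
            )
        fh.write(
            f"{tx.chrom}\ttoy\tCDS\t{tx.cds_start}\t{tx.cds_end}\t.\t{tx.strand}\t0\t"
            f"ID=cds1;Parent={tx.tx_id}\n"
        )
    with open(fasta_path, "w") as fh:
        fh.write(f">{tx.chrom}\n")
        for i in range(0, len(tx.seq), 60):
            fh.write(tx.seq[i:i + 60] + "\n")


def consequence_report(tx: TranscriptModel, mut: PointSubstitution,
                       result: SpliceConsequence) -> str:
    """Human-readable consequence summary."""
    lines = [
        f"transcript {tx.tx_id} ({tx.chrom}, strand {tx.strand}, "
        f"{len(tx.exons)} exons)",
        f"substitution {tx.chrom}:{mut.pos} {mut.ref}>{mut.alt}",
        f"status: {result.status}",
    ]
    if result.status == "OK":
        lines += [
            f"disrupted acceptor: intron {result.disrupted_intron_index + 1} "
            f"(1-based) AG destroyed",
            f"cryptic acceptor: {result.cryptic_offset_nt} exonic nt removed at the junction",
            f"frameshift: {'yes' if result.is_frameshift else 'no'}"
            + (" (stop lost)" if result.stop_lost else ""),
            f"protein: {result.mut_protein_len_aa} aa (reference "
            f"{result.ref_protein_len_aa} aa), intact prefix "
            f"{result.intact_prefix_aa} aa",
        ]
    return "\n".join(lines) + "\n"
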