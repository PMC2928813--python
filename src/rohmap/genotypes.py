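"""Pedigree SNP genotype panels and PLINK-style text I/O.

Genotypes are held in platform-neutral AB coding (``AA``/``AB``/``BB``/missing),
the format emitted by SNP-array calling software and the one used for all
run-of-homozygosity logic downstream.  Internally calls are small integers:

====  ========
code  meaning
====  ========
 0    AA (homozygous for the A allele)
 1    AB (heterozygous; unordered, BA normalises to AB)
 2    BB
-1    missing / no-call
====  ========

Markers live in a :class:`pandas.DataFrame` with columns
``id, chrom, pos_bp, cm, maf`` sorted by (natural chromosome order, position);
coordinates are 1-based and positions are strictly increasing within a
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

CALL_LABELS = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}
LABEL_CALLS["BA"] = AB

MARKER_COLUMNS = ["id", "chrom", "pos_bp", "cm", "maf"]


class GenotypeError(ValueError):
    """Base class for panel parsing/validation failures."""


class PanelParseError(GenotypeError):
    pass


class PanelValidationError(GenotypeError):
    pass


def natural_chrom_key(chrom) -> tuple:
    """Sort key placing numeric chromosomes first (1..22), then labels (X, Y, MT)."""
    s = str(chrom)
    body = s[3:] if s.lower().startswith("chr") else s
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


@dataclass(frozen=True)
class Sample:
    """One pedigree member; parent ids refer to samples in the same panel."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"          # male / female / unknown
    status: str = "unknown"       # affected / unaffected / unknown

    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class GenotypePanel:
    """Ordered markers x samples matrix of AB-coded calls with pedigree metadata."""

    markers: pd.DataFrame
    samples: list[Sample] = field(default_factory=list)
    calls: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int8))

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def affected_ids(self) -> list[str]:
        return [s.id for s in self.samples if s.status == "affected"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [s.id for s in self.samples if s.status == "unaffected"]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.id == sample_id:
                return i
        raise KeyError(f"unknown sample id: {sample_id!r}")

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous (chrom, start_row, stop_row) blocks, stop exclusive."""
        blocks: list[tuple[str, int, int]] = []
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append((str(chroms[start]), start, i))
                start = i
        return blocks

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        m = self.markers
        missing_cols = [c for c in MARKER_COLUMNS if c not in m.columns]
        if missing_cols:
            raise PanelValidationError(f"marker table lacks columns: {missing_cols}")
        if self.calls.shape != (len(m), len(self.samples)):
            raise PanelValidationError(
                f"calls matrix {self.calls.shape} does not match "
                f"{len(m)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, [AA, AB, BB, MISSING])
        if bad.any():
            raise PanelValidationError(
                f"invalid call codes at {int(bad.sum())} cells (allowed: -1,0,1,2)"
            )
        if m["id"].duplicated().any():
            dups = m.loc[m["id"].duplicated(), "id"].tolist()
            raise PanelValidationError(f"duplicate marker ids: {dups[:5]}")
        if (m["pos_bp"] < 1).any():
            raise PanelValidationError("marker positions must be >= 1 (1-based)")
        self._check_sorted(m)
        self._check_pedigree()

    @staticmethod
    def _check_sorted(m: pd.DataFrame) -> None:
        keys = [natural_chrom_key(c) for c in m["chrom"]]
        pos = m["pos_bp"].to_numpy()
        for i in range(1, len(m)):
            if keys[i] < keys[i - 1]:
                raise PanelValidationError(
                    f"markers not sorted by chromosome near row {i} "
                    f"({m['id'].iloc[i - 1]!r}, {m['id'].iloc[i]!r})"
                )
            if keys[i] == keys[i - 1] and pos[i] <= pos[i - 1]:
                raise PanelValidationError(
                    "marker positions not strictly increasing within chromosome "
                    f"{m['chrom'].iloc[i]}: {m['id'].iloc[i - 1]!r} (bp {pos[i - 1]}) vs "
                    f"{m['id'].iloc[i]!r} (bp {pos[i]})"
                )

    def _check_pedigree(self) -> None:
        ids = set(self.sample_ids)
        if len(ids) != len(self.samples):
            raise PanelValidationError("duplicate sample ids")
        parent = {}
        for s in self.samples:
            for pid in (s.father_id, s.mother_id):
                if pid is not None and pid not in ids:
                    raise PanelValidationError(
                        f"sample {s.id!r} references unknown parent {pid!r}"
                    )
            parent[s.id] = [p for p in (s.father_id, s.mother_id) if p is not None]
        # no individual is its own ancestor
        state: dict[str, int] = {}

        def visit(u: str) -> None:
            state[u] = 1
            for p in parent[u]:
                st = state.get(p, 0)
                if st == 1:
                    raise PanelValidationError(f"pedigree cycle involving {u!r}")
                if st == 0:
                    visit(p)
            state[u] = 2

        for sid in parent:
            if state.get(sid, 0) == 0:
                visit(sid)

    # -- helpers ---------------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "GenotypePanel":
        cols = [self.sample_index(s) for s in sample_ids]
        keep = [replace(self.samples[c], father_id=None, mother_id=None) for c in cols]
        return GenotypePanel(self.markers.copy(), keep, self.calls[:, cols].copy())


# ---------------------------------------------------------------------------
# PLINK-style .ped/.map text dialect
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_PHENO = {"2": "affected", "1": "unaffected"}
_PHENO_OUT = {"affected": "2", "unaffected": "1", "unknown": "0"}


def _read_map(map_path) -> pd.DataFrame:
    try:
        m = pd.read_csv(
            map_path, sep=r"\s+", header=None,
            names=["chrom", "id", "cm", "pos_bp"],
            dtype={"chrom": str, "id": str, "cm": float, "pos_bp": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise PanelParseError(f"malformed .map file {map_path}: {exc}") from exc
    m["maf"] = np.nan
    return m[MARKER_COLUMNS]


def _sort_order(markers: pd.DataFrame) -> np.ndarray:
    keys = [(natural_chrom_key(c), p) for c, p in zip(markers["chrom"], markers["pos_bp"])]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.intp)


def _check_unique_positions(markers: pd.DataFrame) -> None:
    dup = markers.duplicated(subset=["chrom", "pos_bp"], keep=False)
    if dup.any():
        pairs = markers.loc[dup, ["id", "chrom", "pos_bp"]]
        raise PanelValidationError(
            "markers share a chromosome/position: "
            + "; ".join(f"{r.id}@{r.chrom}:{r.pos_bp}" for r in pairs.itertuples())
        )


def read_panel(ped_path, map_path) -> GenotypePanel:
    """Read a whitespace-delimited .ped/.map pair into a validated panel.

    Allele pairs are mapped to AB coding per marker: the lexicographically
    smaller observed allele is A, except that files already written in literal
    A/B letters map identically (so write → read round-trips).  ``0`` alleles
    denote missing calls.
    """
    markers = _read_map(map_path)
    if markers["id"].duplicated().any():
        dups = markers.loc[markers["id"].duplicated(), "id"].tolist()
        raise PanelValidationError(f"duplicate marker ids in .map: {dups[:5]}")
    _check_unique_positions(markers)
    n_mark = len(markers)

    samples: list[Sample] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_mark:
                raise PanelParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_mark} fields "
                    f"(6 + 2x{n_mark} markers), found {len(fields)}"
                )
            _fam, ind, father, mother, sex, pheno = fields[:6]
            samples.append(Sample(
                id=ind,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX.get(sex, "unknown"),
                status=_PHENO.get(pheno, "unknown"),
            ))
            rows.append(fields[6:])

    calls = np.full((n_mark, len(samples)), MISSING, dtype=np.int8)
    for j in range(n_mark):
        observed: set[str] = set()
        for alleles in rows:
            for a in (alleles[2 * j], alleles[2 * j + 1]):
                if a != "0":
                    observed.add(a)
        if len(observed) > 2:
            raise PanelValidationError(
                f"marker {markers['id'].iloc[j]!r} has >2 alleles: {sorted(observed)}"
            )
        if observed and observed <= {"A", "B"}:
            b_allele = "B"        # AB-letter files map identically (round-trip)
        else:
            b_allele = max(observed) if len(observed) == 2 else None
        for i, alleles in enumerate(rows):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[j, i] = (a1 == b_allele) + (a2 == b_allele)

    order = _sort_order(markers)
    return GenotypePanel(markers.iloc[order], samples, calls[order, :])


def write_panel(panel: GenotypePanel, ped_path, map_path) -> None:
    """Write panel as .ped/.map; round-trips calls, marker order, pedigree fields.

    AB codes are emitted as allele letters A/B, missing as ``0 0``.  Genetic
    positions that are NaN are written as 0 (the .map dialect has no blank cM).
    """
    if panel.n_samples == 0:
        raise GenotypeError("refusing to write a panel with no samples")
    m = panel.markers
    with open(map_path, "w") as fh:
        for r in m.itertuples():
            cm = 0.0 if pd.isna(r.cm) else r.cm
            fh.write(f"{r.chrom}\t{r.id}\t{cm:g}\t{r.pos_bp}\n")
    pair = {AA: "A A", AB: "A B", BB: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            lead = [
                "FAM1", s.id, s.father_id or "0", s.mother_id or "0",
                _SEX_OUT.get(s.sex, "0"), _PHENO_OUT.get(s.status, "0"),
            ]
            geno = " ".join(pair[int(c)] for c in panel.calls[:, i])
            fh.write(" ".join(lead) + " " + geno + "\n")


# ---------------------------------------------------------------------------
# Marker annotation table (rsID, chrom, bp, cM, MAF)
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read a marker annotation TSV with columns snp, chrom, pos_bp, cm, maf.

    Invalid genetic positions (empty cells, zeros, non-monotone values) are
    preserved as-is for downstream interpolation — flagged there, not silently
    fixed here.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp", "chrom", "pos_bp", "cm", "maf"}
    missing = required - set(table.columns)
    if missing:
        raise PanelParseError(
            f"annotation {path} lacks required columns: {sorted(missing)}"
        )
    table = table.rename(columns={"snp": "id"})[MARKER_COLUMNS]
    table["pos_bp"] = table["pos_bp"].astype(np.int64)
    table["cm"] = pd.to_numeric(table["cm"], errors="coerce")
    _check_unique_positions(table)
    order = _sort_order(table)
    return table.iloc[order].reset_index(drop=True)


def write_annotation(markers: pd.DataFrame, path, repaired: np.ndarray | None = None) -> None:
    out = markers.rename(columns={"id": "snp"}).copy()
    if repaired is not None:
        out["repaired"] = np.asarray(repaired).astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSV genotype matrix alternative (markers x samples, cells AA/AB/BB/NA)
# ---------------------------------------------------------------------------

def read_matrix(genotype_tsv, pedigree_tsv, annotation_tsv) -> GenotypePanel:
    """Read the simple TSV exchange format: genotype matrix + pedigree + annotation."""
    markers = read_annotation(annotation_tsv)
    ped = pd.read_csv(pedigree_tsv, sep="\t", dtype=str).fillna("")
    samples = [
        Sample(
            id=r["id"],
            father_id=r.get("father_id") or None,
            mother_id=r.get("mother_id") or None,
            sex=r.get("sex") or "unknown",
            status=r.get("status") or "unknown",
        )
        for _, r in ped.iterrows()
    ]
    g = pd.read_csv(genotype_tsv, sep="\t", index_col=0, dtype=str,
                    keep_default_na=False)   # "NA" is a genotype label here
    g = g.reindex(index=markers["id"], columns=[s.id for s in samples])
    if g.isna().any().any():
        raise PanelParseError("genotype matrix does not cover all markers/samples")
    try:
        calls = g.map(lambda v: LABEL_CALLS[v]).to_numpy(dtype=np.int8)
    except KeyError as exc:
        raise PanelParseError(f"invalid genotype label {exc} in matrix") from exc
    return GenotypePanel(markers, samples, calls)


def write_matrix(panel: GenotypePanel, genotype_tsv, pedigree_tsv, annotation_tsv) -> None:
    write_annotation(panel.markers, annotation_tsv)
    pd.DataFrame(
        {
            "id": [s.id for s in panel.samples],
            "father_id": [s.father_id or "" for s in panel.samples],
            "mother_id": [s.mother_id or "" for s in panel.samples],
            "sex": [s.sex for s in panel.samples],
            "status": [s.status for s in panel.samples],
        }
    ).to_csv(pedigree_tsv, sep="\t", index=False)
    g = pd.DataFrame(
        [[CALL_LABELS[int(c)] for c in row] for row in panel.calls],
        index=panel.markers["id"],
        columns=[s.id for s in panel.samples],
    )
    g.to_csv(genotype_tsv, sep="\t")
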