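"""Gene-dropping simulator for consanguineous pedigrees.

Generates SNP-panel genotypes for a pedigree with an implanted autozygous
causal region, so every pipeline stage is testable without external data.
Founder haplotypes carry independent per-marker alleles at configurable B
frequencies; one designated founder haplotype carries the causal allele.
Transmission follows the Haldane (no-interference) crossover model: between
adjacent markers at map distance d Morgans the recombination fraction is
(1 - exp(-2d))/2, and each meiosis's inheritance indicator is a two-state
Markov chain along the chromosome.

Autozygosity conditioning is by rejection: inheritance bits at the causal
marker are rejection-sampled (vectorised, cheap per attempt) until every
designated affected is homozygous by descent for the causal haplotype there,
and the accepted single-locus drop is then extended left and right along the
chromosome with the same Markov transitions.  Because a full gene drop
factorises into the bits at one locus times conditionally independent
extensions, this is distribution-identical to rejecting whole drops — just
feasible when the joint autozygosity event is rare.

The genotyping-error model is one-directional, mirroring the error mode seen
on arrays: a truly homozygous call is emitted heterozygous with probability
``het_error_rate``; any call drops out with probability ``missing_rate``.
Heterozygous truth is never converted to homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AB, MISSING, GenotypePanel, Sample, natural_chrom_key


class SimulationError(RuntimeError):
    pass


@dataclass
class PedigreeSpec:
    members: list[Sample]
    designated_affecteds: list[str]

    def __post_init__(self):
        ids = {s.id for s in self.members}
        if len(ids) != len(self.members):
            raise ValueError("duplicate sample ids in pedigree")
        for s in self.members:
            for p in (s.father_id, s.mother_id):
                if p is not None and p not in ids:
                    raise ValueError(f"{s.id}: unknown parent {p}")
            if (s.father_id is None) != (s.mother_id is None):
                raise ValueError(f"{s.id}: must have both parents or neither")
        missing = set(self.designated_affecteds) - ids
        if missing:
            raise ValueError(f"designated affecteds not in pedigree: {sorted(missing)}")
        self._order = self._topological_order()

    def _topological_order(self) -> list[str]:
        by_id = {s.id: s for s in self.members}
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(u: str) -> None:
            state[u] = 1
            s = by_id[u]
            for p in (s.father_id, s.mother_id):
                if p is not None:
                    if state.get(p, 0) == 1:
                        raise ValueError(f"pedigree cycle involving {u}")
                    if state.get(p, 0) == 0:
                        visit(p)
            state[u] = 2
            order.append(u)

        for s in self.members:
            if state.get(s.id, 0) == 0:
                visit(s.id)
        return order

    @property
    def order(self) -> list[str]:
        """Member ids, parents before children."""
        return list(self._order)

    def founders(self) -> list[str]:
        return [s.id for s in self.members if s.is_founder()]

    def by_id(self, sid: str) -> Sample:
        return next(s for s in self.members if s.id == sid)

    def meioses(self) -> list[tuple[str, int, str]]:
        """(child, haplotype slot, parent) triples; slot 0 paternal, 1 maternal."""
        out = []
        for sid in self.order:
            s = self.by_id(sid)
            if not s.is_founder():
                out.append((sid, 0, s.father_id))
                out.append((sid, 1, s.mother_id))
        return out


@dataclass
class SimConfig:
    seed: int
    markers: pd.DataFrame                 # id, chrom, pos_bp, cm, maf
    founder_freqs: np.ndarray             # per-marker B-allele frequency
    causal_chrom: str = "9"
    causal_bp: int | None = None          # default: midpoint marker of causal_chrom
    causal_founder: str | None = None     # default: first founder in pedigree order
    target_region_snps: int | None = 300  # minimum realised shared-IBD tract width
    het_error_rate: float = 5e-4
    missing_rate: float = 0.0
    max_locus_attempts: int = 50_000_000
    max_tract_attempts: int = 200

    def __post_init__(self):
        self.founder_freqs = np.asarray(self.founder_freqs, dtype=float)
        if len(self.founder_freqs) != len(self.markers):
            raise ValueError("founder_freqs length must match markers")
        if not ((0 <= self.founder_freqs) & (self.founder_freqs <= 1)).all():
            raise ValueError("founder allele frequencies must lie in [0, 1]")
        for rate in (self.het_error_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("error rates must lie in [0, 1]")


@dataclass
class FounderPool:
    hap_alleles: np.ndarray               # (2 x n_founders, n_markers) of 0/1
    hap_of: dict[str, tuple[int, int]]    # founder id -> its two haplotype rows
    causal_hap: int


@dataclass
class SimResult:
    panel: GenotypePanel
    truth: dict


# ---------------------------------------------------------------------------
# Map geometry
# ---------------------------------------------------------------------------

def _chrom_blocks(markers: pd.DataFrame) -> list[tuple[str, int, int]]:
    chroms = markers["chrom"].to_numpy()
    blocks, start = [], 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            blocks.append((str(chroms[start]), start, i))
            start = i
    return blocks


def recomb_fractions(markers: pd.DataFrame) -> list[np.ndarray]:
    """Per chromosome block, Haldane recombination fraction between neighbours."""
    out = []
    cm = markers["cm"].to_numpy(dtype=float)
    for _, lo, hi in _chrom_blocks(markers):
        d = np.diff(cm[lo:hi]) / 100.0      # Morgans
        if (d < 0).any():
            raise ValueError("cM positions must be non-decreasing; repair the map first")
        out.append(0.5 * (1.0 - np.exp(-2.0 * d)))
    return out


def map_length_morgans(markers: pd.DataFrame) -> float:
    cm = markers["cm"].to_numpy(dtype=float)
    return float(sum(cm[hi - 1] - cm[lo] for _, lo, hi in _chrom_blocks(markers))) / 100.0


def expected_crossovers_observable(markers: pd.DataFrame) -> float:
    """Expected marker-interval switches per meiosis, sum of recomb fractions.

    Slightly below the map length in Morgans because double crossovers within
    one interval are invisible; negligible on dense maps.
    """
    return float(sum(r.sum() for r in recomb_fractions(markers)))


# ---------------------------------------------------------------------------
# Founders and transmission
# ---------------------------------------------------------------------------

def simulate_founders(config: SimConfig, founder_ids: list[str],
                      rng: np.random.Generator) -> FounderPool:
    """Independent-marker founder haplotypes; hap 0 of the designated founder
    carries the causal allele (allele B at the causal marker, A on all other
    founder haplotypes)."""
    n_mark = len(config.markers)
    haps = (rng.random((2 * len(founder_ids), n_mark))
            < config.founder_freqs[None, :]).astype(np.int8)
    hap_of = {fid: (2 * k, 2 * k + 1) for k, fid in enumerate(founder_ids)}
    causal_founder = config.causal_founder or founder_ids[0]
    if causal_founder not in hap_of:
        raise ValueError(f"causal founder {causal_founder!r} is not a founder")
    causal_hap = hap_of[causal_founder][0]
    c = causal_marker_index(config)
    haps[:, c] = 0
    haps[causal_hap, c] = 1
    return FounderPool(haps, hap_of, causal_hap)


def causal_marker_index(config: SimConfig) -> int:
    m = config.markers
    rows = np.flatnonzero((m["chrom"].astype(str) == str(config.causal_chrom)).to_numpy())
    if len(rows) == 0:
        raise ValueError(f"causal chromosome {config.causal_chrom!r} has no markers")
    pos = m["pos_bp"].to_numpy()[rows]
    target = config.causal_bp if config.causal_bp is not None else pos[len(pos) // 2]
    return int(rows[np.argmin(np.abs(pos - target))])


def _chains_unconditional(n: int, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n independent inheritance chains over a block with inter-marker fractions r."""
    m = len(r) + 1
    v = np.empty((n, m), dtype=np.int8)
    v[:, 0] = rng.integers(0, 2, size=n, dtype=np.int8)
    if m > 1:
        switches = (rng.random((n, len(r))) < r[None, :]).astype(np.int8)
        v[:, 1:] = (v[:, :1] + np.cumsum(switches, axis=1)) % 2
    return v


def _chains_conditional(bits: np.ndarray, r: np.ndarray, c_local: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Chains fixed to ``bits`` at local index ``c_local``, extended both ways.

    Valid because the inheritance chain is a stationary, reversible two-state
    Markov chain: conditioning on one interior state leaves independent
    Markov extensions to either side.
    """
    n, m = len(bits), len(r) + 1
    v = np.empty((n, m), dtype=np.int8)
    v[:, c_local] = bits
    if c_local < m - 1:
        rr = r[c_local:]
        switches = (rng.random((n, len(rr))) < rr[None, :]).astype(np.int8)
        v[:, c_local + 1:] = (bits[:, None] + np.cumsum(switches, axis=1)) % 2
    if c_local > 0:
        rl = r[:c_local][::-1]
        switches = (rng.random((n, len(rl))) < rl[None, :]).astype(np.int8)
        v[:, :c_local] = ((bits[:, None] + np.cumsum(switches, axis=1)) % 2)[:, ::-1]
    return v


def sample_inheritance(
    pedigree: PedigreeSpec, markers: pd.DataFrame, rng: np.random.Generator,
    *, conditioned: tuple[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Inheritance indicators, shape (n_meioses, n_markers), values 0/1.

    ``conditioned`` pins the bits of every meiosis at one global marker index
    (the causal marker) and extends outwards on that chromosome.
    """
    meioses = pedigree.meioses()
    n = len(meioses)
    fracs = recomb_fractions(markers)
    blocks = _chrom_blocks(markers)
    v = np.empty((n, len(markers)), dtype=np.int8)
    for (chrom, lo, hi), r in zip(blocks, fracs):
        if conditioned is not None and lo <= conditioned[0] < hi:
            v[:, lo:hi] = _chains_conditional(conditioned[1], r, conditioned[0] - lo, rng)
        else:
            v[:, lo:hi] = _chains_unconditional(n, r, rng)
    return v


def drop_genes(
    pedigree: PedigreeSpec, pool: FounderPool, markers: pd.DataFrame,
    rng: np.random.Generator, inheritance: np.ndarray | None = None,
) -> np.ndarray:
    """Gene drop: founder-haplotype origin per individual, shape (n_ind, 2, n_markers).

    Each non-founder inherits one recombinant haplotype per parent; crossovers
    between adjacent markers follow Haldane.  Transmissions are Mendelian-
    consistent by construction.
    """
    order = pedigree.order
    idx = {sid: i for i, sid in enumerate(order)}
    if inheritance is None:
        inheritance = sample_inheritance(pedigree, markers, rng)
    n_mark = len(markers)
    hap_ids = np.empty((len(order), 2, n_mark), dtype=np.int16)
    for sid in order:
        s = pedigree.by_id(sid)
        if s.is_founder():
            h0, h1 = pool.hap_of[sid]
            hap_ids[idx[sid], 0, :] = h0
            hap_ids[idx[sid], 1, :] = h1
    for k, (child, slot, parent) in enumerate(pedigree.meioses()):
        v = inheritance[k]
        parent_haps = hap_ids[idx[parent]]           # (2, n_markers)
        hap_ids[idx[child], slot, :] = np.take_along_axis(
            parent_haps, v[None, :].astype(np.intp), axis=0
        )[0]
    return hap_ids


def simulate_meioses(markers: pd.DataFrame, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """n independent unconditioned meioses: inheritance indicators (n, n_markers)."""
    fracs = recomb_fractions(markers)
    v = np.empty((n, len(markers)), dtype=np.int8)
    for (_, lo, hi), r in zip(_chrom_blocks(markers), fracs):
        v[:, lo:hi] = _chains_unconditional(n, r, rng)
    return v


def count_crossovers(inheritance: np.ndarray, markers: pd.DataFrame) -> np.ndarray:
    """Observable crossovers (marker-interval switches) per meiosis."""
    counts = np.zeros(inheritance.shape[0], dtype=np.int64)
    for _, lo, hi in _chrom_blocks(markers):
        counts += (np.diff(inheritance[:, lo:hi], axis=1) != 0).sum(axis=1)
    return counts


# ---------------------------------------------------------------------------
# Autozygosity conditioning (rejection sampling)
# ---------------------------------------------------------------------------

def condition_on_autozygosity(
    pedigree: PedigreeSpec, pool: FounderPool, config: SimConfig,
    rng: np.random.Generator, *, block_size: int = 100_000,
) -> tuple[np.ndarray, int]:
    """Rejection-sample causal-locus inheritance bits until all designated
    affecteds are homozygous by descent for the causal founder haplotype.

    Returns (bits per meiosis at the causal marker, attempts used).  Raises
    SimulationError when ``max_locus_attempts`` is exhausted — usually a
    pedigree without a consanguineous path to the causal founder.
    """
    order = pedigree.order
    idx = {sid: i for i, sid in enumerate(order)}
    meioses = pedigree.meioses()
    aff = [idx[a] for a in config_designated(pedigree)]
    h_star = pool.causal_hap

    attempts = 0
    while attempts < config.max_locus_attempts:
        b = min(block_size, config.max_locus_attempts - attempts)
        bits = rng.integers(0, 2, size=(b, len(meioses)), dtype=np.int8)
        origin = np.empty((b, len(order), 2), dtype=np.int16)
        for sid in order:
            s = pedigree.by_id(sid)
            if s.is_founder():
                h0, h1 = pool.hap_of[sid]
                origin[:, idx[sid], 0] = h0
                origin[:, idx[sid], 1] = h1
        for k, (child, slot, parent) in enumerate(meioses):
            pick = bits[:, k].astype(np.intp)
            origin[:, idx[child], slot] = origin[np.arange(b), idx[parent], pick]
        ok = np.ones(b, dtype=bool)
        for a in aff:
            ok &= (origin[:, a, 0] == h_star) & (origin[:, a, 1] == h_star)
        hit = np.flatnonzero(ok)
        if len(hit):
            return bits[hit[0]].copy(), attempts + int(hit[0]) + 1
        attempts += b
    raise SimulationError(
        f"no gene drop with all affecteds autozygous for the causal haplotype in "
        f"{config.max_locus_attempts} attempts; does the pedigree admit autozygosity "
        f"at this locus?"
    )


def config_designated(pedigree: PedigreeSpec) -> list[str]:
    return pedigree.designated_affecteds


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

def add_genotyping_error(
    panel: GenotypePanel, config: SimConfig, rng: np.random.Generator
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Perturb calls: hom -> AB with ``het_error_rate``; any -> missing with
    ``missing_rate``.  Returns the perturbed panel and a log of changed cells."""
    calls = panel.calls.copy()
    hom = (calls == 0) | (calls == 2)
    to_het = hom & (rng.random(calls.shape) < config.het_error_rate)
    calls[to_het] = AB
    to_miss = rng.random(calls.shape) < config.missing_rate
    calls[to_miss] = MISSING
    changed = np.argwhere((to_het | to_miss) & (calls != panel.calls))
    log = pd.DataFrame(
        {
            "marker_idx": changed[:, 0],
            "marker_id": panel.markers["id"].to_numpy()[changed[:, 0]],
            "sample_id": [panel.samples[j].id for j in changed[:, 1]],
            "before": panel.calls[changed[:, 0], changed[:, 1]],
            "after": calls[changed[:, 0], changed[:, 1]],
        }
    )
    out = GenotypePanel(panel.markers.copy(), list(panel.samples), calls)
    return out, log


# ---------------------------------------------------------------------------
# Truth extraction and the high-level driver
# ---------------------------------------------------------------------------

def _expand_tract(ok: np.ndarray, c: int, lo: int, hi: int) -> tuple[int, int]:
    """Maximal [a, b] within [lo, hi) with ok true throughout and a <= c <= b."""
    a = b = c
    while a - 1 >= lo and ok[a - 1]:
        a -= 1
    while b + 1 < hi and ok[b + 1]:
        b += 1
    return a, b


def simulate_panel(pedigree: PedigreeSpec, config: SimConfig) -> SimResult:
    """Full simulation: founders, conditioned drop, errors, and ground truth.

    All randomness flows from ``config.seed``.  The returned truth dict holds
    the causal marker, the per-affected IBD tract, the tract intersection, its
    IBS-closure on the pre-error calls (the interval a marker-by-marker scan
    should recover with errors disabled), and the perturbation log.
    """
    rng = np.random.default_rng(config.seed)
    markers = config.markers.reset_index(drop=True)
    founder_ids = pedigree.founders()
    c = causal_marker_index(config)
    chrom_block = next(
        (lo, hi) for ch, lo, hi in _chrom_blocks(markers)
        if ch == str(config.causal_chrom)
    )
    order = pedigree.order
    idx = {sid: i for i, sid in enumerate(order)}
    aff = config_designated(pedigree)

    pool = hap_ids = None
    locus_attempts = tract_attempts = 0
    ibd_tracts: dict[str, tuple[int, int]] = {}
    intersection: tuple[int, int] | None = None
    for tract_attempts in range(1, config.max_tract_attempts + 1):
        pool = simulate_founders(config, founder_ids, rng)
        bits, used = condition_on_autozygosity(pedigree, pool, config, rng)
        locus_attempts += used
        inheritance = sample_inheritance(pedigree, markers, rng, conditioned=(c, bits))
        hap_ids = drop_genes(pedigree, pool, markers, rng, inheritance=inheritance)
        ibd_tracts = {}
        for a in aff:
            both = (hap_ids[idx[a], 0] == pool.causal_hap) & \
                   (hap_ids[idx[a], 1] == pool.causal_hap)
            ibd_tracts[a] = _expand_tract(both, c, *chrom_block)
        lo = max(t[0] for t in ibd_tracts.values())
        hi = min(t[1] for t in ibd_tracts.values())
        intersection = (lo, hi)
        if config.target_region_snps is None or hi - lo + 1 >= config.target_region_snps:
            break
    else:
        raise SimulationError(
            f"no drop with a shared IBD tract of >= {config.target_region_snps} markers "
            f"in {config.max_tract_attempts} attempts; densify the map or relax the target"
        )

    # genotypes from founder haplotype origins
    alleles = pool.hap_alleles[hap_ids, np.arange(len(markers))[None, None, :]]
    calls = alleles.sum(axis=1).T.astype(np.int8)      # (n_markers, n_ind); 0/1/2
    samples = [pedigree.by_id(sid) for sid in order]
    clean = GenotypePanel(markers.copy(), samples, calls)

    aff_cols = [idx[a] for a in aff]
    sub = calls[:, aff_cols]
    hom_ibs = ((sub == 0).all(axis=1)) | ((sub == 2).all(axis=1))
    ibs_closure = _expand_tract(hom_ibs, c, *chrom_block)

    noisy, log = add_genotyping_error(clean, config, rng)
    pos = markers["pos_bp"].to_numpy()
    truth = {
        "seed": int(config.seed),
        "causal_marker_idx": int(c),
        "causal_marker_id": str(markers["id"].iloc[c]),
        "causal_chrom": str(config.causal_chrom),
        "causal_bp": int(pos[c]),
        "causal_founder": str(config.causal_founder or founder_ids[0]),
        "causal_hap": int(pool.causal_hap),
        "ibd_tract_markers": {a: [int(t[0]), int(t[1])] for a, t in ibd_tracts.items()},
        "ibd_intersection_markers": [int(intersection[0]), int(intersection[1])],
        "ibd_intersection_bp": [int(pos[intersection[0]]), int(pos[intersection[1]])],
        "shared_ibs_tract_markers": [int(ibs_closure[0]), int(ibs_closure[1])],
        "shared_ibs_tract_bp": [int(pos[ibs_closure[0]]), int(pos[ibs_closure[1]])],
        "locus_attempts": int(locus_attempts),
        "tract_attempts": int(tract_attempts),
        "n_perturbed_cells": int(len(log)),
    }
    return SimResult(panel=noisy, truth={**truth, "perturbation_log": log,
                                         "clean_panel": clean})


# ---------------------------------------------------------------------------
# Independent Mendelian validator
# ---------------------------------------------------------------------------

def mendelian_violations(panel: GenotypePanel) -> pd.DataFrame:
    """Child/parent opposite-homozygote conflicts (AA child vs BB parent etc.)."""
    rows = []
    for s in panel.samples:
        ci = panel.sample_index(s.id)
        for pid in (s.father_id, s.mother_id):
            if pid is None:
                continue
            pi = panel.sample_index(pid)
            child, par = panel.calls[:, ci], panel.calls[:, pi]
            bad = ((child == 0) & (par == 2)) | ((child == 2) & (par == 0))
            for m in np.flatnonzero(bad):
                rows.append({
                    "marker_id": panel.markers["id"].iloc[m],
                    "child": s.id, "parent": pid,
                })
    return pd.DataFrame(rows, columns=["marker_id", "child", "parent"])
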