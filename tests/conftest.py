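"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohmap.genotypes import AA, AB, BB, MISSING, GenotypePanel, Sample

LABELS = {"AA": AA, "AB": AB, "BB": BB, "NA": MISSING, "..": MISSING}


def build_panel(grid, *, chrom="1", start_bp=1_000_000, step_bp=10_000,
                cm_step=0.05, statuses=None, chroms=None, pos=None, cm=None):
    """Build a panel from a markers x samples grid of AA/AB/BB/NA labels."""
    grid = [row.split() if isinstance(row, str) else row for row in grid]
    n_mark, n_samp = len(grid), len(grid[0])
    statuses = statuses or ["affected"] * n_samp
    markers = pd.DataFrame({
        "id": [f"m{i:04d}" for i in range(n_mark)],
        "chrom": chroms if chroms is not None else [chrom] * n_mark,
        "pos_bp": pos if pos is not None else start_bp + step_bp * np.arange(n_mark),
        "cm": cm if cm is not None else cm_step * np.arange(n_mark, dtype=float),
        "maf": 0.3,
    })
    samples = [Sample(id=f"ind{j}", status=statuses[j]) for j in range(n_samp)]
    calls = np.array([[LABELS[v] for v in row] for row in grid], dtype=np.int8)
    return GenotypePanel(markers, samples, calls)


def random_panel(rng, *, max_markers=200, max_samples=8, n_chroms=2):
    """A random panel biased toward homozygosity so shared runs actually occur."""
    n_mark = int(rng.integers(20, max_markers + 1))
    n_samp = int(rng.integers(2, max_samples + 1))
    chrom_of = np.sort(rng.integers(1, n_chroms + 1, size=n_mark))
    pos = np.zeros(n_mark, dtype=np.int64)
    cm = np.zeros(n_mark)
    for c in np.unique(chrom_of):
        rows = np.flatnonzero(chrom_of == c)
        # occasional large physical gaps to exercise gap splitting
        steps = rng.choice([10_000, 30_000, 500_000], size=len(rows),
                           p=[0.8, 0.15, 0.05])
        pos[rows] = 1_000_000 + np.cumsum(steps)
        cm[rows] = np.cumsum(rng.uniform(0.005, 0.2, size=len(rows)))
    calls = rng.choice(
        [AA, BB, AB, MISSING], size=(n_mark, n_samp), p=[0.45, 0.3, 0.2, 0.05]
    ).astype(np.int8)
    markers = pd.DataFrame({
        "id": [f"r{i:05d}" for i in range(n_mark)],
        "chrom": [str(c) for c in chrom_of],
        "pos_bp": pos, "cm": cm, "maf": 0.3,
    })
    samples = [Sample(id=f"ind{j}", status="affected") for j in range(n_samp)]
    return GenotypePanel(markers, samples, calls)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------

def oracle_shared_runs(panel, affected_ids, min_run):
    """Enumerate maximal all-homozygous-identical stretches marker by marker."""
    cols = [panel.sample_index(a) for a in affected_ids]
    out = []
    for chrom, lo, hi in panel.chrom_blocks():
        run = []
        for m in range(lo, hi):
            row = [int(panel.calls[m, c]) for c in cols]
            ok = all(v in (AA, BB) for v in row) and len(set(row)) == 1
            if ok:
                run.append(m)
            else:
                if len(run) >= min_run:
                    out.append((run[0], run[-1]))
                run = []
        if len(run) >= min_run:
            out.append((run[0], run[-1]))
    return sorted(out)


def oracle_rcch(panel, affected_ids, cutoff_cm, largegap_bp):
    """Enumerate maximal discordance-free, gap-free informative stretches."""
    cols = [panel.sample_index(a) for a in affected_ids]
    cm = panel.markers["cm"].to_numpy()
    pos = panel.markers["pos_bp"].to_numpy()
    out = []
    for chrom, lo, hi in panel.chrom_blocks():
        stretches, current = [], []
        for m in range(lo, hi):
            row = [int(panel.calls[m, c]) for c in cols]
            homs = {v for v in row if v in (AA, BB)}
            if not homs:
                continue
            if current and pos[m] - pos[current[-1]] > largegap_bp:
                stretches.append(current)
                current = []
            if len(homs) == 2:           # discordance point: split, exclude
                if current:
                    stretches.append(current)
                current = []
                continue
            current.append(m)
        if current:
            stretches.append(current)
        for s in stretches:
            if cm[s[-1]] - cm[s[0]] >= cutoff_cm:
                out.append((s[0], s[-1]))
    return sorted(out)


CODON = {}
_bases = "TCAG"
_aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_aas):
    CODON[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a


def oracle_translate(cds: str) -> str:
    """Naive codon-table translation up to (excluding) the first stop."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON[cds[i:i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


@pytest.fixture
def toy_transcript():
    from rohmap.datasets import toy_acceptor_transcript

    return toy_acceptor_transcript("+")


@pytest.fixture
def small_sim():
    """A downsized simulation scenario for fast unit tests."""
    from rohmap.datasets import default_sim_config, demo_pedigree, default_marker_map

    markers = default_marker_map(n_chr9=1200, n_other=300, chr9_cm=60.0)
    def make(seed, **overrides):
        overrides.setdefault("target_region_snps", 80)
        return demo_pedigree(), default_sim_config(seed, markers=markers, **overrides)
    return make
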