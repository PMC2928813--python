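"""Gene-dropping simulator: founders, transmission, conditioning, errors."""

import numpy as np
import pandas as pd
import pytest

from rohmap.datasets import default_marker_map, default_sim_config, demo_pedigree
from rohmap.genotypes import AB, MISSING, Sample
from rohmap.simulate import (PedigreeSpec, SimConfig, SimulationError,
                             add_genotyping_error, causal_marker_index,
                             condition_on_autozygosity, count_crossovers,
                             drop_genes, map_length_morgans,
                             mendelian_violations, recomb_fractions,
                             sample_inheritance, simulate_founders,
                             simulate_meioses, simulate_panel)


def _markers(n=50, chrom="9", cm_total=5.0):
    return pd.DataFrame({
        "id": [f"m{i}" for i in range(n)],
        "chrom": chrom,
        "pos_bp": 1_000_000 + 10_000 * np.arange(n, dtype=np.int64),
        "cm": np.linspace(0.0, cm_total, n),
        "maf": 0.4,
    })


def _config(seed=1, n=50, **kw):
    markers = _markers(n)
    kw.setdefault("founder_freqs", np.full(n, 0.4))
    kw.setdefault("causal_chrom", "9")
    kw.setdefault("target_region_snps", None)
    return SimConfig(seed=seed, markers=markers, **kw)


class TestFounders:
    def test_boundary_frequencies(self):
        rng = np.random.default_rng(0)
        cfg = _config(founder_freqs=np.zeros(50))
        pool = simulate_founders(cfg, ["f1", "f2"], rng)
        c = causal_marker_index(cfg)
        mask = np.ones(50, dtype=bool)
        mask[c] = False                        # causal allele is implanted there
        assert (pool.hap_alleles[:, mask] == 0).all()
        assert pool.hap_alleles[pool.causal_hap, c] == 1

        cfg1 = _config(founder_freqs=np.ones(50))
        pool1 = simulate_founders(cfg1, ["f1"], np.random.default_rng(0))
        assert (pool1.hap_alleles[:, mask] == 1).all()

    def test_seed_determinism(self):
        cfg = _config()
        a = simulate_founders(cfg, ["f1", "f2"], np.random.default_rng(9))
        b = simulate_founders(cfg, ["f1", "f2"], np.random.default_rng(9))
        assert np.array_equal(a.hap_alleles, b.hap_alleles)


def _trio():
    return PedigreeSpec(
        [Sample("f", sex="male"), Sample("m", sex="female"),
         Sample("k", "f", "m", status="affected")],
        ["k"],
    )


class TestTransmission:
    def test_zero_map_distance_cotransmits(self):
        markers = _markers(n=30, cm_total=0.0)     # d = 0 everywhere
        v = sample_inheritance(_trio(), markers, np.random.default_rng(3))
        assert (np.diff(v, axis=1) == 0).all()

    def test_recomb_fraction_limits(self):
        markers = pd.DataFrame({
            "id": ["a", "b", "c"], "chrom": "1",
            "pos_bp": [100, 200, 300], "cm": [0.0, 0.0, 1e6], "maf": 0.1,
        })
        r = recomb_fractions(markers)[0]
        assert r[0] == 0.0
        assert r[1] == pytest.approx(0.5)

    def test_transmissions_are_mendelian_consistent(self):
        ped = demo_pedigree()
        cfg = default_sim_config(3, markers=_markers(n=200), target_region_snps=None,
                                 het_error_rate=0.0)
        result = simulate_panel(ped, cfg)
        assert len(mendelian_violations(result.truth["clean_panel"])) == 0

    def test_crossover_count_tracks_map_length(self):
        markers = _markers(n=400, cm_total=150.0)
        rng = np.random.default_rng(21)
        v = simulate_meioses(markers, 2000, rng)
        counts = count_crossovers(v, markers)
        L = map_length_morgans(markers)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - L) < 3 * se


class TestConditioning:
    def test_cousin_mating_becomes_autozygous(self):
        ped = demo_pedigree()
        cfg = default_sim_config(5, markers=_markers(n=100), target_region_snps=None)
        result = simulate_panel(ped, cfg)
        c = result.truth["causal_marker_idx"]
        for a in ped.designated_affecteds:
            lo, hi = result.truth["ibd_tract_markers"][a]
            assert lo <= c <= hi

    def test_unrelated_parents_hit_attempt_limit(self):
        ped = _trio()       # no consanguineous loop: autozygosity impossible
        cfg = _config(max_locus_attempts=2000)
        rng = np.random.default_rng(2)
        pool = simulate_founders(cfg, ped.founders(), rng)
        with pytest.raises(SimulationError, match="attempts"):
            condition_on_autozygosity(ped, pool, cfg, rng, block_size=500)

    def test_seeded_run_reproducible(self):
        ped = demo_pedigree()
        cfg = default_sim_config(11, markers=_markers(n=100), target_region_snps=None)
        a = simulate_panel(ped, cfg)
        b = simulate_panel(ped, cfg)
        assert np.array_equal(a.panel.calls, b.panel.calls)
        assert a.truth["ibd_intersection_markers"] == b.truth["ibd_intersection_markers"]

    def test_tract_width_target_enforced(self, small_sim):
        ped, cfg = small_sim(13)
        result = simulate_panel(ped, cfg)
        lo, hi = result.truth["ibd_intersection_markers"]
        assert hi - lo + 1 >= cfg.target_region_snps


class TestErrorModel:
    def _clean_panel(self):
        ped = demo_pedigree()
        cfg = default_sim_config(4, markers=_markers(n=150), target_region_snps=None,
                                 het_error_rate=0.0, missing_rate=0.0)
        return simulate_panel(ped, cfg).panel, cfg

    def test_zero_rates_identity(self):
        panel, cfg = self._clean_panel()
        out, log = add_genotyping_error(panel, cfg, np.random.default_rng(1))
        assert np.array_equal(out.calls, panel.calls)
        assert len(log) == 0

    def test_rate_one_heterozygotes_all_homozygotes(self):
        panel, cfg = self._clean_panel()
        cfg.het_error_rate = 1.0
        out, _ = add_genotyping_error(panel, cfg, np.random.default_rng(1))
        hom_before = (panel.calls == 0) | (panel.calls == 2)
        assert (out.calls[hom_before] == AB).all()

    def test_true_heterozygotes_never_become_homozygous(self):
        panel, cfg = self._clean_panel()
        cfg.het_error_rate = 1.0
        cfg.missing_rate = 0.0
        out, _ = add_genotyping_error(panel, cfg, np.random.default_rng(8))
        het_before = panel.calls == AB
        assert (out.calls[het_before] == AB).all()

    def test_perturbation_count_near_binomial_expectation(self):
        panel, cfg = self._clean_panel()
        cfg.het_error_rate = 0.01
        out, log = add_genotyping_error(panel, cfg, np.random.default_rng(3))
        n_hom = int(((panel.calls == 0) | (panel.calls == 2)).sum())
        expect = n_hom * 0.01
        sd = np.sqrt(n_hom * 0.01 * 0.99)
        assert abs(len(log) - expect) < 3 * sd

    def test_missing_rate_applies_to_any_call(self):
        panel, cfg = self._clean_panel()
        cfg.missing_rate = 1.0
        out, _ = add_genotyping_error(panel, cfg, np.random.default_rng(5))
        assert (out.calls == MISSING).all()


class TestRecovery:
    def test_zero_error_boundaries_match_truth_closure(self, small_sim):
        from rohmap.ibs import ScanConfig, bridge_runs, rank_candidates, \
            shared_ibs_runs

        ped, cfg = small_sim(42, het_error_rate=0.0, missing_rate=0.0)
        result = simulate_panel(ped, cfg)
        runs = shared_ibs_runs(result.panel, result.panel.affected_ids,
                               ScanConfig())
        merged = bridge_runs(runs, result.panel, result.panel.affected_ids,
                             ScanConfig())
        top = rank_candidates(merged).iloc[0]
        assert [top["start_bp"], top["end_bp"]] == \
            result.truth["shared_ibs_tract_bp"]
        lo, hi = result.truth["ibd_intersection_bp"]
        assert top["start_bp"] <= lo and hi <= top["end_bp"]
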