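"""Shared-IBS run scan: run detection, sizing, bridging, contrast, ranking."""

import numpy as np
import pytest

from rohmap.datasets import reported_runs
from rohmap.genotypes import AA, BB
from rohmap.ibs import (MergedRegion, ScanConfig, SharedRun, bridge_runs,
                        contrast_unaffected, rank_candidates, run_size_bp,
                        shared_ibs_runs)
from .conftest import build_panel, oracle_shared_runs, random_panel


def _flanked_run(n_run, n_samp=6, flank="AB"):
    grid = [" ".join([flank] * n_samp)]
    grid += [" ".join(["AA"] * n_samp)] * n_run
    grid += [" ".join([flank] * n_samp)]
    return build_panel(grid)


class TestSharedRuns:
    def test_flanked_run_detected_with_exact_extent(self):
        panel = _flanked_run(40)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        assert len(runs) == 1
        assert (runs[0].start_idx, runs[0].end_idx, runs[0].n_snps) == (1, 40, 40)

    def test_homozygous_but_not_ibs_is_no_run(self):
        grid = ["AA AA AA AA AA BB"] * 40
        panel = build_panel(grid)
        assert shared_ibs_runs(panel, panel.affected_ids, ScanConfig()) == []

    def test_min_run_threshold_applies(self):
        panel = _flanked_run(34)
        assert shared_ibs_runs(panel, panel.affected_ids, ScanConfig()) == []
        panel = _flanked_run(35)
        assert len(shared_ibs_runs(panel, panel.affected_ids, ScanConfig())) == 1

    def test_chr18_style_fixture_run_count_and_size(self):
        # 57 markers spanning the printed chr18 boundary coordinates
        pos = np.linspace(64_801_868, 64_929_306, 57).round().astype(np.int64)
        pos[0], pos[-1] = 64_801_868, 64_929_306
        grid = ["AA AA AA AA AA AA"] * 57
        panel = build_panel(grid, chrom="18", pos=pos)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        assert len(runs) == 1
        assert runs[0].n_snps == 57
        assert runs[0].size_bp == 127_439

    def test_missing_breaks_a_run(self):
        grid = ["AA AA"] * 40 + ["NA AA"] + ["AA AA"] * 40
        panel = build_panel(grid)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        assert sorted(r.n_snps for r in runs) == [40, 40]

    def test_descending_snp_count_order_with_tiebreak(self):
        grid = (["AB AB"] + ["AA AA"] * 40 + ["AB AB"] + ["BB BB"] * 50 +
                ["AB AB"] + ["AA AA"] * 40 + ["AB AB"])
        panel = build_panel(grid)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        assert [r.n_snps for r in runs] == [50, 40, 40]
        assert runs[1].start_bp < runs[2].start_bp

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        cfg = ScanConfig(min_run_snps=3)
        for _ in range(30):
            panel = random_panel(rng)
            got = [(r.start_idx, r.end_idx)
                   for r in shared_ibs_runs(panel, panel.affected_ids, cfg)]
            assert sorted(got) == oracle_shared_runs(panel, panel.affected_ids, 3)

    def test_maximality_of_reported_runs(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            panel = random_panel(rng)
            cols = list(range(panel.n_samples))

            def conforming(m):
                row = panel.calls[m, cols]
                return bool(((row == AA).all()) or ((row == BB).all()))

            for r in shared_ibs_runs(panel, panel.affected_ids, ScanConfig(min_run_snps=2)):
                chrom_rows = [b for b in panel.chrom_blocks() if b[0] == r.chrom][0]
                if r.start_idx - 1 >= chrom_rows[1]:
                    assert not conforming(r.start_idx - 1)
                if r.end_idx + 1 < chrom_rows[2]:
                    assert not conforming(r.end_idx + 1)


class TestRunSize:
    def test_inclusive_convention_on_published_rows(self):
        table = reported_runs()
        for row in table.itertuples():
            start_bp, end_bp, size_bp = row[5], row[6], row[7]
            run = SharedRun(str(row.Chr), 0, 0, row.StartSNP, row.EndSNP,
                            start_bp, end_bp, row.SNPs, end_bp - start_bp + 1)
            assert run_size_bp(run) == size_bp

    def test_single_marker_interval(self):
        run = SharedRun("1", 0, 0, "a", "a", 100, 100, 1, 1)
        assert run_size_bp(run) == 1


class TestBridging:
    def test_single_het_carrier_merges_with_span_count(self):
        grid = (["AB AB AB AB AB AB"] + ["AA AA AA AA AA AA"] * 40 +
                ["AB AA AA AA AA AA"] + ["AA AA AA AA AA AA"] * 40 +
                ["AB AB AB AB AB AB"])
        panel = build_panel(grid)
        cfg = ScanConfig()
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        merged = bridge_runs(runs, panel, panel.affected_ids, cfg)
        assert len(merged) == 1
        assert merged[0].n_snps == 81
        assert merged[0].n_component_runs == 2

    def test_allele_conflict_never_bridges(self):
        grid = (["AA AA"] * 40 + ["AA BB"] + ["AA AA"] * 40)
        panel = build_panel(grid)
        cfg = ScanConfig()
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        merged = bridge_runs(runs, panel, panel.affected_ids, cfg)
        assert len(merged) == 2

    def test_missing_never_bridges(self):
        grid = (["AA AA"] * 40 + ["NA AA"] + ["AA AA"] * 40)
        panel = build_panel(grid)
        cfg = ScanConfig()
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        assert len(bridge_runs(runs, panel, panel.affected_ids, cfg)) == 2

    def test_too_many_het_carriers_never_bridges(self):
        grid = (["AA AA AA"] * 40 + ["AB AB AA"] + ["AA AA AA"] * 40)
        panel = build_panel(grid)
        cfg = ScanConfig(bridge_max_carriers=1)
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        assert len(bridge_runs(runs, panel, panel.affected_ids, cfg)) == 2
        cfg2 = ScanConfig(bridge_max_carriers=2)
        assert len(bridge_runs(runs, panel, panel.affected_ids, cfg2)) == 1

    def test_transitive_merging_across_chained_interruptions(self):
        block = ["AA AA"] * 35
        grid = block + ["AB AA"] + block + ["AA AB"] + block
        panel = build_panel(grid)
        cfg = ScanConfig()
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        merged = bridge_runs(runs, panel, panel.affected_ids, cfg)
        assert len(merged) == 1
        assert merged[0].n_snps == 107

    def test_zero_gap_budget_is_identity(self):
        grid = (["AA AA"] * 40 + ["AB AA"] + ["AA AA"] * 40)
        panel = build_panel(grid)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        merged = bridge_runs(runs, panel, panel.affected_ids,
                             ScanConfig(bridge_max_gap_snps=0))
        assert [(m.start_idx, m.end_idx) for m in merged] == \
               sorted((r.start_idx, r.end_idx) for r in runs)

    def test_foreign_runs_rejected(self):
        panel = _flanked_run(40)
        runs = shared_ibs_runs(panel, panel.affected_ids, ScanConfig())
        other = build_panel([" ".join(["AA"] * 6)] * 42, start_bp=5_000_000)
        with pytest.raises(ValueError, match="panel"):
            bridge_runs(runs, other, other.affected_ids, ScanConfig())


class TestContrast:
    def _region_panel(self, unaffected_calls):
        grid = [f"AA AA {u}" for u in unaffected_calls]
        return build_panel(grid, statuses=["affected", "affected", "unaffected"])

    def _merged(self, panel):
        cfg = ScanConfig(min_run_snps=2)
        runs = shared_ibs_runs(panel, panel.affected_ids, cfg)
        return bridge_runs(runs, panel, panel.affected_ids, cfg)

    def test_partial_match_below_threshold_retained(self):
        panel = self._region_panel(["AA"] * 7 + ["AB"] * 3)
        regions = contrast_unaffected(self._merged(panel), panel, ["ind2"])
        assert not regions[0].not_segregating
        assert regions[0].unaffected_match_frac["ind2"] == pytest.approx(0.7)

    def test_full_match_flags_not_segregating(self):
        panel = self._region_panel(["AA"] * 10)
        regions = contrast_unaffected(self._merged(panel), panel, ["ind2"])
        assert regions[0].not_segregating

    def test_no_unaffecteds_passes_through(self):
        panel = self._region_panel(["AA"] * 10)
        regions = contrast_unaffected(self._merged(panel), panel, [])
        assert not regions[0].not_segregating


class TestRanking:
    def _mk(self, chrom, start, n):
        return MergedRegion(chrom, 0, n - 1, "a", "b", start, start + n * 1000,
                            n, n * 1000 + 1, 1)

    def test_outlier_ratio(self):
        frame = rank_candidates([self._mk("9", 1, 1359), self._mk("18", 1, 57),
                                 self._mk("21", 1, 49)])
        assert frame["n_snps"].tolist() == [1359, 57, 49]
        assert frame["ratio_to_next"].iloc[0] == pytest.approx(1359 / 57, abs=1e-9)
        assert np.isinf(frame["ratio_to_next"].iloc[-1])

    def test_single_region_ratio_is_infinite(self):
        frame = rank_candidates([self._mk("1", 1, 40)])
        assert np.isinf(frame["ratio_to_next"].iloc[0])

    def test_ties_stable_by_chrom_then_start(self):
        frame = rank_candidates([self._mk("2", 500, 40), self._mk("1", 900, 40),
                                 self._mk("1", 100, 40)])
        assert frame[["chrom", "start_bp"]].values.tolist() == \
            [["1", 100], ["1", 900], ["2", 500]]

    def test_empty_input_gives_empty_report(self):
        assert len(rank_candidates([])) == 0


def test_determinism_byte_identical_reports():
    from rohmap.ibs import runs_to_frame

    rng1, rng2 = np.random.default_rng(99), np.random.default_rng(99)
    p1, p2 = random_panel(rng1), random_panel(rng2)
    cfg = ScanConfig(min_run_snps=3)
    a = runs_to_frame(shared_ibs_runs(p1, p1.affected_ids, cfg)).to_csv()
    b = runs_to_frame(shared_ibs_runs(p2, p2.affected_ids, cfg)).to_csv()
    assert a == b
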