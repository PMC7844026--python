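"""Case-control t-tests, specificity partition, subtype calls, Monte-Carlo."""

import numpy as np
import pandas as pd
import pytest

from tricomp import differential as dm
from tricomp import synthetic_data as sd
from tricomp.differential import (AnalysisConfig, EVMatrix,
                                  chromosome_enrichment_mc,
                                  differential_compartments,
                                  region_gene_enrichment_mc,
                                  specificity_partition, subtype_regions)
from tricomp.hic_io import BinGrid


def _evm(values: np.ndarray, groups: dict[str, str]) -> EVMatrix:
    grid = BinGrid({"chr1": values.shape[0] * 100_000}, 100_000)
    return EVMatrix(grid=grid,
                    values=pd.DataFrame(values, columns=list(groups),
                                        index=grid.bin_ids()),
                    sample_groups=groups)


class TestDifferentialCompartments:
    def test_identical_groups_yield_nothing_significant(self, rng):
        base = rng.uniform(-1, 1, (50, 3))
        values = np.hstack([base, base])
        groups = {f"c{i}": "case" for i in range(3)}
        groups.update({f"k{i}": "ctrl" for i in range(3)})
        res = differential_compartments(_evm(values, groups), "case", "ctrl")
        assert not res["significant"].any()

    def test_planted_shift_recovered_with_controlled_fdr(self):
        """5 vs 5 cohort, 5% of regions shifted by 0.8, within-group sd
        0.05: nearly all planted regions called, null false-positive
        fraction at most alpha."""
        rng = np.random.default_rng(11)
        n = 600
        planted = rng.choice(n, size=30, replace=False)
        base = rng.uniform(-0.9, 0.1, n)
        case = base[:, None] + rng.normal(0, 0.05, (n, 5))
        ctrl = base[:, None] + rng.normal(0, 0.05, (n, 5))
        case[planted] += 0.8
        values = np.clip(np.hstack([case, ctrl]), -1, 1)
        groups = {f"case{i}": "case" for i in range(5)}
        groups.update({f"ctrl{i}": "ctrl" for i in range(5)})
        res = differential_compartments(_evm(values, groups), "case", "ctrl",
                                        AnalysisConfig())
        sig = set(res.loc[res["significant"], "bin_index"])
        recall = len(sig & set(planted.tolist())) / planted.size
        assert recall >= 0.95
        null = np.setdiff1d(np.arange(n), planted)
        fp = len(sig - set(planted.tolist())) / null.size
        assert fp <= 0.05
        # direction follows the sign of the shift
        direction = res.set_index("bin_index").loc[sorted(
            sig & set(planted.tolist())), "direction"]
        assert (direction == "activation").all()

    def test_regions_with_missing_values_removed(self, rng):
        values = rng.uniform(-1, 1, (10, 4))
        values[3, 0] = np.nan
        groups = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}
        res = differential_compartments(_evm(values, groups), "g1", "g2")
        assert 3 not in set(res["bin_index"])
        assert len(res) == 9

    def test_small_group_rejected(self, rng):
        values = rng.uniform(-1, 1, (10, 3))
        groups = {"a1": "g1", "b1": "g2", "b2": "g2"}
        with pytest.raises(ValueError, match="at least 2"):
            differential_compartments(_evm(values, groups), "g1", "g2")

    def test_zero_variance_equal_means_give_p_one(self):
        values = np.ones((12, 4)) * 0.5
        groups = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"}
        res = differential_compartments(_evm(values, groups), "g1", "g2")
        assert (res["p_value"] == 1.0).all()

    def test_bh_adjustment_monotone_and_order_invariant(self, rng):
        values = rng.uniform(-1, 1, (80, 6))
        values[:10, :3] += 0.9
        groups = {f"a{i}": "g1" for i in range(3)}
        groups.update({f"b{i}": "g2" for i in range(3)})
        evm = _evm(np.clip(values, -1, 1), groups)
        res = differential_compartments(evm, "g1", "g2")
        by_p = res.sort_values("p_value")
        assert (np.diff(by_p["p_adjusted"]) >= -1e-12).all()
        # shuffling region order leaves the significant set unchanged
        perm = np.random.default_rng(0).permutation(80)
        evm2 = EVMatrix(grid=evm.grid,
                        values=evm.values.iloc[perm],
                        sample_groups=evm.sample_groups)
        res2 = differential_compartments(evm2, "g1", "g2")
        assert set(res2.loc[res2["significant"], "region"]) == \
            set(res.loc[res["significant"], "region"])


class TestSpecificityPartition:
    def test_published_set_arithmetic(self):
        """348 disease-A regions and 82 disease-B regions sharing 31 give
        317 and 51 specific regions."""
        a = set(range(348))
        b = set(range(317, 317 + 82))     # overlap = 317..347 -> 31 shared
        part = specificity_partition(a, b)
        assert part.counts == {"common": 31, "a_specific": 317,
                               "b_specific": 51}

    def test_disjoint_sets(self):
        part = specificity_partition({1, 2}, {3, 4})
        assert part.common.size == 0
        assert part.counts["a_specific"] == 2
        assert part.counts["b_specific"] == 2

    def test_identical_sets(self):
        part = specificity_partition({1, 2, 3}, {1, 2, 3})
        assert part.counts == {"common": 3, "a_specific": 0,
                               "b_specific": 0}

    def test_inclusion_exclusion_holds(self, rng):
        a = set(rng.choice(200, 60, replace=False).tolist())
        b = set(rng.choice(200, 90, replace=False).tolist())
        part = specificity_partition(a, b)
        assert (part.counts["a_specific"] + part.counts["b_specific"]
                + part.counts["common"]) == len(a | b)
        assert len(a) + len(b) - part.counts["common"] == len(a | b)


class TestSubtypeRegions:
    def test_heterogeneous_region_dropped_at_homogenization(self):
        values = np.array([
            [0.9, 0.4, -0.5, -0.5],   # subtype1 range 0.5 -> dropped
            [0.5, 0.5, -0.1, -0.1],   # homogeneous, delta 0.6 -> kept
        ])
        groups = {"s1a": "sub1", "s1b": "sub1", "s2a": "sub2", "s2b": "sub2"}
        out, retention = subtype_regions(_evm(values, groups), "sub1", "sub2")
        assert out["bin_index"].tolist() == [1]
        assert retention == 0.5

    def test_threshold_rule_on_subtype_means(self):
        values = np.array([[0.3, 0.3, -0.2, -0.2],
                           [0.3, 0.3, 0.1, 0.1]])
        groups = {"a1": "s1", "a2": "s1", "b1": "s2", "b2": "s2"}
        out, _ = subtype_regions(_evm(values, groups), "s1", "s2")
        assert out["significant"].tolist() == [True, False]
        assert out.loc[0, "direction"] == "s1_gain"

    def test_planted_subtype_cohort_recovered(self):
        """Planted subtype-specific regions found with >= 95% recall and
        under 1% false calls among null regions."""
        cfg = sd.SimulationConfig(
            chromosome_sizes={"chr1": 50_000_000, "chr2": 50_000_000})
        design = sd.CohortDesign(
            subtype_specific_regions={"CLL": 10, "MCL": 100})
        cohort = sd.simulate_cohort(cfg, design, seed=23)
        t = cohort.truth
        out, retention = subtype_regions(cohort.ev, "cMCL", "nnMCL")
        found = set(out.loc[out["significant"], "bin_index"])
        planted = set(t.subtype_regions["MCL"].tolist())
        assert len(found & planted) / len(planted) >= 0.95
        null_false = found - planted
        assert len(null_false) / (cfg.grid.n_bins - len(planted)) <= 0.01
        assert retention > 0.9

    def test_empty_subtype_rejected(self, rng):
        values = rng.uniform(-1, 1, (5, 2))
        groups = {"a1": "s1", "a2": "s1"}
        with pytest.raises(ValueError, match="subtype"):
            subtype_regions(_evm(values, groups), "s1", "s2")


class TestChromosomeEnrichmentMC:
    def test_fully_concentrated_regions_hit_the_p_floor(self):
        grid = BinGrid({"chr1": 5_000_000, "chr2": 5_000_000}, 100_000)
        cfg = AnalysisConfig(n_perm=10_000, seed=3)
        out = chromosome_enrichment_mc(np.arange(50), grid, cfg)
        p1 = out.set_index("chromosome").loc["chr1", "p_value"]
        assert p1 == pytest.approx(1 / 10_001)

    def test_p_values_floor_and_range(self, rng):
        grid = BinGrid({"chr1": 3_000_000, "chr2": 3_000_000}, 100_000)
        cfg = AnalysisConfig(n_perm=200, seed=8)
        out = chromosome_enrichment_mc(
            rng.choice(60, 10, replace=False), grid, cfg)
        assert (out["p_value"] >= 1 / 201).all()
        assert (out["p_value"] <= 1.0).all()

    def test_uniform_regions_are_calibrated(self):
        """Uniformly drawn region sets should flag ~5% of chromosomes at
        p < 0.05 across seeds."""
        sizes = {f"chr{i}": 2_000_000 for i in range(1, 9)}
        grid = BinGrid(sizes, 100_000)
        hits = total = 0
        for s in range(40):
            rng_s = np.random.default_rng(5000 + s)
            regions = rng_s.choice(grid.n_bins, 20, replace=False)
            out = chromosome_enrichment_mc(
                regions, grid, AnalysisConfig(n_perm=400, seed=s))
            hits += int((out["p_value"] < 0.05).sum())
            total += len(out)
        assert 0.005 <= hits / total <= 0.12

    def test_deterministic_given_seed(self, rng):
        grid = BinGrid({"chr1": 4_000_000, "chr2": 4_000_000}, 100_000)
        regions = rng.choice(80, 12, replace=False)
        cfg = AnalysisConfig(n_perm=500, seed=77)
        out1 = chromosome_enrichment_mc(regions, grid, cfg)
        out2 = chromosome_enrichment_mc(regions, grid, cfg)
        pd.testing.assert_frame_equal(out1, out2)

    def test_invalid_inputs_rejected(self):
        grid = BinGrid({"chr1": 1_000_000}, 100_000)
        with pytest.raises(ValueError):
            AnalysisConfig(n_perm=0)
        with pytest.raises(ValueError, match="at least one region"):
            chromosome_enrichment_mc([], grid, AnalysisConfig(n_perm=10))
        with pytest.raises(ValueError, match="more regions"):
            chromosome_enrichment_mc(np.arange(10), grid,
                                     AnalysisConfig(n_perm=10),
                                     assignable=np.arange(10) < 5)


class TestRegionGeneEnrichmentMC:
    @staticmethod
    def _genes(grid, n, rng, prefix="g"):
        bins = grid.bins()
        picks = rng.choice(len(bins), n, replace=True)
        return pd.DataFrame({
            "chromosome": bins.iloc[picks]["chromosome"].to_numpy(),
            "start": bins.iloc[picks]["start"].to_numpy() + 10_000,
            "end": bins.iloc[picks]["start"].to_numpy() + 30_000,
            "gene_id": [f"{prefix}{i}" for i in range(n)],
        })

    def test_saturated_case_gives_p_one(self, rng):
        grid = BinGrid({"chr1": 2_000_000}, 100_000)
        genes = self._genes(grid, 5, rng)
        out = region_gene_enrichment_mc(
            np.arange(grid.n_bins), genes, set(genes["gene_id"]), grid,
            AnalysisConfig(n_perm=50, seed=1))
        assert out["p_value"] == 1.0

    def test_no_overlap_floor_case(self, rng):
        grid = BinGrid({"chr1": 2_000_000}, 100_000)
        genes = self._genes(grid, 5, rng).assign(start=0, end=20_000,
                                                 chromosome="chr1")
        out = region_gene_enrichment_mc(
            [grid.n_bins - 1], genes, set(genes["gene_id"]), grid,
            AnalysisConfig(n_perm=50, seed=1))
        assert out["observed"] == 0.0
        assert out["p_value"] == 1.0

    def test_planted_enrichment_detected(self):
        """Flagged genes concentrated in the region set give a small
        one-tailed p."""
        rng = np.random.default_rng(9)
        grid = BinGrid({"chr1": 40_000_000}, 100_000)
        regions = rng.choice(grid.n_bins, 40, replace=False)
        in_bins = rng.choice(regions, 25)
        out_bins = rng.choice(np.setdiff1d(np.arange(grid.n_bins), regions),
                              25)
        all_bins = np.concatenate([in_bins, out_bins])
        genes = pd.DataFrame({
            "chromosome": "chr1",
            "start": all_bins * 100_000 + 1_000,
            "end": all_bins * 100_000 + 50_000,
            "gene_id": [f"g{i}" for i in range(50)],
        })
        flagged = {f"g{i}" for i in range(25)}   # the in-region genes
        out = region_gene_enrichment_mc(
            regions, genes, flagged, grid, AnalysisConfig(n_perm=2000,
                                                          seed=2))
        assert out["p_value"] <= 0.01

    def test_empty_gene_table_rejected(self):
        grid = BinGrid({"chr1": 1_000_000}, 100_000)
        with pytest.raises(ValueError, match="empty gene table"):
            region_gene_enrichment_mc([0], pd.DataFrame(), set(), grid,
                                      AnalysisConfig(n_perm=5))
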