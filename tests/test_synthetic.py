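"""Generator contracts: determinism, balance, moments, planted structure."""

import numpy as np
import pandas as pd
import pytest

from cafeqg.synthetic import (
    ConfigurationError,
    SimulationConfig,
    simulate_annotation,
    simulate_consumption,
    simulate_genotypes,
    simulate_network,
    simulate_study,
    write_fixtures,
)
from cafeqg import io


class TestConfig:
    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError, match="L×E"):
            SimulationConfig(variance_components={"L×E": -1.0})

    def test_nonzero_sum_fixed_effect_rejected(self):
        with pytest.raises(ConfigurationError, match="sum to zero"):
            SimulationConfig(fixed_effects={"S": np.array([1.0, 0.0])})

    def test_infeasible_maf_range(self):
        with pytest.raises(ConfigurationError, match="infeasible"):
            simulate_genotypes(SimulationConfig(n_lines=10, maf_range=(0.01, 0.04)))

    def test_module_larger_than_universe(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=5, planted_module_size=6)


class TestConsumption:
    def test_same_seed_byte_identical(self):
        cfg = SimulationConfig(n_lines=6, n_vials=2, seed=3)
        a, _ = simulate_consumption(cfg)
        b, _ = simulate_consumption(SimulationConfig(n_lines=6, n_vials=2, seed=3))
        assert a.equals(b)
        c, _ = simulate_consumption(SimulationConfig(n_lines=6, n_vials=2, seed=4))
        assert not a.equals(c)

    def test_balanced_every_cell(self):
        cfg = SimulationConfig(n_lines=5, n_vials=3)
        records, _ = simulate_consumption(cfg)
        flies = records[records.is_control == 0]
        counts = flies.groupby(["line_id", "sex", "exposure", "solution"]).size()
        assert (counts == 3).all()
        assert len(counts) == 5 * 2 * 3 * 2

    def test_line_effect_reused_across_cells(self):
        """The truth record's line draw enters every cell of that line."""
        cfg = SimulationConfig(
            n_lines=4, n_vials=2, seed=5,
            variance_components={"L": 100.0, "L×E": 0, "L×S": 0, "L×X": 0,
                                 "L×E×S": 0, "L×E×X": 0, "L×S×X": 0,
                                 "L×E×S×X": 0, "residual": 0},
            fixed_effects={"E": np.zeros(3), "S": np.zeros(2), "X": np.zeros(2)},
            evaporation_sd_mm=0.0,
        )
        records, truth = simulate_consumption(cfg)
        from cafeqg.traits import correct_evaporation
        corrected = correct_evaporation(records)
        per_line = corrected.groupby("line_id")["consumption_mm"].std()
        assert np.allclose(per_line, 0.0, atol=1e-9)  # constant within line
        means = corrected.groupby("line_id")["consumption_mm"].mean()
        expected = np.clip(cfg.grand_mean + truth["random_effects"]["L"], 0, None)
        assert np.allclose(np.sort(means), np.sort(expected), atol=1e-9)

    def test_line_effect_moment_check(self):
        """At 200+ lines the sample variance of the drawn line effects is
        within 3 standard errors of the configured component."""
        v = 60.0
        cfg = SimulationConfig(n_lines=250, n_vials=1, seed=9,
                               variance_components={"L": v, "residual": 10.0})
        _, truth = simulate_consumption(cfg)
        draws = truth["random_effects"]["L"]
        se = v * np.sqrt(2.0 / (len(draws) - 1))
        assert abs(np.var(draws, ddof=1) - v) < 3 * se


class TestGenotypes:
    def test_minor_count_respects_maf_floor(self):
        geno, _, _ = simulate_genotypes(SimulationConfig(n_variants=300, seed=2))
        minor = np.minimum((geno.calls == 2).sum(0), (geno.calls == 0).sum(0))
        assert minor.min() >= int(np.ceil(0.05 * 46)) == 3
        assert (geno.maf() >= 0.05).all()

    def test_positions_sorted_one_based(self):
        geno, _, _ = simulate_genotypes(SimulationConfig(n_variants=100, seed=2))
        assert geno.variants["pos"].is_monotonic_increasing
        assert geno.variants["pos"].min() >= 1

    def test_causal_shift_applied_to_line_means(self):
        cfg = SimulationConfig(n_variants=50, n_causal=1, causal_effect_mm=4.0, seed=6)
        lm = pd.DataFrame({
            "line_id": np.repeat(cfg.line_ids, 2),
            "sex": ["F", "M"] * cfg.n_lines,
            "drug_E1": 0.0,
        })
        geno, adjusted, truth = simulate_genotypes(cfg, line_means=lm)
        j = int(np.flatnonzero(geno.variants["id"] == truth["causal_variants"][0])[0])
        minor_lines = {cfg.line_ids[i] for i in np.flatnonzero(geno.calls[:, j] == 2)}
        vals = adjusted.set_index("line_id")["drug_E1"]
        for line in cfg.line_ids:
            expected = 2.0 if line in minor_lines else -2.0
            assert (vals.loc[line] == expected).all()


class TestNetwork:
    def test_no_background_isolates_the_module(self):
        cfg = SimulationConfig(n_genes=40, planted_module_size=5,
                               background_edge_prob=0.0, seed=4)
        g, truth = simulate_network(cfg)
        comps = [c for c in __import__("networkx").connected_components(g) if len(c) >= 2]
        assert len(comps) == 1
        assert set(truth["module_genes"]) <= comps[0]

    def test_no_module_no_background_means_no_edges(self):
        cfg = SimulationConfig(n_genes=30, planted_module_size=0,
                               background_edge_prob=0.0)
        g, truth = simulate_network(cfg)
        assert g.number_of_edges() == 0 and truth["module_genes"] == []

    def test_er_edge_count_binomial(self):
        p, n = 0.1, 100
        cfg = SimulationConfig(n_genes=n, planted_module_size=0,
                               background_edge_prob=p, seed=8)
        g, _ = simulate_network(cfg)
        n_pairs = n * (n - 1) // 2
        mean, sd = p * n_pairs, np.sqrt(n_pairs * p * (1 - p))
        assert abs(g.number_of_edges() - mean) < 3 * sd

    def test_simple_graph_invariants(self, small_study):
        g = small_study.network
        assert all(a != b for a, b in g.edges)
        assert g.number_of_nodes() == small_study.config.n_genes


class TestFixtures:
    def test_round_trip_and_manifest(self, small_study, tmp_path):
        manifest = write_fixtures(small_study, tmp_path)
        assert len(manifest) == 5
        assert all(p.stat().st_size > 0 for p in manifest.values())

        cons = io.read_consumption(manifest["consumption"])
        pd.testing.assert_frame_equal(
            cons, small_study.consumption.reset_index(drop=True),
            check_dtype=False, atol=1e-9)

        geno = io.read_vcf(manifest["genotypes"])
        assert geno.line_ids == small_study.genotypes.line_ids
        assert np.array_equal(geno.calls, small_study.genotypes.calls)

        ann = io.read_bed(manifest["annotation"])
        pd.testing.assert_frame_equal(
            ann[["chrom", "start", "end", "strand"]],
            small_study.annotation[["chrom", "start", "end", "strand"]],
            check_dtype=False)

        import networkx as nx
        g = io.read_edges(manifest["network"])
        assert set(g.nodes) == set(small_study.network.nodes)
        assert set(map(frozenset, g.edges)) == set(map(frozenset,
                                                       small_study.network.edges))

    def test_vcf_genotypes_all_homozygous(self, small_study, tmp_path):
        path = io.write_vcf(small_study.genotypes, tmp_path / "g.vcf")
        gts = set()
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            gts.update(line.split("\t")[9:])
        assert gts <= {"0/0", "1/1"}


def test_study_truth_is_complete(small_study):
    t = small_study.truth
    assert set(t["causal_genes"]) <= set(t["module_genes"])
    assert len(t["causal_variants"]) == small_study.config.n_causal
    assert set(t["random_effects"]) == {
        "L", "L×E", "L×S", "L×X", "L×E×S", "L×E×X", "L×S×X", "L×E×S×X"}
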