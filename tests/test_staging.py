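"""Staged contrasts, gene mapping, shared-gene inversion, specific sets."""

import numpy as np
import pandas as pd
import pytest

from lamethyl import diffmeth, preprocess, staging, synthetic
from lamethyl.containers import Comparison


def _sites(rows):
    """site-result stub: (probe_id, direction, significant)."""
    return pd.DataFrame(rows, columns=["probe_id", "direction", "significant"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_symbol", "direction"])


class TestRunComparison:
    def test_unknown_name_rejected(self, small_manifest, design):
        signals, _ = synthetic.simulate_intensities(small_manifest, design, seed=0)
        betas = preprocess.compute_beta_matrix(signals)
        with pytest.raises(ValueError, match="unknown comparison"):
            staging.run_comparison(betas, design, "Normal_vs_TypeII")

    def test_swapping_sides_flips_delta_sign(self, small_manifest, design):
        signals, _ = synthetic.simulate_intensities(small_manifest, design, seed=1)
        betas = preprocess.compute_beta_matrix(signals)
        fwd = staging.run_comparison(betas, design, "TypeI_vs_Normal").set_index("probe_id")
        rev_cmp = Comparison.from_design("rev", "Normal", "TypeI", design)
        rev = diffmeth.call_sites(betas, rev_cmp).set_index("probe_id")
        joined = fwd.join(rev, lsuffix="_f", rsuffix="_r")
        assert np.allclose(joined["delta_beta_f"], -joined["delta_beta_r"])

    def test_occurrence_effect_absent_from_progression(self, design):
        man = synthetic.make_manifest(60, 4, seed=3)
        # Type II keeps the Type I level: visible at occurrence, silent at progression
        planted = pd.DataFrame({
            "probe_id": man["probe_id"].iloc[:5],
            "base_beta": 0.3,
            "effect_typeI": 0.3,
            "effect_typeII": 0.3,
        })
        signals, _ = synthetic.simulate_intensities(man, design, truth=planted, noise_sd=0.01, seed=4)
        betas = preprocess.compute_beta_matrix(signals)
        occ = staging.run_comparison(betas, design, staging.OCCURRENCE)
        prog = staging.run_comparison(betas, design, staging.PROGRESSION)
        planted_ids = set(planted["probe_id"])
        occ_sig = set(occ.loc[occ["significant"], "probe_id"])
        prog_sig = set(prog.loc[prog["significant"], "probe_id"])
        assert planted_ids <= occ_sig
        assert not planted_ids & prog_sig


class TestMapToGenes:
    MAN = pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3", "cg4", "cg5"],
        "chromosome": ["chr1"] * 5,
        "position": [1, 2, 3, 4, 5],
        "island_relation": ["OpenSea"] * 5,
        "gene_symbol": ["A", "A", "A", "B", ""],
        "gene_feature": ["Body", "Body", "TSS200", "Body", "Intergenic"],
        "strand": ["+"] * 5,
    })

    def test_unanimous_probes_collapse_to_one_direction(self):
        sites = _sites([("cg1", "hyper", True), ("cg2", "hyper", True), ("cg3", "hyper", True)])
        sites["comparison"] = "TypeI_vs_Normal"
        out = staging.map_to_genes(sites, self.MAN)
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "hyper"
        assert out.iloc[0]["n_probes"] == 3

    def test_disagreeing_probes_are_mixed(self):
        sites = _sites([("cg1", "hyper", True), ("cg2", "hypo", True)])
        sites["comparison"] = "TypeI_vs_Normal"
        out = staging.map_to_genes(sites, self.MAN)
        assert out.iloc[0]["direction"] == "mixed"

    def test_intergenic_sites_excluded_and_empty_ok(self):
        sites = _sites([("cg5", "hyper", True)])
        sites["comparison"] = "x"
        assert staging.map_to_genes(sites, self.MAN).empty
        assert staging.map_to_genes(sites.iloc[:0], self.MAN).empty


class TestClassifyShared:
    def test_printed_gene_lists_reproduce_28_4_87point5(self):
        fx = synthetic.load_shared_gene_fixture()
        occ, prog = fx.to_gene_results()
        cls = staging.classify_shared(occ, prog)
        assert cls.n_shared == 32
        assert cls.n_inverse == 28
        assert cls.n_same == 4
        assert cls.percent_inverse == pytest.approx(87.5)

    def test_disjoint_inputs_give_empty(self):
        cls = staging.classify_shared(_genes([("A", "hyper")]), _genes([("B", "hypo")]))
        assert cls.n_shared == 0

    def test_constructed_enumeration(self):
        occ = _genes([("A", "hyper"), ("B", "hyper"), ("C", "hypo")])
        prog = _genes([("A", "hyper"), ("B", "hypo"), ("C", "hyper")])
        cls = staging.classify_shared(occ, prog)
        assert cls.n_same == 1 and cls.n_inverse == 2
        cats = dict(zip(cls.records["gene_symbol"], cls.records["category"]))
        assert cats == {"A": "same_hyper", "B": "hyper_to_hypo", "C": "hypo_to_hyper"}

    def test_mixed_direction_genes_excluded_with_count(self):
        occ = _genes([("A", "hyper"), ("B", "mixed")])
        prog = _genes([("A", "hyper"), ("B", "hyper")])
        cls = staging.classify_shared(occ, prog)
        assert cls.n_shared == 1
        assert cls.n_mixed_excluded == 1

    def test_categories_partition_shared_set(self):
        fx = synthetic.load_shared_gene_fixture()
        occ, prog = fx.to_gene_results()
        cls = staging.classify_shared(occ, prog)
        assert cls.n_inverse + cls.n_same == cls.n_shared


class TestDeriveSpecific:
    def test_set_arithmetic(self):
        occ, prog = staging.derive_specific({"A", "B"}, {"B", "C"}, {"A", "B", "C"})
        assert occ == {"A"} and prog == {"C"}

    def test_empty_progression_boundary(self):
        occ, prog = staging.derive_specific({"A", "B"}, set(), {"A", "C"})
        assert occ == {"A"} and prog == set()

    def test_all_equal_gives_empty(self):
        s = {"A", "B"}
        occ, prog = staging.derive_specific(s, s, s)
        assert occ == set() and prog == set()

    def test_outputs_disjoint(self):
        rng = np.random.default_rng(0)
        pool = [f"G{i}" for i in range(30)]
        for _ in range(20):
            occ = set(rng.choice(pool, 10, replace=False))
            prog = set(rng.choice(pool, 10, replace=False))
            overall = set(rng.choice(pool, 10, replace=False))
            a, b = staging.derive_specific(occ, prog, overall)
            assert not a & b

    def test_variant_without_exclusion(self):
        occ, prog = staging.derive_specific({"A", "B"}, {"B", "C"}, {"A", "B", "C"},
                                            exclude_other=False)
        assert occ == {"A", "B"} and prog == {"B", "C"}


class TestPlantedStageRecovery:
    def test_planted_roles_recovered(self, design):
        """Planted occurrence-specific genes land in the derived occurrence set."""
        man = synthetic.make_manifest(800, 30, seed=10)
        hits = total = 0
        for seed in range(3):
            planted, gene_truth = synthetic.plant_stage_effects(
                man, seed=seed, n_occurrence=5, n_progression=5, n_inverse=5, n_same=3
            )
            signals, _ = synthetic.simulate_intensities(
                man, design, truth=planted, noise_sd=0.02, seed=seed + 100
            )
            betas = preprocess.compute_beta_matrix(signals)
            tables = {
                name: staging.map_to_genes(staging.run_comparison(betas, design, name), man)
                for name in staging.COMPARISONS
            }
            occ_s, prog_s = staging.derive_specific(
                tables[staging.OCCURRENCE], tables[staging.PROGRESSION], tables[staging.OVERALL]
            )
            want = set(gene_truth.loc[gene_truth["role"] == "occurrence_specific", "gene_symbol"])
            hits += len(want & occ_s)
            total += len(want)
        assert hits / total >= 0.8
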