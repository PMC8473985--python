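"""Birth-death simulator: exact degenerate behaviour, expectations, truth."""

import math

import numpy as np
import pytest

import orthodiv as od
from orthodiv.simulate import BDParams, DEFAULT_SPECIES_TREE


class TestSimulateGeneFamily:
    def test_zero_rates_exact_structure(self):
        fam = od.simulate_gene_family(
            DEFAULT_SPECIES_TREE, BDParams(birth=0, death=0, n_root=4), 0
        )
        assert fam.counts == {"Ccas": 4, "Cper": 4, "Csow": 4}
        assert len(fam.true_orthogroups) == 4
        for og in fam.true_orthogroups:
            assert og.species_present == {"Ccas", "Cper", "Csow"}
            assert not og.in_paralog_clusters
        assert not fam.events

    def test_pure_birth_monotone_growth(self):
        for seed in range(10):
            fam = od.simulate_gene_family(
                DEFAULT_SPECIES_TREE, BDParams(birth=0.1, death=0.0, n_root=2), seed
            )
            assert all(c >= 2 for c in fam.counts.values())

    def test_truth_partitions_leaves(self):
        fam = od.simulate_gene_family(
            DEFAULT_SPECIES_TREE, BDParams(birth=0.06, death=0.03, n_root=5), 3
        )
        members = sorted(
            m for og in fam.true_orthogroups for m in og.members
        )
        assert members == sorted(fam.gene_tree.leaf_labels)
        assert sum(fam.counts.values()) == len(fam.gene_tree.leaf_labels)

    def test_all_lost_is_valid_empty_family(self):
        fam = od.simulate_gene_family(
            DEFAULT_SPECIES_TREE, BDParams(birth=0.0, death=5.0, n_root=2), 0
        )
        assert fam.gene_tree is None
        assert all(c == 0 for c in fam.counts.values())
        assert len(fam.true_orthogroups) == 0

    def test_branch_lengths_are_time_spans(self):
        fam = od.simulate_gene_family(
            DEFAULT_SPECIES_TREE, BDParams(birth=0.05, death=0.0, n_root=1), 12
        )
        # every root-to-leaf path length equals the species-tree depth
        tree = fam.gene_tree.tree
        for leaf in tree.leaf_node_iter():
            depth, nd = 0.0, leaf
            while nd.parent_node is not None:
                depth += nd.edge.length or 0.0
                nd = nd.parent_node
            assert depth == pytest.approx(12.0, abs=1e-9)

    def test_non_ultrametric_tree_rejected(self):
        with pytest.raises(Exception, match="ultrametric"):
            od.simulate_gene_family("((A:1,B:2):1,C:3);", BDParams(), 0)

    def test_expected_copy_number_small(self):
        # E[N_T] = n0 * exp((birth-death) * T) for a linear birth-death process
        birth, death, T, n0, reps = 0.25, 0.1, 1.0, 2, 800
        newick = "((Csow:0.5,Cper:0.5):0.5,Ccas:1.0);"
        means = []
        for seed in range(reps):
            fam = od.simulate_gene_family(
                newick, BDParams(birth=birth, death=death, n_root=n0), seed
            )
            means.append(np.mean(list(fam.counts.values())))
        expected = n0 * math.exp((birth - death) * T)
        se = np.std(means, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(means) - expected) < 3 * se

    def test_orthology_recovers_truth_when_duplication_rare(self):
        exact = 0
        total = 0
        for seed in range(30):
            fam = od.simulate_gene_family(
                DEFAULT_SPECIES_TREE, BDParams(birth=0.001, death=0.0, n_root=3), seed
            )
            if fam.gene_tree is None or len(fam.gene_tree.leaves) < 2:
                continue
            if fam.events:
                continue  # only the no-duplication replicates are exact by contract
            got = {og.members for og in od.extract_orthogroups(fam.gene_tree)}
            want = {og.members for og in fam.true_orthogroups}
            exact += got == want
            total += 1
        assert total > 20 and exact == total


class TestSimulateRepertoire:
    def test_zero_rate_repertoire_uniform_diversity(self):
        specs = [
            ("SFA", 10, BDParams(birth=0, death=0)),
            ("SFB", 10, BDParams(birth=0, death=0)),
        ]
        ds = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=5)
        assert len(ds.abundance.table) == 20
        per_og = od.orthogroup_diversity(ds.abundance)
        assert per_og["H"].tolist() == pytest.approx([math.log(3)] * 20, abs=1e-12)
        pooled = od.species_diversity(ds.abundance)
        assert pooled["H"].tolist() == pytest.approx([math.log(20)] * 3, abs=1e-12)

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        specs = [("SFA", 6, BDParams(birth=0.04, death=0.02))]
        od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=9, out_dir=tmp_path / "a")
        od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=9, out_dir=tmp_path / "b")
        for name in ("SFA.nwk", "registry.tsv", "truth_clusters.tsv", "truth_abundance.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        specs = [("SFA", 6, BDParams(birth=0.04, death=0.02))]
        a = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=1)
        b = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=2)
        assert not a.abundance.table.equals(b.abundance.table)

    def test_specialist_multiplier_lowers_pooled_diversity(self):
        """A 3x duplication/loss multiplier on one terminal branch concentrates
        that species' genes into fewer, larger in-paralog clusters."""
        reps = 40
        gap = []
        for seed in range(reps):
            specs = [
                ("SF1", 25, BDParams(birth=0.03, death=0.01, rate_multipliers={"Ccas": 3.0}))
            ]
            ds = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=seed)
            pooled = od.species_diversity(ds.abundance)
            h = dict(zip(pooled["species"], pooled["H"]))
            gap.append(0.5 * (h["Csow"] + h["Cper"]) - h["Ccas"])
        assert np.mean(gap) > 0


class TestSimulateGlmmCounts:
    def test_zero_truncated_mean(self):
        obs = od.simulate_glmm_counts(
            25_000, ["A"], ["S"], beta0=0.0, seed=0, zero_truncated=True
        )
        x = obs["count"].to_numpy()
        assert x.min() >= 1
        expected = 1.0 / (1.0 - math.exp(-1.0))  # ~1.582
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - expected) < 3 * se

    def test_overdispersion_inflates_variance(self):
        obs = od.simulate_glmm_counts(
            5000, ["A"], ["S"], beta0=0.5, sigma2_e=1.0, seed=1, zero_truncated=False
        )
        x = obs["count"].to_numpy()
        assert x.var() > 1.5 * x.mean()

    def test_fixed_seed_identical(self):
        a = od.simulate_glmm_counts(50, ["A", "B"], ["S1", "S2"], beta0=0.3, seed=4)
        b = od.simulate_glmm_counts(50, ["A", "B"], ["S1", "S2"], beta0=0.3, seed=4)
        assert a.equals(b)


class TestInjectDefects:
    def test_truth_table_matches_classifier(self, rng):
        records = od.make_intact_repertoire(9, rng)
        out, truth = od.inject_sequence_defects(
            records, {"too_short": 3, "premature_stop": 3, "frameshift": 2}, seed=2
        )
        for record, (_, row) in zip(out, truth.iterrows()):
            cls, reason = od.classify_sequence(str(record.seq))
            assert cls == ("intact" if row["defect"] == "none" else "pseudogene")
            if row["defect"] == "too_short":
                assert reason == "too_short"
            if row["defect"] == "premature_stop":
                assert reason == "premature_stop"

    def test_no_defects_identity(self, rng):
        records = od.make_intact_repertoire(3, rng)
        out, truth = od.inject_sequence_defects(records, {}, seed=0)
        assert [str(r.seq) for r in out] == [str(r.seq) for r in records]
        assert (truth["defect"] == "none").all()

    def test_too_many_defects_rejected(self, rng):
        records = od.make_intact_repertoire(2, rng)
        with pytest.raises(ValueError, match="defects"):
            od.inject_sequence_defects(records, {"too_short": 3}, seed=0)

    def test_non_intact_input_rejected(self, rng):
        records = od.make_intact_repertoire(2, rng)
        records[0].seq = records[0].seq[:500]
        with pytest.raises(ValueError, match="not intact"):
            od.inject_sequence_defects(records, {"too_short": 1}, seed=0)
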