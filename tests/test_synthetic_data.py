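from dataclasses import replace

import numpy as np
import pytest

from barcodegap.distances import distance_matrix, k2p, partition
from barcodegap.synthetic_data import (
    OUTGROUP_ID,
    OUTGROUP_SPECIES,
    LocusSpec,
    SimulationParams,
    TreeNode,
    evolve_sequences,
    generate_dataset,
    nonmonophyletic_species,
    preset,
    simulate_gene_tree,
    simulate_species_tree,
)


def _leaf_depths(root):
    out = {}

    def rec(node, acc):
        if not node.children:
            out[node.name] = acc
        for c in node.children:
            rec(c, acc + (node.time - c.time))

    rec(root, 0.0)
    return out


class TestSpeciesTree:
    def test_sections_are_monophyletic_and_tree_ultrametric(self):
        params = SimulationParams(seed=3, n_sections=3, species_per_section=4,
                                  tree_depth=0.02)
        root, section_map = simulate_species_tree(params)
        depths = _leaf_depths(root)
        assert all(abs(d - root.time) < 1e-12 for d in depths.values())

        def leafsets(node):
            if not node.children:
                return [{node.name}]
            groups = []
            below = set()
            for c in node.children:
                sub = leafsets(c)
                groups.extend(sub)
                below |= set().union(*sub)
            groups.append(below)
            return groups

        clades = leafsets(root)
        for section in {v for v in section_map.values() if v != "outgroup"}:
            members = {sp for sp, sec in section_map.items() if sec == section}
            assert members in clades

    def test_two_by_two_shape(self):
        params = SimulationParams(seed=1, n_sections=2, species_per_section=2,
                                  include_outgroup=False)
        root, section_map = simulate_species_tree(params)
        assert len(root.leaves()) == 4
        assert len(set(section_map.values())) == 2

    def test_depth_pinned_to_parameter(self):
        params = SimulationParams(seed=2, n_sections=4, species_per_section=3,
                                  tree_depth=0.05, include_outgroup=False)
        root, _ = simulate_species_tree(params)
        assert root.time == pytest.approx(0.05)


class TestGeneTree:
    def _setup(self, theta, ils, seed=11):
        params = SimulationParams(seed=seed, n_sections=2, species_per_section=3,
                                  tree_depth=0.03, include_outgroup=False)
        rng = np.random.default_rng(seed)
        sp_root, section_map = simulate_species_tree(params, rng)
        samples = {sp: [f"{sp}_{i}" for i in range(3)] for sp in section_map}
        gt = simulate_gene_tree(sp_root, theta, ils, samples, rng)
        true_sp = {sid: sp for sp, sids in samples.items() for sid in sids}
        return gt, true_sp

    def test_collapse_limit_matches_species_tree(self):
        gt, true_sp = self._setup(theta=0.0, ils=0.0)
        # all within-species nodes at depth zero, every species monophyletic
        assert nonmonophyletic_species(gt, true_sp) == set()
        depths = _leaf_depths(gt)
        assert all(d >= 0 for d in depths.values())

    def test_ils_increases_non_monophyly(self):
        lo = hi = 0
        for seed in range(5):
            gt0, sp0 = self._setup(theta=0.004, ils=0.0, seed=100 + seed)
            gt1, sp1 = self._setup(theta=0.004, ils=0.8, seed=100 + seed)
            lo += len(nonmonophyletic_species(gt0, sp0))
            hi += len(nonmonophyletic_species(gt1, sp1))
        assert hi > lo
        assert hi > 0

    def test_all_samples_present_as_leaves(self):
        gt, true_sp = self._setup(theta=0.002, ils=0.3)
        assert {l.name for l in gt.leaves()} == set(true_sp)


class TestEvolveSequences:
    def test_zero_length_tree_identical_sequences(self):
        rng = np.random.default_rng(0)
        a = TreeNode(name="x", time=0.0)
        b = TreeNode(name="y", time=0.0)
        root = TreeNode(time=0.0, children=[a, b])
        a.parent_time = b.parent_time = 0.0
        rows, _ = evolve_sequences(root, LocusSpec("l", 500), 2.0, rng)
        assert rows["x"] == rows["y"]

    def test_branch_length_recovered_by_k2p(self):
        # two leaves at patristic distance 0.2; K2P should estimate it
        ds = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            a = TreeNode(name="x", time=0.0)
            b = TreeNode(name="y", time=0.0)
            root = TreeNode(time=0.1, children=[a, b])
            a.parent_time = b.parent_time = 0.1
            rows, _ = evolve_sequences(root, LocusSpec("l", 4000), 2.0, rng)
            ds.append(k2p(rows["x"], rows["y"]).d)
        assert np.mean(ds) == pytest.approx(0.2, rel=0.05)

    def test_ledger_distances_match_gene_tree(self):
        ds = generate_dataset(preset("gapped", 8))
        paths = ds.ledger.pairwise_path_lengths("locusA")
        sids = ds.alignments["locusA"].sample_ids[:6]
        for i, a in enumerate(sids):
            for b in sids[i + 1 :]:
                key = (a, b) if a < b else (b, a)
                assert paths[key] > 0


class TestGenerateDataset:
    def test_same_seed_byte_identical(self):
        d1 = generate_dataset(preset("gapped", 9))
        d2 = generate_dataset(preset("gapped", 9))
        assert d1.alignments["locusA"].rows == d2.alignments["locusA"].rows
        assert d1.records == d2.records
        assert d1.ledger.species_tree_newick == d2.ledger.species_tree_newick

    def test_written_outputs_round_trip(self, tmp_path):
        from barcodegap.io_metadata import read_fasta_alignment, read_metadata

        ds = generate_dataset(preset("gapped", 10))
        ds.write(tmp_path)
        aln = read_fasta_alignment(tmp_path / "locusA.fasta", "locusA")
        assert aln.rows == ds.alignments["locusA"].rows
        recs = read_metadata(tmp_path / "metadata.tsv")
        assert recs == ds.records
        assert (tmp_path / "truth_ledger.json").exists()

    def test_fraxinus_preset_shape(self):
        params = preset("fraxinus-like", 1)
        ds = generate_dataset(params)
        ingroup = [r for r in ds.records if r.species != OUTGROUP_SPECIES]
        assert len(ingroup) == 253
        species = {r.species for r in ingroup}
        assert len(species) == 56
        sections = {r.section for r in ingroup}
        assert len(sections) == 6
        assert set(ds.alignments) == {"spacerA", "spacerB"}
        assert ds.alignments["spacerA"].n_columns == 698
        assert ds.alignments["spacerB"].n_columns == 1023
        # singletons present, per-species counts within the declared range
        from collections import Counter

        counts = Counter(ds.ledger.true_species[s.sample_id] for s in ingroup)
        assert sum(1 for c in counts.values() if c == 1) == 7
        assert max(counts.values()) <= 28

    def test_mislabel_ledger_consistency(self):
        params = replace(preset("gapped", 12), mislabel_rate=0.05)
        ds = generate_dataset(params)
        assert ds.ledger.label_swaps
        recs = {r.sample_id: r for r in ds.records}
        for swap in ds.ledger.label_swaps:
            r = recs[swap["sample_id"]]
            assert r.species == swap["assigned_species"]
            assert swap["assigned_species"] != swap["true_species"]
            assert (
                ds.ledger.section_map[swap["assigned_species"]]
                != ds.ledger.section_map[swap["true_species"]]
            )

    def test_regime_calibration_across_seeds(self):
        """Mean intra/inter K2P (per 100 sites) stays inside the declared
        envelope (1.0 and 2.0 +/- 50%) averaged over ten seeds."""
        intra_means, inter_means = [], []
        for seed in range(1, 11):
            ds = generate_dataset(preset("fraxinus-like", seed))
            aln = ds.alignments["spacerA"]
            ids = [s for s in aln.sample_ids if s != OUTGROUP_ID]
            m = distance_matrix(aln.subset(ids))
            recs = [r for r in ds.records if r.sample_id in set(ids)]
            part = partition(m, recs)
            intra_means.append(100 * part.intra_values.mean())
            inter_means.append(100 * part.inter_values.mean())
        assert 0.5 <= np.mean(intra_means) <= 1.5
        assert 1.0 <= np.mean(inter_means) <= 3.0

    def test_discrimination_monotone_in_divergence_ratio(self):
        from barcodegap.report import evaluate_dataset

        fractions = []
        for depth in (0.004, 0.02, 0.08):
            vals = []
            for seed in (1, 2, 3):
                params = replace(preset("gapped", seed), tree_depth=depth)
                ds = generate_dataset(params)
                res = evaluate_dataset(
                    "locusA", ds.alignments["locusA"], ds.records, OUTGROUP_ID
                )
                vals.append(
                    res["n_species_discriminated_nj"] / res["n_multisample_species"]
                )
            fractions.append(np.mean(vals))
        assert fractions[0] <= fractions[1] + 1e-9 <= fractions[2] + 2e-9


class TestParamValidation:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(seed=1, theta=-1)
        with pytest.raises(ValueError):
            SimulationParams(seed=1, kappa=0)
        with pytest.raises(ValueError):
            LocusSpec("x", 50)
        with pytest.raises(ValueError):
            preset("nope", 1)
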