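"""Phylogeny I/O and the synthetic-data generators."""

import numpy as np
import pytest

from psgscan import codons
from psgscan.errors import InvalidArgumentError, InvalidTreeError, UnknownBranchError
from psgscan.selection import BranchSiteParams
from psgscan.simulate import (
    CountSimSpec,
    simulate_cds_catalog,
    simulate_codon_alignment,
    simulate_counts,
    simulate_tree,
)
from psgscan.trees import Phylogeny


class TestNewick:
    def test_plain_tree_no_foreground(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert sorted(t.leaf_names) == ["A", "B", "C"]
        assert t.foreground is None

    def test_foreground_tag_on_leaf(self):
        t = Phylogeny.from_newick("((A:0.1 #1,B:0.1):0.05,C:0.2);")
        assert t.foreground is not None
        assert t.labels[t.foreground] == "A"

    def test_foreground_tag_on_internal_node(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1) #1:0.05,C:0.2);")
        assert t.foreground is not None
        assert t.clade_leaves(t.foreground) == ["A", "B"]

    def test_two_tags_rejected(self):
        with pytest.raises(InvalidTreeError):
            Phylogeny.from_newick("((A:0.1 #1,B:0.1 #1):0.05,C:0.2);")

    def test_missing_lengths_rejected(self):
        with pytest.raises(InvalidTreeError):
            Phylogeny.from_newick("((A,B),C);")

    def test_nonbinary_rejected(self):
        with pytest.raises(InvalidTreeError):
            Phylogeny.from_newick("(A:0.1,B:0.1,C:0.1,D:0.1);")

    def test_roundtrip_preserves_topology_and_tag(self):
        t = Phylogeny.from_newick("((A:0.1 #1,B:0.12):0.05,C:0.2);")
        t2 = Phylogeny.from_newick(t.to_newick())
        assert t2.to_newick() == t.to_newick()
        assert t2.labels[t2.foreground] == "A"

    def test_find_branch_by_clade_id(self):
        t = Phylogeny.from_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        node = t.find_branch("A+B")
        assert t.clade_leaves(node) == ["A", "B"]
        with pytest.raises(UnknownBranchError):
            t.find_branch("A+C")


class TestSimulateTree:
    def test_two_taxa_total_path_length(self):
        t = simulate_tree(2, 0.1, seed=7)
        assert len(t.leaves) == 2
        total = t.lengths.sum()
        assert 0.1 <= total <= 0.3  # two branches, each Uniform(0.05, 0.15)

    def test_branch_count_rooted_binary(self):
        t = simulate_tree(6, 0.3, seed=1)
        assert len(t.leaves) == 6
        assert t.n_branches == 10  # 2n - 2
        assert np.all(t.lengths[np.arange(t.n_nodes) != t.root] > 0)

    def test_deterministic_newick(self):
        assert simulate_tree(5, 0.05, seed=3).to_newick() == simulate_tree(5, 0.05, seed=3).to_newick()

    def test_too_few_taxa(self):
        with pytest.raises(InvalidArgumentError):
            simulate_tree(1, 0.1, seed=0)

    def test_unique_leaf_names(self):
        t = simulate_tree(12, 0.05, seed=5)
        assert len(set(t.leaf_names)) == 12


class TestSimulateCodonAlignment:
    def test_zero_length_branches_identical_sequences(self, default_params):
        t = simulate_tree(4, 0.05, seed=2)
        t.lengths[:] = 0.0
        aln, _ = simulate_codon_alignment(t, default_params, 30, foreground="sp1", seed=4)
        assert len(set(aln.seqs)) == 1

    def test_zero_mass_classes_never_drawn(self):
        params = BranchSiteParams(kappa=2, omega0=0.3, omega2=7, p0=0.6, p1=0.4)
        t = simulate_tree(4, 0.05, seed=2).with_foreground("sp1")
        _, truth = simulate_codon_alignment(t, params, 400, seed=6)
        assert set(truth.site_classes) <= {"0", "1"}

    def test_class_frequencies_within_three_sds(self, four_taxon_tree, default_params):
        n = 10_000
        _, truth = simulate_codon_alignment(four_taxon_tree, default_params, n, seed=8)
        expect = {"0": 0.5, "1": 0.3, "2a": 0.125, "2b": 0.075}
        for cls, p in expect.items():
            observed = truth.site_classes.count(cls)
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(observed - n * p) <= 3 * sd

    def test_no_stop_codons(self, four_taxon_tree, default_params):
        aln, _ = simulate_codon_alignment(four_taxon_tree, default_params, 300, seed=10)
        for s in aln.seqs:
            for k in range(0, len(s), 3):
                assert s[k : k + 3] not in codons.STOP_CODONS

    def test_deterministic(self, four_taxon_tree, default_params):
        a1, t1 = simulate_codon_alignment(four_taxon_tree, default_params, 50, seed=11)
        a2, t2 = simulate_codon_alignment(four_taxon_tree, default_params, 50, seed=11)
        assert a1.seqs == a2.seqs and t1.site_classes == t2.site_classes

    def test_unknown_foreground(self, default_params):
        t = simulate_tree(4, 0.05, seed=2)
        with pytest.raises(UnknownBranchError):
            simulate_codon_alignment(t, default_params, 10, foreground="nope", seed=0)


class TestSimulateCounts:
    def test_null_world_all_lfc_zero(self):
        spec = CountSimSpec(n_genes=200, regulated_fraction=0.0, psg_count=0, seed=1)
        _, _, truth = simulate_counts(spec)
        assert all(v == 0.0 for v in truth.lfc_a.values())
        assert all(v == 0.0 for v in truth.lfc_b.values())

    def test_forced_quadrant_planting(self):
        spec = CountSimSpec(n_genes=300, psg_count=50, q1_prob=1.0, seed=2)
        _, _, truth = simulate_counts(spec)
        for g, sel in truth.gene_selected.items():
            if sel:
                assert truth.lfc_a[g] < 0 and truth.lfc_b[g] > 0

    def test_poisson_limit_variance(self):
        spec = CountSimSpec(
            n_genes=400, samples_a=(60, 60), samples_b=(2, 2),
            dispersion=1e-13, regulated_fraction=0.0, psg_count=0, seed=3,
        )
        ca, _, _ = simulate_counts(spec)
        young = ca.counts[:, ca.group_columns("young")].astype(float)
        ratio = young.var(axis=1, ddof=1) / np.maximum(young.mean(axis=1), 1e-9)
        # variance/mean concentrates near 1 in the Poisson limit
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_group_means_recover_fold_changes(self):
        spec = CountSimSpec(
            n_genes=200, samples_a=(100, 100), samples_b=(2, 2),
            dispersion=0.05, regulated_fraction=0.5, psg_count=0,
            min_effect=1.0, seed=4,
        )
        ca, _, truth = simulate_counts(spec)
        young = ca.counts[:, ca.group_columns("young")].mean(axis=1)
        old = ca.counts[:, ca.group_columns("old")].mean(axis=1)
        lfc_hat = np.log2(old / young)
        lfc_true = np.array([truth.lfc_a[g] for g in ca.genes])
        err = lfc_hat - lfc_true
        assert np.abs(np.median(err)) < 0.05
        assert np.percentile(np.abs(err), 90) < 0.25

    def test_counts_shape_and_labels(self):
        spec = CountSimSpec(n_genes=50, psg_count=5, seed=5)
        ca, cb, _ = simulate_counts(spec)
        assert ca.counts.shape == (50, 9)  # 6 young + 3 old
        assert cb.counts.shape == (50, 9)  # 4 young + 5 old
        assert ca.condition.count("young") == 6 and cb.condition.count("old") == 5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dispersion=0.0),
            dict(samples_a=(1, 3)),
            dict(q1_prob=1.5),
            dict(psg_count=10, n_genes=5),
        ],
    )
    def test_invalid_specs(self, kwargs):
        base = dict(n_genes=20, psg_count=2)
        base.update(kwargs)
        with pytest.raises(InvalidArgumentError):
            CountSimSpec(**base)


class TestSimulateCatalog:
    def test_zero_divergence_identical_orthologs(self):
        cats, truth = simulate_cds_catalog(5, 3, isoforms_per_gene=1, divergence=0.0, seed=6)
        by_gene = {}
        for sp, recs in cats.items():
            for r in recs:
                by_gene.setdefault(r.gene, set()).add(r.seq)
        assert all(len(seqs) == 1 for seqs in by_gene.values())

    def test_single_gene_pair(self):
        cats, truth = simulate_cds_catalog(1, 2, isoforms_per_gene=1, divergence=0.05, seed=7)
        assert len(truth.ortholog_pairs) == 1

    def test_cds_structure(self):
        cats, _ = simulate_cds_catalog(10, 2, isoforms_per_gene=3, divergence=0.1, seed=8)
        for recs in cats.values():
            for r in recs:
                assert r.seq.startswith("ATG")
                assert r.seq[-3:] in codons.STOP_CODONS
                assert len(r.seq) % 3 == 0
                body = r.seq[:-3]
                for k in range(0, len(body), 3):
                    assert body[k : k + 3] not in codons.STOP_CODONS

    def test_isoforms_share_core(self):
        cats, _ = simulate_cds_catalog(3, 1, isoforms_per_gene=2, divergence=0.0, seed=9)
        recs = cats["sp01"]
        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.gene, []).append(r)
        for rs in by_gene.values():
            core = min(rs, key=lambda r: len(r.seq)).seq[:-3]
            assert all(r.seq.startswith(core[:30]) for r in rs)
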