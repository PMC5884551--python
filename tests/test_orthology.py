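"""Reciprocal-best-hit orthology, isoform selection, codon alignments."""

import numpy as np
import pytest

from Bio.Align import substitution_matrices

from psgscan.errors import FrameError, InsufficientTaxaError, InvalidArgumentError
from psgscan.orthology import (
    CdsRecord,
    OrthologGroup,
    align_pair,
    assign_orthologs,
    build_codon_alignment,
    merge_dual_assemblies,
    pair_score,
    select_isoforms,
    translate_cds,
)
from psgscan.simulate import simulate_cds_catalog

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATGAAATAA", "MK"), ("ATGANA", "MX"), ("atgaaa", "MK"), ("ATG", "M")],
    )
    def test_translation(self, cds, protein):
        assert translate_cds(cds) == protein

    def test_internal_stop_raises(self):
        with pytest.raises(FrameError):
            translate_cds("ATGTAAAAA")

    def test_bad_length_raises(self):
        with pytest.raises(InvalidArgumentError):
            translate_cds("ATGA")


class TestAlignPair:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKWVLLLWVP"
        score, (a, b) = align_pair(seq, seq)
        assert a == seq and b == seq
        assert score == sum(BLOSUM62[c, c] for c in seq)

    def test_single_residue_pair_matches_brute_force(self):
        # best local score of ("A", "W"): either align the two cells or take
        # the empty alignment, whichever is larger
        score, _ = align_pair("A", "W")
        assert score == max(float(BLOSUM62["A", "W"]), 0.0)

    def test_scores_never_negative(self):
        assert pair_score("AAAA", "WWWW") >= 0.0

    def test_symmetry(self):
        a, b = "MKWVLLLW", "MKWLLLVW"
        assert pair_score(a, b) == pair_score(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidArgumentError):
            align_pair("", "MK")


def _rec(gene, species, isoform, seq, source="transcriptome"):
    return CdsRecord(gene=gene, species=species, isoform=isoform, seq=seq, source=source)


def _cds_from_protein_like(codons_list):
    return "".join(codons_list)


class TestAssignOrthologs:
    def test_identical_catalogs_form_one_group(self):
        seq = "ATGAAATGGGTGCTGCTGTGA"
        cats = {
            "anchor": [_rec("g1", "anchor", "i1", seq)],
            "other": [_rec("g1", "other", "i1", seq)],
        }
        groups = assign_orthologs(cats, anchor="anchor")
        assert len(groups) == 1
        assert "other" in groups[0].candidates

    def test_non_reciprocal_hit_excluded(self):
        # anchor has geneA (long, specific) and geneB; the species gene is
        # most similar to geneA, but geneA's best hit is the species' geneA
        # twin -- the species geneB-like sequence must not join geneA's group
        core = "ATGAAATGGGTGCTGCTGTGGCCGAAATGGGTGTGA"
        other_seq = "ATGCAGCACGAGTTCTACGACTGA"
        cats = {
            "anchor": [_rec("gA", "anchor", "i1", core), _rec("gB", "anchor", "i1", other_seq)],
            "sp": [_rec("x1", "sp", "i1", core), _rec("x2", "sp", "i1", core[:27] + "TGA")],
        }
        groups = {g.anchor_gene: g for g in assign_orthologs(cats, anchor="anchor")}
        # x1 is the reciprocal best hit of gA; x2's best anchor hit is also gA
        # but gA prefers x1, so x2 joins nothing
        assert groups["gA"].candidates["sp"][0].gene == "x1"
        assert "sp" not in groups["gB"].candidates

    def test_missing_anchor_rejected(self):
        with pytest.raises(InvalidArgumentError):
            assign_orthologs({"a": []}, anchor="missing")

    def test_catalog_order_invariance(self):
        cats, _ = simulate_cds_catalog(8, 3, isoforms_per_gene=1, divergence=0.05, seed=3)
        g1 = assign_orthologs(cats, anchor="sp01")
        reversed_cats = dict(reversed(list(cats.items())))
        g2 = assign_orthologs(reversed_cats, anchor="sp01")
        m1 = {g.anchor_gene: {sp: r[0].gene for sp, r in g.candidates.items()} for g in g1}
        m2 = {g.anchor_gene: {sp: r[0].gene for sp, r in g.candidates.items()} for g in g2}
        assert m1 == m2

    def test_paralog_at_higher_divergence_rejected(self):
        """A within-species duplicate that diverged further than the true
        ortholog must lose the reciprocal-best-hit competition."""
        cats, truth = simulate_cds_catalog(6, 2, isoforms_per_gene=1, divergence=0.03, seed=4)
        # clone gene0001 of sp02 into a 'paralog' mutated much further
        from psgscan.simulate import _mutate_codons
        rng = np.random.default_rng(9)
        src = next(r for r in cats["sp02"] if r.gene == "gene0001")
        cod = [src.seq[i : i + 3] for i in range(0, len(src.seq), 3)]
        para_seq = "".join(_mutate_codons(rng, cod, 0.25))
        cats["sp02"].append(_rec("gene0001_para", "sp02", "i1", para_seq))
        groups = {g.anchor_gene: g for g in assign_orthologs(cats, anchor="sp01")}
        assert groups["gene0001"].candidates["sp02"][0].gene == "gene0001"


class TestSelectIsoforms:
    def _group(self, candidates):
        return OrthologGroup(
            group_id="g", anchor_gene="g", anchor_species="anchor", candidates=candidates
        )

    def test_single_isoform_selected(self):
        seq = "ATGAAATGGGTGCTGTGA"
        g = self._group({"anchor": [_rec("g", "anchor", "i1", seq)],
                         "sp": [_rec("g", "sp", "i1", seq)]})
        chosen = select_isoforms(g).chosen
        assert chosen["sp"].isoform == "i1"

    def test_full_length_beats_truncated(self):
        full = "ATGAAATGGGTGCTGCTGTGGCCGAAATGGTGA"
        trunc = full[:18] + "TGA"
        g = self._group({
            "anchor": [_rec("g", "anchor", "i1", full)],
            "sp": [_rec("g", "sp", "short", trunc), _rec("g", "sp", "long", full)],
        })
        assert select_isoforms(g).chosen["sp"].isoform == "long"

    def test_tie_breaks_lexicographically(self):
        seq = "ATGAAATGGGTGCTGTGA"
        g = self._group({
            "anchor": [_rec("g", "anchor", "i1", seq)],
            "sp": [_rec("g", "sp", "iso2", seq), _rec("g", "sp", "iso1", seq)],
        })
        assert select_isoforms(g).chosen["sp"].isoform == "iso1"


class TestMergeDualAssemblies:
    def _groups(self, species_present, source):
        seq = "ATGAAATGGGTGCTGTGA"
        cands = {"anchor": [_rec("g", "anchor", "i1", seq)]}
        if species_present:
            cands["silvery"] = [_rec("g", "silvery", "i1", seq, source=source)]
        return [OrthologGroup(group_id="g", anchor_gene="g", anchor_species="anchor",
                              candidates=cands)]

    def test_transcriptome_takes_precedence(self):
        merged = merge_dual_assemblies(
            self._groups(True, "transcriptome"), self._groups(True, "genome"), "silvery"
        )
        assert merged[0].candidates["silvery"][0].source == "transcriptome"

    def test_genome_fills_gap(self):
        merged = merge_dual_assemblies(
            self._groups(False, "transcriptome"), self._groups(True, "genome"), "silvery"
        )
        assert merged[0].candidates["silvery"][0].source == "genome"

    def test_absent_from_both(self):
        merged = merge_dual_assemblies(
            self._groups(False, "transcriptome"), self._groups(False, "genome"), "silvery"
        )
        assert "silvery" not in merged[0].candidates


class TestBuildCodonAlignment:
    def _group_from_seqs(self, seqs):
        cands = {
            sp: [_rec("g", sp, "i1", seq)] for sp, seq in seqs.items()
        }
        return OrthologGroup(group_id="g", anchor_gene="g", anchor_species="anchor",
                             candidates=cands)

    def test_identical_sequences_align_without_gaps(self):
        seq = "ATGAAATGGGTGCTGCTGTGA"
        g = select_isoforms(self._group_from_seqs({"anchor": seq, "b": seq, "c": seq}))
        aln = build_codon_alignment(g)
        assert aln.n_codons == len(seq) // 3 - 1  # stop trimmed
        assert all("-" not in s for s in aln.seqs)

    def test_internal_deletion_keeps_codon_structure(self):
        full = "ATGAAATGGGTGCATCTGGAGCCGTGGTACTGA"
        deleted = full[:12] + full[15:]  # remove one codon in-frame
        g = select_isoforms(self._group_from_seqs({"anchor": full, "b": deleted}))
        aln = build_codon_alignment(g, max_column_gap=0.6)
        row_b = aln.seqs[aln.species.index("b")]
        assert row_b.count("---") == 1
        assert len(row_b) % 3 == 0

    def test_back_translation_lossless(self):
        cats, _ = simulate_cds_catalog(4, 3, isoforms_per_gene=2, divergence=0.05, seed=5)
        groups = assign_orthologs(cats, anchor="sp01")
        for g in groups:
            g = select_isoforms(g)
            aln = build_codon_alignment(g)
            for sp, row in zip(aln.species, aln.seqs):
                assert row.replace("---", "") == g.chosen[sp].coding_seq

    def test_mostly_gapped_species_dropped(self):
        long = "ATG" + "AAATGGGTGCTG" * 6 + "TGA"
        short = "ATGAAATGA"  # 2 codons of overlap only
        g = select_isoforms(self._group_from_seqs({"anchor": long, "b": short}))
        with pytest.raises(InsufficientTaxaError):
            build_codon_alignment(g)

    def test_fewer_than_two_species_rejected(self):
        g = select_isoforms(self._group_from_seqs({"anchor": "ATGAAATGA"}))
        with pytest.raises(InsufficientTaxaError):
            build_codon_alignment(g)


class TestRecovery:
    def test_rbh_recovers_orthologs_at_low_divergence(self):
        cats, truth = simulate_cds_catalog(20, 3, isoforms_per_gene=1, divergence=0.05, seed=6)
        groups = assign_orthologs(cats, anchor="sp01")
        correct = sum(
            1
            for g in groups
            for sp, recs in g.candidates.items()
            if sp != "sp01" and recs[0].gene == g.anchor_gene
        )
        assert correct >= 0.95 * len(groups) * 2
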