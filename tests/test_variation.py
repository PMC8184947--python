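"""Alignment, variant accounting, diversity, classification, NJ."""

import itertools
import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from mitocomp import (
    Alignment,
    AnalysisError,
    InputError,
    classify_substitutions,
    count_variants,
    divergence_matrix,
    global_align,
    nj_tree,
    nucleotide_diversity,
    per_gene_profile,
)
from mitocomp.variation import align_score


# ---------------------------------------------------------------------------
# independent oracle: enumerate every alignment as a move sequence (no DP)
# ---------------------------------------------------------------------------

def brute_force_score(a, b, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if prev == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if prev == "Y" else gap_open), "Y")

    rec(0, 0, 0, None)
    return best


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.rows == ["ACGT", "ACGT"]
        assert aln.score == 4

    def test_single_gap(self):
        aln = global_align("ACGT", "AGT")
        assert aln.score == 1  # 3 matches (+3) and one 1-column gap (-2)
        assert aln.rows[0] == "ACGT"
        assert aln.rows[1].replace("-", "") == "AGT"
        assert aln.rows[1].count("-") == 1

    def test_non_iupac_rejected(self):
        with pytest.raises(InputError):
            global_align("ACGT", "ACZT")

    def test_exhaustive_oracle_short_pairs(self):
        # every pair over {A,C} up to length 4, full move-sequence enumeration
        seqs = [
            "".join(p)
            for n in range(1, 5)
            for p in itertools.product("AC", repeat=n)
        ]
        for a in seqs:
            for b in seqs:
                assert align_score(a, b) == brute_force_score(a, b), (a, b)

    def test_oracle_random_longer_pairs(self):
        rng = random.Random(7)
        for _ in range(60):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 6)))
            assert align_score(a, b) == brute_force_score(a, b), (a, b)

    def test_alignment_score_is_self_consistent(self):
        # the emitted alignment re-scores to the reported optimum
        rng = random.Random(11)
        for _ in range(40):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 8)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 8)))
            aln = global_align(a, b)
            assert _rescore(aln) == aln.score


def _rescore(aln, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    score = 0.0
    prev = None
    for x, y in zip(*aln.rows):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
            prev = None
        else:
            state = "X" if y == "-" else "Y"
            score += gap_extend if prev == state else gap_open
            prev = state
    return score


class TestCountVariants:
    def test_identical_rows(self):
        s = count_variants(Alignment(["a", "b"], ["ACGT", "ACGT"]))
        assert (s.snp_count, s.indel_sites, s.indel_events) == (0, 0, 0)

    def test_gap_run_is_one_event(self):
        s = count_variants(Alignment(["a", "b"], ["A--GT", "ATCGT"]))
        assert (s.snp_count, s.indel_sites, s.indel_events) == (0, 2, 1)

    def test_snps_and_gaps_mixed(self):
        s = count_variants(Alignment(["a", "b"], ["ACGT", "TC-A"]))
        assert (s.snp_count, s.indel_sites, s.indel_events) == (2, 1, 1)
        assert s.compared_columns == 3

    def test_changing_gap_pattern_splits_events(self):
        s = count_variants(Alignment(["a", "b", "c"],
                                     ["A--T", "AC-T", "ACGT"]))
        # col1 gapped in {a}; col2 gapped in {a,b}: two events
        assert s.indel_sites == 2 and s.indel_events == 2

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            count_variants(Alignment(["a"], ["ACGT"]))


class TestDiversity:
    def test_identical_pair(self):
        pi, k, n = nucleotide_diversity(Alignment(["a", "b"], ["ACGT", "ACGT"]))
        assert pi == 0 and k == 0 and n == 4

    def test_one_difference(self):
        pi, k, n = nucleotide_diversity(Alignment(["a", "b"], ["ACGT", "ACGA"]))
        assert pi == pytest.approx(0.25) and k == 1

    def test_three_rows(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "AAAT", "AATT"])
        pi, k, n = nucleotide_diversity(aln)
        assert pi == pytest.approx((1 + 2 + 1) / 3 / 4)
        assert k == pytest.approx(4 / 3)

    def test_pi_k_identity_two_rows(self):
        rng = random.Random(3)
        for _ in range(25):
            a = "".join(rng.choice("ACGT-") for _ in range(30))
            b = "".join(rng.choice("ACGT") for _ in range(30))
            aln = Alignment(["a", "b"], [a, b])
            try:
                pi, k, compared = nucleotide_diversity(aln)
            except AnalysisError:
                continue
            assert k == pytest.approx(pi * compared)

    def test_complete_vs_pairwise_deletion(self):
        aln = Alignment(["a", "b", "c"], ["ACGT", "AC-T", "ACGA"])
        pi_c, _, n_c = nucleotide_diversity(aln, "complete")
        pi_p, _, _ = nucleotide_diversity(aln, "pairwise")
        assert n_c == 3  # gapped column dropped for everyone
        assert pi_c == pytest.approx((0 + 1 + 1) / 3 / 3)
        # pairwise keeps the a/c comparison at 4 columns
        assert pi_p == pytest.approx((0 / 3 + 1 / 3 + 1 / 4) / 3)

    def test_all_gap_columns_raise(self):
        with pytest.raises(AnalysisError, match="no comparable"):
            nucleotide_diversity(Alignment(["a", "b"], ["A-", "-A"]))


class TestClassifySubstitutions:
    def test_identical(self):
        assert classify_substitutions(
            Alignment(["a", "b"], ["TTATTG", "TTATTG"])) == (0, 0, 0.0)

    def test_synonymous_leucine(self):
        syn, nonsyn, prop = classify_substitutions(
            Alignment(["a", "b"], ["TTA", "TTG"]))
        assert (syn, nonsyn, prop) == (1, 0, 0.0)

    def test_two_codon_gene(self):
        syn, nonsyn, prop = classify_substitutions(
            Alignment(["a", "b"], ["ATAGTA", "ATGGTA"]))
        assert (syn, nonsyn, prop) == (1, 0, 0.0)  # ATA and ATG both Met

    def test_nonsynonymous(self):
        syn, nonsyn, prop = classify_substitutions(
            Alignment(["a", "b"], ["ATAGTA", "ATACTA"]))  # Val -> Leu
        assert (syn, nonsyn) == (0, 1)
        assert prop == pytest.approx(0.5)

    def test_per_substitution_mode(self):
        syn, nonsyn, prop = classify_substitutions(
            Alignment(["a", "b"], ["ATAGTA", "ATACTA"]), mode="per_substitution")
        assert prop == pytest.approx(1.0)

    def test_frame_violation(self):
        with pytest.raises(InputError, match="codon-aware"):
            classify_substitutions(Alignment(["a", "b"], ["ATAG", "ATAC"]))


class TestPerGeneProfile:
    def test_identical_records_all_zero(self, sim_record):
        df, ranking = per_gene_profile([sim_record, sim_record])
        assert len(df) == 13
        assert (df["pi"] == 0).all()
        assert (df["aa_change_proportion"] == 0).all()

    def test_targeted_substitutions_rank_first(self, sim_record):
        # mutate only ATP8: third codon positions to dodge start/stop edges
        from mitocomp.genbank_io import copy_record

        rec = copy_record(sim_record)
        f = rec.get_feature("ATP8")
        seq = list(rec.sequence)
        for pos in range(f.start + 5, f.end - 3, 9):
            seq[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[seq[pos]]
        rec.sequence = "".join(seq)
        rec.id = "mutant"
        df, ranking = per_gene_profile([sim_record, rec])
        assert ranking[0] == "ATP8"
        assert df.drop(index="ATP8")["pi"].eq(0).all()


class TestDivergenceMatrix:
    def test_identical_genomes(self, sim_record):
        from mitocomp.genbank_io import copy_record

        recs = []
        for i in range(3):
            r = copy_record(sim_record)
            r.id = f"t{i}"
            recs.append(r)
        dm = divergence_matrix(recs, "WHOLE")
        assert (dm.k.to_numpy() == 0).all()

    def test_duplicate_ids_rejected(self, sim_record):
        with pytest.raises(InputError, match="duplicate"):
            divergence_matrix([sim_record] * 3, "WHOLE")

    def test_closest_pair_from_simulation(self):
        from mitocomp import EvolutionConfig, SimulationConfig, simulate_clade

        leaves = simulate_clade("((A:0.005,B:0.005):0.05,C:0.055);",
                                SimulationConfig(seed=5),
                                EvolutionConfig(seed=6, indel_rate=0.0))
        dm = divergence_matrix([r for r, _ in leaves], "PCG")
        a, b, _ = dm.minimum_pair()
        assert {a, b} == {"A", "B"}


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _matrix(ids, dist):
    n = len(ids)
    M = np.zeros((n, n))
    for (i, j), v in dist.items():
        M[i, j] = M[j, i] = v
    return pd.DataFrame(M, index=ids, columns=ids)


def _tree_distances(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                t1 = tree.taxon_namespace.get_taxon(a)
                t2 = tree.taxon_namespace.get_taxon(b)
                out[(i, j)] = pdm.patristic_distance(t1, t2)
    return out


def _rf_zero(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick",
                           taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick",
                           taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        df = _matrix(["A", "B", "C"], {(0, 1): 3, (0, 2): 4, (1, 2): 5})
        newick = nj_tree(df)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        source = "((A:1,B:2):1,(C:3,D:4):1);"
        dist = _tree_distances(source, ["A", "B", "C", "D"])
        newick = nj_tree(_matrix(["A", "B", "C", "D"], dist))
        assert _rf_zero(newick, source)
        # branch lengths are recovered exactly on an additive matrix
        round_trip = _tree_distances(newick, ["A", "B", "C", "D"])
        for key in dist:
            assert round_trip[key] == pytest.approx(dist[key])

    def test_five_taxon_additive_recovery(self):
        source = "((A:1,B:1.5):0.7,((C:0.9,D:1.1):0.6,E:2.2):0.4);"
        taxa = ["A", "B", "C", "D", "E"]
        dist = _tree_distances(source, taxa)
        newick = nj_tree(_matrix(taxa, dist))
        assert _rf_zero(newick, source)

    def test_non_symmetric_rejected(self):
        df = _matrix(["A", "B", "C"], {(0, 1): 3, (0, 2): 4, (1, 2): 5})
        df.iloc[0, 1] = 99
        with pytest.raises(InputError, match="symmetric"):
            nj_tree(df)

    def test_negative_branch_clamped(self):
        df = _matrix(["A", "B", "C", "D"],
                     {(0, 1): 0.1, (0, 2): 0.5, (0, 3): 0.6,
                      (1, 2): 0.7, (1, 3): 0.8, (2, 3): 0.05})
        tree = dendropy.Tree.get(data=nj_tree(df), schema="newick")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0
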