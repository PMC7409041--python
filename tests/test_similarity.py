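import numpy as np
import pytest

from viromepipe.io import pad_lineage
from viromepipe.similarity import (
    KmerError,
    jaccard,
    kmer_set,
    select_unassigned,
    shared_fraction,
)
from viromepipe.synthetic import generate_contig_pools

from conftest import LINEAGE_A, make_orf

# ---------------------------------------------------------------------------
# Brute-force oracle: naive window enumeration + per-pair set arithmetic,
# sharing no code with the implementation under test.

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_kmers(seq, k, canonical):
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        if canonical:
            rc = "".join(_RC[c] for c in reversed(w))
            w = min(w, rc)
        out.add(w)
    return out


def oracle_shared(site_a, site_b, k, threshold, canonical=True):
    sets_a = {cid: naive_kmers(s, k, canonical) for cid, s in site_a}
    sets_b = {cid: naive_kmers(s, k, canonical) for cid, s in site_b}
    shared_a, shared_b = set(), set()
    for ca, sa in sets_a.items():
        for cb, sb in sets_b.items():
            union = sa | sb
            j = (len(sa & sb) / len(union)) if union else 0.0
            if j > threshold:
                shared_a.add(ca)
                shared_b.add(cb)
    n = len(sets_a) + len(sets_b)
    return shared_a, shared_b, (len(shared_a) + len(shared_b)) / n


def random_contigs(rng, n, min_len=20, max_len=120, alphabet="ACGTN"):
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len))
        seq = "".join(rng.choice(list(alphabet), size=length, p=[0.24] * 4 + [0.04]))
        out.append((f"c{i}", seq))
    return out


class TestKmerSet:
    def test_short_sequence_gives_empty_set(self):
        assert len(kmer_set("A" * 30, k=31)) == 0

    def test_enumeration_by_hand(self):
        assert kmer_set("ACGTT", k=3, canonical=False).kmers == {"ACG", "CGT", "GTT"}

    def test_windows_with_n_dropped(self):
        assert kmer_set("ACNGT", k=3, canonical=False).kmers == set()
        assert "ACG" in kmer_set("ACGNACG", k=3, canonical=False).kmers

    def test_canonical_collapses_strands(self):
        seq = "ACGTACCGTAGGTT"
        rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(seq))
        assert kmer_set(seq, k=5).kmers == kmer_set(rc, k=5).kmers

    def test_even_or_tiny_k_rejected(self):
        with pytest.raises(KmerError):
            kmer_set("ACGTACGT", k=4)
        with pytest.raises(KmerError):
            kmer_set("ACGTACGT", k=1)

    def test_set_size_bounded_by_window_count(self):
        rng = np.random.default_rng(0)
        for cid, seq in random_contigs(rng, 20):
            prof = kmer_set(seq, k=7)
            assert len(prof) <= max(0, len(seq) - 7 + 1)


class TestJaccard:
    def test_identical_profiles(self):
        p = kmer_set("ACGTACGTACGT", k=5)
        assert jaccard(p, p) == 1.0

    def test_disjoint_profiles(self):
        assert jaccard(kmer_set("AAAAA", k=5), kmer_set("CCCCC", k=5)) == 0.0

    def test_hand_computed_overlap(self):
        a = kmer_set("ACGTT", k=3, canonical=False)
        b = kmer_set("CGTTA", k=3, canonical=False)
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero(self):
        assert jaccard(kmer_set("AC", k=3), kmer_set("GT", k=3)) == 0.0

    def test_mismatched_k_rejected(self):
        with pytest.raises(KmerError):
            jaccard(kmer_set("ACGTACG", k=3), kmer_set("ACGTACG", k=5))


class TestSelectUnassigned:
    def test_phylum_assigned_gene_excludes_contig(self):
        cat = [make_orf("o1", "c1", 300, LINEAGE_A)]
        assert select_unassigned(cat, ["c1", "c2"]) == ["c2"]

    def test_domain_only_gene_keeps_contig(self):
        cat = [make_orf("o1", "c1", 300, pad_lineage(["Bacteria"]))]
        assert select_unassigned(cat, ["c1"]) == ["c1"]

    def test_geneless_and_unannotated_contigs_included(self):
        cat = [make_orf("o1", "c1", 300, ""), make_orf("o2", "c2", 300, LINEAGE_A)]
        assert select_unassigned(cat, ["c1", "c2", "c3"]) == ["c1", "c3"]

    def test_mixed_gene_contig_excluded(self):
        cat = [make_orf("o1", "c1", 300, ""), make_orf("o2", "c1", 300, LINEAGE_A)]
        assert select_unassigned(cat, ["c1"]) == []


class TestSharedFraction:
    def test_identical_sites_fully_shared(self):
        contigs = [("a", "ACGTACGTACGTACGT"), ("b", "TTTTGGGGCCCCAAAA")]
        res = shared_fraction(contigs, [(f"{c}2", s) for c, s in contigs], k=7)
        assert res.shared_fraction_overall == 1.0

    def test_dissimilar_sites_share_nothing(self):
        res = shared_fraction([("a", "A" * 40)], [("b", "C" * 40)], k=7)
        assert res.shared_fraction_overall == 0.0

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            shared_fraction([], [("b", "ACGT")])

    def test_short_contigs_stay_in_denominator(self):
        res = shared_fraction(
            [("long", "ACGTACGTACGTACGT"), ("tiny", "ACG")],
            [("other", "ACGTACGTACGTACGT")],
            k=7,
        )
        assert res.n_a == 2
        assert "tiny" not in res.shared_a
        assert res.shared_fraction_overall == pytest.approx(2 / 3)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = random_contigs(rng, 12), random_contigs(rng, 9)
        r1 = shared_fraction(a, b, k=7, threshold=0.05)
        r2 = shared_fraction(b, a, k=7, threshold=0.05)
        assert r1.shared_fraction_a == r2.shared_fraction_b
        assert r1.shared_fraction_b == r2.shared_fraction_a
        assert r1.shared_fraction_overall == r2.shared_fraction_overall

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        a, b = random_contigs(rng, 15, 30, 60), random_contigs(rng, 15, 30, 60)
        fracs = [
            shared_fraction(a, b, k=5, threshold=t).shared_fraction_overall
            for t in (0.0, 0.05, 0.1, 0.3, 0.9)
        ]
        assert fracs == sorted(fracs, reverse=True)

    @pytest.mark.parametrize("k", [7, 31])
    @pytest.mark.parametrize("canonical", [True, False])
    def test_matches_brute_force_oracle_on_random_instances(self, k, canonical):
        rng = np.random.default_rng(k * 100 + canonical)
        for _ in range(5):
            a = random_contigs(rng, int(rng.integers(3, 25)), 20, 150)
            b = random_contigs(rng, int(rng.integers(3, 25)), 20, 150)
            res = shared_fraction(a, b, k=k, threshold=0.1, canonical=canonical)
            oa, ob, of = oracle_shared(a, b, k=k, threshold=0.1, canonical=canonical)
            assert res.shared_a == oa
            assert res.shared_b == ob
            assert res.shared_fraction_overall == pytest.approx(of)

    def test_pairwise_jaccard_values_match_per_pair_computation(self):
        rng = np.random.default_rng(9)
        a, b = random_contigs(rng, 6, 30, 80), random_contigs(rng, 6, 30, 80)
        res = shared_fraction(a, b, k=7)
        sets_a = {cid: naive_kmers(s, 7, True) for cid, s in a}
        sets_b = {cid: naive_kmers(s, 7, True) for cid, s in b}
        for ca, cb, j in res.pairs:
            union = sets_a[ca] | sets_b[cb]
            expected = len(sets_a[ca] & sets_b[cb]) / len(union) if union else 0.0
            assert j == pytest.approx(expected)


class TestRecoveryOnSyntheticPools:
    def test_recovers_truth_labeled_shared_proportion(self):
        contigs, _, shared = generate_contig_pools(
            n_populations=12,
            shared_population_fraction=0.25,
            contigs_per_population=3,
            contig_length=500,
            mutation_rate=0.005,
            seed=3,
        )
        res = shared_fraction(contigs["site_a"], contigs["site_b"], k=31, threshold=0.1)
        truth_prop = sum(shared.values()) / len(shared)
        n = len(shared)
        se = (truth_prop * (1 - truth_prop) / n) ** 0.5
        assert abs(res.shared_fraction_overall - truth_prop) <= 3 * se

    def test_mutation_keeps_same_population_jaccard_high(self):
        # expected per-window survival in a mutated pair: (1-mu)^(2k)
        contigs, pops, _ = generate_contig_pools(
            n_populations=4, shared_population_fraction=1.0,
            contigs_per_population=2, contig_length=1000,
            mutation_rate=0.005, seed=1,
        )
        res = shared_fraction(contigs["site_a"], contigs["site_b"], k=31)
        for ca, cb, j in res.pairs:
            if pops[ca] == pops[cb]:
                assert j > 0.3
            else:
                assert j < 0.01
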