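"""k-mer Jaccard comparison of taxonomically unassigned contigs.

Contigs none of whose genes received a phylum-level assignment (domain
only, or no classification at all) are compared pairwise across two
metagenomes in 31-mer space. Two contigs with Jaccard index strictly
above 0.1 are "similar" — assumed to derive from the same or a related
population — and a contig is "shared" if it has at least one similar
partner in the other site.

k-mers are canonicalized by default (each window replaced by the
lexicographic minimum of itself and its reverse complement) because
assembled contigs have arbitrary strand; windows containing N are
dropped. Sets are exact — no MinHash sketching — and the cross-site
Jaccard values are accumulated through an inverted k-mer index rather
than per-pair set intersection, which is algebraically equivalent but
touches each shared k-mer once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from viromepipe.io import OrfRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 31
DEFAULT_THRESHOLD = 0.1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class KmerError(ValueError):
    """Invalid k-mer parameterization (bad k, mismatched profiles)."""


@dataclass(frozen=True)
class KmerProfile:
    """Exact set of (optionally canonical) k-mers of one contig."""

    contig_id: str
    k: int
    kmers: frozenset[str]

    def __len__(self) -> int:
        return len(self.kmers)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_set(
    sequence: str, contig_id: str = "", k: int = DEFAULT_K, canonical: bool = True
) -> KmerProfile:
    """All length-k windows of a sequence at step 1.

    Windows containing N are dropped; with ``canonical`` each k-mer is
    replaced by min(kmer, reverse complement). A sequence shorter than k
    yields an empty profile.
    """
    if k < 3 or k % 2 == 0:
        raise KmerError(f"k must be odd and >= 3, got {k}")
    seq = sequence.upper()
    kmers: set[str] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        if canonical:
            rc = reverse_complement(window)
            window = window if window <= rc else rc
        kmers.add(window)
    return KmerProfile(contig_id=contig_id, k=k, kmers=frozenset(kmers))


def jaccard(a: KmerProfile, b: KmerProfile) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    if a.k != b.k:
        raise KmerError(f"mismatched k: {a.k} vs {b.k}")
    if not a.kmers and not b.kmers:
        return 0.0
    inter = len(a.kmers & b.kmers)
    union = len(a.kmers) + len(b.kmers) - inter
    return inter / union


def select_unassigned(catalog: list[OrfRecord], contig_ids: list[str]) -> list[str]:
    """Contigs with no phylum-level gene assignment.

    A contig qualifies if every one of its genes has an empty lineage or
    an unclassified phylum field (only the domain known), or if it has no
    predicted genes at all. Order of ``contig_ids`` is preserved.
    """
    assigned: set[str] = {o.contig_id for o in catalog if o.phylum_assigned}
    return [c for c in contig_ids if c not in assigned]


@dataclass
class ContigSimilarityResult:
    """Cross-site similarity of two pools of unassigned contigs.

    ``pairs`` lists every cross-site (contig_a, contig_b, J); a contig is
    shared iff it has >= 1 cross-site partner with J strictly above the
    threshold. ``shared_fraction_overall`` pools both sites' contigs in
    the denominator; per-site fractions are also reported.
    """

    k: int
    threshold: float
    pairs: list[tuple[str, str, float]]
    shared_a: set[str]
    shared_b: set[str]
    n_a: int
    n_b: int
    within_site_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def shared_fraction_overall(self) -> float:
        return (len(self.shared_a) + len(self.shared_b)) / (self.n_a + self.n_b)

    @property
    def shared_fraction_a(self) -> float:
        return len(self.shared_a) / self.n_a

    @property
    def shared_fraction_b(self) -> float:
        return len(self.shared_b) / self.n_b


def _cross_site_jaccard(
    profiles_a: list[KmerProfile], profiles_b: list[KmerProfile]
) -> dict[tuple[int, int], int]:
    """Intersection sizes for all cross-site pairs via an inverted index.

    Returns (index_a, index_b) -> |A ∩ B|; absent pairs share no k-mer.
    """
    index_b: dict[str, list[int]] = {}
    for j, pb in enumerate(profiles_b):
        for km in pb.kmers:
            index_b.setdefault(km, []).append(j)
    inter: dict[tuple[int, int], int] = {}
    for i, pa in enumerate(profiles_a):
        for km in pa.kmers:
            for j in index_b.get(km, ()):
                key = (i, j)
                inter[key] = inter.get(key, 0) + 1
    return inter


def shared_fraction(
    site_a_contigs: list[tuple[str, str]],
    site_b_contigs: list[tuple[str, str]],
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    canonical: bool = True,
    record_within_site: bool = False,
) -> ContigSimilarityResult:
    """Fraction of unassigned contigs shared between two metagenomes.

    Inputs are (contig_id, sequence) lists, one per site. All cross-site
    pairs are evaluated; contigs shorter than k have empty k-mer sets,
    stay in the denominator and can never be shared.
    """
    if not site_a_contigs or not site_b_contigs:
        raise ValueError("both sites must contribute at least one contig")
    profiles_a = [kmer_set(s, cid, k=k, canonical=canonical) for cid, s in site_a_contigs]
    profiles_b = [kmer_set(s, cid, k=k, canonical=canonical) for cid, s in site_b_contigs]
    n_empty = sum(1 for p in profiles_a + profiles_b if not p.kmers)
    if n_empty:
        logger.info("%d contig(s) shorter than k=%d have empty k-mer sets", n_empty, k)

    inter = _cross_site_jaccard(profiles_a, profiles_b)
    pairs: list[tuple[str, str, float]] = []
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    for i, pa in enumerate(profiles_a):
        for j, pb in enumerate(profiles_b):
            shared_kmers = inter.get((i, j), 0)
            if pa.kmers or pb.kmers:
                union = len(pa.kmers) + len(pb.kmers) - shared_kmers
                j_val = shared_kmers / union
            else:
                j_val = 0.0
            pairs.append((pa.contig_id, pb.contig_id, j_val))
            if j_val > threshold:
                shared_a.add(pa.contig_id)
                shared_b.add(pb.contig_id)

    within: list[tuple[str, str, float]] = []
    if record_within_site:
        for profiles in (profiles_a, profiles_b):
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    within.append(
                        (
                            profiles[i].contig_id,
                            profiles[j].contig_id,
                            jaccard(profiles[i], profiles[j]),
                        )
                    )

    return ContigSimilarityResult(
        k=k,
        threshold=threshold,
        pairs=pairs,
        shared_a=shared_a,
        shared_b=shared_b,
        n_a=len(profiles_a),
        n_b=len(profiles_b),
        within_site_pairs=within,
    )
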