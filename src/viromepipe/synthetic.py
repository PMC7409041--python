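"""Two-site synthetic metagenome communities with known ground truth.

The generator emulates what the real pipeline consumes downstream of
assembly, gene prediction and annotation: an ORF catalog with 7-rank
lineages and function labels, per-site mapped-read counts, and per-site
pools of taxonomically unassigned contigs whose underlying populations
are shared between sites at a controlled rate.

Sampling model
--------------
* Taxon relative abundances per site are drawn from a symmetric
  Dirichlet; the concentration parameter controls evenness (large ->
  near-uniform, small -> a few dominant taxa).
* Read counts are multinomial over ORFs. A taxon's proportion is split
  evenly across its genes and each gene is weighted by its length, so a
  gene's sampling probability is proportional to
  ``proportion / n_genes_of_taxon * length``. Length-proportional
  sampling makes TPM (which divides counts by length) the unbiased
  recovery estimator: summed TPM per taxon converges to the taxon's true
  proportion times 1e6 as the library grows.
* Unassigned-contig pools: each population has one random ancestor
  sequence; populations flagged shared seed mutated contig copies in
  both sites, the rest in exactly one site. Mutations are i.i.d.
  per-base substitutions — no indels — so expected k-mer survival is
  (1 - mu)^k and the Jaccard signal is analytically predictable.

A single global seed is fanned out to per-stage child seeds, so each
stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from viromepipe.io import (
    N_RANKS,
    RANKS,
    OrfRecord,
    pad_lineage,
    write_counts,
    write_fasta,
    write_orf_table,
)

_BASES = np.array(list("ACGT"))

#: small pool of KEGG-like function labels, including typical phage genes
#: (recombinases, tail/capsid proteins) and host-derived metabolic genes
FUNCTION_POOL = (
    "xerD; site-specific tyrosine recombinase",
    "spoIVCA; site-specific DNA recombinase",
    "phage tail tape measure protein",
    "phage major capsid protein",
    "phage replication initiation protein",
    "N-acetylmuramoyl-L-alanine amidase",
    "peptidoglycan hydrolase",
    "psbA; photosystem II P680 reaction center D1 protein",
    "cysH; phosphoadenosine phosphosulfate reductase",
    "folE; GTP cyclohydrolase I",
    "dnaB; replicative DNA helicase",
    "recA; recombination protein",
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters behind one generated two-site dataset."""

    taxon_proportions_per_site: dict[str, dict[str, float]]
    shared_population_fraction: float
    n_populations: int
    mutation_rate: float
    library_size_per_site: int
    seed: int
    contig_population: dict[str, str] = field(default_factory=dict)
    contig_shared: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, props in self.taxon_proportions_per_site.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"site {site}: proportions sum to {total}, not 1")
        if not 0.0 <= self.shared_population_fraction <= 1.0:
            raise ValueError("shared_population_fraction must be in [0, 1]")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5)")
        if self.n_populations < 1 or self.library_size_per_site < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticDataset:
    """One generated two-site dataset: catalog, counts, contigs, truth."""

    orf_catalog: list[OrfRecord]
    read_counts: dict[str, dict[str, int]]
    contigs: dict[str, list[tuple[str, str]]]
    truth: SyntheticTruth

    @property
    def site_ids(self) -> list[str]:
        return list(self.read_counts)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_taxa(n_taxa: int, ranks: int = N_RANKS, seed: int = 0) -> list[str]:
    """``n_taxa`` distinct semicolon-delimited lineage strings.

    Higher ranks are drawn from small shared pools so rollups group
    several taxa; the species field is unique per taxon.
    """
    if n_taxa < 1:
        raise ValueError(f"n_taxa must be >= 1, got {n_taxa}")
    if ranks < 1:
        raise ValueError(f"ranks must be >= 1, got {ranks}")
    rng = np.random.default_rng(seed)
    domains = ["Bacteria", "Archaea", "Eukaryota", "Viruses"]
    # pool sizes grow with depth: few domains/phyla, many genera
    pool_sizes = [len(domains), 6, 8, 10, 14, 20]
    lineages: list[str] = []
    for i in range(n_taxa):
        fields: list[str] = []
        for r in range(ranks - 1):
            rank_name = RANKS[r] if r < N_RANKS else f"rank{r}"
            if r == 0:
                fields.append(domains[rng.integers(len(domains))])
            else:
                size = pool_sizes[r] if r < len(pool_sizes) else 20
                fields.append(f"{rank_name}_{rng.integers(size):02d}")
        fields.append(f"species_{i:04d}")
        lineages.append(";".join(fields))
    return lineages


def generate_community(
    taxa: list[str],
    dirichlet_concentration: float = 0.5,
    n_orfs: int = 500,
    orf_length_range: tuple[int, int] = (200, 3000),
    seed: int = 0,
    viral_fraction: float = 0.3,
    function_probability: float = 0.6,
) -> tuple[list[OrfRecord], dict[str, float]]:
    """ORF catalog plus taxon proportions for one community.

    Every taxon owns at least one ORF (the first ``len(taxa)`` ORFs, one
    each; the remainder are assigned uniformly at random). Proportions
    come from a symmetric Dirichlet with the given concentration; ORF
    lengths are uniform on ``orf_length_range``, rounded down to a
    multiple of 3 (whole codons).
    """
    n_taxa = len(taxa)
    if n_taxa < 1:
        raise ValueError("need at least one taxon")
    if n_orfs < n_taxa:
        raise ValueError(f"n_orfs ({n_orfs}) must be >= number of taxa ({n_taxa})")
    lo, hi = orf_length_range
    if not (100 <= lo <= hi <= 50000):
        raise ValueError(f"orf_length_range must lie within [100, 50000], got {orf_length_range}")
    if dirichlet_concentration <= 0:
        raise ValueError("dirichlet_concentration must be positive")

    rng = np.random.default_rng(seed)
    if n_taxa == 1:
        props = np.array([1.0])
    else:
        props = rng.dirichlet([dirichlet_concentration] * n_taxa)
    taxon_proportions = {t: float(p) for t, p in zip(taxa, props)}

    owner = np.concatenate(
        [np.arange(n_taxa), rng.integers(n_taxa, size=n_orfs - n_taxa)]
    )
    lengths = rng.integers(lo, hi + 1, size=n_orfs) // 3 * 3
    lengths = np.maximum(lengths, 3)
    catalog: list[OrfRecord] = []
    for i in range(n_orfs):
        t = int(owner[i])
        viral = bool(rng.random() < viral_fraction)
        func = (
            FUNCTION_POOL[rng.integers(len(FUNCTION_POOL))]
            if rng.random() < function_probability
            else ""
        )
        catalog.append(
            OrfRecord(
                orf_id=f"orf_{i:05d}",
                contig_id=f"contig_{i:05d}",
                start=1,
                end=int(lengths[i]),
                strand="+" if rng.random() < 0.5 else "-",
                length_bp=int(lengths[i]),
                lineage=taxa[t],
                function_label=func,
                viral_flag=viral,
            )
        )
    return catalog, taxon_proportions


def simulate_read_counts(
    orf_catalog: list[OrfRecord],
    taxon_proportions: dict[str, float],
    library_size: int,
    seed: int = 0,
) -> dict[str, int]:
    """Multinomial read counts over the catalog.

    Each taxon's proportion is split evenly across its genes; each gene
    is then weighted by its length, so p_i ∝ proportion/n_genes × L_i.
    Counts sum exactly to ``library_size``.
    """
    if library_size < 1:
        raise ValueError(f"library_size must be >= 1, got {library_size}")
    if not orf_catalog:
        raise ValueError("empty ORF catalog")
    n_genes: dict[str, int] = {}
    for o in orf_catalog:
        n_genes[o.lineage] = n_genes.get(o.lineage, 0) + 1
    weights = np.array(
        [
            taxon_proportions.get(o.lineage, 0.0) / n_genes[o.lineage] * o.length_bp
            for o in orf_catalog
        ]
    )
    if weights.sum() <= 0:
        raise ValueError("no catalog ORF has positive sampling weight")
    p = weights / weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(library_size, p)
    return {o.orf_id: int(c) for o, c in zip(orf_catalog, counts)}


def _mutate(sequence: np.ndarray, mutation_rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at ``mutation_rate``; substitutions always
    change the base (offset 1-3 in the 4-letter alphabet)."""
    seq = sequence.copy()
    if mutation_rate > 0:
        hits = np.nonzero(rng.random(seq.size) < mutation_rate)[0]
        if hits.size:
            offsets = rng.integers(1, 4, size=hits.size)
            seq[hits] = (seq[hits] + offsets) % 4
    return "".join(_BASES[seq])


def generate_contig_pools(
    n_populations: int = 40,
    shared_population_fraction: float = 0.25,
    contigs_per_population: int = 5,
    contig_length: int = 2000,
    mutation_rate: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, str], dict[str, bool]]:
    """Two pools of unassigned contigs with controlled population sharing.

    ``round(n_populations * shared_population_fraction)`` populations
    seed ``contigs_per_population`` mutated copies of their ancestor in
    BOTH sites; the rest seed copies in exactly one site (alternating).

    Returns (contigs per site, contig -> population, contig -> shared?).
    """
    if contig_length < 200:
        raise ValueError(f"contig_length must be >= 200, got {contig_length}")
    if not 0.0 <= shared_population_fraction <= 1.0:
        raise ValueError("shared_population_fraction must be in [0, 1]")
    if not 0.0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5): higher rates destroy the k-mer signal")
    if n_populations < 1 or contigs_per_population < 1:
        raise ValueError("counts must be positive")

    rng = np.random.default_rng(seed)
    n_shared = round(n_populations * shared_population_fraction)
    contigs: dict[str, list[tuple[str, str]]] = {"site_a": [], "site_b": []}
    population_of: dict[str, str] = {}
    shared_flag: dict[str, bool] = {}
    for p in range(n_populations):
        ancestor = rng.integers(4, size=contig_length)
        pop_id = f"pop_{p:03d}"
        is_shared = p < n_shared
        if is_shared:
            sites = ["site_a", "site_b"]
        else:
            sites = ["site_a" if (p - n_shared) % 2 == 0 else "site_b"]
        for site in sites:
            for c in range(contigs_per_population):
                cid = f"{site}_{pop_id}_c{c}"
                contigs[site].append((cid, _mutate(ancestor, mutation_rate, rng)))
                population_of[cid] = pop_id
                shared_flag[cid] = is_shared
    return contigs, population_of, shared_flag


def generate_two_site_dataset(
    n_taxa: int = 50,
    n_orfs: int = 500,
    library_size: int = 1_000_000,
    dirichlet_concentration: float = 0.5,
    orf_length_range: tuple[int, int] = (200, 3000),
    n_populations: int = 40,
    shared_population_fraction: float = 0.25,
    contigs_per_population: int = 5,
    contig_length: int = 2000,
    mutation_rate: float = 0.005,
    seed: int = 0,
    site_ids: tuple[str, str] = ("site_a", "site_b"),
) -> SyntheticDataset:
    """Full two-site dataset: one shared ORF catalog, per-site taxon
    proportions and read counts, and per-site unassigned-contig pools."""
    rngs = _child_rngs(seed, 6)
    sub = [int(r.integers(2**31)) for r in rngs]

    taxa = generate_taxa(n_taxa, seed=sub[0])
    catalog, props_a = generate_community(
        taxa, dirichlet_concentration, n_orfs, orf_length_range, seed=sub[1]
    )
    # second site: same catalog, independently drawn proportions
    rng_b = np.random.default_rng(sub[2])
    props_b_arr = (
        np.array([1.0]) if n_taxa == 1 else rng_b.dirichlet([dirichlet_concentration] * n_taxa)
    )
    props_b = {t: float(p) for t, p in zip(taxa, props_b_arr)}

    counts_a = simulate_read_counts(catalog, props_a, library_size, seed=sub[3])
    counts_b = simulate_read_counts(catalog, props_b, library_size, seed=sub[4])

    contigs, population_of, shared_flag = generate_contig_pools(
        n_populations,
        shared_population_fraction,
        contigs_per_population,
        contig_length,
        mutation_rate,
        seed=sub[5],
    )
    contigs = {site_ids[0]: contigs["site_a"], site_ids[1]: contigs["site_b"]}
    population_of = {k.replace("site_a", site_ids[0]).replace("site_b", site_ids[1]): v
                     for k, v in population_of.items()}
    shared_flag = {k.replace("site_a", site_ids[0]).replace("site_b", site_ids[1]): v
                   for k, v in shared_flag.items()}

    truth = SyntheticTruth(
        taxon_proportions_per_site={site_ids[0]: props_a, site_ids[1]: props_b},
        shared_population_fraction=shared_population_fraction,
        n_populations=n_populations,
        mutation_rate=mutation_rate,
        library_size_per_site=library_size,
        seed=seed,
        contig_population=population_of,
        contig_shared=shared_flag,
    )
    return SyntheticDataset(
        orf_catalog=catalog,
        read_counts={site_ids[0]: counts_a, site_ids[1]: counts_b},
        contigs=contigs,
        truth=truth,
    )


def expected_rollup_se(
    orf_catalog: list[OrfRecord],
    taxon_proportions: dict[str, float],
    library_size: int,
    rank: str,
    name: str,
) -> float:
    """Delta-method standard error of one rank group's TPM-rollup share.

    The rollup estimate is a ratio of length-weighted multinomial counts,
    so its sampling error is the multinomial standard error computed with
    the length weights (an effective library size smaller than the read
    count). With equal ORF lengths this reduces to sqrt(q(1-q)/N).
    """
    idx = RANKS.index(rank)
    n_genes: dict[str, int] = {}
    for o in orf_catalog:
        n_genes[o.lineage] = n_genes.get(o.lineage, 0) + 1
    raw = np.array(
        [
            taxon_proportions.get(o.lineage, 0.0) / n_genes[o.lineage] * o.length_bp
            for o in orf_catalog
        ]
    )
    p = raw / raw.sum()
    w = np.array([1000.0 / o.length_bp for o in orf_catalog])  # rate weight per read
    in_group = np.array(
        [o.lineage.split(";")[idx] == name for o in orf_catalog], dtype=float
    )
    wbar = float((p * w).sum())
    q = float((p * w * in_group).sum() / wbar)
    g = (w * in_group - q * w) / wbar
    var = float((p * g**2).sum() - (p * g).sum() ** 2) / library_size
    return var**0.5


def true_rank_proportions(
    truth: SyntheticTruth, site_id: str, rank: str
) -> dict[str, float]:
    """Ground-truth proportions rolled up to one rank for one site."""
    idx = RANKS.index(rank)
    acc: dict[str, float] = {}
    for lineage, p in truth.taxon_proportions_per_site[site_id].items():
        name = lineage.split(";")[idx]
        acc[name] = acc.get(name, 0.0) + p
    return acc


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset to a directory: per-site FASTA + counts TSV, the
    ORF catalog TSV, and the truth as a JSON config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_orf_table(outdir / "orfs.tsv", dataset.orf_catalog)
    for site in dataset.site_ids:
        write_counts(outdir / f"counts_{site}.tsv", dataset.read_counts[site])
        write_fasta(outdir / f"contigs_{site}.fasta", dataset.contigs[site])
    t = dataset.truth
    truth_doc = {
        "seed": t.seed,
        "library_size_per_site": t.library_size_per_site,
        "n_populations": t.n_populations,
        "shared_population_fraction": t.shared_population_fraction,
        "mutation_rate": t.mutation_rate,
        "taxon_proportions_per_site": t.taxon_proportions_per_site,
        "contig_population": t.contig_population,
        "contig_shared": t.contig_shared,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=2))
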