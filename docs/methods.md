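# Methods

## The model

The pipeline treats a viral-enriched metagenome as a catalog of
predicted genes (ORFs) on assembled contigs, each gene carrying an
optional 7-rank taxonomic lineage, an optional function label, and a
viral-origin flag, plus a table of mapped-read counts per gene. All
community-level statistics derive from gene-level TPM:

    rate_i = r_i / (L_i / 1000)          reads per kbp
    TPM_i  = rate_i / Σ_j rate_j × 10^6

TPM removes gene-length bias (longer genes soak up more reads at equal
molar abundance) and library-size bias (the normalization makes the
values per-million), which is what makes two sites with different
sequencing depth comparable. TPM is invariant to uniform count
rescaling, so whether the upstream mapper counted read mates or
fragments does not matter; multi-mapping resolution is the mapper's
job and the count table is taken as given.

**Taxon profiles.** Gene TPM is summed per unique full lineage string.
Genes with no annotation accumulate under a fully
`unclassified_<rank>`-padded lineage, so total TPM is conserved and the
unclassified bin is an explicit category. Partial annotations are
padded the same way (`Bacteria;unclassified_phylum;…`), which lets a
domain-only call survive a domain rollup while still counting as
unassigned at phylum. Rank rollups group lineages on one field;
percentages are over the whole profile, unclassified bin included.

**Alpha diversity.** The lineage-TPM table is used in place of an OTU
count table. Chao1 needs integers, so counts are `round(TPM)` with
positive-TPM lineages floored to 1 — observed richness then equals the
number of detected lineages. Indices: Shannon H in nats (log base is a
flag), bias-corrected Chao1 `S + F1(F1−1)/(2(F2+1))` by default
(classic `S + F1²/(2 F2)` as a flag; it falls back to bias-corrected
with a warning when F2 = 0), evenness **E = H/S**, and Pielou
J = H/ln S reported alongside. E = H/S is deliberate: it is the
definition consistent with the published two-site wetland survey this
pipeline's outputs are shaped after (H/ln S is numerically incompatible
with those printed values), and both are emitted so either convention
is available.

**Unassigned-contig sharing.** A contig is taxonomically unassigned if
none of its genes carries a real phylum call (domain-only or nothing),
including contigs with no predicted genes. Each unassigned contig is
reduced to its exact set of 31-mers (sliding window, step 1; windows
containing N dropped; each window replaced by the lexicographic min of
itself and its reverse complement — assembly strand is arbitrary, and a
`canonical=False` switch preserves the literal single-strand reading).
For every cross-site pair, J = |A∩B|/|A∪B|; J strictly greater than
0.1 marks the pair "similar", and a contig is "shared" when it has at
least one similar cross-site partner. The overall shared fraction pools
both sites' unassigned contigs in the denominator; per-site fractions
are reported so either convention can be read off. Contigs shorter
than k stay in the denominator and can never be shared (logged).

Implementation: k-mer sets are exact (no MinHash — desk-scale instances
do not need sketching); cross-site intersections are accumulated
through an inverted k-mer index, which touches each shared k-mer once
instead of intersecting every pair. The test suite checks this against
an independent nested-loop per-pair oracle for exact agreement.

**Site statistics.** VPR = VLP mL⁻¹ / cells mL⁻¹ from
already-tabulated epifluorescence concentrations; mean read length =
round(total bp / reads). The report assembler tolerates missing
components (marked absent, never fatal) and round-trips through JSON.

## The synthetic generator

The generator emulates the *post-annotation* state of two sites — not
reads, not assembly. What it does model:

- **Taxa:** distinct 7-rank lineages; higher ranks drawn from small
  shared pools (4 domains, ~6 phyla per domain pool, …) so rollups
  aggregate several species, the species field unique.
- **Abundances:** symmetric Dirichlet per site (concentration 0.5 by
  default — uneven, a few dominant taxa, which is what real communities
  look like; large concentrations approach uniform). The distribution
  family is a stand-in: the real surveys do not state one, so the
  concentration is an exposed parameter.
- **Catalog:** each taxon owns ≥1 ORF; lengths uniform on
  200–3000 bp, floored to whole codons. Function labels come from a
  small pool of phage-typical and host-metabolic gene names; a 30%
  viral-flag rate reflects a viral-enriched (not pure) preparation.
- **Reads:** one multinomial draw per site over ORFs with
  p_i ∝ (proportion of taxon / its gene count) × L_i. Splitting the
  taxon's share evenly over its genes and then weighting by length is
  exactly the sampling under which TPM is the unbiased recovery
  estimator: summed TPM per taxon → taxon proportion × 10⁶. Default
  library size 10⁶ reads per site.
- **Unassigned contig pools:** 40 populations by default, each one
  i.i.d.-uniform ancestor sequence of 2 kb; a 0.25 fraction of
  populations seeds 5 mutated copies in both sites, the rest in exactly
  one site (alternating). Mutations are i.i.d. substitutions at rate
  μ = 0.005 — no indels — so a window of length k survives in a mutated
  pair with probability (1−μ)^2k ≈ 0.73 at k = 31, putting
  same-population Jaccard near 0.6 (far above the 0.1 threshold) and
  unrelated-contig Jaccard at ~0. μ ≥ 0.5 is rejected outright: it
  destroys the k-mer signal.

One global seed fans out through `SeedSequence.spawn` to per-stage
child seeds, so outputs are byte-identical across runs and stages are
independently reproducible.

What it does **not** emulate — and hence what passing tests do not
show about real data: read-level error and coverage fluctuation,
assembly artifacts (chimeras, fragmentation), indels and realistic
sequence evolution, annotation error (mislabeled lineages), and
abundance distributions beyond the Dirichlet family.

## Recovery error bars

The per-rank TPM rollup is a ratio of length-weighted multinomial
counts, so its sampling error is *not* the plain binomial
√(p(1−p)/N): the 1/L weights reduce the effective library size. The
package computes the delta-method standard error from generator truth
(`expected_rollup_se`), which reduces to the binomial form when all
lengths are equal and matches the empirical spread to within a few
percent at the default settings. Recovery checks require 95% of
(replicate, phylum) comparisons inside 3 SE — conservative against the
nominal 99.7% coverage, tight enough to catch any systematic bias.
Shared-fraction recovery uses the plain binomial SE on the truth-label
proportion, with the rule that ≥19 of 20 replicates fall inside 3 SE.

## Numerical and design choices

- Coordinates 1-based inclusive (GFF convention), stated once in the
  I/O layer and enforced everywhere; `length_bp = end − start + 1` is
  validated on construction.
- Counts are non-negative integers and TPM is real; the two never share
  a column. Zero-count ORFs are retained with TPM = 0 (they do not
  enter richness, which requires positive abundance).
- TPM conservation is held to |Σ − 10⁶| ≤ 10⁻³; in practice float64
  keeps it below 10⁻⁹ at 200 ORFs.
- Strict `>` at the Jaccard threshold; ties at exactly 0.1 are not
  similar.
- `jaccard` of two empty sets is defined as 0 (not 1): two contigs too
  short to yield a k-mer carry no evidence of relatedness.
- Function scopes: `all` (every gene), `viral-genes` (viral-flagged;
  unlabeled genes fall in an explicit `unannotated` bin so scope TPM is
  conserved), `amg` (viral-flagged *and* function-labeled — the
  auxiliary-metabolic-gene view, where an unlabeled bin would be
  meaningless).
- Two-site matrices use the union of keys with explicit zeros, so
  "present here, absent there" is visible rather than dropped.

## Problem sizes

Default validation runs use communities of 30–50 taxa, 200–500 ORFs and
10⁶ reads per site, and contig pools of 40 populations × 5 contigs ×
2 kb — sizes at which every recovery bound above is comfortably
resolvable and the full suite plus the reproduction script complete in
a couple of minutes on one core.

## Known limitations

- The shared-fraction denominator convention (pooled vs per-site) is a
  reporting choice; both are emitted, but published figures rarely say
  which was used, so cross-study comparison needs care.
- Chao1 on an integerized TPM table is a pragmatic surrogate, not a
  sampling-theoretic estimator: TPM "singletons" are not literal
  singleton reads, so the integerization rule (a flag) matters and
  absolute Chao1 values should be compared only within a convention.
- Evenness E = H/S depends on S, which for gene-derived tables is
  catalog-depth-dependent; cross-study evenness comparisons inherit
  that dependence.
- The library is not streaming: contig pools and k-mer sets are held in
  memory, fine for desk-scale (≤ thousands of contigs), not for
  assembly-scale million-contig inputs.
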