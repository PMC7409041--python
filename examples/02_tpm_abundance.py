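"""Per-ORF TPM from a tiny hand-built count table.

TPM divides each gene's mapped-read count by its length in kbp, then
normalizes the rates to sum to one million — removing both gene-length
and library-size bias so sites of different depth are comparable.
"""

from viromepipe import compute_tpm, library_summary
from viromepipe.io import OrfRecord


def orf(orf_id, length):
    return OrfRecord(orf_id=orf_id, contig_id=f"c_{orf_id}", start=1,
                     end=length, strand="+", length_bp=length)


catalog = [orf("gene_a", 1000), orf("gene_b", 2000)]
table = compute_tpm({"gene_a": 10, "gene_b": 10}, catalog, site_id="demo")

print(table.table.to_string(index=False))
print(f"sum(TPM) = {table.total_tpm:,.1f}")
# Equal read counts, but gene_a is half as long: its per-kbp rate is
# twice gene_b's, so it takes two thirds of the TPM mass.

print("mean read length:", library_summary(n_reads=11_614_382,
                                           total_bp=2_558_493_699), "bp")
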