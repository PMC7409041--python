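"""Per-ORF TPM abundance and library summary statistics.

TPM (transcripts per million), applied here to DNA reads mapped to
predicted genes, normalizes each ORF's mapped-read count by (1) the ORF
length in kilobase-pairs and (2) the library's total length-normalized
rate, scaled to one million:

    rate_i = r_i / (L_i / 1000)
    tpm_i  = rate_i / sum_j rate_j * 1e6

TPM is invariant to uniform rescaling of all counts, so whether the
upstream mapper counted read mates or fragments does not change it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from viromepipe.io import OrfRecord


class EmptyLibraryError(ValueError):
    """All mapped-read counts are zero — TPM is undefined."""


class MissingLengthError(KeyError):
    """A counted orf_id has no length in the ORF catalog."""


@dataclass
class AbundanceTable:
    """Per-ORF abundance for one site.

    ``table`` columns: orf_id, mapped_reads, length_kbp, rate (reads per
    kbp), tpm. TPM sums to 1e6 whenever any read mapped; ORFs with zero
    reads have rate = tpm = 0.
    """

    site_id: str
    table: pd.DataFrame

    @property
    def tpm(self) -> dict[str, float]:
        return dict(zip(self.table["orf_id"], self.table["tpm"]))

    @property
    def total_tpm(self) -> float:
        return float(self.table["tpm"].sum())

    @property
    def n_nonzero(self) -> int:
        return int((self.table["mapped_reads"] > 0).sum())


def compute_tpm(
    counts: dict[str, int],
    catalog: list[OrfRecord],
    site_id: str = "",
) -> AbundanceTable:
    """Compute the per-ORF TPM table from mapped-read counts and the catalog.

    Every counted orf_id must have a catalog entry (its length); catalog
    ORFs absent from ``counts`` are retained with zero reads and zero TPM.

    Raises
    ------
    MissingLengthError
        if a counted orf_id is not in the catalog.
    EmptyLibraryError
        if no ORF has a positive count.
    """
    lengths = {o.orf_id: o.length_bp for o in catalog}
    unknown = sorted(set(counts) - set(lengths))
    if unknown:
        raise MissingLengthError(
            f"orf_id(s) with counts but no catalog length: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )

    orf_ids = [o.orf_id for o in catalog]
    r = np.array([counts.get(i, 0) for i in orf_ids], dtype=float)
    if not np.any(r > 0):
        raise EmptyLibraryError("all mapped-read counts are zero")
    length_kbp = np.array([lengths[i] for i in orf_ids], dtype=float) / 1000.0

    rate = r / length_kbp
    tpm = rate / rate.sum() * 1e6

    table = pd.DataFrame(
        {
            "orf_id": orf_ids,
            "mapped_reads": r.astype(int),
            "length_kbp": length_kbp,
            "rate": rate,
            "tpm": tpm,
        }
    )
    return AbundanceTable(site_id=site_id, table=table)


def library_summary(n_reads: int, total_bp: int) -> int:
    """Mean read length in bp, rounded to the nearest integer."""
    if n_reads < 1:
        raise ValueError(f"n_reads must be >= 1, got {n_reads}")
    if total_bp < 0:
        raise ValueError(f"total_bp must be >= 0, got {total_bp}")
    return round(total_bp / n_reads)
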