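"""Readers and writers for the plain-text formats the pipeline touches.

Conventions enforced everywhere:

* ORF coordinates are 1-based inclusive (GFF dialect), ``start <= end``.
* Lineage strings carry exactly seven semicolon-delimited ranks
  (domain;phylum;class;order;family;genus;species) or are empty; partially
  known lineages pad missing ranks with ``unclassified_<rank>``.
* Mapped-read counts are non-negative integers; TPM values are reals —
  the two never share a column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
N_RANKS = len(RANKS)

_FASTA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file violated the format contract (bad header, value or record)."""


@dataclass(frozen=True)
class OrfRecord:
    """One predicted gene on an assembled contig.

    ``length_bp`` must equal ``end - start + 1`` when coordinates are
    present; ``lineage`` is a 7-rank string or empty (unannotated);
    ``viral_flag`` marks genes identified as viral in origin.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    length_bp: int
    lineage: str = ""
    function_label: str = ""
    viral_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"ORF {self.orf_id}: strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise FormatError(f"ORF {self.orf_id}: end ({self.end}) < start ({self.start})")
        if self.length_bp != self.end - self.start + 1:
            raise FormatError(
                f"ORF {self.orf_id}: length_bp={self.length_bp} does not match "
                f"coordinates [{self.start},{self.end}] (expected {self.end - self.start + 1})"
            )
        if self.length_bp < 3:
            raise FormatError(f"ORF {self.orf_id}: length_bp must be >= 3")
        if self.lineage:
            n = len(self.lineage.split(";"))
            if n != N_RANKS:
                raise FormatError(
                    f"ORF {self.orf_id}: lineage has {n} fields, expected {N_RANKS}: "
                    f"{self.lineage!r}"
                )

    @property
    def ranks(self) -> tuple[str, ...]:
        """Lineage split into its 7 rank fields (empty tuple if unannotated)."""
        return tuple(self.lineage.split(";")) if self.lineage else ()

    def rank_name(self, rank: str) -> str:
        """Taxon name at ``rank``; ``unclassified_<rank>`` if unannotated."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
        if not self.lineage:
            return f"unclassified_{rank}"
        return self.ranks[RANKS.index(rank)]

    @property
    def phylum_assigned(self) -> bool:
        """True if the gene carries a real (non-placeholder) phylum call."""
        name = self.rank_name("phylum")
        return name not in ("", "unclassified_phylum")


@dataclass(frozen=True)
class SiteRecord:
    """Per-site metadata: microscopy counts, physicochemistry, library size."""

    site_id: str
    vlp_per_ml: float | None = None
    cells_per_ml: float | None = None
    conductivity: float | None = None
    temperature: float | None = None
    ph: float | None = None
    oxygen: float | None = None
    phosphate: float | None = None
    n_reads: int | None = None
    total_bp: int | None = None

    def __post_init__(self) -> None:
        if self.vlp_per_ml is not None and self.vlp_per_ml <= 0:
            raise FormatError(f"site {self.site_id}: vlp_per_ml must be > 0")
        if self.cells_per_ml is not None and self.cells_per_ml <= 0:
            raise FormatError(f"site {self.site_id}: cells_per_ml must be > 0")


def _version_header(params: dict | None = None) -> str:
    from viromepipe import __version__

    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
    return f"# viromepipe {__version__}{extra}"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (id, sequence).

    Sequences are uppercased and validated against {A,C,G,T,N}. Duplicate
    ids and empty sequences are format errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise FormatError(f"{path}: {rec.id!r} contains invalid characters {sorted(bad)}")
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables

_ORF_COLUMNS = ["orf_id", "contig_id", "start", "end", "strand", "length_bp", "lineage", "function"]
_ORF_OPTIONAL = {"viral_flag"}


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in required and c not in _ORF_OPTIONAL]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
    return df


def read_orf_table(path: str | Path) -> list[OrfRecord]:
    """Read the ORF catalog TSV (orf_id, contig_id, start, end, strand,
    length_bp, lineage, function[, viral_flag])."""
    df = _read_tsv(path, _ORF_COLUMNS)
    out: list[OrfRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                OrfRecord(
                    orf_id=row.orf_id,
                    contig_id=row.contig_id,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    length_bp=int(row.length_bp),
                    lineage=row.lineage,
                    function_label=row.function,
                    viral_flag=str(getattr(row, "viral_flag", "0")).lower()
                    in ("1", "true", "yes"),
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    ids = [r.orf_id for r in out]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise FormatError(f"{path}: duplicate orf_id(s) {dupes}")
    return out


def write_orf_table(path: str | Path, orfs: Iterable[OrfRecord]) -> None:
    rows = [
        (o.orf_id, o.contig_id, o.start, o.end, o.strand, o.length_bp,
         o.lineage, o.function_label, int(o.viral_flag))
        for o in orfs
    ]
    df = pd.DataFrame(rows, columns=_ORF_COLUMNS + ["viral_flag"])
    with open(path, "w") as fh:
        fh.write(_version_header() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts(path: str | Path) -> dict[str, int]:
    """Read a per-ORF mapped-read count TSV (orf_id, count)."""
    df = _read_tsv(path, ["orf_id", "count"])
    counts: dict[str, int] = {}
    for i, (orf_id, raw) in enumerate(zip(df["orf_id"], df["count"]), start=2):
        try:
            c = int(raw)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-integer count {raw!r}") from exc
        if c < 0:
            raise FormatError(f"{path}: line {i}: negative count {c} for {orf_id}")
        if orf_id in counts:
            raise FormatError(f"{path}: duplicate orf_id {orf_id!r}")
        counts[orf_id] = c
    return counts


def write_counts(path: str | Path, counts: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(_version_header() + "\n")
        fh.write("orf_id\tcount\n")
        for orf_id, c in counts.items():
            fh.write(f"{orf_id}\t{c}\n")


_SITE_COLUMNS = ["site_id"]
_SITE_NUMERIC = {
    "vlp_per_ml": float,
    "cells_per_ml": float,
    "conductivity": float,
    "temperature": float,
    "ph": float,
    "oxygen": float,
    "phosphate": float,
    "n_reads": int,
    "total_bp": int,
}


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read the site metadata TSV; only ``site_id`` is required, numeric
    columns are optional and may be blank."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: list[SiteRecord] = []
    for i, row in df.iterrows():
        kwargs: dict = {"site_id": row["site_id"]}
        for col, caster in _SITE_NUMERIC.items():
            if col in df.columns and row[col] != "":
                try:
                    kwargs[col] = caster(float(row[col]))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {i + 2}: bad value {row[col]!r} in {col}"
                    ) from exc
        out.append(SiteRecord(**kwargs))
    return out


def write_sites(path: str | Path, sites: Iterable[SiteRecord]) -> None:
    cols = ["site_id"] + list(_SITE_NUMERIC)
    rows = []
    for s in sites:
        rows.append([s.site_id] + [getattr(s, c) for c in _SITE_NUMERIC])
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_version_header() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def pad_lineage(partial: Sequence[str]) -> str:
    """Pad a partial lineage (ranks known down to some depth) to 7 fields
    with ``unclassified_<rank>`` placeholders.

    >>> pad_lineage(["Bacteria"])
    'Bacteria;unclassified_phylum;unclassified_class;unclassified_order;unclassified_family;unclassified_genus;unclassified_species'
    """
    if len(partial) > N_RANKS:
        raise ValueError(f"lineage deeper than {N_RANKS} ranks: {partial!r}")
    fields = list(partial) + [f"unclassified_{r}" for r in RANKS[len(partial):]]
    return ";".join(fields)
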