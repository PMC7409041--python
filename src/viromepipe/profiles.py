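"""Aggregation of ORF TPM into taxonomy and function profiles.

The taxonomy profile — gene TPM summed per unique 7-rank lineage string —
is the surrogate OTU table used downstream for richness and alpha
diversity; rank rollups produce community bar-plot / heatmap matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from viromepipe.abundance import AbundanceTable
from viromepipe.io import N_RANKS, RANKS, OrfRecord, pad_lineage

#: lineage under which ORFs with no taxonomic annotation accumulate
UNCLASSIFIED_LINEAGE = pad_lineage([])

FUNCTION_SCOPES = ("all", "viral-genes", "amg")

#: function bin for in-scope ORFs lacking a function label
UNANNOTATED_LABEL = "unannotated"


@dataclass
class TaxonProfile:
    """Summed TPM per unique full lineage string for one site."""

    site_id: str
    lineage_tpm: dict[str, float]

    @property
    def total_tpm(self) -> float:
        return float(sum(self.lineage_tpm.values()))


@dataclass
class FunctionProfile:
    """Summed TPM per function label for one site, within a scope.

    scope: ``all`` (every ORF), ``viral-genes`` (viral-flagged ORFs), or
    ``amg`` (viral-flagged ORFs carrying a function annotation — the
    auxiliary-metabolic-gene view).
    """

    site_id: str
    scope: str
    function_tpm: dict[str, float]

    @property
    def total_tpm(self) -> float:
        return float(sum(self.function_tpm.values()))


def aggregate_by_lineage(abundance: AbundanceTable, catalog: list[OrfRecord]) -> TaxonProfile:
    """Sum ORF TPM by unique taxonomic string identifier.

    ORFs with an empty lineage accumulate under a single fully
    unclassified lineage, so total TPM is conserved.
    """
    lineage_of = {o.orf_id: (o.lineage or UNCLASSIFIED_LINEAGE) for o in catalog}
    missing = sorted(set(abundance.table["orf_id"]) - set(lineage_of))
    if missing:
        raise KeyError(f"abundance rows without catalog entries: {missing[:5]}")
    acc: dict[str, float] = {}
    for orf_id, tpm in zip(abundance.table["orf_id"], abundance.table["tpm"]):
        lin = lineage_of[orf_id]
        acc[lin] = acc.get(lin, 0.0) + float(tpm)
    return TaxonProfile(site_id=abundance.site_id, lineage_tpm=acc)


def rollup(profile: TaxonProfile, rank: str) -> dict[str, tuple[float, float]]:
    """Group the profile at one of the 7 ranks.

    Returns name -> (summed TPM, relative %); percentages are over the
    profile's total TPM (the unclassified bin included) and sum to 100.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    idx = RANKS.index(rank)
    acc: dict[str, float] = {}
    for lineage, tpm in profile.lineage_tpm.items():
        name = lineage.split(";")[idx]
        acc[name] = acc.get(name, 0.0) + tpm
    total = sum(acc.values())
    if total == 0:
        return {name: (0.0, 0.0) for name in acc}
    return {name: (tpm, 100.0 * tpm / total) for name, tpm in acc.items()}


def aggregate_by_function(
    abundance: AbundanceTable,
    catalog: list[OrfRecord],
    scope: str = "all",
) -> FunctionProfile:
    """Sum ORF TPM per function label within a scope.

    In-scope ORFs without a label fall in the ``unannotated`` bin except
    under scope ``amg``, which by definition keeps only annotated viral
    genes. TPM is conserved within the set of ORFs the scope selects.
    """
    if scope not in FUNCTION_SCOPES:
        raise ValueError(f"unknown scope {scope!r}; valid scopes: {FUNCTION_SCOPES}")
    by_id = {o.orf_id: o for o in catalog}
    acc: dict[str, float] = {}
    for orf_id, tpm in zip(abundance.table["orf_id"], abundance.table["tpm"]):
        orf = by_id[orf_id]
        if scope in ("viral-genes", "amg") and not orf.viral_flag:
            continue
        if scope == "amg" and not orf.function_label:
            continue
        label = orf.function_label or UNANNOTATED_LABEL
        acc[label] = acc.get(label, 0.0) + float(tpm)
    return FunctionProfile(site_id=abundance.site_id, scope=scope, function_tpm=acc)


def two_site_matrix(
    profile_a: TaxonProfile | FunctionProfile,
    profile_b: TaxonProfile | FunctionProfile,
) -> pd.DataFrame:
    """Joint two-site matrix over the union of keys, zeros filled.

    Keys present in only one site appear with an explicit 0 in the other
    — the heatmap-ready comparison shape.
    """
    def _tpm_map(p: TaxonProfile | FunctionProfile) -> dict[str, float]:
        return p.lineage_tpm if isinstance(p, TaxonProfile) else p.function_tpm

    map_a = _tpm_map(profile_a)
    map_b = _tpm_map(profile_b)
    keys = sorted(set(map_a) | set(map_b))
    return pd.DataFrame(
        {
            profile_a.site_id or "site_a": [map_a.get(k, 0.0) for k in keys],
            profile_b.site_id or "site_b": [map_b.get(k, 0.0) for k in keys],
        },
        index=pd.Index(keys, name="key"),
    )


def profile_to_frame(profile: TaxonProfile) -> pd.DataFrame:
    """Long-form frame (site, lineage, tpm, percent) for writing to TSV."""
    total = profile.total_tpm
    rows = [
        (profile.site_id, lin, tpm, (100.0 * tpm / total if total else 0.0))
        for lin, tpm in sorted(profile.lineage_tpm.items())
    ]
    return pd.DataFrame(rows, columns=["site_id", "lineage", "tpm", "percent"])
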