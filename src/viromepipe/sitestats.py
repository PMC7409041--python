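"""Virus/picoplankton summary statistics and cross-site report assembly.

The virus-to-picoplankton ratio (VPR) is the VLP concentration divided
by the picoplankton cell concentration, both per mL — a dimensionless
index of viral pressure on the cellular community (typically 3-10 in
aquatic ecosystems).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from viromepipe.abundance import library_summary
from viromepipe.diversity import DiversityResult
from viromepipe.io import SiteRecord
from viromepipe.profiles import TaxonProfile, rollup
from viromepipe.similarity import ContigSimilarityResult


def vpr(vlp_per_ml: float, cells_per_ml: float) -> float:
    """Virus-to-picoplankton ratio: VLP mL^-1 / cells mL^-1."""
    if vlp_per_ml <= 0:
        raise ValueError(f"vlp_per_ml must be > 0, got {vlp_per_ml}")
    if cells_per_ml <= 0:
        raise ValueError(f"cells_per_ml must be > 0, got {cells_per_ml}")
    return vlp_per_ml / cells_per_ml


@dataclass
class SiteSummary:
    """Per-site rollup of microscopy, library and diversity results."""

    site_id: str
    vpr: float | None = None
    mean_read_length: int | None = None
    diversity: DiversityResult | None = None
    top_taxa: dict[str, float] | None = None


def summarize_site(
    site: SiteRecord,
    profile: TaxonProfile | None = None,
    diversity: DiversityResult | None = None,
    top_rank: str = "phylum",
    n_top: int = 10,
) -> SiteSummary:
    """Assemble one site's summary from whatever components are present."""
    ratio = None
    if site.vlp_per_ml is not None and site.cells_per_ml is not None:
        ratio = vpr(site.vlp_per_ml, site.cells_per_ml)
    mean_len = None
    if site.n_reads is not None and site.total_bp is not None:
        mean_len = library_summary(site.n_reads, site.total_bp)
    top = None
    if profile is not None:
        rolled = rollup(profile, top_rank)
        top = dict(
            sorted(
                ((name, pct) for name, (_, pct) in rolled.items()),
                key=lambda kv: kv[1],
                reverse=True,
            )[:n_top]
        )
    return SiteSummary(
        site_id=site.site_id,
        vpr=ratio,
        mean_read_length=mean_len,
        diversity=diversity,
        top_taxa=top,
    )


def build_report(
    sites: list[SiteRecord],
    profiles: dict[str, TaxonProfile] | None = None,
    diversity: dict[str, DiversityResult] | None = None,
    similarity: ContigSimilarityResult | None = None,
    top_rank: str = "phylum",
) -> dict:
    """One machine-readable report combining all pipeline outputs.

    Missing components are reported as absent rather than failing; the
    result round-trips through JSON (see :func:`write_report`).
    """
    profiles = profiles or {}
    diversity = diversity or {}
    report: dict = {"sites": {}, "shared_contigs": None}
    for site in sites:
        summary = summarize_site(
            site,
            profile=profiles.get(site.site_id),
            diversity=diversity.get(site.site_id),
            top_rank=top_rank,
        )
        div = summary.diversity
        report["sites"][site.site_id] = {
            "vpr": summary.vpr,
            "mean_read_length": summary.mean_read_length,
            "diversity": None
            if div is None
            else {
                "observed": div.observed,
                "shannon": div.shannon,
                "chao1": div.chao1,
                "evenness": div.evenness,
                "pielou": div.pielou,
                "chao1_variant": div.chao1_variant,
            },
            "top_taxa": summary.top_taxa,
        }
    if similarity is not None:
        report["shared_contigs"] = {
            "k": similarity.k,
            "threshold": similarity.threshold,
            "n_unassigned_a": similarity.n_a,
            "n_unassigned_b": similarity.n_b,
            "n_shared": len(similarity.shared_a) + len(similarity.shared_b),
            "shared_fraction_overall": similarity.shared_fraction_overall,
            "shared_fraction_a": similarity.shared_fraction_a,
            "shared_fraction_b": similarity.shared_fraction_b,
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
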