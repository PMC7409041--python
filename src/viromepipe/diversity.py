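"""Richness and alpha diversity on the TPM-derived surrogate count table.

The taxon profile (summed gene TPM per lineage) stands in for an OTU
table. Because Chao1 needs integer counts, TPM values are integerized by
rounding, flooring positive-TPM lineages to a minimum count of 1 so that
observed richness equals the number of lineages actually detected.

Indices:

* observed richness  S  = number of taxa with positive count
* Shannon            H  = -sum p_i ln p_i   (natural log)
* Chao1 (bias-corrected, default)  S + F1(F1-1) / (2(F2+1))
* Chao1 (classic)                  S + F1^2 / (2 F2)        (needs F2 > 0)
* evenness           E  = H / S   (this pipeline's definition; distinct
  from Pielou's J = H / ln S, which is reported alongside)

F1 and F2 are the singleton and doubleton counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from viromepipe.profiles import TaxonProfile

logger = logging.getLogger(__name__)

CHAO1_VARIANTS = ("bias-corrected", "classic")


@dataclass
class DiversityResult:
    """Alpha-diversity summary for one site's surrogate count table."""

    site_id: str
    observed: int
    shannon: float
    chao1: float
    evenness: float
    pielou: float
    chao1_variant: str = "bias-corrected"


def surrogate_counts(profile: TaxonProfile) -> dict[str, int]:
    """Integerize a TPM profile into surrogate counts.

    count = round(TPM); lineages with positive TPM that would round to 0
    are floored to 1, so every detected lineage contributes to observed
    richness. Zero-TPM lineages are excluded.
    """
    if not profile.lineage_tpm:
        raise ValueError("empty taxon profile")
    counts: dict[str, int] = {}
    for lineage, tpm in profile.lineage_tpm.items():
        if tpm <= 0:
            continue
        counts[lineage] = max(1, round(tpm))
    return counts


def shannon(counts: dict[str, int] | list[int], base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i; natural log by default."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("shannon requires at least one positive count")
    p = values / values.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def chao1(counts: dict[str, int] | list[int], variant: str = "bias-corrected") -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    The classic form is undefined at F2 = 0 and falls back to the
    bias-corrected form with a warning.
    """
    if variant not in CHAO1_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {CHAO1_VARIANTS}")
    values = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts
    )
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("chao1 requires integer counts (see surrogate_counts)")
        values = np.round(values).astype(int)
    values = values[values > 0]
    s = int(values.size)
    f1 = int((values == 1).sum())
    f2 = int((values == 2).sum())
    if variant == "classic":
        if f2 > 0:
            return s + f1 * f1 / (2.0 * f2)
        logger.warning("classic Chao1 undefined at F2=0; using bias-corrected form")
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def evenness(h: float, s: int) -> float:
    """Evenness E = H / S (Shannon over observed richness)."""
    if s < 1:
        raise ValueError(f"observed richness must be >= 1, got {s}")
    return h / s


def pielou(h: float, s: int) -> float:
    """Pielou's J = H / ln S (0 by convention for S = 1, where H = 0)."""
    if s < 1:
        raise ValueError(f"observed richness must be >= 1, got {s}")
    return h / math.log(s) if s > 1 else 0.0


def alpha_diversity(
    profile: TaxonProfile, chao1_variant: str = "bias-corrected"
) -> DiversityResult:
    """Observed richness, Shannon, Chao1, evenness and Pielou J for a
    taxon profile, via the surrogate count table."""
    counts = surrogate_counts(profile)
    if not counts:
        raise ValueError(f"profile for {profile.site_id!r} has no positive-TPM lineage")
    s = len(counts)
    h = shannon(counts)
    return DiversityResult(
        site_id=profile.site_id,
        observed=s,
        shannon=h,
        chao1=chao1(counts, chao1_variant),
        evenness=evenness(h, s),
        pielou=pielou(h, s),
        chao1_variant=chao1_variant,
    )
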