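"""Decline projection and Red List categorization.

Habitat loss observed over a window of ``observed_years`` is converted to an
annual rate ``r = p_loss / observed_years`` (floored at 0 when habitat
increased) and projected over the assessment window — the longer of three
generations and 10 years — with proportional decay::

    decline = 1 - (1 - r) ** window_years

The exploitation decline is added to the deforestation decline; totals above
1 are capped at 1 for classification (raw totals are kept alongside).
Decline thresholds are inclusive (≥): CR 0.80, EN 0.50, VU 0.30, NT 0.15 by
default.  Restricted-range categories use strict upper bounds on EOO:
EN < 500 km², VU < 2000 km².  Listing recommendations are suppressed for
species with less than 80% of their range in the study region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

from .exploitation import ExploitationEstimate
from .habitat import HabitatChange, SpeciesRecord

__all__ = [
    "CATEGORIES",
    "Thresholds",
    "DeclineProjection",
    "RedListAssessment",
    "assessment_window",
    "project_decline",
    "classify_decline",
    "classify_eoo",
    "more_severe",
    "assess",
    "summarize",
    "category_counts",
    "threatened_total",
    "percent_increase",
]

# Severity order, least to most severe.
CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
_SEVERITY = {cat: k for k, cat in enumerate(CATEGORIES)}
THREATENED = ("VU", "EN", "CR")

DEFAULT_OBSERVED_YEARS = 15.0


@dataclass(frozen=True)
class Thresholds:
    """Configurable classification thresholds."""

    nt: float = 0.15  # Fig.-caption variant would be 0.20
    vu: float = 0.30
    en: float = 0.50
    cr: float = 0.80
    eoo_en_km2: float = 500.0
    eoo_vu_km2: float = 2000.0
    endemism: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.nt < self.vu < self.en < self.cr):
            raise ValueError("decline thresholds must be positive and increasing")
        if not (0 < self.eoo_en_km2 < self.eoo_vu_km2):
            raise ValueError("EOO thresholds must be positive and increasing")


@dataclass
class DeclineProjection:
    """Deforestation-driven decline projected over the assessment window."""

    species_id: str
    r_annual: float
    window_years: float
    decline_deforestation: float
    increase: bool = False
    rate_capped: bool = False


@dataclass
class RedListAssessment:
    species_id: str
    decline_deforestation: float
    decline_exploitation: float
    decline_lo: float  # total at exploitation lower bound (capped)
    decline_hi: float
    decline_total_raw: float  # additive total, possibly > 1
    decline_total: float  # capped at 1 for classification
    category_decline: str
    eoo_km2: Optional[float]
    category_eoo: Optional[str]
    final_category: str
    primary_driver: str  # "deforestation" | "exploitation"
    endemic: bool
    region_fraction: float
    flags: List[str] = field(default_factory=list)


def assessment_window(generation_length: Optional[float]) -> float:
    """Assessment window: max(3 generations, 10 years); 10 when unknown."""
    if generation_length is None:
        warnings.warn(
            "generation length unknown; using the 10-year window", stacklevel=2
        )
        return 10.0
    if generation_length <= 0:
        raise ValueError("generation_length must be positive")
    return max(3.0 * generation_length, 10.0)


def project_decline(
    p_loss: float,
    observed_years: float = DEFAULT_OBSERVED_YEARS,
    window_years: float = 10.0,
    species_id: str = "",
) -> DeclineProjection:
    """Project observed habitat loss over the assessment window."""
    if observed_years <= 0:
        raise ValueError("observed_years must be positive")
    increase = p_loss < 0
    r = 0.0 if increase else p_loss / observed_years
    capped = r >= 1.0
    decline = 1.0 if capped else 1.0 - (1.0 - r) ** window_years
    return DeclineProjection(species_id, r, window_years, decline, increase, capped)


def classify_decline(decline_total: float, thresholds: Thresholds = Thresholds()) -> str:
    """Category from total decline; thresholds are inclusive (≥)."""
    if decline_total < 0:
        raise ValueError("decline must be non-negative")
    d = min(decline_total, 1.0)
    if d >= thresholds.cr:
        return "CR"
    if d >= thresholds.en:
        return "EN"
    if d >= thresholds.vu:
        return "VU"
    if d >= thresholds.nt:
        return "NT"
    return "LC"


def classify_eoo(eoo_km2: float, thresholds: Thresholds = Thresholds()) -> Optional[str]:
    """Restricted-range category from EOO; strict upper bounds; None if large."""
    if eoo_km2 < 0:
        raise ValueError("EOO must be non-negative")
    if eoo_km2 < thresholds.eoo_en_km2:
        return "EN"
    if eoo_km2 < thresholds.eoo_vu_km2:
        return "VU"
    return None


def more_severe(a: str, b: Optional[str]) -> str:
    if b is None:
        return a
    return a if _SEVERITY[a] >= _SEVERITY[b] else b


def assess(
    species: Iterable[SpeciesRecord],
    habitat_changes: Mapping[str, HabitatChange],
    exploitation: Mapping[str, ExploitationEstimate],
    region_fraction: Mapping[str, float],
    eoo_km2: Optional[Mapping[str, float]] = None,
    observed_years: float = DEFAULT_OBSERVED_YEARS,
    thresholds: Thresholds = Thresholds(),
) -> List[RedListAssessment]:
    """Assess each species from its habitat change and exploitation estimate.

    Species with missing inputs are skipped with a warning; species whose
    t0 habitat is zero are routed to the EOO criterion only.
    """
    eoo_km2 = eoo_km2 or {}
    out: List[RedListAssessment] = []
    for sp in species:
        change = habitat_changes.get(sp.species_id)
        if change is None:
            warnings.warn(
                f"species {sp.species_id}: no habitat change; skipped", stacklevel=2
            )
            continue
        flags: List[str] = []
        window = assessment_window(sp.generation_length) if sp.generation_length else 10.0
        if sp.generation_length is None:
            flags.append("no_generation_length")

        if change.undefined:
            flags.append("p_loss_undefined")
            proj = DeclineProjection(sp.species_id, 0.0, window, 0.0)
        else:
            proj = project_decline(change.p_loss, observed_years, window, sp.species_id)
            if proj.increase:
                flags.append("habitat_increase")

        est = exploitation.get(sp.species_id)
        exp_point = est.decline_point if est is not None else 0.0
        exp_lo = est.decline_lo if est is not None else 0.0
        exp_hi = est.decline_hi if est is not None else 0.0

        total_raw = proj.decline_deforestation + exp_point
        total = min(total_raw, 1.0)
        if total_raw > 1.0:
            flags.append("decline_capped")
        cat_a = classify_decline(total, thresholds)

        sp_eoo = eoo_km2.get(sp.species_id)
        cat_b = classify_eoo(sp_eoo, thresholds) if sp_eoo is not None else None
        final = more_severe(cat_a, cat_b)

        frac = float(region_fraction.get(sp.species_id, 0.0))
        out.append(
            RedListAssessment(
                species_id=sp.species_id,
                decline_deforestation=proj.decline_deforestation,
                decline_exploitation=exp_point,
                decline_lo=min(proj.decline_deforestation + exp_lo, 1.0),
                decline_hi=min(proj.decline_deforestation + exp_hi, 1.0),
                decline_total_raw=total_raw,
                decline_total=total,
                category_decline=cat_a,
                eoo_km2=sp_eoo,
                category_eoo=cat_b,
                final_category=final,
                primary_driver=(
                    "exploitation"
                    if exp_point > proj.decline_deforestation
                    else "deforestation"
                ),
                endemic=frac >= thresholds.endemism,
                region_fraction=frac,
                flags=flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summary aggregation
# ---------------------------------------------------------------------------


def category_counts(categories: Iterable[str]) -> Dict[str, int]:
    counts = {cat: 0 for cat in CATEGORIES}
    for cat in categories:
        if cat not in counts:
            raise ValueError(f"unknown category {cat!r}")
        counts[cat] += 1
    return counts


def threatened_total(counts: Mapping[str, int]) -> int:
    """Total threatened species: VU + EN + CR."""
    return sum(int(counts.get(cat, 0)) for cat in THREATENED)


def percent_increase(new: float, old: float) -> int:
    """Percent increase from ``old`` to ``new``, rounded to nearest integer."""
    if old <= 0:
        raise ValueError("baseline must be positive")
    return int(round((new - old) / old * 100.0))


def summarize(assessments: Iterable[RedListAssessment], endemic_only: bool = True) -> Dict:
    """Category counts, driver attribution and mean declines for a cohort."""
    pool = [a for a in assessments if a.endemic or not endemic_only]
    counts = category_counts(a.final_category for a in pool)
    exploited = [a for a in pool if a.decline_exploitation > 0]
    summary = {
        "n_assessed": len(pool),
        "category_counts": counts,
        "threatened_total": threatened_total(counts),
        "n_exploited": len(exploited),
        "exploitation_dominant": sum(
            1 for a in exploited if a.primary_driver == "exploitation"
        ),
        "mean_decline_total": float(np.mean([a.decline_total for a in pool]))
        if pool
        else float("nan"),
        "mean_decline_deforestation": float(
            np.mean([a.decline_deforestation for a in pool])
        )
        if pool
        else float("nan"),
        "mean_decline_exploitation_exploited": float(
            np.mean([a.decline_exploitation for a in exploited])
        )
        if exploited
        else float("nan"),
    }
    return summary
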