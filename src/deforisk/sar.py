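"""Species-area relationship extinction projections.

Working in ratio form (c = 1), the fraction of species expected to be lost
after habitat shrinks to ``habitat_ratio`` of its original extent is
``1 - habitat_ratio ** z``.
"""

from __future__ import annotations

import math

__all__ = [
    "Z_LOWER",
    "Z_UPPER",
    "extinction_fraction",
    "invert_habitat_ratio",
    "project_forest_to",
    "species_count",
]

Z_LOWER = 0.18
Z_UPPER = 0.35


def _check_z(z: float) -> None:
    if z <= 0:
        raise ValueError("z must be positive")


def extinction_fraction(habitat_ratio: float, z: float) -> float:
    """Fraction of species lost when habitat shrinks to ``habitat_ratio``."""
    _check_z(z)
    if not 0.0 <= habitat_ratio <= 1.0:
        raise ValueError("habitat_ratio must be in [0, 1]")
    return 1.0 - habitat_ratio**z


def invert_habitat_ratio(fraction: float, z: float) -> float:
    """Habitat ratio implying an extinction ``fraction`` at exponent ``z``.

    Inverse of :func:`extinction_fraction`; round-trips to ~1e-12.
    """
    _check_z(z)
    if not 0.0 <= fraction < 1.0:
        raise ValueError("extinction fraction must be in [0, 1)")
    return (1.0 - fraction) ** (1.0 / z)


def project_forest_to(
    year: float, year_now: float, forest_area: float, annual_rate: float
) -> float:
    """Forest area at ``year`` under a constant proportional loss rate."""
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError("annual_rate must be in [0, 1)")
    years = year - year_now
    if years < 0:
        raise ValueError("projection year precedes the reference year")
    return forest_area * (1.0 - annual_rate) ** years


def species_count(fraction: float, pool: int, mode: str = "truncate") -> int:
    """Species count implied by an extinction fraction of a pool.

    ``truncate`` (default) drops the fractional part toward zero, matching
    the pairing 0.169 × 308 → 52; ``round`` rounds to nearest.
    """
    if pool < 0:
        raise ValueError("pool must be non-negative")
    value = fraction * pool
    if mode == "truncate":
        return math.trunc(value)
    if mode == "round":
        return int(round(value))
    raise ValueError(f"unknown mode {mode!r}")
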