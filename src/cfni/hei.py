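"""HEI-2015 scoring of carts from dietary constituent totals.

The Healthy Eating Index 2015 is a 0-100 diet-quality score built from 13
components, each scored piecewise-linearly against minimum and maximum
density standards.  Densities are *ratios of totals*: constituent amounts
are summed over the whole cart first and divided by the cart's total
energy (per 1000 kcal, as a percent of energy, or as the unsaturated to
saturated fatty-acid ratio); they are never averaged per item.

Adequacy components (fruits, vegetables, whole grains, dairy, proteins,
fatty acids) award more points for higher density; moderation components
(refined grains, sodium, added sugars, saturated fats) award more points
for lower density.  The engine is standards-agnostic: the 13 standards are
configuration (:func:`load_standards`), so tests can run on toy standards
with hand-checkable numbers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError, UndefinedScoreError
from .types import Cart, ConstituentTotals, HEIScore

logger = logging.getLogger(__name__)

_BASES = ("per_1000_kcal", "percent_energy", "fatty_acid_ratio")
_KINDS = ("adequacy", "moderation")


@dataclass(frozen=True)
class HEIComponentStandard:
    """Scoring standard for one HEI component.

    For adequacy components, full points are awarded at densities at or
    above ``standard_for_max`` and zero at or below ``standard_for_min``
    (typically 0, i.e. zero intake).  For moderation components the
    direction reverses: full points at or below ``standard_for_max``, zero
    at or above ``standard_for_min``, so ``standard_for_max <
    standard_for_min`` is required.
    """

    name: str
    constituent: str | None
    max_points: float
    kind: str
    basis: str
    standard_for_max: float
    standard_for_min: float
    energy_per_gram: float = 0.0  # kcal/g, only for percent_energy basis

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"component '{self.name}': unknown kind '{self.kind}'")
        if self.basis not in _BASES:
            raise ConfigurationError(f"component '{self.name}': unknown basis '{self.basis}'")
        if self.max_points not in (5, 10):
            raise ConfigurationError(
                f"component '{self.name}': max_points must be 5 or 10, got {self.max_points}"
            )
        if self.kind == "moderation" and not self.standard_for_max < self.standard_for_min:
            raise ConfigurationError(
                f"moderation component '{self.name}' requires standard_for_max < standard_for_min"
            )
        if self.basis == "percent_energy" and self.energy_per_gram <= 0:
            raise ConfigurationError(
                f"component '{self.name}': percent_energy basis needs energy_per_gram > 0"
            )


def load_standards(path) -> tuple[HEIComponentStandard, ...]:
    """Read a standards YAML file (see the bundled ``hei2015_standards.yaml``)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "components" not in raw:
        raise ConfigurationError("standards config must have a top-level 'components' list")
    standards = []
    for block in raw["components"]:
        standards.append(
            HEIComponentStandard(
                name=block["name"],
                constituent=block.get("constituent"),
                max_points=float(block["max_points"]),
                kind=block["kind"],
                basis=block["basis"],
                standard_for_max=float(block["standard_for_max"]),
                standard_for_min=float(block.get("standard_for_min", 0.0)),
                energy_per_gram=float(block.get("energy_per_gram", 0.0)),
            )
        )
    return tuple(standards)


def accumulate_constituents(cart: Cart) -> ConstituentTotals:
    """Component-wise constituent sums over a cart's items.

    The cart must already be filtered of not-ranked items
    (:func:`cfni.ranker.filter_ranked_items`); the cart-level densities
    downstream use these totals, so per-item densities never enter.

    Raises
    ------
    UndefinedScoreError
        If the energy total is zero (density denominators vanish).
    """
    total = ConstituentTotals()
    for item in cart:
        total = total + item.constituents
    if total.energy <= 0:
        raise UndefinedScoreError(
            f"cart '{cart.cart_id}' has zero total energy; HEI densities undefined"
        )
    return total


def _density(totals: ConstituentTotals, std: HEIComponentStandard) -> float:
    if std.basis == "fatty_acid_ratio":
        unsat = totals.mufa + totals.pufa
        if totals.sfa > 0:
            return unsat / totals.sfa
        # sfa = 0: ratio limit -> full points if any unsaturated fat,
        # zero if no fat at all (no adequacy evidence).
        logger.info("fatty-acid ratio with sfa=0; scoring by limit convention")
        return float("inf") if unsat > 0 else 0.0
    amount = getattr(totals, std.constituent)
    if std.basis == "per_1000_kcal":
        return amount * 1000.0 / totals.energy
    # percent_energy
    return amount * std.energy_per_gram * 100.0 / totals.energy


def component_score(totals: ConstituentTotals, std: HEIComponentStandard) -> float:
    """Piecewise-linear score of one component, clamped to [0, max_points]."""
    if totals.energy <= 0:
        raise UndefinedScoreError("energy must be positive to compute densities")
    d = _density(totals, std)
    if std.kind == "adequacy":
        if d >= std.standard_for_max:
            return std.max_points
        if d <= std.standard_for_min:
            return 0.0
        frac = (d - std.standard_for_min) / (std.standard_for_max - std.standard_for_min)
    else:  # moderation: reversed direction
        if d <= std.standard_for_max:
            return std.max_points
        if d >= std.standard_for_min:
            return 0.0
        frac = (std.standard_for_min - d) / (std.standard_for_min - std.standard_for_max)
    return min(max(std.max_points * frac, 0.0), std.max_points)


def score_cart(cart: Cart, standards: Sequence[HEIComponentStandard]) -> HEIScore:
    """Total HEI score of a cart: the sum of its component scores.

    ``standards`` must be a complete component set whose max points sum
    to 100 so the total lives on the canonical 0-100 scale.
    """
    pts = sum(s.max_points for s in standards)
    if abs(pts - 100.0) > 1e-9:
        raise ConfigurationError(f"standards max_points must sum to 100, got {pts}")
    totals = accumulate_constituents(cart)
    comps = {s.name: component_score(totals, s) for s in standards}
    return HEIScore(cart_id=cart.cart_id, component_scores=comps, total=sum(comps.values()))


def score_totals(
    cart_id: str, totals: ConstituentTotals, standards: Sequence[HEIComponentStandard]
) -> HEIScore:
    """Score pre-accumulated constituent totals (no 100-point completeness check)."""
    comps = {s.name: component_score(totals, s) for s in standards}
    return HEIScore(cart_id=cart_id, component_scores=comps, total=sum(comps.values()))
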