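"""Synthetic inputs with the statistical structure the analysis assumes.

Two levels of simulation:

* **Composition level** — samples of (%green, %yellow, %red, HEI) for one
  cart each, drawn so the marginal tier moments, the HEI spread, and the
  linear HEI-composition dependence match the study conditions: mean
  composition (50.1, 26.0, 23.9) with SDs (14.1, 11.1, 12.4), HEI SD 11.4,
  and a generating plane HEI = 56.72 + 0.270*G - 0.278*R plus Gaussian
  noise.  (%green, %red) are drawn bivariate normal and rejected off the
  simplex; %yellow is the complement.  A symmetric Dirichlet cannot reach
  the strong negative green-red dependence the target multiple correlation
  requires (about -0.69 by moment matching), hence the truncated-normal
  construction.

* **Item level** — food catalogs and carts of :class:`~cfni.types.FoodItem`
  for exercising the tier ranker and HEI scorer end to end, including
  not-ranked items so the exclusion logic runs.

The free dependence and noise parameters are set by
:func:`calibrate_generator` so that the share of HEI variance explained by
the composition matches a target correlation (default 0.585 against an HEI
SD of 11.4).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError
from .types import (
    CATEGORIES,
    NOT_RANKED_CATEGORIES,
    Cart,
    ConstituentTotals,
    FoodItem,
)

DEFAULT_SEED = 20220921


@dataclass(frozen=True)
class CompositionParams:
    """Parameters of the composition-level generator.

    ``corr_green_red`` and ``noise_sd`` default to None, meaning they are
    calibrated at sampling time from ``target_hei_sd`` and
    ``target_cv_corr`` via :func:`calibrate_generator`.
    """

    n_carts: int = 503
    mean_composition: tuple[float, float, float] = (50.1, 26.0, 23.9)
    sd_composition: tuple[float, float, float] = (14.1, 11.1, 12.4)
    corr_green_red: float | None = None
    gen_constant: float = 56.72
    gen_coef_green: float = 0.270
    gen_coef_red: float = -0.278
    noise_sd: float | None = None
    target_hei_sd: float = 11.4
    target_cv_corr: float = 0.585
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if abs(sum(self.mean_composition) - 100.0) > 1e-9:
            raise ValidationError(
                f"mean_composition must sum to 100, got {sum(self.mean_composition)}"
            )
        if self.n_carts < 10:
            raise ValidationError(f"n_carts must be >= 10, got {self.n_carts}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.corr_green_red is not None and not -1.0 <= self.corr_green_red <= 0.0:
            raise ValidationError("corr_green_red must lie in [-1, 0]")


def calibrate_generator(
    target_hei_sd: float = 11.4,
    target_cv_corr: float = 0.585,
    sd_composition: Sequence[float] = (14.1, 11.1, 12.4),
    gen_coef_green: float = 0.270,
    gen_coef_red: float = -0.278,
) -> tuple[float, float]:
    """Moment-match the green-red correlation and the noise SD.

    The linear predictor bG*G + bR*R must carry a ``target_cv_corr``
    fraction of the HEI spread, so its variance is set to
    ``(target_cv_corr * target_hei_sd)**2`` by solving

        bG^2 sG^2 + bR^2 sR^2 + 2 bG bR corr sG sR = (rho * sd_H)^2

    for ``corr``; the residual variance gives
    ``noise_sd = target_hei_sd * sqrt(1 - target_cv_corr^2)``.

    Returns
    -------
    (corr_green_red, noise_sd)

    Raises
    ------
    CalibrationError
        If no correlation in [-1, 0] attains the required predictor
        variance; the message reports the attainable range.
    """
    if not 0.0 < target_cv_corr < 1.0:
        raise ValidationError("target_cv_corr must lie in (0, 1)")
    sG, sR = float(sd_composition[0]), float(sd_composition[2])
    bG, bR = gen_coef_green, gen_coef_red
    base = bG**2 * sG**2 + bR**2 * sR**2
    cross = 2.0 * bG * bR * sG * sR  # variance added per unit of corr
    target = (target_cv_corr * target_hei_sd) ** 2
    lo = min(base, base - cross)
    hi = max(base, base - cross)
    if cross == 0:
        if abs(target - base) > 1e-12:
            raise CalibrationError(
                f"predictor variance fixed at {base:.4g}; target {target:.4g} unattainable"
            )
        corr = 0.0
    else:
        corr = (target - base) / cross
        if not -1.0 <= corr <= 0.0:
            raise CalibrationError(
                f"required predictor variance {target:.4g} outside the attainable "
                f"range [{lo:.4g}, {hi:.4g}] for corr in [-1, 0]"
            )
    noise_sd = target_hei_sd * math.sqrt(1.0 - target_cv_corr**2)
    return float(corr), float(noise_sd)


def _resolved(params: CompositionParams) -> CompositionParams:
    """Fill in calibrated corr_green_red / noise_sd where unset."""
    if params.corr_green_red is not None and params.noise_sd is not None:
        return params
    corr, noise = calibrate_generator(
        params.target_hei_sd,
        params.target_cv_corr,
        params.sd_composition,
        params.gen_coef_green,
        params.gen_coef_red,
    )
    return replace(
        params,
        corr_green_red=params.corr_green_red if params.corr_green_red is not None else corr,
        noise_sd=params.noise_sd if params.noise_sd is not None else noise,
    )


def generate_compositions(params: CompositionParams) -> pd.DataFrame:
    """Sample cart compositions and HEI scores from the generating model.

    (%green, %red) are bivariate normal with the configured means, SDs and
    correlation; draws with any of green, red, or yellow = 100 - green -
    red outside [0, 100] are rejected (rejection preserves approximate
    moments better than clipping).  HEI is the generating plane plus
    Gaussian noise, truncated to [0, 100] since the index is bounded.

    Returns a DataFrame with columns cart_id, pct_green, pct_yellow,
    pct_red, hei.
    """
    p = _resolved(params)
    rng = np.random.default_rng(p.seed)
    mG, _, mR = p.mean_composition
    sG, _, sR = p.sd_composition
    cov = np.array(
        [
            [sG**2, p.corr_green_red * sG * sR],
            [p.corr_green_red * sG * sR, sR**2],
        ]
    )
    mean = np.array([mG, mR])
    out_g: list[np.ndarray] = []
    out_r: list[np.ndarray] = []
    n_have = 0
    max_rounds = 1000
    for _ in range(max_rounds):
        batch = max(2 * (p.n_carts - n_have), 1000)
        draws = rng.multivariate_normal(mean, cov, size=batch, method="svd")
        g, r = draws[:, 0], draws[:, 1]
        y = 100.0 - g - r
        ok = (g >= 0) & (g <= 100) & (r >= 0) & (r <= 100) & (y >= 0) & (y <= 100)
        out_g.append(g[ok])
        out_r.append(r[ok])
        n_have += int(ok.sum())
        if n_have >= p.n_carts:
            break
    else:  # pragma: no cover - requires pathological parameters
        raise CalibrationError("rejection sampling failed to reach the simplex")
    g = np.concatenate(out_g)[: p.n_carts]
    r = np.concatenate(out_r)[: p.n_carts]
    y = 100.0 - g - r
    hei = (
        p.gen_constant
        + p.gen_coef_green * g
        + p.gen_coef_red * r
        + rng.normal(0.0, p.noise_sd, size=p.n_carts)
    )
    hei = np.clip(hei, 0.0, 100.0)
    return pd.DataFrame(
        {
            "cart_id": [f"cart{i:04d}" for i in range(p.n_carts)],
            "pct_green": g,
            "pct_yellow": y,
            "pct_red": r,
            "hei": hei,
        }
    )


# --------------------------------------------------------------------------
# item-level catalog and carts
# --------------------------------------------------------------------------

#: per-category (mean, sd) of per-serving nutrients: sat fat g, sodium mg,
#: added sugar g.  Chosen so each ranked category yields a green/yellow/red
#: mix under the bundled thresholds.
_DEFAULT_NUTRIENTS: dict[str, dict[str, tuple[float, float]]] = {
    "fruits_vegetables": {"sat_fat": (0.2, 0.4), "sodium": (80, 120), "sugar": (2.0, 4.0)},
    "grains": {"sat_fat": (1.0, 1.5), "sodium": (220, 180), "sugar": (4.0, 5.0)},
    "protein": {"sat_fat": (2.5, 2.0), "sodium": (300, 220), "sugar": (1.0, 2.0)},
    "dairy": {"sat_fat": (3.0, 2.5), "sodium": (180, 120), "sugar": (6.0, 6.0)},
    "non_dairy_alternatives": {"sat_fat": (1.0, 1.0), "sodium": (120, 90), "sugar": (5.0, 5.0)},
    "beverages": {"sat_fat": (0.1, 0.2), "sodium": (40, 60), "sugar": (8.0, 10.0)},
    "mixed_dishes": {"sat_fat": (3.5, 2.5), "sodium": (500, 250), "sugar": (3.0, 3.0)},
    "snacks": {"sat_fat": (2.0, 2.0), "sodium": (250, 180), "sugar": (5.0, 6.0)},
    "desserts": {"sat_fat": (4.0, 3.0), "sodium": (180, 120), "sugar": (14.0, 8.0)},
    "condiments_cooking_staples": {"sat_fat": (1.0, 1.5), "sodium": (300, 300), "sugar": (4.0, 6.0)},
    "miscellaneous": {"sat_fat": (1.0, 1.0), "sodium": (100, 100), "sugar": (5.0, 5.0)},
}

#: per-category constituent density templates (per pound of food); zeros
#: elsewhere.  Values are coarse plate-level magnitudes: ~2 cup-eq fruit or
#: vegetable per lb, ~5 oz-eq grain or protein per lb, fats in grams,
#: sodium in mg, added sugar in g.
_DEFAULT_DENSITIES: dict[str, dict[str, float]] = {
    "fruits_vegetables": {"energy": 250, "total_fruit": 1.0, "whole_fruit": 0.8,
                          "total_veg": 1.0, "greens_beans": 0.3},
    "grains": {"energy": 1200, "whole_grain": 2.5, "refined_grain": 2.5},
    "protein": {"energy": 800, "total_protein": 5.0, "seafood_plant_protein": 1.5,
                "mufa": 8.0, "pufa": 6.0, "sfa": 6.0},
    "dairy": {"energy": 400, "dairy": 1.8, "mufa": 4.0, "pufa": 1.0, "sfa": 8.0},
    "non_dairy_alternatives": {"energy": 300, "dairy": 1.5, "mufa": 3.0, "pufa": 3.0, "sfa": 1.0},
    "beverages": {"energy": 200, "total_fruit": 0.5},
    "mixed_dishes": {"energy": 700, "total_veg": 0.8, "refined_grain": 1.5,
                     "total_protein": 2.0, "mufa": 5.0, "pufa": 3.0, "sfa": 5.0},
    "snacks": {"energy": 1800, "refined_grain": 3.0, "mufa": 10.0, "pufa": 8.0, "sfa": 6.0},
    "desserts": {"energy": 1600, "refined_grain": 2.0, "mufa": 6.0, "pufa": 3.0, "sfa": 10.0},
    "condiments_cooking_staples": {"energy": 1000, "mufa": 10.0, "pufa": 10.0, "sfa": 5.0},
    "miscellaneous": {"energy": 400, "total_fruit": 0.3, "total_veg": 0.3},
}


@dataclass(frozen=True)
class CatalogParams:
    """Parameters of the item-level food catalog generator.

    ``n_foods`` is the catalog size per category.  ``nutrients`` maps
    category -> nutrient -> (mean, sd) per serving; negative draws are
    clipped to zero.  ``densities`` maps category -> constituent -> amount
    per pound; per-food multipliers add variety.
    """

    n_foods: int | Mapping[str, int] = 12
    nutrients: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_NUTRIENTS
    )
    densities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_DENSITIES
    )
    min_items: int = 5
    max_items: int = 80
    #: SD of the per-cart latent healthiness preference; 0 makes every cart
    #: draw from the catalog uniformly (no between-cart composition signal)
    preference_sd: float = 1.0
    seed: int = DEFAULT_SEED

    def n_for(self, category: str) -> int:
        n = self.n_foods[category] if isinstance(self.n_foods, Mapping) else self.n_foods
        if n <= 0:
            raise ValidationError(f"category '{category}' requests {n} foods; must be >= 1")
        return int(n)


@dataclass(frozen=True)
class FoodTemplate:
    """A catalog entry: one food type with fixed per-serving nutrients and
    per-pound constituent densities."""

    food_id: str
    category: str
    sat_fat: float
    sodium: float
    added_sugar: float
    density: ConstituentTotals

    def realize(self, item_id: str, cart_id: str, weight: float) -> FoodItem:
        return FoodItem(
            item_id=item_id,
            cart_id=cart_id,
            category=self.category,
            weight=weight,
            sat_fat_per_serving=self.sat_fat,
            sodium_per_serving=self.sodium,
            added_sugar_per_serving=self.added_sugar,
            constituents=self.density.scaled(weight),
        )


def generate_catalog(params: CatalogParams) -> tuple[FoodTemplate, ...]:
    """Draw a deterministic food catalog covering all 11 categories."""
    rng = np.random.default_rng(params.seed)
    catalog: list[FoodTemplate] = []
    for cat in CATEGORIES:
        nut = params.nutrients.get(cat, {"sat_fat": (0, 0), "sodium": (0, 0), "sugar": (0, 0)})
        dens = params.densities.get(cat, {"energy": 500})
        for j in range(params.n_for(cat)):
            vals = {}
            for key in ("sat_fat", "sodium", "sugar"):
                m, s = nut.get(key, (0.0, 0.0))
                vals[key] = max(float(rng.normal(m, s)), 0.0)
            mult = float(rng.lognormal(0.0, 0.3))
            density = ConstituentTotals(
                **{k: v * mult for k, v in dens.items()}
            )
            catalog.append(
                FoodTemplate(
                    food_id=f"{cat}-{j:03d}",
                    category=cat,
                    sat_fat=vals["sat_fat"],
                    sodium=vals["sodium"],
                    added_sugar=vals["sugar"],
                    density=density,
                )
            )
    return tuple(catalog)


#: category-level healthiness offsets used by the cart preference model
_CATEGORY_HEALTH = {
    "fruits_vegetables": 1.5, "grains": 0.3, "protein": 0.0, "dairy": 0.2,
    "non_dairy_alternatives": 0.2, "beverages": -0.5, "mixed_dishes": -0.2,
    "snacks": -1.0, "desserts": -1.5, "condiments_cooking_staples": 0.0,
    "miscellaneous": 0.0,
}


def _health_scores(catalog: Sequence[FoodTemplate]) -> np.ndarray:
    """Healthiness of each catalog food: category offset minus the mean
    z-score of its per-serving nutrients across the catalog."""
    nut = np.array([[t.sat_fat, t.sodium, t.added_sugar] for t in catalog])
    sd = nut.std(axis=0)
    sd[sd == 0] = 1.0
    z = (nut - nut.mean(axis=0)) / sd
    cat = np.array([_CATEGORY_HEALTH.get(t.category, 0.0) for t in catalog])
    return cat - 0.5 * z.mean(axis=1)


def generate_catalog_and_carts(
    params: CatalogParams, n_carts: int, seed: int | None = None
) -> tuple[Cart, ...]:
    """Draw ``n_carts`` carts of 5-80 items from a seeded catalog.

    Carts differ in a latent healthiness preference (normal with SD
    ``preference_sd``) that tilts item selection toward or away from
    healthier foods, creating the between-cart variation in tier
    composition and HEI that real client carts show.  Every cart receives
    at least one condiments/cooking-staples item so the not-ranked
    exclusion path is always exercised; item weights are lognormal around
    one pound.
    """
    if seed is None:
        seed = params.seed
    catalog = generate_catalog(params)
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[FoodTemplate]] = {c: [] for c in CATEGORIES}
    for t in catalog:
        by_cat[t.category].append(t)
    health = _health_scores(catalog)
    carts = []
    for i in range(n_carts):
        cart_id = f"cart{i:04d}"
        n_items = int(rng.integers(params.min_items, params.max_items + 1))
        staples = by_cat["condiments_cooking_staples"]
        chosen = [staples[int(rng.integers(len(staples)))]]
        pref = float(rng.normal(0.0, params.preference_sd))
        logits = pref * health
        p = np.exp(logits - logits.max())
        p /= p.sum()
        idx = rng.choice(len(catalog), size=n_items - 1, replace=True, p=p)
        chosen.extend(catalog[int(k)] for k in idx)
        items = []
        for j, tmpl in enumerate(chosen):
            weight = float(np.clip(rng.lognormal(0.0, 0.6), 0.05, 10.0))
            items.append(tmpl.realize(f"{cart_id}-item{j:03d}", cart_id, weight))
        carts.append(Cart(cart_id=cart_id, items=tuple(items)))
    return tuple(carts)
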