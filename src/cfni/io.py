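"""Cart-table I/O, result serialization, and the end-to-end pipeline.

Cart-item tables are UTF-8 CSV with a mandatory header.  Required columns:
``cart_id, item_id, category, weight_lb, sat_fat_g_serv, sodium_mg_serv,
added_sugar_g_serv`` plus the 15 constituent columns (see
``CONSTITUENT_COLUMNS``).  An optional ``weight_unit`` column (``lb`` or
``g``) allows gram weights, converted to pounds on read; the tier
percentages are unit-invariant ratios, so the choice never affects results.

Reports are JSON with stable key order and floats at 6 significant digits,
so identical inputs and seed produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import hei as hei_mod
from . import model as model_mod
from . import ranker as ranker_mod
from . import validation as validation_mod
from .errors import CfniError, PipelineError, SchemaError, ValidationError
from .simulate import DEFAULT_SEED, CatalogParams, generate_catalog_and_carts
from .types import (
    CONSTITUENT_FIELDS,
    GRAMS_PER_POUND,
    Cart,
    ConstituentTotals,
    FoodItem,
    as_dict,
)

logger = logging.getLogger(__name__)

#: constituent field -> CSV column (units in the suffix)
CONSTITUENT_COLUMNS: dict[str, str] = {
    "energy": "energy_kcal",
    "total_fruit": "total_fruit_cup",
    "whole_fruit": "whole_fruit_cup",
    "total_veg": "total_veg_cup",
    "greens_beans": "greens_beans_cup",
    "dairy": "dairy_cup",
    "whole_grain": "whole_grain_oz",
    "refined_grain": "refined_grain_oz",
    "total_protein": "total_protein_oz",
    "seafood_plant_protein": "seafood_plant_protein_oz",
    "mufa": "mufa_g",
    "pufa": "pufa_g",
    "sfa": "sfa_g",
    "sodium": "sodium_mg",
    "added_sugar": "added_sugar_g",
}

REQUIRED_COLUMNS = (
    "cart_id",
    "item_id",
    "category",
    "weight_lb",
    "sat_fat_g_serv",
    "sodium_mg_serv",
    "added_sugar_g_serv",
) + tuple(CONSTITUENT_COLUMNS.values())


def read_cart_table(path, schema: Mapping[str, str] | None = None) -> tuple[Cart, ...]:
    """Read a cart-item CSV into carts, one per distinct cart_id.

    ``schema`` optionally maps canonical column names to the file's actual
    column names.  Items keep file order within each cart; numeric fields
    are parsed with a locale-independent decimal point.
    """
    schema = dict(schema or {})
    try:
        df = pd.read_csv(path, dtype={"cart_id": str, "item_id": str, "category": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse '{path}' as a cart-item CSV: {exc}") from exc
    colmap = {canon: schema.get(canon, canon) for canon in REQUIRED_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"missing required column '{actual}' (for '{canon}')")
    has_unit = "weight_unit" in df.columns
    carts: dict[str, list[FoodItem]] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rowd = row._asdict()
        weight = float(rowd[colmap["weight_lb"]])
        if has_unit:
            unit = str(rowd["weight_unit"]).strip().lower()
            if unit == "g":
                weight /= GRAMS_PER_POUND
            elif unit not in ("lb", "nan", ""):
                raise ValidationError(f"row {pos}: unknown weight unit '{unit}'")
        try:
            constituents = ConstituentTotals(
                **{f: float(rowd[colmap[c]]) for f, c in CONSTITUENT_COLUMNS.items()}
            )
            item = FoodItem(
                item_id=str(rowd[colmap["item_id"]]),
                cart_id=str(rowd[colmap["cart_id"]]),
                category=str(rowd[colmap["category"]]),
                weight=weight,
                sat_fat_per_serving=float(rowd[colmap["sat_fat_g_serv"]]),
                sodium_per_serving=float(rowd[colmap["sodium_mg_serv"]]),
                added_sugar_per_serving=float(rowd[colmap["added_sugar_g_serv"]]),
                constituents=constituents,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {pos}: {exc}") from exc
        carts.setdefault(item.cart_id, []).append(item)
    return tuple(Cart(cart_id=cid, items=tuple(items)) for cid, items in carts.items())


def write_cart_table(carts: Iterable[Cart], path) -> None:
    """Write carts back to the canonical CSV layout (pounds, no unit column)."""
    rows = []
    for cart in carts:
        for it in cart:
            row = {
                "cart_id": it.cart_id,
                "item_id": it.item_id,
                "category": it.category,
                "weight_lb": it.weight,
                "sat_fat_g_serv": it.sat_fat_per_serving,
                "sodium_mg_serv": it.sodium_per_serving,
                "added_sugar_g_serv": it.added_sugar_per_serving,
            }
            for f, c in CONSTITUENT_COLUMNS.items():
                row[c] = getattr(it.constituents, f)
            rows.append(row)
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def _round_floats(obj, sig: int = 6):
    """Recursively format floats at ``sig`` significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_results(report, path, *, seed: int | None = None, config_digest: str | None = None) -> None:
    """Serialize any result object (dataclass, dict, DataFrame) to JSON.

    Deterministic: stable key order and 6-significant-digit floats, so the
    same report always produces byte-identical files.  ``seed`` and
    ``config_digest`` are recorded alongside when given.
    """
    payload = _to_jsonable(report)
    if seed is not None or config_digest is not None:
        if not isinstance(payload, dict):
            payload = {"result": payload}
        if seed is not None:
            payload.setdefault("seed", seed)
        if config_digest is not None:
            payload.setdefault("config_digest", config_digest)
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory '{path.parent}' does not exist")
    text = json.dumps(_round_floats(payload), sort_keys=True, indent=1)
    path.write_text(text + "\n", encoding="utf-8")


def read_results(path) -> dict:
    """Parse a results JSON file written by :func:`write_results`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(as_dict(obj))
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(obj.columns), "rows": obj.to_numpy().tolist()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):  # numpy scalar
        try:
            return obj.item()
        except Exception:
            return obj
    return obj


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    ``input_path=None`` generates item-level synthetic carts instead of
    reading a table.  ``method`` selects the estimator (model1 = ridge with
    information-criterion penalty, model2 = ridge with cross-validated
    penalty, model3 = OLS); ``k`` is the evaluation CV fold count.
    """

    seed: int = DEFAULT_SEED
    thresholds_path: str | None = None
    standards_path: str | None = None
    input_path: str | None = None
    method: str = "model1"
    k: int = 5
    n_carts: int = 503


def default_thresholds_path() -> Path:
    return Path(__file__).parent / "data" / "her_thresholds.yaml"


def default_standards_path() -> Path:
    return Path(__file__).parent / "data" / "hei2015_standards.yaml"


def config_digest(config: RunConfig) -> str:
    """SHA-256 over the run parameters and the bytes of both config files."""
    h = hashlib.sha256()
    h.update(repr(as_dict(config)).encode())
    for p in (
        config.thresholds_path or default_thresholds_path(),
        config.standards_path or default_standards_path(),
    ):
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute rank -> score -> fit -> transform -> evaluate.

    Returns the full report: tier summaries and their moments, HEI scores,
    the fitted model and index formula, per-cart index values, the
    correlation table, quintile profile, and the k-fold CV result.
    Identical seed and inputs give an identical report.
    """

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CfniError as exc:
                raise PipelineError(name, exc) from exc

        return wrap

    thresholds = stage("config")(ranker_mod.load_thresholds,
                                 config.thresholds_path or default_thresholds_path())
    standards = stage("config")(hei_mod.load_standards,
                                config.standards_path or default_standards_path())

    if config.input_path is not None:
        carts = stage("load")(read_cart_table, config.input_path)
    else:
        carts = stage("load")(
            generate_catalog_and_carts,
            CatalogParams(seed=config.seed), config.n_carts, config.seed,
        )

    summaries, tier_stats = stage("rank")(ranker_mod.summarize_collection, carts, thresholds)

    def score_all():
        kept_ids = set(summaries["cart_id"])
        rows = []
        for cart in carts:
            if cart.cart_id not in kept_ids:
                continue
            ranked = ranker_mod.filter_ranked_items(cart, thresholds)
            score = hei_mod.score_cart(ranked, standards)
            rows.append({"cart_id": score.cart_id, "total": score.total,
                         **score.component_scores})
        return pd.DataFrame(rows)

    hei_table = stage("hei")(score_all)

    fitted = stage("fit")(
        model_mod.fit_model, summaries, hei_table, config.method, seed=config.seed
    )
    formula = stage("transform")(model_mod.to_index_formula, fitted)
    index_values = stage("transform")(model_mod.cfni_scores, formula, summaries)

    correlations = stage("evaluate")(validation_mod.correlation_table, summaries, hei_table)
    labels = stage("evaluate")(validation_mod.assign_quintiles, hei_table["total"].to_numpy())
    quintiles = stage("evaluate")(validation_mod.quintile_profile, summaries, labels)
    cv = stage("evaluate")(
        validation_mod.kfold_cv_correlation,
        summaries, hei_table, config.method, config.k, config.seed,
    )

    return {
        "seed": config.seed,
        "config_digest": config_digest(config),
        "method": config.method,
        "n_carts": int(len(summaries)),
        "tier_stats": {
            "mean": tier_stats.loc["mean"].to_dict(),
            "sd": tier_stats.loc["sd"].to_dict(),
        },
        "hei_stats": {
            "mean": float(hei_table["total"].mean()),
            "sd": float(hei_table["total"].std(ddof=1)),
            "min": float(hei_table["total"].min()),
            "max": float(hei_table["total"].max()),
        },
        "fitted_model": as_dict(fitted),
        "index_formula": as_dict(formula),
        "index_stats": {
            "mean": float(index_values.mean()),
            "sd": float(index_values.std(ddof=1)),
        },
        "correlations": {r["variable"]: {"r": r["r"], "p": r["p"]}
                         for r in correlations.to_dict("records")},
        "quintile_profile": as_dict(quintiles),
        "cv": as_dict(cv),
        "tier_summaries": summaries.to_dict("records"),
        "hei_scores": hei_table[["cart_id", "total"]].to_dict("records"),
        "index_scores": [
            {"cart_id": cid, "cfni": float(v)}
            for cid, v in zip(summaries["cart_id"], index_values)
        ],
    }
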