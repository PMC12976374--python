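"""Synthetic total-diet-study generator.

Emulates the statistical structure a TDS-based dietary exposure assessment
assumes: a catalog of foods partitioned into categories with assigned cooking
methods, a laboratory table of composite-sample PAH measurements with
left-censored non-detects, and a 24-hour-recall consumption survey.  Defaults
mirror the study conditions: 21 food categories spanning 264 foods, two
composite samples per food (≈ 480 composites), 2,000 adult respondents, an
LOD of 0.15 µg/kg, and right-skewed lognormal detected concentrations whose
heavy tail drives the leptokurtic exposure distributions seen downstream.

Every generator is a deterministic function of (config, seed): the root seed
is combined with a fixed per-generator stream key, so the catalog, the
laboratory table and the survey are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tds_data import (
    ANALYTES,
    Catalog,
    ConcentrationRecord,
    ConsumptionEvent,
    FoodItem,
    PersonDay,
    ValidationError,
)

__all__ = [
    "DEFAULT_CATEGORIES",
    "COOKING_METHODS",
    "SynthConfig",
    "generate_catalog",
    "generate_concentrations",
    "generate_survey",
    "generate_bimodal_sample",
]

# Fixed 21-label category vocabulary of a national TDS food list.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "grains and grain-based products",
    "meat and meat products",
    "fish and seafood",
    "vegetables",
    "fruits",
    "milk and dairy products",
    "fats and oils",
    "eggs and egg products",
    "legumes and pulses",
    "nuts and seeds",
    "sauces and condiments",
    "non-alcoholic beverages",
    "alcoholic beverages",
    "sugar and confectionery",
    "fruiting vegetables",
    "leafy vegetables",
    "fungi and seaweed",
    "snacks",
    "composite dishes",
    "herbs and spices",
    "tubers and root vegetables",
)

COOKING_METHODS: tuple[str, ...] = (
    "boiled",
    "steamed",
    "stir-fried",
    "grilled",
    "raw",
    "rte",
)

# Stream keys: each generator draws from default_rng([seed, key]) so the
# three tables are independent yet jointly reproducible from one root seed.
_KEY_CATALOG, _KEY_CONC, _KEY_SURVEY, _KEY_BIMODAL = 11, 22, 33, 44


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic TDS.

    Counts default to the real study's design (21 categories, 264 foods,
    2 composites per food, 2,000 respondents).  Concentration and amount
    laws are lognormal — detected PAH values are sub-µg/kg in the median
    with a heavy right tail, and ~70% of sample × analyte points are
    non-detects at an LOD of 0.15 µg/kg.
    """

    n_categories: int = 21
    n_foods: int = 264
    samples_per_food: int = 2
    n_respondents: int = 2000
    detect_rate: float = 0.3
    conc_log_mean: float = 0.0   # log µg/kg; median detected value 1 µg/kg
    conc_log_sd: float = 1.2
    lod: float = 0.15            # µg/kg
    foods_per_day_mean: float = 8.0
    amount_log_mean: float = 0.5  # log g/kg bw; median event ≈ 1.6 g/kg bw
    amount_log_sd: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.detect_rate <= 1):
            raise ValidationError(f"detect_rate must be in [0, 1], got {self.detect_rate}")
        for name in ("n_categories", "n_foods", "samples_per_food", "n_respondents"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.conc_log_sd <= 0 or self.amount_log_sd <= 0:
            raise ValidationError("conc_log_sd and amount_log_sd must be > 0")
        if self.lod <= 0:
            raise ValidationError(f"lod must be > 0, got {self.lod}")
        if self.foods_per_day_mean < 0:
            raise ValidationError("foods_per_day_mean must be >= 0")


def generate_catalog(cfg: SynthConfig) -> Catalog:
    """Generate ``n_foods`` items partitioned over ``n_categories``.

    Categories cycle through the fixed vocabulary; cooking methods cycle
    through :data:`COOKING_METHODS`.  Deterministic in (cfg, seed).
    """
    if cfg.n_categories > cfg.n_foods:
        raise ValidationError(
            f"n_categories ({cfg.n_categories}) exceeds n_foods ({cfg.n_foods})"
        )
    if cfg.n_categories > len(DEFAULT_CATEGORIES):
        raise ValidationError(
            f"n_categories ({cfg.n_categories}) exceeds the fixed vocabulary "
            f"of {len(DEFAULT_CATEGORIES)} labels"
        )
    cats = DEFAULT_CATEGORIES[: cfg.n_categories]
    items = [
        FoodItem(
            food_id=f"F{i:04d}",
            name=f"food {i:04d}",
            category=cats[i % cfg.n_categories],
            cooking_method=COOKING_METHODS[i % len(COOKING_METHODS)],
        )
        for i in range(cfg.n_foods)
    ]
    return Catalog(items)


def generate_concentrations(catalog: Catalog, cfg: SynthConfig) -> list[ConcentrationRecord]:
    """Generate the laboratory table: samples_per_food composites × 4 analytes.

    Each sample × analyte point is detected with probability ``detect_rate``;
    detected values are lognormal(conc_log_mean, conc_log_sd) µg/kg.  Every
    record carries ``cfg.lod``.
    """
    rng = np.random.default_rng([cfg.seed, _KEY_CONC])
    records: list[ConcentrationRecord] = []
    for item in catalog:
        for j in range(cfg.samples_per_food):
            sample_id = f"{item.food_id}-s{j}"
            for analyte in ANALYTES:
                detected = bool(rng.random() < cfg.detect_rate)
                value = (
                    float(rng.lognormal(cfg.conc_log_mean, cfg.conc_log_sd))
                    if detected
                    else None
                )
                records.append(
                    ConcentrationRecord(
                        item.food_id, sample_id, analyte, detected, value, cfg.lod
                    )
                )
    return records


def generate_survey(catalog: Catalog, cfg: SynthConfig) -> list[PersonDay]:
    """Generate ``n_respondents`` person-days.

    Each respondent consumes max(1, Poisson(foods_per_day_mean)) distinct
    catalog foods with lognormal g/kg-bw amounts; ages are uniform on
    [18, 83] (minimum respondent age to life expectancy).
    """
    rng = np.random.default_rng([cfg.seed, _KEY_SURVEY])
    food_ids = [it.food_id for it in catalog]
    days: list[PersonDay] = []
    for i in range(cfg.n_respondents):
        age = int(rng.integers(18, 84))
        k = max(1, int(rng.poisson(cfg.foods_per_day_mean)))
        k = min(k, len(food_ids))
        chosen = rng.choice(len(food_ids), size=k, replace=False)
        amounts = rng.lognormal(cfg.amount_log_mean, cfg.amount_log_sd, size=k)
        events = tuple(
            ConsumptionEvent(food_ids[f], float(a)) for f, a in zip(chosen, amounts)
        )
        days.append(PersonDay(f"R{i:05d}", age, events))
    return days


def generate_bimodal_sample(
    n: int,
    weight_high: float,
    low_mean: float,
    high_mean: float,
    sd: float,
    seed: int,
    return_components: bool = False,
):
    """Draw a well-separated two-component normal mixture, truncated at 0.

    A test fixture for the exposed/unexposed clustering stage: the high
    component (weight ``weight_high``) plays the exposed subpopulation.
    Requires ``low_mean + 4·sd < high_mean`` so the components barely
    overlap and the component labels serve as a clustering ground truth.
    Truncation is by clipping; with a positive ``low_mean`` under the
    separation precondition it is inactive in practice.
    """
    if not (0 <= weight_high <= 1):
        raise ValidationError(f"weight_high must be in [0, 1], got {weight_high}")
    if not (low_mean + 4 * sd < high_mean):
        raise ValidationError(
            f"components overlap: need low_mean + 4*sd < high_mean, "
            f"got {low_mean} + 4*{sd} >= {high_mean}"
        )
    rng = np.random.default_rng([seed, _KEY_BIMODAL])
    is_high = rng.random(n) < weight_high
    values = rng.normal(np.where(is_high, high_mean, low_mean), sd)
    values = np.clip(values, 0.0, None)
    if return_components:
        return values, is_high
    return values
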