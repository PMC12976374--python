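"""Monte Carlo engine for acute dietary PAH4 exposure.

Each iteration resamples one person-day uniformly from the consumption
survey, draws one composite sample per food in that diet (the same sample
index serves all four analytes, preserving within-sample correlation),
substitutes non-detects according to the scenario — 0 µg/kg under the
optimistic lower bound, the record's LOD (0.15 µg/kg by default) under the
pessimistic upper bound — sums the four analytes into PAH4, multiplies by
the consumption amount and accumulates over the diet:

    exposure (mg/kg bw/d) = 1e-6 · Σ_foods amount(g/kg bw) · PAH4(µg/kg)

The µg→mg factor of 1e-6 is applied exactly once, to the per-iteration
total.  With common random numbers (the default) the person-day and sample
draws are shared across scenarios, so pessimistic ≥ optimistic holds
pathwise: substitution is the only difference between the runs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .tds_data import (
    ANALYTES,
    AnalyteCode,
    ConcentrationRecord,
    PersonDay,
    ValidationError,
)

__all__ = [
    "Scenario",
    "OPTIMISTIC",
    "PESSIMISTIC",
    "SimConfig",
    "ExposureDistribution",
    "substitute",
    "pah4",
    "pah4_by_sample",
    "draw_food_sample",
    "draw_concentration",
    "person_day_exposure",
    "simulate",
    "UG_PER_KG_TO_MG",
]

logger = logging.getLogger(__name__)

#: Conversion factor from (µg/kg food)·(g food/kg bw) to mg/kg bw/d.
UG_PER_KG_TO_MG = 1e-6

# Substream keys for person-day and composite-sample draws.
_KEY_PERSON, _KEY_SAMPLE = 101, 202
_SCENARIO_STREAM = {"optimistic": 1, "pessimistic": 2}


@dataclass(frozen=True)
class Scenario:
    """Non-detect substitution policy.

    ``nd_substitute`` is the µg/kg value assigned to non-detects: 0 for the
    optimistic lower bound; ``None`` means "use each record's own LOD",
    which is the pessimistic upper bound (0.15 µg/kg at the default LOD).
    """

    label: str
    nd_substitute: Optional[float]

    def __post_init__(self) -> None:
        if self.label not in ("optimistic", "pessimistic"):
            raise ValidationError(f"unknown scenario label {self.label!r}")
        if self.nd_substitute is not None and self.nd_substitute < 0:
            raise ValidationError(f"nd_substitute must be >= 0, got {self.nd_substitute}")
        if self.label == "optimistic" and self.nd_substitute != 0.0:
            raise ValidationError("optimistic scenario requires nd_substitute = 0 exactly")


OPTIMISTIC = Scenario("optimistic", 0.0)
PESSIMISTIC = Scenario("pessimistic", None)


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo settings: iteration count, root seed, scenario coupling."""

    iterations: int = 100_000
    seed: int = 0
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError(f"iterations must be >= 1, got {self.iterations}")


@dataclass
class ExposureDistribution:
    """Per-iteration total PAH4 exposures (mg/kg bw/d) for one scenario."""

    scenario: Scenario
    values: np.ndarray
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.iterations:
            raise ValidationError(
                f"{len(self.values)} values for {self.iterations} iterations"
            )
        if np.any(self.values < 0):
            raise ValidationError("exposure values must be >= 0")


def substitute(record: ConcentrationRecord, scenario: Scenario) -> float:
    """Resolve one measurement to a concentration (µg/kg) under a scenario."""
    if record.detected:
        return float(record.value)  # detection overrides substitution
    if scenario.nd_substitute is not None:
        return float(scenario.nd_substitute)
    return float(record.lod)


def pah4(values_by_analyte: Mapping[AnalyteCode, float]) -> float:
    """Sum the four marker-PAH concentrations into PAH4 (µg/kg)."""
    if set(values_by_analyte) != set(ANALYTES):
        missing = [a.value for a in ANALYTES if a not in values_by_analyte]
        extra = [getattr(a, "value", a) for a in values_by_analyte if a not in ANALYTES]
        raise ValidationError(f"pah4 needs exactly one value per analyte; missing={missing} extra={extra}")
    return float(sum(values_by_analyte[a] for a in ANALYTES))


def pah4_by_sample(
    records: Iterable[ConcentrationRecord], scenario: Scenario
) -> dict[str, np.ndarray]:
    """Per-food arrays of composite-sample PAH4 (µg/kg) under a scenario.

    Groups records by (food, sample), substitutes, and sums analytes.  Every
    sample must carry all four analytes.  Sample order within a food follows
    sorted sample_id, so the mapping is deterministic.
    """
    grouped: dict[tuple[str, str], dict[AnalyteCode, float]] = defaultdict(dict)
    for r in records:
        grouped[(r.food_id, r.sample_id)][r.analyte] = substitute(r, scenario)
    per_food: dict[str, list[float]] = defaultdict(list)
    for (fid, sid) in sorted(grouped):
        per_food[fid].append(pah4(grouped[(fid, sid)]))
    return {fid: np.array(vals) for fid, vals in per_food.items()}


def draw_food_sample(
    food_id: str,
    records: Sequence[ConcentrationRecord],
    rng: np.random.Generator,
    scenario: Scenario,
) -> dict[AnalyteCode, float]:
    """Draw one composite sample for a food; return its substituted analytes.

    The sample index is drawn once and shared across the four analytes,
    mirroring that all four were measured on the same composite.
    """
    by_sample: dict[str, dict[AnalyteCode, float]] = defaultdict(dict)
    for r in records:
        if r.food_id == food_id:
            by_sample[r.sample_id][r.analyte] = substitute(r, scenario)
    if not by_sample:
        raise ValidationError(f"no composite samples for food {food_id!r}")
    sample_ids = sorted(by_sample)
    sid = sample_ids[int(rng.integers(len(sample_ids)))]
    return by_sample[sid]


def draw_concentration(
    food_id: str,
    records: Sequence[ConcentrationRecord],
    analyte: AnalyteCode,
    rng: np.random.Generator,
    scenario: Scenario,
) -> float:
    """Draw one substituted concentration (µg/kg) for a food × analyte."""
    return draw_food_sample(food_id, records, rng, scenario)[analyte]


def person_day_exposure(
    day: PersonDay, drawn_conc: Mapping[str, float]
) -> float:
    """Total exposure (mg/kg bw/d) of one person-day given drawn PAH4 values.

    ``drawn_conc`` maps food_id to a drawn PAH4 concentration in µg/kg;
    foods missing from the mapping contribute zero.  The µg→mg conversion
    is applied once, to the total.
    """
    total = sum(e.amount * drawn_conc.get(e.food_id, 0.0) for e in day.events)
    return total * UG_PER_KG_TO_MG


def _flatten_survey(
    survey: Sequence[PersonDay], food_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten person-day events into arrays indexed by a per-person offset."""
    ev_food: list[int] = []
    ev_amount: list[float] = []
    offsets = np.empty(len(survey), dtype=np.int64)
    lengths = np.empty(len(survey), dtype=np.int64)
    for p, day in enumerate(survey):
        offsets[p] = len(ev_food)
        for e in day.events:
            ev_food.append(food_index[e.food_id])
            ev_amount.append(e.amount)
        lengths[p] = len(day.events) if day.events else 0
    return (
        np.asarray(ev_food, dtype=np.int64),
        np.asarray(ev_amount, dtype=float),
        offsets,
        lengths,
    )


def simulate(
    survey: Sequence[PersonDay],
    records: Sequence[ConcentrationRecord],
    scenario: Scenario,
    cfg: SimConfig,
) -> ExposureDistribution:
    """Run the Monte Carlo simulation for one scenario.

    Iteration t draws a person-day uniformly with replacement, then for each
    food in that diet one composite sample uniformly; the substituted PAH4
    of the drawn samples is combined into the person-day exposure.  The run
    is a deterministic function of (inputs, cfg.seed); with
    ``common_random_numbers`` the person and sample draws are identical
    across scenarios at the same seed.

    Surveyed foods with no concentration record contribute zero exposure
    (one warning per food) — the only choice that cannot inflate the
    optimistic lower bound.
    """
    if len(survey) == 0:
        raise ValidationError("empty survey")
    if len(records) == 0:
        raise ValidationError("no concentration records")

    per_food = pah4_by_sample(records, scenario)
    surveyed = {e.food_id for day in survey for e in day.events}
    for fid in sorted(surveyed - set(per_food)):
        logger.warning(
            "food %r appears in the survey but has no concentration record; "
            "it contributes zero exposure",
            fid,
        )
        per_food[fid] = np.zeros(1)

    food_ids = sorted(per_food)
    food_index = {fid: i for i, fid in enumerate(food_ids)}
    n_samples = np.array([len(per_food[fid]) for fid in food_ids], dtype=np.int64)
    sample_offsets = np.concatenate([[0], np.cumsum(n_samples[:-1])])
    pah4_flat = np.concatenate([per_food[fid] for fid in food_ids])

    ev_food, ev_amount, offsets, lengths = _flatten_survey(survey, food_index)

    stream = 0 if cfg.common_random_numbers else _SCENARIO_STREAM[scenario.label]
    seed = int(cfg.seed) & 0x7FFFFFFF
    rng_person = np.random.default_rng([seed, _KEY_PERSON, stream])
    rng_sample = np.random.default_rng([seed, _KEY_SAMPLE, stream])

    persons = rng_person.integers(0, len(survey), size=cfg.iterations)
    lens = lengths[persons]
    starts = offsets[persons]
    total = int(lens.sum())

    if total == 0:
        values = np.zeros(cfg.iterations)
        return ExposureDistribution(scenario, values, cfg.seed, cfg.iterations)

    # Global event indices for every (iteration, event) pair.
    cum = np.cumsum(lens)
    within = np.arange(total) - np.repeat(cum - lens, lens)
    ev_idx = np.repeat(starts, lens) + within
    iter_of_event = np.repeat(np.arange(cfg.iterations), lens)

    f = ev_food[ev_idx]
    # One uniform per (iteration, event); scenario-independent, so shared
    # draws under common random numbers couple the two scenarios pathwise.
    u = rng_sample.random(total)
    s = np.minimum((u * n_samples[f]).astype(np.int64), n_samples[f] - 1)
    conc = pah4_flat[sample_offsets[f] + s]

    contrib = ev_amount[ev_idx] * conc
    totals = np.bincount(iter_of_event, weights=contrib, minlength=cfg.iterations)
    values = totals * UG_PER_KG_TO_MG
    return ExposureDistribution(scenario, values, cfg.seed, cfg.iterations)
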