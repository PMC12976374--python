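"""Lifetime cancer risk, relative risk, attributable fraction and DALYs.

The chain converts a median dietary PAH4 exposure (mg/kg bw/d) into a
population disease burden:

    risk      R   = exposure · SF_avg · exposure_time / life_expectancy
    excess    RR  = 1 + R / (T − R)          (T = total lifetime cancer risk)
    Levin     PAF = p·(RR − 1) / (p·(RR − 1) + 1)   (p = exposure prevalence)
    burden        = PAF · total cancer DALYs

where SF_avg is an average carcinogenic slope factor over the four marker
PAHs.  The literal ratio R / (T − R) is also exposed: as a relative risk it
falls below 1 for realistic dietary exposures and would make Levin's
formula negative, so the chain consumes the excess-risk form above, which
treats R as the *additional* risk conferred on the exposed group.

Exposure is also classified against a PAH4 minimal risk level (MRL), the
daily intake below which adverse effects are considered unlikely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .tds_data import ANALYTES, AnalyteCode, ValidationError

__all__ = [
    "DEFAULT_SLOPE_FACTORS",
    "RiskParams",
    "BurdenResult",
    "sf_avg",
    "cancer_risk",
    "relative_risk",
    "literal_relative_risk",
    "paf",
    "attributable_daly",
    "mrl_classify",
    "burden_chain",
]

#: Oral carcinogenic slope factors, (mg/kg bw/d)^-1.
DEFAULT_SLOPE_FACTORS: dict[AnalyteCode, float] = {
    AnalyteCode.BaA: 1.00e-1,
    AnalyteCode.BaP: 1.00e1,
    AnalyteCode.BbF: 1.00e-1,
    AnalyteCode.Ch: 1.00e-3,
}


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the risk/burden chain.

    ``total_cancer_dalys`` (years lived with disability plus years of life
    lost, all cancers, for the reference population-year) has no default:
    it is a population statistic the caller must supply.  ``exposure_time``
    defaults to life_expectancy − min_age — adult years at risk.
    ``sf_avg_method`` selects how the four slope factors collapse to one:
    their arithmetic mean, or an explicit ``sf_avg_fixed`` override.
    """

    total_cancer_dalys: float
    slope_factors: Mapping[AnalyteCode, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPE_FACTORS)
    )
    sf_avg_method: str = "arithmetic_mean"
    sf_avg_fixed: Optional[float] = None
    life_expectancy: float = 83.0
    min_age: float = 18.0
    exposure_time: Optional[float] = None  # None -> life_expectancy - min_age
    total_cancer_risk: float = 0.25
    mrl_pah4: float = 4.84e-4  # mg/kg bw/d

    def __post_init__(self) -> None:
        if set(self.slope_factors) != set(ANALYTES):
            raise ValidationError("slope_factors must cover exactly the four analytes")
        if any(v <= 0 for v in self.slope_factors.values()):
            raise ValidationError("all slope factors must be > 0")
        if not (0 < self.total_cancer_risk < 1):
            raise ValidationError(
                f"total_cancer_risk must be in (0, 1), got {self.total_cancer_risk}"
            )
        if self.mrl_pah4 <= 0:
            raise ValidationError(f"mrl_pah4 must be > 0, got {self.mrl_pah4}")
        if self.total_cancer_dalys < 0:
            raise ValidationError("total_cancer_dalys must be >= 0")
        if self.sf_avg_method not in ("arithmetic_mean", "fixed"):
            raise ValidationError(f"unknown sf_avg_method {self.sf_avg_method!r}")
        if self.effective_exposure_time <= 0:
            raise ValidationError("exposure_time must be > 0")

    @property
    def effective_exposure_time(self) -> float:
        if self.exposure_time is not None:
            return self.exposure_time
        return self.life_expectancy - self.min_age

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RiskParams":
        """Build from a plain mapping (e.g. a parsed params.yaml)."""
        cfg = dict(cfg)
        if "slope_factors" in cfg:
            cfg["slope_factors"] = {
                AnalyteCode(k): float(v) for k, v in cfg["slope_factors"].items()
            }
        return cls(**cfg)


@dataclass(frozen=True)
class BurdenResult:
    """One scenario's burden-chain outputs."""

    exposure_median: float   # mg/kg bw/d
    cancer_risk: float       # lifetime probability in the exposed group
    relative_risk: float     # excess-risk RR (>= 1)
    prevalence: float        # exposed fraction of the population
    paf: float               # population attributable fraction
    attributable_daly: float  # years
    mrl_status: str          # "below" | "above"

    def to_dict(self) -> dict:
        return {
            "exposure_median": self.exposure_median,
            "cancer_risk": self.cancer_risk,
            "relative_risk": self.relative_risk,
            "prevalence": self.prevalence,
            "paf": self.paf,
            "attributable_daly": self.attributable_daly,
            "mrl_status": self.mrl_status,
        }


def sf_avg(params: RiskParams) -> float:
    """Average slope factor, (mg/kg bw/d)^-1, under the configured rule."""
    if params.sf_avg_method == "fixed":
        if params.sf_avg_fixed is None:
            raise ValidationError("sf_avg_method='fixed' requires sf_avg_fixed")
        return float(params.sf_avg_fixed)
    return float(sum(params.slope_factors[a] for a in ANALYTES) / len(ANALYTES))


def cancer_risk(exposure: float, params: RiskParams) -> float:
    """Lifetime cancer probability from a chronic exposure (mg/kg bw/d)."""
    if exposure < 0:
        raise ValidationError(f"exposure must be >= 0, got {exposure}")
    r = exposure * sf_avg(params) * params.effective_exposure_time / params.life_expectancy
    if r >= 1:
        raise ValidationError(
            f"cancer risk {r:.3g} >= 1: implausible exposure or slope factor"
        )
    return float(r)


def literal_relative_risk(risk_exposed: float, total_risk: float) -> float:
    """The plain ratio R / (T − R).  Falls below 1 whenever R < T/2, which
    makes it unusable in Levin's formula for small dietary risks; exposed
    for inspection only."""
    if not (0 <= risk_exposed < total_risk):
        raise ValidationError(
            f"need 0 <= risk_exposed < total_risk, got {risk_exposed} vs {total_risk}"
        )
    return float(risk_exposed / (total_risk - risk_exposed))


def relative_risk(risk_exposed: float, total_risk: float) -> float:
    """Excess-risk relative risk: 1 + R / (T − R).

    Reads R as the additional lifetime risk the exposure confers over the
    background T, so RR → 1 as R → 0 and Levin's formula stays
    non-negative.
    """
    return 1.0 + literal_relative_risk(risk_exposed, total_risk)


def paf(prevalence: float, rr: float) -> float:
    """Levin's population attributable fraction."""
    if not (0 <= prevalence <= 1):
        raise ValidationError(f"prevalence must be in [0, 1], got {prevalence}")
    if rr < 1:
        raise ValidationError(f"rr must be >= 1 (protective exposures out of scope), got {rr}")
    excess = prevalence * (rr - 1.0)
    return float(excess / (excess + 1.0))


def attributable_daly(paf_value: float, total_dalys: float) -> float:
    """Attributable burden in years: PAF × total cancer DALYs."""
    if not (0 <= paf_value <= 1):
        raise ValidationError(f"paf must be in [0, 1], got {paf_value}")
    if total_dalys < 0:
        raise ValidationError(f"total_dalys must be >= 0, got {total_dalys}")
    return float(paf_value * total_dalys)


def mrl_classify(exposure: float, params: RiskParams) -> str:
    """Classify an exposure against the PAH4 minimal risk level.

    "above" iff exposure strictly exceeds the MRL; an exposure exactly at
    the MRL is "below" (the MRL itself is deemed without appreciable risk).
    """
    if exposure < 0:
        raise ValidationError(f"exposure must be >= 0, got {exposure}")
    return "above" if exposure > params.mrl_pah4 else "below"


def burden_chain(
    exposure_median: float, prevalence: float, params: RiskParams
) -> BurdenResult:
    """Run the full chain for one scenario's median exposure and prevalence."""
    r = cancer_risk(exposure_median, params)
    rr = relative_risk(r, params.total_cancer_risk)
    p = paf(prevalence, rr)
    return BurdenResult(
        exposure_median=float(exposure_median),
        cancer_risk=r,
        relative_risk=rr,
        prevalence=float(prevalence),
        paf=p,
        attributable_daly=attributable_daly(p, params.total_cancer_dalys),
        mrl_status=mrl_classify(exposure_median, params),
    )
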