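"""Stage 2: score individuals against a frozen population categoriser.

Each eligible individual's genotype and exposure data are combined under the
same multiplicative model and calibration shift as the simulated population,
yielding a summary OR (95% CI), a risk category, and — when sex is known — a
lifetime risk obtained by scaling published baseline lifetime risks of
seropositive RA (2.4% for women, 1.1% for men) by the summary OR.

Mixed-resolution HLA typing is handled by scoring each carried allele once,
at the highest resolution at which it is known (see
:func:`rapredict.risk_model.resolve_hla`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .population import Categoriser
from .risk_model import (
    ModelConfig,
    ModelError,
    RiskFactorModel,
    RiskProfile,
    normalise_allele,
    odds_ratio_ci,
    profile_log_odds,
    resolve_hla,  # re-exported: public resolution entry point
)

__all__ = [
    "IndividualRecord",
    "IndividualRisk",
    "IneligibleError",
    "resolve_hla",
    "eligible",
    "score_individual",
    "score_cohort",
    "lifetime_risk",
    "LIFETIME_RISK_BASE_PCT",
]

# Published baseline lifetime risks of RA (percent), women / men.
LIFETIME_RISK_BASE_PCT = {"female": 2.4, "male": 1.1}

SEXES = ("male", "female", "unknown")


class IneligibleError(ModelError):
    """Raised when scoring an individual excluded by the eligibility rules."""

    def __init__(self, reason: str):
        super().__init__(f"individual ineligible: {reason}")
        self.reason = reason


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


@dataclass
class IndividualRecord:
    """One person's risk-factor data (one cohort row)."""

    id: str
    sex: str = "unknown"
    status: Optional[str] = None  # "case" / "control"
    serostatus: Optional[str] = None  # cases: "acpa_pos" / "seropos"
    hla_allele_1: Optional[str] = None
    hla_allele_2: Optional[str] = None
    snp_dosages: dict = field(default_factory=dict)
    ever_smoker: Optional[int] = None
    onset_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ModelError(f"{self.id}: unknown sex {self.sex!r}")
        if self.onset_age is not None and not _is_missing(self.onset_age):
            if self.status == "control":
                raise ModelError(f"{self.id}: onset_age is defined for cases only")

    @classmethod
    def from_row(cls, row: pd.Series, snp_ids) -> "IndividualRecord":
        dosages = {}
        for sid in snp_ids:
            v = row.get(sid)
            dosages[sid] = None if _is_missing(v) else int(v)
        smoker = row.get("ever_smoker")
        onset = row.get("onset_age")
        return cls(
            id=str(row.get("id", row.name)),
            sex=row.get("sex", "unknown") if not _is_missing(row.get("sex")) else "unknown",
            status=None if _is_missing(row.get("status")) else row.get("status"),
            serostatus=None if _is_missing(row.get("serostatus")) else row.get("serostatus"),
            hla_allele_1=None if _is_missing(row.get("hla_1")) else row.get("hla_1"),
            hla_allele_2=None if _is_missing(row.get("hla_2")) else row.get("hla_2"),
            snp_dosages=dosages,
            ever_smoker=None if _is_missing(smoker) else int(smoker),
            onset_age=None if _is_missing(onset) else float(onset),
        )


@dataclass(frozen=True)
class IndividualRisk:
    """An individual's calibrated summary OR, category and lifetime risk."""

    id: str
    model_name: str
    log_or: float
    var_log_or: float
    or_point: float
    ci_low: float
    ci_high: float
    category: str
    lifetime_risk_pct: Optional[float]  # undefined when sex is unknown


def eligible(
    record: IndividualRecord, config: ModelConfig, model: RiskFactorModel
) -> tuple[bool, str]:
    """Apply the per-model eligibility rules; returns (ok, reason).

    Models incorporating ever-smoking are evaluated in males only, and only
    when smoking status is known.  Models incorporating SNPs require every
    modelled SNP dosage; models incorporating HLA require at least one typed
    allele.  The reason names the first failing rule.
    """
    snps, hlas, envs = model.split(config)
    if envs:
        if record.sex != "male":
            return False, "sex_restriction"
        if _is_missing(record.ever_smoker):
            return False, "missing_smoking"
    if snps:
        for f in snps:
            if _is_missing(record.snp_dosages.get(f.id)):
                return False, "missing_snp"
    if hlas:
        if _is_missing(record.hla_allele_1) and _is_missing(record.hla_allele_2):
            return False, "missing_hla"
    return True, "ok"


def score_individual(
    record: IndividualRecord,
    config: ModelConfig,
    model: RiskFactorModel,
    categoriser: Categoriser,
) -> IndividualRisk:
    """Score one eligible individual against the frozen categoriser."""
    ok, reason = eligible(record, config, model)
    if not ok:
        raise IneligibleError(reason)
    snps, hlas, envs = model.split(config)
    dosages = {
        f.id: int(record.snp_dosages.get(f.id, 0) or 0)
        for f in snps
    }
    exposures = {e.id: int(record.ever_smoker or 0) for e in envs}
    alleles = (
        normalise_allele(record.hla_allele_1),
        normalise_allele(record.hla_allele_2),
    )
    profile = RiskProfile(
        snp_dosages=dosages, hla_alleles=alleles, exposures=exposures
    )
    raw_log_or, var = profile_log_odds(profile, config, model)
    log_or = raw_log_or - categoriser.calibration_shift
    or_point, lo, hi = odds_ratio_ci(log_or, var, categoriser.ci_level)
    category = categoriser.classify(lo, hi)
    ltr = (
        lifetime_risk(or_point, record.sex)
        if record.sex in LIFETIME_RISK_BASE_PCT
        else None
    )
    return IndividualRisk(
        id=record.id,
        model_name=config.name,
        log_or=log_or,
        var_log_or=var,
        or_point=or_point,
        ci_low=lo,
        ci_high=hi,
        category=category,
        lifetime_risk_pct=ltr,
    )


def lifetime_risk(or_point: float, sex: str) -> float:
    """Lifetime risk of seropositive RA in percent.

    Published baseline lifetime risks (2.4% women, 1.1% men) multiplied by
    the summary OR (ORs approximate relative risks at low disease
    prevalence), capped at 100%.  Undefined (raises) for unknown sex.
    """
    if or_point <= 0.0:
        raise ModelError(f"OR must be positive, got {or_point}")
    base = LIFETIME_RISK_BASE_PCT.get(sex)
    if base is None:
        raise ModelError(f"lifetime risk undefined for sex {sex!r}")
    return min(or_point * base, 100.0)


def score_cohort(
    cohort: pd.DataFrame,
    config: ModelConfig,
    model: RiskFactorModel,
    categoriser: Categoriser,
) -> pd.DataFrame:
    """Score every cohort row; ineligible rows carry NaN risk and a reason.

    Returns one row per individual with columns id, model, eligible, reason,
    log_or, or_point, ci_low, ci_high, category, lifetime_risk_pct, plus
    carried-through sex/status/serostatus/ever_smoker/onset_age columns.
    """
    snps, _, _ = model.split(config)
    snp_ids = [f.id for f in snps]
    rows = []
    for _, r in cohort.iterrows():
        rec = IndividualRecord.from_row(r, snp_ids)
        ok, reason = eligible(rec, config, model)
        base = {
            "id": rec.id,
            "model": config.name,
            "eligible": ok,
            "reason": reason,
            "sex": rec.sex,
            "status": rec.status,
            "serostatus": rec.serostatus,
            "ever_smoker": rec.ever_smoker,
            "onset_age": rec.onset_age,
        }
        if ok:
            risk = score_individual(rec, config, model, categoriser)
            base.update(
                log_or=risk.log_or,
                var_log_or=risk.var_log_or,
                or_point=risk.or_point,
                ci_low=risk.ci_low,
                ci_high=risk.ci_high,
                category=risk.category,
                lifetime_risk_pct=risk.lifetime_risk_pct,
            )
        else:
            base.update(
                log_or=np.nan,
                var_log_or=np.nan,
                or_point=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                category="unclassified",
                lifetime_risk_pct=np.nan,
            )
        rows.append(base)
    return pd.DataFrame(rows)
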