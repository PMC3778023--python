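"""Multiplicative odds-ratio risk model for rheumatoid arthritis.

Risk factors are published per-allele odds ratios (HLA-DRB1 alleles at two- or
four-digit resolution, non-HLA SNPs) and exposure odds ratios (male
ever-smoking).  A risk profile — one combination of risk-allele dosages and
exposure indicators — is scored by summing log odds ratios under the
assumption of risk-factor independence:

    log OR(profile) = sum_i k_i * ln(OR_i) + sum_e x_e * ln(OR_e)

with ``k_i`` the risk-allele dosage (0/1/2) and ``x_e`` the exposure indicator.
The variance of the profile log OR is the corresponding weighted sum of
squared per-factor standard errors (``k_i^2 * sigma_i^2``), each standard
error recovered from the published 95% confidence interval, or — when only
discovery-study sample sizes are available — from Woolf expected allele
counts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

__all__ = [
    "ModelError",
    "UnknownFactorError",
    "se_from_ci",
    "se_from_counts",
    "odds_ratio_ci",
    "normalise_allele",
    "resolve_hla",
    "GeneticRiskFactor",
    "EnvironmentalRiskFactor",
    "ModelConfig",
    "RiskFactorModel",
    "RiskProfile",
    "ProfileRisk",
    "profile_log_odds",
    "CATEGORIES",
]

CATEGORIES = ("reduced", "average", "elevated", "high")

LOCUS_KINDS = ("snp", "hla_allele")
HLA_RESOLUTIONS = ("two_digit", "four_digit", "not_applicable")
APPLIES_TO = ("all", "males", "females")
SEX_RESTRICTIONS = ("none", "males_only")


class ModelError(ValueError):
    """Invalid risk-factor definition, configuration or input."""


class UnknownFactorError(ModelError):
    """A profile or config references a factor id absent from the model."""


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ModelError(f"confidence level must be in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error of a log OR recovered from a published CI.

    SE = (ln(ci_high) - ln(ci_low)) / (2 z), with z the standard-normal
    quantile at (1 + level) / 2.
    """
    if ci_low <= 0.0 or ci_high <= 0.0:
        raise ModelError(f"CI bounds must be positive, got ({ci_low}, {ci_high})")
    if ci_low > ci_high:
        raise ModelError(f"ci_low must not exceed ci_high, got ({ci_low}, {ci_high})")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * _z(level))


def se_from_counts(freq_ca: float, freq_co: float, n_ca: int, n_co: int) -> float:
    """Woolf SE of a log allelic OR from expected allele counts.

    Expected counts: a = 2*n_ca*freq_ca, b = 2*n_ca*(1-freq_ca),
    c = 2*n_co*freq_co, d = 2*n_co*(1-freq_co); SE = sqrt(1/a+1/b+1/c+1/d).
    """
    for name, f in (("freq_ca", freq_ca), ("freq_co", freq_co)):
        if not 0.0 < f < 1.0:
            raise ModelError(
                f"{name}={f}: precision is incomputable for a frequency of exactly "
                "0 or 1; fall back to a CI-derived standard error"
            )
    if n_ca < 1 or n_co < 1:
        raise ModelError("sample sizes must be >= 1")
    a = 2.0 * n_ca * freq_ca
    b = 2.0 * n_ca * (1.0 - freq_ca)
    c = 2.0 * n_co * freq_co
    d = 2.0 * n_co * (1.0 - freq_co)
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def odds_ratio_ci(
    log_or: float, var_log_or: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Wald interval on the log-odds scale: (OR, ci_low, ci_high).

    Zero variance yields a degenerate interval equal to the point estimate.
    """
    if var_log_or < 0.0:
        raise ModelError(f"variance must be non-negative, got {var_log_or}")
    half = _z(level) * math.sqrt(var_log_or)
    return math.exp(log_or), math.exp(log_or - half), math.exp(log_or + half)


# --- HLA allele codes ------------------------------------------------------

_ALLELE_RE = re.compile(r"^(?:HLA-)?(?:DRB1)?\*?(\d{2})(?::?(\d{2}))?$")


def normalise_allele(code) -> Optional[str]:
    """Canonicalise an HLA-DRB1 allele code.

    Accepts "0401", "*04:01", "DRB1*04:01", "04" and returns "*04:01" or
    "*04"; missing input (None, NaN, empty string) returns None.
    """
    if code is None:
        return None
    if isinstance(code, float):
        if math.isnan(code):
            return None
        raise ModelError(f"malformed HLA allele code: {code!r}")
    s = str(code).strip().upper()
    if not s or s in ("NA", "NAN", ""):
        return None
    m = _ALLELE_RE.match(s)
    if m is None:
        raise ModelError(f"malformed HLA allele code: {code!r}")
    group, subtype = m.group(1), m.group(2)
    return f"*{group}:{subtype}" if subtype else f"*{group}"


def resolve_hla(
    allele_1,
    allele_2,
    model: "RiskFactorModel",
    factor_ids: Optional[Iterable[str]] = None,
) -> dict[str, int]:
    """Map a person's HLA-DRB1 allele pair onto modelled factor counts.

    Each carried allele contributes at the highest resolution at which it is
    known: a four-digit code matching a four-digit factor contributes that
    factor; otherwise its two-digit group (or a two-digit code) contributes
    the two-digit factor if modelled; otherwise nothing.  An allele matched at
    four digits never also contributes its two-digit parent.  Homozygous
    carriage yields count 2.
    """
    if factor_ids is None:
        ids = {f.id for f in model.genetic.values() if f.locus_kind == "hla_allele"}
    else:
        ids = set(factor_ids)
    counts: dict[str, int] = {}
    for code in (allele_1, allele_2):
        norm = normalise_allele(code)
        if norm is None:
            continue
        hit: Optional[str] = None
        if norm in ids:
            hit = norm
        elif ":" in norm:
            parent = norm.split(":", 1)[0]
            if parent in ids:
                hit = parent
        if hit is not None:
            counts[hit] = counts.get(hit, 0) + 1
    return counts


# --- Domain types ----------------------------------------------------------


@dataclass(frozen=True, kw_only=True)
class GeneticRiskFactor:
    """One modelled risk allele (a SNP risk allele or an HLA-DRB1 allele)."""

    id: str
    locus_kind: str
    or_allelic: float
    control_freq: float
    hla_resolution: str = "not_applicable"
    parent_two_digit: Optional[str] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if self.locus_kind not in LOCUS_KINDS:
            raise ModelError(f"{self.id}: unknown locus_kind {self.locus_kind!r}")
        if self.hla_resolution not in HLA_RESOLUTIONS:
            raise ModelError(f"{self.id}: unknown hla_resolution {self.hla_resolution!r}")
        if self.or_allelic <= 0.0:
            raise ModelError(f"{self.id}: OR must be positive")
        if not 0.0 <= self.control_freq <= 1.0:
            raise ModelError(f"{self.id}: control_freq must lie in [0, 1]")
        if self.locus_kind == "snp" and self.hla_resolution != "not_applicable":
            raise ModelError(f"{self.id}: SNPs carry no HLA resolution")
        if self.locus_kind == "hla_allele" and self.hla_resolution == "not_applicable":
            raise ModelError(f"{self.id}: HLA alleles need a typing resolution")
        if self.hla_resolution == "four_digit" and not self.parent_two_digit:
            raise ModelError(f"{self.id}: four-digit alleles must name a parent_two_digit")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ModelError(f"{self.id}: supply both CI bounds or neither")
        if self.ci_low is not None:
            if not self.ci_low <= self.or_allelic <= self.ci_high:
                raise ModelError(
                    f"{self.id}: CI ({self.ci_low}, {self.ci_high}) must bracket "
                    f"OR {self.or_allelic}"
                )

    @property
    def log_or(self) -> float:
        return math.log(self.or_allelic)

    @property
    def se_log_or(self) -> float:
        """Precision: CI-derived when a CI is published, else Woolf counts."""
        if self.ci_low is not None:
            return se_from_ci(self.ci_low, self.ci_high)
        if self.n_cases is not None and self.n_controls is not None:
            odds_co = self.control_freq / (1.0 - self.control_freq)
            odds_ca = self.or_allelic * odds_co
            freq_ca = odds_ca / (1.0 + odds_ca)
            return se_from_counts(freq_ca, self.control_freq, self.n_cases, self.n_controls)
        raise ModelError(f"{self.id}: no CI and no sample sizes; precision unknown")

    @property
    def var_log_or(self) -> float:
        return self.se_log_or ** 2


@dataclass(frozen=True, kw_only=True)
class EnvironmentalRiskFactor:
    """One modelled exposure (ever-smoking), with its published precision."""

    id: str
    or_exposed: float
    exposure_prev: float
    applies_to: str = "all"
    se_log_or: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.or_exposed <= 0.0:
            raise ModelError(f"{self.id}: OR must be positive")
        if not 0.0 <= self.exposure_prev <= 1.0:
            raise ModelError(f"{self.id}: exposure_prev must lie in [0, 1]")
        if self.applies_to not in APPLIES_TO:
            raise ModelError(f"{self.id}: unknown applies_to {self.applies_to!r}")
        has_se = self.se_log_or is not None
        has_ci = self.ci_low is not None or self.ci_high is not None
        if has_se == has_ci:
            raise ModelError(f"{self.id}: supply exactly one of se_log_or / CI pair")
        if has_ci and (self.ci_low is None or self.ci_high is None):
            raise ModelError(f"{self.id}: supply both CI bounds")
        if has_se and self.se_log_or < 0.0:
            raise ModelError(f"{self.id}: se_log_or must be non-negative")

    @property
    def log_or(self) -> float:
        return math.log(self.or_exposed)

    @property
    def se(self) -> float:
        if self.se_log_or is not None:
            return self.se_log_or
        return se_from_ci(self.ci_low, self.ci_high)

    @property
    def var_log_or(self) -> float:
        return self.se ** 2


@dataclass(frozen=True, kw_only=True)
class ModelConfig:
    """A named prediction model: a factor set plus calibration parameters."""

    name: str
    factor_ids: tuple[str, ...]
    prevalence: float
    sex_restriction: str = "none"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ModelError(f"{self.name}: prevalence must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ModelError(f"{self.name}: ci_level must lie in (0, 1)")
        if self.sex_restriction not in SEX_RESTRICTIONS:
            raise ModelError(f"{self.name}: unknown sex_restriction {self.sex_restriction!r}")
        if len(set(self.factor_ids)) != len(self.factor_ids):
            raise ModelError(f"{self.name}: duplicate factor ids")


class RiskFactorModel:
    """Registry of genetic and environmental risk factors."""

    def __init__(
        self,
        genetic: Sequence[GeneticRiskFactor] = (),
        environmental: Sequence[EnvironmentalRiskFactor] = (),
    ) -> None:
        self.genetic: dict[str, GeneticRiskFactor] = {}
        self.environmental: dict[str, EnvironmentalRiskFactor] = {}
        for f in genetic:
            if f.id in self.genetic:
                raise ModelError(f"duplicate genetic factor id {f.id!r}")
            self.genetic[f.id] = f
        for e in environmental:
            if e.id in self.environmental or e.id in self.genetic:
                raise ModelError(f"duplicate factor id {e.id!r}")
            self.environmental[e.id] = e

    def __contains__(self, factor_id: str) -> bool:
        return factor_id in self.genetic or factor_id in self.environmental

    def split(
        self, config: ModelConfig
    ) -> tuple[
        list[GeneticRiskFactor], list[GeneticRiskFactor], list[EnvironmentalRiskFactor]
    ]:
        """Partition a config's factors into (snps, hla_alleles, environmental)."""
        snps: list[GeneticRiskFactor] = []
        hlas: list[GeneticRiskFactor] = []
        envs: list[EnvironmentalRiskFactor] = []
        for fid in config.factor_ids:
            if fid in self.genetic:
                f = self.genetic[fid]
                (snps if f.locus_kind == "snp" else hlas).append(f)
            elif fid in self.environmental:
                envs.append(self.environmental[fid])
            else:
                raise UnknownFactorError(f"factor {fid!r} not in model")
        return snps, hlas, envs

    def validate_config(self, config: ModelConfig) -> None:
        """Sex-restricted exposures require a sex-restricted model."""
        _, _, envs = self.split(config)
        for e in envs:
            if e.applies_to == "males" and config.sex_restriction != "males_only":
                raise ModelError(
                    f"{config.name}: factor {e.id!r} applies to males only; "
                    "the config must set sex_restriction = males_only"
                )


@dataclass(frozen=True)
class RiskProfile:
    """One combination of risk-allele dosages and exposure indicators."""

    snp_dosages: Mapping[str, int] = field(default_factory=dict)
    hla_alleles: tuple = (None, None)
    exposures: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.hla_alleles) != 2:
            raise ModelError("a profile carries exactly two HLA allele slots")
        for sid, k in self.snp_dosages.items():
            if k not in (0, 1, 2):
                raise ModelError(f"{sid}: dosage must be 0, 1 or 2, got {k!r}")
        for eid, x in self.exposures.items():
            if x not in (0, 1):
                raise ModelError(f"{eid}: exposure must be 0 or 1, got {x!r}")


@dataclass(frozen=True)
class ProfileRisk:
    """A profile's calibrated summary OR with CI and assigned category."""

    log_or: float
    var_log_or: float
    or_point: float
    ci_low: float
    ci_high: float
    category: str = "unclassified"

    @classmethod
    def from_log_odds(
        cls,
        log_or: float,
        var_log_or: float,
        level: float = 0.95,
        category: str = "unclassified",
    ) -> "ProfileRisk":
        orp, lo, hi = odds_ratio_ci(log_or, var_log_or, level)
        return cls(log_or, var_log_or, orp, lo, hi, category)


def profile_log_odds(
    profile: RiskProfile, config: ModelConfig, model: RiskFactorModel
) -> tuple[float, float]:
    """Combined log OR and its variance for one profile under a config.

    The all-zero profile (no risk alleles, no exposures) returns (0, 0): risk
    is expressed relative to a profile with no risk factors present, before
    population calibration.
    """
    snps, hlas, envs = model.split(config)
    for sid in profile.snp_dosages:
        if sid not in model.genetic:
            raise UnknownFactorError(f"SNP {sid!r} not in model")
    for eid in profile.exposures:
        if eid not in model.environmental:
            raise UnknownFactorError(f"exposure {eid!r} not in model")
    log_or = 0.0
    var = 0.0
    for f in snps:
        k = int(profile.snp_dosages.get(f.id, 0))
        if k:
            log_or += k * f.log_or
            var += k * k * f.var_log_or
    if hlas:
        counts = resolve_hla(
            profile.hla_alleles[0],
            profile.hla_alleles[1],
            model,
            factor_ids={f.id for f in hlas},
        )
        for fid, k in counts.items():
            f = model.genetic[fid]
            log_or += k * f.log_or
            var += k * k * f.var_log_or
    for e in envs:
        x = int(profile.exposures.get(e.id, 0))
        if x:
            log_or += e.log_or
            var += e.var_log_or
    return log_or, var
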