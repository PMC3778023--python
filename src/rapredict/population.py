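"""Stage 1: simulated population risk distribution and CI-based categorisation.

Risk profiles are drawn from the general-population frequencies of each
factor (SNP dosages under Hardy–Weinberg equilibrium, HLA-DRB1 allele pairs
from a categorical allele distribution with residual mass for unmodelled
alleles, exposures as Bernoulli draws).  Profile ORs are calibrated so that
the population-mean OR is 1.0 — a mean-risk profile is the baseline — and the
four risk categories are frozen from the calibrated distribution:

* ``average``  — CI overlaps the baseline profile's CI;
* ``reduced``  — CI fully below the baseline CI;
* ``elevated`` — CI fully above the baseline CI;
* ``high``     — CI fully above the CI of the first (lowest-OR) profile
  classified elevated.

Small models (<= 12 factors and <= 1e6 genotype states) are enumerated
exactly under HWE weights; larger models are Monte-Carlo sampled.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy import stats

from .risk_model import (
    ModelConfig,
    ModelError,
    ProfileRisk,
    RiskFactorModel,
    RiskProfile,
    _z,
)

__all__ = [
    "ProfileSampler",
    "sample_profile",
    "calibrate",
    "simulate_population",
    "SimulatedPopulation",
    "Categoriser",
    "build_categoriser",
    "categoriser_from_intervals",
    "categorise",
    "category_proportions",
]

# Enumeration is exact and cheap for small models; beyond these bounds the
# genotype state space is Monte-Carlo sampled instead.
ENUMERATION_MAX_FACTORS = 12
ENUMERATION_MAX_STATES = 1_000_000

OTHER_ALLELE = "*99"  # placeholder group for alleles outside the model

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class ProfileDraws:
    """Vectorised profile components for n sampled individuals."""

    snp_dosages: Optional[np.ndarray]  # (n, n_snps) int
    hla_idx: Optional[tuple[np.ndarray, np.ndarray]]  # two (n,) index arrays
    exposures: Optional[np.ndarray]  # (n, n_env) int

    @property
    def n(self) -> int:
        for a in (self.snp_dosages, self.exposures):
            if a is not None:
                return a.shape[0]
        return self.hla_idx[0].shape[0]


class ProfileSampler:
    """Precomputed sampling layout for one model configuration."""

    def __init__(self, config: ModelConfig, model: RiskFactorModel) -> None:
        model.validate_config(config)
        snps, hlas, envs = model.split(config)
        self.config = config
        self.model = model

        self.snp_ids = [f.id for f in snps]
        self.snp_p = np.array([f.control_freq for f in snps], dtype=float)
        self.snp_log_or = np.array([f.log_or for f in snps], dtype=float)
        self.snp_var = np.array([f.var_log_or for f in snps], dtype=float)

        self.env_ids = [e.id for e in envs]
        self.env_p = np.array([e.exposure_prev for e in envs], dtype=float)
        self.env_log_or = np.array([e.log_or for e in envs], dtype=float)
        self.env_var = np.array([e.var_log_or for e in envs], dtype=float)

        self.has_hla = bool(hlas)
        if self.has_hla:
            codes, probs, log_ors, ses = self._hla_allele_table(hlas)
            self.hla_codes = codes
            self.hla_p = probs
            self.hla_log_or = log_ors
            self.hla_se = ses

    @staticmethod
    def _hla_allele_table(hlas):
        """Categorical allele distribution over modelled four-digit alleles,
        residual two-digit-only mass, and an unmodelled "other" group."""
        four = [f for f in hlas if f.hla_resolution == "four_digit"]
        two = [f for f in hlas if f.hla_resolution == "two_digit"]
        codes: list[str] = []
        probs: list[float] = []
        log_ors: list[float] = []
        ses: list[float] = []
        for f in four:
            codes.append(f.id)
            probs.append(f.control_freq)
            log_ors.append(f.log_or)
            ses.append(f.se_log_or)
        for t in two:
            children = sum(
                f.control_freq for f in four if f.parent_two_digit == t.id
            )
            residual = t.control_freq - children
            if residual < -_FREQ_TOL:
                raise ModelError(
                    f"{t.id}: modelled four-digit subtypes carry more frequency "
                    f"({children}) than the two-digit group ({t.control_freq})"
                )
            if residual > _FREQ_TOL:
                codes.append(t.id)
                probs.append(residual)
                log_ors.append(t.log_or)
                ses.append(t.se_log_or)
        total = float(sum(probs))
        if total > 1.0 + 1e-6:
            raise ModelError(f"HLA allele frequencies sum to {total} > 1")
        codes.append(OTHER_ALLELE)
        probs.append(max(1.0 - total, 0.0))
        log_ors.append(0.0)
        ses.append(0.0)
        p = np.array(probs, dtype=float)
        return codes, p / p.sum(), np.array(log_ors), np.array(ses)

    @property
    def n_factors(self) -> int:
        n = len(self.snp_ids) + len(self.env_ids)
        if self.has_hla:
            n += 1  # the multi-allelic locus counts once
        return n

    @property
    def n_states(self) -> int:
        n = 3 ** len(self.snp_ids) * 2 ** len(self.env_ids)
        if self.has_hla:
            a = len(self.hla_codes)
            n *= a * (a + 1) // 2
        return n

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> ProfileDraws:
        snp = (
            rng.binomial(2, self.snp_p, size=(n, len(self.snp_ids)))
            if self.snp_ids
            else None
        )
        hla = None
        if self.has_hla:
            h1 = rng.choice(len(self.hla_p), size=n, p=self.hla_p)
            h2 = rng.choice(len(self.hla_p), size=n, p=self.hla_p)
            hla = (h1, h2)
        env = (
            (rng.random((n, len(self.env_ids))) < self.env_p).astype(int)
            if self.env_ids
            else None
        )
        return ProfileDraws(snp, hla, env)

    def log_odds(self, draws: ProfileDraws) -> tuple[np.ndarray, np.ndarray]:
        """Raw (uncalibrated) log OR and variance per sampled profile."""
        n = draws.n
        log_or = np.zeros(n)
        var = np.zeros(n)
        if draws.snp_dosages is not None:
            log_or += draws.snp_dosages @ self.snp_log_or
            var += (draws.snp_dosages.astype(float) ** 2) @ self.snp_var
        if draws.hla_idx is not None:
            h1, h2 = draws.hla_idx
            log_or += self.hla_log_or[h1] + self.hla_log_or[h2]
            s1, s2 = self.hla_se[h1], self.hla_se[h2]
            # homozygous carriage is dosage 2: variance 4*sigma^2, not 2*sigma^2
            var += s1**2 + s2**2 + 2.0 * s1 * s2 * (h1 == h2)
        if draws.exposures is not None:
            log_or += draws.exposures @ self.env_log_or
            var += draws.exposures @ self.env_var
        return log_or, var

    def allele_codes(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.hla_codes, dtype=object)[idx]

    def profile(self, draws: ProfileDraws, i: int) -> RiskProfile:
        snp = (
            {sid: int(draws.snp_dosages[i, j]) for j, sid in enumerate(self.snp_ids)}
            if draws.snp_dosages is not None
            else {}
        )
        alleles = (None, None)
        if draws.hla_idx is not None:
            alleles = (
                self.hla_codes[int(draws.hla_idx[0][i])],
                self.hla_codes[int(draws.hla_idx[1][i])],
            )
        env = (
            {eid: int(draws.exposures[i, j]) for j, eid in enumerate(self.env_ids)}
            if draws.exposures is not None
            else {}
        )
        return RiskProfile(snp_dosages=snp, hla_alleles=alleles, exposures=env)

    # -- exact enumeration -------------------------------------------------

    def enumerate(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All genotype/exposure states with HWE weights: (log_or, var, w)."""
        if self.n_states > ENUMERATION_MAX_STATES:
            raise ModelError(
                f"state space {self.n_states} too large to enumerate"
            )
        log_or = np.array([0.0])
        var = np.array([0.0])
        w = np.array([1.0])

        def _combine(blk_lor, blk_var, blk_w):
            nonlocal log_or, var, w
            log_or = (log_or[:, None] + blk_lor[None, :]).ravel()
            var = (var[:, None] + blk_var[None, :]).ravel()
            w = (w[:, None] * blk_w[None, :]).ravel()

        for j in range(len(self.snp_ids)):
            p, l, v = self.snp_p[j], self.snp_log_or[j], self.snp_var[j]
            _combine(
                np.array([0.0, l, 2.0 * l]),
                np.array([0.0, v, 4.0 * v]),
                np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]),
            )
        if self.has_hla:
            a = len(self.hla_p)
            pairs = [(i, j) for i in range(a) for j in range(i, a)]
            blk_lor = np.array(
                [self.hla_log_or[i] + self.hla_log_or[j] for i, j in pairs]
            )
            blk_var = np.array(
                [
                    (2.0 * self.hla_se[i]) ** 2
                    if i == j
                    else self.hla_se[i] ** 2 + self.hla_se[j] ** 2
                    for i, j in pairs
                ]
            )
            blk_w = np.array(
                [
                    self.hla_p[i] ** 2
                    if i == j
                    else 2.0 * self.hla_p[i] * self.hla_p[j]
                    for i, j in pairs
                ]
            )
            _combine(blk_lor, blk_var, blk_w)
        for j in range(len(self.env_ids)):
            p, l, v = self.env_p[j], self.env_log_or[j], self.env_var[j]
            _combine(np.array([0.0, l]), np.array([0.0, v]), np.array([1 - p, p]))
        return log_or, var, w


def sample_profile(
    config: ModelConfig, model: RiskFactorModel, rng: np.random.Generator
) -> RiskProfile:
    """Draw a single population risk profile."""
    sampler = ProfileSampler(config, model)
    draws = sampler.sample(1, rng)
    return sampler.profile(draws, 0)


def calibrate(
    raw_log_ors: Sequence[float], weights: Optional[Sequence[float]] = None
) -> float:
    """Calibration shift: the log of the (weighted) arithmetic-mean OR.

    Subtracting the shift from every raw log OR makes the population-mean OR
    exactly 1.0, so a mean-OR profile is the baseline.  Disease prevalence
    enters only downstream, when ORs are converted to absolute risks.
    """
    x = np.asarray(raw_log_ors, dtype=float)
    if x.size == 0:
        raise ModelError("cannot calibrate an empty population")
    if weights is None:
        return float(logsumexp(x) - math.log(x.size))
    wgt = np.asarray(weights, dtype=float)
    return float(logsumexp(x, b=wgt) - math.log(wgt.sum()))


@dataclass(frozen=True)
class SimulatedPopulation:
    """Calibrated population risk distribution over unique profiles.

    Profiles are collapsed to unique (log OR, variance) pairs with
    multiplicity ``weight`` (summing to 1) and sorted ascending by OR.
    """

    log_or: np.ndarray
    var_log_or: np.ndarray
    weight: np.ndarray
    calibration_shift: float
    m: int
    method: str
    seed: Optional[int]
    config_name: str
    ci_level: float

    @property
    def or_point(self) -> np.ndarray:
        return np.exp(self.log_or)

    def cis(self, level: Optional[float] = None) -> tuple[np.ndarray, np.ndarray]:
        z = _z(level if level is not None else self.ci_level)
        half = z * np.sqrt(self.var_log_or)
        return np.exp(self.log_or - half), np.exp(self.log_or + half)


def simulate_population(
    config: ModelConfig,
    model: RiskFactorModel,
    m: int = 100_000,
    seed: int = 0,
    method: str = "auto",
) -> SimulatedPopulation:
    """Simulate (or enumerate) the general-population risk distribution."""
    sampler = ProfileSampler(config, model)
    if method == "auto":
        method = (
            "enumerate"
            if sampler.n_factors <= ENUMERATION_MAX_FACTORS
            and sampler.n_states <= ENUMERATION_MAX_STATES
            else "mc"
        )
    if method == "enumerate":
        raw, var, w = sampler.enumerate()
        m_eff = raw.size
        used_seed: Optional[int] = None
    elif method == "mc":
        if m < 1000:
            raise ModelError(f"m must be >= 1000, got {m}")
        rng = np.random.default_rng(seed)
        draws = sampler.sample(m, rng)
        raw, var = sampler.log_odds(draws)
        w = np.full(m, 1.0 / m)
        m_eff = m
        used_seed = seed
    else:
        raise ModelError(f"unknown method {method!r}")

    shift = calibrate(raw, w)
    cal = raw - shift
    # collapse duplicate profiles so boundary scanning is well-defined
    key = np.column_stack([np.round(cal, 12), np.round(var, 12)])
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    weight = np.zeros(uniq.shape[0])
    np.add.at(weight, inverse, w)
    return SimulatedPopulation(
        log_or=uniq[:, 0],
        var_log_or=uniq[:, 1],
        weight=weight,
        calibration_shift=float(shift),
        m=m_eff,
        method=method,
        seed=used_seed,
        config_name=config.name,
        ci_level=config.ci_level,
    )


# --- Categorisation --------------------------------------------------------


@dataclass(frozen=True)
class Categoriser:
    """Frozen classification boundaries from a simulated population.

    ``baseline`` is the CI of the profile whose calibrated OR is nearest 1.0;
    ``first_elevated`` is the CI of the lowest-OR profile lying fully above
    the baseline CI (absent when no profile qualifies, in which case neither
    elevated- nor high-risk assignments can occur).
    """

    baseline_low: float
    baseline_high: float
    first_elevated_low: Optional[float] = None
    first_elevated_high: Optional[float] = None
    ci_level: float = 0.95
    calibration_shift: float = 0.0
    provenance: dict = field(default_factory=dict)

    def classify(self, ci_low: float, ci_high: float) -> str:
        if not (math.isfinite(ci_low) and math.isfinite(ci_high)):
            raise ModelError("cannot categorise a non-finite CI")
        if ci_high < self.baseline_low:
            return "reduced"
        if ci_low <= self.baseline_high:  # overlap (shared endpoints count)
            return "average"
        if self.first_elevated_high is not None and ci_low > self.first_elevated_high:
            return "high"
        return "elevated"

    def classify_arrays(self, ci_low: np.ndarray, ci_high: np.ndarray) -> np.ndarray:
        lo = np.asarray(ci_low, dtype=float)
        hi = np.asarray(ci_high, dtype=float)
        out = np.full(lo.shape, "average", dtype=object)
        out[hi < self.baseline_low] = "reduced"
        above = lo > self.baseline_high
        out[above] = "elevated"
        if self.first_elevated_high is not None:
            out[above & (lo > self.first_elevated_high)] = "high"
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "baseline_ci": [self.baseline_low, self.baseline_high],
            "first_elevated_ci": (
                None
                if self.first_elevated_low is None
                else [self.first_elevated_low, self.first_elevated_high]
            ),
            "ci_level": self.ci_level,
            "calibration_shift": self.calibration_shift,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Categoriser":
        fe = d.get("first_elevated_ci")
        return cls(
            baseline_low=d["baseline_ci"][0],
            baseline_high=d["baseline_ci"][1],
            first_elevated_low=None if fe is None else fe[0],
            first_elevated_high=None if fe is None else fe[1],
            ci_level=d.get("ci_level", 0.95),
            calibration_shift=d.get("calibration_shift", 0.0),
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Categoriser":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _build_categoriser(
    or_point: np.ndarray,
    ci_low: np.ndarray,
    ci_high: np.ndarray,
    tie_width: np.ndarray,
    ci_level: float,
    calibration_shift: float,
    provenance: dict,
) -> Categoriser:
    if or_point.size == 0:
        raise ModelError("cannot build a categoriser from an empty population")
    order = np.argsort(or_point, kind="stable")
    orp = or_point[order]
    lo = ci_low[order]
    hi = ci_high[order]
    width = tie_width[order]
    # baseline: profile nearest OR 1.0 on the log scale; ties -> most precise
    base_idx = np.lexsort((width, np.abs(np.log(orp))))[0]
    b_lo, b_hi = float(lo[base_idx]), float(hi[base_idx])
    fe_lo = fe_hi = None
    above = np.nonzero(lo > b_hi)[0]
    if above.size:
        j = above[0]  # lowest-OR profile fully above baseline
        fe_lo, fe_hi = float(lo[j]), float(hi[j])
    return Categoriser(
        baseline_low=b_lo,
        baseline_high=b_hi,
        first_elevated_low=fe_lo,
        first_elevated_high=fe_hi,
        ci_level=ci_level,
        calibration_shift=calibration_shift,
        provenance=provenance,
    )


def build_categoriser(
    pop: SimulatedPopulation, level: Optional[float] = None
) -> Categoriser:
    """Freeze the four-category boundaries from a simulated population."""
    level = level if level is not None else pop.ci_level
    lo, hi = pop.cis(level)
    return _build_categoriser(
        pop.or_point,
        lo,
        hi,
        tie_width=np.sqrt(pop.var_log_or),
        ci_level=level,
        calibration_shift=pop.calibration_shift,
        provenance={
            "config": pop.config_name,
            "m": pop.m,
            "seed": pop.seed,
            "method": pop.method,
        },
    )


def categoriser_from_intervals(
    or_points: Sequence[float],
    ci_lows: Sequence[float],
    ci_highs: Sequence[float],
    ci_level: float = 0.95,
    calibration_shift: float = 0.0,
    provenance: Optional[dict] = None,
) -> Categoriser:
    """Build a categoriser from explicitly supplied profile intervals."""
    orp = np.asarray(or_points, dtype=float)
    lo = np.asarray(ci_lows, dtype=float)
    hi = np.asarray(ci_highs, dtype=float)
    return _build_categoriser(
        orp,
        lo,
        hi,
        tie_width=np.log(hi) - np.log(lo),
        ci_level=ci_level,
        calibration_shift=calibration_shift,
        provenance=provenance or {},
    )


def categorise(risk: ProfileRisk, categoriser: Categoriser) -> str:
    """Assign one of reduced/average/elevated/high to a profile's CI."""
    return categoriser.classify(risk.ci_low, risk.ci_high)


def category_proportions(
    pop: SimulatedPopulation,
    categoriser: Categoriser,
    level: Optional[float] = None,
) -> dict[str, float]:
    """Population weight in each of the four risk categories."""
    lo, hi = pop.cis(level if level is not None else categoriser.ci_level)
    labels = categoriser.classify_arrays(lo, hi)
    out = {c: 0.0 for c in ("reduced", "average", "elevated", "high")}
    for c in out:
        out[c] = float(pop.weight[labels == c].sum())
    return out
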