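import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from rapredict import (
    GeneticRiskFactor,
    ModelConfig,
    RiskFactorModel,
    bundled_configs,
    bundled_model,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

Z95 = 1.959963984540054


def make_snp(sid: str, or_: float, freq: float, se: float) -> GeneticRiskFactor:
    """SNP factor whose published CI encodes exactly the requested SE."""
    half = Z95 * se
    return GeneticRiskFactor(
        id=sid,
        locus_kind="snp",
        or_allelic=or_,
        ci_low=or_ * math.exp(-half),
        ci_high=or_ * math.exp(half),
        control_freq=freq,
    )


@pytest.fixture(scope="session")
def model():
    return bundled_model()


@pytest.fixture(scope="session")
def configs():
    return bundled_configs()


@pytest.fixture(scope="session")
def toy_model():
    """Three independent HWE SNPs with known ORs, frequencies and SEs."""
    return RiskFactorModel(
        [
            make_snp("snpA", 1.5, 0.3, 0.08),
            make_snp("snpB", 1.3, 0.2, 0.06),
            make_snp("snpC", 1.2, 0.4, 0.05),
        ]
    )


@pytest.fixture(scope="session")
def toy_config():
    return ModelConfig(
        name="toy3",
        factor_ids=("snpA", "snpB", "snpC"),
        prevalence=0.01,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def hwe_category_oracle(model, config, level_z=Z95):
    """Brute-force oracle: exhaustive enumeration of all SNP genotype
    combinations under HWE weights, with the categorisation rules applied
    from first principles (independent of the package's samplers)."""
    snps = [model.genetic[s] for s in config.factor_ids]
    profiles = []
    for combo in itertools.product(range(3), repeat=len(snps)):
        w = 1.0
        lor = 0.0
        var = 0.0
        for k, f in zip(combo, snps):
            p = f.control_freq
            w *= [(1 - p) ** 2, 2 * p * (1 - p), p**2][k]
            lor += k * math.log(f.or_allelic)
            var += k * k * f.se_log_or**2
        profiles.append((lor, var, w))
    shift = math.log(sum(w * math.exp(l) for l, _, w in profiles))
    cis = []
    for l, v, w in profiles:
        half = level_z * math.sqrt(v)
        cis.append((math.exp(l - shift), math.exp(l - shift - half),
                    math.exp(l - shift + half), w))
    base = min(cis, key=lambda t: (abs(math.log(t[0])), t[2] - t[1]))
    b_lo, b_hi = base[1], base[2]
    above = sorted((t for t in cis if t[1] > b_hi), key=lambda t: t[0])
    fe_hi = above[0][2] if above else None
    props = {"reduced": 0.0, "average": 0.0, "elevated": 0.0, "high": 0.0}
    for orp, lo, hi, w in cis:
        if hi < b_lo:
            props["reduced"] += w
        elif lo <= b_hi:
            props["average"] += w
        elif fe_hi is not None and lo > fe_hi:
            props["high"] += w
        else:
            props["elevated"] += w
    return props
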