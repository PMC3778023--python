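"""Reading risk-factor tables, model configurations and cohort tables.

Risk factors arrive as delimited text (one row per factor); model
configurations as YAML naming factor sets, the disease prevalence used for
calibration and the CI level.  The package ships fixture files transcribing
the published HLA-DRB1 allele table, the non-HLA SNP table and the male
ever-smoking meta-analysis row, plus the five standard model configurations.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
import yaml

from .risk_model import (
    EnvironmentalRiskFactor,
    GeneticRiskFactor,
    ModelConfig,
    ModelError,
    RiskFactorModel,
)

__all__ = [
    "load_factor_table",
    "load_model",
    "load_model_configs",
    "bundled_model",
    "bundled_configs",
    "bundled_smoking_tables",
    "load_cohort",
    "save_cohort",
]

_DATA = resources.files("rapredict.data")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(f)


def load_factor_table(path) -> tuple[list[GeneticRiskFactor], list[EnvironmentalRiskFactor]]:
    """Parse one delimited factor table into genetic/environmental factors.

    Columns: id, kind (snp | hla_allele | environment), resolution, parent,
    or, ci_low, ci_high, control_freq, n_cases, n_controls, exposure_prev,
    applies_to.  Unused columns may be empty.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    genetic: list[GeneticRiskFactor] = []
    environmental: list[EnvironmentalRiskFactor] = []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip()
        if kind == "environment":
            environmental.append(
                EnvironmentalRiskFactor(
                    id=row["id"],
                    or_exposed=float(row["or"]),
                    ci_low=_opt_float(row.get("ci_low")),
                    ci_high=_opt_float(row.get("ci_high")),
                    se_log_or=_opt_float(row.get("se_log_or")),
                    exposure_prev=float(row["exposure_prev"]),
                    applies_to=str(row.get("applies_to", "all")).strip(),
                )
            )
        elif kind in ("snp", "hla_allele"):
            resolution = row.get("resolution")
            parent = row.get("parent")
            genetic.append(
                GeneticRiskFactor(
                    id=row["id"],
                    locus_kind=kind,
                    hla_resolution=(
                        "not_applicable"
                        if kind == "snp"
                        else str(resolution).strip()
                    ),
                    parent_two_digit=(
                        None
                        if parent is None or (isinstance(parent, float) and math.isnan(parent))
                        else str(parent).strip()
                    ),
                    or_allelic=float(row["or"]),
                    ci_low=_opt_float(row.get("ci_low")),
                    ci_high=_opt_float(row.get("ci_high")),
                    control_freq=float(row["control_freq"]),
                    n_cases=_opt_int(row.get("n_cases")),
                    n_controls=_opt_int(row.get("n_controls")),
                )
            )
        else:
            raise ModelError(f"{row['id']}: unknown factor kind {kind!r}")
    return genetic, environmental


def load_model(paths: Iterable) -> RiskFactorModel:
    """Combine one or more factor tables into a RiskFactorModel."""
    genetic: list[GeneticRiskFactor] = []
    environmental: list[EnvironmentalRiskFactor] = []
    for p in paths:
        g, e = load_factor_table(p)
        genetic.extend(g)
        environmental.extend(e)
    return RiskFactorModel(genetic, environmental)


def load_model_configs(path) -> dict[str, ModelConfig]:
    """Parse model configurations from YAML.

    Layout::

        prevalence: 0.008
        ci_level: 0.95
        factor_sets:
          hla_all: ["*01", ...]
        models:
          HLA: {factors: ["@hla_all"]}
          HLA_smoking:
            factors: ["@hla_all", "ever_smoking_male"]
            sex_restriction: males_only

    ``@name`` entries expand to the named factor set.
    """
    if hasattr(path, "read"):
        doc = yaml.safe_load(path)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    prevalence = float(doc.get("prevalence", 0.008))
    ci_level = float(doc.get("ci_level", 0.95))
    sets = {k: list(v) for k, v in (doc.get("factor_sets") or {}).items()}
    configs: dict[str, ModelConfig] = {}
    for name, spec in (doc.get("models") or {}).items():
        ids: list[str] = []
        for entry in spec["factors"]:
            if isinstance(entry, str) and entry.startswith("@"):
                ref = entry[1:]
                if ref not in sets:
                    raise ModelError(f"{name}: unknown factor set {ref!r}")
                ids.extend(sets[ref])
            else:
                ids.append(entry)
        configs[name] = ModelConfig(
            name=name,
            factor_ids=tuple(ids),
            prevalence=float(spec.get("prevalence", prevalence)),
            sex_restriction=spec.get("sex_restriction", "none"),
            ci_level=float(spec.get("ci_level", ci_level)),
        )
    return configs


def bundled_model() -> RiskFactorModel:
    """The packaged risk-factor model (HLA + SNP + male ever-smoking)."""
    return load_model(
        [
            _DATA / "hla_factors.tsv",
            _DATA / "snp_factors.tsv",
            _DATA / "environment_factors.tsv",
        ]
    )


def bundled_configs() -> dict[str, ModelConfig]:
    """The five packaged model configurations."""
    with (_DATA / "model_configs.yaml").open() as fh:
        return load_model_configs(fh)


def bundled_smoking_tables() -> pd.DataFrame:
    """Published 2x2 ever-smoking tables by cohort and sex (cell counts)."""
    return pd.read_csv(_DATA / "smoking_2x2.tsv", sep="\t")


def load_cohort(path) -> pd.DataFrame:
    """Read an individual-level cohort table (TSV, one row per person)."""
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)
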