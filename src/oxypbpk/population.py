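"""Virtual population templates and individual sampling.

A :class:`PopulationTemplate` is a thin data record of the distributions from
which virtual individuals are drawn: demographic ranges, lognormal system
parameters (body weight, liver weight, MPPGL, hepatic blood flow), lognormal
enzyme abundances parameterized by mean and CV, a multiplicative female CYP3A4
shift, CYP3A5 phenotype frequencies, and disease modifiers.  Only values with
published provenance are shipped in the built-in templates (Caucasian CYP3A4
137 pmol/mg, CV 41%; genotype and rheumatoid-arthritis overrides); the rest
are documented placeholders that users can override in config.

Abundances are lognormal because they are strictly positive and that is the
standard convention for enzyme expression variability.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import KNOWN_ENZYMES, SystemPhysiology

__all__ = ["AbundanceDist", "PopulationTemplate", "make_template", "sample_individual", "BASE_TEMPLATES"]


class AbundanceDist(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean: float = Field(ge=0.0, description="pmol/mg")
    cv: float = Field(ge=0.0, description="percent")


class PopulationTemplate(BaseModel):
    """Distributions and frequencies defining one virtual population."""

    model_config = ConfigDict(frozen=True)

    name: str
    age_range: tuple[float, float] = (20.0, 50.0)
    prop_female: float = Field(default=0.5, ge=0.0, le=1.0)
    weight_mean: float = Field(default=67.5, gt=0.0)
    weight_cv: float = Field(default=15.0, ge=0.0)
    liver_weight_mean: float = Field(default=1737.11, gt=0.0)
    liver_weight_cv: float = Field(default=20.0, ge=0.0)
    mppgl_mean: float = Field(default=39.79, gt=0.0)
    mppgl_cv: float = Field(default=30.0, ge=0.0)
    q_h_mean: float = Field(default=90.0, gt=0.0)
    q_h_cv: float = Field(default=15.0, ge=0.0)
    hematocrit_mean: float = Field(default=0.45, gt=0.0, lt=1.0)
    hematocrit_cv: float = Field(default=5.0, ge=0.0)
    abundances: dict[str, AbundanceDist] = Field(default_factory=dict)
    female_cyp3a4_multiplier: float = Field(default=1.24, gt=0.0)
    cyp3a5_phenotype_freqs: dict[str, float] = Field(
        default_factory=lambda: {"EM": 0.17, "IM": 0.0, "PM": 0.83}
    )
    cyp3a5_abundance_by_phenotype: dict[str, float] = Field(
        default_factory=lambda: {"EM": 103.0, "IM": 51.5, "PM": 1.0}
    )
    cardiac_output_multiplier: float = Field(default=1.0, gt=0.0)
    hematocrit_multiplier: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "PopulationTemplate":
        total = sum(self.cyp3a5_phenotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"CYP3A5 phenotype frequencies sum to {total}, not 1")
        for enzyme in self.abundances:
            if enzyme not in KNOWN_ENZYMES:
                raise ValueError(f"unknown enzyme {enzyme!r} in template abundances")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        return self


def _default_abundances() -> dict[str, AbundanceDist]:
    return {
        "CYP3A4": AbundanceDist(mean=137.0, cv=41.0),
        "CYP3A7": AbundanceDist(mean=2.0, cv=41.0),
        "CYP27A1": AbundanceDist(mean=41.93, cv=30.0),
    }


#: Built-in base templates.  The Asian-like template carries a 16% lower
#: CYP3A4 mean and the higher CYP3A5 extensive-metabolizer frequency (0.48 vs
#: 0.17); other ethnic system parameters are user-editable placeholders.
BASE_TEMPLATES: dict[str, PopulationTemplate] = {
    "caucasian_healthy": PopulationTemplate(
        name="caucasian_healthy",
        abundances=_default_abundances(),
        cyp3a5_phenotype_freqs={"EM": 0.17, "IM": 0.0, "PM": 0.83},
    ),
    "asian_healthy": PopulationTemplate(
        name="asian_healthy",
        abundances={**_default_abundances(), "CYP3A4": AbundanceDist(mean=115.1, cv=41.0)},
        cyp3a5_phenotype_freqs={"EM": 0.48, "IM": 0.0, "PM": 0.52},
        weight_mean=63.5,
    ),
}

#: Genotype-specific CYP3A4 mean abundances (pmol/mg), retrograde-derived.
GENOTYPE_CYP3A4_MEAN = {"*1/*1": 137.0, "*1/*22": 100.86, "*22/*22": 51.27}


def make_template(
    base: str = "caucasian_healthy",
    *,
    genotype: Literal["*1/*1", "*1/*22", "*22/*22"] | None = None,
    disease: Literal["RA"] | None = None,
    **overrides,
) -> PopulationTemplate:
    """Derive a population template from a registered base.

    ``genotype`` applies the CYP3A4*22 retrograde abundance means (100.86 /
    51.27 pmol/mg, CV 41% retained); ``disease="RA"`` applies the rheumatoid
    arthritis modifiers (CYP3A4 mean 82.07 pmol/mg, cardiac output ×1.05,
    hematocrit ×0.83).  Additional keyword overrides replace template fields.
    """
    if base not in BASE_TEMPLATES:
        raise KeyError(f"unknown base template {base!r}; available: {sorted(BASE_TEMPLATES)}")
    if genotype is not None and disease is not None:
        raise ValueError("genotype and disease overrides conflict; apply one at a time")
    template = BASE_TEMPLATES[base]
    updates: dict = {}
    abundances = dict(template.abundances)
    name_parts = [base]
    if genotype is not None:
        if genotype not in GENOTYPE_CYP3A4_MEAN:
            raise KeyError(f"unknown genotype {genotype!r}")
        old = abundances["CYP3A4"]
        abundances["CYP3A4"] = AbundanceDist(mean=GENOTYPE_CYP3A4_MEAN[genotype], cv=old.cv)
        name_parts.append(f"CYP3A4{genotype}")
    if disease == "RA":
        old = abundances["CYP3A4"]
        abundances["CYP3A4"] = AbundanceDist(mean=82.07, cv=old.cv)
        updates["cardiac_output_multiplier"] = 1.05
        updates["hematocrit_multiplier"] = 0.83
        name_parts.append("RA")
    updates["abundances"] = abundances
    updates["name"] = "+".join(name_parts)
    updates.update(overrides)
    return template.model_copy(update=updates)


def _lognormal(rng: np.random.Generator, mean: float, cv_pct: float) -> float:
    """Draw from a lognormal with the given arithmetic mean and CV (percent)."""
    if mean == 0.0:
        return 0.0
    cv = cv_pct / 100.0
    if cv == 0.0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def sample_individual(
    template: PopulationTemplate, rng: np.random.Generator
) -> SystemPhysiology:
    """Draw one virtual individual from the template's distributions.

    Sex is Bernoulli(prop_female); the female CYP3A4 multiplier shifts the
    CYP3A4 abundance mean before sampling.  The CYP3A5 phenotype is drawn from
    the template frequencies and sets the CYP3A5 abundance mean (PMs are
    near-null expressers).  Deterministic given the generator state.
    """
    sex = "female" if rng.random() < template.prop_female else "male"
    age = float(rng.uniform(*template.age_range))
    weight = _lognormal(rng, template.weight_mean, template.weight_cv)
    liver_weight = _lognormal(rng, template.liver_weight_mean, template.liver_weight_cv)
    mppgl = _lognormal(rng, template.mppgl_mean, template.mppgl_cv)
    q_h = _lognormal(rng, template.q_h_mean, template.q_h_cv) * template.cardiac_output_multiplier
    hct = _lognormal(rng, template.hematocrit_mean, template.hematocrit_cv)
    hct = min(hct * template.hematocrit_multiplier, 0.95)

    abundances: dict[str, float] = {}
    for enzyme, dist in template.abundances.items():
        mean = dist.mean
        if enzyme == "CYP3A4" and sex == "female":
            mean *= template.female_cyp3a4_multiplier
        abundances[enzyme] = _lognormal(rng, mean, dist.cv)

    phenotypes = sorted(template.cyp3a5_phenotype_freqs)
    probs = np.array([template.cyp3a5_phenotype_freqs[p] for p in phenotypes])
    phenotype = phenotypes[int(rng.choice(len(phenotypes), p=probs / probs.sum()))]
    cyp3a5_mean = template.cyp3a5_abundance_by_phenotype[phenotype]
    cyp3a5_cv = template.abundances.get("CYP3A4", AbundanceDist(mean=0, cv=41.0)).cv
    abundances["CYP3A5"] = _lognormal(rng, cyp3a5_mean, cyp3a5_cv)

    return SystemPhysiology(
        body_weight=weight,
        liver_weight=liver_weight,
        mppgl=mppgl,
        hepatic_blood_flow=q_h,
        hematocrit=hct,
        sex=sex,
        age=age,
        abundances=abundances,
    )
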