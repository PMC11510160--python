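"""Synthetic fixtures: study tables, noisy observed profiles, recovery datasets.

These generators stand in for data this package cannot ship — the literature
meta-analysis tables and the clinical concentration profiles used for model
verification — so that every pipeline stage can be exercised end to end with
no external downloads.  All generators are pure functions of (spec, seed);
noise is multiplicative lognormal, because concentrations are strictly
positive and variability is conventionally reported as a CV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .engine import SimulationOutput
from .params import ModelConfig
from .stats import StudyRecord

__all__ = [
    "SyntheticStudySpec",
    "gen_study_table",
    "gen_observed_profiles",
    "recovery_fixture",
]


class SyntheticStudySpec(BaseModel):
    """Generating process for a synthetic meta-analysis study table.

    Defaults emulate the published pooling target: a true population mean of
    29.85 ng/mL over 38 studies with between-study SD 4.5 ng/mL and
    within-study CV 45%, so the pooled SD lands near the reported ~14.9 ng/mL
    scale.  Strata apply multiplicative shifts to the stratum's true mean
    (e.g. a 1.31× female shift).
    """

    model_config = ConfigDict(frozen=True)

    n_studies: int = Field(default=38, ge=1)
    n_range: tuple[int, int] = (20, 200)
    true_mean: float = Field(default=29.85, gt=0.0, description="ng/mL")
    between_study_sd: float = Field(default=4.5, ge=0.0, description="ng/mL")
    within_study_cv: float = Field(default=45.0, ge=0.0, description="percent")
    strata: dict[str, float] = Field(default_factory=dict, description="label -> mean multiplier")
    seed: int


def gen_study_table(spec: SyntheticStudySpec) -> list[StudyRecord]:
    """Draw per-study (n, mean, SD) records around the spec's true mean.

    Study means are lognormal around the (stratum-shifted) truth with the
    between-study SD; per-study SDs follow the within-study CV.  Reproducible
    by seed, and every record validates against the StudyRecord schema.
    """
    rng = np.random.default_rng(spec.seed)
    strata = list(spec.strata.items()) or [("all", 1.0)]
    records = []
    for i in range(spec.n_studies):
        label, mult = strata[i % len(strata)]
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        center = spec.true_mean * mult
        if spec.between_study_sd > 0:
            cv = spec.between_study_sd / spec.true_mean  # absolute SD on the unshifted scale
            sigma2 = np.log1p(cv * cv)
            mean = float(center * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))
        else:
            mean = center
        sd = mean * spec.within_study_cv / 100.0
        records.append(
            StudyRecord(study_id=f"synthetic_{i + 1:02d}", n=n, mean=mean, sd=sd, sex=label)
        )
    return records


def gen_observed_profiles(
    simulation: SimulationOutput,
    noise_cv: float,
    sampling_times_h: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Observed-style concentration table from a simulated profile.

    Samples both analytes at the given times and applies mean-preserving
    multiplicative lognormal noise with the given CV (%).  An empty sampling
    schedule yields an empty table.
    """
    times = np.asarray(sampling_times_h, dtype=float)
    if times.size == 0:
        return pd.DataFrame(columns=["time_h", "analyte", "value", "units"])
    if times.min() < simulation.time_h[0] or times.max() > simulation.time_h[-1]:
        raise ValueError("sampling times outside the simulated range")
    rng = np.random.default_rng(seed)
    cv = noise_cv / 100.0
    sigma = np.sqrt(np.log1p(cv * cv)) if cv > 0 else 0.0
    rows = []
    for analyte, series, units in (
        ("parent", simulation.plasma_parent_mg_l, "mg/L"),
        ("metabolite", simulation.plasma_metabolite_ng_ml, "ng/mL"),
    ):
        values = np.interp(times, simulation.time_h, series)
        if sigma > 0:
            values = values * rng.lognormal(-sigma**2 / 2.0, sigma, size=values.shape)
        for t, v in zip(times, values):
            rows.append({"time_h": t, "analyte": analyte, "value": v, "units": units})
    return pd.DataFrame(rows)


@dataclass
class RecoveryFixture:
    """Synthetic calibration dataset with its hidden generating truth."""

    observed_baseline_css_ng_ml: float
    observed_ddi_ratio: float
    truth: dict


def recovery_fixture(
    true_clint_cyp3a4: float,
    config: ModelConfig,
    seed: int,
    *,
    noise_cv: float = 5.0,
    ddi_fold: float = 10.0,
    dose_mg_kg_day: float = 1.73,
) -> RecoveryFixture:
    """Generate a noisy baseline Css + DDI observation from a known CYP3A4 CLint.

    The truth record carries the generating CLint so calibration round-trips
    can score their recovery error; two seeds give different noise around the
    same truth.
    """
    from .engine import analytic_steady_state
    from .trials import METABOLITE, PARENT, _recalibrated_parent
    from .params import scaled_liver_clint

    phys = config.physiology
    clmet_ref = sum(scaled_liver_clint(p, phys) for p in config.compounds[PARENT].pathways)
    parent = _recalibrated_parent(config, true_clint_cyp3a4, 5.6, 2.8, clmet_ref)
    metabolite = config.compounds[METABOLITE]
    rate = dose_mg_kg_day * phys.body_weight / 24.0
    base = analytic_steady_state(parent, metabolite, phys, rate).css_metabolite_ng_ml
    induced = analytic_steady_state(
        parent, metabolite, phys, rate, enzyme_fold=ddi_fold
    ).css_metabolite_ng_ml

    rng = np.random.default_rng(seed)
    cv = noise_cv / 100.0
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=2)
    else:
        noise = np.ones(2)
    return RecoveryFixture(
        observed_baseline_css_ng_ml=float(base * noise[0]),
        observed_ddi_ratio=float(induced / base * noise[1]),
        truth={
            "clint_cyp3a4": true_clint_cyp3a4,
            "baseline_css_ng_ml": base,
            "ddi_fold": ddi_fold,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )
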