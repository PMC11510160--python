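"""Domain types, unit conventions, and configuration I/O.

The model works in a fixed internal unit system: time in hours, volume in
litres, mass in milligrams, enzyme amount in picomoles.  In vitro intrinsic
clearances are carried in the conventional microsomal units — µL/min/pmol of
enzyme for CYP pathways and µL/min/mg microsomal protein for the aggregate
human-liver-microsome (HLM) pathway — and scaled to whole-liver L/h through
liver weight × MPPGL (× enzyme abundance for per-pmol pathways) with the
exact factor 60/10^6.

Configuration files are YAML or JSON documents validated into
:class:`ModelConfig`; a bundled default describes the cholesterol /
4β-hydroxycholesterol (4β-OHC) model with its published compound parameters.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "KNOWN_ENZYMES",
    "CYP3A_FAMILY",
    "PER_PMOL_SCALE",
    "PathwayClearance",
    "CompoundParams",
    "EnzymeSystem",
    "SystemPhysiology",
    "DoseRegimen",
    "InteractionSpec",
    "PerpetratorPK",
    "Perpetrator",
    "ModelConfig",
    "scaled_liver_clint",
    "load_config",
    "save_config",
    "default_config",
]

#: Enzyme labels the model understands.  "HLM" is the aggregate microsomal
#: pathway holding clearance not assigned to a specific CYP (here standing in
#: for CYP7A1, whose hepatic abundance is not available).
KNOWN_ENZYMES = frozenset({"CYP3A4", "CYP3A5", "CYP3A7", "CYP27A1", "HLM"})

#: The CYP3A isoforms that share the induction signal and form 4β-OHC.
CYP3A_FAMILY = ("CYP3A4", "CYP3A5", "CYP3A7")

#: µL/min → L/h, i.e. the 10^6/60 divisor of the scaling equations, inverted.
PER_PMOL_SCALE = 60.0 / 1.0e6

#: Default first-order CYP3A degradation rate (1/h); ≈36 h turnover half-life,
#: the conventional hepatic CYP3A value.
DEFAULT_KDEG = 0.0193


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class PathwayClearance(_Frozen):
    """One enzymatic elimination pathway of a compound.

    ``clint`` is in µL/min/pmol enzyme for ``basis='per_pmol'`` and in
    µL/min/mg microsomal protein for ``basis='per_mg'`` (HLM only).
    """

    enzyme: str
    clint: float = Field(ge=0.0)
    basis: Literal["per_pmol", "per_mg"]

    @field_validator("enzyme")
    @classmethod
    def _known_enzyme(cls, v: str) -> str:
        if v not in KNOWN_ENZYMES:
            raise ValueError(f"unknown enzyme label {v!r}; expected one of {sorted(KNOWN_ENZYMES)}")
        return v

    @model_validator(mode="after")
    def _basis_matches_enzyme(self) -> "PathwayClearance":
        if (self.basis == "per_mg") != (self.enzyme == "HLM"):
            raise ValueError("basis must be 'per_mg' if and only if enzyme is 'HLM'")
        return self


class CompoundParams(_Frozen):
    """Physicochemical, binding, distribution, and clearance description of one analyte."""

    name: str
    molecular_weight: float = Field(gt=0.0, description="g/mol")
    logP: float
    blood_to_plasma: float = Field(gt=0.0, description="B/P ratio")
    fu_plasma: float = Field(gt=0.0, le=1.0, description="fraction unbound in plasma")
    vss: float = Field(gt=0.0, description="L/kg")
    kp_liver: float = Field(gt=0.0, description="liver:plasma partition coefficient")
    binding_protein: str = "apolipoprotein B"
    pathways: tuple[PathwayClearance, ...] = ()

    @model_validator(mode="after")
    def _unique_pathways(self) -> "CompoundParams":
        names = [p.enzyme for p in self.pathways]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate pathway enzymes in compound {self.name!r}: {names}")
        return self

    def pathway(self, enzyme: str) -> PathwayClearance | None:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        return None

    def with_clints(self, clints: Mapping[str, float]) -> "CompoundParams":
        """Return a copy with the given pathway ``clint`` values replaced.

        Enzymes absent from the compound are added with the appropriate basis.
        """
        existing = {p.enzyme: p for p in self.pathways}
        for enzyme, clint in clints.items():
            basis = "per_mg" if enzyme == "HLM" else "per_pmol"
            existing[enzyme] = PathwayClearance(enzyme=enzyme, clint=clint, basis=basis)
        return self.model_copy(update={"pathways": tuple(existing.values())})


class EnzymeSystem(_Frozen):
    """Population-level description of one hepatic enzyme."""

    enzyme: str
    abundance_mean: float = Field(ge=0.0, description="pmol/mg microsomal protein")
    abundance_cv: float = Field(ge=0.0, description="percent")
    kdeg: float = Field(default=DEFAULT_KDEG, gt=0.0, description="1/h")

    @field_validator("enzyme")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in KNOWN_ENZYMES:
            raise ValueError(f"unknown enzyme label {v!r}")
        return v


class SystemPhysiology(_Frozen):
    """One virtual individual's system parameters."""

    body_weight: float = Field(gt=0.0, description="kg")
    liver_weight: float = Field(gt=0.0, description="g")
    mppgl: float = Field(gt=0.0, description="mg microsomal protein / g liver")
    hepatic_blood_flow: float = Field(gt=0.0, description="L/h")
    hematocrit: float = Field(default=0.45, gt=0.0, lt=1.0)
    sex: Literal["male", "female"] = "male"
    age: float = Field(default=35.0, gt=0.0, description="years")
    abundances: dict[str, float] = Field(default_factory=dict, description="pmol/mg per enzyme")

    @field_validator("abundances")
    @classmethod
    def _validate_abundances(cls, v: dict[str, float]) -> dict[str, float]:
        for enzyme, abundance in v.items():
            if enzyme not in KNOWN_ENZYMES:
                raise ValueError(f"unknown enzyme label {enzyme!r} in abundances")
            if abundance < 0:
                raise ValueError(f"abundance for {enzyme} must be >= 0")
        return v

    def microsomal_protein(self) -> float:
        """Total microsomal protein in the liver (mg)."""
        return self.liver_weight * self.mppgl


class DoseRegimen(_Frozen):
    """A dosing schedule.

    For the endogenous IV infusion ``dose`` is mg/kg/day (delivered as a
    continuous constant-rate infusion); for perpetrators it is mg per
    administration at the given interval.
    """

    compound: str
    route: Literal["iv_infusion", "oral"]
    dose: float = Field(gt=0.0)
    interval: float = Field(default=24.0, gt=0.0, description="h")
    start_day: float = Field(default=0.0, ge=0.0)
    duration_days: float = Field(gt=0.0)


class InteractionSpec(_Frozen):
    """Perpetrator mechanism acting on the target enzymes."""

    mechanism: Literal["induction", "competitive_inhibition"]
    ind_max: float | None = Field(default=None, description="maximal fold induction")
    ind_c50: float | None = Field(default=None, description="µM unbound, half-maximal induction")
    ki: float | None = Field(default=None, description="µM unbound")
    target_enzymes: tuple[str, ...] = CYP3A_FAMILY

    @model_validator(mode="after")
    def _mechanism_params(self) -> "InteractionSpec":
        if self.mechanism == "induction":
            if self.ind_max is None or self.ind_c50 is None:
                raise ValueError("induction requires ind_max and ind_c50")
            if self.ind_max < 1.0:
                raise ValueError("ind_max must be >= 1")
            if self.ind_c50 <= 0.0:
                raise ValueError("ind_c50 must be > 0")
        else:
            if self.ki is None or self.ki <= 0.0:
                raise ValueError("competitive_inhibition requires ki > 0")
        for enzyme in self.target_enzymes:
            if enzyme not in KNOWN_ENZYMES:
                raise ValueError(f"unknown target enzyme {enzyme!r}")
        return self


class PerpetratorPK(_Frozen):
    """One-compartment oral PK of a perpetrator drug."""

    ka: float = Field(gt=0.0, description="1/h")
    v_f: float = Field(gt=0.0, description="L (V/F)")
    cl_f: float = Field(gt=0.0, description="L/h (CL/F)")
    fu: float = Field(gt=0.0, le=1.0)
    kp_liver: float = Field(default=1.0, gt=0.0)
    molecular_weight: float = Field(gt=0.0, description="g/mol")


class Perpetrator(_Frozen):
    name: str
    pk: PerpetratorPK
    regimen: DoseRegimen
    interaction: InteractionSpec


class ModelConfig(_Frozen):
    """Fully validated model configuration: compounds, physiology, enzymes, dosing."""

    name: str = "model"
    physiology: SystemPhysiology
    enzymes: dict[str, EnzymeSystem] = Field(default_factory=dict)
    compounds: dict[str, CompoundParams]
    dosing: dict[str, DoseRegimen] = Field(default_factory=dict)
    perpetrators: dict[str, Perpetrator] = Field(default_factory=dict)
    reference: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _keys_consistent(self) -> "ModelConfig":
        for key, compound in self.compounds.items():
            if compound.name != key:
                raise ValueError(f"compound key {key!r} does not match name {compound.name!r}")
        for key, enz in self.enzymes.items():
            if enz.enzyme != key:
                raise ValueError(f"enzyme key {key!r} does not match label {enz.enzyme!r}")
        return self

    def kdeg(self, enzyme: str) -> float:
        enz = self.enzymes.get(enzyme)
        return enz.kdeg if enz is not None else DEFAULT_KDEG


def scaled_liver_clint(pathway: PathwayClearance, phys: SystemPhysiology) -> float:
    """Whole-liver unbound intrinsic clearance of one pathway, in L/h.

    Per-pmol pathways scale as clint × liver weight × MPPGL × abundance ×
    60/10^6; the per-mg HLM pathway omits the abundance term.
    """
    base = pathway.clint * phys.liver_weight * phys.mppgl
    if pathway.basis == "per_pmol":
        try:
            abundance = phys.abundances[pathway.enzyme]
        except KeyError:
            raise KeyError(
                f"physiology has no abundance for enzyme {pathway.enzyme!r}"
            ) from None
        base *= abundance
    return base * PER_PMOL_SCALE


def _parse(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON model configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ModelConfig.model_validate(_parse(path))


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML or JSON (by suffix)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_config() -> ModelConfig:
    """The bundled cholesterol / 4β-OHC model configuration."""
    source = resources.files("oxypbpk.data").joinpath("default_model.yaml")
    return ModelConfig.model_validate(yaml.safe_load(source.read_text()))
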