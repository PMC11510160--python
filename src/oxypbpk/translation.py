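"""Reverse translation of in vivo clearances to per-enzyme intrinsic clearances.

The chain starts from a compound's in vivo elimination half-life and
steady-state volume of distribution, derives the systemic (IV) clearance,
inverts the well-stirred liver model to obtain the whole-liver unbound
metabolic intrinsic clearance CLmet,H, splits it across enzymatic pathways by
their fractions metabolized (fm), and scales each pathway down to microsomal
units (µL/min/pmol enzyme, or µL/min/mg microsomal protein for the aggregate
HLM pathway).  The same relations run forward turn per-enzyme intrinsic
clearances back into hepatic clearance, which is how the dynamic model and the
retrograde genotype calculation use them.

All functions are pure and operate in the package's internal units
(h, L, mg, pmol); see :mod:`oxypbpk.params`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from scipy.optimize import brentq

from .params import (
    PER_PMOL_SCALE,
    CompoundParams,
    PathwayClearance,
    SystemPhysiology,
    scaled_liver_clint,
)

__all__ = [
    "cliv_from_halflife",
    "whole_liver_intrinsic_from_iv",
    "forward_wellstirred",
    "split_pathway",
    "per_enzyme_intrinsic",
    "per_mg_intrinsic",
    "sibling_isoform_clint",
    "fm_from_clint",
    "TranslationResult",
    "reverse_translate",
    "genotype_retrograde_abundance",
    "midazolam_like_probe",
]

LN2 = 0.693  # the conventional rounding used in half-life/clearance relations


def cliv_from_halflife(t_half: float, vss: float, weight: float) -> float:
    """Systemic IV clearance (L/h) from elimination half-life.

    CLiv = 0.693 × Vss × W / t1/2, with ``t_half`` in hours, ``vss`` in L/kg
    and ``weight`` in kg.
    """
    if t_half <= 0 or vss <= 0 or weight <= 0:
        raise ValueError("t_half, vss and weight must all be positive")
    return LN2 * vss * weight / t_half


def whole_liver_intrinsic_from_iv(
    cliv: float, q_h: float, fu_plasma: float, blood_to_plasma: float
) -> float:
    """Invert the well-stirred liver model: CLmet,H (L/h) from CLiv.

    CLmet,H = QH × CLiv / (fup × (QH − CLiv / (B/P))).  The inversion is only
    physical while the blood clearance CLiv/(B/P) stays below hepatic blood
    flow.
    """
    if cliv < 0:
        raise ValueError("cliv must be >= 0")
    if q_h <= 0 or fu_plasma <= 0 or blood_to_plasma <= 0:
        raise ValueError("q_h, fu_plasma and blood_to_plasma must be positive")
    cl_blood = cliv / blood_to_plasma
    if cl_blood >= q_h:
        raise ValueError(
            f"blood clearance {cl_blood:.4g} L/h >= hepatic blood flow {q_h:.4g} L/h; "
            "the well-stirred inversion has no physical solution"
        )
    return q_h * cliv / (fu_plasma * (q_h - cl_blood))


def forward_wellstirred(
    cl_uint_total: float, q_h: float, fu_plasma: float, blood_to_plasma: float
) -> float:
    """Hepatic (plasma) clearance from total unbound intrinsic clearance.

    CL_H = QH × fup × CLuint / (QH + fup × CLuint / (B/P)); exact inverse of
    :func:`whole_liver_intrinsic_from_iv`, approaching flow-limited clearance
    QH × B/P as CLuint → ∞.
    """
    if cl_uint_total < 0:
        raise ValueError("cl_uint_total must be >= 0")
    if q_h <= 0 or fu_plasma <= 0 or blood_to_plasma <= 0:
        raise ValueError("q_h, fu_plasma and blood_to_plasma must be positive")
    num = q_h * fu_plasma * cl_uint_total
    return num / (q_h + fu_plasma * cl_uint_total / blood_to_plasma)


def split_pathway(clmet_h: float, fm: float) -> float:
    """Pathway-specific whole-liver clearance: fm × CLmet,H."""
    if not 0.0 <= fm <= 1.0:
        raise ValueError(f"fm must be in [0, 1], got {fm}")
    return fm * clmet_h


def per_enzyme_intrinsic(
    clmet_pathway: float, phys: SystemPhysiology, enzyme: str
) -> float:
    """Per-pmol intrinsic clearance (µL/min/pmol) from pathway liver clearance.

    CLint,u = CLmet,pathway / (liver weight × MPPGL × abundance) × 10^6/60.
    """
    abundance = phys.abundances.get(enzyme)
    if abundance is None:
        raise KeyError(f"physiology has no abundance for enzyme {enzyme!r}")
    if abundance <= 0:
        raise ValueError(f"abundance for {enzyme} must be > 0 to back-scale clint")
    return clmet_pathway / (phys.microsomal_protein() * abundance * PER_PMOL_SCALE)


def per_mg_intrinsic(cl_hlm: float, phys: SystemPhysiology) -> float:
    """Per-mg microsomal intrinsic clearance (µL/min/mg) of the HLM pathway."""
    if cl_hlm < 0:
        raise ValueError("cl_hlm must be >= 0")
    return cl_hlm / (phys.microsomal_protein() * PER_PMOL_SCALE)


def sibling_isoform_clint(
    clint_3a4: float, pct_3a5: float, pct_3a7: float
) -> tuple[float, float, float]:
    """Distribute an optimized CYP3A4 CLint across the CYP3A family.

    The optimized CYP3A4 value is taken as (1 − %3A5 − %3A7) of the total
    CYP3A intrinsic clearance; returns (total, CYP3A5, CYP3A7) in the same
    per-pmol units.
    """
    pct = pct_3a5 + pct_3a7
    if pct >= 100.0:
        raise ValueError("sibling percentages must sum to < 100")
    if pct_3a5 < 0 or pct_3a7 < 0:
        raise ValueError("percentages must be >= 0")
    total = clint_3a4 / (1.0 - pct / 100.0)
    return total, total * pct_3a5 / 100.0, total * pct_3a7 / 100.0


def fm_from_clint(
    clint: float, phys: SystemPhysiology, enzyme: str, clmet_h: float
) -> float:
    """Back-calculate a pathway's fraction metabolized from its per-pmol CLint."""
    if clmet_h <= 0:
        raise ValueError("clmet_h must be > 0")
    pathway = PathwayClearance(enzyme=enzyme, clint=clint, basis="per_pmol")
    fm = scaled_liver_clint(pathway, phys) / clmet_h
    if fm > 1.0 + 1e-9:
        raise ValueError(
            f"back-calculated fm {fm:.4g} > 1; pathway clint and CLmet,H are inconsistent"
        )
    return fm


@dataclass
class TranslationResult:
    """Output of the full reverse-translation chain for one compound."""

    cliv: float  # L/h
    clmet_h: float  # L/h
    per_pathway_clmet: dict[str, float] = field(default_factory=dict)  # L/h
    per_pathway_clint: dict[str, float] = field(default_factory=dict)  # µL/min/pmol or µL/min/mg
    fm: dict[str, float] = field(default_factory=dict)


def reverse_translate(
    *,
    t_half: float,
    vss: float,
    weight: float,
    q_h: float,
    fu_plasma: float,
    blood_to_plasma: float,
    fm_map: Mapping[str, float],
    phys: SystemPhysiology,
) -> TranslationResult:
    """Run the full chain: half-life → CLiv → CLmet,H → per-pathway CLint.

    ``fm_map`` assigns fractions metabolized to named enzymes (per-pmol
    pathways); whatever fraction is left over is attributed to the aggregate
    HLM pathway, fm_HLM = 1 − Σ fm.
    """
    fm_sum = sum(fm_map.values())
    if any(not 0.0 <= f <= 1.0 for f in fm_map.values()) or fm_sum > 1.0 + 1e-9:
        raise ValueError("fm values must lie in [0, 1] and sum to <= 1")
    cliv = cliv_from_halflife(t_half, vss, weight)
    clmet_h = whole_liver_intrinsic_from_iv(cliv, q_h, fu_plasma, blood_to_plasma)

    per_clmet: dict[str, float] = {}
    per_clint: dict[str, float] = {}
    fm_out: dict[str, float] = dict(fm_map)
    for enzyme, fm in fm_map.items():
        cl_path = split_pathway(clmet_h, fm)
        per_clmet[enzyme] = cl_path
        per_clint[enzyme] = per_enzyme_intrinsic(cl_path, phys, enzyme)
    fm_hlm = 1.0 - fm_sum
    cl_hlm = split_pathway(clmet_h, fm_hlm)
    per_clmet["HLM"] = cl_hlm
    per_clint["HLM"] = per_mg_intrinsic(cl_hlm, phys)
    fm_out["HLM"] = fm_hlm
    return TranslationResult(
        cliv=cliv,
        clmet_h=clmet_h,
        per_pathway_clmet=per_clmet,
        per_pathway_clint=per_clint,
        fm=fm_out,
    )


def midazolam_like_probe() -> CompoundParams:
    """Default CYP3A probe substrate for the retrograde genotype calculation.

    A midazolam-like compound cleared by CYP3A4 and CYP3A5.  The intrinsic
    clearances (0.3 and 0.076 µL/min/pmol) give a CYP3A4 share of ≈0.84 of the
    hepatic metabolic clearance and moderate hepatic extraction at the
    reference physiology (CYP3A4 137, CYP3A5 103 pmol/mg), which recovers the
    published genotype abundances from the stated 20%/50% clearance
    reductions.
    """
    return CompoundParams(
        name="cyp3a-probe",
        molecular_weight=325.8,
        logP=3.9,
        blood_to_plasma=0.66,
        fu_plasma=0.03,
        vss=1.0,
        kp_liver=1.0,
        binding_protein="albumin",
        pathways=(
            PathwayClearance(enzyme="CYP3A4", clint=0.3, basis="per_pmol"),
            PathwayClearance(enzyme="CYP3A5", clint=0.076, basis="per_pmol"),
        ),
    )


def _probe_hepatic_clearance(
    probe: CompoundParams, phys: SystemPhysiology, cyp3a4_abundance: float
) -> float:
    abundances = dict(phys.abundances)
    abundances["CYP3A4"] = cyp3a4_abundance
    phys_a = phys.model_copy(update={"abundances": abundances})
    cl_uint = sum(scaled_liver_clint(p, phys_a) for p in probe.pathways)
    return forward_wellstirred(
        cl_uint, phys.hepatic_blood_flow, probe.fu_plasma, probe.blood_to_plasma
    )


def genotype_retrograde_abundance(
    baseline_abundance: float,
    fractional_cl_reduction: float,
    probe: CompoundParams | None = None,
    phys: SystemPhysiology | None = None,
) -> float:
    """CYP3A4 abundance consistent with a reduced probe hepatic clearance.

    Mirrors the retrograde genotype procedure: the hepatic clearance of a
    CYP3A4/CYP3A5 probe substrate, computed through the forward well-stirred
    model, is lowered by ``fractional_cl_reduction`` while CYP3A5 abundance
    and all other scalars stay fixed, and the CYP3A4 abundance producing that
    reduced clearance is solved for.  Raises if CYP3A4's share of the probe's
    clearance is smaller than the requested reduction (no solution in
    ``(0, baseline_abundance)``).
    """
    if not 0.0 < fractional_cl_reduction < 1.0:
        raise ValueError("fractional_cl_reduction must be in (0, 1)")
    if baseline_abundance <= 0:
        raise ValueError("baseline_abundance must be > 0")
    if probe is None:
        probe = midazolam_like_probe()
    if probe.pathway("CYP3A4") is None:
        raise ValueError("probe must have a CYP3A4 pathway")
    if phys is None:
        from .params import default_config

        base = default_config().physiology
        abundances = dict(base.abundances)
        abundances["CYP3A5"] = 103.0  # reference expresser abundance for the probe
        phys = base.model_copy(update={"abundances": abundances})

    cl_base = _probe_hepatic_clearance(probe, phys, baseline_abundance)
    target = (1.0 - fractional_cl_reduction) * cl_base

    def objective(a: float) -> float:
        return _probe_hepatic_clearance(probe, phys, a) - target

    lo = 1e-9 * baseline_abundance
    if objective(lo) > 0.0:
        raise ValueError(
            "requested clearance reduction exceeds CYP3A4's share of the probe's "
            "hepatic clearance; no abundance in (0, baseline) achieves it"
        )
    return float(brentq(objective, lo, baseline_abundance, xtol=1e-12, rtol=1e-12))
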