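"""Minimal-PBPK simulation of a parent/metabolite pair with inducible CYP3A.

Model topology
--------------
Each analyte occupies a single well-mixed systemic compartment of volume
Vss × body weight; elimination is hepatic, through the well-stirred liver
model driven by the sum of the compound's scaled pathway intrinsic
clearances.  Competing pathways share the extraction in proportion to their
scaled CLint, and the CYP3A share of the parent's elimination forms the
metabolite (with molecular-weight mass conversion).  The liver is not a
separate kinetic compartment; liver concentrations are reported through the
tissue:plasma partition coefficient K_p.

CYP3A activity is a single relative level E(t) (1 at baseline) obeying
first-order turnover dE/dt = kdeg (F(t) − E) toward the instantaneous
induction fold F(t) = 1 + (Indmax − 1)·Cu/(IndC50 + Cu) of the unbound liver
perpetrator exposure.  Competitive inhibition instead divides the CYP3A
intrinsic clearances by (1 + Cu/Ki) with no turnover lag.  CYP27A1 and the
aggregate HLM pathway are never induced.

For a constant infusion with constant enzyme levels the steady state has a
closed form (:func:`analytic_steady_state`); the ODE integrator
(:func:`simulate`) must agree with it, which is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .params import (
    CYP3A_FAMILY,
    CompoundParams,
    DoseRegimen,
    InteractionSpec,
    PerpetratorPK,
    SystemPhysiology,
    scaled_liver_clint,
)
from .translation import forward_wellstirred

__all__ = [
    "induction_fold",
    "enzyme_turnover_rhs",
    "inhibited_clint",
    "SteadyState",
    "analytic_steady_state",
    "Perturbation",
    "SimulationOutput",
    "simulate",
    "ddi_ratio",
    "post_perturbation_halflife",
]

_CYP3A = frozenset(CYP3A_FAMILY)


def induction_fold(c_unbound_liver: float, ind_max: float, ind_c50: float) -> float:
    """Emax-type induction fold, 1 + (Indmax − 1)·C/(IndC50 + C).

    Monotone nondecreasing in the unbound liver concentration (µM), equal to
    1 with no perpetrator and bounded above by ``ind_max``.
    """
    if c_unbound_liver < 0:
        raise ValueError("concentration must be >= 0")
    if ind_max < 1 or ind_c50 <= 0:
        raise ValueError("ind_max must be >= 1 and ind_c50 > 0")
    return 1.0 + (ind_max - 1.0) * c_unbound_liver / (ind_c50 + c_unbound_liver)


def enzyme_turnover_rhs(e_level: float, fold_signal: float, kdeg: float) -> float:
    """dE/dt for first-order enzyme turnover toward the induction signal."""
    if e_level < 0:
        raise ValueError("enzyme level must be >= 0")
    return kdeg * (fold_signal - e_level)


def inhibited_clint(clint: float, c_unbound_liver: float, ki: float) -> float:
    """Competitively inhibited intrinsic clearance, clint / (1 + C/Ki)."""
    if ki <= 0:
        raise ValueError("ki must be > 0")
    return clint / (1.0 + c_unbound_liver / ki)


def _pathway_clearances(
    compound: CompoundParams,
    phys: SystemPhysiology,
    enzyme_fold: float | Mapping[str, float] = 1.0,
) -> dict[str, float]:
    """Scaled whole-liver pathway clearances (L/h) with CYP3A activity folds applied."""
    out: dict[str, float] = {}
    for p in compound.pathways:
        cl = scaled_liver_clint(p, phys)
        if p.enzyme in _CYP3A:
            if isinstance(enzyme_fold, Mapping):
                cl *= enzyme_fold.get(p.enzyme, 1.0)
            else:
                cl *= enzyme_fold
        out[p.enzyme] = cl
    return out


@dataclass
class SteadyState:
    """Closed-form steady state of the infused parent/metabolite pair."""

    css_parent_mg_ml: float
    css_metabolite_ng_ml: float
    liver_parent_mg_ml: float
    liver_metabolite_ng_ml: float
    cl_h_parent: float  # L/h, plasma-referenced hepatic clearance
    cl_h_metabolite: float
    cyp3a_formation_share: float  # fraction of parent elimination forming metabolite
    formation_rate: float  # mg/h of metabolite


def analytic_steady_state(
    parent: CompoundParams,
    metabolite: CompoundParams,
    phys: SystemPhysiology,
    infusion_rate: float,
    enzyme_fold: float | Mapping[str, float] = 1.0,
) -> SteadyState:
    """Steady state under a constant parent infusion (mg/h) and fixed CYP3A fold.

    Css,parent = rate / CL_H(parent); the metabolite forms at the parent
    elimination rate times the CYP3A CLint share (mass-converted by the MW
    ratio) and clears through its own hepatic clearance.
    """
    if infusion_rate <= 0:
        raise ValueError("infusion_rate must be > 0")
    cls_p = _pathway_clearances(parent, phys, enzyme_fold)
    cl_uint_p = sum(cls_p.values())
    if cl_uint_p <= 0:
        raise ValueError(f"compound {parent.name!r} has zero total intrinsic clearance")
    q_h = phys.hepatic_blood_flow
    cl_h_p = forward_wellstirred(cl_uint_p, q_h, parent.fu_plasma, parent.blood_to_plasma)
    css_p = infusion_rate / cl_h_p  # mg/L plasma

    share = sum(cl for enz, cl in cls_p.items() if enz in _CYP3A) / cl_uint_p
    formation = infusion_rate * share * metabolite.molecular_weight / parent.molecular_weight

    cls_m = _pathway_clearances(metabolite, phys, enzyme_fold)
    cl_uint_m = sum(cls_m.values())
    if cl_uint_m <= 0:
        raise ValueError(f"compound {metabolite.name!r} has zero total intrinsic clearance")
    cl_h_m = forward_wellstirred(cl_uint_m, q_h, metabolite.fu_plasma, metabolite.blood_to_plasma)
    css_m = formation / cl_h_m  # mg/L plasma

    return SteadyState(
        css_parent_mg_ml=css_p / 1000.0,
        css_metabolite_ng_ml=css_m * 1000.0,
        liver_parent_mg_ml=parent.kp_liver * css_p / 1000.0,
        liver_metabolite_ng_ml=metabolite.kp_liver * css_m * 1000.0,
        cl_h_parent=cl_h_p,
        cl_h_metabolite=cl_h_m,
        cyp3a_formation_share=share,
        formation_rate=formation,
    )


@dataclass
class Perturbation:
    """A perpetrator exposure window acting on the CYP3A pathways.

    ``mode`` selects how the unbound liver exposure is produced:

    - ``"oral"``: one-compartment first-order absorption PK of repeated oral
      doses (``dose_mg`` every ``interval_h``) using ``pk``;
    - ``"constant"``: a held unbound liver concentration ``conc_unbound_um``;
    - ``"fold"``: the induction signal itself is imposed directly (bypassing
      the concentration–fold relation), useful for step-response analyses.
    """

    spec: InteractionSpec
    start_day: float
    duration_days: float
    mode: Literal["oral", "constant", "fold"] = "constant"
    conc_unbound_um: float = 0.0
    fold: float = 1.0
    pk: PerpetratorPK | None = None
    dose_mg: float = 0.0
    interval_h: float = 24.0

    @property
    def start_h(self) -> float:
        return self.start_day * 24.0

    @property
    def end_h(self) -> float:
        return (self.start_day + self.duration_days) * 24.0


@dataclass
class SimulationOutput:
    """Trajectories and steady-state summaries for one subject."""

    time_h: np.ndarray
    plasma_parent_mg_l: np.ndarray
    plasma_metabolite_ng_ml: np.ndarray
    liver_parent_mg_l: np.ndarray
    liver_metabolite_ng_ml: np.ndarray
    enzyme_level: np.ndarray
    perpetrator_plasma_mg_l: np.ndarray
    cum_infused_mg: np.ndarray
    cum_eliminated_parent_mg: np.ndarray
    cum_formed_metabolite_mg: np.ndarray
    cum_eliminated_metabolite_mg: np.ndarray
    css_parent_mg_ml: float
    css_metabolite_ng_ml: float
    css_window_h: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def window_mean(self, t0: float, t1: float, series: str = "metabolite") -> float:
        """Mean of a plasma trajectory over the time window [t0, t1] hours."""
        if t0 < self.time_h[0] - 1e-9 or t1 > self.time_h[-1] + 1e-9 or t1 <= t0:
            raise ValueError(
                f"window ({t0}, {t1}) h outside simulated range "
                f"({self.time_h[0]}, {self.time_h[-1]}) h"
            )
        mask = (self.time_h >= t0) & (self.time_h <= t1)
        values = (
            self.plasma_metabolite_ng_ml if series == "metabolite" else self.plasma_parent_mg_l
        )
        return float(np.mean(values[mask]))


def _dose_times(pert: Perturbation) -> np.ndarray:
    n = int(np.floor(pert.duration_days * 24.0 / pert.interval_h + 1e-9))
    return pert.start_h + pert.interval_h * np.arange(max(n, 1))


def simulate(
    phys: SystemPhysiology,
    parent: CompoundParams,
    metabolite: CompoundParams,
    infusion: DoseRegimen,
    duration_days: float,
    perturbation: Perturbation | None = None,
    *,
    kdeg: float = 0.0193,
    init: Literal["zero", "steady_state"] = "zero",
    n_output: int = 1500,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    css_window_days: float = 30.0,
) -> SimulationOutput:
    """Integrate the coupled parent/metabolite/enzyme/perpetrator ODEs.

    The endogenous regimen must be an IV infusion in mg/kg/day; it is applied
    as a continuous constant-rate input over its active window.  With
    ``init="steady_state"`` the analyte amounts start at the analytic baseline
    steady state (warm start), which is exact for the linear baseline system.
    Deterministic for a fixed subject.
    """
    if infusion.route != "iv_infusion":
        raise ValueError("the endogenous regimen must be an iv_infusion")
    t_end = duration_days * 24.0
    if infusion.start_day * 24.0 >= t_end:
        raise ValueError("simulation duration does not cover the infusion")
    if perturbation is not None and perturbation.end_h > t_end + 1e-9:
        raise ValueError("simulation duration does not cover the perturbation window")

    rate = infusion.dose * phys.body_weight / 24.0  # mg/h while active
    inf_start = infusion.start_day * 24.0
    inf_end = min((infusion.start_day + infusion.duration_days) * 24.0, t_end)

    v_p = parent.vss * phys.body_weight
    v_m = metabolite.vss * phys.body_weight
    mw_ratio = metabolite.molecular_weight / parent.molecular_weight

    base_p = _pathway_clearances(parent, phys)
    base_m = _pathway_clearances(metabolite, phys)
    cl3a_p = sum(cl for e, cl in base_p.items() if e in _CYP3A)
    clother_p = sum(cl for e, cl in base_p.items() if e not in _CYP3A)
    cl3a_m = sum(cl for e, cl in base_m.items() if e in _CYP3A)
    clother_m = sum(cl for e, cl in base_m.items() if e not in _CYP3A)
    q_h = phys.hepatic_blood_flow

    pert = perturbation
    induction = pert is not None and pert.spec.mechanism == "induction"
    inhibition = pert is not None and pert.spec.mechanism == "competitive_inhibition"

    def perp_conc_um(a_central: float) -> float:
        if pert is None or pert.mode == "fold":
            return 0.0
        if pert.mode == "constant":
            return pert.conc_unbound_um
        pk = pert.pk
        c_plasma = a_central / pk.v_f  # mg/L
        return pk.fu * pk.kp_liver * c_plasma / pk.molecular_weight * 1000.0  # µM

    def fold_signal(t: float, a_central: float) -> float:
        if pert is None or not induction:
            return 1.0
        if not (pert.start_h <= t <= pert.end_h):
            return 1.0
        if pert.mode == "fold":
            return pert.fold
        return induction_fold(perp_conc_um(a_central), pert.spec.ind_max, pert.spec.ind_c50)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        a_p, a_m, e_level, a_gut, a_cent = y[:5]
        in_rate = rate if inf_start <= t <= inf_end else 0.0

        factor = e_level
        if inhibition and pert.start_h <= t <= pert.end_h:
            cu = perp_conc_um(a_cent)
            factor = e_level / (1.0 + cu / pert.spec.ki)

        cl3a_p_t = cl3a_p * factor
        cl_uint_p = cl3a_p_t + clother_p
        cl_h_p = forward_wellstirred(cl_uint_p, q_h, parent.fu_plasma, parent.blood_to_plasma)
        c_p = a_p / v_p
        elim_p = cl_h_p * c_p
        share = cl3a_p_t / cl_uint_p if cl_uint_p > 0 else 0.0
        form_m = elim_p * share * mw_ratio

        cl3a_m_t = cl3a_m * factor
        cl_uint_m = cl3a_m_t + clother_m
        cl_h_m = forward_wellstirred(
            cl_uint_m, q_h, metabolite.fu_plasma, metabolite.blood_to_plasma
        )
        c_m = a_m / v_m
        elim_m = cl_h_m * c_m

        de = enzyme_turnover_rhs(e_level, fold_signal(t, a_cent), kdeg)

        if pert is not None and pert.mode == "oral" and pert.pk is not None:
            da_gut = -pert.pk.ka * a_gut
            da_cent = pert.pk.ka * a_gut - (pert.pk.cl_f / pert.pk.v_f) * a_cent
        else:
            da_gut = 0.0
            da_cent = 0.0

        return np.array(
            [in_rate - elim_p, form_m - elim_m, de, da_gut, da_cent, elim_p, form_m, elim_m]
        )

    y0 = np.zeros(8)
    y0[2] = 1.0
    if init == "steady_state":
        ss = analytic_steady_state(parent, metabolite, phys, rate)
        y0[0] = ss.css_parent_mg_ml * 1000.0 * v_p
        y0[1] = ss.css_metabolite_ng_ml / 1000.0 * v_m

    # Integration breakpoints: infusion edges, perturbation edges, oral doses.
    breaks = {0.0, t_end, inf_start, inf_end}
    dose_events: list[float] = []
    if pert is not None:
        breaks.update({pert.start_h, pert.end_h})
        if pert.mode == "oral":
            dose_events = [t for t in _dose_times(pert) if t < t_end]
            breaks.update(dose_events)
    t_breaks = sorted(b for b in breaks if 0.0 <= b <= t_end)
    dose_set = set(dose_events)

    grid = np.linspace(0.0, t_end, n_output)
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y = y0.copy()
    for t0, t1 in zip(t_breaks[:-1], t_breaks[1:]):
        if t0 in dose_set:
            y = y.copy()
            y[3] += pert.dose_mg
        if t1 - t0 < 1e-12:
            continue
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        t_eval = np.unique(np.concatenate([[t0], t_eval, [t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{t0}, {t1}] h: {sol.message}")
        times.append(sol.t)
        states.append(sol.y)
        y = sol.y[:, -1]

    t = np.concatenate(times)
    ys = np.concatenate(states, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t, ys = t[keep], ys[:, keep]

    c_p = ys[0] / v_p  # mg/L
    c_m = ys[1] / v_m * 1000.0  # ng/mL
    perp_c = ys[4] / pert.pk.v_f if (pert is not None and pert.pk is not None) else np.zeros_like(t)
    cum_in = rate * (np.clip(t, inf_start, inf_end) - inf_start)

    if pert is not None:
        w1 = pert.start_h
    else:
        w1 = t_end
    w0 = max(0.0, w1 - css_window_days * 24.0)
    if w1 <= w0:
        w0, w1 = 0.0, t_end
    mask = (t >= w0) & (t <= w1)
    css_p = float(np.mean(c_p[mask])) / 1000.0  # mg/mL
    css_m = float(np.mean(c_m[mask]))  # ng/mL

    return SimulationOutput(
        time_h=t,
        plasma_parent_mg_l=c_p,
        plasma_metabolite_ng_ml=c_m,
        liver_parent_mg_l=c_p * parent.kp_liver,
        liver_metabolite_ng_ml=c_m * metabolite.kp_liver,
        enzyme_level=ys[2],
        perpetrator_plasma_mg_l=perp_c,
        cum_infused_mg=cum_in,
        cum_eliminated_parent_mg=ys[5],
        cum_formed_metabolite_mg=ys[6],
        cum_eliminated_metabolite_mg=ys[7],
        css_parent_mg_ml=css_p,
        css_metabolite_ng_ml=css_m,
        css_window_h=(w0, w1),
        meta={"duration_days": duration_days, "init": init, "kdeg": kdeg},
    )


def ddi_ratio(
    output_baseline: SimulationOutput,
    output_perturbed: SimulationOutput,
    window: tuple[float, float],
) -> float:
    """Ratio of window-mean metabolite concentrations, perturbed / baseline."""
    base = output_baseline.window_mean(*window)
    pert = output_perturbed.window_mean(*window)
    if base <= 0:
        raise ValueError("baseline window mean is not positive")
    return pert / base


def post_perturbation_halflife(output: SimulationOutput, window_start_h: float) -> float:
    """Apparent half-life (h) of the metabolite's approach to its new steady state.

    Log-linear regression of |C(t) − C_new| on the segment after
    ``window_start_h``; the final simulated concentration is taken as the new
    steady state, so the fit captures the dominant (slowest) eigen-phase.
    Raises on flat or non-monotone segments.
    """
    mask = output.time_h >= window_start_h
    t = output.time_h[mask]
    c = output.plasma_metabolite_ng_ml[mask]
    if t.size < 4:
        raise ValueError("too few points after window_start_h")
    c_scale = max(np.abs(c).max(), 1e-30)
    if np.ptp(c) <= 1e-9 * c_scale:
        raise ValueError("profile is flat after window_start_h; no relaxation to fit")
    if np.any(np.diff(c) > 1e-6 * np.ptp(c)) and np.any(np.diff(c) < -1e-6 * np.ptp(c)):
        raise ValueError("segment after window_start_h is not monotone")
    # Lagged differences d(t) = C(t) − C(t + Δ) cancel the unknown asymptote:
    # for a single exponential phase, log|d| is exactly linear in t.
    n = 400
    t_u = np.linspace(t[0], t[-1], n)
    c_u = np.interp(t_u, t, c)
    lag = n // 4
    d = np.abs(c_u[:-lag] - c_u[lag:])
    d_scale = d.max()
    if d_scale <= 1e-12 * c_scale:
        raise ValueError("profile is flat after window_start_h; no relaxation to fit")
    # Fit the tail (dominant, slowest eigen-phase), clear of the numeric floor.
    ok = (d > 1e-4 * d_scale) & (d <= 0.5 * d_scale)
    if ok.sum() < 4:
        ok = d > 1e-4 * d_scale
    if ok.sum() < 4:
        raise ValueError("too few usable points for the log-linear fit")
    fit = linregress(t_u[:-lag][ok], np.log(d[ok]))
    if fit.slope >= 0:
        raise ValueError("no decaying phase found after window_start_h")
    return float(np.log(2.0) / -fit.slope)
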