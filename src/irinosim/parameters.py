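"""Parameter containers and hybrid <-> elementary conversions.

The hepatic handling of a compound is described either by *elementary*
clearances — sinusoidal active uptake ``PS_act_inf_h``, passive influx/efflux
``PS_dif_inf_h = PS_dif_eff_h``, metabolic clearance ``CL_met_h`` and biliary
excretion ``CL_bile`` — or by the identifiable *hybrid* combinations of the
extended clearance concept:

    CL_int_all = (PS_act_inf_h + PS_dif_inf_h) * (CL_met_h + CL_bile)
                 / (PS_dif_eff_h + CL_met_h + CL_bile)
    R_dif_h    = PS_dif_inf_h / PS_act_inf_h
    beta       = (CL_met_h + CL_bile) / (PS_dif_eff_h + CL_met_h + CL_bile)
    f_bile     = CL_bile / (CL_met_h + CL_bile)

On the intestinal side the apical membrane carries both passive diffusion
(the basolateral passive clearance scaled by the apical/basolateral area
ratio AR = 20) and active efflux; their ratio is the hybrid

    R_dif_ent  = AR * PS_dif_eff_ent / PS_act_eff_ent

Both directions of the conversion are closed-form and are exact inverses of
one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .compounds import COMPOUND_NAMES

__all__ = [
    "AREA_RATIO",
    "HybridParameters",
    "ElementaryParameters",
    "PhysiologyParameters",
    "CompoundDisposition",
    "PBPKParameterSet",
    "hybrid_to_elementary",
    "elementary_to_hybrid",
    "apical_efflux",
    "ParameterDomainError",
    "BetaAtUpperLimitError",
]

#: apical/basolateral membrane area ratio of enterocytes
AREA_RATIO = 20.0


class ParameterDomainError(ValueError):
    """A parameter value is outside its physical domain."""


class BetaAtUpperLimitError(ParameterDomainError):
    """beta = 1 (or PS_dif = 0) makes the hepatic split undetermined."""


@dataclass
class HybridParameters:
    """Identifiable hepatic (and apical-efflux) parameter combinations.

    Units: ``cl_int_all`` L/h/kg; the rest dimensionless.
    """

    cl_int_all: float
    r_dif_h: float
    beta: float
    f_bile: float
    r_dif_ent: float | None = None

    def validate(self) -> None:
        if self.cl_int_all <= 0:
            raise ParameterDomainError("CL_int_all must be positive")
        if self.r_dif_h < 0:
            raise ParameterDomainError("R_dif_h must be non-negative")
        if not (0.0 < self.beta <= 1.0):
            raise ParameterDomainError("beta must be in (0, 1]")
        if not (0.0 <= self.f_bile <= 1.0):
            raise ParameterDomainError("f_bile must be in [0, 1]")


@dataclass
class ElementaryParameters:
    """Elementary rate parameters of one compound's sub-model.

    Clearances and permeability-surface products are intrinsic values in
    L/h/kg body weight; first-order rate constants in /h.  ``cl_met_paths``
    maps a product name ("SN38", "NPC", "APC", "SN38G", "others") to its
    hepatic formation clearance; ``cl_met_ent_paths`` is the enterocyte
    analogue.
    """

    v_central: float  # L/kg, must exceed blood volume
    ps_act_inf_h: float = 0.0
    ps_dif_inf_h: float = 0.0
    ps_dif_eff_h: float = 0.0
    cl_bile: float = 0.0
    cl_met_paths: dict[str, float] = field(default_factory=dict)
    ps_dif_eff_ent: float = 0.0
    ps_dif_inf_ent: float = 0.0
    ps_act_eff_ent: float = 0.0
    cl_met_ent_paths: dict[str, float] = field(default_factory=dict)
    k_a: float = 0.0
    k_feces: float = 0.0
    k_bile: float = 0.0
    k_dec: float = 0.0  # luminal deconjugation, SN-38G only

    @property
    def cl_met_h(self) -> float:
        return sum(self.cl_met_paths.values())

    @property
    def cl_met_ent(self) -> float:
        return sum(self.cl_met_ent_paths.values())

    def validate(self) -> None:
        vals = [
            self.v_central, self.ps_act_inf_h, self.ps_dif_inf_h,
            self.ps_dif_eff_h, self.cl_bile, self.ps_dif_eff_ent,
            self.ps_dif_inf_ent, self.ps_act_eff_ent, self.k_a,
            self.k_feces, self.k_bile, self.k_dec,
        ]
        if any(v < 0 for v in vals) or self.v_central <= 0:
            raise ParameterDomainError("elementary parameters must be non-negative")
        if any(v < 0 for v in self.cl_met_paths.values()):
            raise ParameterDomainError("metabolic clearances must be non-negative")
        if not np.isclose(self.ps_dif_inf_h, self.ps_dif_eff_h, rtol=1e-9):
            raise ParameterDomainError("PS_dif_inf_h must equal PS_dif_eff_h")
        if not np.isclose(self.ps_dif_inf_ent, self.ps_dif_eff_ent, rtol=1e-9):
            raise ParameterDomainError("PS_dif_inf_ent must equal PS_dif_eff_ent")


def hybrid_to_elementary(h: HybridParameters) -> dict[str, float]:
    """Convert hybrid hepatic parameters to elementary clearances.

    Returns a dict with ``ps_act_inf_h``, ``ps_dif_inf_h`` (=``ps_dif_eff_h``),
    ``cl_met_h`` and ``cl_bile`` such that :func:`elementary_to_hybrid`
    recovers the input exactly.

    Raises
    ------
    BetaAtUpperLimitError
        if ``beta == 1`` while passive diffusion is non-zero (the metabolic +
        biliary clearance would be unbounded), or if ``ps_dif = 0`` with
        ``beta < 1`` (the split is undetermined).
    """
    h.validate()
    ps_total = h.cl_int_all / h.beta  # PS_act + PS_dif
    ps_dif = ps_total * h.r_dif_h / (1.0 + h.r_dif_h)
    ps_act = ps_total - ps_dif
    if h.beta >= 1.0:
        if ps_dif > 0:
            raise BetaAtUpperLimitError(
                "beta at upper limit: CL_met + CL_bile unbounded for PS_dif > 0"
            )
        # no passive efflux: beta = 1 identically, CL_int_all = CL_met + CL_bile
        cl_elim = h.cl_int_all
    else:
        if ps_dif == 0.0:
            raise BetaAtUpperLimitError(
                "PS_dif = 0 with beta < 1: CL_met + CL_bile undetermined"
            )
        cl_elim = ps_dif * h.beta / (1.0 - h.beta)
    cl_bile = h.f_bile * cl_elim
    return {
        "ps_act_inf_h": ps_act,
        "ps_dif_inf_h": ps_dif,
        "ps_dif_eff_h": ps_dif,
        "cl_met_h": cl_elim - cl_bile,
        "cl_bile": cl_bile,
    }


def elementary_to_hybrid(
    ps_act_inf_h: float,
    ps_dif_inf_h: float,
    cl_met_h: float,
    cl_bile: float,
) -> HybridParameters:
    """Exact inverse of :func:`hybrid_to_elementary` (hepatic part)."""
    if ps_act_inf_h <= 0:
        raise ParameterDomainError("R_dif_h undefined for PS_act_inf_h = 0")
    if min(ps_dif_inf_h, cl_met_h, cl_bile) < 0:
        raise ParameterDomainError("elementary clearances must be non-negative")
    cl_elim = cl_met_h + cl_bile
    if cl_elim <= 0:
        raise ParameterDomainError("CL_met_h + CL_bile must be positive")
    beta = cl_elim / (ps_dif_inf_h + cl_elim)
    cl_int_all = (ps_act_inf_h + ps_dif_inf_h) * beta
    return HybridParameters(
        cl_int_all=cl_int_all,
        r_dif_h=ps_dif_inf_h / ps_act_inf_h,
        beta=beta,
        f_bile=cl_bile / cl_elim,
    )


def apical_efflux(
    r_dif_ent: float, ps_dif_eff_ent: float, area_ratio: float = AREA_RATIO
) -> tuple[float, float]:
    """Split apical enterocyte efflux into passive and active components.

    Returns ``(PS_passive_apical, PS_act_eff_ent)`` where the passive apical
    clearance is ``AR * PS_dif_eff_ent`` and the active transporter clearance
    follows from ``R_dif_ent = AR * PS_dif_eff_ent / PS_act_eff_ent``.
    """
    if r_dif_ent <= 0:
        raise ParameterDomainError(
            "R_dif_ent must be positive for transporter substrates"
        )
    passive = area_ratio * ps_dif_eff_ent
    return passive, passive / r_dif_ent


@dataclass
class PhysiologyParameters:
    """Fixed anatomy: volumes (L/kg), blood flows (L/h/kg), splits.

    The liver is represented as five equal units in series (a tanks-in-series
    surrogate of the dispersion model), each split into an extrahepatic
    (sinusoidal blood) and a hepatocyte compartment.  Portal blood flow is
    segregated into a mucosal stream that perfuses the enterocytes and a
    serosal stream perfusing the gut serosa.  Three transit compartments
    carry biliary output to the intestinal lumen.
    """

    q_hepatic_artery: float = 0.31
    q_portal: float = 0.93
    mucosal_fraction: float = 0.8
    q_muscle: float = 0.64
    q_skin: float = 0.26
    q_adipose: float = 0.22
    v_muscle: float = 0.40
    v_skin: float = 0.11
    v_adipose: float = 0.19
    v_gut_serosa: float = 0.012
    v_mucosal_blood: float = 0.002
    v_liver_extrahepatic: float = 0.0065
    v_liver_hepatocyte: float = 0.0195
    v_enterocyte: float = 0.004
    n_liver_units: int = 5
    n_bile_transit: int = 3
    hematocrit: float = 0.45
    gfr: float = 0.09  # L/h/kg (~6.3 L/h at 70 kg)
    filtration_fraction: float = 0.2
    area_ratio: float = AREA_RATIO

    @property
    def q_liver(self) -> float:
        return self.q_hepatic_artery + self.q_portal

    @property
    def q_mucosa(self) -> float:
        return self.mucosal_fraction * self.q_portal

    @property
    def q_serosa(self) -> float:
        return (1.0 - self.mucosal_fraction) * self.q_portal


@dataclass
class CompoundDisposition:
    """Binding, partitioning and renal disposition of one compound."""

    f_p: float  # plasma unbound fraction
    f_b: float  # blood unbound fraction
    f_h: float  # hepatocyte unbound fraction
    f_gut: float  # enterocyte unbound fraction
    kp_muscle: float
    kp_skin: float
    kp_adipose: float
    kp_gut: float
    cl_r: float  # renal blood clearance, L/h (absolute, not per kg)

    def validate(self) -> None:
        for name in ("f_p", "f_b", "f_h", "f_gut"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0) and name != "f_b":
                raise ParameterDomainError(f"{name} must be in (0, 1]")
        if self.f_b <= 0:
            raise ParameterDomainError("f_b must be positive")
        if self.cl_r < 0:
            raise ParameterDomainError("CL_r must be non-negative")


@dataclass
class PBPKParameterSet:
    """Everything one whole-body simulation needs.

    ``elementary`` and ``disposition`` are keyed by compound name; per-kg
    clearances are scaled by ``body_weight`` inside the simulator.
    """

    elementary: dict[str, ElementaryParameters]
    disposition: dict[str, CompoundDisposition]
    physiology: PhysiologyParameters = field(default_factory=PhysiologyParameters)
    dose_mg_per_m2: float = 180.0
    infusion_duration_h: float = 1.5
    body_weight: float = 70.0  # kg
    body_surface_area: float = 1.85  # m^2

    def validate(self) -> None:
        missing = [c for c in COMPOUND_NAMES if c not in self.elementary]
        if missing:
            raise ParameterDomainError(f"missing elementary parameters: {missing}")
        missing = [c for c in COMPOUND_NAMES if c not in self.disposition]
        if missing:
            raise ParameterDomainError(f"missing disposition parameters: {missing}")
        for e in self.elementary.values():
            e.validate()
        for d in self.disposition.values():
            d.validate()
        if self.dose_mg_per_m2 < 0 or self.infusion_duration_h <= 0:
            raise ParameterDomainError("dose must be >= 0, infusion duration > 0")

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_m2 * self.body_surface_area

    def copy(self) -> "PBPKParameterSet":
        return PBPKParameterSet(
            elementary={
                k: replace(
                    v,
                    cl_met_paths=dict(v.cl_met_paths),
                    cl_met_ent_paths=dict(v.cl_met_ent_paths),
                )
                for k, v in self.elementary.items()
            },
            disposition={k: replace(v) for k, v in self.disposition.items()},
            physiology=replace(self.physiology),
            dose_mg_per_m2=self.dose_mg_per_m2,
            infusion_duration_h=self.infusion_duration_h,
            body_weight=self.body_weight,
            body_surface_area=self.body_surface_area,
        )
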