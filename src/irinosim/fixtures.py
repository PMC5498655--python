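"""Synthetic study inputs: search ranges, base parameter sets, genetics and
variability tables, and noisy reference profiles.

Everything the pipeline needs is generated here without downloads.  Two
provenance classes are mixed and clearly separated:

* the search ranges of the 46 unknown parameters and the genotype
  contribution fractions are the established values for this model class;
* allele frequencies, activity ratios, variability CVs/shapes, binding and
  fixed physiological values are package-chosen placeholders at
  literature-typical magnitudes (flagged ``placeholder`` in exports); a
  user holding calibrated tables can override them through the YAML
  interface without code changes.

The base ("truth") parameter set lies inside every search range and was
chosen so the simulated exposure ordering is qualitatively that of the
clinical profiles: irinotecan >> APC > SN-38G > SN-38 ~ NPC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnm import Bound, ParameterBounds
from .compounds import COMPOUND_NAMES
from .model import IrinotecanPBPK
from .parameters import (
    AREA_RATIO,
    CompoundDisposition,
    ElementaryParameters,
    HybridParameters,
    PBPKParameterSet,
    PhysiologyParameters,
    hybrid_to_elementary,
)
from .population import (
    DistributionSpec,
    body_surface_area as body_surface_area_of,
    GeneticsTable,
    LocusSpec,
    binding_fractions,
    renal_clearance,
)

__all__ = [
    "parameter_bounds",
    "vector_to_params",
    "params_to_vector",
    "default_fixture_tables",
    "FixtureTables",
    "ReferenceProfile",
    "make_reference_profile",
    "DEFAULT_SAMPLING_TIMES_H",
]

#: blood sampling grid of the synthetic reference study (h)
DEFAULT_SAMPLING_TIMES_H = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)


# ----------------------------------------------------------------------
# search-space definition
# ----------------------------------------------------------------------
def parameter_bounds() -> ParameterBounds:
    """The 46 unknown parameters with their initial ranges and theoretical
    lower limits.  Reciprocal quantities keep their conventional tabular
    form (1/beta, 1/f_bile, 1/f_glu, hepatic/enterocyte clearance ratios)."""
    b: list[Bound] = []

    def add(name, lo, hi, tl=0.0):
        b.append(Bound(name, lo, hi, tl))

    for c in COMPOUND_NAMES:
        add(f"V_central({c})", 0.075, 0.75, 0.074)
        add(f"k_a({c})", 0.06, 6.0)
        add(f"k_feces({c})", 0.06, 6.0)
        add(f"k_bile({c})", 0.06, 6.0)
    for c in ("SN38", "SN38G"):
        add(f"R_dif_h({c})", 0.01, 1.0)
    for c in ("SN38", "SN38G", "NPC", "APC"):
        add(f"1/beta({c})", 1.1, 10.0, 1.0)
        add(f"CL_int_all({c})", 0.1, 100.0)
    add("1/f_bile(NPC)", 1.1, 10.0, 1.0)
    for c in ("irinotecan", "SN38", "SN38G"):
        add(f"R_dif_ent({c})", 0.1, 10.0)
    add("PS_dif_inf_h(irinotecan)", 0.1, 100.0)
    add("CL_SN38_h(irinotecan)", 0.1, 100.0)
    add("CL_NPC_h(irinotecan)", 0.1, 100.0)
    add("CL_APC_h(irinotecan)", 0.1, 100.0)
    add("CL_others_h(irinotecan)", 0.1, 100.0)
    add("CL_bile(irinotecan)", 0.1, 100.0)
    add("PS_dif_eff_ent(irinotecan)", 0.1, 100.0)
    add("CL_SN38_h/ent(irinotecan)", 1.1, 10.0, 1.0)
    add("CL_NPC_h/ent(irinotecan)", 1.1, 10.0, 1.0)
    add("1/f_glu(SN38)", 1.1, 10.0, 1.0)
    add("CL_SN38G_h/ent(SN38)", 1.1, 10.0, 1.0)
    add("k_dec(SN38G)", 0.06, 6.0)
    assert len(b) == 46
    return ParameterBounds(b)


def vector_to_params(
    values: dict[str, float], template: PBPKParameterSet
) -> PBPKParameterSet:
    """Build a full parameter set from the 46 searched values.

    Disposition, physiology and regimen come from ``template``.  Hepatic
    hybrids are converted to elementary clearances; compounds without
    active uptake (irinotecan, NPC, APC) have ``PS_act_inf_h = 0`` so their
    overall intrinsic clearance factorizes as ``CL_int_all = PS_dif * beta``.
    Metabolites share irinotecan's basolateral enterocyte permeability.
    """
    v = values
    p = template.copy()
    ps_ent = v["PS_dif_eff_ent(irinotecan)"]

    def common(c: str) -> dict:
        return dict(
            v_central=v[f"V_central({c})"],
            k_a=v[f"k_a({c})"],
            k_feces=v[f"k_feces({c})"],
            k_bile=v[f"k_bile({c})"],
            ps_dif_eff_ent=ps_ent,
            ps_dif_inf_ent=ps_ent,
        )

    def act_eff(c: str) -> float:
        return AREA_RATIO * ps_ent / v[f"R_dif_ent({c})"]

    # irinotecan: elementary parameterization, no active hepatic uptake
    cl_sn38 = v["CL_SN38_h(irinotecan)"]
    cl_npc = v["CL_NPC_h(irinotecan)"]
    p.elementary["irinotecan"] = ElementaryParameters(
        ps_act_inf_h=0.0,
        ps_dif_inf_h=v["PS_dif_inf_h(irinotecan)"],
        ps_dif_eff_h=v["PS_dif_inf_h(irinotecan)"],
        cl_bile=v["CL_bile(irinotecan)"],
        cl_met_paths={
            "SN38": cl_sn38,
            "NPC": cl_npc,
            "APC": v["CL_APC_h(irinotecan)"],
            "others": v["CL_others_h(irinotecan)"],
        },
        ps_act_eff_ent=act_eff("irinotecan"),
        cl_met_ent_paths={
            "SN38": cl_sn38 / v["CL_SN38_h/ent(irinotecan)"],
            "NPC": cl_npc / v["CL_NPC_h/ent(irinotecan)"],
        },
        **common("irinotecan"),
    )

    # SN-38: hybrid hepatic parameters; f_bile = 1 - f_glu
    f_glu = 1.0 / v["1/f_glu(SN38)"]
    h = HybridParameters(
        cl_int_all=v["CL_int_all(SN38)"],
        r_dif_h=v["R_dif_h(SN38)"],
        beta=1.0 / v["1/beta(SN38)"],
        f_bile=1.0 - f_glu,
    )
    el = hybrid_to_elementary(h)
    cl_glu = el["cl_met_h"]
    p.elementary["SN38"] = ElementaryParameters(
        ps_act_inf_h=el["ps_act_inf_h"],
        ps_dif_inf_h=el["ps_dif_inf_h"],
        ps_dif_eff_h=el["ps_dif_eff_h"],
        cl_bile=el["cl_bile"],
        cl_met_paths={"SN38G": cl_glu},
        ps_act_eff_ent=act_eff("SN38"),
        cl_met_ent_paths={"SN38G": cl_glu / v["CL_SN38G_h/ent(SN38)"]},
        **common("SN38"),
    )

    # SN-38G: hybrid with f_bile fixed at 1 (no further metabolism)
    h = HybridParameters(
        cl_int_all=v["CL_int_all(SN38G)"],
        r_dif_h=v["R_dif_h(SN38G)"],
        beta=1.0 / v["1/beta(SN38G)"],
        f_bile=1.0,
    )
    el = hybrid_to_elementary(h)
    p.elementary["SN38G"] = ElementaryParameters(
        ps_act_inf_h=el["ps_act_inf_h"],
        ps_dif_inf_h=el["ps_dif_inf_h"],
        ps_dif_eff_h=el["ps_dif_eff_h"],
        cl_bile=el["cl_bile"],
        cl_met_paths={},
        ps_act_eff_ent=act_eff("SN38G"),
        k_dec=v["k_dec(SN38G)"],
        **common("SN38G"),
    )

    # NPC / APC: no transporters; CL_int_all = PS_dif * beta
    for c, f_bile in (("NPC", 1.0 / v["1/f_bile(NPC)"]), ("APC", 1.0)):
        beta = 1.0 / v[f"1/beta({c})"]
        ps_dif = v[f"CL_int_all({c})"] / beta
        cl_elim = v[f"CL_int_all({c})"] / (1.0 - beta)
        cl_bile = f_bile * cl_elim
        p.elementary[c] = ElementaryParameters(
            ps_act_inf_h=0.0,
            ps_dif_inf_h=ps_dif,
            ps_dif_eff_h=ps_dif,
            cl_bile=cl_bile,
            cl_met_paths={"others": cl_elim - cl_bile} if cl_elim > cl_bile else {},
            ps_act_eff_ent=0.0,
            **common(c),
        )
    return p


def params_to_vector(p: PBPKParameterSet) -> dict[str, float]:
    """Inverse of :func:`vector_to_params` for sets built by it."""
    out: dict[str, float] = {}
    for c in COMPOUND_NAMES:
        e = p.elementary[c]
        out[f"V_central({c})"] = e.v_central
        out[f"k_a({c})"] = e.k_a
        out[f"k_feces({c})"] = e.k_feces
        out[f"k_bile({c})"] = e.k_bile
    e = p.elementary["irinotecan"]
    out["PS_dif_inf_h(irinotecan)"] = e.ps_dif_inf_h
    out["CL_SN38_h(irinotecan)"] = e.cl_met_paths["SN38"]
    out["CL_NPC_h(irinotecan)"] = e.cl_met_paths["NPC"]
    out["CL_APC_h(irinotecan)"] = e.cl_met_paths["APC"]
    out["CL_others_h(irinotecan)"] = e.cl_met_paths["others"]
    out["CL_bile(irinotecan)"] = e.cl_bile
    out["PS_dif_eff_ent(irinotecan)"] = e.ps_dif_eff_ent
    out["CL_SN38_h/ent(irinotecan)"] = (
        e.cl_met_paths["SN38"] / e.cl_met_ent_paths["SN38"]
    )
    out["CL_NPC_h/ent(irinotecan)"] = e.cl_met_paths["NPC"] / e.cl_met_ent_paths["NPC"]
    out["R_dif_ent(irinotecan)"] = AREA_RATIO * e.ps_dif_eff_ent / e.ps_act_eff_ent
    for c in ("SN38", "SN38G"):
        e = p.elementary[c]
        cl_elim = e.cl_met_h + e.cl_bile
        beta = cl_elim / (e.ps_dif_eff_h + cl_elim)
        out[f"R_dif_h({c})"] = e.ps_dif_inf_h / e.ps_act_inf_h
        out[f"1/beta({c})"] = 1.0 / beta
        out[f"CL_int_all({c})"] = (e.ps_act_inf_h + e.ps_dif_inf_h) * beta
        out[f"R_dif_ent({c})"] = AREA_RATIO * e.ps_dif_eff_ent / e.ps_act_eff_ent
    e = p.elementary["SN38"]
    f_glu = e.cl_met_h / (e.cl_met_h + e.cl_bile)
    out["1/f_glu(SN38)"] = 1.0 / f_glu
    out["CL_SN38G_h/ent(SN38)"] = e.cl_met_paths["SN38G"] / e.cl_met_ent_paths["SN38G"]
    out["k_dec(SN38G)"] = p.elementary["SN38G"].k_dec
    for c in ("NPC", "APC"):
        e = p.elementary[c]
        cl_elim = e.cl_met_h + e.cl_bile
        beta = cl_elim / (e.ps_dif_eff_h + cl_elim)
        out[f"1/beta({c})"] = 1.0 / beta
        out[f"CL_int_all({c})"] = e.ps_dif_inf_h * beta
    out["1/f_bile(NPC)"] = (
        (p.elementary["NPC"].cl_met_h + p.elementary["NPC"].cl_bile)
        / p.elementary["NPC"].cl_bile
    )
    return out


# ----------------------------------------------------------------------
# fixture tables (placeholders flagged as such)
# ----------------------------------------------------------------------
# base values of the 46 searched parameters (inside every range)
_BASE_VECTOR = {
    "V_central(irinotecan)": 0.15, "k_a(irinotecan)": 0.3,
    "k_feces(irinotecan)": 0.6, "k_bile(irinotecan)": 1.0,
    "V_central(SN38)": 0.30, "k_a(SN38)": 0.15, "k_feces(SN38)": 0.6,
    "k_bile(SN38)": 1.0,
    "V_central(SN38G)": 0.15, "k_a(SN38G)": 0.1, "k_feces(SN38G)": 1.0,
    "k_bile(SN38G)": 1.0,
    "V_central(NPC)": 0.30, "k_a(NPC)": 0.3, "k_feces(NPC)": 0.6,
    "k_bile(NPC)": 1.0,
    "V_central(APC)": 0.20, "k_a(APC)": 0.3, "k_feces(APC)": 0.6,
    "k_bile(APC)": 1.0,
    "R_dif_h(SN38)": 0.2, "R_dif_h(SN38G)": 0.2,
    "1/beta(SN38)": 4.0, "1/beta(SN38G)": 3.0, "1/beta(NPC)": 2.0,
    "1/beta(APC)": 2.0,
    "CL_int_all(SN38)": 20.0, "CL_int_all(SN38G)": 0.8,
    "CL_int_all(NPC)": 0.6, "CL_int_all(APC)": 0.3,
    "1/f_bile(NPC)": 5.0,
    "R_dif_ent(irinotecan)": 1.0, "R_dif_ent(SN38)": 1.0,
    "R_dif_ent(SN38G)": 2.0,
    "PS_dif_inf_h(irinotecan)": 1.0,
    "CL_SN38_h(irinotecan)": 0.15, "CL_NPC_h(irinotecan)": 0.1,
    "CL_APC_h(irinotecan)": 0.5, "CL_others_h(irinotecan)": 0.8,
    "CL_bile(irinotecan)": 1.2,
    "PS_dif_eff_ent(irinotecan)": 1.5,
    "CL_SN38_h/ent(irinotecan)": 1.2, "CL_NPC_h/ent(irinotecan)": 4.0,
    "1/f_glu(SN38)": 1.18, "CL_SN38G_h/ent(SN38)": 6.0,
    "k_dec(SN38G)": 0.15,
}

# binding/partitioning placeholders per compound
_BINDING = {
    # n[Pt]/Kd implies f_p = 1/(1+x); f_r is the blood-cell unbound fraction
    "irinotecan": {"n_pt_over_kd": 1.857, "f_r": 0.5},
    "SN38": {"n_pt_over_kd": 49.0, "f_r": 0.1},
    "SN38G": {"n_pt_over_kd": 5.667, "f_r": None},
    "NPC": {"n_pt_over_kd": 2.333, "f_r": 0.5},
    "APC": {"n_pt_over_kd": 2.333, "f_r": 0.5},
}
_TISSUE = {
    # f_h, f_gut, Kp muscle/skin/adipose/gut (placeholders)
    "irinotecan": (0.20, 0.25, 2.0, 2.0, 4.0, 3.0),
    "SN38": (0.05, 0.06, 1.5, 1.5, 2.0, 2.0),
    "SN38G": (0.30, 0.35, 0.5, 0.5, 0.3, 0.8),
    "NPC": (0.20, 0.25, 1.5, 1.5, 2.0, 2.0),
    "APC": (0.20, 0.25, 1.2, 1.2, 1.5, 1.5),
}
# intrinsic renal secretion clearance, L/h/kg (placeholders)
_RENAL = {
    "irinotecan": 0.15,
    "SN38": 0.08,
    "SN38G": 0.03,
    "NPC": 0.08,
    "APC": 0.08,
}


def _base_disposition(hct: float = 0.45, gfr_per_kg: float = 0.09,
                      ff: float = 0.2, bw: float = 70.0) -> dict[str, CompoundDisposition]:
    out = {}
    for c in COMPOUND_NAMES:
        f_p, f_b = binding_fractions(
            _BINDING[c]["n_pt_over_kd"], _BINDING[c]["f_r"], hct, c
        )
        f_h, f_gut, kp_m, kp_s, kp_a, kp_g = _TISSUE[c]
        cl_r = renal_clearance(f_b, gfr_per_kg * bw, _RENAL[c] * bw, ff, hct)
        out[c] = CompoundDisposition(
            f_p=f_p, f_b=f_b, f_h=f_h, f_gut=f_gut,
            kp_muscle=kp_m, kp_skin=kp_s, kp_adipose=kp_a, kp_gut=kp_g,
            cl_r=cl_r,
        )
    return out


def _default_dists() -> dict[str, DistributionSpec]:
    """Variability table (placeholders; the CL_int_sec CV reproduces
    clinical renal-clearance variability)."""
    d = {
        "v_central": DistributionSpec(1.0, 0.20),
        "ps_act_inf_h": DistributionSpec(1.0, 0.30),
        "ps_dif_inf_h": DistributionSpec(1.0, 0.30),
        "cl_bile": DistributionSpec(1.0, 0.30),
        "cl_met": DistributionSpec(1.0, 0.15),
        "ps_dif_eff_ent": DistributionSpec(1.0, 0.15),
        "ps_act_eff_ent": DistributionSpec(1.0, 0.15),
        "k_a": DistributionSpec(1.0, 0.15),
        "k_feces": DistributionSpec(1.0, 0.15),
        "k_bile": DistributionSpec(1.0, 0.15),
        "k_dec": DistributionSpec(1.0, 0.15),
        "BW": DistributionSpec(78.8, 0.117, "normal"),
        "BSA_noise": DistributionSpec(1.0, 0.055, "normal"),
        "Hct": DistributionSpec(0.45, 0.05, "normal"),
        "GFR": DistributionSpec(0.09, 0.15, "normal"),
        "FF": DistributionSpec(0.2, 0.10, "normal"),
        "nPt_Kd_AGP": DistributionSpec(1.0, 0.25),
        "nPt_Kd_albumin": DistributionSpec(1.0, 0.25),
        # average CV reproducing clinical renal-clearance variability
        "CL_int_sec": DistributionSpec(1.0, 0.342),
    }
    return d


def _default_genetics() -> GeneticsTable:
    """Allele frequencies and activity ratios are placeholders; the
    affected processes and contribution fractions follow the standard
    irinotecan pathway assignment (UGT1A1 100%, SLCO1B1 100%, ABCG2 33%,
    ABCB1 50%/33%, ABCC2 50%/33%/100%)."""
    return GeneticsTable(
        loci={
            "UGT1A1*28": LocusSpec(
                0.30, {"wild": 1.0, "het": 0.70, "hom": 0.40},
                [("SN38", "CL_SN38G_h", 1.0), ("SN38", "CL_SN38G_ent", 1.0)],
            ),
            "SLCO1B1_521": LocusSpec(
                0.15, {"wild": 1.0, "het": 0.70, "hom": 0.40},
                [("SN38", "PS_act_inf_h", 1.0), ("SN38G", "PS_act_inf_h", 1.0)],
            ),
            "SLCO1B1_388": LocusSpec(
                0.40, {"wild": 1.0, "het": 0.95, "hom": 0.90},
                [("SN38", "PS_act_inf_h", 1.0), ("SN38G", "PS_act_inf_h", 1.0)],
            ),
            "ABCG2_421": LocusSpec(
                0.10, {"wild": 1.0, "het": 0.75, "hom": 0.50},
                [("SN38", "CL_bile", 0.33), ("SN38", "PS_act_eff_ent", 0.33)],
            ),
            "ABCB1_3435": LocusSpec(
                0.50, {"wild": 1.0, "het": 0.85, "hom": 0.70},
                [
                    ("irinotecan", "CL_bile", 0.50),
                    ("irinotecan", "PS_act_eff_ent", 0.50),
                    ("SN38", "CL_bile", 0.33),
                    ("SN38", "PS_act_eff_ent", 0.33),
                ],
            ),
            "ABCC2_-24": LocusSpec(
                0.20, {"wild": 1.0, "het": 0.85, "hom": 0.70},
                [
                    ("irinotecan", "CL_bile", 0.50),
                    ("irinotecan", "PS_act_eff_ent", 0.50),
                    ("SN38", "CL_bile", 0.33),
                    ("SN38", "PS_act_eff_ent", 0.33),
                    ("SN38G", "CL_bile", 1.0),
                    ("SN38G", "PS_act_eff_ent", 1.0),
                ],
            ),
        }
    )


@dataclass
class FixtureTables:
    bounds: ParameterBounds
    dists: dict[str, DistributionSpec]
    genetics: GeneticsTable
    base_params: PBPKParameterSet
    binding: dict[str, dict] = field(default_factory=lambda: dict(_BINDING))
    renal: dict[str, float] = field(default_factory=lambda: dict(_RENAL))


def default_fixture_tables(
    dose_mg_per_m2: float = 180.0, body_weight: float = 70.0
) -> FixtureTables:
    """Internally consistent bounds, variability, genetics and base set."""
    template = PBPKParameterSet(
        elementary={},
        disposition=_base_disposition(bw=body_weight),
        physiology=PhysiologyParameters(),
        dose_mg_per_m2=dose_mg_per_m2,
        body_weight=body_weight,
        body_surface_area=round(body_surface_area_of(body_weight), 3),
    )
    base = vector_to_params(_BASE_VECTOR, template)
    return FixtureTables(
        bounds=parameter_bounds(),
        dists=_default_dists(),
        genetics=_default_genetics(),
        base_params=base,
    )


# ----------------------------------------------------------------------
# synthetic reference profiles
# ----------------------------------------------------------------------
@dataclass
class ReferenceProfile:
    """Noisy observed concentrations with known ground truth."""

    observed: pd.DataFrame  # time_h, compound, concentration_nM
    truth: PBPKParameterSet
    noise_cv: float
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.observed["time_h"].unique())


def make_reference_profile(
    truth: PBPKParameterSet,
    times: np.ndarray | tuple = DEFAULT_SAMPLING_TIMES_H,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> ReferenceProfile:
    """Simulate the truth set and overlay multiplicative lognormal noise.

    The noise factor has mean 1 and coefficient of variation ``noise_cv``,
    so the expected WSS of the truth against its own noisy observations is
    approximately ``n_points * noise_cv**2``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(times, dtype=float)
    profile = IrinotecanPBPK(truth).profile_at(times)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        factors = np.exp(
            rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(profile))
        )
        profile = profile.assign(
            concentration_nM=profile["concentration_nM"] * factors
        )
    return ReferenceProfile(profile, truth, noise_cv, seed)
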