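"""Virtual-patient generation.

A virtual patient is a fully resolved :class:`~irinosim.parameters.PBPKParameterSet`
obtained by Monte-Carlo sampling around a population base set:

* a genotype at six pharmacogenetic loci (UGT1A1*28, SLCO1B1 c.521T>C and
  c.388A>G, ABCG2 c.421C>A, ABCB1 c.3435C>T, ABCC2 c.-24C>T) drawn under
  Hardy-Weinberg equilibrium from configured allele frequencies;
* body weight (normal) and body surface area (power law of body weight with
  multiplicative noise);
* plasma/blood binding from a Langmuir-type relation, with a single protein
  concentration draw shared among compounds bound to the same protein;
* renal clearance as filtration plus a dispersion-model tubular secretion;
* every kinetic parameter perturbed from its population mean according to a
  per-parameter distribution (CV and shape).

Genotype effects scale the affected parameter P to ``P * ((1 - c) + c * a)``
where ``c`` is the fraction of the process carried by the affected protein
and ``a`` the activity ratio of the patient's diplotype (wild type = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compounds import COMPOUND_NAMES, COMPOUNDS
from .parameters import PBPKParameterSet, ParameterDomainError

__all__ = [
    "GENOTYPE_LOCI",
    "DIPLOTYPES",
    "GenotypeProfile",
    "LocusSpec",
    "GeneticsTable",
    "DistributionSpec",
    "VirtualPatient",
    "PopulationModel",
    "sample_genotypes",
    "apply_genotype_effects",
    "body_surface_area",
    "sample_body_size",
    "binding_fractions",
    "renal_clearance",
    "ugt1a1_reference_correction",
]

GENOTYPE_LOCI = (
    "UGT1A1*28",
    "SLCO1B1_521",
    "SLCO1B1_388",
    "ABCG2_421",
    "ABCB1_3435",
    "ABCC2_-24",
)
DIPLOTYPES = ("wild", "het", "hom")

#: dispersion number of the renal tubular secretion model
DISPERSION_NUMBER = 0.17


@dataclass(frozen=True)
class GenotypeProfile:
    """Diplotype state at each of the six loci."""

    states: tuple[str, ...]  # aligned with GENOTYPE_LOCI

    def __post_init__(self) -> None:
        if len(self.states) != len(GENOTYPE_LOCI):
            raise ValueError("profile must cover all six loci")
        for s in self.states:
            if s not in DIPLOTYPES:
                raise ValueError(f"unknown diplotype {s!r}")

    def __getitem__(self, locus: str) -> str:
        return self.states[GENOTYPE_LOCI.index(locus)]

    @classmethod
    def all_wild(cls) -> "GenotypeProfile":
        return cls(("wild",) * len(GENOTYPE_LOCI))


@dataclass
class LocusSpec:
    """Allele frequency, diplotype activity ratios and affected processes.

    ``effects`` lists ``(compound, parameter, contribution)`` triples; the
    parameter names follow the hepatic/intestinal process nomenclature
    ("CL_SN38G_h", "CL_SN38G_ent", "PS_act_inf_h", "CL_bile",
    "PS_act_eff_ent").
    """

    allele_freq: float
    activity: dict[str, float]  # diplotype -> activity ratio, wild = 1
    effects: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ParameterDomainError("allele frequency must be in [0, 1]")
        for d in DIPLOTYPES:
            if d not in self.activity:
                raise ParameterDomainError(f"missing activity ratio for {d}")


@dataclass
class GeneticsTable:
    loci: dict[str, LocusSpec]

    def validate(self) -> None:
        for locus in GENOTYPE_LOCI:
            if locus not in self.loci:
                raise ParameterDomainError(f"missing locus {locus}")
            self.loci[locus].validate()


@dataclass
class DistributionSpec:
    """Inter-individual distribution of one parameter."""

    mean: float
    cv: float
    shape: str = "lognormal"  # or "normal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ParameterDomainError("CV must be non-negative")
        if self.shape not in ("normal", "lognormal"):
            raise ParameterDomainError(f"unknown shape {self.shape!r}")
        if self.shape == "lognormal" and self.mean <= 0:
            raise ParameterDomainError("lognormal mean must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        if self.cv == 0:
            return self.mean
        if self.shape == "lognormal":
            sigma2 = math.log1p(self.cv**2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return float(np.exp(rng.normal(mu, math.sqrt(sigma2))))
        # normal, truncated at +/- 4 SD and at zero (resample)
        sd = self.mean * self.cv
        for _ in range(100):
            x = rng.normal(self.mean, sd)
            if abs(x - self.mean) <= 4 * sd and x > 0:
                return float(x)
        raise ParameterDomainError("normal truncation failed repeatedly")


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def sample_genotypes(
    freqs: dict[str, float], n: int, rng: np.random.Generator
) -> list[GenotypeProfile]:
    """Sample ``n`` independent-locus profiles under Hardy-Weinberg."""
    for locus, q in freqs.items():
        if not (0.0 <= q <= 1.0):
            raise ParameterDomainError(f"allele frequency for {locus} outside [0,1]")
    probs = {
        locus: ((1 - q) ** 2, 2 * q * (1 - q), q**2)
        for locus, q in freqs.items()
    }
    out = []
    for _ in range(n):
        states = tuple(
            DIPLOTYPES[rng.choice(3, p=probs[locus])] for locus in GENOTYPE_LOCI
        )
        out.append(GenotypeProfile(states))
    return out


_PARAM_SETTERS = {
    "PS_act_inf_h": ("ps_act_inf_h", None),
    "CL_bile": ("cl_bile", None),
    "PS_act_eff_ent": ("ps_act_eff_ent", None),
    "CL_SN38G_h": ("cl_met_paths", "SN38G"),
    "CL_SN38G_ent": ("cl_met_ent_paths", "SN38G"),
}


def apply_genotype_effects(
    params: PBPKParameterSet, profile: GenotypeProfile, genetics: GeneticsTable
) -> PBPKParameterSet:
    """Return a copy of ``params`` with genotype activity scaling applied."""
    genetics.validate()
    scaled = params.copy()
    for locus in GENOTYPE_LOCI:
        spec = genetics.loci[locus]
        state = profile[locus]
        if state not in spec.activity:
            raise ParameterDomainError(f"no activity ratio for {locus}/{state}")
        a = spec.activity[state]
        for compound, param, contribution in spec.effects:
            factor = (1.0 - contribution) + contribution * a
            attr, key = _PARAM_SETTERS[param]
            e = scaled.elementary[compound]
            if key is None:
                setattr(e, attr, getattr(e, attr) * factor)
            else:
                d = getattr(e, attr)
                if key in d:
                    d[key] = d[key] * factor
    return scaled


def ugt1a1_reference_correction(
    params: PBPKParameterSet, het_activity: float
) -> PBPKParameterSet:
    """Rescale SN-38 glucuronidation to a UGT1A1 *1/*1 reference.

    The fitted population-mean glucuronidation clearance represents a 50/50
    mix of *1/*1 and *1/*28 subjects, so the wild-type value is recovered by
    dividing by the mean activity of that mix, ``(1 + a_het) / 2``.
    """
    corrected = params.copy()
    factor = 2.0 / (1.0 + het_activity)
    e = corrected.elementary["SN38"]
    for d in (e.cl_met_paths, e.cl_met_ent_paths):
        if "SN38G" in d:
            d["SN38G"] = d["SN38G"] * factor
    return corrected


# ----------------------------------------------------------------------
# body size
# ----------------------------------------------------------------------
def body_surface_area(bw_kg: float) -> float:
    """BSA (m^2) from body weight by the power law with weight-dependent
    exponent: ``BSA[cm^2] = 4.688 * BW[g] ** (0.8168 - 0.0154 * log10(BW[g]))``.
    """
    bw_g = bw_kg * 1000.0
    if bw_g <= 0:
        raise ParameterDomainError("body weight must be positive")
    exponent = 0.8168 - 0.0154 * math.log10(bw_g)
    return 4.688 * bw_g**exponent / 1e4


def sample_body_size(
    rng: np.random.Generator,
    mean_bw: float = 78.8,
    cv_bw: float = 0.117,
    cv_bsa: float = 0.055,
) -> tuple[float, float]:
    """Draw (BW kg, BSA m^2): normal BW, power-law BSA with 5.5% noise."""
    bw = DistributionSpec(mean_bw, cv_bw, "normal").sample(rng)
    bsa = body_surface_area(bw)
    if cv_bsa > 0:
        bsa *= DistributionSpec(1.0, cv_bsa, "normal").sample(rng)
    return bw, bsa


# ----------------------------------------------------------------------
# binding and renal clearance
# ----------------------------------------------------------------------
def binding_fractions(
    n_pt_over_kd: float, f_r: float | None, hct: float, compound: str
) -> tuple[float, float]:
    """Plasma and blood unbound fractions.

    ``f_p = 1 / (1 + n[Pt]/Kd)``; the blood fraction assumes equal unbound
    concentration in plasma and blood cells,
    ``f_b = f_p / (1 - (1 - f_p/f_r) * Hct)`` with ``f_r`` the unbound
    fraction in blood cells.  SN-38G does not enter blood cells, giving the
    limiting value ``f_b = f_p / (1 - Hct)``.
    """
    if n_pt_over_kd < 0:
        raise ParameterDomainError("n[Pt]/Kd must be non-negative")
    if not (0.0 < hct < 1.0):
        raise ParameterDomainError("hematocrit must be in (0, 1)")
    f_p = 1.0 / (1.0 + n_pt_over_kd)
    if not COMPOUNDS[compound].blood_cell_partitioning:
        return f_p, f_p / (1.0 - hct)
    if f_r is None or f_r <= 0:
        raise ParameterDomainError("f_r required for blood-cell partitioning")
    f_b = f_p / (1.0 - (1.0 - f_p / f_r) * hct)
    return f_p, f_b


def renal_clearance(
    f_b: float,
    gfr: float,
    cl_int_sec: float,
    ff: float,
    hct: float,
    d_n: float = DISPERSION_NUMBER,
) -> float:
    """Renal blood clearance: filtration plus dispersion-model secretion.

    ``CL_r = f_b * GFR + CL_sec`` with the secretion clearance bounded above
    by the tubular blood flow ``Q_rtb = GFR/FF/(1 - Hct) - GFR``.
    """
    if min(f_b, gfr) <= 0 or cl_int_sec < 0 or not (0 < ff < 1):
        raise ParameterDomainError("invalid renal inputs")
    if not (0.0 < hct < 1.0):
        raise ParameterDomainError("hematocrit must be in (0, 1)")
    erpf = gfr / ff
    q_r = erpf / (1.0 - hct)
    q_rtb = q_r - gfr
    if q_rtb <= 0:
        raise ParameterDomainError("nonphysical FF/Hct: tubular flow <= 0")
    a = math.sqrt(1.0 + 4.0 * d_n * f_b * cl_int_sec / q_rtb)
    num = 4.0 * a
    den = (a + 1.0) ** 2 * math.exp((a - 1.0) / (2.0 * d_n)) - (
        a - 1.0
    ) ** 2 * math.exp(-(a - 1.0) / (2.0 * d_n))
    cl_sec = q_rtb * (1.0 - num / den)
    return f_b * gfr + cl_sec


# ----------------------------------------------------------------------
# patient assembly
# ----------------------------------------------------------------------
@dataclass
class VirtualPatient:
    genotype: GenotypeProfile
    body_weight: float
    body_surface_area: float
    params: PBPKParameterSet

    @property
    def dose_mg(self) -> float:
        return self.params.dose_mg


# elementary fields perturbed per patient, with fallback CV keys
_VARYING_FIELDS = (
    "v_central",
    "ps_act_inf_h",
    "ps_dif_inf_h",
    "cl_bile",
    "ps_dif_eff_ent",
    "ps_act_eff_ent",
    "k_a",
    "k_feces",
    "k_bile",
    "k_dec",
)


@dataclass
class PopulationModel:
    """Sampler producing simulate-ready virtual patients.

    Parameters
    ----------
    base_params
        Population-mean parameter set on the elementary scale (the UGT1A1
        reference correction is applied here once at construction).
    dists
        Per-quantity :class:`DistributionSpec`.  Kinetic parameters are
        keyed by elementary field name (CV applied multiplicatively around
        the base value); physiological draws use the keys ``BW``,
        ``BSA_noise``, ``Hct``, ``GFR``, ``FF``, ``nPt_Kd_AGP``,
        ``nPt_Kd_albumin`` and ``CL_int_sec``.
    genetics
        Allele frequencies, activity ratios and affected processes.
    binding
        Per-compound ``{"n_pt_over_kd": float, "f_r": float | None}``.
    renal
        Per-compound intrinsic secretion clearance (L/h/kg).
    """

    base_params: PBPKParameterSet
    dists: dict[str, DistributionSpec]
    genetics: GeneticsTable
    binding: dict[str, dict]
    renal: dict[str, float]
    apply_ugt_reference_correction: bool = True

    def __post_init__(self) -> None:
        self.genetics.validate()
        missing = [c for c in COMPOUND_NAMES if c not in self.binding]
        if missing:
            raise ParameterDomainError(f"missing binding config: {missing}")
        missing = [c for c in COMPOUND_NAMES if c not in self.renal]
        if missing:
            raise ParameterDomainError(f"missing renal config: {missing}")
        if self.apply_ugt_reference_correction:
            het = self.genetics.loci["UGT1A1*28"].activity["het"]
            self.base_params = ugt1a1_reference_correction(self.base_params, het)

    # -- draws -----------------------------------------------------------
    def _cv_of(self, key: str, default: float = 0.0) -> DistributionSpec:
        return self.dists.get(key, DistributionSpec(1.0, default))

    def _perturb(self, value: float, key: str, rng: np.random.Generator) -> float:
        if value == 0.0:
            return 0.0
        spec = self.dists.get(key)
        if spec is None or spec.cv == 0:
            return value
        factor = DistributionSpec(1.0, spec.cv, spec.shape).sample(rng)
        return value * factor

    def sample_patient(
        self, rng: np.random.Generator, genotype: GenotypeProfile | None = None
    ) -> VirtualPatient:
        p = self.base_params.copy()
        # body size and dose scaling
        bw_spec = self.dists.get("BW", DistributionSpec(78.8, 0.117, "normal"))
        bsa_noise = self.dists.get("BSA_noise", DistributionSpec(1.0, 0.055, "normal"))
        bw, bsa = sample_body_size(rng, bw_spec.mean, bw_spec.cv, bsa_noise.cv)
        p.body_weight, p.body_surface_area = bw, bsa

        # kinetic parameter variability (multiplicative around base)
        for comp in COMPOUND_NAMES:
            e = p.elementary[comp]
            for f_name in _VARYING_FIELDS:
                setattr(e, f_name, self._perturb(getattr(e, f_name), f_name, rng))
            e.ps_dif_eff_h = e.ps_dif_inf_h  # preserve the passive symmetry
            e.ps_dif_inf_ent = e.ps_dif_eff_ent
            for d_name in ("cl_met_paths", "cl_met_ent_paths"):
                dd = getattr(e, d_name)
                for k in dd:
                    dd[k] = self._perturb(dd[k], "cl_met", rng)

        # genotype
        if genotype is None:
            freqs = {
                locus: self.genetics.loci[locus].allele_freq
                for locus in GENOTYPE_LOCI
            }
            genotype = sample_genotypes(freqs, 1, rng)[0]
        p = apply_genotype_effects(p, genotype, self.genetics)

        # binding: one [Pt] draw per protein, shared across its compounds
        hct = self.dists.get("Hct", DistributionSpec(0.45, 0.0, "normal")).sample(rng)
        if not (0.0 < hct < 1.0):
            hct = min(max(hct, 1e-3), 0.95)
        protein_factor = {
            "AGP": self._cv_of("nPt_Kd_AGP").sample(rng),
            "albumin": self._cv_of("nPt_Kd_albumin").sample(rng),
        }
        gfr_kg = self.dists.get("GFR", DistributionSpec(0.09, 0.0, "normal")).sample(rng)
        ff = self.dists.get("FF", DistributionSpec(0.2, 0.0, "normal")).sample(rng)
        gfr = gfr_kg * bw
        p.physiology.hematocrit = hct
        p.physiology.gfr = gfr_kg
        p.physiology.filtration_fraction = ff
        for comp in COMPOUND_NAMES:
            b = self.binding[comp]
            x = b["n_pt_over_kd"] * protein_factor[COMPOUNDS[comp].binding_protein]
            f_p, f_b = binding_fractions(x, b.get("f_r"), hct, comp)
            d = p.disposition[comp]
            d.f_p, d.f_b = f_p, f_b
            cl_int_sec = self.renal[comp] * bw
            if cl_int_sec > 0 and comp != "SN38G":
                # SN-38G secretion is a minor route whose variability cannot
                # be resolved from clinical CL_r data; it is held fixed.
                cl_int_sec = self._perturb(cl_int_sec, "CL_int_sec", rng)
            d.cl_r = renal_clearance(f_b, gfr, cl_int_sec, ff, hct)
        return VirtualPatient(genotype, bw, bsa, p)

    def sample_population(
        self, n: int, rng: np.random.Generator
    ) -> list[VirtualPatient]:
        return [self.sample_patient(rng) for _ in range(n)]
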