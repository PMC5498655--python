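"""Compound registry for irinotecan and its four circulating metabolites.

Irinotecan (CPT-11) is hydrolysed by carboxylesterases to the active
topoisomerase-I inhibitor SN-38, which is glucuronidated by UGT1A1 to
SN-38G.  CYP3A4/5 oxidises irinotecan to the inactive metabolites NPC and
APC.  Each compound gets its own whole-body disposition sub-model; the five
sub-models are coupled through the metabolic network (see
:mod:`irinosim.model`).

Binding behaviour follows basic pKa: compounds with basic pKa > 7
(irinotecan, NPC, APC) bind alpha-1-acid glycoprotein, the two lactone
metabolites SN-38 and SN-38G bind albumin.  SN-38G does not partition into
blood cells, and only SN-38 and SN-38G are substrates of hepatic uptake
transporters (OATP1B1).  NPC and APC carry no active uptake or efflux.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompoundSpec", "COMPOUNDS", "COMPOUND_NAMES", "MOLECULAR_WEIGHTS"]


@dataclass(frozen=True)
class CompoundSpec:
    """Qualitative disposition traits of one compound."""

    name: str
    binding_protein: str  # "AGP" or "albumin"
    blood_cell_partitioning: bool
    has_active_hepatic_uptake: bool
    has_active_intestinal_efflux: bool

    def __post_init__(self) -> None:
        if self.binding_protein not in ("AGP", "albumin"):
            raise ValueError(f"unknown binding protein {self.binding_protein!r}")


COMPOUND_NAMES = ("irinotecan", "SN38", "SN38G", "NPC", "APC")

COMPOUNDS: dict[str, CompoundSpec] = {
    "irinotecan": CompoundSpec("irinotecan", "AGP", True, False, True),
    "SN38": CompoundSpec("SN38", "albumin", True, True, True),
    "SN38G": CompoundSpec("SN38G", "albumin", False, True, True),
    "NPC": CompoundSpec("NPC", "AGP", True, False, False),
    "APC": CompoundSpec("APC", "AGP", True, False, False),
}

# g/mol; only the parent's weight matters for dosing (states are molar).
MOLECULAR_WEIGHTS = {
    "irinotecan": 586.7,
    "SN38": 392.4,
    "SN38G": 568.5,
    "NPC": 518.6,
    "APC": 618.7,
}
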