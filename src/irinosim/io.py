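"""Readers, writers and run provenance.

All artifacts are plain text: YAML for configuration (parameter sets,
search ranges, genetics and variability tables), tidy long-format CSV for
profiles and populations, JSON for summaries.  Parameter-set YAML is keyed
by the conventional parameter nomenclature (``CL_int_all``, ``R_dif_h``,
``k_dec`` ...), so a user can paste values straight from the original
tables.  Every loader validates its schema and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cnm import Bound, ParameterBounds
from .compounds import COMPOUND_NAMES
from .parameters import (
    CompoundDisposition,
    PBPKParameterSet,
    PhysiologyParameters,
)
from .population import DistributionSpec, GeneticsTable, LocusSpec

__all__ = [
    "ConfigError",
    "RunManifest",
    "save_parameter_set",
    "load_parameter_set",
    "save_bounds",
    "load_bounds",
    "save_genetics",
    "load_genetics",
    "save_dists",
    "load_dists",
    "read_profile_csv",
    "write_profile_csv",
]

PROFILE_COLUMNS = ("time_h", "compound", "concentration_nM")


class ConfigError(ValueError):
    """A configuration file violates its schema."""


def _require_keys(d: dict, allowed: set[str], required: set[str], what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{what}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ConfigError(f"{what}: missing keys {sorted(missing)}")


# ----------------------------------------------------------------------
# parameter sets
# ----------------------------------------------------------------------
def _plain(obj):
    """Recursively convert numpy scalars so YAML stays human-readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def save_parameter_set(params: PBPKParameterSet, path: str | Path) -> None:
    from .fixtures import params_to_vector  # local import to avoid a cycle

    doc = {
        "schema": "irinosim/parameter-set/1",
        "vector": params_to_vector(params),
        "disposition": {c: asdict(params.disposition[c]) for c in COMPOUND_NAMES},
        "physiology": asdict(params.physiology),
        "regimen": {
            "dose_mg_per_m2": params.dose_mg_per_m2,
            "infusion_duration_h": params.infusion_duration_h,
            "body_weight": params.body_weight,
            "body_surface_area": params.body_surface_area,
        },
    }
    Path(path).write_text(yaml.safe_dump(_plain(doc), sort_keys=True))


def load_parameter_set(path: str | Path) -> PBPKParameterSet:
    from .fixtures import vector_to_params

    doc = yaml.safe_load(Path(path).read_text())
    _require_keys(
        doc,
        {"schema", "vector", "disposition", "physiology", "regimen"},
        {"schema", "vector", "disposition", "regimen"},
        "parameter set",
    )
    if doc["schema"] != "irinosim/parameter-set/1":
        raise ConfigError(f"unsupported schema {doc['schema']!r}")
    phys_fields = {f.name for f in dataclasses.fields(PhysiologyParameters)}
    phys_doc = doc.get("physiology", {})
    _require_keys(phys_doc, phys_fields, set(), "physiology")
    disp = {}
    disp_fields = {f.name for f in dataclasses.fields(CompoundDisposition)}
    for c in COMPOUND_NAMES:
        if c not in doc["disposition"]:
            raise ConfigError(f"disposition missing compound {c}")
        block = doc["disposition"][c]
        _require_keys(block, disp_fields, disp_fields, f"disposition[{c}]")
        disp[c] = CompoundDisposition(**block)
    reg = doc["regimen"]
    _require_keys(
        reg,
        {"dose_mg_per_m2", "infusion_duration_h", "body_weight", "body_surface_area"},
        {"dose_mg_per_m2"},
        "regimen",
    )
    template = PBPKParameterSet(
        elementary={},
        disposition=disp,
        physiology=PhysiologyParameters(**phys_doc),
        **reg,
    )
    params = vector_to_params(doc["vector"], template)
    params.validate()
    return params


# ----------------------------------------------------------------------
# bounds / genetics / distributions
# ----------------------------------------------------------------------
def save_bounds(bounds: ParameterBounds, path: str | Path) -> None:
    doc = {
        "schema": "irinosim/bounds/1",
        "parameters": [asdict(b) for b in bounds.bounds],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_bounds(path: str | Path) -> ParameterBounds:
    doc = yaml.safe_load(Path(path).read_text())
    _require_keys(doc, {"schema", "parameters"}, {"schema", "parameters"}, "bounds")
    entries = []
    for row in doc["parameters"]:
        _require_keys(
            row,
            {"name", "lower", "upper", "theoretical_lower"},
            {"name", "lower", "upper", "theoretical_lower"},
            "bounds entry",
        )
        entries.append(Bound(**row))
    return ParameterBounds(entries)


def save_genetics(genetics: GeneticsTable, path: str | Path, provenance: str = "placeholder") -> None:
    doc = {
        "schema": "irinosim/genetics/1",
        "provenance": provenance,
        "loci": {
            locus: {
                "allele_freq": spec.allele_freq,
                "activity": dict(spec.activity),
                "effects": [list(e) for e in spec.effects],
            }
            for locus, spec in genetics.loci.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_genetics(path: str | Path) -> GeneticsTable:
    doc = yaml.safe_load(Path(path).read_text())
    _require_keys(doc, {"schema", "provenance", "loci"}, {"schema", "loci"}, "genetics")
    loci = {}
    for locus, block in doc["loci"].items():
        _require_keys(
            block,
            {"allele_freq", "activity", "effects"},
            {"allele_freq", "activity"},
            f"locus {locus}",
        )
        loci[locus] = LocusSpec(
            allele_freq=block["allele_freq"],
            activity=block["activity"],
            effects=[tuple(e) for e in block.get("effects", [])],
        )
    table = GeneticsTable(loci)
    table.validate()
    return table


def save_dists(dists: dict[str, DistributionSpec], path: str | Path,
               provenance: str = "placeholder") -> None:
    doc = {
        "schema": "irinosim/distributions/1",
        "provenance": provenance,
        "parameters": {k: asdict(v) for k, v in dists.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_dists(path: str | Path) -> dict[str, DistributionSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    _require_keys(
        doc, {"schema", "provenance", "parameters"}, {"schema", "parameters"}, "dists"
    )
    out = {}
    for k, block in doc["parameters"].items():
        _require_keys(block, {"mean", "cv", "shape"}, {"mean", "cv"}, f"dist {k}")
        out[k] = DistributionSpec(**block)
    return out


# ----------------------------------------------------------------------
# profiles
# ----------------------------------------------------------------------
def write_profile_csv(profile: pd.DataFrame, path: str | Path) -> None:
    missing = set(PROFILE_COLUMNS) - set(profile.columns)
    if missing:
        raise ConfigError(f"profile missing columns {sorted(missing)}")
    profile[list(PROFILE_COLUMNS)].to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"profile missing columns {sorted(missing)}")
    unknown = set(df["compound"].unique()) - set(COMPOUND_NAMES)
    if unknown:
        raise ConfigError(f"unknown compounds in profile: {sorted(unknown)}")
    return df[list(PROFILE_COLUMNS)]


# ----------------------------------------------------------------------
# provenance
# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Provenance stamp attached to every generated artifact set."""

    seed: int
    config_hash: str
    fixture_provenance: str  # "calibrated" | "placeholder" | "mixed"
    version: str = __version__
    created_utc: str = ""

    def __post_init__(self) -> None:
        if not self.created_utc:
            self.created_utc = datetime.now(timezone.utc).isoformat()

    @classmethod
    def for_config(cls, config: dict, seed: int,
                   fixture_provenance: str = "placeholder") -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return cls(seed=seed, config_hash=digest,
                   fixture_provenance=fixture_provenance)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
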