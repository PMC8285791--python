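"""Read, validate and write parameter sets as structured YAML.

Parameter files are the scientific payload of this tool: each file carries a
schema version, one baseline spiking-neuron parameter set, and any number of
named (isoform, temperature) T-type kinetic sets with free-text provenance.
Every numeric field is validated on load (positive time constants, correct
gate polarity, non-negative conductances) and errors name the offending key.
Serialization is lossless: floats round-trip exactly and provenance text is
preserved byte-for-byte, including unicode.

Units throughout: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .gating import ACTIVATION, INACTIVATION, GateSpec
from .model import CaTParams, Channel, NeuronParams, with_cat

__all__ = [
    "SCHEMA_VERSION",
    "ParamValidationError",
    "RegistryEntry",
    "ParamRegistry",
    "load_params",
    "write_params",
    "load_default_baseline",
    "default_template_path",
]

SCHEMA_VERSION = 1

_GATE_FIELDS = (
    "polarity",
    "v_half",
    "slope",
    "tau_depol",
    "tau_hyper",
    "tau_v_mid",
    "tau_slope",
    "exponent",
)


class ParamValidationError(ValueError):
    """Raised when a parameter file violates the schema; names the bad key."""


@dataclass(frozen=True)
class RegistryEntry:
    cat: CaTParams
    provenance: str = ""


@dataclass
class ParamRegistry:
    """Baseline neuron plus named (isoform, temperature) CaT slots."""

    baseline: NeuronParams
    entries: dict[tuple[str, str], RegistryEntry] = field(default_factory=dict)

    def add(self, cat: CaTParams, provenance: str = "") -> None:
        key = (cat.isoform_label, cat.temperature_label)
        if key in self.entries:
            raise ParamValidationError(f"duplicate registry entry {key}")
        self.entries[key] = RegistryEntry(cat=cat, provenance=provenance)

    def neuron_for(self, key: tuple[str, str]) -> NeuronParams:
        """Baseline with the keyed CaT inserted."""
        return with_cat(self.baseline, self.entries[key].cat)

    def keys(self):
        return self.entries.keys()

    def __len__(self) -> int:
        return len(self.entries)


def _require(mapping, key, path):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ParamValidationError(f"missing required field {path}.{key}")
    return mapping[key]


def _number(mapping, key, path):
    val = _require(mapping, key, path)
    if isinstance(val, bool) or not isinstance(val, (int, float)):
        raise ParamValidationError(f"{path}.{key} must be a number, got {val!r}")
    if not np.isfinite(val):
        raise ParamValidationError(f"{path}.{key} must be finite, got {val!r}")
    return float(val)


def _parse_gate(d, path, expected_polarity=None) -> GateSpec:
    polarity = _require(d, "polarity", path)
    if polarity not in (ACTIVATION, INACTIVATION):
        raise ParamValidationError(
            f"{path}.polarity must be 'activation' or 'inactivation', got {polarity!r}"
        )
    if expected_polarity is not None and polarity != expected_polarity:
        raise ParamValidationError(
            f"{path}.polarity must be {expected_polarity!r} for this slot, "
            f"got {polarity!r}"
        )
    kwargs = {}
    for name in ("v_half", "slope", "tau_depol", "tau_hyper", "tau_v_mid", "tau_slope"):
        kwargs[name] = _number(d, name, path)
    exponent = d.get("exponent", 1)
    if isinstance(exponent, bool) or not isinstance(exponent, int) or exponent < 1:
        raise ParamValidationError(f"{path}.exponent must be a positive integer")
    unknown = set(d) - set(_GATE_FIELDS)
    if unknown:
        raise ParamValidationError(f"unknown field(s) {sorted(unknown)} in {path}")
    try:
        return GateSpec(polarity=polarity, exponent=exponent, **kwargs)
    except ValueError as exc:
        raise ParamValidationError(f"{path}: {exc}") from exc


def _parse_channel(d, path) -> Channel:
    g_max = _number(d, "g_max", path)
    e_rev = _number(d, "e_rev", path)
    gates = []
    for gate_name, gate_d in (d.get("gates") or {}).items():
        gates.append((gate_name, _parse_gate(gate_d, f"{path}.gates.{gate_name}")))
    try:
        return Channel(g_max=g_max, e_rev=e_rev, gates=tuple(gates))
    except ValueError as exc:
        raise ParamValidationError(f"{path}: {exc}") from exc


def _parse_baseline(d, path="baseline") -> NeuronParams:
    c_m = _number(d, "c_m", path)
    na = _parse_channel(_require(d, "na", path), f"{path}.na")
    k = _parse_channel(_require(d, "k", path), f"{path}.k")
    leak = _parse_channel(_require(d, "leak", path), f"{path}.leak")
    try:
        return NeuronParams(c_m=c_m, na=na, k=k, leak=leak)
    except ValueError as exc:
        raise ParamValidationError(f"{path}: {exc}") from exc


def _parse_cat(d, path) -> tuple[CaTParams, str]:
    isoform = str(_require(d, "isoform", path))
    temperature = str(_require(d, "temperature", path))
    g_max = _number(d, "g_max", path)
    if g_max < 0:
        raise ParamValidationError(f"{path}.g_max must be >= 0, got {g_max}")
    e_rev = _number(d, "e_rev", path)
    act = _parse_gate(_require(d, "activation", path), f"{path}.activation", ACTIVATION)
    inact = _parse_gate(
        _require(d, "inactivation", path), f"{path}.inactivation", INACTIVATION
    )
    provenance = str(d.get("provenance", ""))
    try:
        cat = CaTParams(
            isoform_label=isoform,
            temperature_label=temperature,
            g_max=g_max,
            e_rev=e_rev,
            activation=act,
            inactivation=inact,
        )
    except ValueError as exc:
        raise ParamValidationError(f"{path}: {exc}") from exc
    return cat, provenance


def load_params(path) -> ParamRegistry:
    """Load and fully validate a parameter file into a registry."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return parse_registry(doc)


def parse_registry(doc) -> ParamRegistry:
    if not isinstance(doc, dict):
        raise ParamValidationError("parameter file must be a mapping")
    version = doc.get("schema_version")
    if version is None:
        raise ParamValidationError("missing required field schema_version")
    if version != SCHEMA_VERSION:
        raise ParamValidationError(
            f"unknown schema_version {version!r}; this build reads version "
            f"{SCHEMA_VERSION}"
        )
    baseline = _parse_baseline(_require(doc, "baseline", "<root>"))
    registry = ParamRegistry(baseline=baseline)
    for i, entry in enumerate(doc.get("cat_sets") or []):
        cat, provenance = _parse_cat(entry, f"cat_sets[{i}]")
        registry.add(cat, provenance)
    return registry


def _gate_doc(spec: GateSpec) -> dict:
    return {
        "polarity": spec.polarity,
        "v_half": spec.v_half,
        "slope": spec.slope,
        "tau_depol": spec.tau_depol,
        "tau_hyper": spec.tau_hyper,
        "tau_v_mid": spec.tau_v_mid,
        "tau_slope": spec.tau_slope,
        "exponent": int(spec.exponent),
    }


def _channel_doc(chan: Channel) -> dict:
    out = {"g_max": chan.g_max, "e_rev": chan.e_rev}
    if chan.gates:
        out["gates"] = {name: _gate_doc(spec) for name, spec in chan.gates}
    return out


def registry_doc(registry: ParamRegistry) -> dict:
    b = registry.baseline
    doc = {
        "schema_version": SCHEMA_VERSION,
        "baseline": {
            "c_m": b.c_m,
            "na": _channel_doc(b.na),
            "k": _channel_doc(b.k),
            "leak": _channel_doc(b.leak),
        },
        "cat_sets": [],
    }
    for (_, _), entry in registry.entries.items():
        cat = entry.cat
        doc["cat_sets"].append(
            {
                "isoform": cat.isoform_label,
                "temperature": cat.temperature_label,
                "provenance": entry.provenance,
                "g_max": cat.g_max,
                "e_rev": cat.e_rev,
                "activation": _gate_doc(cat.activation),
                "inactivation": _gate_doc(cat.inactivation),
            }
        )
    return doc


def write_params(registry: ParamRegistry, path) -> None:
    """Serialize a registry to YAML with stable key order and full precision."""
    doc = registry_doc(registry)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def _data_path(name: str):
    return resources.files("tburst.data").joinpath(name)


def load_default_baseline() -> NeuronParams:
    """The packaged default baseline spiker (no CaT)."""
    with resources.as_file(_data_path("default_neuron.yaml")) as p:
        return load_params(p).baseline


def default_template_path() -> Path:
    """Path to the shipped six-slot (isoform x temperature) template file.

    The template's kinetic values are placeholders flagged in each entry's
    provenance; transcribe published voltage-clamp measurements into the same
    schema before treating any entry as a real isoform.
    """
    with resources.as_file(_data_path("cav3_template.yaml")) as p:
        return Path(p)
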