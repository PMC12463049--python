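"""Contact-based linear binding free-energy model.

dG_binding = sum_k w_ic[k] * IC[k]
           + w_nis_apolar * %NIS_apolar + w_nis_charged * %NIS_charged
           + intercept                                        [kcal/mol]

where IC[k] are interfacial residue-residue contact counts by polarity-class
pair and %NIS are the charged/apolar percentages of the non-interacting
surface.  Weights are data (a flat key=value parameter file); the packaged
default reproduces a published contact-based consensus model, so the
pipeline's arithmetic is testable with toy weights independently of any
particular parameterization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from .interface import (ContactCriteria, HBondCriteria, InterfaceDescriptor,
                        SaltBridgeCriteria, ConfigurationError, IC_KEYS,
                        interface_report)
from .structure import ComplexView, StructureError

_REQUIRED_KEYS = ("w_cc", "w_cp", "w_ca", "w_pp", "w_pa", "w_aa",
                  "w_nis_apolar", "w_nis_charged", "intercept", "provenance")


@dataclass
class AffinityModelParams:
    w_ic: dict[str, float]
    w_nis_apolar: float
    w_nis_charged: float
    intercept: float
    provenance: str

    def __post_init__(self) -> None:
        missing = [k for k in IC_KEYS if k not in self.w_ic]
        if missing:
            raise ConfigurationError(f"missing contact weights: {missing}")
        values = list(self.w_ic.values()) + [self.w_nis_apolar,
                                             self.w_nis_charged, self.intercept]
        if not all(math.isfinite(v) for v in values):
            raise ConfigurationError("non-finite model weight")
        if not self.provenance:
            raise ConfigurationError("provenance must be non-empty")


@dataclass
class BindingPrediction:
    dg: float
    descriptor: InterfaceDescriptor
    params_provenance: str

    def to_json(self, path=None) -> str:
        payload = {"dg_kcal_mol": self.dg,
                   "params_provenance": self.params_provenance,
                   "descriptor": json.loads(self.descriptor.to_json())}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _parse_flat(text: str) -> dict[str, str]:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"malformed parameter line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def load_model_params(path=None) -> AffinityModelParams:
    """Load model parameters from a flat key=value file.

    With no path the packaged default parameter file is used.
    """
    if path is None:
        text = resources.files("impscan.data").joinpath(
            "affinity_default.cfg").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = _parse_flat(text)
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigurationError(f"parameter file missing keys: {missing}")
    return AffinityModelParams(
        w_ic={k: float(raw[f"w_{k}"]) for k in IC_KEYS},
        w_nis_apolar=float(raw["w_nis_apolar"]),
        w_nis_charged=float(raw["w_nis_charged"]),
        intercept=float(raw["intercept"]),
        provenance=raw["provenance"])


def save_model_params(params: AffinityModelParams, path) -> None:
    lines = [f"w_{k} = {params.w_ic[k]!r}" for k in IC_KEYS]
    lines += [f"w_nis_apolar = {params.w_nis_apolar!r}",
              f"w_nis_charged = {params.w_nis_charged!r}",
              f"intercept = {params.intercept!r}",
              f"provenance = {params.provenance}"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def predict_binding_energy(descriptor: InterfaceDescriptor,
                           params: AffinityModelParams) -> BindingPrediction:
    """Pure linear evaluation of the model on one descriptor."""
    dg = params.intercept
    for k in IC_KEYS:
        dg += params.w_ic[k] * descriptor.ic.get(k, 0)
    dg += params.w_nis_apolar * descriptor.nis_apolar_pct
    dg += params.w_nis_charged * descriptor.nis_charged_pct
    return BindingPrediction(dg=float(dg), descriptor=descriptor,
                             params_provenance=params.provenance)


def _check_same_composition(wt: ComplexView, mut: ComplexView) -> None:
    if wt.group_a != mut.group_a or wt.group_b != mut.group_b:
        raise StructureError("wild-type and mutant views differ in chain groups")
    for cid in sorted(wt.chain_ids()):
        cw = wt.structure.get_chain(cid)
        cm = mut.structure.get_chain(cid)
        if len(cw.residues) != len(cm.residues):
            raise StructureError(f"chain {cid} differs in residue count")


def affinity_descriptor(view: ComplexView,
                        contact_criteria: ContactCriteria | None = None,
                        nis_threshold: float = 0.05,
                        n_points: int = 960) -> InterfaceDescriptor:
    """Descriptor restricted to the model's regressors (no BSA quadratures).

    Hydrogen-bond and salt-bridge counts are still populated; only the
    buried-surface-area term, which the affinity model does not use, is
    skipped for speed.
    """
    return interface_report(view, contact_criteria, HBondCriteria(),
                            SaltBridgeCriteria(), nis_threshold,
                            n_points=n_points, include_bsa=False)


def delta_delta_g_binding(wt: ComplexView, mut: ComplexView,
                          contact_criteria: ContactCriteria | None = None,
                          params: AffinityModelParams | None = None,
                          nis_threshold: float = 0.05,
                          n_points: int = 960) -> float:
    """ddG_binding = dG(mutant) - dG(wild type); positive = weaker binding."""
    _check_same_composition(wt, mut)
    params = params or load_model_params()
    d_wt = affinity_descriptor(wt, contact_criteria, nis_threshold, n_points)
    d_mut = affinity_descriptor(mut, contact_criteria, nis_threshold, n_points)
    dg_wt = predict_binding_energy(d_wt, params).dg
    dg_mut = predict_binding_energy(d_mut, params).dg
    return float(dg_mut - dg_wt)
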