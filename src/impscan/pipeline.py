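"""End-to-end run orchestration with config files and reproducible manifests.

A run config is flat INI-style text (key = value under sections); every run
writes its effective config back out together with a manifest recording
input/output SHA-256 digests per stage, so identical configs and seeds can
be verified to reproduce identical results byte for byte (wall-clock fields
are recorded but excluded from any comparison).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .affinity import (load_model_params, predict_binding_energy)
from .interface import (ContactCriteria, HBondCriteria, SaltBridgeCriteria,
                        interface_report)
from .mutscan import (PairNominationParams, SelectionCriteria,
                      StabilityScorerParams, scan_pair, write_candidates_tsv,
                      write_heatmap)
from .structure import ComplexView, read_structure

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    complex_path: str = ""
    group_a: tuple[str, ...] = ()
    group_b: tuple[str, ...] = ()
    params_path: str | None = None
    sites: list[tuple[str, int, str]] = field(default_factory=list)
    contact: ContactCriteria = field(default_factory=ContactCriteria)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    bridge: SaltBridgeCriteria = field(default_factory=SaltBridgeCriteria)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    stability: StabilityScorerParams = field(default_factory=StabilityScorerParams)
    nomination: PairNominationParams = field(default_factory=PairNominationParams)
    nis_threshold: float = 0.05
    scan_n_points: int = 320
    seed: int = 0
    out_dir: str = "runs"
    alt_complex_path: str | None = None

    def validate_inputs(self) -> None:
        for p in (self.complex_path, self.alt_complex_path, self.params_path):
            if p and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if not self.group_a or not self.group_b:
            raise ConfigError("both chain groups must be set")


def parse_site(text: str) -> tuple[str, int, str]:
    """'B:1518' or 'B:100A' -> (chain, number, insertion code)."""
    chain, _, rest = text.partition(":")
    if not chain or not rest:
        raise ConfigError(f"bad site spec {text!r} (expected CHAIN:NUMBER)")
    icode = ""
    if rest and rest[-1].isalpha():
        icode = rest[-1]
        rest = rest[:-1]
    return (chain, int(rest), icode)


def load_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read config {path}")
    cfg = RunConfig()
    if cp.has_section("input"):
        sec = cp["input"]
        cfg.complex_path = sec.get("complex", cfg.complex_path)
        cfg.alt_complex_path = sec.get("alt_complex", cfg.alt_complex_path)
        cfg.params_path = sec.get("model_params", cfg.params_path)
        if "sites" in sec:
            cfg.sites = [parse_site(s.strip())
                         for s in sec["sites"].split(",") if s.strip()]
    if cp.has_section("groups"):
        cfg.group_a = tuple(c.strip() for c in cp["groups"]["group_a"].split(","))
        cfg.group_b = tuple(c.strip() for c in cp["groups"]["group_b"].split(","))
    if cp.has_section("contact"):
        cfg.contact = ContactCriteria(heavy_atom_cutoff=cp["contact"].getfloat(
            "heavy_atom_cutoff", 5.5))
        cfg.nis_threshold = cp["contact"].getfloat("nis_threshold", 0.05)
    if cp.has_section("hbond"):
        sec = cp["hbond"]
        cfg.hbond = HBondCriteria(
            donor_acceptor_max=sec.getfloat("donor_acceptor_max", 3.5),
            hydrogen_acceptor_max=sec.getfloat("hydrogen_acceptor_max", 2.5),
            min_angle_deg=sec.getfloat("min_angle_deg", 90.0))
    if cp.has_section("bridge"):
        cfg.bridge = SaltBridgeCriteria(
            max_distance=cp["bridge"].getfloat("max_distance", 4.0),
            include_histidine=cp["bridge"].getboolean("include_histidine", False))
    if cp.has_section("selection"):
        sec = cp["selection"]
        cfg.selection = SelectionCriteria(
            ddg_binding_min=sec.getfloat("ddg_binding_min", 0.8),
            ddg_folding_max=sec.getfloat("ddg_folding_max", 0.05))
    if cp.has_section("stability"):
        sec = cp["stability"]
        cfg.stability = StabilityScorerParams(
            w_clash=sec.getfloat("w_clash", 1.0),
            clash_distance=sec.getfloat("clash_distance", 2.6),
            w_lost_hbond=sec.getfloat("w_lost_hbond", 0.5),
            w_lost_bridge=sec.getfloat("w_lost_bridge", 0.5),
            w_burial=sec.getfloat("w_burial", 0.012))
    if cp.has_section("nomination"):
        sec = cp["nomination"]
        cfg.nomination = PairNominationParams(
            occupancy_min=sec.getfloat("occupancy_min", 0.5),
            proximity_cutoff=sec.getfloat("proximity_cutoff", 8.0),
            representative_pose=sec.getint("representative_pose", 0))
    if cp.has_section("run"):
        cfg.seed = cp["run"].getint("seed", 0)
        cfg.out_dir = cp["run"].get("out_dir", cfg.out_dir)
        cfg.scan_n_points = cp["run"].getint("scan_n_points", 320)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _effective_config_text(cfg: RunConfig) -> str:
    payload = {
        "complex": cfg.complex_path, "alt_complex": cfg.alt_complex_path,
        "group_a": list(cfg.group_a), "group_b": list(cfg.group_b),
        "model_params": cfg.params_path,
        "sites": [list(s) for s in cfg.sites],
        "contact": {"heavy_atom_cutoff": cfg.contact.heavy_atom_cutoff,
                    "nis_threshold": cfg.nis_threshold},
        "hbond": {"donor_acceptor_max": cfg.hbond.donor_acceptor_max,
                  "hydrogen_acceptor_max": cfg.hbond.hydrogen_acceptor_max,
                  "min_angle_deg": cfg.hbond.min_angle_deg},
        "bridge": {"max_distance": cfg.bridge.max_distance},
        "selection": {"ddg_binding_min": cfg.selection.ddg_binding_min,
                      "ddg_folding_max": cfg.selection.ddg_folding_max},
        "stability": {"w_clash": cfg.stability.w_clash,
                      "clash_distance": cfg.stability.clash_distance,
                      "w_lost_hbond": cfg.stability.w_lost_hbond,
                      "w_lost_bridge": cfg.stability.w_lost_bridge,
                      "w_burial": cfg.stability.w_burial},
        "nomination": {"occupancy_min": cfg.nomination.occupancy_min,
                       "proximity_cutoff": cfg.nomination.proximity_cutoff,
                       "representative_pose": cfg.nomination.representative_pose},
        "scan_n_points": cfg.scan_n_points,
        "seed": cfg.seed,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


class RunManifest:
    def __init__(self, cfg: RunConfig, out_dir: Path):
        self.out_dir = out_dir
        self.data = {"tool_version": __version__,
                     "config": json.loads(_effective_config_text(cfg)),
                     "stages": {}}

    def record(self, stage: str, inputs: list[Path], outputs: list[Path],
               seconds: float) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
            "wall_clock_s": round(seconds, 3),
        }

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @staticmethod
    def comparable(path) -> dict:
        """Manifest content with wall-clock fields stripped, for reproducibility
        comparisons."""
        with open(path) as fh:
            data = json.load(fh)
        for stage in data.get("stages", {}).values():
            stage.pop("wall_clock_s", None)
        return data


def _prepare(cfg: RunConfig):
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "effective_config.json", "w") as fh:
        fh.write(_effective_config_text(cfg) + "\n")
    st = read_structure(cfg.complex_path)
    if isinstance(st, list):
        st = st[0]
    view = ComplexView(st, frozenset(cfg.group_a), frozenset(cfg.group_b))
    params = load_model_params(cfg.params_path)
    return out, view, params


def run_interface(cfg: RunConfig) -> dict:
    """Interface descriptor + binding prediction; writes JSON and manifest."""
    t0 = time.time()
    out, view, params = _prepare(cfg)
    desc = interface_report(view, cfg.contact, cfg.hbond, cfg.bridge,
                            cfg.nis_threshold)
    pred = predict_binding_energy(desc, params)
    desc_path = out / "descriptor.json"
    desc.to_json(desc_path)
    pred_path = out / "prediction.json"
    pred.to_json(pred_path)
    manifest = RunManifest(cfg, out)
    manifest.record("interface", [Path(cfg.complex_path)],
                    [desc_path, pred_path], time.time() - t0)
    manifest.write()
    return {"descriptor": desc, "prediction": pred, "out_dir": str(out)}


def run_scan(cfg: RunConfig) -> dict:
    """19x19 paired scan at the two configured sites; writes heatmap TSVs,
    candidate table and manifest."""
    if len(cfg.sites) != 2:
        raise ConfigError(f"scan needs exactly 2 sites, got {len(cfg.sites)}")
    t0 = time.time()
    out, view, params = _prepare(cfg)
    matrix = scan_pair(view, cfg.sites[0], cfg.sites[1], cfg.contact,
                       params, cfg.stability, cfg.selection,
                       seed=cfg.seed, n_points=cfg.scan_n_points)
    outputs = []
    for channel in ("binding", "folding", "filter"):
        path = out / f"heatmap_{channel}.tsv"
        write_heatmap(matrix, path, channel)
        outputs.append(path)
    cand_path = out / "candidates.tsv"
    write_candidates_tsv(matrix, cand_path)
    outputs.append(cand_path)
    manifest = RunManifest(cfg, out)
    manifest.record("scan", [Path(cfg.complex_path)], outputs, time.time() - t0)
    manifest.write()
    return {"matrix": matrix, "out_dir": str(out)}


def run_compare_affinity(cfg: RunConfig) -> dict:
    """Binding energies of two alternative ligands against one receptor.

    The primary complex and `alt_complex` must share the receptor group;
    more negative dG is reported as the stronger binder."""
    if not cfg.alt_complex_path:
        raise ConfigError("compare needs alt_complex in [input]")
    t0 = time.time()
    out, view1, params = _prepare(cfg)
    st2 = read_structure(cfg.alt_complex_path)
    if isinstance(st2, list):
        st2 = st2[0]
    view2 = ComplexView(st2, frozenset(cfg.group_a), frozenset(cfg.group_b))
    d1 = interface_report(view1, cfg.contact, cfg.hbond, cfg.bridge,
                          cfg.nis_threshold)
    d2 = interface_report(view2, cfg.contact, cfg.hbond, cfg.bridge,
                          cfg.nis_threshold)
    dg1 = predict_binding_energy(d1, params).dg
    dg2 = predict_binding_energy(d2, params).dg
    if dg1 < dg2:
        stronger = "complex_1"
    elif dg2 < dg1:
        stronger = "complex_2"
    else:
        stronger = "tie"
    report = {"complex_1": {"path": cfg.complex_path, "dg_kcal_mol": dg1},
              "complex_2": {"path": cfg.alt_complex_path, "dg_kcal_mol": dg2},
              "difference_kcal_mol": dg2 - dg1,
              "stronger_binder": stronger}
    path = out / "comparison.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    manifest = RunManifest(cfg, out)
    manifest.record("compare",
                    [Path(cfg.complex_path), Path(cfg.alt_complex_path)],
                    [path], time.time() - t0)
    manifest.write()
    return report
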