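"""Interface descriptors for a two-group protein complex.

The descriptor collects, for one binary chain partition: interfacial
residue-residue contacts classified by polarity (charged/polar/apolar pairs),
buried surface area, the composition of the non-interacting surface (NIS),
and geometric hydrogen-bond and salt-bridge counts.  The classified contact
counts and NIS percentages are the regressors of the linear binding-affinity
model in :mod:`impscan.affinity`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .constants import HBOND_ACCEPTORS, HBOND_DONORS, POLARITY_CLASSES
from .sasa import SasaResult, compute_sasa
from .structure import ComplexView, Residue, heavy_atom_table

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]
IC_KEYS = ("cc", "cp", "ca", "pp", "pa", "aa")
_CLASS_LETTER = {"charged": "c", "polar": "p", "apolar": "a"}


class ConfigurationError(ValueError):
    pass


@dataclass
class ContactCriteria:
    """A contact is a cross-partition residue pair with any heavy-atom pair
    within `heavy_atom_cutoff`; residues are classified by `class_map`."""

    heavy_atom_cutoff: float = 5.5
    class_map: dict[str, str] = field(default_factory=lambda: dict(POLARITY_CLASSES))

    def __post_init__(self) -> None:
        if self.heavy_atom_cutoff <= 0:
            raise ConfigurationError("heavy_atom_cutoff must be positive")

    def residue_class(self, aa: str) -> str | None:
        if aa == "X":
            return None
        try:
            return self.class_map[aa]
        except KeyError:
            raise ConfigurationError(
                f"class_map has no entry for amino acid {aa!r}") from None


@dataclass
class HBondCriteria:
    donor_acceptor_max: float = 3.5
    hydrogen_acceptor_max: float = 2.5
    min_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if min(self.donor_acceptor_max, self.hydrogen_acceptor_max) <= 0:
            raise ConfigurationError("distance cutoffs must be positive")
        if not (0 < self.min_angle_deg <= 180):
            raise ConfigurationError("angle must be in (0, 180]")


@dataclass
class SaltBridgeCriteria:
    max_distance: float = 4.0
    include_histidine: bool = False
    basic_atoms: dict[str, frozenset[str]] = field(default_factory=lambda: {
        "K": frozenset({"NZ"}), "R": frozenset({"NE", "NH1", "NH2"})})
    acidic_atoms: dict[str, frozenset[str]] = field(default_factory=lambda: {
        "D": frozenset({"OD1", "OD2"}), "E": frozenset({"OE1", "OE2"})})

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ConfigurationError("max_distance must be positive")
        if self.include_histidine and "H" not in self.basic_atoms:
            self.basic_atoms = dict(self.basic_atoms)
            self.basic_atoms["H"] = frozenset({"ND1", "NE2"})


@dataclass
class InterfaceDescriptor:
    ic: dict[str, int]
    bsa: float
    nis_charged_pct: float
    nis_apolar_pct: float
    nis_polar_pct: float
    n_hbonds: int
    n_salt_bridges: int
    interface_residues_a: frozenset[ResidueKey]
    interface_residues_b: frozenset[ResidueKey]

    def total_contacts(self) -> int:
        return sum(self.ic.values())

    def to_json(self, path=None) -> str:
        payload = {
            "ic": dict(self.ic), "bsa": self.bsa,
            "nis_charged_pct": self.nis_charged_pct,
            "nis_apolar_pct": self.nis_apolar_pct,
            "nis_polar_pct": self.nis_polar_pct,
            "n_hbonds": self.n_hbonds,
            "n_salt_bridges": self.n_salt_bridges,
            "interface_residues_a": sorted(list(k) for k in self.interface_residues_a),
            "interface_residues_b": sorted(list(k) for k in self.interface_residues_b),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "InterfaceDescriptor":
        if isinstance(text_or_path, str) and text_or_path.lstrip().startswith("{"):
            payload = json.loads(text_or_path)
        else:
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            ic={k: int(v) for k, v in payload["ic"].items()},
            bsa=float(payload["bsa"]),
            nis_charged_pct=float(payload["nis_charged_pct"]),
            nis_apolar_pct=float(payload["nis_apolar_pct"]),
            nis_polar_pct=float(payload["nis_polar_pct"]),
            n_hbonds=int(payload["n_hbonds"]),
            n_salt_bridges=int(payload["n_salt_bridges"]),
            interface_residues_a=frozenset(
                (c, int(n), i) for c, n, i in payload["interface_residues_a"]),
            interface_residues_b=frozenset(
                (c, int(n), i) for c, n, i in payload["interface_residues_b"]),
        )


def ic_key(class_a: str, class_b: str) -> str:
    """Unordered class-pair key, e.g. ('polar','charged') -> 'cp'."""
    la, lb = _CLASS_LETTER[class_a], _CLASS_LETTER[class_b]
    order = {"c": 0, "p": 1, "a": 2}
    return la + lb if order[la] <= order[lb] else lb + la


def _side_atoms(view: ComplexView, group: frozenset[str]):
    return heavy_atom_table(view.structure, sorted(group))


def find_interface(view: ComplexView, criteria: ContactCriteria | None = None):
    """Interfacial residues and cross-partition contact pairs.

    Returns (residues_a, residues_b, contact_pairs) where contact pairs are
    ((key_a, key_b)) residue-address tuples.
    """
    criteria = criteria or ContactCriteria()
    coords_a, _, keys_a = _side_atoms(view, view.group_a)
    coords_b, _, keys_b = _side_atoms(view, view.group_b)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(coords_a) and len(coords_b):
        tree_a = cKDTree(coords_a)
        tree_b = cKDTree(coords_b)
        hits = tree_a.query_ball_tree(tree_b, criteria.heavy_atom_cutoff)
        for ia, blist in enumerate(hits):
            if not blist:
                continue
            ra = keys_a[ia][:3]
            for ib in blist:
                pairs.add((ra, keys_b[ib][:3]))
    residues_a = frozenset(p[0] for p in pairs)
    residues_b = frozenset(p[1] for p in pairs)
    return residues_a, residues_b, sorted(pairs)


def _residue_lookup(view: ComplexView) -> dict[ResidueKey, Residue]:
    return {(cid, r.author_number, r.insertion_code): r
            for cid, r in view.structure.iter_residues(sorted(view.chain_ids()))}


def classify_contacts(view: ComplexView, criteria: ContactCriteria | None = None,
                      contact_pairs=None) -> dict[str, int]:
    """Count contacts by unordered polarity-class pair {cc,cp,ca,pp,pa,aa}."""
    criteria = criteria or ContactCriteria()
    if contact_pairs is None:
        _, _, contact_pairs = find_interface(view, criteria)
    lookup = _residue_lookup(view)
    counts = {k: 0 for k in IC_KEYS}
    for ka, kb in contact_pairs:
        ca_class = criteria.residue_class(lookup[ka].aa)
        cb_class = criteria.residue_class(lookup[kb].aa)
        if ca_class is None or cb_class is None:
            log.warning("skipping contact with non-canonical residue: %s-%s", ka, kb)
            continue
        counts[ic_key(ca_class, cb_class)] += 1
    return counts


def _donor_acceptor_atoms(view: ComplexView, group: frozenset[str]):
    """(coords, keys, is_donor, is_acceptor) arrays for one side."""
    coords, keys, don, acc = [], [], [], []
    for cid, res in view.structure.iter_residues(sorted(group)):
        donors = set(HBOND_DONORS.get(res.aa, ()))
        if res.aa != "P":
            donors.add("N")
        acceptors = set(HBOND_ACCEPTORS.get(res.aa, ()))
        acceptors.add("O")
        for a in res.heavy_atoms():
            d = a.name in donors
            c = a.name in acceptors
            if d or c:
                coords.append(a.coords)
                keys.append((cid, res.author_number, res.insertion_code, a.name))
                don.append(d)
                acc.append(c)
    if not coords:
        return np.zeros((0, 3)), [], np.zeros(0, bool), np.zeros(0, bool)
    return np.asarray(coords), keys, np.asarray(don), np.asarray(acc)


def _hydrogens_near(view: ComplexView):
    """Map donor heavy-atom key -> list of hydrogen coords covalently close."""
    hyd: dict[tuple, list[np.ndarray]] = {}
    any_h = False
    for cid, res in view.structure.iter_residues(sorted(view.chain_ids())):
        hs = [a for a in res.atoms if not a.is_heavy]
        if not hs:
            continue
        any_h = True
        for heavy in res.heavy_atoms():
            key = (cid, res.author_number, res.insertion_code, heavy.name)
            for h in hs:
                if np.linalg.norm(h.coords - heavy.coords) < 1.25:
                    hyd.setdefault(key, []).append(h.coords)
    return any_h, hyd


def count_hydrogen_bonds(view: ComplexView, criteria: HBondCriteria | None = None):
    """Cross-partition hydrogen bonds.

    Without explicit hydrogens the rule is purely the donor-acceptor heavy
    atom distance; when the file carries hydrogens the HBplus-style H-A
    distance and D-H-A angle conditions are applied as well.  Each
    donor-acceptor atom pair counts once.
    """
    criteria = criteria or HBondCriteria()
    ca_, ka, da, aa_ = _donor_acceptor_atoms(view, view.group_a)
    cb_, kb, db, ab_ = _donor_acceptor_atoms(view, view.group_b)
    any_h, hyd = _hydrogens_near(view)
    bonds = []
    seen = set()
    if len(ca_) and len(cb_):
        tree_b = cKDTree(cb_)
        hits = cKDTree(ca_).query_ball_tree(tree_b, criteria.donor_acceptor_max)
        for ia, blist in enumerate(hits):
            for ib in blist:
                pair_id = frozenset((ka[ia], kb[ib]))
                if pair_id in seen:
                    continue
                ok = False
                for (di, dk, dc), (aj, ak_, ac) in (
                        ((da[ia], ka[ia], ca_[ia]), (ab_[ib], kb[ib], cb_[ib])),
                        ((db[ib], kb[ib], cb_[ib]), (aa_[ia], ka[ia], ca_[ia]))):
                    if not (di and aj):
                        continue
                    if not any_h:
                        ok = True
                        break
                    hlist = hyd.get(dk, [])
                    if not hlist:
                        ok = True   # donor lacking modeled H: heavy-atom rule
                        break
                    for h in hlist:
                        ha = np.linalg.norm(h - ac)
                        if ha > criteria.hydrogen_acceptor_max:
                            continue
                        v1 = dc - h
                        v2 = ac - h
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2))
                        angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if angle >= criteria.min_angle_deg:
                            ok = True
                            break
                    if ok:
                        break
                if ok:
                    seen.add(pair_id)
                    bonds.append((ka[ia], kb[ib]))
    return len(bonds), sorted(bonds)


def count_salt_bridges(view: ComplexView, criteria: SaltBridgeCriteria | None = None):
    """Cross-partition (basic, acidic) residue pairs with a close N-O contact.

    A pair counts once if the minimum distance between any listed basic
    nitrogen and any listed acidic oxygen is within `max_distance`.
    """
    criteria = criteria or SaltBridgeCriteria()

    def collect(group, table):
        out: dict[ResidueKey, list[np.ndarray]] = {}
        for cid, res in view.structure.iter_residues(sorted(group)):
            names = table.get(res.aa)
            if not names:
                continue
            coords = [a.coords for a in res.heavy_atoms() if a.name in names]
            if coords:
                out[(cid, res.author_number, res.insertion_code)] = coords
        return out

    bridges = set()
    for basic_group, acidic_group in ((view.group_a, view.group_b),
                                      (view.group_b, view.group_a)):
        basics = collect(basic_group, criteria.basic_atoms)
        acidics = collect(acidic_group, criteria.acidic_atoms)
        for bk, bcoords in basics.items():
            for ak, acoords in acidics.items():
                dmin = min(np.linalg.norm(b - a)
                           for b in bcoords for a in acoords)
                if dmin <= criteria.max_distance:
                    # orient key as (group_a residue, group_b residue)
                    if bk[0] in view.group_a:
                        bridges.add((bk, ak))
                    else:
                        bridges.add((ak, bk))
    return len(bridges), sorted(bridges)


def buried_surface_area(view: ComplexView, probe_radius: float = 1.4,
                        n_points: int = 960) -> float:
    """BSA = SASA(A alone) + SASA(B alone) - SASA(AB), clamped at zero."""
    st = view.structure
    sasa_ab = compute_sasa(st, sorted(view.chain_ids()), probe_radius, n_points)
    sasa_a = compute_sasa(st, sorted(view.group_a), probe_radius, n_points)
    sasa_b = compute_sasa(st, sorted(view.group_b), probe_radius, n_points)
    bsa = (sum(sasa_a.per_atom.values()) + sum(sasa_b.per_atom.values())
           - sum(sasa_ab.per_atom.values()))
    if bsa < 0:
        if bsa < -1.0:
            warnings.warn(f"negative BSA ({bsa:.2f} A^2) clamped to 0")
        bsa = 0.0
    return float(bsa)


def nis_percentages(view: ComplexView, sasa_threshold_relative: float = 0.05,
                    criteria: ContactCriteria | None = None,
                    complex_sasa: SasaResult | None = None,
                    interface_sets=None) -> tuple[float, float, float]:
    """Composition of the non-interacting surface of the bound complex.

    Over residues with relative SASA >= threshold that are NOT interfacial,
    returns (charged %, apolar %, polar %) of the NIS residue count.
    """
    criteria = criteria or ContactCriteria()
    if complex_sasa is None:
        complex_sasa = compute_sasa(view.structure, sorted(view.chain_ids()))
    if interface_sets is None:
        ra, rb, _ = find_interface(view, criteria)
    else:
        ra, rb = interface_sets
    interfacial = ra | rb
    lookup = _residue_lookup(view)
    counts = {"charged": 0, "polar": 0, "apolar": 0}
    for rkey, rel in complex_sasa.per_residue_relative.items():
        if rel < sasa_threshold_relative or rkey in interfacial:
            continue
        cls = criteria.residue_class(lookup[rkey].aa)
        if cls is None:
            continue
        counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no NIS residues; percentages set to 0")
        return (0.0, 0.0, 0.0)
    return (100.0 * counts["charged"] / total,
            100.0 * counts["apolar"] / total,
            100.0 * counts["polar"] / total)


def interface_report(view: ComplexView,
                     contact_criteria: ContactCriteria | None = None,
                     hbond_criteria: HBondCriteria | None = None,
                     bridge_criteria: SaltBridgeCriteria | None = None,
                     nis_threshold: float = 0.05,
                     probe_radius: float = 1.4, n_points: int = 960,
                     include_bsa: bool = True) -> InterfaceDescriptor:
    """One-pass fully populated interface descriptor (deterministic)."""
    contact_criteria = contact_criteria or ContactCriteria()
    ra, rb, pairs = find_interface(view, contact_criteria)
    ic = classify_contacts(view, contact_criteria, contact_pairs=pairs)
    nhb, _ = count_hydrogen_bonds(view, hbond_criteria)
    nsb, _ = count_salt_bridges(view, bridge_criteria)
    complex_sasa = compute_sasa(view.structure, sorted(view.chain_ids()),
                                probe_radius, n_points)
    nis_c, nis_a, nis_p = nis_percentages(
        view, nis_threshold, contact_criteria,
        complex_sasa=complex_sasa, interface_sets=(ra, rb))
    bsa = buried_surface_area(view, probe_radius, n_points) if include_bsa else 0.0
    return InterfaceDescriptor(
        ic=ic, bsa=bsa, nis_charged_pct=nis_c, nis_apolar_pct=nis_a,
        nis_polar_pct=nis_p, n_hbonds=nhb, n_salt_bridges=nsb,
        interface_residues_a=ra, interface_residues_b=rb)
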