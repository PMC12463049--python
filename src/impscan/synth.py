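"""Synthetic test-input generators with planted, self-verified ground truth.

The generators build geometric toys, not physical proteins: residues are
compact atom groups with correct names/elements placed so that exactly the
requested interface features exist under the package's default criteria
(contacts at 4.6 A between anchor atoms, salt bridges at 3.7 A between
charged-group atoms — inside the 4.0 A bridge cutoff but outside the 3.5 A
hydrogen-bond cutoff — and hydrogen bonds at 2.9 A between a backbone
carbonyl O and a backbone N placed at a lateral offset, so one residue pair
can host both a bridge and an H-bond).  Every generator re-runs the analysis
modules on its output and asserts equality with its truth ledger before
returning, retrying with small jitter a bounded number of times, so a
returned fixture is a verified test input by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .fg import (ConformerEnsemble, FgClusterCriteria, annotate_ensemble,
                 find_fg_motifs)
from .geometry import build_peptide_chain, rotation_about_axis
from .interface import (ContactCriteria, HBondCriteria, IC_KEYS,
                        SaltBridgeCriteria, classify_contacts,
                        count_hydrogen_bonds, count_salt_bridges,
                        find_interface, interface_report, nis_percentages)
from .sasa import sphere_points
from .structure import (Atom, Chain, ComplexView, PoseEnsemble, Residue,
                        Structure, StructureError)

GOLDEN_ANGLE = 2.399963229728653


class GenerationError(RuntimeError):
    pass


@dataclass
class ComplexSpec:
    """Recipe for a two-chain toy complex with planted interface features."""

    n_residues_a: int = 16
    n_residues_b: int = 16
    planted_ic: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in IC_KEYS})
    planted_salt_bridges: int = 0
    planted_hbonds: int = 0
    separation: float = 10.0
    seed: int = 0
    contact_positions: list[float] | None = None
    backbone_anchored: bool = False

    def __post_init__(self) -> None:
        for k in IC_KEYS:
            self.planted_ic.setdefault(k, 0)
        if any(v < 0 for v in self.planted_ic.values()):
            raise GenerationError("negative planted contact count")
        if self.planted_salt_bridges > self.planted_ic["cc"]:
            raise GenerationError(
                "each salt bridge implies one cc contact: need "
                f"cc >= {self.planted_salt_bridges}")
        total = sum(self.planted_ic.values())
        if self.planted_hbonds > total:
            raise GenerationError(
                f"can host at most one H-bond per contact pair ({total})")
        if self.contact_positions is not None \
                and len(self.contact_positions) != total:
            raise GenerationError("contact_positions length != total contacts")


@dataclass
class TruthLedger:
    """Planted ground truth for a generated fixture."""

    contact_pairs: list = field(default_factory=list)
    bridge_pairs: list = field(default_factory=list)
    hbond_atom_pairs: list = field(default_factory=list)
    interface_residues_a: set = field(default_factory=set)
    interface_residues_b: set = field(default_factory=set)
    ic: dict = field(default_factory=dict)
    n_hbonds: int = 0
    n_salt_bridges: int = 0
    nis_pcts: tuple = (0.0, 0.0, 0.0)
    bsa: float = 0.0
    occupancy: dict = field(default_factory=dict)
    fg: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(list(x) for x in o)
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(type(o))
        text = json.dumps(asdict(self), indent=2, default=default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# residue types used per class pair: (A-side aa, B-side aa)
_PAIR_TYPES = {
    "cc": ("K", "R"), "cp": ("K", "S"), "ca": ("K", "L"),
    "pp": ("S", "T"), "pa": ("S", "L"), "aa": ("L", "L"),
}
_BRIDGE_TYPES = ("K", "E")
_SIDECHAIN_ANCHOR = {"K": "NZ", "R": "NH1", "E": "OE1", "S": "OG",
                     "T": "OG1", "L": "CD1"}
_FILLER_CYCLE = ("K", "S", "L")

CONTACT_ANCHOR_DIST = 4.6   # generic contact, anchor-to-anchor, A
BRIDGE_ANCHOR_DIST = 3.7    # salt bridge: <= 4.0 but > 3.5 (never an H-bond)
HBOND_DIST = 2.9            # backbone O...N
HBOND_LATERAL = 3.0         # lateral offset of the O/N pair from the anchors
DEFAULT_SPACING = 14.0


def _element_of(name: str) -> str:
    n = name.lstrip("0123456789")
    return "S" if n[:1] == "S" and name in ("SG", "SD") else n[0]


def _spiral_residue(aa: str, author_number: int, column_x: float, side: int,
                    anchor_atom: str, anchor_pos: np.ndarray,
                    special: dict[str, np.ndarray] | None = None,
                    jitter: np.ndarray | None = None) -> Residue:
    """Toy residue: anchor (and any special atoms) at exact positions, the
    remaining atoms on a deterministic spiral receding from the interface.

    `side` is -1 for the group-a half-space (z < 0) and +1 for group-b.
    """
    from .constants import SIDECHAIN_ATOMS
    names = ["N", "CA", "C", "O"] + SIDECHAIN_ATOMS[aa]
    special = special or {}
    atoms = []
    j = 0
    for name in names:
        if name == anchor_atom:
            pos = np.asarray(anchor_pos, float)
        elif name in special:
            pos = np.asarray(special[name], float)
        else:
            pos = np.array([column_x + 0.9 * np.cos(GOLDEN_ANGLE * j),
                            0.9 * np.sin(GOLDEN_ANGLE * j),
                            side * (3.2 + 0.55 * j)])
            if jitter is not None:
                pos = pos + jitter[j % len(jitter)]
            j += 1
        atoms.append(Atom(name=name, element=_element_of(name), coords=pos))
    return Residue(aa=aa, author_number=author_number, atoms=atoms)


def _blob_residue(aa: str, author_number: int, center: np.ndarray,
                  scale: float = 1.7) -> Residue:
    """Compact isolated residue: CA at `center`, other atoms on a small
    deterministic sphere around it."""
    from .constants import SIDECHAIN_ATOMS
    names = ["N", "CA", "C", "O"] + SIDECHAIN_ATOMS[aa]
    n_other = len(names) - 1
    dirs = sphere_points(max(32, n_other * 3))[::3][:n_other]
    atoms = []
    k = 0
    for name in names:
        if name == "CA":
            pos = np.asarray(center, float)
        else:
            pos = np.asarray(center, float) + scale * dirs[k]
            k += 1
        atoms.append(Atom(name=name, element=_element_of(name), coords=pos))
    return Residue(aa=aa, author_number=author_number, atoms=atoms)


def _filler_positions(n: int, side: int, separation: float):
    for i in range(n):
        row, col = divmod(i, 6)
        yield np.array([9.0 * col, 28.0 + 7.0 * row,
                        side * (separation / 2.0 + 7.0 + 6.0 * row)])


def build_toy_complex(spec: ComplexSpec,
                      max_attempts: int = 100) -> tuple[Structure, TruthLedger]:
    """Two-chain complex (chains A and B) with exactly the planted features.

    The returned ledger records contact pairs with classes, bridge and
    H-bond pairs, interface residue sets, analytic NIS percentages, and the
    measured BSA; generation self-verifies against the interface module and
    raises after `max_attempts` jittered retries.
    """
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for attempt in range(max_attempts):
        jitter = (rng.normal(0.0, 0.02, size=(16, 3)) if attempt else
                  np.zeros((16, 3)))
        try:
            return _build_toy_complex_once(spec, jitter)
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"could not realize spec after {max_attempts} attempts: {last_err}")


def _build_toy_complex_once(spec: ComplexSpec, jitter: np.ndarray):
    # expand the ordered feature list
    features = []        # (class_pair, is_bridge, hosts_hbond)
    bridges_left = spec.planted_salt_bridges
    for key in IC_KEYS:
        for _ in range(spec.planted_ic[key]):
            is_bridge = key == "cc" and bridges_left > 0
            if is_bridge:
                bridges_left -= 1
            features.append([key, is_bridge, False])
    for i in range(spec.planted_hbonds):
        features[i][2] = True
    total = len(features)
    if spec.n_residues_a < total or spec.n_residues_b < total:
        raise GenerationError(
            f"need at least {total} residues per chain for {total} contacts")
    xs = (list(spec.contact_positions) if spec.contact_positions is not None
          else [DEFAULT_SPACING * k for k in range(total)])

    ledger = TruthLedger(ic={k: spec.planted_ic[k] for k in IC_KEYS},
                         n_hbonds=spec.planted_hbonds,
                         n_salt_bridges=spec.planted_salt_bridges)
    res_a: list[Residue] = []
    res_b: list[Residue] = []
    for k, (key, is_bridge, hosts_hb) in enumerate(features):
        x = xs[k]
        if is_bridge:
            aa_a, aa_b = _BRIDGE_TYPES
            dist = BRIDGE_ANCHOR_DIST
        else:
            aa_a, aa_b = _PAIR_TYPES[key]
            dist = CONTACT_ANCHOR_DIST
        if spec.backbone_anchored and not is_bridge:
            anchor_a, anchor_b = "CA", "CA"
        else:
            anchor_a = _SIDECHAIN_ANCHOR[aa_a]
            anchor_b = _SIDECHAIN_ANCHOR[aa_b]
        num = k + 1
        special_a: dict[str, np.ndarray] = {}
        special_b: dict[str, np.ndarray] = {}
        if hosts_hb:
            special_a["O"] = np.array([x + HBOND_LATERAL, 0.0, -HBOND_DIST / 2])
            special_b["N"] = np.array([x + HBOND_LATERAL, 0.0, +HBOND_DIST / 2])
        ra = _spiral_residue(aa_a, num, x, -1, anchor_a,
                             np.array([x, 0.0, -dist / 2]), special_a, jitter)
        rb = _spiral_residue(aa_b, num, x, +1, anchor_b,
                             np.array([x, 0.0, +dist / 2]), special_b, jitter)
        res_a.append(ra)
        res_b.append(rb)
        ka = ("A", num, "")
        kb = ("B", num, "")
        ledger.contact_pairs.append((ka, kb, key))
        ledger.interface_residues_a.add(ka)
        ledger.interface_residues_b.add(kb)
        if is_bridge:
            ledger.bridge_pairs.append((ka, kb))
        if hosts_hb:
            ledger.hbond_atom_pairs.append(((*ka, "O"), (*kb, "N")))

    # non-interacting surface fillers, classes cycling charged/polar/apolar
    filler_counts = {"charged": 0, "polar": 0, "apolar": 0}
    cls_of = {"K": "charged", "S": "polar", "L": "apolar"}
    for side, res_list, n_total, cid in ((-1, res_a, spec.n_residues_a, "A"),
                                         (+1, res_b, spec.n_residues_b, "B")):
        n_fill = n_total - total
        for i, pos in enumerate(_filler_positions(n_fill, side,
                                                  spec.separation)):
            aa = _FILLER_CYCLE[i % 3]
            filler_counts[cls_of[aa]] += 1
            res_list.append(_blob_residue(aa, total + 1 + i, pos))
    structure = Structure(chains=[Chain("A", res_a), Chain("B", res_b)])
    view = ComplexView(structure, frozenset("A"), frozenset("B"))

    n_fillers = sum(filler_counts.values())
    if n_fillers:
        ledger.nis_pcts = tuple(100.0 * filler_counts[c] / n_fillers
                                for c in ("charged", "apolar", "polar"))

    _verify_complex(view, ledger)
    desc = interface_report(view)
    ledger.bsa = desc.bsa
    ledger.extras["descriptor"] = json.loads(desc.to_json())
    return structure, ledger


def _verify_complex(view: ComplexView, ledger: TruthLedger) -> None:
    ra, rb, pairs = find_interface(view)
    want_pairs = sorted((tuple(a), tuple(b)) for a, b, _ in ledger.contact_pairs)
    if sorted(pairs) != want_pairs:
        raise GenerationError(
            f"contact pairs mismatch: got {len(pairs)}, want {len(want_pairs)}")
    ic = classify_contacts(view, contact_pairs=pairs)
    if ic != ledger.ic:
        raise GenerationError(f"ic mismatch: {ic} != {ledger.ic}")
    nhb, hb_pairs = count_hydrogen_bonds(view)
    if nhb != ledger.n_hbonds:
        raise GenerationError(f"hbond mismatch: {nhb} != {ledger.n_hbonds}")
    nsb, sb_pairs = count_salt_bridges(view)
    if nsb != ledger.n_salt_bridges:
        raise GenerationError(
            f"bridge mismatch: {nsb} != {ledger.n_salt_bridges}")
    want_sb = sorted((tuple(a), tuple(b)) for a, b in ledger.bridge_pairs)
    if sorted(sb_pairs) != want_sb:
        raise GenerationError("bridge pairs mismatch")
    nis = nis_percentages(view)
    if not np.allclose(nis, ledger.nis_pcts, atol=1e-9):
        raise GenerationError(f"NIS mismatch: {nis} != {ledger.nis_pcts}")


def build_peptide(sequence: str, conformation: str = "extended",
                  seed: int = 0, chain_id: str = "A",
                  first_number: int = 1) -> Chain:
    """Idealized full-atom peptide chain (extended or alpha-helical)."""
    return build_peptide_chain(sequence, conformation, chain_id, first_number)


# ---------------------------------------------------------------------------
# Pose ensembles

def _transform_ligand(structure: Structure, ligand_chains, R: np.ndarray,
                      center: np.ndarray, translation: np.ndarray) -> Structure:
    out = structure.copy()
    for cid, res in out.iter_residues(sorted(ligand_chains)):
        for atom in res.atoms:
            atom.coords = center + R @ (atom.coords - center) + translation
    return out


def build_pose_ensemble(view: ComplexView, n_poses: int,
                        jitter_translation: float = 0.0,
                        jitter_rotation: float = 0.0,
                        hot_residues=None, hot_occupancies=None,
                        decoy_occupancy: float = 0.25,
                        seed: int = 0) -> tuple[PoseEnsemble, TruthLedger]:
    """Rigid-body pose ensemble of the ligand group with an occupancy ledger.

    Without `hot_residues` the poses are small random rigid jitters of the
    ligand (zero jitter gives identical poses).  With `hot_residues` (ligand
    residue addresses) the ensemble is built so each hot residue stays
    interfacial in its requested fraction of poses (`hot_occupancies`,
    default 0.9) while every other interfacial ligand residue ("decoy")
    survives in only `decoy_occupancy` of poses; pose 0 always keeps all
    contacts and is the natural representative pose.
    """
    if n_poses < 1:
        raise GenerationError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    st = view.structure
    ligand = view.group_b
    lig_coords = [a.coords for cid, r in st.iter_residues(sorted(ligand))
                  for a in r.atoms]
    center = np.mean(lig_coords, axis=0)
    ledger = TruthLedger()

    if hot_residues is None:
        poses = []
        for p in range(n_poses):
            if jitter_rotation > 0 or jitter_translation > 0:
                axis = rng.standard_normal(3)
                angle = rng.uniform(-jitter_rotation, jitter_rotation)
                R = rotation_about_axis(axis, angle) if jitter_rotation > 0 \
                    else np.eye(3)
                t = (rng.uniform(-1, 1, 3) * jitter_translation
                     if jitter_translation > 0 else np.zeros(3))
            else:
                R, t = np.eye(3), np.zeros(3)
            poses.append(ComplexView(_transform_ligand(st, ligand, R, center, t),
                                     view.group_a, view.group_b))
        ensemble = PoseEnsemble(poses=poses)
        ledger.occupancy = _occupancy_table(ensemble, ligand)
        return ensemble, ledger

    hot_residues = [tuple(h) for h in hot_residues]
    if hot_occupancies is None:
        hot_occupancies = [0.9] * len(hot_residues)
    if len(hot_occupancies) != len(hot_residues):
        raise GenerationError("hot_occupancies length mismatch")
    base_ra, base_rb, _ = find_interface(view)
    base_lig = {k for k in base_rb if k[0] in ligand} | \
               {k for k in base_ra if k[0] in ligand}
    for h in hot_residues:
        if h not in base_lig:
            raise GenerationError(f"hot residue {h} not interfacial in input")
    decoys = sorted(base_lig - set(hot_residues))
    kept_hot = [round(o * n_poses) for o in hot_occupancies]
    kept_decoy = round(decoy_occupancy * n_poses)
    if kept_decoy > min(kept_hot):
        raise GenerationError(
            "decoy_occupancy must not exceed the smallest hot occupancy")
    order = sorted(range(len(hot_residues)), key=lambda i: -kept_hot[i])

    poses = []
    for p in range(n_poses):
        keep_hots = [hot_residues[i] for i in order if p < kept_hot[i]]
        keep_decoys = p < kept_decoy
        target = set(keep_hots) | (set(decoys) if keep_decoys else set())
        pose_st = _realize_pose(st, view, ligand, base_lig, target, keep_hots)
        poses.append(ComplexView(pose_st, view.group_a, view.group_b))
    ensemble = PoseEnsemble(poses=poses)
    ledger.occupancy = _occupancy_table(ensemble, ligand)
    for h, occ in zip(hot_residues, hot_occupancies):
        got = ledger.occupancy.get(h, 0.0)
        want = round(occ * n_poses) / n_poses
        if abs(got - want) > 1e-9:
            raise GenerationError(
                f"occupancy of {h}: achieved {got}, wanted {want}")
    ledger.extras["hot_residues"] = [list(h) for h in hot_residues]
    ledger.extras["decoys"] = [list(d) for d in decoys]
    return ensemble, ledger


def _realize_pose(st: Structure, view: ComplexView, ligand, base_lig,
                  target: set, keep_hots: list) -> Structure:
    if target == base_lig:
        return st.copy()
    if not target:
        return _transform_ligand(st, ligand, np.eye(3), np.zeros(3),
                                 np.array([0.0, 0.0, 40.0]))
    # tilt about a y-parallel axis through the kept residues' heavy centroid
    pts = []
    for key in keep_hots or sorted(target):
        cid, num, icode = key
        res = st.get_chain(cid).get_residue(num, icode)
        pts.extend(a.coords for a in res.heavy_atoms())
    pivot = np.mean(pts, axis=0)
    for angle in (3, 5, 8, 12, 16, 20, 25, 30, 40, 55, 70):
        for sign in (1, -1):
            R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), sign * angle)
            cand = _transform_ligand(st, ligand, R, pivot, np.zeros(3))
            cview = ComplexView(cand, view.group_a, view.group_b)
            ra, rb, _ = find_interface(cview)
            lig_now = {k for k in (ra | rb) if k[0] in ligand}
            if lig_now == target:
                return cand
    raise GenerationError(f"no rigid tilt realizes interface pattern {target}")


def _occupancy_table(ensemble: PoseEnsemble, ligand) -> dict:
    counts: dict[tuple, int] = {}
    for pose in ensemble.poses:
        ra, rb, _ = find_interface(pose)
        for k in (ra | rb):
            if k[0] in ligand:
                counts[k] = counts.get(k, 0) + 1
    return {k: c / len(ensemble) for k, c in counts.items()}


# ---------------------------------------------------------------------------
# FG conformer fixtures

def _fg_sequence(sequence_length: int, n_fg: int) -> tuple[str, list[int]]:
    if sequence_length < 5 * n_fg + 3:
        raise GenerationError(
            f"sequence_length {sequence_length} too short for {n_fg} FG motifs")
    seq = ["S"] * sequence_length
    positions = []
    for m in range(n_fg):
        p = 3 + 5 * m            # 0-based index of the F
        seq[p] = "F"
        seq[p + 1] = "G"
        positions.append(p + 1)  # 1-based
    return "".join(seq), positions


def build_fg_fixture(n_conformers: int, sequence_length: int, n_fg: int,
                     planted: tuple[int, int, float], seed: int = 0,
                     chain_id: str = "R",
                     max_attempts: int = 20) -> tuple[ConformerEnsemble, TruthLedger]:
    """Conformer ensemble of one FG-motif chain with a planted best cluster.

    `planted` = (conformer index, clique size, mutual distance cutoff): the
    designated conformer carries exactly `clique size` exposed FG motifs that
    are mutually within the cutoff, while every other conformer's largest
    mutual cluster is strictly smaller (its remaining motifs are dispersed).
    Self-verified against the FG analysis module.
    """
    p_idx, p_clique, within = planted
    if not (0 <= p_idx < n_conformers):
        raise GenerationError("planted conformer index out of range")
    if not (2 <= p_clique <= n_fg):
        raise GenerationError("planted clique size must be in [2, n_fg]")
    seq, fg_positions = _fg_sequence(sequence_length, n_fg)
    rng = np.random.default_rng(seed)
    criteria = FgClusterCriteria(min_exposed_motifs=p_clique,
                                 mutual_distance_cutoff=within)
    last = None
    for attempt in range(max_attempts):
        jitter_scale = 0.0 if attempt == 0 else 0.3
        conformers, sizes = [], []
        for c in range(n_conformers):
            k = p_clique if c == p_idx else 1 + (c % max(1, p_clique - 1))
            sizes.append(k)
            conformers.append(_fg_conformer(seq, fg_positions, k, within,
                                            chain_id, rng, jitter_scale))
        ensemble = ConformerEnsemble(
            conformers=conformers,
            provenance={"seed": seed, "planted": list(planted)})
        annotations = annotate_ensemble(ensemble, criteria)
        got_sizes = [a["cluster_size"] for a in annotations]
        if got_sizes == sizes and all(
                len(a["exposed"]) == n_fg for a in annotations):
            ledger = TruthLedger(fg={
                "positions": fg_positions,
                "planted_conformer": p_idx,
                "planted_clique_size": p_clique,
                "within": within,
                "cluster_sizes": sizes,
                "exposed": [list(fg_positions)] * n_conformers,
                "clique_members": annotations[p_idx]["cluster_members"],
            })
            return ensemble, ledger
        last = (got_sizes, sizes)
    raise GenerationError(f"FG fixture failed to verify: {last}")


def _fg_conformer(seq: str, fg_positions: list[int], cluster_size: int,
                  within: float, chain_id: str, rng, jitter_scale: float
                  ) -> Structure:
    n_fg = len(fg_positions)
    ring_r = 0.4 * within
    centers = {}
    for j in range(cluster_size):
        th = 2 * np.pi * j / cluster_size
        centers[fg_positions[j]] = np.array(
            [ring_r * np.cos(th), ring_r * np.sin(th), 0.0])
    for m in range(cluster_size, n_fg):
        centers[fg_positions[m]] = np.array(
            [1.8 * within * (m - cluster_size + 1) + ring_r + within,
             -40.0, 0.0])
    if jitter_scale:
        for k in centers:
            centers[k] = centers[k] + rng.normal(0, jitter_scale, 3)
    residues = []
    blob_i = 0
    for i, aa in enumerate(seq):
        pos1 = i + 1
        if pos1 in centers:
            center = centers[pos1]
        elif (pos1 - 1) in centers:     # the G right after its F
            center = centers[pos1 - 1] + np.array([0.0, 6.0, 0.0])
        else:
            row, col = divmod(blob_i, 14)
            center = np.array([8.0 * col, 120.0 + 8.0 * row, 0.0])
            blob_i += 1
        residues.append(_blob_residue(aa, pos1, center))
    return Structure(chains=[Chain(chain_id, residues)])


def build_buried_phe(n_shell: int = 48) -> tuple[Structure, int]:
    """Single-chain fixture: one Phe fully enclosed by a shell of serines.

    Returns (structure, 1-based position of the Phe)."""
    phe = _blob_residue("F", 1, np.zeros(3))
    residues = [phe]
    pts_inner = sphere_points(max(32, n_shell // 2)) * 4.6
    pts_outer = sphere_points(max(32, n_shell - n_shell // 2)) * 6.4
    num = 2
    for pts in (pts_inner[:n_shell // 2], pts_outer[:n_shell - n_shell // 2]):
        for p in pts:
            residues.append(_blob_residue("S", num, p, scale=0.9))
            num += 1
    return Structure(chains=[Chain("R", residues)]), 1
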