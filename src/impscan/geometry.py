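"""Geometric primitives: internal-coordinate placement, idealized residue
templates, chi-angle manipulation and peptide backbone construction.

Residue template coordinates come from the chemical-component dictionary
bundled with biotite; side chains are grafted onto a target backbone by
superimposing the template's N/CA/C frame and chi angles are set by rotating
the distal part of the side chain about the chi bond.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bsinfo

from .constants import AA_1TO3, CHI_ATOMS, SIDECHAIN_ATOMS
from .structure import Atom, Chain, Residue, Structure, StructureError


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D with bond C-D, angle B-C-D and dihedral A-B-C-D (NeRF)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(tor),
                  bond * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = _normalize(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through origin."""
    u = _normalize(np.asarray(axis, dtype=float))
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


# ---------------------------------------------------------------------------
# Residue templates

@lru_cache(maxsize=32)
def residue_template(aa: str) -> tuple[tuple[str, ...], np.ndarray, dict[str, set[str]]]:
    """Idealized heavy-atom template for one amino acid.

    Returns (atom names, coordinates, bond adjacency by atom name).
    """
    if aa not in AA_1TO3:
        raise StructureError(f"not a canonical amino acid: {aa!r}")
    arr = bsinfo.residue(AA_1TO3[aa])
    heavy = arr[arr.element != "H"]
    wanted = set(("N", "CA", "C", "O")) | set(SIDECHAIN_ATOMS[aa])
    mask = np.isin(heavy.atom_name, list(wanted))
    heavy = heavy[mask]
    names = tuple(heavy.atom_name.tolist())
    coords = np.asarray(heavy.coord, dtype=float)
    adjacency: dict[str, set[str]] = {n: set() for n in names}
    bonds = heavy.bonds.as_array()
    for i, j, _ in bonds:
        ni, nj = names[int(i)], names[int(j)]
        adjacency[ni].add(nj)
        adjacency[nj].add(ni)
    return names, coords, adjacency


def _moving_atoms(adjacency: dict[str, set[str]], pivot: str, blocked: str) -> set[str]:
    """Atoms reachable from `pivot` without passing through `blocked`."""
    seen = {blocked, pivot}
    stack = [pivot]
    out = set()
    while stack:
        cur = stack.pop()
        for nb in adjacency[cur]:
            if nb not in seen:
                seen.add(nb)
                out.add(nb)
                stack.append(nb)
    return out


def set_chi(names: list[str], coords: np.ndarray, adjacency: dict[str, set[str]],
            chi_quad: tuple[str, str, str, str], value_deg: float) -> np.ndarray:
    """Return coordinates with one chi dihedral rotated to `value_deg`."""
    idx = {n: i for i, n in enumerate(names)}
    a, b, c, d = chi_quad
    cur = dihedral(coords[idx[a]], coords[idx[b]], coords[idx[c]], coords[idx[d]])
    delta = value_deg - cur
    moving = _moving_atoms(adjacency, c, b)
    R = rotation_about_axis(coords[idx[c]] - coords[idx[b]], delta)
    out = coords.copy()
    pivot = coords[idx[c]]
    for n in moving:
        out[idx[n]] = pivot + R @ (out[idx[n]] - pivot)
    return out


def build_sidechain(backbone_n: np.ndarray, backbone_ca: np.ndarray,
                    backbone_c: np.ndarray, aa: str,
                    chi_values: tuple[float, ...] | None = None
                    ) -> list[tuple[str, str, np.ndarray]]:
    """Graft an idealized side chain (CB and beyond) onto a backbone frame.

    Returns a list of (atom_name, element, coords) for the side-chain heavy
    atoms.  `chi_values` sets successive chi dihedrals; None keeps the
    template's ideal conformation.
    """
    if aa == "G":
        return []
    names, coords, adjacency = residue_template(aa)
    names = list(names)
    idx = {n: i for i, n in enumerate(names)}
    tmpl_bb = np.array([coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]]])
    target_bb = np.array([backbone_n, backbone_ca, backbone_c])
    R, t = kabsch(tmpl_bb, target_bb)
    placed = coords @ R.T + t
    if chi_values:
        quads = CHI_ATOMS[aa]
        for quad, val in zip(quads, chi_values):
            placed = set_chi(names, placed, adjacency, quad, val)
    out = []
    for n in SIDECHAIN_ATOMS[aa]:
        el = "S" if n.startswith("S") else n[0]
        out.append((n, el, placed[idx[n]]))
    return out


# ---------------------------------------------------------------------------
# Peptide backbone construction

_BB_GEOM = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "omega": 180.0,
}

PHI_PSI = {"extended": (-140.0, 135.0), "helix": (-57.0, -47.0)}


def build_backbone(n_residues: int, conformation: str = "extended"
                   ) -> list[dict[str, np.ndarray]]:
    """Idealized backbone (N, CA, C, O per residue) for a homoconformation."""
    if conformation not in PHI_PSI:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = PHI_PSI[conformation]
    g = _BB_GEOM
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(g["ang_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       g["c_n"], g["ang_ca_c_n"], psi)
        ca = place_atom(prev["CA"], prev["C"], n,
                        g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c = place_atom(prev["C"], n, ca, g["ca_c"], g["ang_n_ca_c"], phi)
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: O_i placed off C_i, trans to the next N (psi + 180)
    for i, r in enumerate(res):
        r["O"] = place_atom(r["N"], r["CA"], r["C"],
                            g["c_o"], g["ang_ca_c_o"], psi + 180.0)
    return res


def build_peptide_chain(sequence: str, conformation: str = "extended",
                        chain_id: str = "A", first_number: int = 1,
                        chi: float = 180.0) -> Chain:
    """Full-atom idealized peptide chain; side chains in template conformation
    with all rotatable chi set to `chi`."""
    for aa in sequence:
        if aa not in AA_1TO3:
            raise StructureError(f"non-canonical letter {aa!r} in sequence")
    backbone = build_backbone(len(sequence), conformation)
    residues = []
    for i, aa in enumerate(sequence):
        bb = backbone[i]
        atoms = [Atom("N", "N", bb["N"]), Atom("CA", "C", bb["CA"]),
                 Atom("C", "C", bb["C"]), Atom("O", "O", bb["O"])]
        nchi = len(CHI_ATOMS[aa])
        chis = tuple([chi] * nchi) if nchi else None
        for name, el, xyz in build_sidechain(bb["N"], bb["CA"], bb["C"], aa, chis):
            atoms.append(Atom(name, el, xyz))
        residues.append(Residue(aa=aa, author_number=first_number + i, atoms=atoms))
    return Chain(id=chain_id, residues=residues)


def structure_from_chain(chain: Chain) -> Structure:
    return Structure(chains=[chain])
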