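"""Deterministic Shrake-Rupley solvent-accessible surface area.

Quadrature points come from a fixed golden-spiral (Fibonacci) sphere set, so
identical inputs always give bit-identical areas; no random number generator
is involved.  Only heavy atoms are considered, with standard van der Waals
radii and a 1.4-angstrom water probe by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_SASA, VDW_DEFAULT, VDW_RADII
from .structure import Structure, heavy_atom_table

AtomKey = tuple[str, int, str, str]          # chain, number, icode, atom name
ResidueKey = tuple[str, int, str]            # chain, number, icode


class SasaError(ValueError):
    pass


from functools import lru_cache


@lru_cache(maxsize=8)
def _sphere_points_cached(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    pts = np.stack([np.cos(theta) * np.sin(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(phi)], axis=1)
    pts.setflags(write=False)
    return pts


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    if n < 32:
        raise SasaError(f"n_points must be >= 32 (got {n})")
    return _sphere_points_cached(n)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


def atom_sasa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
              n_points: int = 960) -> np.ndarray:
    """Per-atom accessible areas for arbitrary spheres (vectorized)."""
    pts = sphere_points(n_points)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    ext = radii + probe_radius
    ext2 = ext ** 2
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    areas = 4.0 * np.pi * ext2.copy()
    if len(pairs) == 0:
        return areas
    d2pair = ((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2).sum(axis=1)
    close = d2pair < (ext[pairs[:, 0]] + ext[pairs[:, 1]]) ** 2
    pairs = pairs[close]
    if len(pairs) == 0:
        return areas
    # directed pairs (i buried-by j), grouped by i for one batched test:
    # a point p on sphere i is inside neighbor j iff
    #   |x_i + e_i p - x_j|^2 = e_i^2 + 2 e_i (p . d) + |d|^2 < e_j^2,  d = x_i - x_j
    ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
    jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(ii, kind="stable")
    ii, jj = ii[order], jj[order]
    dvec = coords[ii] - coords[jj]
    dd2 = (dvec ** 2).sum(axis=1)
    proj = dvec @ pts.T                                    # (npairs, n_points)
    buried_pair = (ext2[ii] + dd2)[:, None] + \
        (2.0 * ext[ii])[:, None] * proj < ext2[jj][:, None]
    starts = np.searchsorted(ii, np.arange(n))
    uniq = np.unique(ii)
    grouped = np.logical_or.reduceat(buried_pair, starts[uniq], axis=0)
    accessible = np.full(n, n_points, dtype=float)
    accessible[uniq] = n_points - grouped.sum(axis=1)
    return 4.0 * np.pi * ext2 * accessible / n_points


@dataclass
class SasaResult:
    per_atom: dict[AtomKey, float]
    per_residue: dict[ResidueKey, float]
    per_residue_relative: dict[ResidueKey, float] = field(default_factory=dict)

    def residue_area(self, key: ResidueKey) -> float:
        return self.per_residue.get(key, 0.0)


def compute_sasa(structure: Structure, chain_ids: Sequence[str] | None = None,
                 probe_radius: float = 1.4, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA over the heavy atoms of (a subset of) a structure.

    Relative per-residue values divide by the theoretical Gly-X-Gly maximum
    for the amino acid; residues of unknown type (X) get no relative value.
    """
    coords, elements, keys = heavy_atom_table(structure, chain_ids)
    if len(coords) == 0:
        raise SasaError("no heavy atoms in selection")
    radii = np.array([vdw_radius(e) for e in elements])
    areas = atom_sasa(coords, radii, probe_radius, n_points)
    per_atom: dict[AtomKey, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for key, area in zip(keys, areas):
        per_atom[key] = float(area)
        rkey = key[:3]
        per_residue[rkey] = per_residue.get(rkey, 0.0) + float(area)
    per_rel: dict[ResidueKey, float] = {}
    aa_of: dict[ResidueKey, str] = {}
    for cid, res in structure.iter_residues(chain_ids):
        aa_of[(cid, res.author_number, res.insertion_code)] = res.aa
    for rkey, area in per_residue.items():
        aa = aa_of.get(rkey, "X")
        if aa in MAX_SASA:
            per_rel[rkey] = area / MAX_SASA[aa]
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      per_residue_relative=per_rel)


def relative_sasa(sasa: SasaResult, residue_key: ResidueKey) -> float:
    """Relative accessibility of one residue (fraction of Gly-X-Gly maximum)."""
    if residue_key in sasa.per_residue_relative:
        return sasa.per_residue_relative[residue_key]
    if residue_key in sasa.per_residue:
        raise SasaError(
            f"relative SASA undefined for non-canonical residue {residue_key}")
    raise KeyError(f"residue {residue_key} not in SASA result")


def total_sasa(structure: Structure, chain_ids: Sequence[str] | None = None,
               probe_radius: float = 1.4, n_points: int = 960) -> float:
    res = compute_sasa(structure, chain_ids, probe_radius, n_points)
    return float(sum(res.per_atom.values()))
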