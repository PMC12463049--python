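"""Independent test oracles, deliberately coded apart from the package's
implementations (straightforward loops, different quadrature points)."""

from __future__ import annotations

import itertools

import numpy as np


def random_sphere_points(n: int, seed: int) -> np.ndarray:
    """Uniform random unit vectors — a different point set from the package's
    golden-spiral quadrature."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def dense_sasa_oracle(coords: np.ndarray, radii: np.ndarray,
                      probe: float = 1.4, n_points: int = 10_000,
                      seed: int = 1234) -> np.ndarray:
    """Per-atom SASA by dense Monte-Carlo quadrature (independent of the
    package's deterministic spiral implementation)."""
    pts = random_sphere_points(n_points, seed)
    n = len(coords)
    ext = np.asarray(radii) + probe
    # neighbor prune by plain distance matrix
    dmat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    areas = np.empty(n)
    for i in range(n):
        nb = [j for j in range(n)
              if j != i and dmat[i, j] < ext[i] + ext[j]]
        if not nb:
            areas[i] = 4 * np.pi * ext[i] ** 2
            continue
        sphere = coords[i] + ext[i] * pts
        buried = np.zeros(n_points, dtype=bool)
        for j in nb:
            buried |= ((sphere - coords[j]) ** 2).sum(axis=1) < ext[j] ** 2
        areas[i] = 4 * np.pi * ext[i] ** 2 * (~buried).sum() / n_points
    return areas


def structure_heavy(structure):
    """(coords, radii) of all heavy atoms using the package's radii table."""
    from impscan.sasa import vdw_radius
    coords, radii = [], []
    for _, res in structure.iter_residues():
        for a in res.heavy_atoms():
            coords.append(a.coords)
            radii.append(vdw_radius(a.element))
    return np.asarray(coords), np.asarray(radii)


def bsa_oracle(structure, group_a, group_b, n_points: int = 10_000) -> float:
    """Dense-quadrature buried surface area, independent code path."""
    def total(chain_ids):
        sub_coords, sub_radii = [], []
        from impscan.sasa import vdw_radius
        for cid, res in structure.iter_residues(sorted(chain_ids)):
            for a in res.heavy_atoms():
                sub_coords.append(a.coords)
                sub_radii.append(vdw_radius(a.element))
        return dense_sasa_oracle(np.asarray(sub_coords),
                                 np.asarray(sub_radii),
                                 n_points=n_points).sum()
    return total(group_a) + total(group_b) - total(group_a | group_b)


def linear_model_oracle(ic: dict, nis_apolar: float, nis_charged: float,
                        weights: dict, w_na: float, w_nc: float,
                        intercept: float) -> float:
    """Plain arithmetic evaluation of the contact-based linear model."""
    total = intercept
    for key, count in ic.items():
        total = total + weights[key] * count
    total = total + w_na * nis_apolar + w_nc * nis_charged
    return total


def brute_force_max_clique(dist: np.ndarray, cutoff: float) -> int:
    """Largest all-pairs-within-cutoff subset by exhaustive enumeration."""
    n = len(dist)
    best = 0
    for r in range(n, 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(range(n), r):
            ok = all(dist[i, j] <= cutoff
                     for i, j in itertools.combinations(combo, 2))
            if ok:
                best = r
                break
        if best == r:
            break
    return best


def brute_force_filter(entries, bmin: float, fmax: float):
    return [e for e in entries if e[1] >= bmin and e[2] <= fmax]
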