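"""Elastic-network conformer sampling and FG-motif cluster selection.

A Calpha anisotropic network model (uniform springs within a distance
cutoff) supplies low-frequency collective modes; conformers are random
linear combinations of those modes scaled to a target Calpha RMSD, with a
clash-rejection step standing in for energy minimization.  Conformers are
then ranked by the largest set of solvent-exposed phenylalanine-glycine
(FG) motifs that are mutually within a distance cutoff — a maximum clique
on the motif threshold graph — which is the docking-readiness criterion for
FG-nucleoporin chains.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import rotation_about_axis, _normalize
from .sasa import compute_sasa, relative_sasa
from .structure import Structure, StructureError


class SamplingError(RuntimeError):
    pass


@dataclass
class AnmModel:
    node_coords: np.ndarray          # (N, 3) Calpha positions
    cutoff: float
    spring_constant: float
    eigenvalues: np.ndarray          # ascending
    eigenvectors: np.ndarray         # (3N, 3N), columns are modes
    residue_keys: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def n_zero_modes(self, tol: float = 1e-8) -> int:
        lam_max = float(self.eigenvalues[-1])
        return int((self.eigenvalues < tol * lam_max).sum())


@dataclass
class FgClusterCriteria:
    min_exposed_motifs: int = 5
    mutual_distance_cutoff: float = 30.0
    exposure_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.min_exposed_motifs < 1:
            raise ValueError("min_exposed_motifs must be >= 1")
        if min(self.mutual_distance_cutoff, self.exposure_threshold) < 0 \
                or self.mutual_distance_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class ConformerEnsemble:
    conformers: list[Structure]
    provenance: dict = field(default_factory=dict)
    per_conformer_annotations: list[dict] | None = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise StructureError("empty conformer ensemble")
        seqs = {tuple(c.sequence for c in st.chains) for st in self.conformers}
        if len(seqs) != 1:
            raise StructureError("conformers differ in sequence")

    def __len__(self) -> int:
        return len(self.conformers)


def _ca_table(structure: Structure):
    coords, keys = [], []
    for cid, res in structure.iter_residues():
        ca = res.get_atom("CA")
        if ca is not None:
            coords.append(ca.coords)
            keys.append((cid, res.author_number, res.insertion_code))
    return np.asarray(coords), keys


def build_anm(structure: Structure, cutoff: float = 15.0,
              spring_constant: float = 1.0) -> AnmModel:
    """Calpha anisotropic network model Hessian and its eigendecomposition.

    Connected networks have exactly six near-zero (rigid-body) modes; a
    disconnected network triggers a warning naming the components.
    """
    coords, keys = _ca_table(structure)
    n = len(coords)
    if n < 10:
        raise StructureError(f"need >= 10 Calpha nodes, got {n}")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = np.zeros((n, n))
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        dvec = coords[j] - coords[i]
        d2 = float(dvec @ dvec)
        block = -spring_constant * np.outer(dvec, dvec) / d2
        hess[3*i:3*i+3, 3*j:3*j+3] += block
        hess[3*j:3*j+3, 3*i:3*i+3] += block
        hess[3*i:3*i+3, 3*i:3*i+3] -= block
        hess[3*j:3*j+3, 3*j:3*j+3] -= block
        adj[i, j] = adj[j, i] = 1
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = [int((labels == k).sum()) for k in range(n_comp)]
        warnings.warn(f"elastic network is disconnected: {n_comp} components "
                      f"of sizes {sizes}")
    eigenvalues, eigenvectors = scipy.linalg.eigh(hess)
    return AnmModel(node_coords=coords, cutoff=cutoff,
                    spring_constant=spring_constant,
                    eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                    residue_keys=keys)


def spring_energy(model: AnmModel, displaced: np.ndarray) -> float:
    """Harmonic network energy of displaced node coordinates (for testing
    the Hessian against finite differences)."""
    coords = model.node_coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(model.cutoff, output_type="ndarray")
    e = 0.0
    for i, j in pairs:
        d0 = np.linalg.norm(coords[j] - coords[i])
        d = np.linalg.norm(displaced[j] - displaced[i])
        e += 0.5 * model.spring_constant * (d - d0) ** 2
    return float(e)


def _transport_full_atoms(structure: Structure, ca_keys, old_ca: np.ndarray,
                          new_ca: np.ndarray) -> Structure:
    """Carry side chains along mode displacement by per-residue rigid motion.

    Each residue is translated by its Calpha displacement and rotated by the
    minimal rotation aligning its old local chain tangent to the new one.
    """
    out = structure.copy()
    index = {k: i for i, k in enumerate(ca_keys)}
    n = len(ca_keys)
    for cid, res in out.iter_residues():
        key = (cid, res.author_number, res.insertion_code)
        if key not in index:
            continue
        i = index[key]
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        t_old = old_ca[hi] - old_ca[lo]
        t_new = new_ca[hi] - new_ca[lo]
        R = np.eye(3)
        n_old, n_new = np.linalg.norm(t_old), np.linalg.norm(t_new)
        if n_old > 1e-9 and n_new > 1e-9:
            u, v = t_old / n_old, t_new / n_new
            cross = np.cross(u, v)
            s = np.linalg.norm(cross)
            if s > 1e-9:
                angle = np.degrees(np.arctan2(s, float(u @ v)))
                R = rotation_about_axis(cross, angle)
        for atom in res.atoms:
            atom.coords = new_ca[i] + R @ (atom.coords - old_ca[i])
    return out


def sample_conformers(model: AnmModel, structure: Structure, n: int,
                      target_rmsd: float, n_modes: int = 10, seed: int = 0,
                      min_ca_distance: float = 2.5,
                      n_generations: int = 1,
                      max_attempts_factor: int = 100) -> ConformerEnsemble:
    """Sample `n` conformers by random mode combinations at fixed Calpha RMSD.

    Each conformer displaces the Calpha trace along a random linear
    combination of the lowest `n_modes` non-rigid modes, scaled so the RMSD
    to its parent equals `target_rmsd`; conformers with Calpha pairs closer
    than `min_ca_distance` are rejected and resampled.  With
    `n_generations` > 1 accepted conformers re-seed the next generation
    (round-robin parents).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    rng = np.random.default_rng(seed)
    n_zero = model.n_zero_modes()
    modes = model.eigenvectors[:, n_zero:n_zero + n_modes]
    if modes.shape[1] < 1:
        raise SamplingError("no non-rigid modes available")
    nn = model.n_nodes

    def one_sample(parent_struct: Structure, parent_ca: np.ndarray):
        coeff = rng.standard_normal(modes.shape[1])
        disp = (modes @ coeff).reshape(nn, 3)
        norm = np.linalg.norm(disp)
        if target_rmsd == 0 or norm < 1e-12:
            return parent_struct.copy(), parent_ca.copy()
        disp *= target_rmsd * np.sqrt(nn) / norm
        new_ca = parent_ca + disp
        if len(new_ca) >= 2:
            dmin = cKDTree(new_ca).query_pairs(min_ca_distance)
            if dmin:
                return None
        return (_transport_full_atoms(parent_struct, model.residue_keys,
                                      parent_ca, new_ca), new_ca)

    base_ca = model.node_coords
    accepted: list[tuple[Structure, np.ndarray]] = []
    parents = [(structure, base_ca)]
    per_gen = max(1, n // n_generations)
    attempts = 0
    max_attempts = max_attempts_factor * n
    gen = 0
    while len(accepted) < n:
        want = min(per_gen, n - len(accepted)) if gen < n_generations - 1 \
            else n - len(accepted)
        got = 0
        while got < want:
            attempts += 1
            if attempts > max_attempts:
                raise SamplingError(
                    f"rejection rate too high: {attempts} attempts for "
                    f"{len(accepted)} accepted conformers "
                    f"(target_rmsd={target_rmsd}, min_ca={min_ca_distance})")
            parent = parents[got % len(parents)]
            res = one_sample(*parent)
            if res is None:
                continue
            accepted.append(res)
            got += 1
        parents = accepted[-got:] if got else parents
        gen += 1
    conformers = [st for st, _ in accepted[:n]]
    return ConformerEnsemble(
        conformers=conformers,
        provenance={"seed": seed, "n": n, "target_rmsd": target_rmsd,
                    "n_modes": n_modes, "n_generations": n_generations,
                    "cutoff": model.cutoff})


def ca_rmsd(a: Structure, b: Structure) -> float:
    ca_a, _ = _ca_table(a)
    ca_b, _ = _ca_table(b)
    if ca_a.shape != ca_b.shape:
        raise StructureError("Calpha count mismatch")
    return float(np.sqrt(((ca_a - ca_b) ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# FG motifs

_EXTENDED_PATTERNS = ("FXFG", "GLFG")


def find_fg_motifs(sequence: str, extended: bool = False) -> list[int]:
    """1-based positions of the Phe of every FG dipeptide (overlaps allowed).

    With `extended`, FxFG and GLFG occurrences are also reported (position
    of the Phe that starts the terminal FG)."""
    if not sequence:
        raise ValueError("empty sequence")
    positions = {m.start() + 1 for m in re.finditer("(?=FG)", sequence)}
    if extended:
        for m in re.finditer("(?=F.FG)", sequence):
            positions.add(m.start() + 3)
        for m in re.finditer("(?=GLFG)", sequence):
            positions.add(m.start() + 3)
    return sorted(positions)


def _residue_by_index(structure: Structure, position: int):
    """Residue at a 1-based sequence index of the (single-chain) structure."""
    chain = structure.chains[0]
    return chain.id, chain.residues[position - 1]


def fg_exposure(conformer: Structure, fg_positions: list[int],
                criteria: FgClusterCriteria | None = None,
                sasa=None) -> list[int]:
    """Subset of motif positions whose Phe is solvent exposed.

    A motif is exposed iff the relative SASA of its phenylalanine is at or
    above `exposure_threshold` in this conformer."""
    criteria = criteria or FgClusterCriteria()
    if sasa is None:
        sasa = compute_sasa(conformer)
    exposed = []
    for pos in fg_positions:
        cid, res = _residue_by_index(conformer, pos)
        if res.aa != "F":
            raise ValueError(f"position {pos} is {res.aa}, not F")
        rel = relative_sasa(sasa, (cid, res.author_number, res.insertion_code))
        if rel >= criteria.exposure_threshold:
            exposed.append(pos)
    return exposed


def max_mutual_cluster(points: np.ndarray, cutoff: float,
                       exact_limit: int = 25) -> list[int]:
    """Largest index set with ALL pairwise distances <= cutoff.

    Exact maximum clique for up to `exact_limit` points, greedy with local
    improvement beyond.  Ties resolve to the clique with the smallest mean
    intra-clique distance, then lexicographically smallest index set."""
    n = len(points)
    if n == 0:
        return []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    adjacent = (d <= cutoff)
    np.fill_diagonal(adjacent, False)

    def mean_dist(clique):
        if len(clique) < 2:
            return 0.0
        return float(np.mean([d[i, j] for i, j in
                              itertools.combinations(clique, 2)]))

    if n <= exact_limit:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((i, j) for i in range(n) for j in range(i + 1, n)
                         if adjacent[i, j])
        best: list[int] = []
        best_key = None
        for clique in nx.find_cliques(g):
            clique = sorted(clique)
            key = (-len(clique), mean_dist(clique), tuple(clique))
            if best_key is None or key < best_key:
                best_key = key
                best = clique
        return best
    # greedy from each seed vertex + single-swap improvement
    best = []
    for seed_v in range(n):
        clique = [seed_v]
        for v in sorted(range(n), key=lambda u: -int(adjacent[seed_v, u])):
            if v not in clique and all(adjacent[v, u] for u in clique):
                clique.append(v)
        improved = True
        while improved:
            improved = False
            for v in range(n):
                if v in clique:
                    continue
                missing = [u for u in clique if not adjacent[v, u]]
                if len(missing) == 1:
                    trial = [u for u in clique if u != missing[0]] + [v]
                    ext = [w for w in range(n) if w not in trial
                           and all(adjacent[w, u] for u in trial)]
                    if ext:
                        clique = trial + ext[:1]
                        improved = True
                        break
        if len(clique) > len(best):
            best = sorted(clique)
    return best


def motif_ca_coords(conformer: Structure, positions: list[int]) -> np.ndarray:
    out = []
    for pos in positions:
        _, res = _residue_by_index(conformer, pos)
        out.append(res.coord("CA"))
    return np.asarray(out) if out else np.zeros((0, 3))


def annotate_ensemble(ensemble: ConformerEnsemble,
                      criteria: FgClusterCriteria | None = None,
                      cluster_mode: str = "clique") -> list[dict]:
    """Per-conformer FG annotations: exposed motifs, best cluster, mean
    intra-cluster distance.  `cluster_mode` 'component' replaces the clique
    rule by connectivity at the cutoff."""
    criteria = criteria or FgClusterCriteria()
    annotations = []
    seq = ensemble.conformers[0].chains[0].sequence
    positions = find_fg_motifs(seq)
    for st in ensemble.conformers:
        exposed = fg_exposure(st, positions, criteria)
        coords = motif_ca_coords(st, exposed)
        if cluster_mode == "clique":
            members_idx = max_mutual_cluster(
                coords, criteria.mutual_distance_cutoff)
        elif cluster_mode == "component":
            members_idx = _largest_component(
                coords, criteria.mutual_distance_cutoff)
        else:
            raise ValueError(f"unknown cluster_mode {cluster_mode!r}")
        members = [exposed[i] for i in members_idx]
        if len(members_idx) >= 2:
            sub = coords[members_idx]
            dm = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
            mean_d = float(dm[np.triu_indices(len(sub), 1)].mean())
        else:
            mean_d = 0.0
        annotations.append({"fg_positions": positions,
                            "exposed": exposed,
                            "cluster_members": members,
                            "cluster_size": len(members),
                            "mean_intra_cluster_distance": mean_d})
    ensemble.per_conformer_annotations = annotations
    return annotations


def _largest_component(points: np.ndarray, cutoff: float) -> list[int]:
    n = len(points)
    if n == 0:
        return []
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    adj = (d <= cutoff).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = [(labels == k).sum() for k in range(n_comp)]
    k = int(np.argmax(sizes))
    return [i for i in range(n) if labels[i] == k]


def select_fg_clustered_conformers(ensemble: ConformerEnsemble,
                                   criteria: FgClusterCriteria | None = None,
                                   cluster_mode: str = "clique"):
    """Conformers whose exposed-FG cluster reaches `min_exposed_motifs`.

    Returns a ranked list of (conformer index, annotation dict), largest
    cluster first, then smallest mean intra-cluster distance."""
    criteria = criteria or FgClusterCriteria()
    annotations = annotate_ensemble(ensemble, criteria, cluster_mode)
    hits = [(i, ann) for i, ann in enumerate(annotations)
            if ann["cluster_size"] >= criteria.min_exposed_motifs]
    hits.sort(key=lambda t: (-t[1]["cluster_size"],
                             t[1]["mean_intra_cluster_distance"], t[0]))
    return hits
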