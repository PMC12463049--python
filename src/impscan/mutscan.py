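"""Point/multi mutant construction, binding and folding ddG scoring, the
exhaustive 19x19 paired-substitution scan and the dual selection criterion.

Side chains are rebuilt from idealized templates over a minimal rotamer grid
({-60, 60, 180} degrees per rotatable chi) by minimum heavy-atom clash count,
with ties broken by enumeration order; the procedure is deterministic.  The
folding scorer is a deliberately simple surrogate with a pluggable contract:
it penalizes introduced clashes, lost intra-chain hydrogen bonds and salt
bridges, and lost buried apolar side-chain area, each with a configurable
weight.  Its absolute values are not comparable to a physics force field;
only its role inside the dual filter is exercised here.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .affinity import (AffinityModelParams, affinity_descriptor,
                       load_model_params, predict_binding_energy)
from .constants import AA1, BACKBONE_ATOMS, CHI_ATOMS, MAX_SASA
from .interface import (ContactCriteria, ConfigurationError, HBondCriteria,
                        SaltBridgeCriteria, find_interface)
from .geometry import build_sidechain
from .sasa import compute_sasa
from .structure import (Atom, ComplexView, PoseEnsemble, Structure,
                        StructureError, get_residue)

ResidueKey = tuple[str, int, str]
ROTAMER_GRID = (-60.0, 60.0, 180.0)
CLASH_CUTOFF = 2.6  # heavy-atom distance used by the rotamer objective, A


@dataclass
class Mutation:
    chain_id: str
    author_number: int
    wt_aa: str
    target_aa: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.target_aa not in AA1:
            raise StructureError(f"target {self.target_aa!r} not canonical")
        if self.wt_aa not in AA1:
            raise StructureError(f"wild-type {self.wt_aa!r} not canonical")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.author_number}{self.target_aa}"

    @property
    def site(self) -> ResidueKey:
        return (self.chain_id, self.author_number, self.insertion_code)


@dataclass
class StabilityScorerParams:
    w_clash: float = 1.0
    clash_distance: float = 2.6
    w_lost_hbond: float = 0.5
    w_lost_bridge: float = 0.5
    w_burial: float = 0.012

    def __post_init__(self) -> None:
        vals = (self.w_clash, self.clash_distance, self.w_lost_hbond,
                self.w_lost_bridge, self.w_burial)
        if any(v < 0 for v in vals):
            raise ConfigurationError("stability weights must be >= 0")


@dataclass
class SelectionCriteria:
    """Dual filter: binding destabilized by at least `ddg_binding_min` while
    folding change stays at or below `ddg_folding_max` (both inclusive)."""

    ddg_binding_min: float = 0.8
    ddg_folding_max: float = 0.05

    def __post_init__(self) -> None:
        if self.ddg_binding_min <= 0:
            raise ConfigurationError("ddg_binding_min must be positive")

    def passes(self, ddg_binding: float, ddg_folding: float) -> bool:
        return (ddg_binding >= self.ddg_binding_min
                and ddg_folding <= self.ddg_folding_max)


@dataclass
class PairNominationParams:
    occupancy_min: float = 0.5
    proximity_cutoff: float = 8.0
    representative_pose: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_min <= 1):
            raise ConfigurationError("occupancy_min must be in (0, 1]")
        if self.proximity_cutoff <= 0:
            raise ConfigurationError("proximity_cutoff must be positive")


# ---------------------------------------------------------------------------
# Mutant construction

def _environment_atoms(structure: Structure, exclude_site: ResidueKey):
    coords = []
    for cid, res in structure.iter_residues():
        if (cid, res.author_number, res.insertion_code) == exclude_site:
            continue
        for a in res.heavy_atoms():
            coords.append(a.coords)
    return np.asarray(coords) if coords else np.zeros((0, 3))


def _clash_count(sidechain_coords: np.ndarray, env_tree: cKDTree | None) -> int:
    if env_tree is None or len(sidechain_coords) == 0:
        return 0
    return int(sum(len(hits) for hits in
                   env_tree.query_ball_point(sidechain_coords, CLASH_CUTOFF)))


def mutate_residue(structure: Structure, mutation: Mutation,
                   seed: int = 0) -> Structure:
    """Return a new structure with one residue's side chain replaced.

    Backbone heavy atoms (N, CA, C, O) are kept.  The new side chain comes
    from an idealized template; each rotatable chi is scanned over
    {-60, 60, 180} degrees and the rotamer with the fewest heavy-atom clashes
    against the rest of the structure is kept (first in enumeration order on
    ties, so the result is deterministic; the seed is accepted for interface
    stability but never consulted by the deterministic tie-break).
    """
    res = get_residue(structure, mutation.chain_id, mutation.author_number,
                      mutation.insertion_code)
    if res.aa != mutation.wt_aa:
        raise StructureError(
            f"wild-type mismatch at {mutation.site}: structure has {res.aa}, "
            f"mutation declares {mutation.wt_aa}")
    for bb in ("N", "CA", "C"):
        if res.get_atom(bb) is None:
            raise StructureError(f"missing backbone atom {bb} at {mutation.site}")
    if mutation.target_aa == res.aa:
        return structure.copy()

    out = structure.copy()
    new_res = get_residue(out, mutation.chain_id, mutation.author_number,
                          mutation.insertion_code)
    backbone = [a for a in new_res.atoms if a.name in BACKBONE_ATOMS]
    n, ca, c = (new_res.coord("N"), new_res.coord("CA"), new_res.coord("C"))
    target = mutation.target_aa
    nchi = len(CHI_ATOMS[target])
    if target == "G":
        new_res.atoms = [a for a in backbone]
    elif nchi == 0:
        side = build_sidechain(n, ca, c, target, None)
        new_res.atoms = backbone + [Atom(nm, el, xyz) for nm, el, xyz in side]
    else:
        env = _environment_atoms(out, mutation.site)
        env_tree = cKDTree(env) if len(env) else None
        best = None
        for combo in itertools.product(ROTAMER_GRID, repeat=nchi):
            side = build_sidechain(n, ca, c, target, combo)
            coords = np.array([xyz for _, _, xyz in side])
            clashes = _clash_count(coords, env_tree)
            if best is None or clashes < best[0]:
                best = (clashes, side)
            if best[0] == 0:
                break
        new_res.atoms = backbone + [Atom(nm, el, xyz) for nm, el, xyz in best[1]]
    new_res.aa = target
    return out


def apply_mutations(structure: Structure, mutations: list[Mutation],
                    seed: int = 0) -> Structure:
    sites = [m.site for m in mutations]
    if len(sites) != len(set(sites)):
        raise StructureError(f"duplicate mutation sites: {sites}")
    out = structure
    for m in mutations:
        out = mutate_residue(out, m, seed=seed)
    return out


# ---------------------------------------------------------------------------
# Folding-stability surrogate

_PEPTIDE_EXCLUDE = {("C", "N"), ("C", "CA"), ("CA", "N"), ("O", "N")}


def _stability_terms(structure: Structure, chain_scope,
                     n_points: int = 960) -> dict[str, float]:
    """(n_clash, n_hbond, n_bridge, buried apolar side-chain area) within scope."""
    scope = sorted(chain_scope) if chain_scope else [c.id for c in structure.chains]
    sub = Structure(chains=[structure.get_chain(cid) for cid in scope])

    # clashes: heavy-atom pairs below threshold, excluding intra-residue pairs
    # and atoms separated by <= 3 bonds across a peptide link
    coords, keys, order = [], [], {}
    for ci, (cid, res) in enumerate(sub.iter_residues()):
        rkey = (cid, res.author_number, res.insertion_code)
        order.setdefault(cid, []).append(rkey)
        for a in res.heavy_atoms():
            coords.append(a.coords)
            keys.append((rkey, a.name))
    coords = np.asarray(coords)
    seq_index = {}
    for cid, rkeys in order.items():
        for i, rkey in enumerate(rkeys):
            seq_index[rkey] = (cid, i)
    n_clash = 0
    if len(coords) >= 2:
        pairs = cKDTree(coords).query_pairs(CLASH_CUTOFF, output_type="ndarray")
        for i, j in pairs:
            (ri, ni), (rj, nj) = keys[i], keys[j]
            if ri == rj:
                continue
            ci_, oi = seq_index[ri]
            cj_, oj = seq_index[rj]
            if ci_ == cj_ and abs(oi - oj) == 1:
                first, second = ((ni, nj) if oi < oj else (nj, ni))
                if (first, second) in _PEPTIDE_EXCLUDE:
                    continue
            n_clash += 1

    # intra-scope hydrogen bonds and salt bridges: reuse the cross-partition
    # detectors over an artificial split is not possible for a single chain,
    # so count directly with the same atom tables
    from .constants import HBOND_ACCEPTORS, HBOND_DONORS
    dons, accs = [], []
    for cid, res in sub.iter_residues():
        rkey = (cid, res.author_number, res.insertion_code)
        donors = set(HBOND_DONORS.get(res.aa, ()))
        if res.aa != "P":
            donors.add("N")
        acceptors = set(HBOND_ACCEPTORS.get(res.aa, ()))
        acceptors.add("O")
        for a in res.heavy_atoms():
            if a.name in donors:
                dons.append((rkey, a.name, a.coords))
            if a.name in acceptors:
                accs.append((rkey, a.name, a.coords))
    n_hb = 0
    seen = set()
    hb_max = HBondCriteria().donor_acceptor_max
    for drk, dn, dxyz in dons:
        for ark, an, axyz in accs:
            if drk == ark:
                continue
            ci_, oi = seq_index[drk]
            cj_, oj = seq_index[ark]
            if ci_ == cj_ and abs(oi - oj) == 1 and dn in BACKBONE_ATOMS \
                    and an in BACKBONE_ATOMS:
                continue
            pair = frozenset(((drk, dn), (ark, an)))
            if pair in seen:
                continue
            if np.linalg.norm(dxyz - axyz) <= hb_max:
                seen.add(pair)
                n_hb += 1

    sb = SaltBridgeCriteria()
    basics, acidics = [], []
    for cid, res in sub.iter_residues():
        rkey = (cid, res.author_number, res.insertion_code)
        bnames = sb.basic_atoms.get(res.aa)
        anames = sb.acidic_atoms.get(res.aa)
        if bnames:
            basics.append((rkey, [a.coords for a in res.heavy_atoms()
                                  if a.name in bnames]))
        if anames:
            acidics.append((rkey, [a.coords for a in res.heavy_atoms()
                                   if a.name in anames]))
    n_bridge = 0
    for brk, bcs in basics:
        for ark, acs in acidics:
            if brk == ark or not bcs or not acs:
                continue
            dmin = min(np.linalg.norm(b - a) for b in bcs for a in acs)
            if dmin <= sb.max_distance:
                n_bridge += 1

    # buried apolar side-chain area: for apolar-class residues, the part of
    # the side-chain reference area (GlyXGly max minus Gly max) not exposed
    sasa = compute_sasa(sub, n_points=n_points)
    buried = 0.0
    from .constants import POLARITY_CLASSES
    for cid, res in sub.iter_residues():
        if POLARITY_CLASSES.get(res.aa) != "apolar" or res.aa == "G":
            continue
        rkey = (cid, res.author_number, res.insertion_code)
        side_area = sum(v for (c_, n_, i_, an), v in sasa.per_atom.items()
                        if (c_, n_, i_) == rkey and an not in BACKBONE_ATOMS)
        side_ref = MAX_SASA[res.aa] - MAX_SASA["G"]
        buried += max(0.0, side_ref - side_area)

    return {"n_clash": float(n_clash), "n_hbond": float(n_hb),
            "n_bridge": float(n_bridge), "buried_apolar": buried}


def score_folding_change(wt: Structure, mut: Structure,
                         params: StabilityScorerParams | None = None,
                         chain_scope=None, n_points: int = 960,
                         _wt_terms: dict[str, float] | None = None) -> float:
    """Surrogate folding ddG (mutant minus wild type); positive destabilizes."""
    params = params or StabilityScorerParams()
    wt_chains = sorted(c.id for c in wt.chains)
    mut_chains = sorted(c.id for c in mut.chains)
    if wt_chains != mut_chains:
        raise StructureError("wild-type/mutant chain mismatch")
    t_wt = _wt_terms if _wt_terms is not None else _stability_terms(
        wt, chain_scope, n_points)
    t_mut = _stability_terms(mut, chain_scope, n_points)
    d_clash = t_mut["n_clash"] - t_wt["n_clash"]
    d_hb = t_mut["n_hbond"] - t_wt["n_hbond"]
    d_br = t_mut["n_bridge"] - t_wt["n_bridge"]
    d_bur = t_mut["buried_apolar"] - t_wt["buried_apolar"]
    return float(params.w_clash * d_clash
                 + params.w_lost_hbond * max(0.0, -d_hb)
                 + params.w_lost_bridge * max(0.0, -d_br)
                 + params.w_burial * max(0.0, -d_bur))


# ---------------------------------------------------------------------------
# Pair nomination from pose ensembles

def sidechain_centroid(res) -> np.ndarray:
    side = [a.coords for a in res.heavy_atoms() if a.name not in ("N", "C", "O")]
    if not side:
        side = [a.coords for a in res.heavy_atoms()]
    return np.mean(side, axis=0)


def nominate_interface_pairs(ensemble: PoseEnsemble, ligand_chain: str,
                             params: PairNominationParams | None = None,
                             criteria: ContactCriteria | None = None):
    """Ligand residue pairs that are both frequently interfacial across poses
    and mutually close in the representative pose.

    Occupancy of a ligand residue is the fraction of poses in which it is
    interfacial.  Pairs with both occupancies >= occupancy_min and side-chain
    centroid distance <= proximity_cutoff are nominated, sorted by minimum
    pair occupancy (descending) then distance (ascending).
    """
    params = params or PairNominationParams()
    criteria = criteria or ContactCriteria()
    if len(ensemble) == 0:
        raise StructureError("empty pose ensemble")
    counts: dict[ResidueKey, int] = {}
    for view in ensemble.poses:
        ra, rb, _ = find_interface(view, criteria)
        for rkey in (ra | rb):
            if rkey[0] == ligand_chain:
                counts[rkey] = counts.get(rkey, 0) + 1
    n = len(ensemble)
    occupancy = {k: c / n for k, c in counts.items()}
    rep = ensemble.poses[params.representative_pose]
    chain = rep.structure.get_chain(ligand_chain)
    centroids = {}
    for res in chain.residues:
        rkey = (ligand_chain, res.author_number, res.insertion_code)
        centroids[rkey] = sidechain_centroid(res)
    eligible = sorted(k for k, occ in occupancy.items()
                      if occ >= params.occupancy_min)
    nominations = []
    for i, ka in enumerate(eligible):
        for kb in eligible[i + 1:]:
            dist = float(np.linalg.norm(centroids[ka] - centroids[kb]))
            if dist <= params.proximity_cutoff:
                nominations.append(
                    (ka, kb, min(occupancy[ka], occupancy[kb]), dist))
    nominations.sort(key=lambda t: (-t[2], t[3], t[0], t[1]))
    return [(ka, kb) for ka, kb, _, _ in nominations], occupancy


# ---------------------------------------------------------------------------
# Mutant evaluation and the 19x19 scan

def _mutation_side(view: ComplexView, mutations: list[Mutation]) -> frozenset[str]:
    chains = {m.chain_id for m in mutations}
    if chains <= view.group_a:
        return view.group_a
    if chains <= view.group_b:
        return view.group_b
    raise StructureError(
        "mutations must all lie on one side of the partition")


def evaluate_mutant(view: ComplexView, mutations: list[Mutation],
                    contact_criteria: ContactCriteria | None = None,
                    affinity_params: AffinityModelParams | None = None,
                    stability_params: StabilityScorerParams | None = None,
                    seed: int = 0, n_points: int = 960,
                    _wt_cache: dict | None = None) -> tuple[float, float]:
    """(ddG_binding, ddG_folding) for a multi-mutant; (0, 0) for no mutations."""
    contact_criteria = contact_criteria or ContactCriteria()
    affinity_params = affinity_params or load_model_params()
    stability_params = stability_params or StabilityScorerParams()
    if not mutations:
        return (0.0, 0.0)
    sites = [m.site for m in mutations]
    if len(sites) != len(set(sites)):
        raise StructureError(f"duplicate mutation sites: {sites}")
    side = _mutation_side(view, mutations)

    if _wt_cache is None:
        d_wt = affinity_descriptor(view, contact_criteria, n_points=n_points)
        dg_wt = predict_binding_energy(d_wt, affinity_params).dg
        wt_terms = _stability_terms(view.structure, side, n_points)
    else:
        dg_wt = _wt_cache["dg_wt"]
        wt_terms = _wt_cache["wt_terms"]

    mut_structure = apply_mutations(view.structure, mutations, seed=seed)
    mut_view = ComplexView(mut_structure, view.group_a, view.group_b)
    d_mut = affinity_descriptor(mut_view, contact_criteria, n_points=n_points)
    dg_mut = predict_binding_energy(d_mut, affinity_params).dg
    ddg_f = score_folding_change(view.structure, mut_structure,
                                 stability_params, side, n_points,
                                 _wt_terms=wt_terms)
    return (float(dg_mut - dg_wt), ddg_f)


@dataclass
class ScanMatrix:
    sites: list[tuple[str, int, str, str]]   # (chain, number, icode, wt_aa)
    aa_order: tuple[str, ...]
    subs_a: tuple[str, ...]
    subs_b: tuple[str, ...]
    ddg_binding: np.ndarray
    ddg_folding: np.ndarray
    passes_filter: np.ndarray
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    def entry_label(self, i: int, j: int) -> str:
        (ca, na, ia, wa), (cb, nb, ib, wb) = self.sites
        return f"{wa}{na}{self.subs_a[i]}-{wb}{nb}{self.subs_b[j]}"

    def candidates(self) -> list[tuple[str, float, float, bool]]:
        out = []
        for i in range(len(self.subs_a)):
            for j in range(len(self.subs_b)):
                out.append((self.entry_label(i, j),
                            float(self.ddg_binding[i, j]),
                            float(self.ddg_folding[i, j]),
                            bool(self.passes_filter[i, j])))
        return out


def scan_pair(view: ComplexView, site_a: ResidueKey, site_b: ResidueKey,
              contact_criteria: ContactCriteria | None = None,
              affinity_params: AffinityModelParams | None = None,
              stability_params: StabilityScorerParams | None = None,
              selection: SelectionCriteria | None = None,
              seed: int = 0, n_points: int = 320,
              allow_receptor_sites: bool = False) -> ScanMatrix:
    """Exhaustive 19x19 paired-substitution scan at two ligand sites.

    Rows are substitutions at site_a, columns at site_b, both in alphabetical
    one-letter order with each site's wild type excluded.
    """
    contact_criteria = contact_criteria or ContactCriteria()
    affinity_params = affinity_params or load_model_params()
    stability_params = stability_params or StabilityScorerParams()
    selection = selection or SelectionCriteria()

    res_a = get_residue(view.structure, *site_a)
    res_b = get_residue(view.structure, *site_b)
    for site in (site_a, site_b):
        if site[0] not in view.group_b and not allow_receptor_sites:
            if site[0] in view.group_a:
                raise StructureError(
                    f"site {site} is on the receptor side "
                    "(pass allow_receptor_sites=True to override)")
            raise StructureError(f"site chain {site[0]} not in view")
    wt_a, wt_b = res_a.aa, res_b.aa
    subs_a = tuple(a for a in AA1 if a != wt_a)
    subs_b = tuple(a for a in AA1 if a != wt_b)

    d_wt = affinity_descriptor(view, contact_criteria, n_points=n_points)
    dg_wt = predict_binding_energy(d_wt, affinity_params).dg
    side = view.group_b if site_a[0] in view.group_b else view.group_a
    cache = {"dg_wt": dg_wt,
             "wt_terms": _stability_terms(view.structure, side, n_points)}

    nb = len(subs_b)
    ddg_b = np.zeros((len(subs_a), nb))
    ddg_f = np.zeros((len(subs_a), nb))
    for i, sa in enumerate(subs_a):
        for j, sb in enumerate(subs_b):
            muts = [Mutation(site_a[0], site_a[1], wt_a, sa, site_a[2]),
                    Mutation(site_b[0], site_b[1], wt_b, sb, site_b[2])]
            b, f = evaluate_mutant(view, muts, contact_criteria,
                                   affinity_params, stability_params,
                                   seed=seed, n_points=n_points,
                                   _wt_cache=cache)
            ddg_b[i, j] = b
            ddg_f[i, j] = f
    passes = (ddg_b >= selection.ddg_binding_min) & \
             (ddg_f <= selection.ddg_folding_max)
    return ScanMatrix(
        sites=[(site_a[0], site_a[1], site_a[2], wt_a),
               (site_b[0], site_b[1], site_b[2], wt_b)],
        aa_order=tuple(AA1), subs_a=subs_a, subs_b=subs_b,
        ddg_binding=ddg_b, ddg_folding=ddg_f, passes_filter=passes,
        criteria=selection)


def filter_candidates(entries, criteria: SelectionCriteria | None = None):
    """Retain entries meeting the dual criterion, preserving order.

    Entries are (label, ddg_binding, ddg_folding) triples.
    """
    criteria = criteria or SelectionCriteria()
    out = []
    for label, ddg_b, ddg_f in entries:
        if not (np.isfinite(ddg_b) and np.isfinite(ddg_f)):
            raise ValueError(f"non-finite ddG for {label}")
        if criteria.passes(ddg_b, ddg_f):
            out.append((label, ddg_b, ddg_f))
    return out


def write_heatmap(matrix: ScanMatrix, path, channel: str = "binding",
                  image_path=None) -> None:
    """Write one scan channel as a TSV grid (optionally also a PNG).

    Rows are site_a substitutions, columns site_b substitutions; cells are
    kcal/mol for the energy channels or 0/1 for the filter channel.
    """
    grids = {"binding": matrix.ddg_binding, "folding": matrix.ddg_folding,
             "filter": matrix.passes_filter.astype(int)}
    if channel not in grids:
        raise ValueError(f"unknown channel {channel!r}")
    grid = grids[channel]
    (ca, na, ia, wa), (cb, nb_, ib, wb) = matrix.sites
    header = [f"{wa}{na}\\{wb}{nb_}"] + list(matrix.subs_b)
    lines = ["\t".join(header)]
    for i, sa in enumerate(matrix.subs_a):
        if channel == "filter":
            cells = [str(int(v)) for v in grid[i]]
        else:
            cells = [f"{v:.6f}" for v in grid[i]]
        lines.append("\t".join([sa] + cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(np.asarray(grid, dtype=float), cmap="RdBu_r")
        ax.set_xticks(range(len(matrix.subs_b)), matrix.subs_b)
        ax.set_yticks(range(len(matrix.subs_a)), matrix.subs_a)
        ax.set_xlabel(f"{wb}{nb_} substitution")
        ax.set_ylabel(f"{wa}{na} substitution")
        if channel != "filter":
            ys, xs = np.where(matrix.passes_filter)
            for y, x in zip(ys, xs):
                ax.add_patch(plt.Rectangle((x - 0.5, y - 0.5), 1, 1,
                                           fill=False, edgecolor="green", lw=1.5))
        fig.colorbar(im, ax=ax, label="kcal/mol" if channel != "filter" else "pass")
        fig.tight_layout()
        fig.savefig(image_path, dpi=120)
        plt.close(fig)


def read_heatmap(path) -> np.ndarray:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    return np.array([[float(c) for c in line.split("\t")[1:]]
                     for line in lines[1:]])


def write_candidates_tsv(matrix: ScanMatrix, path) -> None:
    lines = ["label\tddg_binding\tddg_folding\tpass"]
    for label, b, f, p in matrix.candidates():
        lines.append(f"{label}\t{b:.6f}\t{f:.6f}\t{int(p)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def scan_manifest(matrix: ScanMatrix, seed: int) -> str:
    payload = {
        "sites": [list(s) for s in matrix.sites],
        "criteria": {"ddg_binding_min": matrix.criteria.ddg_binding_min,
                     "ddg_folding_max": matrix.criteria.ddg_folding_max},
        "seed": seed,
        "n_pass": int(matrix.passes_filter.sum()),
    }
    return json.dumps(payload, indent=2)
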