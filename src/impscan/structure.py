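"""Lightweight protein structure hierarchy with PDB read/write.

The coordinate model is deliberately minimal: atoms carry coordinates in
angstroms, residues are addressed exclusively by PDB *author* numbering
(integer + insertion code) and no renumbering is ever performed.  Hydrogens
are read when present but every geometric default downstream operates on
heavy atoms, so hydrogen-free modeled structures are first-class inputs.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .constants import AA_1TO3, AA_3TO1


class StructureError(ValueError):
    """Raised for malformed or empty structure inputs."""


class LookupResidueError(KeyError):
    """Raised when a residue address does not exist."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise StructureError(f"empty element for atom {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    aa: str
    author_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def name3(self) -> str:
        return AA_1TO3.get(self.aa, "UNK")

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.get_atom(name)
        if a is None:
            raise LookupResidueError(
                f"atom {name} not found in residue {self.aa}{self.author_number}")
        return a.coords

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    @property
    def address(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def get_residue(self, author_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids: {ids}")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise LookupResidueError(
            f"chain {chain_id!r} not found (have {[c.id for c in self.chains]})")

    def iter_residues(self, chain_ids: Sequence[str] | None = None
                      ) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            if chain_ids is None or c.id in chain_ids:
                for r in c.residues:
                    yield c.id, r

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def copy(self) -> "Structure":
        chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [Atom(a.name, a.element, a.coords.copy(),
                              a.occupancy, a.altloc) for a in r.atoms]
                residues.append(Residue(r.aa, r.author_number,
                                        r.insertion_code, atoms))
            chains.append(Chain(c.id, residues))
        return Structure(chains=chains, model_index=self.model_index)


def get_residue(structure: Structure, chain_id: str, author_number: int,
                insertion_code: str = "") -> Residue:
    """Return the unique residue at an author-numbered address."""
    chain = structure.get_chain(chain_id)
    res = chain.get_residue(author_number, insertion_code)
    if res is None:
        numbers = sorted(r.author_number for r in chain.residues)
        nearest = sorted(numbers, key=lambda n: abs(n - author_number))[:5]
        raise LookupResidueError(
            f"residue {author_number}{insertion_code} not in chain {chain_id}; "
            f"nearest author numbers: {nearest}")
    return res


@dataclass
class ComplexView:
    """A binary partition of a structure's chains into receptor/ligand groups."""

    structure: Structure
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        if not self.group_a or not self.group_b:
            raise StructureError("both groups must be non-empty")
        if self.group_a & self.group_b:
            raise StructureError(
                f"groups overlap: {sorted(self.group_a & self.group_b)}")
        present = {c.id for c in self.structure.chains}
        missing = (self.group_a | self.group_b) - present
        if missing:
            raise StructureError(f"chains not in structure: {sorted(missing)}")

    def swapped(self) -> "ComplexView":
        return ComplexView(self.structure, self.group_b, self.group_a)

    def chain_ids(self) -> frozenset[str]:
        return self.group_a | self.group_b


def make_complex_view(structure: Structure, group_a, group_b) -> ComplexView:
    return ComplexView(structure, frozenset(group_a), frozenset(group_b))


@dataclass
class PoseEnsemble:
    """Alternative rigid-body poses of one complex (e.g. docking output)."""

    poses: list[ComplexView]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.poses:
            raise StructureError("empty pose ensemble")
        if not self.labels:
            self.labels = [f"pose_{i}" for i in range(len(self.poses))]
        if len(self.labels) != len(self.poses):
            raise StructureError("labels/poses length mismatch")
        ref = self.poses[0]
        ref_sig = _composition_signature(ref)
        for p in self.poses[1:]:
            if _composition_signature(p) != ref_sig:
                raise StructureError("poses differ in chain composition")

    def __len__(self) -> int:
        return len(self.poses)


def _composition_signature(view: ComplexView):
    sig = []
    for cid in sorted(view.chain_ids()):
        chain = view.structure.get_chain(cid)
        sig.append((cid, chain.sequence,
                    tuple(len(r.atoms) for r in chain.residues)))
    return tuple(sig)


# ---------------------------------------------------------------------------
# PDB I/O

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].upper() in ("SE",):
        return "SE"
    return name[0].upper()


def _convert_gemmi_model(model: gemmi.Model, model_index: int) -> Structure:
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            if gres.het_flag != "A":
                continue  # HETATM (ligands, waters, modified residues) dropped
            aa = AA_3TO1.get(gres.name, "X")
            # collapse altlocs: keep highest occupancy per atom name
            best: dict[str, Atom] = {}
            for ga in gres:
                el = ga.element.name if ga.element and ga.element.name != "X" \
                    else _infer_element(ga.name)
                atom = Atom(name=ga.name, element=el,
                            coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            occupancy=ga.occ,
                            altloc=ga.altloc if ga.altloc != "\x00" else "")
                prev = best.get(ga.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[ga.name] = atom
            atoms = list(best.values())
            for a in atoms:
                a.altloc = ""
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(Residue(aa=aa, author_number=gres.seqid.num,
                                    insertion_code=icode, atoms=atoms))
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    return Structure(chains=chains, model_index=model_index)


def read_structure(path, format: str = "pdb"):
    """Read a PDB file into the package hierarchy.

    Returns a single :class:`Structure` for single-model files and a list of
    Structures for multi-model files.  HETATM records and waters are dropped;
    altlocs are collapsed to the highest-occupancy atom; author numbering is
    preserved verbatim.
    """
    if format not in ("pdb", "cif"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        st = gemmi.read_structure(str(path),
                                  format=gemmi.CoorFormat.Pdb if format == "pdb"
                                  else gemmi.CoorFormat.Mmcif)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read structure from {path}: {exc}") from exc
    models = [_convert_gemmi_model(m, i) for i, m in enumerate(st)]
    models = [m for m in models]
    if not models or all(m.n_residues() == 0 for m in models):
        raise StructureError(f"no protein residues in {path}")
    if len(models) == 1:
        return models[0]
    return models


def _format_atom_line(serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    name = atom.name
    if len(name) < 4:
        # element-aligned padding: single-letter elements start at column 14
        name = (" " + name) if len(atom.element) == 1 else name
    x, y, z = atom.coords
    return (f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.name3:>3s} "
            f"{chain_id:1s}{res.author_number:4d}{res.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}")


def write_structure(structure: Structure, path) -> None:
    """Write a structure as PDB v3 text (fixed columns, TER between chains)."""
    if structure.n_residues() == 0:
        raise StructureError("refusing to write empty structure")
    lines = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(serial, atom, res, chain.id))
        serial += 1
        last = chain.residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name3:>3s} "
                     f"{chain.id:1s}{last.author_number:4d}"
                     f"{last.insertion_code or ' ':1s}")
    lines.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def write_models(structures: Sequence[Structure], path) -> None:
    """Write several conformations of the same molecule as a multi-model PDB."""
    if not structures:
        raise StructureError("no models to write")
    lines = []
    for i, st in enumerate(structures, start=1):
        lines.append(f"MODEL     {i:4d}")
        serial = 0
        for chain in st.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    lines.append(_format_atom_line(serial, atom, res, chain.id))
            serial += 1
            last = chain.residues[-1]
            lines.append(f"TER   {serial:5d}      {last.name3:>3s} "
                         f"{chain.id:1s}{last.author_number:4d}"
                         f"{last.insertion_code or ' ':1s}")
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def heavy_atom_table(structure: Structure, chain_ids: Sequence[str] | None = None):
    """Flatten heavy atoms into parallel arrays for vectorized geometry.

    Returns (coords (N,3), elements list, keys list) where each key is
    (chain_id, author_number, insertion_code, atom_name).
    """
    coords, elements, keys = [], [], []
    for cid, res in structure.iter_residues(chain_ids):
        for a in res.heavy_atoms():
            coords.append(a.coords)
            elements.append(a.element)
            keys.append((cid, res.author_number, res.insertion_code, a.name))
    if not coords:
        return np.zeros((0, 3)), [], []
    return np.asarray(coords, dtype=float), elements, keys
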