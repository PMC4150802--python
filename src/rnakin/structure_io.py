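"""PDB structure and base-pair list input/output.

Covalent topology is inferred from canonical ribonucleotide name templates
(hydrogens included) plus the inter-residue O3'-P link; it is never guessed
from interatomic distances, so mildly strained fixtures parse identically to
ideal ones.  gemmi does the PDB parsing and writing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import chem


class MissingAtomError(ValueError):
    """A template atom required for the kinematic model is absent."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int          # 1-based sequential along the chain
    coords: np.ndarray          # reference coordinates, Angstrom
    vdw_radius: float

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class Residue:
    index: int                  # 1-based sequential
    base: str                   # A / C / G / U
    atom_indices: dict          # name -> global atom index
    orig_seqid: int = 0
    chain_id: str = "A"


@dataclass
class Bond:
    i: int
    j: int
    rotatable: bool
    label: str | None = None    # alpha..zeta, chi for named backbone torsions


@dataclass
class Topology:
    atoms: list
    residues: list
    bonds: list
    ref_coords: np.ndarray = field(default=None)

    def __post_init__(self):
        self.neighbors = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            self.neighbors[b.i].append(b.j)
            self.neighbors[b.j].append(b.i)
        self._name_maps = [r.atom_indices for r in self.residues]

    # -- lookups ------------------------------------------------------------
    def atom_index(self, residue_index: int, name: str) -> int:
        try:
            return self._name_maps[residue_index - 1][name]
        except KeyError:
            raise MissingAtomError(
                f"residue {residue_index} "
                f"({self.residues[residue_index - 1].base}): no atom {name!r}")

    def has_atom(self, residue_index: int, name: str) -> bool:
        return name in self._name_maps[residue_index - 1]

    def base(self, residue_index: int) -> str:
        return self.residues[residue_index - 1].base

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def c4_indices(self):
        return [self.atom_index(r.index, "C4'") for r in self.residues]

    def rotatable_bonds(self):
        return [b for b in self.bonds if b.rotatable]

    def residue_of(self, atom_index: int) -> int:
        return self.atoms[atom_index].residue_index

    def pairs_12_13(self):
        """Atom index pairs separated by one or two covalent bonds."""
        out = set()
        for b in self.bonds:
            out.add((min(b.i, b.j), max(b.i, b.j)))
        for mid, nbrs in self.neighbors.items():
            for a in nbrs:
                for c in nbrs:
                    if a < c:
                        out.add((a, c))
        return out


@dataclass
class WCPair:
    residue_i: int
    residue_j: int
    pair_type: str              # "AU" or "GC"

    def __post_init__(self):
        if self.residue_i >= self.residue_j:
            raise ValueError("require residue_i < residue_j")
        if self.pair_type not in chem.WC_HBONDS:
            raise ValueError(f"non-canonical pair type {self.pair_type!r}")

    @property
    def hbonds(self):
        """[(donor_atom, hydrogen_atom, acceptor_atom)] name triples, with
        the base letter each atom belongs to."""
        dl, dn, hn, al, an = chem.WC_HBONDS[self.pair_type]
        return [((dl, dn), (dl, hn), (al, an))]

    def resolve(self, topology: Topology):
        """Map the hydrogen-bond triple onto atom indices.

        Returns [(donor_idx, hydrogen_idx, acceptor_idx)].
        """
        bi = topology.base(self.residue_i)
        bj = topology.base(self.residue_j)
        want = {self.pair_type[0], self.pair_type[1]}
        if {bi, bj} != want:
            raise ValueError(
                f"pair {self.residue_i}-{self.residue_j} declared "
                f"{self.pair_type} but residues are {bi}-{bj}")
        out = []
        for (dl, dn), (_, hn), (al, an) in self.hbonds:
            dres = self.residue_i if bi == dl else self.residue_j
            ares = self.residue_i if bi == al else self.residue_j
            out.append((topology.atom_index(dres, dn),
                        topology.atom_index(dres, hn),
                        topology.atom_index(ares, an)))
        return out


# ---------------------------------------------------------------------------
# PDB reading

_BASE_ALIASES = {"A": "A", "C": "C", "G": "G", "U": "U",
                 "RA": "A", "RC": "C", "RG": "G", "RU": "U"}


def _template_for(base, has_p, is_first, is_last, present):
    """(atoms, bonds) name lists for one residue given its terminal status."""
    atoms = list(chem.SUGAR_ATOMS)
    bonds = list(chem.SUGAR_BONDS)
    if not has_p:
        atoms = [a for a in atoms if a[0] not in ("P", "OP1", "OP2")]
        bonds = [b for b in bonds if "P" not in (b[0], b[1])]
        if "HO5'" in present:
            atoms += chem.FIVE_PRIME_OH
            bonds += chem.FIVE_PRIME_OH_BONDS
    elif "OP3" in present:
        atoms += chem.FIVE_PRIME_OP3
        bonds += chem.FIVE_PRIME_OP3_BONDS
    if is_last and "HO3'" in present:
        atoms += chem.THREE_PRIME_OH
        bonds += chem.THREE_PRIME_OH_BONDS
    atoms += chem.BASE_ATOMS[base]
    bonds += [(a, b, False) for a, b in chem.BASE_BONDS[base]]
    gb = chem.glycosidic_bond(base)
    bonds += [(gb[0], gb[1], True)]
    return atoms, bonds


def _structure_to_topology(st: gemmi.Structure, model_index: int):
    if not (1 <= model_index <= len(st)):
        raise ValueError(
            f"model {model_index} requested but file has {len(st)} model(s)")
    model = st[model_index - 1]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 1:
        raise ValueError(f"expected a single chain, found {len(chains)}")
    chain = chains[0]

    atoms, residues, coords = [], [], []
    for ridx, res in enumerate(chain, start=1):
        rname = res.name.strip().upper()
        if rname not in _BASE_ALIASES:
            raise ValueError(f"unsupported residue {res.name!r} at {res.seqid}")
        base = _BASE_ALIASES[rname]
        # collapse alternate locations: highest occupancy wins
        by_name = {}
        for at in res:
            nm = at.name.strip()
            prev = by_name.get(nm)
            if prev is None or at.occ > prev.occ:
                if prev is not None:
                    warnings.warn(
                        f"altloc on {nm} in residue {res.seqid}: "
                        "keeping highest occupancy")
                by_name[nm] = at
        name_to_idx = {}
        for nm, at in by_name.items():
            gi = len(atoms)
            el = at.element.name if at.element else nm[0]
            rad = chem.VDW_RADII.get(el)
            if rad is None:
                raise ValueError(f"no vdW radius for element {el!r}")
            atoms.append(Atom(at.serial, nm, el, ridx,
                              np.array([at.pos.x, at.pos.y, at.pos.z]), rad))
            coords.append(atoms[-1].coords)
            name_to_idx[nm] = gi
        residues.append(Residue(ridx, base, name_to_idx,
                                orig_seqid=res.seqid.num,
                                chain_id=chain.name))

    bonds = []
    nres = len(residues)
    for r in residues:
        present = set(r.atom_indices)
        has_p = "P" in present
        t_atoms, t_bonds = _template_for(
            r.base, has_p, r.index == 1, r.index == nres, present)
        missing = [nm for nm, _el in t_atoms if nm not in present]
        if missing:
            hint = ("add hydrogens (e.g. with a protonation tool) and retry"
                    if all(m.startswith("H") for m in missing)
                    else "complete the residue before sampling")
            raise MissingAtomError(
                f"residue {r.index} ({r.base}): missing atom(s) "
                f"{', '.join(missing)}; {hint}")
        for a, b, rot in t_bonds:
            label = chem.BOND_LABELS.get((a, b)) or chem.BOND_LABELS.get((b, a))
            if (a, b) == chem.glycosidic_bond(r.base):
                label = "chi"
            bonds.append(Bond(r.atom_indices[a], r.atom_indices[b], rot, label))
        if r.index < nres:
            nxt = residues[r.index]  # 0-based list; r.index is next residue
            if "P" not in nxt.atom_indices:
                raise MissingAtomError(
                    f"residue {nxt.index}: missing P for the O3'-P link")
            bonds.append(Bond(r.atom_indices["O3'"],
                              nxt.atom_indices["P"], True, "zeta"))

    topo = Topology(atoms, residues, bonds,
                    ref_coords=np.asarray(coords, dtype=float))
    return topo


def read_pdb(path, model_index: int = 1):
    """Read an RNA chain from a PDB file.

    Returns (Topology, coords) where coords are the coordinates of the
    selected model (1-based index over the MODEL records).
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    topo = _structure_to_topology(st, model_index)
    return topo, topo.ref_coords.copy()


def read_all_models(path):
    """(Topology from model 1, list of per-model coordinate arrays)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    topo = _structure_to_topology(st, 1)
    out = []
    for mi in range(1, len(st) + 1):
        t = _structure_to_topology(st, mi)
        if [a.name for a in t.atoms] != [a.name for a in topo.atoms]:
            raise ValueError(f"model {mi} atom list differs from model 1")
        out.append(t.ref_coords.copy())
    return topo, out


# ---------------------------------------------------------------------------
# pair lists

_TSV_RE = re.compile(r"^\s*(\d+)[\s,]+(\d+)[\s,]+([AUGCaugc]{2})\s*$")
_RNAVIEW_RE = re.compile(
    r"^\s*(\d+)_(\d+),.*?([AUGCaugc])-([AUGCaugc]).*?(\+/\+|W/W).*?cis")


def read_pairs(path):
    """Read canonical WC pairs from a 3-column TSV (i, j, AU|GC) or from
    RNAView-style output (only W/W or +/+ cis lines are kept).

    Non-canonical classes (e.g. GU) are skipped with a warning.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            m = _TSV_RE.match(line)
            if m:
                i, j, cls = int(m.group(1)), int(m.group(2)), m.group(3).upper()
            else:
                m = _RNAVIEW_RE.match(line)
                if not m:
                    continue
                i, j = int(m.group(1)), int(m.group(2))
                cls = (m.group(3) + m.group(4)).upper()
            canon = "".join(sorted(cls))  # AU or CG alphabetical
            if canon == "AU":
                ptype = "AU"
            elif canon == "CG":
                ptype = "GC"
            else:
                warnings.warn(f"skipping non-canonical pair {i}-{j} {cls}")
                continue
            if i > j:
                i, j = j, i
            pairs.append(WCPair(i, j, ptype))
    return pairs


def write_pairs(pairs, path):
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.residue_i}\t{p.residue_j}\t{p.pair_type}\n")


# ---------------------------------------------------------------------------
# PDB writing

def coords_to_structure(topology: Topology, coord_sets, name="rnakin"):
    st = gemmi.Structure()
    st.name = name
    for mi, coords in enumerate(coord_sets, start=1):
        model = gemmi.Model(mi)
        chain = gemmi.Chain(topology.residues[0].chain_id or "A")
        for r in topology.residues:
            res = gemmi.Residue()
            res.name = r.base
            res.seqid = gemmi.SeqId(r.orig_seqid or r.index, " ")
            for nm, gi in r.atom_indices.items():
                at = gemmi.Atom()
                at.name = nm
                at.element = gemmi.Element(topology.atoms[gi].element)
                at.serial = gi + 1
                x, y, z = coords[gi]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_samples(pool, path):
    """Write a pool of conformations as a multi-model PDB.

    `pool` may be a SamplePool, a list of Conformation objects, or a list of
    coordinate arrays paired with a topology via ``pool.topology``.
    """
    coord_sets, topology = _pool_coords(pool)
    if not coord_sets:
        raise ValueError("refusing to write an empty pool")
    st = coords_to_structure(topology, coord_sets)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def _pool_coords(pool):
    topology = getattr(pool, "topology", None)
    members = getattr(pool, "conformations", pool)
    coord_sets = []
    for m in members:
        c = getattr(m, "coords", m)
        coord_sets.append(np.asarray(c, dtype=float))
        if topology is None:
            topology = getattr(getattr(m, "tree", None), "topology", None)
    if topology is None:
        raise ValueError("cannot infer topology from pool")
    return coord_sets, topology
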