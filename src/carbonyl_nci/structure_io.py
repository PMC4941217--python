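"""Structure reading/writing and identification of acceptor and donor groups.

PDB files are parsed with gemmi and converted into lightweight records that
the classifiers consume. A structure is an ordered list of protein residues
(each an ordered atom list) plus explicit water molecules. Alternate
locations are resolved to a single conformer at read time; MODEL blocks
become separate snapshot structures.

Hydrogen-to-heavy-atom bonding is always inferred from distance (<= 1.2 A),
never from atom names, so both PDB v2 ("1HB") and v3 ("HB1") hydrogen
naming dialects work.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

from .geometry import distance

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL", "TIP", "T3P"}

#: maximum covalent H-heavy bond length used for bond inference (A)
H_BOND_INFER_MAX = 1.2

#: maximum C(i)-N(i+1) distance accepted as a peptide bond (A)
PEPTIDE_BOND_MAX = 1.8

# standard residues whose side-chain amide carbonyls also act as acceptors
SIDECHAIN_CARBONYLS = {
    "ASN": ("CG", "OD1", "CB"),
    "GLN": ("CD", "OE1", "CG"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise PDBParseError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise PDBParseError(f"atom {self.name} has empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


ResidueId = tuple  # (chain_id, res_seq, i_code)


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str
    name: str
    atoms: list = field(default_factory=list)
    incomplete: bool = False

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.res_seq, self.i_code)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def hydrogens(self) -> list:
        return [a for a in self.atoms if a.is_hydrogen]


@dataclass
class Water:
    index: int
    O: AtomRecord
    hydrogens: list = field(default_factory=list)

    @property
    def residue_id(self) -> ResidueId:
        return (self.O.chain_id, self.O.res_seq, self.O.i_code)


@dataclass
class Structure:
    id: str
    residues: list = field(default_factory=list)
    waters: list = field(default_factory=list)
    snapshot_index: int = 0
    #: frozen chain topology (residue id -> successor residue id); set on
    #: snapshot ensembles so distorted geometries keep the reference
    #: connectivity. None means adjacency is decided by the peptide-bond
    #: distance check.
    fixed_adjacency: Optional[dict] = None

    def __post_init__(self):
        self._index = {r.residue_id: r for r in self.residues}
        self._adj_cache = None

    def residue(self, residue_id: ResidueId) -> Optional[Residue]:
        return self._index.get(tuple(residue_id))

    def reindex(self) -> None:
        self._index = {r.residue_id: r for r in self.residues}
        self._adj_cache = None

    def compute_adjacency(self) -> dict:
        """residue id -> successor id for every peptide-bonded (i, i+1)
        pair (C_i-N_{i+1} <= 1.8 A, same chain, consecutive in order)."""
        adj = {}
        for i, res in enumerate(self.residues[:-1]):
            nxt = self.residues[i + 1]
            if nxt.chain_id != res.chain_id:
                continue
            c, n = res.atom("C"), nxt.atom("N")
            if c is None or n is None:
                continue
            if distance(c.xyz, n.xyz) <= PEPTIDE_BOND_MAX:
                adj[res.residue_id] = nxt.residue_id
        return adj

    def _adjacency(self) -> dict:
        if self.fixed_adjacency is not None:
            return self.fixed_adjacency
        if self._adj_cache is None:
            self._adj_cache = self.compute_adjacency()
        return self._adj_cache

    def freeze_adjacency(self, adjacency: Optional[dict] = None) -> None:
        self.fixed_adjacency = (
            dict(adjacency) if adjacency is not None else self.compute_adjacency()
        )

    def successor(self, res: Residue) -> Optional[Residue]:
        """Next residue in the chain if peptide-bonded to ``res``."""
        nxt_id = self._adjacency().get(res.residue_id)
        return self.residue(nxt_id) if nxt_id is not None else None

    def predecessor(self, res: Residue) -> Optional[Residue]:
        for a, b in self._adjacency().items():
            if b == res.residue_id:
                return self.residue(a)
        return None

    def all_atoms(self) -> Iterable:
        for r in self.residues:
            yield from r.atoms
        for w in self.waters:
            yield w.O
            yield from w.hydrogens

    def copy(self) -> "Structure":
        import copy as _copy

        return _copy.deepcopy(self)


# --------------------------------------------------------------------------
# acceptor / donor typing

@dataclass
class CarbonylSite:
    residue_id: ResidueId
    C: AtomRecord
    O: AtomRecord
    CA: AtomRecord
    kind: str = "mainchain"  # or "sidechain"

    def covalent_ok(self, lo: float = 1.1, hi: float = 1.4) -> bool:
        """C=O bond length within the covalent range expected of a
        well-formed structure. Identification is topological (atom names),
        so heavily perturbed snapshot geometries still yield sites; this
        check flags them."""
        return lo <= distance(self.C.xyz, self.O.xyz) <= hi


DONOR_CATEGORIES = ("NH_bb", "NH_sc", "OH_sc", "CaH", "CH_X", "HOH")


@dataclass
class DonorGroup:
    category: str
    heavy: AtomRecord
    hydrogens: list
    residue_id: ResidueId

    def __post_init__(self):
        if self.category not in DONOR_CATEGORIES:
            raise ValueError(f"unknown donor category {self.category}")


# --------------------------------------------------------------------------
# reading

def _resolve_altlocs(atoms: list) -> list:
    """Keep one conformer per atom name: highest occupancy, ties broken to
    the alphabetically first altLoc (so 'A' wins)."""
    by_name: dict = {}
    order: list = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    out = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            out.append(group[0])
        else:
            group.sort(key=lambda a: (-a.occupancy, a.alt_loc or "~"))
            out.append(group[0])
    return out


def _structure_from_model(model, struct_id: str, snapshot_index: int) -> Structure:
    residues: list = []
    waters: list = []
    widx = 0
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name or "X",
                        alt_loc=at.altloc if at.altloc != "\x00" else "",
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        i_code=res.seqid.icode.strip(),
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ,
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if res.name in WATER_NAMES:
                oxy = [a for a in atoms if a.element.upper() == "O"]
                hyd = [a for a in atoms if a.is_hydrogen]
                if not oxy:
                    logger.warning("water %s has no oxygen; skipped", res.seqid.num)
                    continue
                waters.append(Water(index=widx, O=oxy[0], hydrogens=hyd))
                widx += 1
            else:
                r = Residue(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    i_code=res.seqid.icode.strip(),
                    name=res.name,
                    atoms=atoms,
                )
                residues.append(r)
    residues.sort(key=lambda r: (r.chain_id, r.res_seq, r.i_code))
    s = Structure(
        id=struct_id, residues=residues, waters=waters, snapshot_index=snapshot_index
    )
    _flag_incomplete(s)
    return s


def _flag_incomplete(s: Structure) -> None:
    for i, r in enumerate(s.residues):
        if not r.has_backbone():
            is_terminal = (
                s.predecessor(r) is None or s.successor(r) is None
            )
            r.incomplete = True
            if not is_terminal:
                logger.warning(
                    "residue %s %s missing backbone atoms (non-terminal)",
                    r.name,
                    r.residue_id,
                )


def read_models(path) -> list:
    """Read a PDB file; every MODEL block becomes one Structure with
    snapshot_index 0, 1, ..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    out = []
    for i, model in enumerate(st):
        out.append(_structure_from_model(model, struct_id=path.stem, snapshot_index=i))
    if not out:
        raise PDBParseError(f"{path}: no models found")
    if len(out) > 1:
        # a multi-model file is a trajectory: topology is constant, so the
        # first model's peptide connectivity applies to every snapshot
        adj = out[0].compute_adjacency()
        for s in out:
            s.freeze_adjacency(adj)
    return out


def read_pdb(path) -> Structure:
    """Read the first (or only) model of a PDB file as one Structure."""
    return read_models(path)[0]


# --------------------------------------------------------------------------
# writing (fixed-width ATOM/HETATM formatting; parsing stays in gemmi)

def _format_atom(a: AtomRecord, serial: int, hetatm: bool) -> str:
    name = a.name
    # PDB column alignment: 1-2 char element symbols start at column 13,
    # 4-char names fill 13-16, others start at column 14.
    if len(name) < 4 and len(a.element) == 1:
        name = f" {name}"
    rec = "HETATM" if hetatm else "ATOM  "
    return (
        f"{rec}{serial:5d} {name:<4s}{'':1s}{a.res_name:>3s} {a.chain_id:1s}"
        f"{a.res_seq:4d}{a.i_code or ' ':1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(structures, path) -> None:
    """Write one Structure or a list of Structures (multi-MODEL) to PDB."""
    if isinstance(structures, Structure):
        structures = [structures]
    lines = []
    multi = len(structures) > 1
    for s in structures:
        if multi:
            lines.append(f"MODEL     {s.snapshot_index + 1:4d}")
        serial = 0
        last_chain = None
        for r in s.residues:
            for a in r.atoms:
                serial += 1
                lines.append(_format_atom(a, serial, hetatm=False))
            last_chain = r.chain_id
        if last_chain is not None:
            lines.append("TER")
        for w in s.waters:
            for a in [w.O] + list(w.hydrogens):
                serial += 1
                lines.append(_format_atom(a, serial, hetatm=True))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# site identification

def identify_carbonyls(s: Structure, include_sidechain: bool = True) -> list:
    """Backbone C=O acceptor sites, one per residue with a peptide-bonded
    successor (the C-terminal carboxylate is not an amide carbonyl and is
    excluded), plus Asn/Gln side-chain amide carbonyls."""
    sites = []
    for r in s.residues:
        if r.incomplete or not r.has_backbone():
            logger.debug("skipping incomplete residue %s", r.residue_id)
            continue
        if s.successor(r) is not None:
            site = CarbonylSite(
                residue_id=r.residue_id,
                C=r.atom("C"),
                O=r.atom("O"),
                CA=r.atom("CA"),
                kind="mainchain",
            )
            if not site.covalent_ok():
                logger.debug(
                    "distorted C=O bond at %s (kept; geometry screens decide)",
                    r.residue_id,
                )
            sites.append(site)
        if include_sidechain and r.name in SIDECHAIN_CARBONYLS:
            cn, on, can = SIDECHAIN_CARBONYLS[r.name]
            c, o, ca = r.atom(cn), r.atom(on), r.atom(can)
            if c is not None and o is not None and ca is not None:
                sites.append(
                    CarbonylSite(
                        residue_id=r.residue_id, C=c, O=o, CA=ca, kind="sidechain"
                    )
                )
    return sites


def _bonded_hydrogens(heavy: AtomRecord, hydrogens: list) -> list:
    return [
        h for h in hydrogens if distance(heavy.xyz, h.xyz) <= H_BOND_INFER_MAX
    ]


def identify_donors(s: Structure) -> list:
    """All candidate donor groups with explicit hydrogens.

    Categories: backbone amide NH (``NH_bb``, absent for proline), side-chain
    NH (``NH_sc``), side-chain hydroxyl (``OH_sc``), alpha-carbon H
    (``CaH``), any other side-chain C-H (``CH_X``) and water (``HOH``).
    Waters without hydrogens cannot be measured and are excluded (use
    :func:`count_dry_waters` to report how many there are).
    """
    donors = []
    for r in s.residues:
        hyds = r.hydrogens()
        for heavy in r.heavy_atoms():
            bh = _bonded_hydrogens(heavy, hyds)
            if not bh:
                continue
            el = heavy.element.upper()
            if heavy.name == "N":
                if r.name == "PRO":
                    continue
                donors.append(DonorGroup("NH_bb", heavy, bh, r.residue_id))
            elif el == "N":
                donors.append(DonorGroup("NH_sc", heavy, bh, r.residue_id))
            elif el == "O":
                donors.append(DonorGroup("OH_sc", heavy, bh, r.residue_id))
            elif el == "C":
                if heavy.name == "CA":
                    donors.append(DonorGroup("CaH", heavy, bh, r.residue_id))
                else:
                    donors.append(DonorGroup("CH_X", heavy, bh, r.residue_id))
    for w in s.waters:
        bh = _bonded_hydrogens(w.O, w.hydrogens)
        if bh:
            donors.append(DonorGroup("HOH", w.O, bh, ("W", w.index, "")))
        else:
            logger.debug("water %d has no bonded hydrogens", w.index)
    return donors


def count_dry_waters(s: Structure) -> int:
    """Waters lacking explicit hydrogens (undetectable as donors)."""
    return sum(
        1 for w in s.waters if not _bonded_hydrogens(w.O, w.hydrogens)
    )


def structure_summary(s: Structure) -> dict:
    donors = identify_donors(s)
    by_cat: dict = {c: 0 for c in DONOR_CATEGORIES}
    for d in donors:
        by_cat[d.category] += 1
    dry = count_dry_waters(s)
    return {
        "id": s.id,
        "snapshot_index": s.snapshot_index,
        "n_residues": len(s.residues),
        "n_waters": len(s.waters),
        "n_waters_without_hydrogens": dry,
        "n_carbonyl_sites": len(identify_carbonyls(s)),
        "donors_by_category": by_cat,
    }


def write_summary_json(s: Structure, path) -> None:
    Path(path).write_text(json.dumps(structure_summary(s), indent=2) + "\n")
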