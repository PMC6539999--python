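"""Active-site scaffolds: PDB I/O, substrate anchoring, and shell extraction.

A scaffold is a single-model protein structure with one substrate anchor
residue (the native ligand the ncAA core is superposed onto) and an optional
set of fixed (catalytic) positions that are never designed.  Residue numbering
is preserved verbatim from the input; positions are keyed ``(chain, number)``.

PDB reading/writing goes through biotite's ``AtomArray``; alternate locations
are resolved by occupancy, waters are dropped, and insertion codes are
rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .errors import AnchorError, ParseError, UnderdeterminedError
from .geometry import kabsch_superpose
from .ligand import Conformer

Position = tuple[str, int]

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_BACKBONE = ("N", "CA", "C", "O", "OXT")


@dataclass
class Residue:
    chain_id: str
    number: int
    res_name: str
    atoms: dict[str, np.ndarray]
    hetero: bool = False

    @property
    def identity(self) -> str:
        return chemistry.ONE_LETTER.get(self.res_name, "X")

    @property
    def key(self) -> Position:
        return (self.chain_id, self.number)

    def side_chain_atoms(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.atoms.items()
                if k not in _BACKBONE and chemistry.element_of(k) != "H"}

    def backbone_frame(self):
        """(N, CA, C) coordinates; raises KeyError if incomplete."""
        return self.atoms["N"], self.atoms["CA"], self.atoms["C"]

    def heavy_coords(self) -> np.ndarray:
        pts = [v for k, v in self.atoms.items() if chemistry.element_of(k) != "H"]
        return np.array(pts, float) if pts else np.empty((0, 3))


@dataclass
class Scaffold:
    residues: dict[Position, Residue]
    anchor: Position
    anchor_atom_map: dict[str, str] = field(default_factory=dict)
    fixed_positions: set[Position] = field(default_factory=set)
    note: str = "author numbering preserved verbatim"

    @property
    def anchor_residue(self) -> Residue:
        return self.residues[self.anchor]

    def protein_positions(self) -> list[Position]:
        return sorted(k for k, r in self.residues.items()
                      if k != self.anchor and not r.hetero)

    def wild_type(self) -> dict[Position, str]:
        return {k: self.residues[k].identity for k in self.protein_positions()}


@dataclass
class LigandPose:
    """A conformer rigidly placed in the scaffold frame."""

    conformer: Conformer
    rotation: np.ndarray
    translation: np.ndarray
    core_rmsd: float

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        xyz = self.conformer.coords @ self.rotation.T + self.translation
        if heavy_only:
            xyz = xyz[self.conformer.template.heavy_indices()]
        return xyz

    def atom_coord(self, name: str) -> np.ndarray:
        i = self.conformer.template.index_of(name)
        return self.conformer.coords[i] @ self.rotation.T + self.translation


def read_structure(pdb_text: str, anchor: dict, fixed_positions=(),
                   anchor_atom_map=None) -> Scaffold:
    """Parse PDB text into a Scaffold.

    ``anchor`` selects the substrate residue, either ``{"res_name": "LIG"}`` or
    ``{"chain": "A", "number": 500}``.  Insertion codes are rejected; malformed
    coordinate fields are reported with their line number; among alternate
    locations the highest-occupancy one is kept; waters are ignored.
    """
    _prescan(pdb_text)
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except ParseError:
        raise
    except Exception as exc:  # biotite raises its own hierarchy
        raise ParseError(f"unparseable PDB: {exc}") from exc

    residues: dict[Position, Residue] = {}
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).strip()
        if res_name in _WATER_NAMES:
            continue
        key = (str(arr.chain_id[i]).strip() or "A", int(arr.res_id[i]))
        res = residues.get(key)
        if res is None:
            res = Residue(key[0], key[1], res_name, {}, hetero=bool(arr.hetero[i]))
            residues[key] = res
        res.atoms[str(arr.atom_name[i]).strip()] = np.array(arr.coord[i], float)

    anchor_key = _resolve_anchor(residues, anchor)
    fixed = {(p if isinstance(p, tuple) else ("A", int(p))) for p in fixed_positions}
    return Scaffold(residues, anchor_key, dict(anchor_atom_map or {}), fixed)


def _prescan(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) > 26 and line[26] not in (" ", ""):
            raise ParseError("insertion codes are not supported", line=lineno)
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except (ValueError, IndexError):
            raise ParseError("malformed coordinate field", line=lineno)


def _resolve_anchor(residues, anchor: dict) -> Position:
    if "res_name" in anchor:
        hits = [k for k, r in residues.items() if r.res_name == anchor["res_name"]]
        if not hits:
            raise AnchorError(f"no residue named {anchor['res_name']!r} in structure")
        return sorted(hits)[0]
    key = (str(anchor.get("chain", "A")), int(anchor["number"]))
    if key not in residues:
        raise AnchorError(f"anchor residue {key} not found")
    return key


def write_structure(scaffold: Scaffold) -> str:
    """Serialize a scaffold back to PDB text (single model)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    rows = []
    for key in sorted(scaffold.residues):
        res = scaffold.residues[key]
        for name in sorted(res.atoms):
            rows.append((res, name))
    n = len(rows)
    arr = struc.AtomArray(n)
    for i, (res, name) in enumerate(rows):
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.number
        arr.res_name[i] = res.res_name
        arr.atom_name[i] = name
        arr.hetero[i] = res.hetero
        arr.element[i] = chemistry.element_of(name)
        arr.coord[i] = res.atoms[name]
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def shell_positions(scaffold: Scaffold, pose: LigandPose,
                    inner_radius: float = 6.0, outer_radius: float = 9.0):
    """First/second-shell positions around the posed ligand.

    Half-open bands: first shell is any side-chain heavy atom in [0, inner),
    second shell in [inner, outer).  Fixed positions and the anchor are
    excluded.  Glycine, having no side-chain heavy atoms, uses CA as proxy.
    """
    if not (0 < inner_radius < outer_radius):
        raise ValueError("need 0 < inner_radius < outer_radius")
    lig = pose.coords(heavy_only=True)
    first, second = [], []
    for key in scaffold.protein_positions():
        if key in scaffold.fixed_positions:
            continue
        res = scaffold.residues[key]
        sc = res.side_chain_atoms()
        pts = np.array(list(sc.values())) if sc else res.atoms.get("CA")
        if pts is None:
            continue
        pts = np.atleast_2d(pts)
        d = np.min(np.linalg.norm(pts[:, None, :] - lig[None, :, :], axis=2))
        if d < inner_radius:
            first.append(key)
        elif d < outer_radius:
            second.append(key)
    return sorted(first), sorted(second)


def anchor_superpose(conformer: Conformer, scaffold: Scaffold) -> LigandPose:
    """Superpose the conformer's rigid core onto the scaffold's substrate anchor.

    The core-atom correspondence defaults to identical atom names, optionally
    remapped through ``scaffold.anchor_atom_map``.
    """
    anchor = scaffold.anchor_residue
    amap = scaffold.anchor_atom_map
    pairs = []
    for name in sorted(conformer.template.core_atoms):
        target_name = amap.get(name, name)
        if target_name in anchor.atoms:
            pairs.append((name, target_name))
    if len(pairs) < 3:
        raise UnderdeterminedError(
            f"only {len(pairs)} corresponding core atoms; need at least 3")
    mobile = np.array([conformer.atom_coord(a) for a, _ in pairs])
    target = np.array([anchor.atoms[b] for _, b in pairs])
    R, t, rmsd = kabsch_superpose(mobile, target)
    return LigandPose(conformer, R, t, rmsd)
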