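"""Reduced side-chain chemistry shared by the matcher, designer and fixtures.

Residue identities are represented as linear heavy-atom side-chain stubs built
outward from the backbone by internal coordinates: CB, then up to three more
chain atoms, each rotatable bond carrying one chi angle.  The terminal atom may
carry hydrogen-bond donor/acceptor capability.  This is deliberately a
parameterized toy chemistry - no rings, no branches - chosen so that packing and
matching state spaces stay exhaustively enumerable in tests, while preserving
the features the pipeline logic depends on: sterics (vdW radii), polarity, and
discrete rotamers on an sp3 chi grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral_deg, place_atom

# van der Waals radii (Angstrom), heavy atoms only
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# heavy-atom bond lengths (Angstrom), element-pair keyed, order-insensitive
_BOND_LENGTHS = {
    frozenset(["C"]): 1.53,
    frozenset(["C", "O"]): 1.43,
    frozenset(["C", "N"]): 1.47,
    frozenset(["C", "S"]): 1.81,
}

SIDE_CHAIN_ANGLE = 111.0  # generic sp3 chain angle, degrees
CB_BOND = 1.53
CB_ANGLE = 110.5  # N-CA-CB
CB_DIHEDRAL = 122.5  # C-N-CA-CB improper placement

# sp3 chi grid; the declared stand-in for a backbone-dependent rotamer library
SP3_CHI_GRID = (-60.0, 60.0, 180.0)

_GREEK = "BGDEZ"


@dataclass(frozen=True)
class SideChainSpec:
    """Linear stub: chain of elements outward from CA; polar flags on the tip."""

    elements: tuple[str, ...]
    donor: bool = False
    acceptor: bool = False

    @property
    def n_chi(self) -> int:
        return max(0, len(self.elements) - 1)

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(e + _GREEK[i] for i, e in enumerate(self.elements))

    @property
    def terminal_name(self) -> str | None:
        names = self.atom_names
        return names[-1] if names else None

    @property
    def polar_terminal(self) -> bool:
        return bool(self.elements) and (self.donor or self.acceptor)


# Twenty canonical identities mapped onto stub chains.  Chain lengths track the
# real side chains loosely (rings collapsed to chains, long chains truncated at
# four heavy atoms); polar flags follow the real terminal groups.
SIDE_CHAINS: dict[str, SideChainSpec] = {
    "G": SideChainSpec(()),
    "A": SideChainSpec(("C",)),
    "S": SideChainSpec(("C", "O"), donor=True, acceptor=True),
    "C": SideChainSpec(("C", "S"), donor=True),
    "T": SideChainSpec(("C", "O"), donor=True, acceptor=True),
    "P": SideChainSpec(("C", "C")),
    "V": SideChainSpec(("C", "C")),
    "N": SideChainSpec(("C", "C", "N"), donor=True, acceptor=True),
    "D": SideChainSpec(("C", "C", "O"), acceptor=True),
    "L": SideChainSpec(("C", "C", "C")),
    "I": SideChainSpec(("C", "C", "C")),
    "M": SideChainSpec(("C", "C", "S")),
    "H": SideChainSpec(("C", "C", "N"), donor=True, acceptor=True),
    "F": SideChainSpec(("C", "C", "C")),
    "Q": SideChainSpec(("C", "C", "C", "N"), donor=True, acceptor=True),
    "E": SideChainSpec(("C", "C", "C", "O"), acceptor=True),
    "K": SideChainSpec(("C", "C", "C", "N"), donor=True),
    "R": SideChainSpec(("C", "C", "C", "N"), donor=True),
    "Y": SideChainSpec(("C", "C", "C", "O"), donor=True, acceptor=True),
    "W": SideChainSpec(("C", "C", "C", "N"), donor=True),
}

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}


def bond_length(elem_a: str, elem_b: str) -> float:
    return _BOND_LENGTHS[frozenset([elem_a, elem_b])]


def element_of(atom_name: str) -> str:
    """First alphabetic character convention; matches this package's atom naming."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def vdw_radius(atom_name: str) -> float:
    return VDW_RADII.get(element_of(atom_name), 1.70)


def build_side_chain(identity: str, n, ca, c, chis=()) -> dict[str, np.ndarray]:
    """Build stub side-chain coordinates on a backbone frame.

    ``chis`` supplies one dihedral per rotatable bond (chi1 = N-CA-CB-G1, ...).
    Returns atom name -> coordinate; empty dict for glycine.
    """
    spec = SIDE_CHAINS[identity]
    if not spec.elements:
        return {}
    chis = tuple(chis)
    if len(chis) != spec.n_chi:
        raise ValueError(
            f"identity {identity} needs {spec.n_chi} chi angles, got {len(chis)}"
        )
    names = spec.atom_names
    atoms: dict[str, np.ndarray] = {}
    cb = place_atom(c, n, ca, CB_BOND, CB_ANGLE, CB_DIHEDRAL)
    atoms[names[0]] = cb
    prev3 = (np.asarray(n, float), np.asarray(ca, float), cb)
    for i in range(1, len(spec.elements)):
        bl = bond_length(spec.elements[i - 1], spec.elements[i])
        pos = place_atom(*prev3, bl, SIDE_CHAIN_ANGLE, chis[i - 1])
        atoms[names[i]] = pos
        prev3 = (prev3[1], prev3[2], pos)
    return atoms


def measure_chis(identity: str, n, ca, atoms: dict[str, np.ndarray]) -> tuple[float, ...]:
    """Recover chi angles of a stub side chain from its coordinates."""
    spec = SIDE_CHAINS[identity]
    names = spec.atom_names
    path = [np.asarray(n, float), np.asarray(ca, float)] + [atoms[nm] for nm in names]
    return tuple(
        dihedral_deg(path[i], path[i + 1], path[i + 2], path[i + 3])
        for i in range(spec.n_chi)
    )


def default_rotamers(identities=None) -> dict[str, list[tuple[float, ...]]]:
    """Discrete rotamer sets: full sp3 chi grid per rotatable bond.

    Glycine and alanine contribute a single (chi-less) rotamer.
    """
    if identities is None:
        identities = SIDE_CHAINS.keys()
    out = {}
    for ident in identities:
        spec = SIDE_CHAINS[ident]
        out[ident] = [tuple(c) for c in itertools.product(SP3_CHI_GRID, repeat=spec.n_chi)]
    return out


# --- scoring wells -----------------------------------------------------------

CLASH_FACTOR = 0.8  # heavy-atom pair closer than 0.8 x sum of vdW radii = clash

# hydrogen-bond geometry defaults ("standard H bond")
HBOND_D_MIN = 2.6
HBOND_D_MAX = 3.2
HBOND_D_IDEAL = 2.9
HBOND_ANGLE_MIN = 120.0

_STERIC_REP_WEIGHT = 4.0
_STERIC_ATT_DEPTH = 0.05
_STERIC_ATT_WIDTH = 1.0
_STERIC_ATT_OFFSET = 0.25


def soft_lj_pair(r: float, r0: float) -> tuple[float, float]:
    """Soft steric well for one heavy-atom pair at distance ``r``.

    Returns ``(repulsion, attraction)``.  Repulsion is a quadratic well that is
    exactly zero at the vdW contact distance ``r0`` and switches to a linear
    ramp below the 0.8*r0 overlap-softening point; attraction is a shallow
    inverted parabola centred just outside contact.
    """
    soft = CLASH_FACTOR * r0
    if r < soft:
        # linear continuation matching value and slope at the softening point
        e_soft = _STERIC_REP_WEIGHT * ((r0 - soft) / r0) ** 2
        slope = 2.0 * _STERIC_REP_WEIGHT * (r0 - soft) / r0**2
        rep = e_soft + slope * (soft - r)
    elif r < r0:
        rep = _STERIC_REP_WEIGHT * ((r0 - r) / r0) ** 2
    else:
        rep = 0.0
    rmin = r0 + _STERIC_ATT_OFFSET
    x = (r - rmin) / _STERIC_ATT_WIDTH
    att = -_STERIC_ATT_DEPTH * (1.0 - x * x) if abs(x) < 1.0 else 0.0
    return rep, att


def hbond_well(distance: float, angle_donor: float, angle_acceptor: float) -> float:
    """Geometric H-bond well: -1 at ideal geometry, 0 at the range edges.

    Linear taper in each dimension; zero outside 2.6-3.2 A donor-acceptor
    distance or below 120 deg at either partner.
    """
    half = max(HBOND_D_IDEAL - HBOND_D_MIN, HBOND_D_MAX - HBOND_D_IDEAL)
    fd = max(0.0, 1.0 - abs(distance - HBOND_D_IDEAL) / half)
    if not (HBOND_D_MIN <= distance <= HBOND_D_MAX):
        fd = 0.0
    fa = max(0.0, (angle_donor - HBOND_ANGLE_MIN) / (180.0 - HBOND_ANGLE_MIN))
    fb = max(0.0, (angle_acceptor - HBOND_ANGLE_MIN) / (180.0 - HBOND_ANGLE_MIN))
    return -fd * fa * fb


def is_clash(r: float, r0: float) -> bool:
    return r < CLASH_FACTOR * r0
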