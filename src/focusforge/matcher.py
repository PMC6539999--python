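"""Geometric matching: placing H-bonding residues against the posed ncAA.

For every conformer in an ensemble, the matcher enumerates
(position x identity x rotamer) candidates per declared geometric constraint,
keeps those whose terminal polar atom satisfies the distance/angle (and
optional torsion) ranges to the ligand's named polar group, and combines one
candidate per constraint into a match, requiring distinct positions and no
steric clash among the placed side chains or with the ligand.  Output is
deduplicated to sequence-unique matches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .errors import ConfigurationError
from .geometry import angle_deg, dihedral_deg
from .ligand import ConformerEnsemble
from .scaffold import LigandPose, Position, Scaffold, anchor_superpose


@dataclass(frozen=True)
class GeometricConstraint:
    """Distance/angle ranges between a ligand polar group and a residue tip.

    ``rotamer_policy`` is ``"full"`` (all allowed identities at all positions,
    discrete rotamer grid) or ``"native-only"`` (only the wild-type side chain
    in its crystallographic state, at positions whose identity is allowed).
    All ranges are closed intervals.
    """

    name: str
    ligand_group: str
    allowed_identities: frozenset[str]
    distance: tuple[float, float]
    angle_at_ligand: tuple[float, float] | None = (120.0, 180.0)
    angle_at_residue: tuple[float, float] | None = (120.0, 180.0)
    torsion: tuple[float, float] | None = None
    rotamer_policy: str = "full"

    def __post_init__(self):
        if not self.allowed_identities:
            raise ConfigurationError(f"{self.name}: empty identity set")
        for rng in (self.distance, self.angle_at_ligand,
                    self.angle_at_residue, self.torsion):
            if rng is not None and rng[0] > rng[1]:
                raise ConfigurationError(f"{self.name}: min > max in range {rng}")


def standard_hbond_constraint(name: str, ligand_group: str, identities,
                              policy: str = "full") -> GeometricConstraint:
    """Constraint with the declared standard H-bond geometry defaults."""
    return GeometricConstraint(
        name=name,
        ligand_group=ligand_group,
        allowed_identities=frozenset(identities),
        distance=(chemistry.HBOND_D_MIN, chemistry.HBOND_D_MAX),
        angle_at_ligand=(chemistry.HBOND_ANGLE_MIN, 180.0),
        angle_at_residue=(chemistry.HBOND_ANGLE_MIN, 180.0),
        rotamer_policy=policy,
    )


def evaluate_constraint(ligand_atoms, residue_atoms,
                        constraint: GeometricConstraint):
    """Check one ligand-atom/residue-atom pairing against a constraint.

    ``ligand_atoms`` is ``(polar_atom_xyz, base_atom_xyz)`` on the ligand side,
    ``residue_atoms`` likewise on the residue side (tip atom and its chain
    antecedent).  Returns ``(satisfied, measured)`` where ``measured`` holds
    the distance, both angles, and the torsion if declared.
    """
    (lp, lb), (rp, rb) = ligand_atoms, residue_atoms
    lp, lb, rp, rb = (np.asarray(p, float) for p in (lp, lb, rp, rb))
    measured = {"distance": float(np.linalg.norm(lp - rp))}
    ok = _in_range(measured["distance"], constraint.distance)
    if constraint.angle_at_ligand is not None:
        measured["angle_at_ligand"] = angle_deg(lb, lp, rp)
        ok &= _in_range(measured["angle_at_ligand"], constraint.angle_at_ligand)
    if constraint.angle_at_residue is not None:
        measured["angle_at_residue"] = angle_deg(rb, rp, lp)
        ok &= _in_range(measured["angle_at_residue"], constraint.angle_at_residue)
    if constraint.torsion is not None:
        measured["torsion"] = dihedral_deg(lb, lp, rp, rb)
        ok &= _in_range(measured["torsion"], constraint.torsion)
    return ok, measured


def _in_range(value: float, rng) -> bool:
    return rng[0] <= value <= rng[1]


@dataclass(frozen=True)
class Assignment:
    identity: str
    chis: tuple[float, ...] | None  # None = native side chain
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    constraint: str
    geometry: tuple[tuple[str, float], ...]

    def atom_dict(self) -> dict[str, np.ndarray]:
        return {n: np.array(c) for n, c in self.atoms}


@dataclass
class Match:
    scaffold: Scaffold
    pose: LigandPose
    conformer_index: int
    assignments: dict[Position, Assignment]
    constraints: tuple[GeometricConstraint, ...]
    match_id: str = ""

    @property
    def signature(self) -> str:
        parts = [f"{c}:{n}:{a.identity}"
                 for (c, n), a in sorted(self.assignments.items())]
        return ",".join(parts)

    def geometry_record(self) -> dict:
        return {f"{pos[0]}:{pos[1]}": dict(a.geometry)
                for pos, a in self.assignments.items()}


def _ligand_polar_sites(pose: LigandPose, group: str):
    """(atom_name, xyz, base_xyz) for each polar heavy atom of a ligand group."""
    tmpl = pose.conformer.template
    sites = []
    for name in tmpl.polar_groups[group]:
        elem = tmpl.atoms[tmpl.index_of(name)].element
        if elem not in ("N", "O", "S"):
            continue
        base = tmpl.neighbor(name)
        sites.append((name, pose.atom_coord(name), pose.atom_coord(base)))
    return sites


def _residue_tip(identity: str, atoms: dict[str, np.ndarray], ca):
    spec = chemistry.SIDE_CHAINS[identity]
    names = spec.atom_names
    if not spec.polar_terminal or names[-1] not in atoms:
        return None
    tip = atoms[names[-1]]
    base = atoms[names[-2]] if len(names) > 1 else np.asarray(ca, float)
    return tip, base


def _candidate_geometry(pose, constraint, identity, atoms, ca):
    tip = _residue_tip(identity, atoms, ca)
    if tip is None:
        return None
    best = None
    for name, lig_xyz, base_xyz in _ligand_polar_sites(pose, constraint.ligand_group):
        ok, measured = evaluate_constraint((lig_xyz, base_xyz), tip, constraint)
        if ok:
            measured["ligand_atom_dev"] = abs(
                measured["distance"]
                - 0.5 * (constraint.distance[0] + constraint.distance[1]))
            if best is None or measured["ligand_atom_dev"] < best[1]["ligand_atom_dev"]:
                measured["ligand_atom"] = name
                best = (name, measured)
    if best is None:
        return None
    geom = {k: v for k, v in best[1].items() if k != "ligand_atom_dev"}
    return geom


def _clashes_ligand(atoms: dict[str, np.ndarray], pose: LigandPose,
                    check_clash: bool) -> bool:
    if not check_clash or not atoms:
        return False
    tmpl = pose.conformer.template
    heavy = pose.coords(heavy_only=True)
    radii = np.array([chemistry.VDW_RADII.get(tmpl.elements[i], 1.7)
                      for i in tmpl.heavy_indices()])
    for name, xyz in atoms.items():
        r = chemistry.vdw_radius(name)
        d = np.linalg.norm(heavy - np.asarray(xyz), axis=1)
        if np.any(d < chemistry.CLASH_FACTOR * (radii + r)):
            return True
    return False


def _pair_clash(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> bool:
    for na, xa in a.items():
        for nb, xb in b.items():
            r0 = chemistry.vdw_radius(na) + chemistry.vdw_radius(nb)
            if np.linalg.norm(np.asarray(xa) - np.asarray(xb)) < chemistry.CLASH_FACTOR * r0:
                return True
    return False


def find_matches(scaffold: Scaffold, ensemble: ConformerEnsemble,
                 constraints: list[GeometricConstraint],
                 rotamer_set: dict[str, list[tuple[float, ...]]] | None = None,
                 positions: list[Position] | None = None,
                 check_clash: bool = True) -> list[Match]:
    """Enumerate sequence-unique constraint-satisfying placements.

    Every constraint must be satisfied at a distinct position; placed side
    chains may not clash with each other or the ligand (heavy-atom pair below
    0.8x the sum of vdW radii).  Results are deduplicated by sequence
    signature, keeping the lexicographically smallest
    (conformer index, position tuple) representative, and sorted by signature.
    """
    if not constraints:
        raise ConfigurationError("at least one constraint is required")
    if rotamer_set is None:
        rotamer_set = chemistry.default_rotamers()
    for cst in constraints:
        if cst.rotamer_policy == "full":
            for ident in cst.allowed_identities:
                if ident not in rotamer_set:
                    raise ConfigurationError(
                        f"{cst.name}: identity {ident} has no rotamers in rotamer_set")
    if positions is None:
        positions = [p for p in scaffold.protein_positions()
                     if p not in scaffold.fixed_positions]
    # fixed (catalytic) residues stay out of identity sampling but remain
    # visible to native-only constraints (e.g. the native Gln contact)
    native_positions = scaffold.protein_positions()

    raw: list[Match] = []
    for ci, conf in enumerate(ensemble):
        pose = anchor_superpose(conf, scaffold)
        cand_lists = []
        for cst in constraints:
            pool = native_positions if cst.rotamer_policy == "native-only" else positions
            cands = _constraint_candidates(scaffold, pose, cst, rotamer_set,
                                           pool, check_clash)
            cand_lists.append(cands)
        for combo in itertools.product(*cand_lists):
            pos_list = [c[0] for c in combo]
            if len(set(pos_list)) != len(pos_list):
                continue
            if check_clash and _combo_clashes(combo):
                continue
            assignments = {pos: asn for pos, asn in combo}
            raw.append(Match(scaffold, pose, ci, assignments, tuple(constraints)))
    return dedupe_matches(raw)


def _constraint_candidates(scaffold, pose, cst, rotamer_set, positions,
                           check_clash):
    out = []
    for key in positions:
        res = scaffold.residues[key]
        try:
            n, ca, c = res.backbone_frame()
        except KeyError:
            continue
        if cst.rotamer_policy == "native-only":
            if res.identity not in cst.allowed_identities:
                continue
            atoms = res.side_chain_atoms()
            geom = _candidate_geometry(pose, cst, res.identity, atoms, ca)
            if geom is not None and not _clashes_ligand(atoms, pose, check_clash):
                out.append((key, _make_assignment(res.identity, None, atoms,
                                                  cst.name, geom)))
            continue
        for ident in sorted(cst.allowed_identities):
            spec = chemistry.SIDE_CHAINS[ident]
            if not spec.polar_terminal:
                continue
            for chis in rotamer_set[ident]:
                atoms = chemistry.build_side_chain(ident, n, ca, c, chis)
                geom = _candidate_geometry(pose, cst, ident, atoms, ca)
                if geom is None:
                    continue
                if _clashes_ligand(atoms, pose, check_clash):
                    continue
                out.append((key, _make_assignment(ident, chis, atoms,
                                                  cst.name, geom)))
    return out


def _make_assignment(identity, chis, atoms, cst_name, geom) -> Assignment:
    return Assignment(
        identity=identity,
        chis=tuple(chis) if chis is not None else None,
        atoms=tuple((n, tuple(map(float, xyz))) for n, xyz in sorted(atoms.items())),
        constraint=cst_name,
        geometry=tuple(sorted((k, float(v)) for k, v in geom.items()
                              if isinstance(v, (int, float)))),
    )


def _combo_clashes(combo) -> bool:
    for (_, a), (_, b) in itertools.combinations(combo, 2):
        if _pair_clash(a.atom_dict(), b.atom_dict()):
            return True
    return False


def dedupe_matches(matches: list[Match]) -> list[Match]:
    """One representative per sequence signature, sorted by signature.

    The representative is the match with the lexicographically smallest
    (conformer index, sorted position tuple); idempotent and order-insensitive.
    """
    best: dict[str, Match] = {}
    for m in matches:
        sig = m.signature
        keyfn = (m.conformer_index, tuple(sorted(m.assignments)))
        cur = best.get(sig)
        if cur is None or keyfn < (cur.conformer_index, tuple(sorted(cur.assignments))):
            best[sig] = m
    out = [best[s] for s in sorted(best)]
    for i, m in enumerate(out):
        if not m.match_id:
            m.match_id = f"m{i:04d}"
    return out


def constraint_from_native(scaffold: Scaffold, position: Position,
                           pose: LigandPose, ligand_group: str,
                           tol_distance: float = 0.3, tol_angle: float = 20.0,
                           name: str = "native") -> GeometricConstraint:
    """Build a constraint from the scaffold's native anchor-residue geometry.

    Measures the wild-type residue's tip geometry against the ligand group and
    returns a native-only constraint whose ranges are the measured values plus/
    minus the given tolerances.
    """
    res = scaffold.residues[position]
    tip = _residue_tip(res.identity, res.side_chain_atoms(), res.atoms["CA"])
    if tip is None:
        raise ConfigurationError(
            f"residue {position} has no polar side-chain tip to measure")
    best = None
    for aname, lig_xyz, base_xyz in _ligand_polar_sites(pose, ligand_group):
        d = float(np.linalg.norm(np.asarray(lig_xyz) - tip[0]))
        if best is None or d < best[0]:
            best = (d, lig_xyz, base_xyz)
    d, lig_xyz, base_xyz = best
    ang_l = angle_deg(base_xyz, lig_xyz, tip[0])
    ang_r = angle_deg(tip[1], tip[0], lig_xyz)
    return GeometricConstraint(
        name=name,
        ligand_group=ligand_group,
        allowed_identities=frozenset({res.identity}),
        distance=(d - tol_distance, d + tol_distance),
        angle_at_ligand=(max(0.0, ang_l - tol_angle), min(180.0, ang_l + tol_angle)),
        angle_at_residue=(max(0.0, ang_r - tol_angle), min(180.0, ang_r + tol_angle)),
        rotamer_policy="native-only",
    )
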