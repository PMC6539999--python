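"""Synthetic fixtures with planted ground truth for every pipeline stage.

The fixtures are geometric toys, not chemically real molecules: the ligand is
a photocaged-tyrosine-shaped template (backbone + phenyl core + caging arm
ending in a nitro group), residues are the reduced side-chain stubs from
:mod:`focusforge.chemistry`, and scaffolds are built backwards from the answer
key - H-bond satisfying placements are constructed by inverse kinematics from
the desired geometry, decoy residues are placed at controlled distances, and
the generator verifies by exhaustive sweep that exactly the planted placements
satisfy the constraints.  Every fixture is reproducible from (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .errors import PlacementError
from .geometry import angle_deg, place_atom, rotate_about_axis
from .library import (CurationRules, DEFAULT_SIMILARITY_GROUPS, LibrarySpec,
                      ProfilePosition, SequenceProfile)
from .ligand import (Conformer, LigandTemplate, build_ligand_template,
                     set_chis, template_conformer)
from .matcher import GeometricConstraint, evaluate_constraint, standard_hbond_constraint
from .scaffold import LigandPose, Residue, Scaffold, anchor_superpose


# --- toy ligand --------------------------------------------------------------


@dataclass
class LigandRecipe:
    include_caging_arm: bool = True
    ring_bond: float = 1.39
    chi1_ref: float = -60.0
    chi3_ref: float = 75.0
    chi4_ref: float = 180.0
    chi5_ref: float = 120.0


def make_toy_ligand(recipe: LigandRecipe | None = None) -> LigandTemplate:
    """Photocaged-tyrosine-shaped template: backbone, phenyl core, nitro arm.

    Without the caging arm only chi1-2 are defined.  Polar groups: "nitro"
    (the two nitro oxygens), "m_hydroxy" (ring hydroxyl), "carboxylate"
    (backbone O/OXT).
    """
    r = recipe or LigandRecipe()
    xyz: dict[str, np.ndarray] = {}
    xyz["N"] = np.array([0.0, 0.0, 0.0])
    xyz["CA"] = np.array([1.46, 0.0, 0.0])
    xyz["C"] = place_atom([0.0, 0.0, 1.0], xyz["N"], xyz["CA"], 1.52, 111.0, 25.0)
    xyz["O"] = place_atom(xyz["N"], xyz["CA"], xyz["C"], 1.23, 120.0, 0.0)
    xyz["OXT"] = place_atom(xyz["N"], xyz["CA"], xyz["C"], 1.23, 120.0, 180.0)
    xyz["CB"] = place_atom(xyz["C"], xyz["N"], xyz["CA"], chemistry.CB_BOND,
                           chemistry.CB_ANGLE, chemistry.CB_DIHEDRAL)
    xyz["CG"] = place_atom(xyz["N"], xyz["CA"], xyz["CB"], 1.51, 113.0, r.chi1_ref)
    # regular hexagon attached at CG, extending along the CB->CG direction
    u = xyz["CG"] - xyz["CB"]
    u /= np.linalg.norm(u)
    w = xyz["CB"] - xyz["CA"]
    v = np.cross(np.cross(u, w), u)
    v /= np.linalg.norm(v)
    center = xyz["CG"] + r.ring_bond * u
    ring = {"CG": 0.0, "CD1": 60.0, "CE1": 120.0, "CZ": 180.0,
            "CE2": 240.0, "CD2": 300.0}
    for name, theta in ring.items():
        t = np.radians(theta)
        xyz[name] = center + r.ring_bond * (-np.cos(t) * u + np.sin(t) * v)
    xyz["OM"] = xyz["CE1"] + 1.36 * (xyz["CE1"] - center) / r.ring_bond

    atoms = ["N", "CA", "C", "O", "OXT", "CB", "CG", "CD1", "CD2",
             "CE1", "CE2", "CZ", "OM"]
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"), ("CA", "CB"),
             ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
             ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CE1", "OM")]
    ddefs = {"chi1": ("N", "CA", "CB", "CG"),
             "chi2": ("CA", "CB", "CG", "CD1")}
    polar = {"m_hydroxy": ("OM",), "carboxylate": ("O", "OXT")}

    if r.include_caging_arm:
        xyz["OZ"] = xyz["CZ"] + 1.36 * u
        xyz["C7"] = place_atom(xyz["CE1"], xyz["CZ"], xyz["OZ"], 1.43, 117.0,
                               r.chi3_ref)
        xyz["C8"] = place_atom(xyz["CZ"], xyz["OZ"], xyz["C7"], 1.51, 111.0,
                               r.chi4_ref)
        xyz["N9"] = place_atom(xyz["OZ"], xyz["C7"], xyz["C8"], 1.47, 114.0,
                               r.chi5_ref)
        xyz["O10"] = place_atom(xyz["C7"], xyz["C8"], xyz["N9"], 1.22, 119.0, 0.0)
        xyz["O11"] = place_atom(xyz["C7"], xyz["C8"], xyz["N9"], 1.22, 119.0, 180.0)
        atoms += ["OZ", "C7", "C8", "N9", "O10", "O11"]
        bonds += [("CZ", "OZ"), ("OZ", "C7"), ("C7", "C8"), ("C8", "N9"),
                  ("N9", "O10"), ("N9", "O11")]
        ddefs.update({"chi3": ("CE1", "CZ", "OZ", "C7"),
                      "chi4": ("CZ", "OZ", "C7", "C8"),
                      "chi5": ("OZ", "C7", "C8", "N9")})
        polar["nitro"] = ("O10", "O11")

    table = [{"name": n, "element": _elem(n), "x": xyz[n][0], "y": xyz[n][1],
              "z": xyz[n][2]} for n in atoms]
    core = ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    return build_ligand_template(table, bonds, ddefs, core, polar)


def _elem(name: str) -> str:
    return chemistry.element_of(name)


def default_grid_spec(values=(-120.0, -60.0, 0.0, 60.0, 120.0, 180.0),
                      jitter: float = 15.0) -> dict:
    return {"chi": {"values": list(values), "jitter": jitter}}


def default_sampling(template: LigandTemplate, jitter: float = 15.0):
    """(fixed chi1-2 at template values, jittered grids over chi3-5)."""
    ref = template_conformer(template).chi_values
    fixed = {k: ref[k] for k in ("chi1", "chi2") if k in ref}
    sampled = {k: {"values": [-120.0, -60.0, 0.0, 60.0, 120.0, 180.0],
                   "jitter": jitter}
               for k in ref if k not in fixed}
    return fixed, sampled


# --- toy scaffold with planted matches ---------------------------------------


@dataclass
class PlantedMatch:
    position: int
    identity: str
    chis: tuple[float, ...]
    ligand_group: str = "nitro"
    constraint: str = "cst_nitro"


@dataclass
class FixtureRecipe:
    """Pocket geometry + planted ground truth for a toy scaffold."""

    seed: int = 0
    ligand: LigandRecipe = field(default_factory=LigandRecipe)
    planted: tuple[PlantedMatch, ...] = (
        PlantedMatch(10, "S", (-60.0,)),
        PlantedMatch(12, "N", (60.0, 180.0)),
        PlantedMatch(14, "Q", (-60.0, 60.0, 180.0)),
    )
    native_anchor: tuple[int, str] | None = (73, "Q")  # carboxylate contact
    n_first_shell: int = 2
    n_second_shell: int = 2
    bands: tuple[float, float] = (5.0, 8.0)
    decoy_identities: tuple[str, ...] = ("A", "V", "L", "F", "M")
    hbond_distance: float = 2.9
    angle_at_ligand: float = 170.0
    angle_at_residue: float = 165.0
    max_retries: int = 60


def fixture_constraints(recipe: FixtureRecipe, scaffold: Scaffold | None = None,
                        pose: LigandPose | None = None):
    """Constraints matching the recipe's planted groups.

    Identities per constraint are chosen with pairwise-distinct stub chain
    lengths so a placement planted for one identity cannot be satisfied by
    another.  If the recipe plants a native carboxylate contact and a scaffold
    is given, a native-only constraint measured from that geometry is added.
    """
    groups = sorted({p.ligand_group for p in recipe.planted})
    csts = [standard_hbond_constraint(f"cst_{g}", g, {"S", "N", "Q"})
            for g in groups]
    if recipe.native_anchor and scaffold is not None and pose is not None:
        from .matcher import constraint_from_native

        pos = ("A", recipe.native_anchor[0])
        csts.insert(0, constraint_from_native(scaffold, pos, pose,
                                              "carboxylate", name="cst_native"))
    return csts


def make_toy_scaffold(recipe: FixtureRecipe | None = None, seed: int | None = None):
    """Build a toy pocket PDB-ready scaffold plus a ground-truth manifest.

    The scaffold contains the substrate anchor (the ligand's rigid core), one
    H-bond-satisfying residue per planted match, an optional native
    carboxylate-contacting residue (fixed, for the native-only constraint),
    and decoy residues in the requested distance bands.  The generator sweeps
    all (position x identity x rotamer) combinations of the planted
    constraints to verify that exactly the planted placements satisfy them,
    retrying decoy placement on accidental hits.
    """
    recipe = recipe or FixtureRecipe()
    if seed is None:
        seed = recipe.seed
    template = make_toy_ligand(recipe.ligand)
    conf = template_conformer(template)
    constraints = [c for c in fixture_constraints(recipe)
                   if c.rotamer_policy == "full"]
    expected = {(("A", p.position), p.identity) for p in recipe.planted}

    scaffold = None
    for outer in range(recipe.max_retries):
        rng = np.random.default_rng([seed, outer])
        residues: dict = {}
        anchor = Residue("A", 500, "LIG",
                         {n: conf.atom_coord(n).copy()
                          for n in template.core_atoms}, hetero=True)
        residues[anchor.key] = anchor
        for plant in recipe.planted:
            res = _plant_hbond_residue(template, conf, plant, recipe, rng)
            residues[res.key] = res
        fixed = set()
        if recipe.native_anchor:
            pos, ident = recipe.native_anchor
            plant = PlantedMatch(
                pos, ident,
                tuple([-60.0] * chemistry.SIDE_CHAINS[ident].n_chi),
                ligand_group="carboxylate", constraint="cst_native")
            res = _plant_hbond_residue(template, conf, plant, recipe, rng)
            residues[res.key] = res
            fixed.add(res.key)
        base = Scaffold(residues, anchor.key, {}, fixed)
        pose = anchor_superpose(conf, base)
        # planted backbones must not host any off-plan satisfying placement
        if _exhaustive_hits(base, pose, constraints) != expected:
            continue
        # decoys: retry until the sweep still sees only the planted hits
        for attempt in range(recipe.max_retries):
            decoys = _place_decoys(template, conf, recipe, residues,
                                   np.random.default_rng([seed, outer,
                                                          attempt]))
            trial = dict(residues)
            trial.update({r.key: r for r, _ in decoys.values()})
            trial_scaffold = Scaffold(trial, anchor.key, {}, fixed)
            if _exhaustive_hits(trial_scaffold, pose, constraints) == expected:
                scaffold = trial_scaffold
                break
        if scaffold is not None:
            break
    if scaffold is None:
        raise PlacementError("could not build a scaffold with exactly the "
                             "planted satisfiable placements")

    first, second = [], []
    for num, (res, d) in decoys.items():
        (first if d < 6.0 else second).append(("A", num))
    first.extend(("A", p.position) for p in recipe.planted)

    manifest = {
        "seed": seed,
        "anchor": list(anchor.key),
        "fixed_positions": sorted(list(k) for k in fixed),
        "planted_signatures": sorted(f"A:{p.position}:{p.identity}"
                                     for p in recipe.planted),
        "n_planted": len(recipe.planted),
        "first_shell": sorted(first),
        "second_shell": sorted(second),
        "bands": list(recipe.bands),
    }
    return scaffold, manifest


def _plant_hbond_residue(template, conf: Conformer, plant: PlantedMatch,
                         recipe: FixtureRecipe, rng) -> Residue:
    """Inverse-kinematics placement of a residue whose tip H-bonds the ligand."""
    spec = chemistry.SIDE_CHAINS[plant.identity]
    if len(plant.chis) != spec.n_chi:
        raise PlacementError(
            f"{plant.identity} needs {spec.n_chi} chis, got {len(plant.chis)}")
    group = template.polar_groups[plant.ligand_group]
    p_name = group[0]
    lig_p = conf.atom_coord(p_name)
    lig_b = conf.atom_coord(template.neighbor(p_name))

    for _ in range(recipe.max_retries):
        atoms = _try_plant(template, conf, plant, recipe, lig_p, lig_b, rng)
        if atoms is not None:
            res = Residue("A", plant.position,
                          chemistry.THREE_LETTER[plant.identity], atoms)
            return res
    raise PlacementError(f"cannot plant residue at position {plant.position}")


def _rand_perp(v, rng):
    v = v / np.linalg.norm(v)
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def _try_plant(template, conf, plant, recipe, lig_p, lig_b, rng):
    spec = chemistry.SIDE_CHAINS[plant.identity]
    names = spec.atom_names
    # tip position: distance d from the ligand polar atom, tilted off the
    # base->polar axis so the angle at the ligand is recipe.angle_at_ligand
    w1 = lig_p - lig_b
    w1 /= np.linalg.norm(w1)
    tilt_axis = _rand_perp(w1, rng)
    d_dir = rotate_about_axis((lig_p + w1)[None, :], lig_p, tilt_axis,
                              180.0 - recipe.angle_at_ligand)[0] - lig_p
    tip = lig_p + recipe.hbond_distance * d_dir

    # walk back down the chain with the planted chis as backward dihedrals
    e = lig_p - tip
    e /= np.linalg.norm(e)
    perp = _rand_perp(e, rng)
    ang = np.radians(recipe.angle_at_residue)
    if len(names) >= 2:
        bl = chemistry.bond_length(spec.elements[-2], spec.elements[-1])
    else:
        bl = chemistry.CB_BOND
    prev = tip + bl * (np.cos(ang) * e + np.sin(ang) * perp)

    # path indices: [N, CA, s0, ..., s_{L-1}]; we know the last two entries
    L = len(names)
    path: list = [None] * (L + 2)
    path[L + 1] = tip
    path[L] = prev
    for j in range(L - 1, -1, -1):
        a = path[j + 3] if j + 3 <= L + 1 else lig_p
        if j >= 2:
            bond = chemistry.bond_length(spec.elements[j - 2], spec.elements[j - 1])
            angle = chemistry.SIDE_CHAIN_ANGLE
        elif j == 1:  # CA
            bond = chemistry.CB_BOND
            angle = chemistry.SIDE_CHAIN_ANGLE
        else:  # N
            bond = 1.46
            angle = chemistry.CB_ANGLE
        if j + 1 <= spec.n_chi:
            dihedral = plant.chis[j]  # chi_{j+1} with 0-based storage
        else:
            dihedral = float(rng.uniform(-180.0, 180.0))
        path[j] = place_atom(a, path[j + 2], path[j + 1], bond, angle, dihedral)

    n_xyz, ca_xyz = path[0], path[1]
    # carbonyl C: try both improper signs, keep the one whose forward-built
    # side chain reproduces the planted atoms
    for sign in (1.0, -1.0):
        c_xyz = place_atom(path[2], n_xyz, ca_xyz, 1.52, 111.0,
                           sign * chemistry.CB_DIHEDRAL)
        built = chemistry.build_side_chain(plant.identity, n_xyz, ca_xyz,
                                           c_xyz, plant.chis)
        ok = all(np.linalg.norm(built[names[i]] - path[i + 2]) < 1e-6
                 for i in range(L))
        if ok:
            o_xyz = place_atom(n_xyz, ca_xyz, c_xyz, 1.23, 120.0,
                               float(rng.uniform(-180, 180)))
            atoms = {"N": n_xyz, "CA": ca_xyz, "C": c_xyz, "O": o_xyz}
            atoms.update(built)
            if _clashes_template(atoms, template, conf):
                return None
            return atoms
    return None


def _clashes_template(atoms, template, conf, factor=None) -> bool:
    factor = chemistry.CLASH_FACTOR if factor is None else factor
    heavy = conf.coords[template.heavy_indices()]
    radii = np.array([chemistry.VDW_RADII.get(template.elements[i], 1.7)
                      for i in template.heavy_indices()])
    for name, xyz in atoms.items():
        r = chemistry.vdw_radius(name)
        d = np.linalg.norm(heavy - np.asarray(xyz), axis=1)
        if np.any(d < factor * (radii + r)):
            return True
    return False


def _place_decoys(template, conf, recipe, existing, rng):
    """Decoy residues whose nearest side-chain atom sits at a band distance."""
    heavy = conf.coords[template.heavy_indices()]
    centroid = heavy.mean(axis=0)
    out = {}
    num = 20
    targets = ([recipe.bands[0]] * recipe.n_first_shell
               + [recipe.bands[1]] * recipe.n_second_shell)
    for d_target in targets:
        for _ in range(recipe.max_retries):
            ident = str(rng.choice(list(recipe.decoy_identities)))
            local = _local_residue(ident, rng)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            res_atoms = _march_to_distance(local, heavy, centroid, u, d_target)
            if res_atoms is None:
                continue
            if _clashes_template(res_atoms, template, conf):
                continue
            if _clashes_existing(res_atoms, existing, out):
                continue
            out[num] = (Residue("A", num, chemistry.THREE_LETTER[ident],
                                res_atoms), d_target)
            num += 2
            break
        else:
            raise PlacementError(f"cannot place decoy at {d_target} A")
    return out


def _local_residue(ident, rng):
    n = np.array([0.0, 1.46, 0.0])
    ca = np.zeros(3)
    c = place_atom([0.0, 0.0, 1.0], n, ca, 1.52, 111.0,
                   float(rng.uniform(-180, 180)))
    spec = chemistry.SIDE_CHAINS[ident]
    chis = tuple(float(rng.choice(chemistry.SP3_CHI_GRID))
                 for _ in range(spec.n_chi))
    atoms = {"N": n, "CA": ca, "C": c}
    atoms["O"] = place_atom(n, ca, c, 1.23, 120.0, 0.0)
    atoms.update(chemistry.build_side_chain(ident, n, ca, c, chis))
    rot = _random_rotation(rng)
    return {k: rot @ v for k, v in atoms.items()}


def _random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31 - 1))).as_matrix()


def _march_to_distance(local, lig_heavy, centroid, u, d_target):
    sc_names = [k for k in local if k not in ("N", "CA", "C", "O")]
    probe = sc_names or ["CA"]

    def min_dist(t):
        pts = np.array([local[k] for k in probe]) + centroid + t * u
        return np.min(np.linalg.norm(pts[:, None, :] - lig_heavy[None, :, :],
                                     axis=2))

    lo, hi = 0.0, 60.0
    if min_dist(lo) > d_target or min_dist(hi) < d_target:
        return None
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < d_target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return {k: v + centroid + t * u for k, v in local.items()}


def _clashes_existing(atoms, existing, decoys) -> bool:
    others = [r for r in existing.values() if not r.hetero]
    others += [r for r, _ in decoys.values()]
    for other in others:
        for na, xa in atoms.items():
            for nb, xb in other.atoms.items():
                r0 = chemistry.vdw_radius(na) + chemistry.vdw_radius(nb)
                if np.linalg.norm(xa - xb) < chemistry.CLASH_FACTOR * r0:
                    return True
    return False


def _exhaustive_hits(scaffold, pose, constraints):
    """Sweep every (position, identity, rotamer); return satisfying (pos, ident).

    Deliberately a flat sweep with direct geometry evaluation, separate from
    the matcher's candidate/combination machinery.
    """
    rotamers = chemistry.default_rotamers()
    hits = set()
    for cst in constraints:
        sites = []
        tmpl = pose.conformer.template
        for name in tmpl.polar_groups[cst.ligand_group]:
            if tmpl.atoms[tmpl.index_of(name)].element in ("N", "O", "S"):
                sites.append((pose.atom_coord(name),
                              pose.atom_coord(tmpl.neighbor(name))))
        for key in scaffold.protein_positions():
            if key in scaffold.fixed_positions:
                continue
            res = scaffold.residues[key]
            try:
                n, ca, c = res.backbone_frame()
            except KeyError:
                continue
            for ident in sorted(cst.allowed_identities):
                spec = chemistry.SIDE_CHAINS[ident]
                if not spec.polar_terminal:
                    continue
                for chis in rotamers[ident]:
                    atoms = chemistry.build_side_chain(ident, n, ca, c, chis)
                    tip = atoms[spec.atom_names[-1]]
                    base = (atoms[spec.atom_names[-2]] if len(spec.atom_names) > 1
                            else ca)
                    for lig_xyz, base_xyz in sites:
                        ok, _ = evaluate_constraint((lig_xyz, base_xyz),
                                                    (tip, base), cst)
                        if ok:
                            hits.add((key, ident))
    return hits


# --- toy profiles ------------------------------------------------------------


@dataclass
class ProfileRecipe:
    """Inverse-constructed sequence profiles for curation tests.

    ``target_sets`` maps position -> (wild type, allowed identities after
    curation); ``target_sizes`` instead plants raw per-position set sizes to
    hit a target diversity.  With neither, a minimal one-position profile is
    produced.
    """

    target_sets: dict | None = None
    target_sizes: tuple[int, ...] | None = None
    n_models: int = 49
    min_frequency: float = 0.05
    noise: bool = True
    distal_removals: dict = field(default_factory=dict)  # pos -> (wt, removed)
    wt_only_positions: dict = field(default_factory=dict)  # pos -> wt
    similarity_groups: tuple = DEFAULT_SIMILARITY_GROUPS
    seed: int = 0

    def rules(self) -> CurationRules:
        reinstate = set()
        if self.target_sets:
            for pos, (wt, allowed) in self.target_sets.items():
                if _needs_reinstatement(wt, allowed, self.similarity_groups):
                    reinstate.add(pos)
        return CurationRules(
            min_frequency=self.min_frequency,
            similarity_groups=tuple(self.similarity_groups),
            distal_conservative_removals={
                pos: (removed,) for pos, (_, removed) in
                self.distal_removals.items()},
            wt_reinstatement_positions=frozenset(reinstate),
        )


_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _needs_reinstatement(wt, allowed, groups) -> bool:
    if wt not in allowed:
        return False
    for g in groups:
        if wt in g and any(i in g and i != wt for i in allowed):
            return True
    return False


def make_toy_profile(recipe: ProfileRecipe | None = None) -> SequenceProfile:
    recipe = recipe or ProfileRecipe()
    n = recipe.n_models
    positions: list[ProfilePosition] = []
    if recipe.target_sizes is not None:
        for i, size in enumerate(recipe.target_sizes, start=1):
            idents = _ALPHABET[:size]
            counts = _spread_counts(list(idents), n, min_count=1)
            positions.append(ProfilePosition(i, idents[0], counts))
        return SequenceProfile(positions)
    if recipe.target_sets is None:
        return SequenceProfile([ProfilePosition(1, "A", {"A": n})])

    min_count = max(1, int(np.ceil(recipe.min_frequency * n)))
    for pos in sorted(recipe.target_sets):
        wt, allowed = recipe.target_sets[pos]
        raw = set(allowed)
        if _needs_reinstatement(wt, allowed, recipe.similarity_groups):
            raw.discard(wt)
        for g in recipe.similarity_groups:
            if len(g & raw) > 1:
                raise PlacementError(
                    f"position {pos}: target set {allowed} unreachable "
                    f"(two members of group {sorted(g)} survive collapse)")
        counts = _spread_counts(sorted(raw), n, min_count=min_count)
        if recipe.noise:
            noise_count = max(1, min_count - 1)
            if noise_count / n < recipe.min_frequency:
                cand = [c for c in _ALPHABET if c not in raw and c != wt]
                biggest = max(counts, key=lambda k: (counts[k], k))
                if counts[biggest] - noise_count >= min_count:
                    counts[biggest] -= noise_count
                    counts[cand[pos % len(cand)]] = noise_count
        positions.append(ProfilePosition(pos, wt, counts))
    for pos, (wt, removed) in sorted(recipe.distal_removals.items()):
        counts = {wt: n - min_count, removed: min_count}
        positions.append(ProfilePosition(pos, wt, counts))
    for pos, wt in sorted(recipe.wt_only_positions.items()):
        noise_count = max(1, min_count - 1)
        ident = next(c for c in _ALPHABET if c != wt)
        positions.append(ProfilePosition(pos, wt, {wt: n - noise_count,
                                                   ident: noise_count}))
    positions.sort(key=lambda p: p.position)
    return SequenceProfile(positions)


def _spread_counts(idents, n, min_count=1):
    k = len(idents)
    if k * min_count > n:
        raise PlacementError(f"cannot give {k} identities >= {min_count}/{n}")
    base, rem = divmod(n, k)
    counts = {ident: base + (1 if i < rem else 0)
              for i, ident in enumerate(idents)}
    if min(counts.values()) < min_count:
        raise PlacementError("counts fall below the frequency threshold")
    return counts


def curated_library_recipe() -> ProfileRecipe:
    """Recipe whose curation reproduces the reference focused-library table.

    Plants a 26-position raw profile: the 17 positions of the reference table
    (constructed backwards through the curation rules) plus 9 positions that
    curation reduces to wild type only - one of them via the distal
    conservative rule (an L->I example), the rest via the frequency rule.
    """
    from .data import onby_library

    target_sets = {pos: (wt, allowed)
                   for pos, wt, allowed, _ in onby_library.LIBRARY_TABLE}
    return ProfileRecipe(
        target_sets=target_sets,
        distal_removals={66: ("L", "I")},
        wt_only_positions={63: "D", 68: "G", 106: "E", 110: "K", 155: "Q",
                           161: "T", 163: "P", 165: "S"},
    )


def raw_profile_recipe() -> ProfileRecipe:
    """Raw 26-position profile with the pre-curation diversity scale (8.4e17).

    Set sizes: sixteen positions with 10 observed identities, plus sizes
    4, 3 and 7, plus seven single-identity positions:
    10^16 * 4 * 3 * 7 = 8.4e17 exactly.
    """
    sizes = (10,) * 16 + (4, 3, 7) + (1,) * 7
    return ProfileRecipe(target_sizes=sizes, n_models=49)
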