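"""Noncanonical amino-acid ligand templates and dihedral-diversified conformers.

A :class:`LigandTemplate` is a user-declared atom table (no chemical
perception) with a bond graph, named chi dihedrals, a rigid core (peptide
backbone plus central phenyl ring) and named polar groups.  Conformers are
produced by rigid rotation about the chi axes only, so bond lengths and angles
are invariant across an ensemble.  Sampling diversifies the distal chi angles
(chi3-5 for a photocaged tyrosine) on a jittered grid while chi1-2 stay pinned
to the values observed for the native substrate in the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DefinitionError, SamplingExhaustedError, TopologyError
from .geometry import dihedral_deg, rotate_about_axis, wrap_angle

#: two chi vectors closer than this (per component, deg) count as duplicates
CHI_DISTINCT_TOL = 1.0

#: intramolecular heavy-atom contact threshold (Angstrom), 1-2/1-3 pairs excluded
INTRA_CLASH_DIST = 2.4


@dataclass(frozen=True)
class LigandAtom:
    name: str
    element: str
    coord: np.ndarray


@dataclass
class LigandTemplate:
    """Validated ncAA template: atoms, bonds, chi definitions, core, polar groups."""

    atoms: list[LigandAtom]
    bonds: list[tuple[str, str]]
    dihedral_defs: dict[str, tuple[str, str, str, str]]
    core_atoms: frozenset[str]
    polar_groups: dict[str, tuple[str, ...]]
    graph: nx.Graph = field(repr=False, default=None)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def index_of(self, name: str) -> int:
        return self._index[name]

    def __post_init__(self):
        self._index = {a.name: i for i, a in enumerate(self.atoms)}

    def mobile_atoms(self, chi_name: str) -> frozenset[str]:
        """Atom names displaced by rotating ``chi_name`` (distal to its b-c axis)."""
        a, b, c, d = self.dihedral_defs[chi_name]
        g = self.graph.copy()
        g.remove_edge(b, c)
        comp = nx.node_connected_component(g, c)
        return frozenset(comp - {c})

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.element != "H"], int)

    def neighbor(self, name: str, exclude=()) -> str:
        """A bonded heavy-atom neighbor, used as the base of a polar group atom."""
        for nb in sorted(self.graph.neighbors(name)):
            if nb not in exclude and self.atoms[self._index[nb]].element != "H":
                return nb
        raise DefinitionError(f"atom {name} has no heavy neighbor")


def build_ligand_template(atom_table, bonds, dihedral_defs, core_atoms,
                          polar_groups=None) -> LigandTemplate:
    """Validate and assemble a ligand template from tabular atom records.

    ``atom_table`` is an iterable of mappings with keys name/element/x/y/z (a
    pandas DataFrame's ``to_dict("records")`` works).  Dihedral definitions must
    name four distinct atoms bonded in sequence; the bond graph must be
    connected.
    """
    records = list(atom_table)
    if len(records) < 4:
        raise DefinitionError("atom table must contain at least 4 atoms")
    atoms = []
    seen = set()
    for rec in records:
        name = str(rec["name"])
        if name in seen:
            raise DefinitionError(f"duplicate atom name {name!r}")
        seen.add(name)
        atoms.append(
            LigandAtom(name, str(rec["element"]),
                       np.array([rec["x"], rec["y"], rec["z"]], float))
        )
    names = seen
    bond_list = []
    for a, b in bonds:
        if a not in names or b not in names:
            raise DefinitionError(f"bond ({a}, {b}) references unknown atom")
        bond_list.append((a, b))
    g = nx.Graph(bond_list)
    g.add_nodes_from(names)
    if not nx.is_connected(g):
        raise TopologyError("bond graph is disconnected")
    ddefs = {}
    for chi, quad in dihedral_defs.items():
        quad = tuple(quad)
        if len(quad) != 4 or len(set(quad)) != 4:
            raise DefinitionError(f"{chi}: dihedral needs 4 distinct atoms")
        for nm in quad:
            if nm not in names:
                raise DefinitionError(f"{chi}: unknown atom {nm!r}")
        for u, v in zip(quad, quad[1:]):
            if not g.has_edge(u, v):
                raise TopologyError(f"{chi}: atoms {u}-{v} are not bonded")
        ddefs[chi] = quad
    core = frozenset(core_atoms)
    if not core <= names:
        raise DefinitionError("core_atoms contains unknown atom names")
    pgroups = {}
    for gname, members in (polar_groups or {}).items():
        members = tuple(members)
        for nm in members:
            if nm not in names:
                raise DefinitionError(f"polar group {gname}: unknown atom {nm!r}")
        pgroups[gname] = members
    return LigandTemplate(atoms, bond_list, ddefs, core, pgroups, graph=g)


@dataclass
class Conformer:
    """A rigid-dihedral variant of the template; chi values in [-180, 180)."""

    template: LigandTemplate
    coords: np.ndarray
    chi_values: dict[str, float]

    def measure_chis(self) -> dict[str, float]:
        out = {}
        for chi, (a, b, c, d) in self.template.dihedral_defs.items():
            idx = [self.template.index_of(n) for n in (a, b, c, d)]
            out[chi] = dihedral_deg(*(self.coords[i] for i in idx))
        return out

    def atom_coord(self, name: str) -> np.ndarray:
        return self.coords[self.template.index_of(name)]


@dataclass
class ConformerEnsemble:
    members: list[Conformer]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def template_conformer(template: LigandTemplate) -> Conformer:
    conf = Conformer(template, template.coords.copy(), {})
    conf.chi_values = conf.measure_chis()
    return conf


def set_chi(conformer: Conformer, chi_name: str, target_deg: float) -> Conformer:
    """Return a new conformer with one chi rotated rigidly to ``target_deg``."""
    tmpl = conformer.template
    a, b, c, d = tmpl.dihedral_defs[chi_name]
    idx = [tmpl.index_of(n) for n in (a, b, c, d)]
    current = dihedral_deg(*(conformer.coords[i] for i in idx))
    delta = wrap_angle(target_deg - current)
    mobile = tmpl.mobile_atoms(chi_name)
    mob_idx = [tmpl.index_of(n) for n in sorted(mobile)]
    coords = conformer.coords.copy()
    origin = coords[tmpl.index_of(b)]
    axis = coords[tmpl.index_of(c)] - origin
    # rotating the distal side by +delta about the b->c axis raises the
    # measured dihedral by +delta under the IUPAC sign convention
    coords[mob_idx] = rotate_about_axis(coords[mob_idx], origin, axis, delta)
    chis = dict(conformer.chi_values)
    chis[chi_name] = wrap_angle(target_deg)
    return Conformer(tmpl, coords, chis)


def set_chis(conformer: Conformer, targets: dict[str, float]) -> Conformer:
    out = conformer
    for chi in sorted(targets):
        out = set_chi(out, chi, targets[chi])
    return out


def _clash_mask(tmpl: LigandTemplate) -> np.ndarray:
    """Boolean (n_heavy, n_heavy) mask of pairs subject to the clash check.

    Pairs at bond-graph distance <= 2 (1-2 and 1-3) are excluded; cached on
    the template.
    """
    cached = getattr(tmpl, "_clash_mask_cache", None)
    if cached is not None:
        return cached
    heavy = tmpl.heavy_indices()
    names = [tmpl.atoms[i].name for i in heavy]
    dists = dict(nx.all_pairs_shortest_path_length(tmpl.graph, cutoff=2))
    n = len(names)
    mask = np.zeros((n, n), bool)
    for i in range(n):
        near_i = dists.get(names[i], {})
        for j in range(i + 1, n):
            if names[j] not in near_i:
                mask[i, j] = True
    tmpl._clash_mask_cache = mask
    return mask


def _clash_free(conf: Conformer) -> bool:
    tmpl = conf.template
    coords = conf.coords[tmpl.heavy_indices()]
    mask = _clash_mask(tmpl)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    return not np.any(d2[mask] < INTRA_CLASH_DIST**2)


def _chi_key(chis: dict[str, float], names) -> tuple[float, ...]:
    return tuple(chis[n] for n in names)


def _is_duplicate(vec, accepted) -> bool:
    for other in accepted:
        if all(abs(wrap_angle(a - b)) <= CHI_DISTINCT_TOL for a, b in zip(vec, other)):
            return True
    return False


def sample_conformers(template: LigandTemplate, fixed_chi: dict[str, float],
                      sampled_chi: dict[str, dict], n: int, seed: int) -> ConformerEnsemble:
    """Sample ``n`` distinct clash-free conformers on a jittered chi grid.

    ``fixed_chi`` pins chi1/chi2 to the substrate-anchor values; ``sampled_chi``
    maps each diversified chi to a grid spec ``{"values": [...], "jitter": j}``.
    Duplicates (all chi within 1 deg) and intramolecular heavy-atom contacts
    below 2.4 A (1-2/1-3 pairs excluded) are rejected and resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for chi, spec in sampled_chi.items():
        if not spec.get("values"):
            raise ValueError(f"{chi}: empty grid")
    rng = np.random.default_rng(seed)
    base = set_chis(template_conformer(template), fixed_chi)
    sampled_names = sorted(sampled_chi)
    members: list[Conformer] = []
    accepted_keys: list[tuple[float, ...]] = []
    pure_grid = all(not sampled_chi[c].get("jitter") for c in sampled_names)
    if pure_grid:
        n_grid = 1
        for c in sampled_names:
            n_grid *= len({wrap_angle(v) for v in sampled_chi[c]["values"]})
        if n > n_grid:
            raise SamplingExhaustedError(
                n, _count_achievable(base, sampled_chi, sampled_names))
        max_attempts = max(2000, 50 * n_grid)
    else:
        max_attempts = max(2000, 200 * n)
    attempts = 0
    while len(members) < n and attempts < max_attempts:
        attempts += 1
        targets = {}
        for chi in sampled_names:
            spec = sampled_chi[chi]
            val = float(rng.choice(np.asarray(spec["values"], float)))
            jitter = float(spec.get("jitter", 0.0))
            if jitter:
                val += float(rng.uniform(-jitter, jitter))
            targets[chi] = wrap_angle(val)
        key = tuple(targets[c] for c in sampled_names)
        if _is_duplicate(key, accepted_keys):
            continue
        conf = set_chis(base, targets)
        if not _clash_free(conf):
            continue
        conf.chi_values = conf.measure_chis()
        members.append(conf)
        accepted_keys.append(key)
    if len(members) < n:
        achievable = _count_achievable(base, sampled_chi, sampled_names)
        raise SamplingExhaustedError(n, max(achievable, len(members)))
    prov = {"seed": seed, "n": n, "fixed_chi": dict(fixed_chi),
            "sampled_chi": {k: dict(v) for k, v in sampled_chi.items()}}
    return ConformerEnsemble(members, prov)


def _count_achievable(base: Conformer, sampled_chi, sampled_names) -> int:
    """Exhaustively count distinct clash-free grid points (jitter ignored)."""
    import itertools

    grids = [sorted({wrap_angle(v) for v in sampled_chi[c]["values"]})
             for c in sampled_names]
    count = 0
    seen: list[tuple[float, ...]] = []
    for combo in itertools.product(*grids):
        if _is_duplicate(combo, seen):
            continue
        conf = set_chis(base, dict(zip(sampled_names, combo)))
        if _clash_free(conf):
            seen.append(combo)
            count += 1
    return count


def flip_chi2(ensemble: ConformerEnsemble, chi_name: str = "chi2") -> ConformerEnsemble:
    """Double the ensemble by adding a 180-deg-rotated chi2 twin of every member.

    Originals are preserved in order, followed by the flipped copies in the same
    order.  This lets a substituent (e.g. the m-hydroxy group) sit on either
    side of the caging arm.
    """
    flipped = []
    for conf in ensemble.members:
        target = wrap_angle(conf.chi_values[chi_name] + 180.0)
        twin = set_chi(conf, chi_name, target)
        twin.chi_values = twin.measure_chis()
        flipped.append(twin)
    prov = dict(ensemble.provenance)
    prov["chi2_flipped"] = True
    return ConformerEnsemble(list(ensemble.members) + flipped, prov)
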