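"""Active-site redesign by simulated-annealing rotamer/identity packing.

The score is a deliberately simple three-term function (this package does not
attempt to reproduce any production force field): a soft Lennard-Jones-like
steric well over heavy-atom pairs, a geometric hydrogen-bond well worth -1 at
ideal geometry tapering to 0 at the range edges, and harmonic penalties for
geometry outside declared constraint ranges.  Packing state is one
(identity, rotamer) choice per designable position; moves are annealed on a
geometric temperature schedule and finished with a zero-temperature quench,
returning the best state visited.  Identical inputs and seed give identical
results.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .errors import ConfigurationError, ScoringError, SequenceError
from .geometry import angle_deg
from .matcher import GeometricConstraint, Match, _ligand_polar_sites, _residue_tip
from .scaffold import LigandPose, Position, Scaffold, anchor_superpose


@dataclass(frozen=True)
class ScoreWeights:
    steric: float = 1.0
    hbond: float = 1.0
    constraint: float = 1.0
    reference: dict = field(default_factory=dict)  # per-identity offset, flat default

    def __post_init__(self):
        if min(self.steric, self.hbond, self.constraint) < 0:
            raise ValueError("weights must be >= 0")

    def ref(self, identity: str) -> float:
        return float(self.reference.get(identity, 0.0))


@dataclass
class DesignParams:
    sweeps: int = 200
    t_start: float = 5.0
    t_end: float = 0.1
    radius: float = 9.0
    alphabet: tuple[str, ...] | None = None  # None = all 20 identities
    restrictions: dict | None = None  # position -> allowed identities
    rotamer_set: dict | None = None
    quench_passes: int = 8


@dataclass
class DesignModel:
    """A redesigned sequence with its ligand pose and component scores."""

    scaffold: Scaffold
    pose: LigandPose | None
    sequence: dict[Position, str]
    rotamers: dict[Position, tuple[float, ...] | None]
    side_chains: dict[Position, dict[str, np.ndarray]]
    designable: list[Position]
    match_positions: list[Position]
    constraints: tuple[tuple[GeometricConstraint, Position | None], ...]
    provenance: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    match_sequence: dict = field(default_factory=dict)  # match-assigned identities
    preorg_rms: float | None = None
    model_id: str = ""

    def identity_at(self, pos: Position) -> str:
        if pos in self.sequence:
            return self.sequence[pos]
        if pos in self.match_sequence:
            return self.match_sequence[pos]
        return self.scaffold.residues[pos].identity


def designable_positions(scaffold: Scaffold, pose: LigandPose, radius: float = 9.0,
                         fixed=(), exclude=()) -> list[Position]:
    """Positions with any side-chain heavy atom within ``radius`` of the ligand.

    Fixed (catalytic) positions and explicitly excluded (match-assigned)
    positions are removed.  Glycine uses CA as proxy.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    fixed = set(fixed) | set(exclude)
    lig = pose.coords(heavy_only=True)
    out = []
    for key in scaffold.protein_positions():
        if key in fixed:
            continue
        res = scaffold.residues[key]
        sc = res.side_chain_atoms()
        pts = np.array(list(sc.values())) if sc else res.atoms.get("CA")
        if pts is None:
            continue
        pts = np.atleast_2d(pts)
        if np.min(np.linalg.norm(pts[:, None, :] - lig[None, :, :], axis=2)) < radius:
            out.append(key)
    return sorted(out)


# --- scoring -----------------------------------------------------------------

_BACKBONE_HEAVY = ("N", "CA", "C", "O", "OXT")


def _residue_rows(res, names):
    return [(res.key, nm, res.atoms[nm], chemistry.vdw_radius(nm))
            for nm in sorted(names) if nm in res.atoms
            and chemistry.element_of(nm) != "H"]


def _env_rows_and_tips(scaffold: Scaffold, active: set[Position]):
    """Static environment: full inactive residues + backbones of active ones."""
    rows, tips = [], []
    for key in scaffold.protein_positions():
        res = scaffold.residues[key]
        if key in active:
            rows.extend(_residue_rows(res, _BACKBONE_HEAVY))
            continue
        rows.extend(_residue_rows(res, res.atoms.keys()))
        tip = _residue_tip(res.identity, res.side_chain_atoms(),
                           res.atoms.get("CA", np.zeros(3)))
        if tip is not None:
            spec = chemistry.SIDE_CHAINS[res.identity]
            tips.append((key, tip[0], tip[1], spec.donor, spec.acceptor))
    return rows, tips


def _steric_vs_rows(atoms: dict[str, np.ndarray], rows, own_key=None) -> float:
    if not atoms or not rows:
        return 0.0
    keep = [r for r in rows if r[0] != own_key]
    if not keep:
        return 0.0
    xyz = np.array([r[2] for r in keep], float)
    rad = np.array([r[3] for r in keep], float)
    total = 0.0
    for name, pos in atoms.items():
        d = np.linalg.norm(xyz - np.asarray(pos, float), axis=1)
        r0 = rad + chemistry.vdw_radius(name)
        for di, ri in zip(d, r0):
            rep, att = chemistry.soft_lj_pair(float(di), float(ri))
            total += rep + att
    return total


def _steric_pair(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> float:
    total = 0.0
    for na, xa in a.items():
        ra = chemistry.vdw_radius(na)
        for nb, xb in b.items():
            r = float(np.linalg.norm(np.asarray(xa) - np.asarray(xb)))
            rep, att = chemistry.soft_lj_pair(r, ra + chemistry.vdw_radius(nb))
            total += rep + att
    return total


def _steric_vs_ligand(atoms: dict[str, np.ndarray], pose: LigandPose) -> float:
    if pose is None or not atoms:
        return 0.0
    tmpl = pose.conformer.template
    heavy = pose.coords(heavy_only=True)
    radii = np.array([chemistry.VDW_RADII.get(tmpl.elements[i], 1.7)
                      for i in tmpl.heavy_indices()])
    total = 0.0
    for name, xyz in atoms.items():
        d = np.linalg.norm(heavy - np.asarray(xyz), axis=1)
        r0 = radii + chemistry.vdw_radius(name)
        for di, ri in zip(d, r0):
            rep, att = chemistry.soft_lj_pair(float(di), float(ri))
            total += rep + att
    return total


def _tip_of(identity: str, atoms: dict[str, np.ndarray], res):
    ca = res.atoms.get("CA", np.zeros(3))
    tip = _residue_tip(identity, atoms, ca)
    if tip is None:
        return None
    spec = chemistry.SIDE_CHAINS[identity]
    return (res.key, tip[0], tip[1], spec.donor, spec.acceptor)


def _hbond_tip_pair(tip_a, tip_b) -> float:
    _, pa, ba, da, aa = tip_a
    _, pb, bb, db, ab = tip_b
    if not ((da and ab) or (aa and db)):
        return 0.0
    d = float(np.linalg.norm(np.asarray(pa) - np.asarray(pb)))
    if d > chemistry.HBOND_D_MAX + 0.5:
        return 0.0
    ang_a = angle_deg(ba, pa, pb)
    ang_b = angle_deg(bb, pb, pa)
    return chemistry.hbond_well(d, ang_a, ang_b)


def _hbond_vs_ligand(tip, lig_sites) -> float:
    # ligand polar atoms act as both donors and acceptors in this reduced model
    if tip is None:
        return 0.0
    total = 0.0
    for _, lig_xyz, base_xyz in lig_sites:
        d = float(np.linalg.norm(np.asarray(lig_xyz) - tip[1]))
        if d > chemistry.HBOND_D_MAX + 0.5:
            continue
        ang_l = angle_deg(base_xyz, lig_xyz, tip[1])
        ang_r = angle_deg(tip[2], tip[1], lig_xyz)
        total += chemistry.hbond_well(d, ang_l, ang_r)
    return total


def _all_ligand_sites(pose: LigandPose):
    if pose is None:
        return []
    sites = []
    for group in pose.conformer.template.polar_groups:
        sites.extend(_ligand_polar_sites(pose, group))
    # one atom may belong to several groups; deduplicate by name
    seen, out = set(), []
    for s in sites:
        if s[0] not in seen:
            seen.add(s[0])
            out.append(s)
    return out


def constraint_penalty(pose: LigandPose, constraint: GeometricConstraint,
                       tip) -> float:
    """Harmonic penalty (spring constant 1 per unit violation) outside ranges.

    Evaluated against every polar atom of the ligand group; the best
    (lowest-penalty) group atom counts.
    """
    if pose is None or tip is None:
        return 0.0
    best = None
    for _, lig_xyz, base_xyz in _ligand_polar_sites(pose, constraint.ligand_group):
        d = float(np.linalg.norm(np.asarray(lig_xyz) - tip[1]))
        pen = _violation(d, constraint.distance) ** 2
        if constraint.angle_at_ligand is not None:
            pen += _violation(angle_deg(base_xyz, lig_xyz, tip[1]),
                              constraint.angle_at_ligand) ** 2
        if constraint.angle_at_residue is not None:
            pen += _violation(angle_deg(tip[2], tip[1], lig_xyz),
                              constraint.angle_at_residue) ** 2
        if best is None or pen < best:
            best = pen
    return best or 0.0


def _violation(value: float, rng) -> float:
    if value < rng[0]:
        return rng[0] - value
    if value > rng[1]:
        return value - rng[1]
    return 0.0


def score_pose(model: DesignModel, weights: ScoreWeights | None = None) -> dict:
    """Component scores for a complete design model.

    Returns ``{"interface", "internal", "constraint", "total"}`` with
    total = interface + internal + constraint exactly.  Interface collects
    ligand/protein terms, internal collects protein/protein terms among the
    repacked side chains and the static environment plus per-identity
    reference offsets; environment self-energy is a constant and excluded.
    """
    weights = weights or ScoreWeights()
    active = set(model.designable) | set(model.match_positions)
    env_rows, env_tips = _env_rows_and_tips(model.scaffold, active)
    lig_sites = _all_ligand_sites(model.pose)

    tips = {}
    for pos in sorted(active):
        res = model.scaffold.residues[pos]
        ident = model.identity_at(pos)
        atoms = model.side_chains.get(pos, {})
        spec = chemistry.SIDE_CHAINS[ident]
        if spec.elements and spec.atom_names[-1] not in atoms:
            raise ScoringError(f"residue {pos} is missing side-chain atoms")
        tips[pos] = _tip_of(ident, atoms, res)

    ist = inb = nst = nhb = 0.0
    for pos in sorted(active):
        atoms = model.side_chains.get(pos, {})
        ist += _steric_vs_ligand(atoms, model.pose)
        inb += _hbond_vs_ligand(tips[pos], lig_sites)
        nst += _steric_vs_rows(atoms, env_rows, own_key=pos)
        for tip in env_tips:
            if tips[pos] is not None:
                nhb += _hbond_tip_pair(tips[pos], tip)
    for pa, pb in itertools.combinations(sorted(active), 2):
        nst += _steric_pair(model.side_chains.get(pa, {}),
                            model.side_chains.get(pb, {}))
        if tips[pa] is not None and tips[pb] is not None:
            nhb += _hbond_tip_pair(tips[pa], tips[pb])
    # ligand vs static environment belongs to the interface as well
    if model.pose is not None:
        tmpl = model.pose.conformer.template
        lig_heavy = model.pose.coords(heavy_only=True)
        lig_radii = np.array([chemistry.VDW_RADII.get(tmpl.elements[i], 1.7)
                              for i in tmpl.heavy_indices()])
        for _key, _nm, xyz, radius in env_rows:
            d = np.linalg.norm(lig_heavy - np.asarray(xyz), axis=1)
            for di, ri in zip(d, lig_radii + radius):
                rep, att = chemistry.soft_lj_pair(float(di), float(ri))
                ist += rep + att
        for tip in env_tips:
            inb += _hbond_vs_ligand(tip, lig_sites)

    ref = sum(weights.ref(model.sequence[p]) for p in model.designable)
    cpen = 0.0
    for cst, pos in model.constraints:
        tip = tips.get(pos)
        if tip is None and pos is not None and pos not in active:
            res = model.scaffold.residues[pos]
            tip = _tip_of(res.identity, res.side_chain_atoms(), res)
        cpen += constraint_penalty(model.pose, cst, tip)

    interface = weights.steric * ist + weights.hbond * inb
    internal = weights.steric * nst + weights.hbond * nhb + ref
    constraint = weights.constraint * cpen
    return {
        "interface": interface,
        "internal": internal,
        "constraint": constraint,
        "total": interface + internal + constraint,
    }


# --- annealing ---------------------------------------------------------------


@dataclass
class _Option:
    identity: str
    chis: tuple[float, ...]
    atoms: dict[str, np.ndarray]
    tip: tuple | None


class _PackingTables:
    """Precomputed single-body and pairwise energies over discrete options."""

    def __init__(self, scaffold, pose, variable, frozen_side_chains,
                 weights, params):
        self.variable = list(variable)
        rotamers = params.rotamer_set or chemistry.default_rotamers()
        restrictions = params.restrictions or {}
        alphabet = params.alphabet or tuple(sorted(chemistry.SIDE_CHAINS))
        active = set(variable) | set(frozen_side_chains)
        env_rows, env_tips = _env_rows_and_tips(scaffold, active)
        # frozen (match-assigned) side chains join the static environment,
        # keeping their assigned identity's polar tip
        for key, (ident, atoms) in frozen_side_chains.items():
            env_rows.extend((key, nm, xyz, chemistry.vdw_radius(nm))
                            for nm, xyz in sorted(atoms.items()))
            tip = _tip_of(ident, atoms, scaffold.residues[key])
            if tip is not None:
                env_tips = env_tips + [tip]
        lig_sites = _all_ligand_sites(pose)

        self.options: dict[Position, list[_Option]] = {}
        self.e_single: dict[Position, np.ndarray] = {}
        for pos in self.variable:
            res = scaffold.residues[pos]
            n, ca, c = res.backbone_frame()
            idents = tuple(restrictions.get(pos, alphabet))
            opts = []
            for ident in idents:
                if ident not in rotamers:
                    raise ConfigurationError(
                        f"identity {ident} has no rotamers in rotamer_set")
                rots = rotamers[ident] or [()]
                for chis in rots:
                    atoms = chemistry.build_side_chain(ident, n, ca, c, chis)
                    opts.append(_Option(ident, tuple(chis), atoms,
                                        _tip_of(ident, atoms, res)))
            if not opts:
                raise ConfigurationError(f"no options at position {pos}")
            self.options[pos] = opts
            e = np.zeros(len(opts))
            for k, opt in enumerate(opts):
                val = weights.steric * (
                    _steric_vs_rows(opt.atoms, env_rows, own_key=pos)
                    + _steric_vs_ligand(opt.atoms, pose))
                hb = _hbond_vs_ligand(opt.tip, lig_sites)
                for tip in env_tips:
                    if opt.tip is not None:
                        hb += _hbond_tip_pair(opt.tip, tip)
                val += weights.hbond * hb + weights.ref(opt.identity)
                e[k] = val
            self.e_single[pos] = e

        self.e_pair: dict[tuple[Position, Position], np.ndarray] = {}
        for pa, pb in itertools.combinations(self.variable, 2):
            oa, ob = self.options[pa], self.options[pb]
            mat = np.zeros((len(oa), len(ob)))
            for i, x in enumerate(oa):
                for j, y in enumerate(ob):
                    v = weights.steric * _steric_pair(x.atoms, y.atoms)
                    if x.tip is not None and y.tip is not None:
                        v += weights.hbond * _hbond_tip_pair(x.tip, y.tip)
                    mat[i, j] = v
            self.e_pair[(pa, pb)] = mat

    def pair(self, pa, pb, ka, kb) -> float:
        if (pa, pb) in self.e_pair:
            return float(self.e_pair[(pa, pb)][ka, kb])
        return float(self.e_pair[(pb, pa)][kb, ka])

    def energy(self, state: dict) -> float:
        e = sum(float(self.e_single[p][state[p]]) for p in self.variable)
        for pa, pb in itertools.combinations(self.variable, 2):
            e += self.pair(pa, pb, state[pa], state[pb])
        return e

    def delta(self, state, pos, new_k) -> float:
        old_k = state[pos]
        d = float(self.e_single[pos][new_k] - self.e_single[pos][old_k])
        for q in self.variable:
            if q == pos:
                continue
            d += self.pair(pos, q, new_k, state[q]) - self.pair(pos, q, old_k, state[q])
        return d


def _anneal(tables: _PackingTables, init_state: dict, params: DesignParams,
            rng: np.random.Generator):
    state = dict(init_state)
    best = dict(state)
    e = tables.energy(state)
    best_e = e
    n = len(tables.variable)
    if params.sweeps > 0 and n > 0:
        temps = np.geomspace(params.t_start, params.t_end, params.sweeps)
        for t in temps:
            for pos in tables.variable:
                k = int(rng.integers(len(tables.options[pos])))
                if k == state[pos]:
                    continue
                d = tables.delta(state, pos, k)
                if d <= 0 or rng.random() < np.exp(-d / t):
                    state[pos] = k
                    e += d
                    if e < best_e - 1e-12:
                        best_e, best = e, dict(state)
        # zero-temperature quench: greedy passes to convergence
        for _ in range(params.quench_passes):
            changed = False
            for pos in tables.variable:
                local = np.array([tables.delta(state, pos, k)
                                  for k in range(len(tables.options[pos]))])
                k = int(np.argmin(local))
                if local[k] < -1e-12:
                    e += float(local[k])
                    state[pos] = k
                    changed = True
            if not changed:
                break
        if e < best_e - 1e-12:
            best_e, best = e, dict(state)
    return best, best_e


def mix_seed(base_seed: int, match_id: str, repeat: int) -> int:
    """SHA-256 mixing of (base seed, match id, repeat), truncated to 64 bits."""
    h = hashlib.sha256(f"{base_seed}:{match_id}:{repeat}".encode()).digest()
    return int.from_bytes(h[:8], "big")


def redesign(match: Match, weights: ScoreWeights | None = None,
             params: DesignParams | None = None, seed: int = 0,
             extra_constraints=(), repeat: int = 0) -> DesignModel:
    """Redesign the designable shell around one match.

    Match-assigned and fixed positions are immutable; all other shell positions
    sample (identity, rotamer) moves under the three-term score.  Ends with a
    zero-temperature quench and returns the best-scoring state visited.  With
    ``sweeps=0`` the initial (wild-type identity) state is returned, scored.
    """
    weights = weights or ScoreWeights()
    params = params or DesignParams()
    scaffold, pose = match.scaffold, match.pose
    designable = designable_positions(
        scaffold, pose, params.radius,
        fixed=scaffold.fixed_positions, exclude=match.assignments.keys())
    if not designable:
        raise ConfigurationError("designable set is empty")
    frozen = {pos: (asn.identity, asn.atom_dict())
              for pos, asn in match.assignments.items()}
    tables = _PackingTables(scaffold, pose, designable,
                            {k: v for k, v in frozen.items()}, weights, params)

    init = {}
    for pos in designable:
        wt = scaffold.residues[pos].identity
        opts = tables.options[pos]
        idx = [k for k, o in enumerate(opts) if o.identity == wt]
        pool = idx or list(range(len(opts)))
        init[pos] = min(pool, key=lambda k: tables.e_single[pos][k])

    rng = np.random.default_rng(seed)
    state, _ = _anneal(tables, init, params, rng)

    side_chains = {pos: dict(tables.options[pos][state[pos]].atoms)
                   for pos in designable}
    for pos, (_ident, atoms) in frozen.items():
        side_chains[pos] = dict(atoms)
    sequence = {pos: tables.options[pos][state[pos]].identity for pos in designable}
    rotamers = {pos: tables.options[pos][state[pos]].chis for pos in designable}
    for pos, asn in match.assignments.items():
        rotamers[pos] = asn.chis

    csts = [(cst, _constraint_position(match, cst)) for cst in match.constraints]
    csts.extend(extra_constraints)
    model = DesignModel(
        scaffold=scaffold, pose=pose, sequence=sequence, rotamers=rotamers,
        side_chains=side_chains, designable=designable,
        match_positions=sorted(match.assignments),
        constraints=tuple(csts),
        provenance={"match_id": match.match_id, "repeat": repeat, "seed": seed},
        match_sequence={p: a.identity for p, a in match.assignments.items()},
        model_id=f"{match.match_id}_r{repeat:02d}",
    )
    model.scores = score_pose(model, weights)
    return model


def _constraint_position(match: Match, cst: GeometricConstraint):
    for pos, asn in match.assignments.items():
        if asn.constraint == cst.name:
            return pos
    return None


def run_design_stage(matches: list[Match], n_repeats: int,
                     weights: ScoreWeights | None = None,
                     params: DesignParams | None = None,
                     base_seed: int = 0, extra_constraints=()) -> list[DesignModel]:
    """Redesign every match ``n_repeats`` times; len(matches) x n_repeats models.

    Repeat r of match m runs with seed SHA-256(base_seed, match id, r)
    truncated to 64 bits, so models carry reproducible provenance.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    models = []
    for match in matches:
        for r in range(n_repeats):
            seed = mix_seed(base_seed, match.match_id, r)
            models.append(redesign(match, weights, params, seed=seed,
                                   extra_constraints=extra_constraints, repeat=r))
    return models


def model_variant_complex(scaffold: Scaffold, variant: dict, conformer,
                          weights: ScoreWeights | None = None,
                          params: DesignParams | None = None,
                          seed: int = 0):
    """Thread a variant sequence, repack, anchor the ligand, and report H bonds.

    ``variant`` maps positions (ints or (chain, number) tuples) to identities.
    Identities are fixed; side-chain rotamers of the variant plus shell
    positions are repacked with the same annealer.  Returns
    ``(DesignModel, hbond_report)`` where the report lists every donor/acceptor
    pair passing H-bond geometry, residue-ligand and residue-residue alike.
    """
    weights = weights or ScoreWeights()
    params = params or DesignParams()
    norm: dict[Position, str] = {}
    for pos, ident in variant.items():
        key = pos if isinstance(pos, tuple) else ("A", int(pos))
        if key not in scaffold.residues:
            raise SequenceError(f"variant references unknown position {key}")
        norm[key] = ident
    pose = anchor_superpose(conformer, scaffold)
    shell = designable_positions(scaffold, pose, params.radius,
                                 fixed=scaffold.fixed_positions)
    repack = sorted(set(shell) | set(norm))
    restrictions = {pos: (norm.get(pos, scaffold.residues[pos].identity),)
                    for pos in repack}
    local = DesignParams(**{**params.__dict__, "restrictions": restrictions})
    tables = _PackingTables(scaffold, pose, repack, {}, weights, local)
    init = {pos: int(np.argmin(tables.e_single[pos])) for pos in repack}
    rng = np.random.default_rng(seed)
    state, _ = _anneal(tables, init, local, rng)
    side_chains = {pos: dict(tables.options[pos][state[pos]].atoms)
                   for pos in repack}
    sequence = {pos: tables.options[pos][state[pos]].identity for pos in repack}
    model = DesignModel(
        scaffold=scaffold, pose=pose, sequence=sequence,
        rotamers={pos: tables.options[pos][state[pos]].chis for pos in repack},
        side_chains=side_chains, designable=repack, match_positions=[],
        constraints=(), provenance={"variant": True, "seed": seed},
        model_id="variant",
    )
    model.scores = score_pose(model, weights)
    return model, hbond_report(model)


def hbond_report(model: DesignModel) -> list[dict]:
    """All donor/acceptor pairs passing standard H-bond geometry.

    Covers repacked-residue tips against the ligand's polar atoms and against
    each other plus static-environment tips.  Each entry records both partners,
    the heavy-atom distance, and the angles at each partner.
    """
    active = set(model.designable) | set(model.match_positions)
    env_rows, env_tips = _env_rows_and_tips(model.scaffold, active)
    tips = []
    for pos in sorted(active):
        res = model.scaffold.residues[pos]
        tip = _tip_of(model.identity_at(pos), model.side_chains.get(pos, {}), res)
        if tip is not None:
            tips.append(tip)
    all_tips = tips + env_tips
    report = []
    lig_sites = _all_ligand_sites(model.pose)
    for tip in all_tips:
        for name, lig_xyz, base_xyz in lig_sites:
            d = float(np.linalg.norm(np.asarray(lig_xyz) - tip[1]))
            ang_l = angle_deg(base_xyz, lig_xyz, tip[1])
            ang_r = angle_deg(tip[2], tip[1], lig_xyz)
            if chemistry.hbond_well(d, ang_l, ang_r) < 0:
                report.append({
                    "partner_a": f"{tip[0][0]}:{tip[0][1]}",
                    "partner_b": f"ligand:{name}",
                    "distance": round(d, 3),
                    "angle_at_a": round(ang_r, 2),
                    "angle_at_b": round(ang_l, 2),
                })
    for ta, tb in itertools.combinations(all_tips, 2):
        val = _hbond_tip_pair(ta, tb)
        if val < 0:
            d = float(np.linalg.norm(np.asarray(ta[1]) - np.asarray(tb[1])))
            report.append({
                "partner_a": f"{ta[0][0]}:{ta[0][1]}",
                "partner_b": f"{tb[0][0]}:{tb[0][1]}",
                "distance": round(d, 3),
                "angle_at_a": round(angle_deg(ta[2], ta[1], tb[1]), 2),
                "angle_at_b": round(angle_deg(tb[2], tb[1], ta[1]), 2),
            })
    return report
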