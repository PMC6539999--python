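"""Design triage: preorganization check, score filters, orientation clustering.

Survivors must bind (ligand-interface score), keep the catalytic geometry
(constraint score), and be preorganized: after repacking the active-site side
chains without the ligand, the side chains should barely move.  Survivors are
then clustered greedily by ligand-orientation RMSD (poses already share the
scaffold frame, so no re-superposition) and the library is built from the
largest cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .designer import (DesignModel, DesignParams, ScoreWeights, _anneal,
                       _PackingTables)
from .errors import ComparabilityError
from .geometry import coord_rmsd


@dataclass(frozen=True)
class FilterThresholds:
    """Upper bounds on the three triage criteria; +inf passes everything."""

    max_ligand_score: float = 0.0
    max_constraint_score: float = 1.0
    max_preorg_rms: float = 1.0

    def __post_init__(self):
        for v in (self.max_ligand_score, self.max_constraint_score,
                  self.max_preorg_rms):
            if math.isnan(v):
                raise ValueError("thresholds must be finite or +inf")


@dataclass
class Cluster:
    leader_id: str
    member_ids: list[str]
    leader_pose: np.ndarray
    members: list[DesignModel]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def preorganization_rms(model: DesignModel, weights: ScoreWeights | None = None,
                        params: DesignParams | None = None, seed: int = 0) -> float:
    """Heavy-atom side-chain RMS after repacking without the ligand.

    Identities stay fixed; rotamers of the active-site positions (designable
    plus match-assigned) repack with the same annealer, starting from and
    including the designed rotamers among the options.  The RMS is taken over
    side-chain heavy atoms of those positions, designed vs. ligand-free state.
    """
    weights = weights or ScoreWeights()
    params = params or DesignParams()
    positions = sorted(set(model.designable) | set(model.match_positions))
    if not positions:
        return 0.0
    restrictions = {pos: (model.identity_at(pos),) for pos in positions}
    local = DesignParams(**{**params.__dict__, "restrictions": restrictions})
    tables = _PackingTables(model.scaffold, None, positions, {}, weights, local)
    # start at the designed rotamer, injecting it if off-grid (native matches)
    init = {}
    for pos in positions:
        opts = tables.options[pos]
        designed = model.side_chains.get(pos, {})
        best_k, best_d = 0, float("inf")
        for k, opt in enumerate(opts):
            d = _atoms_rms(opt.atoms, designed)
            if d < best_d:
                best_k, best_d = k, d
        init[pos] = best_k
    rng = np.random.default_rng(seed)
    state, _ = _anneal(tables, init, local, rng)

    before, after = [], []
    for pos in positions:
        designed = model.side_chains.get(pos, {})
        repacked = tables.options[pos][state[pos]].atoms
        for name in sorted(designed):
            if name in repacked:
                before.append(np.asarray(designed[name], float))
                after.append(np.asarray(repacked[name], float))
    if not before:
        return 0.0
    return coord_rmsd(np.array(before), np.array(after))


def _atoms_rms(a: dict, b: dict) -> float:
    common = sorted(set(a) & set(b))
    if not common:
        return float("inf") if (a or b) else 0.0
    pa = np.array([a[n] for n in common], float)
    pb = np.array([b[n] for n in common], float)
    return coord_rmsd(pa, pb)


def annotate_preorganization(models, weights=None, params=None, seed: int = 0):
    """Compute and store ``preorg_rms`` on every model; returns the models."""
    for i, m in enumerate(models):
        m.preorg_rms = preorganization_rms(m, weights, params, seed=seed + i)
    return models


def filter_designs(models, thresholds: FilterThresholds):
    """Keep models passing all three criteria, preserving input order."""
    out = []
    for m in models:
        if m.scores["interface"] > thresholds.max_ligand_score:
            continue
        if m.scores["constraint"] > thresholds.max_constraint_score:
            continue
        rms = m.preorg_rms if m.preorg_rms is not None else 0.0
        if rms > thresholds.max_preorg_rms:
            continue
        out.append(m)
    return out


def _ligand_heavy(model: DesignModel) -> np.ndarray:
    return model.pose.coords(heavy_only=True)


def cluster_by_orientation(models, rmsd_cutoff: float = 2.0) -> list[Cluster]:
    """Greedy leader clustering on ligand heavy-atom RMSD.

    Models are visited best total score first (ascending; ties by model id);
    each model joins the first existing cluster whose leader pose is within the
    cutoff, else founds a new cluster.  Poses share the scaffold frame, so no
    re-superposition is applied.  Clusters partition the input and are returned
    sorted by size descending (ties by leader id).
    """
    if not models:
        return []
    atom_counts = {m.pose.conformer.template.heavy_indices().shape[0] for m in models}
    if len(atom_counts) != 1:
        raise ComparabilityError("models have inconsistent ligand atom sets")
    ordered = sorted(models, key=lambda m: (m.scores.get("total", 0.0), m.model_id))
    clusters: list[Cluster] = []
    for m in ordered:
        xyz = _ligand_heavy(m)
        placed = False
        for cl in clusters:
            if coord_rmsd(xyz, cl.leader_pose) <= rmsd_cutoff:
                cl.member_ids.append(m.model_id)
                cl.members.append(m)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(m.model_id, [m.model_id], xyz, [m]))
    clusters.sort(key=lambda c: (-c.size, c.leader_id))
    return clusters


def select_largest_cluster(clusters) -> list[DesignModel]:
    """Members of the largest cluster (ties broken by smallest leader id)."""
    if not clusters:
        return []
    return list(clusters[0].members)
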