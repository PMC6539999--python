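"""File formats: ligand templates, conformer ensembles, constraints, results.

Template files are YAML with the atom block as an embedded TSV table; conformer
ensembles are multi-model PDB with a chi-provenance TSV sidecar; constraints
and curation rules are YAML; matches, design models and profiles are JSON.
"""

from __future__ import annotations

import io as _io
import json

import numpy as np
import pandas as pd
import yaml

from . import chemistry
from .library import CurationRules, ProfilePosition, SequenceProfile
from .ligand import (Conformer, ConformerEnsemble, LigandTemplate,
                     build_ligand_template)
from .matcher import Assignment, GeometricConstraint, Match
from .scaffold import LigandPose, Scaffold, anchor_superpose

# --- ligand templates --------------------------------------------------------


def template_to_yaml(template: LigandTemplate) -> str:
    atoms_tsv = "name\telement\tx\ty\tz\n" + "\n".join(
        f"{a.name}\t{a.element}\t{a.coord[0]:.6f}\t{a.coord[1]:.6f}\t{a.coord[2]:.6f}"
        for a in template.atoms
    )
    doc = {
        "bonds": [list(b) for b in template.bonds],
        "dihedral_defs": {k: list(v) for k, v in template.dihedral_defs.items()},
        "core_atoms": sorted(template.core_atoms),
        "polar_groups": {k: list(v) for k, v in template.polar_groups.items()},
        "atoms": atoms_tsv,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def template_from_yaml(text: str) -> LigandTemplate:
    doc = yaml.safe_load(text)
    table = pd.read_csv(_io.StringIO(doc["atoms"]), sep="\t")
    return build_ligand_template(
        table.to_dict("records"),
        [tuple(b) for b in doc["bonds"]],
        {k: tuple(v) for k, v in doc["dihedral_defs"].items()},
        doc["core_atoms"],
        {k: tuple(v) for k, v in doc.get("polar_groups", {}).items()},
    )


# --- conformer ensembles -----------------------------------------------------


def ensemble_to_pdb(ensemble: ConformerEnsemble) -> str:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not ensemble.members:
        return "END\n"
    tmpl = ensemble.members[0].template
    n_atoms = len(tmpl.atoms)
    stack = struc.AtomArrayStack(len(ensemble.members), n_atoms)
    for i, atom in enumerate(tmpl.atoms):
        stack.chain_id[i] = "A"
        stack.res_id[i] = 1
        stack.res_name[i] = "LIG"
        stack.atom_name[i] = atom.name
        stack.hetero[i] = True
        stack.element[i] = atom.element
    for m, conf in enumerate(ensemble.members):
        stack.coord[m] = conf.coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = _io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def ensemble_chi_tsv(ensemble: ConformerEnsemble) -> str:
    rows = []
    for i, conf in enumerate(ensemble.members):
        row = {"model": i + 1}
        row.update({k: round(v, 4) for k, v in sorted(conf.chi_values.items())})
        rows.append(row)
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def ensemble_from_pdb(pdb_text: str, template: LigandTemplate) -> ConformerEnsemble:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(_io.StringIO(pdb_text))
    stack = pdb.get_structure()
    name_to_model_idx = {str(stack.atom_name[i]).strip(): i
                         for i in range(stack.array_length())}
    order = [name_to_model_idx[a.name] for a in template.atoms]
    members = []
    for m in range(stack.stack_depth()):
        coords = np.array(stack.coord[m][order], float)
        conf = Conformer(template, coords, {})
        conf.chi_values = conf.measure_chis()
        members.append(conf)
    return ConformerEnsemble(members, {"source": "pdb"})


# --- constraints and rules ---------------------------------------------------


def constraints_from_yaml(text: str, scaffold: Scaffold | None = None,
                          pose: LigandPose | None = None) -> list[GeometricConstraint]:
    """Parse the constraint-file dialect.

    Each block either declares explicit ranges, or ``native_from`` (a residue
    selector) to derive a native-only constraint from the scaffold's observed
    geometry with the given tolerances.
    """
    doc = yaml.safe_load(text)
    out = []
    for block in doc["constraints"]:
        if "native_from" in block:
            from .matcher import constraint_from_native

            if scaffold is None or pose is None:
                raise ValueError("native_from constraints need scaffold and pose")
            sel = block["native_from"]
            tol = block.get("tolerance", {})
            out.append(constraint_from_native(
                scaffold, (str(sel.get("chain", "A")), int(sel["number"])), pose,
                block["ligand_group"],
                tol_distance=float(tol.get("distance", 0.3)),
                tol_angle=float(tol.get("angle", 20.0)),
                name=block.get("name", "native")))
            continue
        out.append(GeometricConstraint(
            name=block.get("name", block["ligand_group"]),
            ligand_group=block["ligand_group"],
            allowed_identities=frozenset(block["identities"]),
            distance=tuple(block.get("distance",
                                     (chemistry.HBOND_D_MIN, chemistry.HBOND_D_MAX))),
            angle_at_ligand=_opt_range(block.get("angle_at_ligand",
                                                 (chemistry.HBOND_ANGLE_MIN, 180.0))),
            angle_at_residue=_opt_range(block.get("angle_at_residue",
                                                  (chemistry.HBOND_ANGLE_MIN, 180.0))),
            torsion=_opt_range(block.get("torsion")),
            rotamer_policy=block.get("rotamer_policy", "full"),
        ))
    return out


def _opt_range(rng):
    return tuple(rng) if rng is not None else None


def rules_from_yaml(text: str) -> CurationRules:
    doc = yaml.safe_load(text)
    return CurationRules(
        min_frequency=float(doc.get("min_frequency", 0.05)),
        similarity_groups=tuple(frozenset(g) for g in
                                doc.get("similarity_groups", ["ST", "VIL"])),
        distal_conservative_removals={
            int(k): tuple(v) for k, v in
            doc.get("distal_conservative_removals", {}).items()},
        wt_reinstatement_positions=frozenset(
            int(p) for p in doc.get("wt_reinstatement_positions", [])),
        target_size=doc.get("target_size"),
    )


# --- matches and models ------------------------------------------------------


def matches_to_json(matches: list[Match]) -> str:
    out = []
    for m in matches:
        out.append({
            "match_id": m.match_id,
            "signature": m.signature,
            "conformer_index": m.conformer_index,
            "chi_values": {k: round(v, 6) for k, v in
                           m.pose.conformer.chi_values.items()},
            "assignments": [
                {"chain": pos[0], "number": pos[1], "identity": a.identity,
                 "chis": list(a.chis) if a.chis is not None else None,
                 "constraint": a.constraint, "geometry": dict(a.geometry)}
                for pos, a in sorted(m.assignments.items())],
        })
    return json.dumps(out, indent=1)


def matches_from_json(text: str, scaffold: Scaffold, template: LigandTemplate,
                      constraints: list[GeometricConstraint]) -> list[Match]:
    """Rebuild Match objects: conformer from chi values, side chains from chis."""
    from .ligand import set_chis, template_conformer
    from .matcher import _make_assignment

    by_name = {c.name: c for c in constraints}
    out = []
    for rec in json.loads(text):
        conf = set_chis(template_conformer(template), rec["chi_values"])
        conf.chi_values = conf.measure_chis()
        pose = anchor_superpose(conf, scaffold)
        assignments = {}
        for a in rec["assignments"]:
            pos = (a["chain"], int(a["number"]))
            res = scaffold.residues[pos]
            if a["chis"] is None:
                atoms = res.side_chain_atoms()
                chis = None
            else:
                chis = tuple(a["chis"])
                n, ca, c = res.backbone_frame()
                atoms = chemistry.build_side_chain(a["identity"], n, ca, c, chis)
            assignments[pos] = Assignment(
                identity=a["identity"], chis=chis,
                atoms=tuple((nm, tuple(map(float, xyz)))
                            for nm, xyz in sorted(atoms.items())),
                constraint=a["constraint"],
                geometry=tuple(sorted(a["geometry"].items())))
        cst_list = tuple(by_name[a["constraint"]] for a in rec["assignments"]
                         if a["constraint"] in by_name)
        out.append(Match(scaffold, pose, rec["conformer_index"], assignments,
                         cst_list, match_id=rec["match_id"]))
    return out


def models_to_json(models) -> str:
    out = []
    for m in models:
        out.append({
            "model_id": m.model_id,
            "provenance": {k: v for k, v in m.provenance.items()
                           if isinstance(v, (str, int, float, bool))},
            "sequence": {f"{p[0]}:{p[1]}": s for p, s in m.sequence.items()},
            "match_sequence": {f"{p[0]}:{p[1]}": s
                               for p, s in m.match_sequence.items()},
            "scores": {k: round(v, 6) for k, v in m.scores.items()},
            "preorg_rms": m.preorg_rms,
            "chi_values": {k: round(v, 6) for k, v in
                           m.pose.conformer.chi_values.items()}
            if m.pose is not None else None,
            "rotamers": {f"{p[0]}:{p[1]}": (list(r) if r is not None else None)
                         for p, r in m.rotamers.items()},
        })
    return json.dumps(out, indent=1)


def profile_to_json(profile: SequenceProfile) -> str:
    return json.dumps({
        "positions": [{"position": p.position, "wild_type": p.wild_type,
                       "counts": p.counts} for p in profile.positions]
    }, indent=1)


def profile_from_json(text: str) -> SequenceProfile:
    doc = json.loads(text)
    return SequenceProfile([
        ProfilePosition(int(p["position"]), p["wild_type"],
                        {k: int(v) for k, v in p["counts"].items()})
        for p in doc["positions"]])
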