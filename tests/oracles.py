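"""Independent reference implementations used as test oracles.

Everything here is written from the declared definitions with its own geometry
code (no imports from the package's geometry module) so that the package can
be checked against a second, structurally different implementation.
"""

import itertools
import math

import numpy as np

# geometry ------------------------------------------------------------------


def o_angle(a, b, c):
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def o_dihedral(p0, p1, p2, p3):
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return ((ang + 180.0) % 360.0) - 180.0


def o_place(a, b, c, bond, angle, dihedral):
    """Independent internal-coordinate placement (rotation-matrix route)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    # start from d0 extending the b->c direction, then bend and twist
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    d = c + bond * bc
    d = _rot(d, c, n, 180.0 - angle)
    d = _rot(d, c, bc, dihedral)
    # _rot about bc by chi: calibrate sign so o_dihedral(a,b,c,d) == dihedral
    if abs(((o_dihedral(a, b, c, d) - dihedral) + 180) % 360 - 180) > 1e-6:
        d = c + bond * bc
        d = _rot(d, c, n, 180.0 - angle)
        d = _rot(d, c, bc, -dihedral)
    return d


def _rot(point, origin, axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    p = np.asarray(point, float) - origin
    # Rodrigues formula
    return (p * math.cos(th) + np.cross(axis, p) * math.sin(th)
            + axis * np.dot(axis, p) * (1 - math.cos(th))) + origin


def o_kabsch_rmsd(mobile, target):
    """Minimum RMSD over rigid motions, via SVD."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    Pc = P - P.mean(0)
    Qc = Q - Q.mean(0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = Pc @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - Qc) ** 2, axis=1))))


# side-chain stubs ----------------------------------------------------------

from focusforge import chemistry  # parameter tables only; builders unused


def o_build_side_chain(identity, n, ca, c, chis):
    """Rebuild a stub side chain with the oracle's own placement routine."""
    spec = chemistry.SIDE_CHAINS[identity]
    if not spec.elements:
        return {}
    names = spec.atom_names
    atoms = {}
    cb = o_place(c, n, ca, chemistry.CB_BOND, chemistry.CB_ANGLE,
                 chemistry.CB_DIHEDRAL)
    atoms[names[0]] = cb
    prev = [np.asarray(n, float), np.asarray(ca, float), cb]
    for i in range(1, len(spec.elements)):
        bl = chemistry.bond_length(spec.elements[i - 1], spec.elements[i])
        pos = o_place(prev[0], prev[1], prev[2], bl, chemistry.SIDE_CHAIN_ANGLE,
                      chis[i - 1])
        atoms[names[i]] = pos
        prev = [prev[1], prev[2], pos]
    return atoms


# brute-force matcher -------------------------------------------------------


def brute_force_signatures(scaffold, pose, constraints, check_clash=True):
    """Exhaustive enumeration of sequence-unique matches for one pose.

    Completely flat loops; geometry measured with the oracle's own angle and
    dihedral code; candidate combination honours distinct positions and the
    pairwise/ligand clash rule.
    """
    rotamers = chemistry.default_rotamers()
    tmpl = pose.conformer.template
    lig_heavy = pose.coords(heavy_only=True)
    lig_radii = [chemistry.VDW_RADII.get(tmpl.elements[i], 1.7)
                 for i in tmpl.heavy_indices()]

    def group_sites(group):
        sites = []
        for name in tmpl.polar_groups[group]:
            if tmpl.atoms[tmpl.index_of(name)].element in ("N", "O", "S"):
                sites.append((pose.atom_coord(name),
                              pose.atom_coord(tmpl.neighbor(name))))
        return sites

    def satisfied(cst, tip, base):
        for lp, lb in group_sites(cst.ligand_group):
            d = float(np.linalg.norm(lp - tip))
            if not (cst.distance[0] <= d <= cst.distance[1]):
                continue
            if cst.angle_at_ligand is not None:
                ang = o_angle(lb, lp, tip)
                if not (cst.angle_at_ligand[0] <= ang <= cst.angle_at_ligand[1]):
                    continue
            if cst.angle_at_residue is not None:
                ang = o_angle(base, tip, lp)
                if not (cst.angle_at_residue[0] <= ang <= cst.angle_at_residue[1]):
                    continue
            if cst.torsion is not None:
                tor = o_dihedral(lb, lp, tip, base)
                if not (cst.torsion[0] <= tor <= cst.torsion[1]):
                    continue
            return True
        return False

    def lig_clash(atoms):
        if not check_clash:
            return False
        for name, xyz in atoms.items():
            r = chemistry.vdw_radius(name)
            for lx, lr in zip(lig_heavy, lig_radii):
                if np.linalg.norm(lx - xyz) < 0.8 * (lr + r):
                    return True
        return False

    cand_lists = []
    for cst in constraints:
        cands = []
        if cst.rotamer_policy == "native-only":
            pool = scaffold.protein_positions()
        else:
            pool = [p for p in scaffold.protein_positions()
                    if p not in scaffold.fixed_positions]
        for key in pool:
            res = scaffold.residues[key]
            if not all(k in res.atoms for k in ("N", "CA", "C")):
                continue
            n, ca, c = res.atoms["N"], res.atoms["CA"], res.atoms["C"]
            if cst.rotamer_policy == "native-only":
                if res.identity not in cst.allowed_identities:
                    continue
                spec = chemistry.SIDE_CHAINS[res.identity]
                if not spec.polar_terminal:
                    continue
                atoms = res.side_chain_atoms()
                if spec.atom_names[-1] not in atoms:
                    continue
                tip = atoms[spec.atom_names[-1]]
                base = (atoms[spec.atom_names[-2]]
                        if len(spec.atom_names) > 1 else ca)
                if satisfied(cst, tip, base) and not lig_clash(atoms):
                    cands.append((key, res.identity, atoms))
                continue
            for ident in sorted(cst.allowed_identities):
                spec = chemistry.SIDE_CHAINS[ident]
                if not spec.polar_terminal:
                    continue
                for chis in rotamers[ident]:
                    atoms = o_build_side_chain(ident, n, ca, c, chis)
                    tip = atoms[spec.atom_names[-1]]
                    base = (atoms[spec.atom_names[-2]]
                            if len(spec.atom_names) > 1 else ca)
                    if satisfied(cst, tip, base) and not lig_clash(atoms):
                        cands.append((key, ident, atoms))
        cand_lists.append(cands)

    def pair_clash(a, b):
        if not check_clash:
            return False
        for na, xa in a.items():
            for nb, xb in b.items():
                r0 = chemistry.vdw_radius(na) + chemistry.vdw_radius(nb)
                if np.linalg.norm(np.asarray(xa) - np.asarray(xb)) < 0.8 * r0:
                    return True
        return False

    sigs = set()
    for combo in itertools.product(*cand_lists):
        keys = [c[0] for c in combo]
        if len(set(keys)) != len(keys):
            continue
        if any(pair_clash(a[2], b[2])
               for a, b in itertools.combinations(combo, 2)):
            continue
        sigs.add(",".join(f"{k[0]}:{k[1]}:{ident}"
                          for k, ident, _ in sorted(zip(keys,
                                                        [c[1] for c in combo],
                                                        [c[2] for c in combo]),
                                                    key=lambda t: t[0])))
    return sigs


# independent design-model scorer ------------------------------------------


def _o_soft_lj(r, r0):
    rep_w, soften = 4.0, 0.8
    att_depth, att_w, att_off = 0.05, 1.0, 0.25
    soft = soften * r0
    if r < soft:
        e_soft = rep_w * ((r0 - soft) / r0) ** 2
        slope = 2.0 * rep_w * (r0 - soft) / r0 ** 2
        rep = e_soft + slope * (soft - r)
    elif r < r0:
        rep = rep_w * ((r0 - r) / r0) ** 2
    else:
        rep = 0.0
    x = (r - (r0 + att_off)) / att_w
    att = -att_depth * (1.0 - x * x) if abs(x) < 1.0 else 0.0
    return rep + att


def _o_hbond_well(d, ang_a, ang_b):
    if not (2.6 <= d <= 3.2):
        return 0.0
    fd = max(0.0, 1.0 - abs(d - 2.9) / 0.3)
    fa = max(0.0, (ang_a - 120.0) / 60.0)
    fb = max(0.0, (ang_b - 120.0) / 60.0)
    return -fd * fa * fb


def _o_tip(identity, atoms, ca):
    spec = chemistry.SIDE_CHAINS[identity]
    names = spec.atom_names
    if not spec.polar_terminal or not names or names[-1] not in atoms:
        return None
    tip = np.asarray(atoms[names[-1]], float)
    base = (np.asarray(atoms[names[-2]], float) if len(names) > 1
            else np.asarray(ca, float))
    return tip, base, spec.donor, spec.acceptor


def _o_lig_sites(pose):
    tmpl = pose.conformer.template
    seen, sites = set(), []
    for group in tmpl.polar_groups:
        for name in tmpl.polar_groups[group]:
            if name in seen:
                continue
            if tmpl.atoms[tmpl.index_of(name)].element not in ("N", "O", "S"):
                continue
            seen.add(name)
            sites.append((pose.atom_coord(name),
                          pose.atom_coord(tmpl.neighbor(name))))
    return sites


def o_score_model(model, weights):
    """Independent re-implementation of the three-term design score."""
    scaffold = model.scaffold
    pose = model.pose
    active = sorted(set(model.designable) | set(model.match_positions))
    backbone = ("N", "CA", "C", "O", "OXT")

    env_rows, env_tips = [], []
    for key in scaffold.protein_positions():
        res = scaffold.residues[key]
        if key in active:
            names = [n for n in backbone if n in res.atoms]
        else:
            names = [n for n in res.atoms if chemistry.element_of(n) != "H"]
            tip = _o_tip(res.identity, res.side_chain_atoms(),
                         res.atoms.get("CA", np.zeros(3)))
            if tip is not None:
                env_tips.append((key, tip))
        for n in sorted(names):
            env_rows.append((key, res.atoms[n], chemistry.vdw_radius(n)))

    lig_xyz, lig_rad = [], []
    if pose is not None:
        tmpl = pose.conformer.template
        coords = pose.coords()
        for i, atom in enumerate(tmpl.atoms):
            if atom.element != "H":
                lig_xyz.append(coords[i])
                lig_rad.append(chemistry.VDW_RADII.get(atom.element, 1.7))
        sites = _o_lig_sites(pose)
    else:
        sites = []

    def steric_vs_lig(atoms):
        tot = 0.0
        for n, x in atoms.items():
            for lx, lr in zip(lig_xyz, lig_rad):
                tot += _o_soft_lj(np.linalg.norm(np.asarray(x) - lx),
                                  lr + chemistry.vdw_radius(n))
        return tot

    def hb_vs_lig(tip):
        if tip is None:
            return 0.0
        tot = 0.0
        for lp, lb in sites:
            d = float(np.linalg.norm(lp - tip[0]))
            tot += _o_hbond_well(d, o_angle(lb, lp, tip[0]),
                                 o_angle(tip[1], tip[0], lp))
        return tot

    def hb_pair(ta, tb):
        if not ((ta[2] and tb[3]) or (ta[3] and tb[2])):
            return 0.0
        d = float(np.linalg.norm(ta[0] - tb[0]))
        return _o_hbond_well(d, o_angle(ta[1], ta[0], tb[0]),
                             o_angle(tb[1], tb[0], ta[0]))

    tips = {}
    for pos in active:
        res = scaffold.residues[pos]
        ident = (model.sequence.get(pos) or model.match_sequence.get(pos)
                 or res.identity)
        tips[pos] = _o_tip(ident, model.side_chains.get(pos, {}),
                           res.atoms.get("CA", np.zeros(3)))

    ist = inb = nst = nhb = 0.0
    for pos in active:
        atoms = model.side_chains.get(pos, {})
        ist += steric_vs_lig(atoms)
        inb += hb_vs_lig(tips[pos])
        for key, x, r in env_rows:
            if key == pos:
                continue
            for n, y in atoms.items():
                nst += _o_soft_lj(np.linalg.norm(np.asarray(y) - x),
                                  r + chemistry.vdw_radius(n))
        if tips[pos] is not None:
            for _, tip in env_tips:
                nhb += hb_pair(tips[pos], tip)
    for i, pa in enumerate(active):
        for pb in active[i + 1:]:
            for na, xa in model.side_chains.get(pa, {}).items():
                for nb, xb in model.side_chains.get(pb, {}).items():
                    nst += _o_soft_lj(
                        np.linalg.norm(np.asarray(xa) - np.asarray(xb)),
                        chemistry.vdw_radius(na) + chemistry.vdw_radius(nb))
            if tips[pa] is not None and tips[pb] is not None:
                nhb += hb_pair(tips[pa], tips[pb])
    if pose is not None:
        for key, x, r in env_rows:
            for lx, lr in zip(lig_xyz, lig_rad):
                ist += _o_soft_lj(np.linalg.norm(x - lx), lr + r)
        for _, tip in env_tips:
            inb += hb_vs_lig(tip)

    ref = sum(float(weights.reference.get(model.sequence[p], 0.0))
              for p in model.designable)
    cpen = 0.0
    for cst, pos in model.constraints:
        tip = tips.get(pos)
        if tip is None and pos is not None and pos not in active:
            res = scaffold.residues[pos]
            tip = _o_tip(res.identity, res.side_chain_atoms(),
                         res.atoms.get("CA", np.zeros(3)))
        if tip is None or pose is None:
            continue
        tmpl = pose.conformer.template
        best = None
        for name in tmpl.polar_groups[cst.ligand_group]:
            if tmpl.atoms[tmpl.index_of(name)].element not in ("N", "O", "S"):
                continue
            lp = pose.atom_coord(name)
            lb = pose.atom_coord(tmpl.neighbor(name))
            d = float(np.linalg.norm(lp - tip[0]))
            pen = _o_viol(d, cst.distance) ** 2
            if cst.angle_at_ligand is not None:
                pen += _o_viol(o_angle(lb, lp, tip[0]),
                               cst.angle_at_ligand) ** 2
            if cst.angle_at_residue is not None:
                pen += _o_viol(o_angle(tip[1], tip[0], lp),
                               cst.angle_at_residue) ** 2
            if best is None or pen < best:
                best = pen
        cpen += best or 0.0

    interface = weights.steric * ist + weights.hbond * inb
    internal = weights.steric * nst + weights.hbond * nhb + ref
    constraint = weights.constraint * cpen
    return {"interface": interface, "internal": internal,
            "constraint": constraint,
            "total": interface + internal + constraint}


def _o_viol(value, rng):
    if value < rng[0]:
        return rng[0] - value
    if value > rng[1]:
        return value - rng[1]
    return 0.0
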