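"""Ideal-geometry peptide structures and pseudo-ensembles.

This module builds poly-peptides from canonical backbone torsions (NeRF
internal-coordinate chain extension), places amide/alpha/side-chain
hydrogens at ideal positions, adds explicit waters hydrogen-bonded to
exposed carbonyl groups, and produces snapshot ensembles by seeded Gaussian
coordinate jitter. Every downstream stage of the inventory pipeline is
exercised against these structures, whose designed interaction content is
known by construction.

Supported sequence alphabet: A, G, S, T (alanine suffices for backbone
interactions; Ser/Thr provide hydroxyl donors for capping-motif fixtures).

The ensemble model is deliberately statistical, not physical: coordinate
jitter reproduces the occupancy fluctuations of interaction counts seen in
snapshot ensembles without any force field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, Residue, Structure, Water, ONE_TO_THREE
from .geometry import distance

# ideal covalent geometry (A, degrees)
B_N_CA = 1.46
B_CA_C = 1.52
B_C_N = 1.33
B_C_O = 1.23
B_N_H = 1.01
B_C_H = 1.09
B_CA_CB = 1.53
B_C_OH = 1.42  # Ser/Thr C-O(gamma)
B_O_H = 0.96
B_WAT_OH = 0.957

A_N_CA_C = 111.0
A_CA_C_N = 116.6
A_C_N_CA = 121.7
A_CA_C_O = 121.0

TEMPLATES = {
    "alpha_helix": (-57.0, -47.0),
    "three10_helix": (-49.0, -26.0),
    "antiparallel_sheet": (-139.0, 135.0),
    "parallel_sheet": (-119.0, 113.0),
    "extended": (-139.0, 135.0),
}


@dataclass
class BuildSpec:
    template: str = "alpha_helix"
    n_res: int = 12
    sequence: str | None = None  # 1-letter; default poly-Ala
    phi_psi: list | None = None  # custom per-residue (phi, psi) degrees
    solvation: str = "none"  # or "exposed_carbonyls"
    waters_per_site: int = 2
    noise_sigma: float = 0.0
    n_snapshots: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.template != "custom" and self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.template == "custom" and not self.phi_psi:
            raise ValueError("custom template requires phi_psi")
        if self.sequence is None:
            self.sequence = "A" * self.n_res
        if len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")


def place_atom(a, b, c, bond: float, ang: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = ang and
    dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang_r = math.radians(ang)
    tor_r = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang_r),
            bond * math.sin(ang_r) * math.cos(tor_r),
            bond * math.sin(ang_r) * math.sin(tor_r),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class _AtomFactory:
    def __init__(self):
        self.serial = 0

    def make(self, name, element, res_name, chain_id, res_seq, xyz):
        self.serial += 1
        return AtomRecord(
            serial=self.serial,
            name=name,
            element=element,
            alt_loc="",
            res_name=res_name,
            chain_id=chain_id,
            res_seq=res_seq,
            i_code="",
            xyz=np.asarray(xyz, dtype=float),
            occupancy=1.0,
        )


def _tetra_pair(ca, n, c):
    """The two tetrahedral substituent directions at CA: first the CB
    direction (L-configuration), then the HA direction (for Gly, the two
    HA)."""
    n1 = _unit(np.asarray(n) - ca)
    n2 = _unit(np.asarray(c) - ca)
    bis = _unit(n1 + n2)
    perp = _unit(np.cross(n1, n2))
    u = -bis
    # angle(sub-CA-N) ~ 110.4 deg
    cos_target = math.cos(math.radians(110.4))
    cos_g = cos_target / float(np.dot(u, n1))
    cos_g = max(-1.0, min(1.0, cos_g))
    sin_g = math.sqrt(1.0 - cos_g**2)
    d1 = u * cos_g + perp * sin_g
    d2 = u * cos_g - perp * sin_g
    return d1, d2


# Rotamer convention for sp3 substituents: the first substituent sits at
# +100 deg from the reference eclipse about the bond axis. The offset is a
# free convention of the builder; it is chosen so that idealized helix
# side-chain hydrogens stay clear of the preceding carbonyl oxygen, keeping
# the designed interaction content of the templates exact (ensemble jitter
# randomizes side-chain contacts anyway).
ROTAMER_OFFSET_DEG = 75.0


def _methyl_hydrogens(cb, ca, ref):
    """Three H directions around a methyl carbon about the CA->CB axis,
    referenced to ``ref``."""
    e1 = _unit(np.asarray(cb) - ca)
    r = np.asarray(ref) - ca
    p1 = _unit(r - np.dot(r, e1) * e1)
    p2 = np.cross(e1, p1)
    out = []
    for k in range(3):
        phi = math.radians(ROTAMER_OFFSET_DEG + 120.0 * k)
        d = e1 * math.cos(math.radians(70.5)) + (
            p1 * math.cos(phi) + p2 * math.sin(phi)
        ) * math.sin(math.radians(70.5))
        out.append(cb + B_C_H * _unit(d))
    return out


def _tetra_around(center, axis_from, ref):
    """Three substituent positions around ``center`` (sp3), bonded away from
    ``axis_from``, staggered relative to ``ref``; returns unit directions."""
    e1 = _unit(np.asarray(center) - axis_from)
    r = np.asarray(ref) - axis_from
    p1 = _unit(r - np.dot(r, e1) * e1)
    p2 = np.cross(e1, p1)
    dirs = []
    for k in range(3):
        phi = math.radians(ROTAMER_OFFSET_DEG + 120.0 * k)
        d = e1 * math.cos(math.radians(70.5)) + (
            p1 * math.cos(phi) + p2 * math.sin(phi)
        ) * math.sin(math.radians(70.5))
        dirs.append(_unit(d))
    return dirs


def build_peptide(spec: BuildSpec, chain_id: str = "A", start_seq: int = 1) -> Structure:
    """Build a single chain from ideal internal coordinates.

    Sheet templates build two peptide chains with canonical inter-strand
    hydrogen-bond registry (see :func:`build_sheet`).
    """
    if spec.template in ("antiparallel_sheet", "parallel_sheet"):
        return build_sheet(spec)
    if spec.template == "custom":
        phi_psi = [tuple(p) for p in spec.phi_psi]
    else:
        phi_psi = [TEMPLATES[spec.template]] * spec.n_res
    s = _build_chain(spec.sequence, phi_psi, chain_id, start_seq)
    if spec.solvation == "exposed_carbonyls":
        s = solvate_carbonyls(s, per_site=spec.waters_per_site, seed=spec.seed)
    return s


def _build_chain(sequence: str, phi_psi: list, chain_id: str, start_seq: int) -> Structure:
    fac = _AtomFactory()
    n_res = len(sequence)
    # backbone trace
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    O = [None] * n_res
    N[0] = np.zeros(3)
    CA[0] = np.array([B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i + 1 < n_res:
            N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi)
            CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, 180.0)
            phi_next = phi_psi[i + 1][0]
            C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi_next)
        # carbonyl O trans to the next amide N (or virtual psi for the C-terminus)
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi - 180.0)

    residues = []
    for i, one in enumerate(sequence):
        res_name = ONE_TO_THREE.get(one.upper())
        if res_name is None:
            raise ValueError(f"unsupported residue {one!r}")
        if res_name not in ("ALA", "GLY", "SER", "THR"):
            raise ValueError(f"builder supports A/G/S/T, got {one!r}")
        seq = start_seq + i
        atoms = []

        def add(name, element, xyz):
            atoms.append(fac.make(name, element, res_name, chain_id, seq, xyz))

        add("N", "N", N[i])
        add("CA", "C", CA[i])
        add("C", "C", C[i])
        add("O", "O", O[i])
        if i > 0:  # amide H in the peptide plane, anti to the carbonyl
            u1 = _unit(C[i - 1] - N[i])
            u2 = _unit(CA[i] - N[i])
            add("H", "H", N[i] - B_N_H * _unit(u1 + u2))
        d_cb, d_ha = _tetra_pair(CA[i], N[i], C[i])
        if res_name == "GLY":
            add("HA2", "H", CA[i] + B_C_H * d_cb)
            add("HA3", "H", CA[i] + B_C_H * d_ha)
        else:
            cb = CA[i] + B_CA_CB * d_cb
            add("HA", "H", CA[i] + B_C_H * d_ha)
            add("CB", "C", cb)
            if res_name == "ALA":
                for j, h in enumerate(_methyl_hydrogens(cb, CA[i], N[i]), 1):
                    add(f"HB{j}", "H", h)
            elif res_name == "SER":
                dirs = _tetra_around(cb, CA[i], N[i])
                og = cb + B_C_OH * dirs[0]
                add("OG", "O", og)
                add("HB2", "H", cb + B_C_H * dirs[1])
                add("HB3", "H", cb + B_C_H * dirs[2])
                hg_dirs = _tetra_around(og, cb, CA[i])
                add("HG", "H", og + B_O_H * hg_dirs[0])
            elif res_name == "THR":
                dirs = _tetra_around(cb, CA[i], N[i])
                og1 = cb + B_C_OH * dirs[0]
                cg2 = cb + B_CA_CB * dirs[1]
                add("OG1", "O", og1)
                add("CG2", "C", cg2)
                add("HB", "H", cb + B_C_H * dirs[2])
                hg_dirs = _tetra_around(og1, cb, CA[i])
                add("HG1", "H", og1 + B_O_H * hg_dirs[0])
                for j, h in enumerate(_methyl_hydrogens(cg2, cb, CA[i]), 1):
                    add(f"HG2{j}"[:4], "H", h)
        residues.append(
            Residue(chain_id=chain_id, res_seq=seq, i_code="", name=res_name, atoms=atoms)
        )
    return Structure(id=f"synthetic", residues=residues, waters=[])


# --------------------------------------------------------------------------
# two-strand sheets

def _rigid(params, coords):
    """Apply rotation (Rodrigues vector) + translation."""
    rvec = params[:3]
    t = params[3:]
    theta = np.linalg.norm(rvec)
    if theta < 1e-12:
        R = np.eye(3)
    else:
        k = rvec / theta
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
    return coords @ R.T + t


def build_sheet(spec: BuildSpec) -> Structure:
    """Two extended strands with canonical inter-strand hydrogen bonds.

    Strand B is rigid-body fitted (least squares) so that the registry's
    N-H...O=C pairs reach ideal hydrogen-bond geometry (d(H...O) ~ 1.95 A,
    collinear N-H...O). Antiparallel registry pairs residue i of strand A
    with residue n-1-i of strand B, with both hydrogen bonds on alternating
    rungs; parallel registry uses the textbook wide pairing.
    """
    from scipy.optimize import least_squares

    n = spec.n_res
    phi, psi = TEMPLATES[spec.template]
    seq = spec.sequence
    sA = _build_chain(seq, [(phi, psi)] * n, "A", 1)
    sB = _build_chain(seq, [(phi, psi)] * n, "B", 1)

    antiparallel = spec.template == "antiparallel_sheet"
    pairs = []  # (donor chain, donor index, acceptor chain, acceptor index)
    if antiparallel:
        # hydrogen-bonded rungs alternate: residue i of A pairs n-1-i of B
        for i in range(0, n, 2):
            j = n - 1 - i
            if i > 0 and j < n - 1:
                pairs.append(("A", i, "B", j))
            if j > 0 and i < n - 1:
                pairs.append(("B", j, "A", i))
        w_rho, rho_target = 0.8, 150.0
    else:
        # parallel: symmetric NH(X,i) -> O(Y,i-1) bonds on every rung; two
        # identical uniformly-twisted strands cannot satisfy them all, so
        # the robust fit distributes the misfit (a known limitation of this
        # template; the antiparallel template is the primary beta fixture)
        for i in range(1, n):
            pairs.append(("A", i, "B", i - 1))
            pairs.append(("B", i, "A", i - 1))
        w_rho, rho_target = 2.0, 120.0

    bxyz = np.array([a.xyz for r in sB.residues for a in r.atoms])
    index_b = {}
    k = 0
    for r in sB.residues:
        for a in r.atoms:
            index_b[(r.res_seq, a.name)] = k
            k += 1

    def atom_a(i, name):
        return sA.residues[i].atom(name).xyz

    def residuals(params):
        moved = _rigid(params, bxyz)
        res = []
        for dch, di, ach, ai in pairs:
            if dch == "A":
                h = atom_a(di, "H")
                nn = atom_a(di, "N")
                o = moved[index_b[(ai + 1, "O")]]
                c = moved[index_b[(ai + 1, "C")]]
            else:
                h = moved[index_b[(di + 1, "H")]]
                nn = moved[index_b[(di + 1, "N")]]
                o = atom_a(ai, "O")
                c = atom_a(ai, "C")
            if h is None:
                continue
            # targeting both H...O and N...O distances enforces a nearly
            # collinear N-H...O geometry without angular terms; the third
            # term steers the H onto the lone-pair side of the carbonyl
            # (H...O=C angle near 150 deg)
            res.append(np.linalg.norm(h - o) - 1.95)
            res.append(0.7 * (np.linalg.norm(nn - o) - 2.96))
            res.append(
                w_rho
                * (
                    float(np.dot(_unit(h - o), _unit(c - o)))
                    - math.cos(math.radians(rho_target))
                )
            )
        return np.array(res)

    # multistart rigid fit: strand axis is ~x; try flips/rotations about it,
    # axial shifts and both lateral sides
    starts = []
    base_rots = [
        (0.0, 0.0, 0.0),
        (math.pi, 0.0, 0.0),
        (0.0, math.pi, 0.0),
        (0.0, 0.0, math.pi),
        (0.5 * math.pi, 0.0, 0.0),
        (1.5 * math.pi, 0.0, 0.0),
    ]
    for rot in base_rots:
        for dx in (-3.0, -1.5, 0.0, 1.5, 3.0):
            for side in (4.8, -4.8):
                starts.append(np.array([*rot, dx, side, 0.0]))
    best = None
    for x in starts:
        sol = least_squares(
            residuals, x, method="trf", loss="soft_l1", f_scale=0.3, max_nfev=300
        )
        if best is None or sol.cost < best.cost:
            best = sol
    moved = _rigid(best.x, bxyz)
    k = 0
    for r in sB.residues:
        for a in r.atoms:
            a.xyz = moved[k]
            k += 1
    residues = sA.residues + sB.residues
    out = Structure(id="synthetic_sheet", residues=residues, waters=[])
    if spec.solvation == "exposed_carbonyls":
        out = solvate_carbonyls(out, per_site=spec.waters_per_site, seed=spec.seed)
    return out


# --------------------------------------------------------------------------
# solvation

def solvate_carbonyls(s: Structure, per_site: int = 2, seed: int = 0) -> Structure:
    """Place waters hydrogen-bonded to each mainchain carbonyl oxygen.

    Waters sit along the sp2 lone-pair directions (+-60 deg from the C=O
    axis in the carbonyl plane; a third, axial direction is used when
    ``per_site`` is 3), with one O-H bond pointing at the carbonyl oxygen at
    d(H...O) = 1.9 A. Sites where a water would clash (< 2.4 A to any other
    heavy atom) are skipped.
    """
    from .structure_io import identify_carbonyls

    if per_site not in (0, 1, 2, 3):
        raise ValueError("per_site must be 0..3")
    out = s.copy()
    if per_site == 0:
        return out
    heavy = [a.xyz for r in out.residues for a in r.atoms if not a.is_hydrogen]
    fac = _AtomFactory()
    fac.serial = 90000
    widx = len(out.waters)
    for site in identify_carbonyls(out, include_sidechain=False):
        c, o, ca = site.C.xyz, site.O.xyz, site.CA.xyz
        e_co = _unit(o - c)
        normal = _unit(np.cross(o - c, ca - c))
        p = np.cross(normal, e_co)
        dirs = []
        for sign in (+1.0, -1.0):
            dirs.append(_unit(e_co * math.cos(math.radians(60.0))
                              + sign * p * math.sin(math.radians(60.0))))
        dirs.append(e_co)
        for u in dirs[:per_site]:
            h1 = o + 1.9 * u
            ow = h1 + B_WAT_OH * u
            ok = True
            for hv in heavy:
                if np.linalg.norm(ow - hv) < 2.4:
                    ok = False
                    break
            for w in out.waters:
                if np.linalg.norm(ow - w.O.xyz) < 2.4:
                    ok = False
                    break
            if not ok:
                continue
            # second water hydrogen at the tetrahedral water angle
            perp = _unit(np.cross(u, normal))
            h2 = ow + B_WAT_OH * (
                -u * math.cos(math.radians(104.5)) + perp * math.sin(math.radians(104.5))
            )
            oat = fac.make("O", "O", "HOH", "W", widx + 1, ow)
            h1a = fac.make("H1", "H", "HOH", "W", widx + 1, h1)
            h2a = fac.make("H2", "H", "HOH", "W", widx + 1, h2)
            out.waters.append(Water(index=widx, O=oat, hydrogens=[h1a, h2a]))
            widx += 1
    return out


# --------------------------------------------------------------------------
# ensembles

def perturb_ensemble(s: Structure, sigma: float, n: int, seed: int = 0) -> list:
    """n snapshot copies with i.i.d. Gaussian coordinate displacement of
    standard deviation ``sigma`` (A) on every atom. sigma = 0 reproduces the
    input exactly."""
    if sigma < 0 or n < 1:
        raise ValueError("sigma >= 0 and n >= 1 required")
    rng = np.random.default_rng(seed)
    adjacency = s.compute_adjacency()
    out = []
    for k in range(n):
        c = s.copy()
        c.snapshot_index = k
        c.freeze_adjacency(adjacency)
        for a in c.all_atoms():
            if sigma > 0:
                a.xyz = a.xyz + rng.normal(0.0, sigma, size=3)
            else:
                rng.normal(0.0, 1.0, size=3)  # keep stream position comparable
        out.append(c)
    return out


# --------------------------------------------------------------------------
# motif fixtures

MOTIF_FIXTURES = ("M1", "M2_bifurcated", "M3_capping", "water_only", "undersatisfied")


def build_motif_fixture(motif: str, n_res: int = 12) -> Structure:
    """Hand-tuned structures guaranteeing a named interaction multiset.

    M1            mid-helix carbonyl with NH_bb + n->pi* + an added CH_X probe
    M2_bifurcated helix N-terminal carbonyl accepting NH_bb from both i+3 and
                  i+4 (bifurcated donor) plus the n->pi*
    M3_capping    helix C-terminal-turn carbonyl with NH_bb + OH_sc (serine)
                  + n->pi*
    water_only    extended solvated peptide: every carbonyl sees only water
    undersatisfied dry helix: the penultimate carbonyl sustains a single NCI
    """
    if motif not in MOTIF_FIXTURES:
        raise ValueError(f"unknown motif fixture {motif!r}")
    if motif == "water_only":
        spec = BuildSpec(template="extended", n_res=max(n_res, 6),
                         solvation="exposed_carbonyls", waters_per_site=2)
        return build_peptide(spec)
    if motif == "undersatisfied":
        return build_peptide(BuildSpec(template="alpha_helix", n_res=max(n_res, 8)))

    s = build_peptide(BuildSpec(template="alpha_helix", n_res=max(n_res, 12)))
    if motif == "M1":
        # CH_X probe: an alanine side-chain methyl aimed at a free lone pair
        # of the mid-helix carbonyl, in its sp2 plane
        t = len(s.residues) // 2
        r = s.residues[t]
        c, o, ca = r.atom("C").xyz, r.atom("O").xyz, r.atom("CA").xyz
        e_co = _unit(o - c)
        normal = _unit(np.cross(o - c, ca - c))
        p = np.cross(normal, e_co)
        # pick the in-plane lone-pair direction not occupied by the i+4 NH
        h_i4 = s.residues[t + 4].atom("H")
        u1 = _unit(e_co * 0.5 + p * math.sqrt(3) / 2)
        u2 = _unit(e_co * 0.5 - p * math.sqrt(3) / 2)
        if h_i4 is not None and np.dot(_unit(h_i4.xyz - o), u1) > np.dot(
            _unit(h_i4.xyz - o), u2
        ):
            u = u2
        else:
            u = u1
        hb1 = o + 2.3 * u
        cb = hb1 + B_C_H * u
        fac = _AtomFactory()
        fac.serial = 80000
        atoms = [fac.make("CB", "C", "ALA", "X", 1, cb)]
        atoms.append(fac.make("HB1", "H", "ALA", "X", 1, hb1))
        for j, d in enumerate(_tetra_around(cb, hb1, hb1 + normal), 2):
            atoms.append(fac.make(f"HB{j}", "H", "ALA", "X", 1, cb + B_C_H * d))
        s.residues.append(
            Residue(chain_id="X", res_seq=1, i_code="", name="ALA", atoms=atoms)
        )
        s.reindex()
        return s
    if motif == "M2_bifurcated":
        # aim the amide H of residue t+3 at the midpoint of carbonyls t and
        # t-1 so it donates to both (bifurcated; the i+4 NH of O_t persists)
        t = 2
        o_t = s.residues[t].atom("O").xyz
        o_tm1 = s.residues[t - 1].atom("O").xyz
        donor = s.residues[t + 3]
        nn = donor.atom("N").xyz
        h = donor.atom("H")
        u = _unit(_unit(o_t - nn) + _unit(o_tm1 - nn))
        h.xyz = nn + B_N_H * u
        return s
    if motif == "M3_capping":
        # serine in the C-terminal turn donating its hydroxyl to the
        # carbonyl four residues back
        n = len(s.residues)
        t = n - 5  # acceptor carbonyl: still has an i+4 NH donor (last residue)
        seq = ["A"] * n
        ser_pos = t + 3
        seq[ser_pos] = "S"
        s = build_peptide(BuildSpec(template="alpha_helix", n_res=n,
                                    sequence="".join(seq)))
        acc = s.residues[t]
        o = acc.atom("O").xyz
        ser = s.residues[ser_pos]
        cb = ser.atom("CB").xyz
        og = cb + B_C_OH * _unit(o - cb)
        hg = og + B_O_H * _unit(o - og)
        ser.atom("OG").xyz = og
        ser.atom("HG").xyz = hg
        return s
    raise AssertionError


def build_crankshaft_fixture(n_res: int = 12) -> Structure:
    """Helix in which one amide NH is re-aimed to donate to both its i-3 and
    i-4 carbonyls (one bifurcated hydrogen bond); used to test the
    bifurcation statistics against a hand-countable case."""
    return build_motif_fixture("M2_bifurcated", n_res=n_res)
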