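"""Geometric classification of backbone-carbonyl noncovalent interactions.

Eight interaction categories are assigned to each backbone carbonyl oxygen:

==========  ===============================================================
NH_bb       hydrogen bond from a backbone amide N-H
NH_sc       hydrogen bond from a side-chain N-H
OH_sc       hydrogen bond from a side-chain hydroxyl
CaH         hydrogen bond from the alpha-carbon H
CH_X        hydrogen bond from any other side-chain C-H
HOH         hydrogen bond from a water molecule
npistar     lone-pair donation into the pi* of a neighbouring backbone C=O
npistar_sc  the same, with an Asn/Gln side-chain carbonyl as acceptor
==========  ===============================================================

Default geometric cutoffs (all inclusive):

* N-H donors:  d(H...O) <= 2.44 A, omega >= 90 deg, rho >= 90 deg
* O-H donors (hydroxyl, water):  d(H...O) <= 2.31 A, same angles
* C-H donors:  d(H...O) <= 2.68 A, same angles, plus elevation of H above
  the acceptor sp2 carbonyl plane < 50 deg
* n->pi*:  d(O...C) <= 3.22 A, 95 <= theta <= 125 deg (Burgi-Dunitz-type
  approach window), planarity dihedral chi >= 120 deg

omega is the angle at the hydrogen (donor-heavy - H ... O) and rho the
angle at the acceptor oxygen (H ... O = C). For the n->pi* screen, theta is
the O(donor)...C(acceptor)=O(acceptor) angle and chi the magnitude of the
dihedral Ca(acceptor)-C(acceptor)...O(donor)...H, where H is the polar
hydrogen hydrogen-bonded to the donor oxygen (its nearest N-H/O-H hydrogen
within 2.5 A, covalent neighbours excluded). chi >= 120 deg requires the
hydrogen bond and the pi* approach to engage the two carbonyl lone pairs on
opposite (trans) sides, screening out O...C contacts that are merely part
of a hydrogen-bond cluster. A donor oxygen with no hydrogen-bond partner
passes the screen. The anchor is configurable (``chi_hydrogen``:
"hbond_partner", "donor" = donor-residue amide H, "acceptor" =
acceptor-residue amide H, or "none" to skip).

A carbonyl whose only qualifying interactions are to water is assumed fully
solvated and is reported as making exactly two water hydrogen bonds
(water-saturation rule), so that under-solvated snapshots do not bias the
counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    GeometricMeasurement,
    angle,
    dihedral,
    distance,
    elevation,
)
from .structure_io import (
    CarbonylSite,
    DonorGroup,
    Structure,
    identify_carbonyls,
    identify_donors,
)

NCI_TYPES = (
    "NH_bb", "NH_sc", "OH_sc", "CaH", "CH_X", "HOH", "npistar", "npistar_sc",
)

#: interaction types that count as hydrogen bonds with traditional
#: (electronegative) donors
STRONG_HBOND_TYPES = ("NH_bb", "NH_sc", "OH_sc", "HOH")


@dataclass(frozen=True)
class NCIThresholds:
    """Geometric cutoffs; defaults are the operational definitions used
    throughout (distances in A, angles in degrees, all inclusive)."""

    d_NH_max: float = 2.44
    d_OH_max: float = 2.31
    d_CH_max: float = 2.68
    omega_min: float = 90.0
    rho_min: float = 90.0
    elevation_max: float = 50.0
    d_npistar_max: float = 3.22
    theta_min: float = 95.0
    theta_max: float = 125.0
    chi_min: float = 120.0
    #: water O within this distance of a carbonyl O marks the carbonyl as
    #: solvent-exposed for the water-saturation rule
    water_exposure_max: float = 3.5
    #: which hydrogen anchors the chi dihedral: "hbond_partner" (default:
    #: the polar H hydrogen-bonded to the donor O), "donor"/"acceptor"
    #: (that residue's amide H), or "none" (skip the chi screen)
    chi_hydrogen: str = "hbond_partner"
    #: search radius for the chi anchor hydrogen (A)
    chi_partner_max: float = 2.5

    def __post_init__(self):
        if self.theta_min >= self.theta_max:
            raise ValueError("theta_min must be < theta_max")
        if self.chi_hydrogen not in ("hbond_partner", "acceptor", "donor", "none"):
            raise ValueError(
                "chi_hydrogen must be hbond_partner/acceptor/donor/none"
            )
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be positive")

    def d_max_for(self, category: str) -> float:
        if category in ("NH_bb", "NH_sc"):
            return self.d_NH_max
        if category in ("OH_sc", "HOH"):
            return self.d_OH_max
        if category in ("CaH", "CH_X"):
            return self.d_CH_max
        raise KeyError(category)

    @classmethod
    def from_dict(cls, d: dict) -> "NCIThresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown threshold keys: {sorted(bad)}")
        return cls(**d)


#: prefilter radii used by inventory_structure; the donor prefilter must
#: exceed the largest H...O cutoff plus the covalent heavy-H offset
DONOR_PREFILTER_RADIUS = 5.0
NPISTAR_PREFILTER_PAD = 1.0


@dataclass
class NCIRecord:
    acceptor: CarbonylSite
    nci_type: str
    partner_residue_id: tuple
    partner_atoms: tuple  # (heavy name, H name) or (donor O name,)
    geometry: GeometricMeasurement
    sequence_separation: object  # signed int, "water" or "interchain"

    def key(self):
        return (
            self.acceptor.residue_id,
            self.acceptor.kind,
            self.nci_type,
            self.partner_residue_id,
            self.partner_atoms,
        )


@dataclass
class ResidueInventory:
    residue_id: tuple
    snapshot_index: int
    records: list = field(default_factory=list)
    water_only: bool = False

    @property
    def raw_count(self) -> int:
        return len(self.records)

    @property
    def reported_count(self) -> int:
        return 2 if self.water_only else self.raw_count

    @property
    def combo(self) -> tuple:
        """Unordered multiset of interaction types (sorted tuple). Under the
        water rule the combination is two waters."""
        if self.water_only:
            return ("HOH", "HOH")
        return tuple(sorted(r.nci_type for r in self.records))


def _sequence_separation(s: Structure, acceptor_id, donor_id):
    if donor_id[0] == "W":
        return "water"
    if donor_id[0] != acceptor_id[0]:
        return "interchain"
    return donor_id[1] - acceptor_id[1]


def _excluded_pair(site: CarbonylSite, donor: DonorGroup) -> bool:
    """Covalent-neighbourhood exclusions: donors of the acceptor's own
    residue, and the amide NH of the following residue (the N-H of the same
    peptide unit as the carbonyl), are not noncovalent partners."""
    if donor.residue_id == site.residue_id:
        return True
    if (
        donor.category == "NH_bb"
        and donor.residue_id[0] == site.residue_id[0]
        and donor.residue_id[2] == site.residue_id[2]
        and donor.residue_id[1] == site.residue_id[1] + 1
        and site.kind == "mainchain"
    ):
        return True
    return False


def classify_hbond(
    site: CarbonylSite,
    donor: DonorGroup,
    th: NCIThresholds = NCIThresholds(),
    structure: Optional[Structure] = None,
) -> Optional[NCIRecord]:
    """Test one donor group against one carbonyl acceptor.

    Every hydrogen of the group is measured; the qualifying hydrogen with
    the smallest d(H...O) is reported, so a donor group contributes at most
    one record per carbonyl (it may still bond a second carbonyl, which is
    what a bifurcated hydrogen bond is).
    """
    if _excluded_pair(site, donor):
        return None
    d_max = th.d_max_for(donor.category)
    o = site.O.xyz
    c = site.C.xyz
    best = None
    for h in donor.hydrogens:
        d = distance(h.xyz, o)
        if d > d_max:
            continue
        om = angle(donor.heavy.xyz, h.xyz, o)
        if om < th.omega_min:
            continue
        rho = angle(h.xyz, o, c)
        if rho < th.rho_min:
            continue
        elev = float("nan")
        if donor.category in ("CaH", "CH_X"):
            elev = elevation(
                h.xyz, (site.CA.xyz, c, o), reference=o
            )
            if elev >= th.elevation_max:
                continue
        if best is None or d < best[0]:
            best = (d, h, om, rho, elev)
    if best is None:
        return None
    d, h, om, rho, elev = best
    sep = (
        _sequence_separation(structure, site.residue_id, donor.residue_id)
        if structure is not None
        else (
            "water"
            if donor.category == "HOH"
            else donor.residue_id[1] - site.residue_id[1]
        )
    )
    nci_type = "HOH" if donor.category == "HOH" else donor.category
    return NCIRecord(
        acceptor=site,
        nci_type=nci_type,
        partner_residue_id=donor.residue_id,
        partner_atoms=(donor.heavy.name, h.name),
        geometry=GeometricMeasurement(d=d, omega=om, rho=rho, elevation=elev),
        sequence_separation=sep,
    )


def _chi_anchor_hydrogen(structure: Structure, donor_site: CarbonylSite, th):
    """Position of the hydrogen anchoring the chi dihedral for a donor
    carbonyl oxygen, or None (screen passes) if there is none."""
    o = donor_site.O.xyz
    ch, seq, ic = donor_site.residue_id
    best = None
    for res in structure.residues:
        # covalent neighbourhood: own residue entirely, and the amide H of
        # the next residue (same peptide unit as the carbonyl)
        if res.residue_id == donor_site.residue_id:
            continue
        next_unit = (
            res.chain_id == ch and res.i_code == ic and res.res_seq == seq + 1
        )
        next_n = res.atom("N") if next_unit else None
        for a in res.atoms:
            if not a.is_hydrogen:
                continue
            if next_n is not None and distance(a.xyz, next_n.xyz) <= 1.2:
                continue
            if not _is_polar_hydrogen(res, a):
                continue
            d = distance(a.xyz, o)
            if d <= th.chi_partner_max and (best is None or d < best[0]):
                best = (d, a.xyz)
    for w in structure.waters:
        for a in w.hydrogens:
            d = distance(a.xyz, o)
            if d <= th.chi_partner_max and (best is None or d < best[0]):
                best = (d, a.xyz)
    return None if best is None else best[1]


def _is_polar_hydrogen(res, h) -> bool:
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        if a.element.upper() in ("N", "O") and distance(a.xyz, h.xyz) <= 1.2:
            return True
    return False


def classify_npistar(
    donor_site: CarbonylSite,
    acceptor_site: CarbonylSite,
    th: NCIThresholds = NCIThresholds(),
    structure: Optional[Structure] = None,
) -> Optional[NCIRecord]:
    """n->pi* screen: lone pair of ``donor_site``'s oxygen donating into the
    pi* of ``acceptor_site``'s carbonyl carbon. The record belongs to the
    donor carbonyl's inventory (its lone pair is what is being satisfied)."""
    if (
        donor_site.residue_id == acceptor_site.residue_id
        and donor_site.kind == acceptor_site.kind
    ):
        return None
    o_d = donor_site.O.xyz
    c_a = acceptor_site.C.xyz
    o_a = acceptor_site.O.xyz
    d = distance(o_d, c_a)
    if d > th.d_npistar_max:
        return None
    th_ang = angle(o_d, c_a, o_a)
    if not (th.theta_min <= th_ang <= th.theta_max):
        return None
    chi = float("nan")
    if structure is not None and th.chi_hydrogen != "none":
        if th.chi_hydrogen == "hbond_partner":
            h_xyz = _chi_anchor_hydrogen(structure, donor_site, th)
        else:
            anchor_id = (
                acceptor_site.residue_id
                if th.chi_hydrogen == "acceptor"
                else donor_site.residue_id
            )
            anchor_res = structure.residue(anchor_id)
            h = anchor_res.atom("H") if anchor_res is not None else None
            h_xyz = None if h is None else h.xyz
        if h_xyz is not None:
            chi = dihedral(acceptor_site.CA.xyz, c_a, o_d, h_xyz)
            if chi < th.chi_min:
                return None
    sep = (
        "interchain"
        if acceptor_site.residue_id[0] != donor_site.residue_id[0]
        else acceptor_site.residue_id[1] - donor_site.residue_id[1]
    )
    nci_type = "npistar" if acceptor_site.kind == "mainchain" else "npistar_sc"
    return NCIRecord(
        acceptor=donor_site,
        nci_type=nci_type,
        partner_residue_id=acceptor_site.residue_id,
        partner_atoms=(acceptor_site.C.name, acceptor_site.O.name),
        geometry=GeometricMeasurement(d=d, theta=th_ang, chi=chi),
        sequence_separation=sep,
    )


def apply_water_rule(inv: ResidueInventory, exposed: bool) -> ResidueInventory:
    """Water-saturation rule: a carbonyl whose qualifying interactions are
    all to water (possibly none), and which is solvent-exposed, is reported
    as making exactly two water hydrogen bonds."""
    inv.water_only = exposed and all(r.nci_type == "HOH" for r in inv.records)
    return inv


def inventory_structure(
    s: Structure,
    th: NCIThresholds = NCIThresholds(),
    apply_water: bool = True,
    interchain: bool = True,
) -> list:
    """Classify every (carbonyl, donor) and (carbonyl, carbonyl) pair and
    return one :class:`ResidueInventory` per mainchain carbonyl, in residue
    order.

    A 5 A donor-heavy-atom prefilter and a d_max + 1 A carbonyl prefilter
    bound the pair search; both strictly exceed the largest geometric
    cutoff, so they cannot change the result.
    """
    assert DONOR_PREFILTER_RADIUS > max(th.d_NH_max, th.d_OH_max, th.d_CH_max) + 1.2
    sites = identify_carbonyls(s)
    donors = identify_donors(s)
    mainchain = [x for x in sites if x.kind == "mainchain"]
    invs = {
        x.residue_id: ResidueInventory(
            residue_id=x.residue_id, snapshot_index=s.snapshot_index
        )
        for x in mainchain
    }
    # hydrogen bonds
    if donors:
        tree = cKDTree(np.array([d.heavy.xyz for d in donors]))
        for site in mainchain:
            idx = tree.query_ball_point(site.O.xyz, DONOR_PREFILTER_RADIUS)
            for i in sorted(idx):
                donor = donors[i]
                if not interchain and donor.residue_id[0] not in (
                    site.residue_id[0],
                    "W",
                ):
                    continue
                rec = classify_hbond(site, donor, th, structure=s)
                if rec is not None:
                    invs[site.residue_id].records.append(rec)
    # n->pi*: every mainchain carbonyl O against every other carbonyl C
    if sites:
        ctree = cKDTree(np.array([x.C.xyz for x in sites]))
        for dsite in mainchain:
            idx = ctree.query_ball_point(
                dsite.O.xyz, th.d_npistar_max + NPISTAR_PREFILTER_PAD
            )
            for i in sorted(idx):
                asite = sites[i]
                if not interchain and asite.residue_id[0] != dsite.residue_id[0]:
                    continue
                rec = classify_npistar(dsite, asite, th, structure=s)
                if rec is not None:
                    invs[dsite.residue_id].records.append(rec)
    # water rule
    out = []
    wtree = (
        cKDTree(np.array([w.O.xyz for w in s.waters])) if s.waters else None
    )
    for site in mainchain:
        inv = invs[site.residue_id]
        if apply_water:
            exposed = bool(
                wtree is not None
                and wtree.query_ball_point(site.O.xyz, th.water_exposure_max)
            )
            apply_water_rule(inv, exposed)
        out.append(inv)
    return out


def inventory_to_rows(s: Structure, inventories: list) -> list:
    """Flatten inventories to TSV-ready dicts: one row per record plus one
    summary row per residue."""
    rows = []
    for inv in inventories:
        ch, seq, ic = inv.residue_id
        res = s.residue(inv.residue_id)
        base = {
            "structure_id": s.id,
            "snapshot": inv.snapshot_index,
            "chain": ch,
            "res_seq": seq,
            "i_code": ic,
            "res_name": res.name if res else "",
        }
        for r in inv.records:
            g = r.geometry
            rows.append(
                {
                    **base,
                    "row_type": "record",
                    "nci_type": r.nci_type,
                    "partner_chain": r.partner_residue_id[0],
                    "partner_res_seq": r.partner_residue_id[1],
                    "partner_atom": "/".join(r.partner_atoms),
                    "d": round(g.d, 3),
                    "omega": round(g.omega, 2),
                    "rho": round(g.rho, 2),
                    "theta": round(g.theta, 2),
                    "chi": round(g.chi, 2),
                    "elevation": round(g.elevation, 2),
                    "raw_count": inv.raw_count,
                    "reported_count": inv.reported_count,
                    "water_only": inv.water_only,
                }
            )
        rows.append(
            {
                **base,
                "row_type": "summary",
                "nci_type": "+".join(inv.combo) if inv.combo else "",
                "partner_chain": "",
                "partner_res_seq": "",
                "partner_atom": "",
                "d": "",
                "omega": "",
                "rho": "",
                "theta": "",
                "chi": "",
                "elevation": "",
                "raw_count": inv.raw_count,
                "reported_count": inv.reported_count,
                "water_only": inv.water_only,
            }
        )
    return rows
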