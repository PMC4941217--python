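"""Interaction classification: threshold arithmetic, designed-geometry
recovery, the water-saturation rule and brute-force oracle equivalence."""

import math

import numpy as np
import pytest

from carbonyl_nci.geometry import angle, dihedral, distance, elevation
from carbonyl_nci.nci_classify import (
    DONOR_PREFILTER_RADIUS,
    NCIThresholds,
    ResidueInventory,
    apply_water_rule,
    classify_hbond,
    classify_npistar,
    inventory_structure,
)
from carbonyl_nci.structure_io import (
    AtomRecord,
    CarbonylSite,
    DonorGroup,
    identify_carbonyls,
    identify_donors,
)
from carbonyl_nci.synthetic_data import BuildSpec, build_peptide, perturb_ensemble, solvate_carbonyls
from conftest import apply_rigid, random_rigid_motion


def _atom(name, element, xyz, res=("A", 1, "")):
    return AtomRecord(
        serial=1, name=name, element=element, alt_loc="", res_name="ALA",
        chain_id=res[0], res_seq=res[1], i_code=res[2], xyz=np.asarray(xyz, float),
    )


def _make_site(res=("A", 1, "")):
    """Carbonyl in the xy-plane: C at origin, O along +x, CA behind."""
    c = _atom("C", "C", (0, 0, 0), res)
    o = _atom("O", "O", (1.23, 0, 0), res)
    ca = _atom("CA", "C", (-0.9, -1.2, 0), res)
    return CarbonylSite(residue_id=res, C=c, O=o, CA=ca, kind="mainchain")


def _make_nh_donor(d, omega, rho, res=("A", 5, "")):
    """Place H at distance d from O with H-O=C angle rho (in-plane), then N
    so that the donor angle N-H...O equals omega."""
    o = np.array([1.23, 0.0, 0.0])
    rho_r = math.radians(rho)
    h = o + d * np.array([math.cos(math.pi - rho_r), math.sin(math.pi - rho_r), 0.0])
    # N in the same plane, at 1.01 A from H, making the requested omega
    u_oh = (h - o) / np.linalg.norm(h - o)
    om_r = math.radians(omega)
    # rotate u_oh by (180 - omega) about z to get the H->N direction
    th = math.pi - om_r
    rot = np.array(
        [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
    )
    n = h + 1.01 * (rot @ u_oh)
    heavy = _atom("N", "N", n, res)
    hyd = _atom("H", "H", h, res)
    return DonorGroup("NH_bb", heavy, [hyd], res)


class TestHbondThresholds:
    def test_good_nh_bond_accepted(self):
        site = _make_site()
        donor = _make_nh_donor(2.0, 150.0, 120.0)
        rec = classify_hbond(site, donor)
        assert rec is not None and rec.nci_type == "NH_bb"
        assert rec.geometry.d == pytest.approx(2.0)
        assert rec.geometry.omega == pytest.approx(150.0)
        assert rec.geometry.rho == pytest.approx(120.0)

    def test_distance_beyond_nh_cutoff_rejected(self):
        rec = classify_hbond(_make_site(), _make_nh_donor(2.50, 150.0, 120.0))
        assert rec is None

    def test_cutoffs_are_inclusive(self):
        rec = classify_hbond(_make_site(), _make_nh_donor(2.44, 90.0, 90.0))
        assert rec is not None

    def test_angle_criteria(self):
        assert classify_hbond(_make_site(), _make_nh_donor(2.0, 89.0, 120.0)) is None
        assert classify_hbond(_make_site(), _make_nh_donor(2.0, 150.0, 89.0)) is None

    def test_oh_cutoff_tighter_than_nh(self):
        donor = _make_nh_donor(2.40, 150.0, 120.0)
        oh = DonorGroup(
            "OH_sc",
            _atom("OG", "O", donor.heavy.xyz, donor.residue_id),
            donor.hydrogens,
            donor.residue_id,
        )
        assert classify_hbond(_make_site(), donor) is not None
        assert classify_hbond(_make_site(), oh) is None  # 2.40 > 2.31

    def test_ch_donor_needs_low_elevation(self):
        site = _make_site()
        donor = _make_nh_donor(2.5, 150.0, 120.0)
        # in-plane C-H donor: elevation 0, accepted at 2.5 (< 2.68)
        ch = DonorGroup(
            "CH_X",
            _atom("CB", "C", donor.heavy.xyz),
            donor.hydrogens,
            donor.residue_id,
        )
        rec = classify_hbond(site, ch)
        assert rec is not None and rec.geometry.elevation == pytest.approx(0.0)
        # lift the hydrogen out of the carbonyl plane beyond 50 deg
        o = site.O.xyz
        d = np.linalg.norm(donor.hydrogens[0].xyz - o)
        elev_dir = np.array([0.3, 0.3, 0.9])  # elevation ~65 deg, rho > 90
        h2 = _atom("H", "H", o + d * elev_dir / np.linalg.norm(elev_dir))
        cb = _atom("CB", "C", h2.xyz + (h2.xyz - o) / np.linalg.norm(h2.xyz - o) * 1.09)
        ch2 = DonorGroup("CH_X", cb, [h2], ("A", 5, ""))
        assert classify_hbond(site, ch2) is None

    def test_own_residue_and_peptide_unit_excluded(self):
        site = _make_site(res=("A", 3, ""))
        same = _make_nh_donor(2.0, 150.0, 120.0, res=("A", 3, ""))
        nxt = _make_nh_donor(2.0, 150.0, 120.0, res=("A", 4, ""))
        far = _make_nh_donor(2.0, 150.0, 120.0, res=("A", 7, ""))
        assert classify_hbond(site, same) is None
        assert classify_hbond(site, nxt) is None
        assert classify_hbond(site, far) is not None

    def test_best_hydrogen_selected(self):
        site = _make_site()
        d1 = _make_nh_donor(2.2, 150.0, 120.0)
        d2 = _make_nh_donor(1.9, 150.0, 120.0)
        donor = DonorGroup("NH_bb", d1.heavy, [d1.hydrogens[0], d2.hydrogens[0]], d1.residue_id)
        rec = classify_hbond(site, donor)
        assert rec.geometry.d == pytest.approx(1.9)


class TestNpistar:
    def _sites(self, d, theta):
        acc = _make_site(res=("A", 2, ""))
        th_r = math.radians(theta)
        # donor O at angle theta from the acceptor C=O axis, distance d from C
        pos = np.array([d * math.cos(th_r), d * math.sin(th_r), 0.0])
        don = CarbonylSite(
            residue_id=("A", 1, ""),
            C=_atom("C", "C", pos + np.array([0.0, 1.23, 0.0]), ("A", 1, "")),
            O=_atom("O", "O", pos, ("A", 1, "")),
            CA=_atom("CA", "C", pos + np.array([1.2, 1.9, 0.0]), ("A", 1, "")),
            kind="mainchain",
        )
        return don, acc

    def test_qualifying_geometry(self):
        don, acc = self._sites(3.0, 110.0)
        rec = classify_npistar(don, acc)
        assert rec is not None and rec.nci_type == "npistar"
        assert rec.acceptor.residue_id == ("A", 1, "")  # donor O owns the record
        assert rec.geometry.d == pytest.approx(3.0)
        assert rec.geometry.theta == pytest.approx(110.0)

    def test_distance_cutoff(self):
        don, acc = self._sites(3.30, 110.0)
        assert classify_npistar(don, acc) is None

    def test_theta_window(self):
        for theta in (94.0, 126.0):
            don, acc = self._sites(3.0, theta)
            assert classify_npistar(don, acc) is None
        for theta in (95.5, 124.5):
            don, acc = self._sites(3.0, theta)
            assert classify_npistar(don, acc) is not None

    def test_helix_i_to_ip1(self, helix20, helix20_inventory):
        for inv in helix20_inventory[2:15]:
            nps = [r for r in inv.records if r.nci_type == "npistar"]
            assert len(nps) == 1
            assert nps[0].sequence_separation == 1
            g = nps[0].geometry
            assert g.d <= 3.22 and 95 <= g.theta <= 125 and g.chi >= 120


class TestWaterRule:
    def test_water_only_reports_two(self):
        inv = ResidueInventory(residue_id=("A", 1, ""), snapshot_index=0)
        inv.records = [_DummyRec("HOH")]
        apply_water_rule(inv, exposed=True)
        assert inv.reported_count == 2 and inv.water_only

    def test_mixed_records_keep_raw_count(self):
        inv = ResidueInventory(residue_id=("A", 1, ""), snapshot_index=0)
        inv.records = [_DummyRec("HOH"), _DummyRec("NH_bb")]
        apply_water_rule(inv, exposed=True)
        assert not inv.water_only and inv.reported_count == 2  # raw count

    def test_buried_empty_stays_zero(self):
        inv = ResidueInventory(residue_id=("A", 1, ""), snapshot_index=0)
        apply_water_rule(inv, exposed=False)
        assert inv.reported_count == 0 and not inv.water_only

    def test_exposed_empty_counts_two(self):
        inv = ResidueInventory(residue_id=("A", 1, ""), snapshot_index=0)
        apply_water_rule(inv, exposed=True)
        assert inv.reported_count == 2 and inv.water_only

    def test_solvated_extended_all_water_only(self, solvated_extended):
        for inv in inventory_structure(solvated_extended):
            assert inv.water_only and inv.reported_count == 2
            assert inv.combo == ("HOH", "HOH")


class _DummyRec:
    def __init__(self, t):
        self.nci_type = t


def brute_force_keys(s, th):
    """Independent no-prefilter double loop re-deriving every record from
    the raw thresholds (the oracle for inventory_structure)."""
    keys = set()
    sites = identify_carbonyls(s)
    mainchain = [x for x in sites if x.kind == "mainchain"]
    donors = identify_donors(s)
    for site in mainchain:
        for don in donors:
            if don.residue_id == site.residue_id:
                continue
            if (
                don.category == "NH_bb"
                and don.residue_id[0] == site.residue_id[0]
                and don.residue_id[2] == site.residue_id[2]
                and don.residue_id[1] == site.residue_id[1] + 1
            ):
                continue
            dmax = {
                "NH_bb": th.d_NH_max, "NH_sc": th.d_NH_max,
                "OH_sc": th.d_OH_max, "HOH": th.d_OH_max,
                "CaH": th.d_CH_max, "CH_X": th.d_CH_max,
            }[don.category]
            best = None
            for h in don.hydrogens:
                d = distance(h.xyz, site.O.xyz)
                if d > dmax:
                    continue
                if angle(don.heavy.xyz, h.xyz, site.O.xyz) < th.omega_min:
                    continue
                if angle(h.xyz, site.O.xyz, site.C.xyz) < th.rho_min:
                    continue
                if don.category in ("CaH", "CH_X"):
                    e = elevation(
                        h.xyz, (site.CA.xyz, site.C.xyz, site.O.xyz),
                        reference=site.O.xyz,
                    )
                    if e >= th.elevation_max:
                        continue
                if best is None or d < best[0]:
                    best = (d, h)
            if best is not None:
                t = "HOH" if don.category == "HOH" else don.category
                keys.add(
                    (site.residue_id, site.kind, t, don.residue_id,
                     (don.heavy.name, best[1].name))
                )
    for dsite in mainchain:
        for asite in sites:
            if (
                dsite.residue_id == asite.residue_id
                and dsite.kind == asite.kind
            ):
                continue
            d = distance(dsite.O.xyz, asite.C.xyz)
            if d > th.d_npistar_max:
                continue
            theta = angle(dsite.O.xyz, asite.C.xyz, asite.O.xyz)
            if not (th.theta_min <= theta <= th.theta_max):
                continue
            # chi anchor: nearest polar H hydrogen-bonded to the donor O,
            # skipping the donor's own residue and the next amide H
            ch, seq, ic = dsite.residue_id
            cands = []
            for r2 in s.residues:
                if r2.residue_id == dsite.residue_id:
                    continue
                nxt_n = (
                    r2.atom("N")
                    if (r2.chain_id == ch and r2.i_code == ic and r2.res_seq == seq + 1)
                    else None
                )
                polar = [
                    a for a in r2.atoms
                    if not a.is_hydrogen and a.element.upper() in ("N", "O")
                ]
                for a in r2.atoms:
                    if not a.is_hydrogen:
                        continue
                    if nxt_n is not None and distance(a.xyz, nxt_n.xyz) <= 1.2:
                        continue
                    if not any(distance(a.xyz, p.xyz) <= 1.2 for p in polar):
                        continue
                    cands.append(a.xyz)
            for w in s.waters:
                cands.extend(a.xyz for a in w.hydrogens)
            near = [
                x for x in cands if distance(x, dsite.O.xyz) <= th.chi_partner_max
            ]
            if near:
                h_xyz = min(near, key=lambda x: distance(x, dsite.O.xyz))
                chi = dihedral(asite.CA.xyz, asite.C.xyz, dsite.O.xyz, h_xyz)
                if chi < th.chi_min:
                    continue
            t = "npistar" if asite.kind == "mainchain" else "npistar_sc"
            keys.add(
                (dsite.residue_id, dsite.kind, t, asite.residue_id,
                 (asite.C.name, asite.O.name))
            )
    return keys


def _inventory_keys(invs):
    keys = set()
    for inv in invs:
        for r in inv.records:
            keys.add(r.key())
    return keys


def _random_structure(rng):
    template = rng.choice(["alpha_helix", "three10_helix", "extended", "custom"])
    n = int(rng.integers(4, 31))
    kwargs = {}
    if template == "custom":
        kwargs["phi_psi"] = [
            (float(rng.uniform(-180, 0)), float(rng.uniform(-90, 180)))
            for _ in range(n)
        ]
    seq = "".join(rng.choice(list("AAGS"), size=n))
    s = build_peptide(BuildSpec(template=template, n_res=n, sequence=seq, **kwargs))
    if rng.random() < 0.5:
        s = solvate_carbonyls(
            s, per_site=int(rng.integers(1, 3)), seed=int(rng.integers(1_000_000))
        )
    sigma = float(rng.uniform(0.0, 0.3))
    return perturb_ensemble(s, sigma=sigma, n=1, seed=int(rng.integers(1_000_000)))[0]


def test_oracle_equivalence_on_random_structures(thresholds):
    """Prefiltered classifier == no-prefilter brute force, exactly, on 50
    random small structures."""
    rng = np.random.default_rng(20160225)
    for _ in range(50):
        s = _random_structure(rng)
        got = _inventory_keys(inventory_structure(s, thresholds, apply_water=False))
        want = brute_force_keys(s, thresholds)
        assert got == want


def test_records_recheck_against_thresholds(helix20_inventory, thresholds):
    for inv in helix20_inventory:
        for r in inv.records:
            g = r.geometry
            if r.nci_type in ("npistar", "npistar_sc"):
                assert g.d <= thresholds.d_npistar_max
                assert thresholds.theta_min <= g.theta <= thresholds.theta_max
                if not math.isnan(g.chi):
                    assert g.chi >= thresholds.chi_min
            else:
                assert g.d <= thresholds.d_max_for(r.nci_type)
                assert g.omega >= thresholds.omega_min
                assert g.rho >= thresholds.rho_min


def test_rigid_motion_invariance(helix20):
    rng = np.random.default_rng(99)
    R, t = random_rigid_motion(rng)
    moved = apply_rigid(helix20, R, t)
    a = _inventory_keys(inventory_structure(helix20))
    b = _inventory_keys(inventory_structure(moved))
    assert a == b


def test_prefilter_radius_exceeds_cutoffs(thresholds):
    assert DONOR_PREFILTER_RADIUS > max(
        thresholds.d_NH_max, thresholds.d_OH_max, thresholds.d_CH_max
    ) + 1.2


def test_threshold_validation():
    with pytest.raises(ValueError):
        NCIThresholds(theta_min=130.0, theta_max=125.0)
    with pytest.raises(ValueError):
        NCIThresholds(d_NH_max=-1.0)
    with pytest.raises(KeyError):
        NCIThresholds.from_dict({"bogus": 1.0})


def test_no_donor_structure_counts_zero():
    s = build_peptide(BuildSpec(template="extended", n_res=4, sequence="GGGG"))
    # strip all hydrogens: nothing can donate
    for r in s.residues:
        r.atoms = [a for a in r.atoms if not a.is_hydrogen]
    invs = inventory_structure(s)
    assert all(inv.reported_count == 0 for inv in invs)
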