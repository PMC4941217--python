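"""Mining of sustained under- and over-satisfied carbonyl motifs.

Over-satisfied backbone carbonyls (three simultaneous interactions) cluster
into recurring local-structure motifs:

M1_helix_NHbb_npistar_CHX
    mid-helix carbonyl with the canonical NH_bb + n->pi* pair plus a
    side-chain C-H hydrogen bond; position-independent along helices.
M2_Nterm_2NHbb_npistar
    helix carbonyl accepting a bifurcated pair of backbone NH bonds from
    the residues three and four ahead, plus the n->pi*; enriched in the
    first (N-terminal) helical turn, a sequence-independent capping
    arrangement.
M3_Cterm_NHbb_OHsc_npistar
    C-terminal-turn carbonyl capped by a Ser/Thr hydroxyl alongside NH_bb
    and n->pi*.
M4_strand_NHbb_CaH_HOH
    exposed strand carbonyl with NH_bb + CaH + a water hydrogen bond.

Under-satisfied carbonyls (a single sustained interaction) are reported as
``undersatisfied_1NCI`` with an optional scan for sub-van-der-Waals
O...H-N / O...H-Ca contacts that may quietly compensate them.

A residue qualifies as *sustained* at count k when its modal count over the
ensemble is k and it holds that count in at least half the snapshots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .ensemble_stats import EnsembleInventory, modal_count, occupancy_at_mode
from .geometry import distance
from .structure_io import Structure

MOTIF_LABELS = (
    "M1_helix_NHbb_npistar_CHX",
    "M2_Nterm_2NHbb_npistar",
    "M3_Cterm_NHbb_OHsc_npistar",
    "M4_strand_NHbb_CaH_HOH",
    "undersatisfied_1NCI",
    "none",
)

#: multiset definitions of the named 3-interaction clusters
MOTIF_COMBOS = {
    "M1_helix_NHbb_npistar_CHX": ("CH_X", "NH_bb", "npistar"),
    "M2_Nterm_2NHbb_npistar": ("NH_bb", "NH_bb", "npistar"),
    "M3_Cterm_NHbb_OHsc_npistar": ("NH_bb", "OH_sc", "npistar"),
    "M4_strand_NHbb_CaH_HOH": ("CaH", "HOH", "NH_bb"),
}

#: default O...H sub-van-der-Waals cutoff: r_vdW(O) 1.52 + r_vdW(H) 1.20 A
SUBVDW_OH_CUTOFF = 2.72


@dataclass
class MotifHit:
    residue_id: tuple
    motif: str
    occupancy: float
    snapshots_matching: int
    ss_class: str
    little_h: bool
    helix_terminus: str
    modal_combo: tuple
    donor_residues: tuple = ()

    def __post_init__(self):
        if self.motif not in MOTIF_LABELS:
            raise ValueError(f"unknown motif {self.motif}")
        if self.occupancy < 0.5:
            raise ValueError("reported hits must be sustained (occupancy >= 0.5)")


def find_sustained(
    ei: EnsembleInventory, target_count: int, min_occupancy: float = 0.5
) -> list:
    """Residues whose modal count equals ``target_count`` held for at least
    ``min_occupancy`` of the snapshots."""
    out = []
    for i, rid in enumerate(ei.residues):
        series = ei.counts[i]
        if modal_count(series) != target_count:
            continue
        if occupancy_at_mode(series) >= min_occupancy:
            out.append(rid)
    return out


def _modal_combo(ei: EnsembleInventory, i: int, target: int) -> tuple:
    series = ei.counts[i]
    combos = [
        ei.combos[i][k] for k in range(len(series)) if series[k] == target
    ]
    return Counter(combos).most_common(1)[0][0]


def _nhbb_donor_separations(ei: EnsembleInventory, i: int, target: int):
    """Sequence separations of NH_bb donors in the modal-state snapshots
    (majority vote across snapshots)."""
    if ei.records is None:
        return ()
    seps = Counter()
    series = ei.counts[i]
    for k in range(len(series)):
        if series[k] != target:
            continue
        recs = ei.records[i][k]
        key = tuple(
            sorted(
                r.sequence_separation
                for r in recs
                if r.nci_type == "NH_bb"
                and isinstance(r.sequence_separation, int)
            )
        )
        seps[key] += 1
    return seps.most_common(1)[0][0] if seps else ()


def classify_motif(
    residue_id, ei: EnsembleInventory, structure: Structure | None = None
) -> MotifHit | None:
    """Classify one sustained 3- or 1-count residue against the named motif
    definitions; residues sustained at other counts return None."""
    i = ei.residues.index(residue_id)
    series = ei.counts[i]
    target = modal_count(series)
    occ = occupancy_at_mode(series)
    if occ < 0.5 or target not in (1, 3):
        return None
    combo = _modal_combo(ei, i, target)
    lab = ei.ss_labels.get(residue_id)
    ss_class = ei.ss.get(residue_id, "none")
    little_h = lab.little_h if lab else False
    terminus = lab.helix_terminus if lab else ""
    matching = int((series == target).sum())
    donor_residues = ()

    motif = "none"
    if target == 1:
        motif = "undersatisfied_1NCI"
    else:
        if (
            combo == MOTIF_COMBOS["M1_helix_NHbb_npistar_CHX"]
            and ss_class == "alpha_helix"
        ):
            motif = "M1_helix_NHbb_npistar_CHX"
        elif (
            combo == MOTIF_COMBOS["M2_Nterm_2NHbb_npistar"]
            and ss_class == "alpha_helix"
        ):
            # bifurcated pair: the two NH_bb donors come from i+3 and i+4
            seps = _nhbb_donor_separations(ei, i, target)
            if seps == (3, 4) and (little_h or terminus in ("N", "NC")):
                motif = "M2_Nterm_2NHbb_npistar"
        elif (
            combo == MOTIF_COMBOS["M3_Cterm_NHbb_OHsc_npistar"]
            and ss_class == "alpha_helix"
            and (little_h or terminus in ("C", "NC"))
        ):
            ok = True
            if structure is not None and ei.records is not None:
                ok = _ohsc_from_ser_thr(ei, i, target, structure)
            if ok:
                motif = "M3_Cterm_NHbb_OHsc_npistar"
        elif (
            combo == MOTIF_COMBOS["M4_strand_NHbb_CaH_HOH"]
            and ss_class == "beta_strand"
        ):
            motif = "M4_strand_NHbb_CaH_HOH"
    return MotifHit(
        residue_id=residue_id,
        motif=motif,
        occupancy=occ,
        snapshots_matching=matching,
        ss_class=ss_class,
        little_h=little_h,
        helix_terminus=terminus,
        modal_combo=combo,
        donor_residues=donor_residues,
    )


def _ohsc_from_ser_thr(ei, i, target, structure: Structure) -> bool:
    series = ei.counts[i]
    for k in range(len(series)):
        if series[k] != target:
            continue
        for r in ei.records[i][k]:
            if r.nci_type == "OH_sc":
                res = structure.residue(r.partner_residue_id)
                return res is not None and res.name in ("SER", "THR")
    return False


def find_motifs(ei: EnsembleInventory, structure: Structure | None = None) -> list:
    """All sustained 3- and 1-count residues with their motif labels."""
    hits = []
    for target in (3, 1):
        for rid in find_sustained(ei, target):
            hit = classify_motif(rid, ei, structure)
            if hit is not None:
                hits.append(hit)
    return hits


def bifurcation_fraction(ei: EnsembleInventory) -> float | None:
    """Fraction of backbone-NH hydrogen bonds whose donor NH also donates a
    qualifying bond to a second carbonyl in the same snapshot, pooled over
    residue-steps. None when no NH_bb records exist."""
    if ei.records is None:
        raise ValueError("ensemble lacks stored records")
    total = 0
    bifurcated = 0
    n_snap = len(ei.snapshots)
    for k in range(n_snap):
        donor_counts = Counter()
        recs_k = []
        for i in range(len(ei.residues)):
            for r in ei.records[i][k] or ():
                if r.nci_type == "NH_bb":
                    donor = (r.partner_residue_id, r.partner_atoms[0])
                    donor_counts[donor] += 1
                    recs_k.append(donor)
        for donor in recs_k:
            total += 1
            if donor_counts[donor] >= 2:
                bifurcated += 1
    if total == 0:
        return None
    return bifurcated / total


def unique_bond_bifurcation_fraction(ei: EnsembleInventory) -> float | None:
    """Variant denominator: unique (donor, acceptor) bonds over the whole
    ensemble rather than residue-step records."""
    if ei.records is None:
        raise ValueError("ensemble lacks stored records")
    bonds = set()
    donors = Counter()
    for k in range(len(ei.snapshots)):
        for i, rid in enumerate(ei.residues):
            for r in ei.records[i][k] or ():
                if r.nci_type == "NH_bb":
                    key = (rid, r.partner_residue_id, r.partner_atoms[0])
                    if key not in bonds:
                        bonds.add(key)
    if not bonds:
        return None
    for acceptor, donor_rid, donor_atom in bonds:
        donors[(donor_rid, donor_atom)] += 1
    bifurcated = sum(
        1
        for acceptor, donor_rid, donor_atom in bonds
        if donors[(donor_rid, donor_atom)] >= 2
    )
    return bifurcated / len(bonds)


def sequence_profile(
    hits: list, structure: Structure, flank: int = 3
) -> pd.DataFrame:
    """Amino-acid frequency table around motif anchor residues, positions
    -flank..+flank; frequencies sum to 1 within each populated position."""
    tallies = {p: Counter() for p in range(-flank, flank + 1)}
    order = {r.residue_id: i for i, r in enumerate(structure.residues)}
    for hit in hits:
        if hit.residue_id not in order:
            continue
        i = order[hit.residue_id]
        for p in range(-flank, flank + 1):
            j = i + p
            if 0 <= j < len(structure.residues):
                r = structure.residues[j]
                if r.chain_id == hit.residue_id[0]:
                    tallies[p][r.name] += 1
    rows = []
    for p in range(-flank, flank + 1):
        total = sum(tallies[p].values())
        for aa, c in sorted(tallies[p].items()):
            rows.append(
                {
                    "position": p,
                    "res_name": aa,
                    "count": c,
                    "frequency": c / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["position", "res_name", "count", "frequency"])


def subvdw_scan(
    structure: Structure,
    residue_ids: list,
    cutoff: float = SUBVDW_OH_CUTOFF,
) -> pd.DataFrame:
    """For 1-count residues, distances from the carbonyl O to the same
    residue's amide H and to the next residue's Ha, with sub-vdW flags.
    Glycine contributes the closer of its two Ha."""
    rows = []
    for rid in residue_ids:
        res = structure.residue(rid)
        if res is None:
            continue
        o = res.atom("O")
        entry = {
            "chain": rid[0],
            "res_seq": rid[1],
            "d_O_HN_same": float("nan"),
            "subvdw_HN": None,
            "d_O_HA_next": float("nan"),
            "subvdw_HA": None,
        }
        if o is not None:
            h = res.atom("H")
            if h is not None:
                d = distance(o.xyz, h.xyz)
                entry["d_O_HN_same"] = round(d, 3)
                entry["subvdw_HN"] = bool(d < cutoff)
            nxt = structure.successor(res)
            if nxt is not None:
                has = [
                    a for a in nxt.atoms if a.name in ("HA", "HA2", "HA3")
                ]
                if has:
                    d = min(distance(o.xyz, a.xyz) for a in has)
                    entry["d_O_HA_next"] = round(d, 3)
                    entry["subvdw_HA"] = bool(d < cutoff)
        rows.append(entry)
    return pd.DataFrame(
        rows,
        columns=[
            "chain",
            "res_seq",
            "d_O_HN_same",
            "subvdw_HN",
            "d_O_HA_next",
            "subvdw_HA",
        ],
    )


def hits_to_rows(hits: list) -> list:
    return [
        {
            "chain": h.residue_id[0],
            "res_seq": h.residue_id[1],
            "motif": h.motif,
            "occupancy": round(h.occupancy, 4),
            "snapshots_matching": h.snapshots_matching,
            "ss_class": h.ss_class,
            "little_h": h.little_h,
            "helix_terminus": h.helix_terminus,
            "modal_combo": "+".join(h.modal_combo),
        }
        for h in hits
    ]
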