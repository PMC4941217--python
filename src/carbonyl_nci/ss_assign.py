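"""Secondary-structure assignment from backbone hydrogen bonding.

A Kabsch-Sander-style electrostatic model scores each candidate
N-H...O=C backbone hydrogen bond,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond assigned when E < -0.5 kcal/mol. From the resulting bond map,
n-turns (i -> i+3, i+4, i+5) define helices (two consecutive turns of the
same type), inter-strand bonds define parallel/antiparallel bridges and
ladders, and remaining turn positions and tight Ca-trace bends fill in
turn/bend labels. Raw labels follow the DSSP alphabet (H, G, I, E, B, T, S)
and collapse into six classes: alpha-helix, beta-strand (E and B merged),
3-10/pi-helix (G and I merged), turn, bend, and none.

The first and last helical turn of each helix segment are additionally
flagged ("little h"), the context in which terminal capping motifs live.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .geometry import angle, distance
from .structure_io import Structure

KS_Q1Q2_F = 0.084 * 332.0  # electrostatic prefactor, kcal/mol * A
KS_EMAX = -0.5  # hydrogen-bond energy cutoff, kcal/mol
NO_BOND = float("inf")

BEND_VERTEX_ANGLE_MAX = 110.0  # Ca(i-2)-Ca(i)-Ca(i+2) vertex angle, degrees

RAW_LABELS = ("H", "G", "I", "E", "B", "T", "S", "-")

COLLAPSE = {
    "H": "alpha_helix",
    "E": "beta_strand",
    "B": "beta_strand",
    "G": "three10_pi",
    "I": "three10_pi",
    "T": "turn",
    "S": "bend",
    "-": "none",
}

SS_CLASSES = ("alpha_helix", "beta_strand", "three10_pi", "turn", "bend", "none")


@dataclass
class SSLabel:
    residue_id: tuple
    raw: str
    little_h: bool = False
    #: for helical residues: "N", "C", "NC" (both/short helix) or ""
    helix_terminus: str = ""

    @property
    def collapsed(self) -> str:
        return COLLAPSE[self.raw]


def ks_energy(donor_res, acceptor_res) -> float:
    """Kabsch-Sander hydrogen-bond energy for donor N-H against acceptor
    C=O, in kcal/mol. Returns +inf when the donor has no amide H (proline,
    N-terminus) or atoms are missing."""
    if donor_res is None or acceptor_res is None:
        return NO_BOND
    if donor_res.name == "PRO":
        return NO_BOND
    n = donor_res.atom("N")
    h = donor_res.atom("H")
    c = acceptor_res.atom("C")
    o = acceptor_res.atom("O")
    if n is None or h is None or c is None or o is None:
        return NO_BOND
    r_on = distance(o.xyz, n.xyz)
    r_ch = distance(c.xyz, h.xyz)
    r_oh = distance(o.xyz, h.xyz)
    r_cn = distance(c.xyz, n.xyz)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return NO_BOND  # colliding atoms: not a meaningful bond
    return KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_map(s: Structure) -> set:
    """Set of (acceptor index, donor index) pairs: CO(a) accepts NH(d).
    Indices are positions in s.residues."""
    res = s.residues
    n = len(res)
    coords = np.array(
        [r.atom("CA").xyz if r.atom("CA") else [1e9] * 3 for r in res]
    )
    bonds = set()
    for a in range(n):
        for d in range(n):
            if a == d:
                continue
            # CA-CA distance screen (as in the original algorithm, 9 A)
            if np.linalg.norm(coords[a] - coords[d]) > 9.0:
                continue
            # exclude the amide of the same peptide unit
            if res[d].chain_id == res[a].chain_id and res[d].res_seq == res[a].res_seq + 1:
                continue
            if ks_energy(res[d], res[a]) < KS_EMAX:
                bonds.add((a, d))
    return bonds


def assign_ss(s: Structure) -> list:
    """Per-residue raw and collapsed secondary-structure labels."""
    res = s.residues
    n = len(res)
    bonds = _hbond_map(s)

    def same_chain(i, j):
        return 0 <= i < n and 0 <= j < n and res[i].chain_id == res[j].chain_id

    def turn_at(i, k):
        return same_chain(i, i + k) and (i, i + k) in bonds

    raw = ["-"] * n

    # helices: two consecutive n-turns of the same type
    helix4 = [False] * n
    for i in range(n):
        if turn_at(i - 1, 4) and turn_at(i, 4):
            for j in range(i, min(i + 4, n)):
                helix4[j] = True
    helix3 = [False] * n
    for i in range(n):
        if turn_at(i - 1, 3) and turn_at(i, 3):
            for j in range(i, min(i + 3, n)):
                helix3[j] = True
    helix5 = [False] * n
    for i in range(n):
        if turn_at(i - 1, 5) and turn_at(i, 5):
            for j in range(i, min(i + 5, n)):
                helix5[j] = True

    # bridges
    def hb(a, d):
        return (a, d) in bonds

    bridge = [None] * n  # "P" or "A"
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3 and res[i].chain_id == res[j].chain_id:
                continue
            if i == j:
                continue
            par = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if par or anti:
                bridge[i] = "P" if par and not anti else "A"

    # ladders: a bridge with a bridged sequence neighbour -> E, isolated -> B
    for i in range(n):
        if bridge[i]:
            neighbour = (i > 0 and bridge[i - 1]) or (i + 1 < n and bridge[i + 1])
            raw[i] = "E" if neighbour else "B"

    # helix priority: H beats strand labels, then G, I
    for i in range(n):
        if helix4[i]:
            raw[i] = "H"
    for i in range(n):
        if helix3[i] and raw[i] == "-":
            raw[i] = "G"
    for i in range(n):
        if helix5[i] and raw[i] == "-":
            raw[i] = "I"

    # turns: any residue within an n-turn span not already structured
    for i in range(n):
        for k in (3, 4, 5):
            if turn_at(i, k):
                for j in range(i + 1, min(i + k, n)):
                    if raw[j] == "-":
                        raw[j] = "T"

    # bends: tight Ca-trace kinks
    for i in range(2, n - 2):
        if raw[i] != "-":
            continue
        if not (same_chain(i - 2, i) and same_chain(i, i + 2)):
            continue
        ca0, ca1, ca2 = (
            res[i - 2].atom("CA"),
            res[i].atom("CA"),
            res[i + 2].atom("CA"),
        )
        if ca0 is None or ca1 is None or ca2 is None:
            continue
        if angle(ca0.xyz, ca1.xyz, ca2.xyz) < BEND_VERTEX_ANGLE_MAX:
            raw[i] = "S"

    labels = [SSLabel(residue_id=res[i].residue_id, raw=raw[i]) for i in range(n)]
    _flag_little_h(labels)
    return labels


def _flag_little_h(labels: list) -> None:
    """Mark the first and last 4-residue turn of every helix (H) segment and
    record which terminus each helical residue is nearer to."""
    n = len(labels)
    i = 0
    while i < n:
        if labels[i].raw != "H":
            i += 1
            continue
        j = i
        while j < n and labels[j].raw == "H":
            j += 1
        seg = range(i, j)
        length = j - i
        for k in seg:
            if k < i + 4 or k >= j - 4:
                labels[k].little_h = True
            if length <= 8:
                labels[k].helix_terminus = "NC"
            elif k - i < (length // 2):
                labels[k].helix_terminus = "N"
            else:
                labels[k].helix_terminus = "C"
        i = j


def collapse(labels: list) -> dict:
    """Counts per collapsed class; totals conserve the residue count."""
    counts = Counter(lab.collapsed for lab in labels)
    return {cls: counts.get(cls, 0) for cls in SS_CLASSES}


def labels_to_rows(labels: list) -> list:
    return [
        {
            "chain": lab.residue_id[0],
            "res_seq": lab.residue_id[1],
            "raw": lab.raw,
            "collapsed": lab.collapsed,
            "little_h": lab.little_h,
        }
        for lab in labels
    ]


def read_dssp_labels(path, structure: Structure) -> list:
    """Import an external DSSP output file as SSLabel overrides (classic
    .dssp column format; only chain, residue number and the summary letter
    are read)."""
    labels = {r.residue_id: "-" for r in structure.residues}
    in_data = False
    for line in open(path):
        if line.startswith("  #  RESIDUE"):
            in_data = True
            continue
        if not in_data or len(line) < 17:
            continue
        try:
            res_seq = int(line[5:10])
        except ValueError:
            continue
        chain = line[11].strip()
        code = line[16].strip() or "-"
        if code not in COLLAPSE:
            code = "-"
        key = (chain, res_seq, "")
        if key in labels:
            labels[key] = code
    out = [
        SSLabel(residue_id=r.residue_id, raw=labels[r.residue_id])
        for r in structure.residues
    ]
    _flag_little_h(out)
    return out
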