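"""Statistics over snapshot ensembles of carbonyl-interaction inventories.

Counting conventions
--------------------
The unit of observation is the *residue-step*: one (residue, snapshot)
cell. Count distributions are reported in four modes:

static
    counts from a single reference structure only;
per_snapshot
    pooled over every residue-step of the ensemble;
modal
    one value per residue: the modal (most frequent) count along its
    snapshot series, ties broken to the smaller value;
modal_occupancy_filtered
    residue-steps pooled from only those residues that spend at least half
    of the ensemble at their modal count.

Combination tables tabulate the unordered multiset of interaction types a
carbonyl makes, resolved by collapsed secondary-structure class. The NCI
density is the mean reported count per residue-step; hydrogen bonds per
residue counts only traditional (N-H, O-H, water) donors.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nci_classify import ResidueInventory, STRONG_HBOND_TYPES

COUNT_MODES = ("static", "per_snapshot", "modal", "modal_occupancy_filtered")


@dataclass
class CountDistribution:
    mode_of_computation: str
    histogram: dict  # count value -> percentage
    n: int  # number of pooled observations

    def __post_init__(self):
        if self.histogram:
            total = sum(self.histogram.values())
            if abs(total - 100.0) > 0.01:
                raise ValueError(f"histogram mass {total} != 100")


@dataclass
class EnsembleInventory:
    """Residue x snapshot matrix of reported counts plus the per-cell
    interaction multisets and per-residue secondary structure."""

    residues: list  # ordered residue ids
    snapshots: list  # ordered snapshot indices
    counts: np.ndarray  # (n_res, n_snap) int
    combos: list  # list (per residue) of list (per snapshot) of type-tuples
    records: list = None  # same layout, lists of NCIRecord (optional)
    ss: dict = field(default_factory=dict)  # residue id -> collapsed class
    ss_labels: dict = field(default_factory=dict)  # residue id -> SSLabel

    @classmethod
    def from_snapshots(cls, snapshot_inventories: list, ss_labels=None):
        """Build from a list of per-snapshot inventory lists (one
        ``ResidueInventory`` list per snapshot, identical residue sets)."""
        if not snapshot_inventories:
            raise ValueError("no snapshots")
        first = [inv.residue_id for inv in snapshot_inventories[0]]
        for k, snap in enumerate(snapshot_inventories):
            ids = [inv.residue_id for inv in snap]
            if ids != first:
                missing = set(first) ^ set(ids)
                raise ValueError(
                    f"snapshot {k} residue set mismatch: {sorted(missing)[:5]}"
                )
        n_res, n_snap = len(first), len(snapshot_inventories)
        counts = np.zeros((n_res, n_snap), dtype=int)
        combos = [[None] * n_snap for _ in range(n_res)]
        records = [[None] * n_snap for _ in range(n_res)]
        for k, snap in enumerate(snapshot_inventories):
            for i, inv in enumerate(snap):
                counts[i, k] = inv.reported_count
                combos[i][k] = inv.combo
                records[i][k] = inv.records
        ss = {}
        labels = {}
        if ss_labels is not None:
            for lab in ss_labels:
                ss[lab.residue_id] = lab.collapsed
                labels[lab.residue_id] = lab
        return cls(
            residues=first,
            snapshots=list(range(n_snap)),
            counts=counts,
            combos=combos,
            records=records,
            ss={rid: ss.get(rid, "none") for rid in first},
            ss_labels=labels,
        )

    def series(self, residue_id) -> np.ndarray:
        return self.counts[self.residues.index(residue_id)]


def modal_count(series) -> int:
    """Most frequent value; ties break to the smallest tied value."""
    series = list(series)
    if not series:
        raise ValueError("empty series")
    freq = Counter(series)
    best = max(freq.values())
    return min(v for v, c in freq.items() if c == best)


def occupancy_at_mode(series) -> float:
    """Fraction of the series spent at its modal count, in (0, 1]."""
    series = list(series)
    if not series:
        raise ValueError("empty series")
    m = modal_count(series)
    return sum(1 for v in series if v == m) / len(series)


def _histogram(values, mode, n=None) -> CountDistribution:
    values = list(values)
    if not values:
        return CountDistribution(mode_of_computation=mode, histogram={}, n=0)
    freq = Counter(values)
    total = len(values)
    hist = {int(v): 100.0 * c / total for v, c in sorted(freq.items())}
    return CountDistribution(mode_of_computation=mode, histogram=hist, n=total)


def distributions(ei: EnsembleInventory, static_inv: list) -> dict:
    """The four count distributions (percent of observations at each count).

    ``static_inv`` is the inventory of the reference structure; it must
    cover the same residues as the ensemble.
    """
    static_ids = [inv.residue_id for inv in static_inv]
    if set(static_ids) != set(ei.residues):
        missing = set(static_ids) ^ set(ei.residues)
        raise ValueError(f"static/ensemble residue mismatch: {sorted(missing)[:5]}")
    static_counts = [inv.reported_count for inv in static_inv]
    per_snapshot = ei.counts.ravel()
    modal = [modal_count(ei.counts[i]) for i in range(len(ei.residues))]
    occ_ok = [
        i
        for i in range(len(ei.residues))
        if occupancy_at_mode(ei.counts[i]) >= 0.5
    ]
    filtered = ei.counts[occ_ok].ravel() if occ_ok else []
    return {
        "static": _histogram(static_counts, "static"),
        "per_snapshot": _histogram(per_snapshot, "per_snapshot"),
        "modal": _histogram(modal, "modal"),
        "modal_occupancy_filtered": _histogram(
            filtered, "modal_occupancy_filtered"
        ),
    }


def combo_frequencies(
    ei: EnsembleInventory,
    n_target: int,
    occupancy_filter: bool = False,
    min_percent: float = 0.0,
) -> pd.DataFrame:
    """Frequencies of interaction-type combinations at a given count.

    For ``occupancy_filter=True`` (the convention for the under- and
    over-satisfied counts 1 and 3) only residues whose *modal* count equals
    ``n_target`` with occupancy >= 0.5 contribute, and each contributes its
    modal combination once. Otherwise (the count-2 convention) all
    residue-steps with that count are pooled.

    Returns a tidy frame with columns ss_class, combo, percent; percentages
    normalise within each secondary-structure class.
    """
    tallies: dict = {}
    if occupancy_filter:
        for i, rid in enumerate(ei.residues):
            series = ei.counts[i]
            if modal_count(series) != n_target:
                continue
            if occupancy_at_mode(series) < 0.5:
                continue
            combos_at_mode = [
                ei.combos[i][k]
                for k in range(len(series))
                if series[k] == n_target
            ]
            combo = Counter(combos_at_mode).most_common(1)[0][0]
            tallies.setdefault(ei.ss.get(rid, "none"), Counter())[combo] += 1
    else:
        for i, rid in enumerate(ei.residues):
            cls = ei.ss.get(rid, "none")
            for k in range(ei.counts.shape[1]):
                if ei.counts[i, k] == n_target:
                    tallies.setdefault(cls, Counter())[ei.combos[i][k]] += 1
    rows = []
    for cls, counter in tallies.items():
        total = sum(counter.values())
        for combo, c in sorted(counter.items()):
            pct = 100.0 * c / total
            if pct >= min_percent:
                rows.append(
                    {
                        "ss_class": cls,
                        "combo": "+".join(combo) if combo else "(none)",
                        "count": c,
                        "percent": pct,
                    }
                )
    return pd.DataFrame(rows, columns=["ss_class", "combo", "count", "percent"])


def nci_density(ei: EnsembleInventory, ss_class: str | None = None) -> float:
    """Mean reported count per residue-step, optionally restricted to one
    collapsed secondary-structure class."""
    if ss_class is None:
        return float(ei.counts.mean())
    rows = [i for i, rid in enumerate(ei.residues) if ei.ss.get(rid) == ss_class]
    if not rows:
        return float("nan")
    return float(ei.counts[rows].mean())


def hbonds_per_residue(ei: EnsembleInventory, ss_class: str | None = None) -> float:
    """Mean number of traditional hydrogen bonds (N-H, O-H and water
    donors; C-H donors and n->pi* excluded) per residue-step. Water-only
    carbonyls count their reported two water bonds."""
    rows = range(len(ei.residues))
    if ss_class is not None:
        rows = [i for i in rows if ei.ss.get(ei.residues[i]) == ss_class]
        if not rows:
            return float("nan")
    total = 0
    cells = 0
    for i in rows:
        for k in range(ei.counts.shape[1]):
            combo = ei.combos[i][k]
            total += sum(1 for t in combo if t in STRONG_HBOND_TYPES)
            cells += 1
    return total / cells if cells else float("nan")


def class_count_table(ei: EnsembleInventory, max_count: int = 6) -> pd.DataFrame:
    """Secondary-structure class x count summary: mean number of residues
    (over snapshots) at each count, with the count of residues whose modal
    value is x alongside (columns ``mean_x`` and ``modal_x``)."""
    rows = []
    classes = sorted(set(ei.ss.values()))
    for cls in classes:
        idx = [i for i, rid in enumerate(ei.residues) if ei.ss.get(rid) == cls]
        if not idx:
            continue
        sub = ei.counts[idx]
        row = {"ss_class": cls, "total_residues": len(idx)}
        modal = [modal_count(sub[i]) for i in range(len(idx))]
        for x in range(max_count + 1):
            row[f"mean_{x}"] = float((sub == x).sum(axis=0).mean())
            row[f"modal_{x}"] = int(sum(1 for m in modal if m == x))
        rows.append(row)
    return pd.DataFrame(rows)


def ensemble_report(ei: EnsembleInventory, static_inv: list) -> dict:
    """Full JSON-serialisable statistics bundle."""
    dists = distributions(ei, static_inv)
    report = {
        "n_residues": len(ei.residues),
        "n_snapshots": len(ei.snapshots),
        "distributions": {
            mode: {"histogram": d.histogram, "n": d.n}
            for mode, d in dists.items()
        },
        "nci_density": {
            "all": nci_density(ei),
            **{
                cls: nci_density(ei, cls)
                for cls in sorted(set(ei.ss.values()))
            },
        },
        "hbonds_per_residue": {
            "all": hbonds_per_residue(ei),
            **{
                cls: hbonds_per_residue(ei, cls)
                for cls in sorted(set(ei.ss.values()))
            },
        },
        "combo_frequencies": {
            "n2_per_snapshot": combo_frequencies(ei, 2).to_dict("records"),
            "n1_sustained": combo_frequencies(
                ei, 1, occupancy_filter=True
            ).to_dict("records"),
            "n3_sustained": combo_frequencies(
                ei, 3, occupancy_filter=True
            ).to_dict("records"),
        },
        "class_count_table": class_count_table(ei).to_dict("records"),
    }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
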