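"""Repertoire-level statistics: gene usage, CDR3 length distribution,
shared rearrangements, per-cell summaries and group comparisons.

The rearrangement identity used for sharing/multi-pattern counting is the
``pattern_key``: gene-level (allele-collapsed) V|D|J calls plus the exact
junction nucleotide sequence — two cells share a clone only when the
junction matches byte-for-byte.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .annotate import VDJAssignment
from .germline import family_of, gene_of

__all__ = [
    "CellRecord", "build_cells", "usage_frequencies",
    "Cdr3Distribution", "cdr3_distribution",
    "SharedPattern", "find_shared_patterns",
    "cell_summaries", "mann_whitney_u", "compare_shm_groups", "significance_stars",
]


# ---------------------------------------------------------------------------
# cells

@dataclass
class CellRecord:
    """One cell's assignments, expressed isotypes and distinct patterns."""

    cell_id: str
    individual_id: str
    group: str
    assignments: list[VDJAssignment] = field(default_factory=list)

    @property
    def isotypes_expressed(self) -> set[str]:
        return {a.read.isotype for a in self.assignments}

    @property
    def n_functional_patterns(self) -> int:
        return len({a.pattern_key for a in self.assignments
                    if a.productive and a.pattern_key is not None})


def build_cells(assignments: list[VDJAssignment]) -> list[CellRecord]:
    """Group assignments into CellRecords (sorted by cell_id)."""
    cells: dict[str, CellRecord] = {}
    for a in assignments:
        cid = a.read.cell_id
        if cid not in cells:
            cells[cid] = CellRecord(
                cell_id=cid,
                individual_id=a.read.individual_id,
                group=a.read.group,
            )
        cells[cid].assignments.append(a)
    return [cells[c] for c in sorted(cells)]


# ---------------------------------------------------------------------------
# usage

def usage_frequencies(assignments: list[VDJAssignment], level: str = "family",
                      by_group: bool = False,
                      dedup_per_cell: bool = False) -> pd.DataFrame:
    """V/D/J usage counts and frequencies at family or gene level.

    Frequencies are per segment type and (optionally) cohort; reads with
    no D call are excluded from the D denominator and reported under the
    ``n_unassigned`` column of a ``D`` pseudo-row. ``dedup_per_cell``
    collapses to unique (cell, isotype, pattern) before counting; the
    default counts every sequence, matching per-sequence reporting.
    """
    if level not in ("family", "gene"):
        raise ValueError("level must be 'family' or 'gene'")
    if dedup_per_cell:
        seen = set()
        kept = []
        for a in assignments:
            key = (a.read.cell_id, a.read.isotype, a.pattern_key)
            if key not in seen:
                seen.add(key)
                kept.append(a)
        assignments = kept
    rows = []
    for a in assignments:
        grp = a.read.group if by_group else "all"
        for stype, seg_id in (("V", a.v.segment_id),
                              ("D", a.d.segment_id if a.d else None),
                              ("J", a.j.segment_id)):
            if seg_id is None:
                rows.append({"group": grp, "segment_type": stype, "category": None})
                continue
            cat = family_of(seg_id) if level == "family" else gene_of(seg_id)
            rows.append({"group": grp, "segment_type": stype, "category": cat})
    if not rows:
        return pd.DataFrame(
            columns=["group", "segment_type", "category", "count", "frequency",
                     "n_unassigned"])
    df = pd.DataFrame(rows)
    out = []
    for (grp, stype), sub in df.groupby(["group", "segment_type"], sort=True):
        n_unassigned = int(sub["category"].isna().sum())
        counts = sub["category"].value_counts().sort_index()
        total = int(counts.sum())
        for cat, cnt in counts.items():
            out.append({
                "group": grp, "segment_type": stype, "category": cat,
                "count": int(cnt), "frequency": cnt / total,
                "n_unassigned": n_unassigned,
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# CDR3 length distribution

@dataclass
class Cdr3Distribution:
    lengths: pd.Series                 # index: length (nt), values: counts
    amplitude: float | None
    mean: float | None
    sd: float | None
    r_squared: float | None

    @property
    def fitted(self) -> bool:
        return self.r_squared is not None


def _gauss(x: np.ndarray, a: float, mu: float, sd: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))


def cdr3_distribution(lengths: list[int] | np.ndarray) -> Cdr3Distribution:
    """Integer CDR3-length histogram with a least-squares Gaussian fit.

    The histogram is binned on the lattice the data actually occupy
    (bin step = gcd of pairwise length differences; productive-only
    repertoires occupy the multiple-of-3 lattice), over the observed
    range, zeros included. The fit is A*exp(-(x-mu)^2 / 2 sigma^2),
    initialized at (max count, sample mean, sample sd), and R^2 is
    1 - SS_res/SS_tot against the mean-count baseline. With fewer than
    4 distinct lengths the fit is refused and r_squared is None.
    """
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        return Cdr3Distribution(pd.Series(dtype=int), None, None, None, None)
    lo, hi = int(lengths.min()), int(lengths.max())
    uniq = np.unique(lengths)
    step = 0
    for u in uniq[1:]:
        step = math.gcd(step, int(u - uniq[0]))
    step = step or 1
    xs = np.arange(lo, hi + 1, step)
    counts = np.array([(lengths == x).sum() for x in xs])
    hist = pd.Series(counts, index=xs, name="count")
    if uniq.size < 4:
        return Cdr3Distribution(hist, None, None, None, None)
    p0 = (float(counts.max()), float(lengths.mean()), float(lengths.std() or 1.0))
    try:
        popt, _ = optimize.curve_fit(
            _gauss, xs.astype(float), counts.astype(float), p0=p0,
            bounds=([0.0, lo - (hi - lo), 1e-6], [np.inf, hi + (hi - lo), np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return Cdr3Distribution(hist, None, None, None, None)
    resid = counts - _gauss(xs.astype(float), *popt)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else None
    return Cdr3Distribution(hist, float(popt[0]), float(popt[1]), float(popt[2]), r2)


# ---------------------------------------------------------------------------
# shared rearrangements

@dataclass
class SharedPattern:
    pattern_key: str
    members: list[tuple[str, str]]     # (cell_id, individual_id), sorted
    cross_individual: bool


def find_shared_patterns(cells: list[CellRecord],
                         productive_only: bool = True) -> list[SharedPattern]:
    """Identical rearrangements (same pattern_key) present in >= 2 cells.

    Deterministically ordered by pattern_key; invariant to input cell
    order. ``cross_individual`` marks patterns spanning >= 2 individuals.
    """
    members: dict[str, set[tuple[str, str]]] = {}
    for cell in cells:
        for a in cell.assignments:
            if a.pattern_key is None:
                continue
            if productive_only and not a.productive:
                continue
            members.setdefault(a.pattern_key, set()).add(
                (cell.cell_id, cell.individual_id))
    out = []
    for key in sorted(members):
        cells_set = members[key]
        if len(cells_set) < 2:
            continue
        individuals = {ind for _, ind in cells_set}
        out.append(SharedPattern(
            pattern_key=key,
            members=sorted(cells_set),
            cross_individual=len(individuals) >= 2,
        ))
    return out


# ---------------------------------------------------------------------------
# per-cell summaries

def cell_summaries(cells: list[CellRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group co-expression and multi-pattern fractions + per-cell listing.

    Co-expression: >= 2 distinct isotypes in one cell. Multi-pattern:
    >= 2 distinct productive pattern_keys. Returns (per-group summary,
    per-cell table); the summary includes an ``all`` row and a pooled
    ``patients`` row (every non-HC group) when HC is present.
    """
    per_cell = pd.DataFrame([{
        "cell_id": c.cell_id,
        "individual_id": c.individual_id,
        "group": c.group,
        "n_sequences": len(c.assignments),
        "isotypes": ",".join(sorted(c.isotypes_expressed)),
        "n_isotypes": len(c.isotypes_expressed),
        "n_functional_patterns": c.n_functional_patterns,
        "coexpressing": len(c.isotypes_expressed) >= 2,
        "multi_pattern": c.n_functional_patterns >= 2,
    } for c in cells])

    def _row(label: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        return {
            "group": label,
            "n_cells": n,
            "n_coexpressing": int(sub["coexpressing"].sum()),
            "fraction_coexpressing": sub["coexpressing"].mean() if n else np.nan,
            "n_multi_pattern": int(sub["multi_pattern"].sum()),
            "fraction_multi_pattern": sub["multi_pattern"].mean() if n else np.nan,
        }

    rows = [_row(g, sub) for g, sub in per_cell.groupby("group", sort=True)]
    if (per_cell["group"] == "HC").any() and (per_cell["group"] != "HC").any():
        rows.append(_row("patients", per_cell[per_cell["group"] != "HC"]))
    rows.append(_row("all", per_cell))
    return pd.DataFrame(rows), per_cell


# ---------------------------------------------------------------------------
# group comparisons

def mann_whitney_u(sample_a, sample_b) -> dict:
    """Two-sided Mann-Whitney U with tie-midrank handling.

    Exact p by enumeration of label assignments when n_a + n_b <= 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction. All-identical input is degenerate: p = 1.
    Returns {"U", "p_two_sided", "method"}.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    u_stat = float(sps.rankdata(pooled)[:a.size].sum() - a.size * (a.size + 1) / 2)
    if np.unique(pooled).size == 1:
        return {"U": u_stat, "p_two_sided": 1.0, "method": "degenerate"}
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        method = "normal_approx_tie_corrected"
    return {"U": float(res.statistic), "p_two_sided": min(float(res.pvalue), 1.0),
            "method": method}


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_shm_groups(values_by_group: dict[str, list[float]],
                       control_group: str = "HC",
                       holm_adjust: bool = False) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of SHM frequency, plus a
    pooled patients-vs-control row when the control group is present.

    No multiplicity adjustment by default (raw p-values with significance
    stars); ``holm_adjust`` adds a Holm-corrected column.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()
              if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        res = mann_whitney_u(groups[ga], groups[gb])
        rows.append({"group_a": ga, "group_b": gb,
                     "n_a": groups[ga].size, "n_b": groups[gb].size, **res})
    if control_group in groups and len(groups) > 2:
        pooled = np.concatenate([v for g, v in groups.items() if g != control_group])
        res = mann_whitney_u(pooled, groups[control_group])
        rows.append({"group_a": "patients", "group_b": control_group,
                     "n_a": pooled.size, "n_b": groups[control_group].size, **res})
    df = pd.DataFrame(rows)
    df["stars"] = df["p_two_sided"].map(significance_stars)
    if holm_adjust:
        p = df["p_two_sided"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(p) - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
    return df
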