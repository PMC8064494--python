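"""Somatic hypermutation quantification and AID hotspot-motif analysis.

SHM is quantified as substitutions per germline-aligned nucleotide over
the region from FR2 (on the V) through the end of the aligned J, the
stretch the nested FR2/JH amplification actually covers. A sequence is
"mutated" at >= 2% mutation frequency (< 98% germline homology). AID
hotspots are the degenerate 4-mers RGYW and its reverse-complement form
WRCY (R = A/G, Y = C/T, W = A/T), scanned on the germline sequence: the
motif a mutation hit may no longer exist in the mutated read. A hotspot
mutation ratio (share of mutations falling in hotspot positions) above
25% is the antigen-driven-selection criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import VDJAssignment
from .germline import GermlineReference

__all__ = [
    "MutationProfile", "find_hotspot_windows", "hotspot_mask",
    "mutation_profile", "profile_table", "shm_by_class", "pooled_hotspot_ratio",
    "MUTATED_FREQ_THRESHOLD", "ANTIGEN_SELECTED_RATIO",
]

MUTATED_FREQ_THRESHOLD = 0.02   # inclusive: "2% or more mutations"
ANTIGEN_SELECTED_RATIO = 0.25   # strict: "above 25%"

_R = set("AG")
_Y = set("CT")
_W = set("AT")


def _is_rgyw(w: str) -> bool:
    return w[0] in _R and w[1] == "G" and w[2] in _Y and w[3] in _W


def _is_wrcy(w: str) -> bool:
    return w[0] in _W and w[1] in _R and w[2] == "C" and w[3] in _Y


def find_hotspot_windows(germline_seq: str,
                         motifs: tuple[str, ...] = ("RGYW", "WRCY")
                         ) -> list[tuple[int, int]]:
    """All 4-mer windows of the germline matching RGYW and/or WRCY.

    Both motifs are scanned on the given strand (WRCY is the
    reverse-complement reading of RGYW, i.e. the same AID target on the
    opposite strand). Overlapping windows are all returned.
    """
    checks = []
    if "RGYW" in motifs:
        checks.append(_is_rgyw)
    if "WRCY" in motifs:
        checks.append(_is_wrcy)
    windows = []
    for i in range(len(germline_seq) - 3):
        w = germline_seq[i:i + 4]
        if any(c(w) for c in checks):
            windows.append((i, i + 4))
    return windows


def hotspot_mask(germline_seq: str,
                 motifs: tuple[str, ...] = ("RGYW", "WRCY")) -> np.ndarray:
    """Boolean per-position array: covered by >= 1 hotspot window."""
    mask = np.zeros(len(germline_seq), dtype=bool)
    for s, e in find_hotspot_windows(germline_seq, motifs):
        mask[s:e] = True
    return mask


@dataclass
class MutationProfile:
    read_id: str
    isotype: str
    group: str
    region_evaluated: str        # "FR2->JH" or "partial(<start>)->JH"
    aligned_length: int
    mutation_count: int
    mutations_in_hotspots: int
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.mutations_in_hotspots <= self.mutation_count
                <= self.aligned_length):
            raise ValueError(
                f"{self.read_id}: inconsistent mutation counts "
                f"({self.mutations_in_hotspots}/{self.mutation_count}/"
                f"{self.aligned_length})"
            )

    @property
    def mutation_frequency(self) -> float:
        return self.mutation_count / self.aligned_length

    @property
    def is_mutated(self) -> bool:
        return self.mutation_frequency >= MUTATED_FREQ_THRESHOLD

    @property
    def hotspot_ratio(self) -> float | None:
        if self.mutation_count == 0:
            return None
        return self.mutations_in_hotspots / self.mutation_count

    @property
    def antigen_selected(self) -> bool | None:
        r = self.hotspot_ratio
        return None if r is None else r > ANTIGEN_SELECTED_RATIO


def mutation_profile(asg: VDJAssignment, reference: GermlineReference,
                     motifs: tuple[str, ...] = ("RGYW", "WRCY")
                     ) -> MutationProfile:
    """Count substitutions and hotspot hits over FR2 -> end of aligned J.

    Only germline-aligned positions enter numerator and denominator; the
    N-insert positions (np1/np2) are non-templated and never counted.
    Mutations in the D segment count, and D hotspots are scanned like V
    and J. When the V alignment starts after FR2 the profile is flagged
    partial and the region starts at the first aligned V position.
    """
    v_seg = reference[asg.v.segment_id]
    assert v_seg.regions is not None
    fr2_start = v_seg.regions["FR2"][0]
    v_start_aligned = asg.v.ref_interval[0]
    partial = v_start_aligned > fr2_start
    region_start = max(fr2_start, v_start_aligned)

    aligned = 0
    mutations = 0
    hotspot_hits = 0
    segments = [(asg.v, region_start)]
    if asg.d is not None:
        segments.append((asg.d, 0))
    segments.append((asg.j, 0))
    for al, lo in segments:
        mask = hotspot_mask(reference[al.segment_id].sequence, motifs)
        in_region = al.pairs_ref >= lo
        aligned += int(in_region.sum())
        mm = [p for p in al.mismatch_positions if p >= lo]
        mutations += len(mm)
        hotspot_hits += int(sum(bool(mask[p]) for p in mm))
    return MutationProfile(
        read_id=asg.read.read_id,
        isotype=asg.read.isotype,
        group=asg.read.group,
        region_evaluated="FR2->JH" if not partial else f"partial({region_start})->JH",
        aligned_length=aligned,
        mutation_count=mutations,
        mutations_in_hotspots=hotspot_hits,
        partial=partial,
    )


def profile_table(profiles: list[MutationProfile]) -> pd.DataFrame:
    """Per-read SHM table (one row per profile)."""
    return pd.DataFrame([{
        "read_id": p.read_id,
        "isotype": p.isotype,
        "group": p.group,
        "region_evaluated": p.region_evaluated,
        "aligned_length": p.aligned_length,
        "mutation_count": p.mutation_count,
        "mutation_frequency": p.mutation_frequency,
        "is_mutated": p.is_mutated,
        "mutations_in_hotspots": p.mutations_in_hotspots,
        "hotspot_ratio": p.hotspot_ratio,
        "antigen_selected": p.antigen_selected,
    } for p in profiles])


def shm_by_class(profiles: list[MutationProfile],
                 classes: tuple[str, ...] = ("IgD", "IgM", "IgA", "IgG", "IgE")
                 ) -> pd.DataFrame:
    """Per-isotype SHM summary: n, mean/median frequency, mutated and
    antigen-selected fractions (the latter among mutation_count > 0)."""
    rows = []
    for cls in classes:
        sub = [p for p in profiles if p.isotype == cls]
        if not sub:
            rows.append({"isotype": cls, "n": 0, "mean_frequency": np.nan,
                         "median_frequency": np.nan, "fraction_mutated": np.nan,
                         "fraction_antigen_selected": np.nan})
            continue
        freqs = np.array([p.mutation_frequency for p in sub])
        with_mut = [p for p in sub if p.mutation_count > 0]
        rows.append({
            "isotype": cls,
            "n": len(sub),
            "mean_frequency": float(freqs.mean()),
            "median_frequency": float(np.median(freqs)),
            "fraction_mutated": float(np.mean([p.is_mutated for p in sub])),
            "fraction_antigen_selected": (
                float(np.mean([p.antigen_selected for p in with_mut]))
                if with_mut else np.nan
            ),
        })
    return pd.DataFrame(rows)


def pooled_hotspot_ratio(profiles: list[MutationProfile]) -> float | None:
    """Alternative aggregate: all hotspot mutations / all mutations, pooled
    across sequences (the per-sequence average is the default reading)."""
    total = sum(p.mutation_count for p in profiles)
    if total == 0:
        return None
    return sum(p.mutations_in_hotspots for p in profiles) / total
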