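"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import itertools
import re

import numpy as np
from skbio import DNA
from skbio.alignment import pair_align


def sw_score_skbio(query: str, ref: str) -> int:
    """Optimal local alignment score via scikit-bio (independent of the
    biotite-backed implementation). gap_cost=(3,1) reproduces the package
    convention where a length-L gap costs 4 + (L-1)."""
    res = pair_align(DNA(query), DNA(ref), mode="local",
                     sub_score=(2.0, -2.0), gap_cost=(3.0, 1.0), max_paths=0)
    return int(res.score)


def sw_score_python(query: str, ref: str, match: int = 2, mismatch: int = -2,
                    gap_open: int = -4, gap_extend: int = -1) -> int:
    """Plain Gotoh local alignment (first gap position costs gap_open)."""
    n, m = len(query), len(ref)
    neg = -10**9
    h_prev = [0] * (m + 1)
    f_prev = [neg] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f_cur = [neg] * (m + 1)
        for j in range(1, m + 1):
            e_cur[j] = max(h_cur[j - 1] + gap_open, e_cur[j - 1] + gap_extend)
            f_cur[j] = max(h_prev[j] + gap_open, f_prev[j] + gap_extend)
            s = match if query[i - 1] == ref[j - 1] else mismatch
            h_cur[j] = max(0, h_prev[j - 1] + s, e_cur[j], f_cur[j])
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, f_prev = h_cur, f_cur
    return best


_RGYW = re.compile(r"(?=[AG]G[CT][AT])")
_WRCY = re.compile(r"(?=[AT][AG]C[CT])")


def hotspot_windows_regex(seq: str) -> list[tuple[int, int]]:
    """Regex oracle for RGYW/WRCY 4-mer windows (overlaps included)."""
    starts = {m.start() for m in _RGYW.finditer(seq)}
    starts |= {m.start() for m in _WRCY.finditer(seq)}
    return [(s, s + 4) for s in sorted(starts)]


def mann_whitney_exact_enum(a, b) -> tuple[float, float]:
    """(U, two-sided p) by enumerating all label assignments of the pooled
    sample (ties not supported)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"

    def u_of(sample_a, sample_b):
        return float(sum(1 for x in sample_a for y in sample_b if x > y))

    u_obs = u_of(a, b)
    center = n_a * len(b) / 2.0
    dev = abs(u_obs - center)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_of(sa, sb) - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
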