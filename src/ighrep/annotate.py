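"""V(D)J assignment, junction decomposition and productivity calling.

Given a rearranged IgH read and a germline reference, this module finds
the best-matching germline V, D and J segments, decomposes the junction
into trimmed termini and non-templated (N) inserts, extracts the
junction/CDR3, and classifies productivity (in-frame and stop-free).

Conventions
-----------
* Junction = 2nd-CYS codon of V through the J-TRP codon of J, inclusive;
  CDR3 = junction minus both anchor codons (so len(junction) = CDR3 + 6).
* Tie-breaking everywhere: higher score, then longer aligned length, then
  lexicographically smallest segment_id; surviving ties set ``ambiguous``.
* Input is assumed coding-strand; a reverse-complement rescue pass runs
  only when forward V assignment fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, Scoring, SegmentAlignment, align_local
from .germline import GermlineReference, GermlineSegment, gene_of

__all__ = [
    "QueryRead", "VDJAssignment", "AnnotateConfig",
    "assign_v", "assign_j", "assign_d",
    "decompose_junction", "call_productivity",
    "annotate_read", "annotate_reads", "airr_table", "reconstruct_span",
]

GROUPS = ("HC", "MN", "IgAN", "IN", "other")
ISOTYPES = ("IgA", "IgG", "IgM", "IgD", "IgE", "unknown")
_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class QueryRead:
    """One IgH amplicon with its cell/individual/group/isotype metadata."""

    read_id: str
    sequence: str
    cell_id: str = ""
    individual_id: str = ""
    group: str = "other"
    isotype: str = "unknown"

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 60:
            raise ValueError(f"{self.read_id}: read shorter than 60 nt")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: sequence must be uppercase ACGT(N)")


@dataclass(frozen=True)
class AnnotateConfig:
    scoring: Scoring = DEFAULT_SCORING
    v_min_ref_cov: int = 100     # nt of V reference that must be aligned
    j_min_aligned: int = 18      # nt of J that must be aligned
    d_min_run: int = 5           # contiguous exact matches required for a D call
    primer_trim_5p: int = 0
    primer_trim_3p: int = 0
    rc_rescue: bool = True


@dataclass
class VDJAssignment:
    """Full annotation of one read: segment calls, junction and productivity."""

    read: QueryRead
    v: SegmentAlignment
    j: SegmentAlignment
    d: SegmentAlignment | None
    n1: str
    n2: str
    trims: dict[str, int]
    junction_nt: str | None
    cdr3_nt: str | None
    cdr3_length: int | None
    in_frame: bool | None
    has_stop: bool | None
    productive: bool | None      # None when productivity is indeterminate
    rev_comp: bool = False

    @property
    def v_gene(self) -> str:
        return gene_of(self.v.segment_id)

    @property
    def d_gene(self) -> str:
        return gene_of(self.d.segment_id) if self.d is not None else ""

    @property
    def j_gene(self) -> str:
        return gene_of(self.j.segment_id)

    @property
    def pattern_key(self) -> str | None:
        """Canonical rearrangement identity: genes plus exact junction."""
        if self.junction_nt is None:
            return None
        return f"{self.v_gene}|{self.d_gene}|{self.j_gene}|{self.junction_nt}"


def _pick_best(candidates: list[SegmentAlignment]) -> SegmentAlignment | None:
    """Deterministic winner: score desc, aligned length desc, id asc."""
    if not candidates:
        return None
    ranked = sorted(
        candidates,
        key=lambda a: (-a.score, -a.aligned_length, a.segment_id),
    )
    best = ranked[0]
    if len(ranked) > 1:
        second = ranked[1]
        if (second.score, second.aligned_length) == (best.score, best.aligned_length):
            best.ambiguous = True
    return best


def assign_v(query: str, reference: GermlineReference,
             config: AnnotateConfig = AnnotateConfig()) -> SegmentAlignment | None:
    """Best-matching germline V, or None when no V covers the floor."""
    candidates = []
    for seg in reference.of_type("V"):
        al = align_local(query, seg.sequence, config.scoring, seg.segment_id)
        # coverage floor is enforced on the score: a chance alignment can
        # span (and even gap-free-cover) >= 100 reference nt, but cannot
        # reach the score of 100 cleanly matched positions
        if al is None:
            continue
        if (al.aligned_length >= config.v_min_ref_cov
                and al.score >= config.scoring.match * config.v_min_ref_cov):
            candidates.append(al)
    return _pick_best(candidates)


def assign_j(query: str, reference: GermlineReference,
             v_alignment: SegmentAlignment,
             config: AnnotateConfig = AnnotateConfig()) -> SegmentAlignment | None:
    """Best-matching J in the query region 3' of the V alignment end."""
    offset = v_alignment.query_interval[1]
    tail = query[offset:]
    if len(tail) < config.j_min_aligned:
        return None
    candidates = []
    for seg in reference.of_type("J"):
        al = align_local(tail, seg.sequence, config.scoring, seg.segment_id)
        if al is not None and al.aligned_length >= config.j_min_aligned:
            candidates.append(al.shifted(offset))
    return _pick_best(candidates)


def _scan_d_segment(window: np.ndarray, dseq: np.ndarray, scoring: Scoring,
                    min_run: int) -> tuple[int, int, int, int] | None:
    """Best ungapped placement of one D in the junction window.

    Returns (score, length, w_start, d_start) of the highest-scoring
    ungapped segment that contains >= min_run contiguous exact matches,
    or None. Exact over all diagonals via prefix sums.
    """
    nw, nd = window.size, dseq.size
    best: tuple[int, int, int, int] | None = None
    for k in range(-(nd - 1), nw):
        d0 = max(0, -k)
        w0 = d0 + k
        L = min(nd - d0, nw - w0)
        if L < min_run:
            continue
        m = window[w0:w0 + L] == dseq[d0:d0 + L]
        s = np.where(m, scoring.match, scoring.mismatch)
        # exact-match runs of length >= min_run on this diagonal
        runs = []
        run_start = None
        for i in range(L + 1):
            if i < L and m[i]:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start >= min_run:
                    runs.append((run_start, i))
                run_start = None
        if not runs:
            continue
        pref = np.concatenate(([0], np.cumsum(s)))
        # prefix_min[i] = min(pref[0..i]); suffix_max[i] = max(pref[i..L])
        prefix_min = np.minimum.accumulate(pref)
        suffix_max = np.maximum.accumulate(pref[::-1])[::-1]
        for r0, r1 in runs:
            left = prefix_min[r0]
            right = suffix_max[r1]
            score = int(right - left)
            a = int(np.argmax(pref[:r0 + 1] == left))
            # rightmost b achieving the max keeps the longest segment
            b_rel = int(np.max(np.nonzero(pref[r1:] == right)[0])) + r1
            cand = (score, b_rel - a, w0 + a, d0 + a)
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    return best


def assign_d(query: str, reference: GermlineReference,
             v_alignment: SegmentAlignment, j_alignment: SegmentAlignment,
             config: AnnotateConfig = AnnotateConfig()) -> SegmentAlignment | None:
    """Best ungapped D in the window strictly between V end and J start.

    Absence is a legal outcome: returns None when the window is shorter
    than the match floor or no D has >= d_min_run contiguous matches.
    """
    w_lo = v_alignment.query_interval[1]
    w_hi = j_alignment.query_interval[0]
    if w_hi - w_lo < config.d_min_run:
        return None
    window = np.frombuffer(query[w_lo:w_hi].encode(), dtype=np.uint8)
    results = []
    for seg in reference.of_type("D"):
        dseq = np.frombuffer(seg.sequence.encode(), dtype=np.uint8)
        hit = _scan_d_segment(window, dseq, config.scoring, config.d_min_run)
        if hit is None:
            continue
        score, length, w_start, d_start = hit
        q0 = w_lo + w_start
        qs = query[q0:q0 + length]
        rs = seg.sequence[d_start:d_start + length]
        mism = [d_start + i for i in range(length) if qs[i] != rs[i]]
        results.append(SegmentAlignment(
            segment_id=seg.segment_id,
            score=score,
            query_interval=(q0, q0 + length),
            ref_interval=(d_start, d_start + length),
            mismatch_positions=mism,
            gap_count=0,
            identity=(length - len(mism)) / length,
            pairs_query=np.arange(q0, q0 + length),
            pairs_ref=np.arange(d_start, d_start + length),
        ))
    return _pick_best(results)


def decompose_junction(query: str, v_al: SegmentAlignment,
                       d_al: SegmentAlignment | None, j_al: SegmentAlignment,
                       reference: GermlineReference) -> dict:
    """N-insert strings and terminal trim lengths from the three alignments.

    n1 is the query between V end and D start (the whole window when no D
    was called, with n2 empty); n2 the query between D end and J start.
    Trims are the unaligned germline termini: v3 on the V 3' end, d5/d3 on
    the D, j5 on the J 5' end.
    """
    v_end = v_al.query_interval[1]
    j_start = j_al.query_interval[0]
    if j_start < v_end:
        raise ValueError("V and J query intervals overlap")
    v_seq = reference[v_al.segment_id].sequence
    j5 = j_al.ref_interval[0]
    trims = {
        "v3": len(v_seq) - v_al.ref_interval[1],
        "d5": 0,
        "d3": 0,
        "j5": j5,
    }
    if d_al is None:
        return {"n1": query[v_end:j_start], "n2": "", "trims": trims}
    d_start, d_end = d_al.query_interval
    if d_start < v_end or j_start < d_end:
        raise ValueError("D query interval overlaps V or J")
    d_seq = reference[d_al.segment_id].sequence
    trims["d5"] = d_al.ref_interval[0]
    trims["d3"] = len(d_seq) - d_al.ref_interval[1]
    return {
        "n1": query[v_end:d_start],
        "n2": query[d_end:j_start],
        "trims": trims,
    }


def call_productivity(query: str, v_al: SegmentAlignment, j_al: SegmentAlignment,
                      v_segment: GermlineSegment, j_segment: GermlineSegment) -> dict:
    """Junction extraction and in-frame / stop-codon classification.

    The reading frame is anchored at the 2nd-CYS codon; in-frame means the
    CYS-to-J-TRP distance is a multiple of 3; stop codons are scanned in
    that frame from the first aligned V position through the end of the
    aligned J. When an anchor falls in a trimmed/unaligned region the
    junction is undefined and productivity is indeterminate (None).
    """
    cys_q = v_al.ref_to_query(v_segment.cdr3_anchor)
    trp_q = j_al.ref_to_query(j_segment.j_anchor)
    out = {
        "in_frame": None, "has_stop": None, "productive": None,
        "junction_nt": None, "cdr3_nt": None, "cdr3_length": None,
    }
    if cys_q is None or trp_q is None or trp_q + 3 > len(query):
        return out
    in_frame = (trp_q - cys_q) % 3 == 0
    junction = query[cys_q:trp_q + 3]
    # stop scan in the CYS frame over the aligned span
    start = v_al.query_interval[0]
    start += (cys_q - start) % 3
    end = j_al.query_interval[1]
    has_stop = any(
        query[i:i + 3] in _STOPS for i in range(start, end - 2, 3)
    )
    out.update(
        in_frame=in_frame,
        has_stop=has_stop,
        productive=in_frame and not has_stop,
        junction_nt=junction,
        cdr3_nt=junction[3:-3],
        cdr3_length=len(junction) - 6,
    )
    return out


def annotate_read(read: QueryRead, reference: GermlineReference,
                  config: AnnotateConfig = AnnotateConfig()
                  ) -> tuple[VDJAssignment | None, str | None]:
    """Annotate one read; returns (assignment, None) or (None, reason)."""
    seq = read.sequence
    if config.primer_trim_5p or config.primer_trim_3p:
        seq = seq[config.primer_trim_5p:len(seq) - config.primer_trim_3p or None]
    rev = False
    v_al = assign_v(seq, reference, config)
    if v_al is None and config.rc_rescue:
        rc = revcomp(seq)
        v_al = assign_v(rc, reference, config)
        if v_al is not None:
            seq, rev = rc, True
    if v_al is None:
        return None, "no_v_assignment"
    j_al = assign_j(seq, reference, v_al, config)
    if j_al is None:
        return None, "no_j_assignment"
    d_al = assign_d(seq, reference, v_al, j_al, config)
    junction_parts = decompose_junction(seq, v_al, d_al, j_al, reference)
    prod = call_productivity(
        seq, v_al, j_al, reference[v_al.segment_id], reference[j_al.segment_id]
    )
    read_used = read if not rev else QueryRead(
        read_id=read.read_id, sequence=seq, cell_id=read.cell_id,
        individual_id=read.individual_id, group=read.group, isotype=read.isotype,
    )
    return VDJAssignment(
        read=read_used, v=v_al, j=j_al, d=d_al,
        n1=junction_parts["n1"], n2=junction_parts["n2"],
        trims=junction_parts["trims"],
        rev_comp=rev,
        **prod,
    ), None


def annotate_reads(reads: list[QueryRead], reference: GermlineReference,
                   config: AnnotateConfig = AnnotateConfig()
                   ) -> tuple[list[VDJAssignment], pd.DataFrame]:
    """Annotate a batch; unassignable reads go to the QC table with reasons."""
    assignments = []
    qc_rows = []
    for read in reads:
        asg, reason = annotate_read(read, reference, config)
        if asg is None:
            qc_rows.append({"read_id": read.read_id, "cell_id": read.cell_id,
                            "reason": reason})
        else:
            assignments.append(asg)
    qc = pd.DataFrame(qc_rows, columns=["read_id", "cell_id", "reason"])
    return assignments, qc


def reconstruct_span(asg: VDJAssignment, reference: GermlineReference) -> str | None:
    """Rebuild the aligned query span from germline + recorded mutations.

    germline-V-prefix + n1 + D-core + n2 + germline-J-suffix, with the
    query base substituted at every recorded mismatch position. Equals the
    query over [V start, J end) for gap-free alignments; returns None when
    any alignment is gapped (the substitution-only identity does not
    apply).
    """
    parts = []
    pieces = [(asg.v, asg.n1)]
    if asg.d is not None:
        pieces.append((asg.d, asg.n2))
    pieces.append((asg.j, ""))
    query = asg.read.sequence
    for al, insert in pieces:
        if al.gap_count:
            return None
        seg = reference[al.segment_id].sequence
        s, e = al.ref_interval
        chunk = list(seg[s:e])
        for q, r in zip(al.pairs_query.tolist(), al.pairs_ref.tolist()):
            if r in al.mismatch_positions:
                chunk[r - s] = query[q]
        parts.append("".join(chunk))
        parts.append(insert)
    return "".join(parts)


def airr_table(assignments: list[VDJAssignment]) -> pd.DataFrame:
    """AIRR rearrangement table (standard columns plus extensions)."""
    rows = []
    for a in assignments:
        rows.append({
            "sequence_id": a.read.read_id,
            "sequence": a.read.sequence,
            "cell_id": a.read.cell_id,
            "individual_id": a.read.individual_id,
            "group": a.read.group,
            "isotype": a.read.isotype,
            "v_call": a.v.segment_id,
            "d_call": a.d.segment_id if a.d is not None else "",
            "j_call": a.j.segment_id,
            "junction": a.junction_nt or "",
            "junction_length": len(a.junction_nt) if a.junction_nt else 0,
            "cdr3": a.cdr3_nt or "",
            "cdr3_length": a.cdr3_length if a.cdr3_length is not None else -1,
            "np1": a.n1,
            "np2": a.n2,
            "productive": {True: "T", False: "F", None: ""}[a.productive],
            "rev_comp": "T" if a.rev_comp else "F",
            "v_identity": round(a.v.identity, 6),
            "v3_trim": a.trims["v3"],
            "d5_trim": a.trims["d5"],
            "d3_trim": a.trims["d3"],
            "j5_trim": a.trims["j5"],
            "v_ambiguous": a.v.ambiguous,
            "d_ambiguous": bool(a.d.ambiguous) if a.d is not None else False,
            "j_ambiguous": a.j.ambiguous,
            "pattern_key": a.pattern_key or "",
        })
    return pd.DataFrame(rows)
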