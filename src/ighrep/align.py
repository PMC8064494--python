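"""Pairwise local alignment of reads against germline segments.

Thin wrapper around biotite's banded-free optimal aligner exposing the
quantities the annotation stage needs: score, half-open query/reference
intervals, reference-coordinate mismatch positions, gap count, identity,
and an aligned-position map used to project germline anchors onto the
query.

Scoring defaults follow short-read Ig alignment practice: match +2,
mismatch -2, gap open -4, gap extend -1, where a length-L gap costs
open + (L-1) * extend. A local alignment whose best score is <= 0 is
reported as no alignment (``None``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = ["Scoring", "SegmentAlignment", "align_local"]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1

    def matrix(self) -> balign.SubstitutionMatrix:
        mat = np.full((4, 4), self.mismatch, dtype=np.int32)
        np.fill_diagonal(mat, self.match)
        alpha = bseq.NucleotideSequence.alphabet_unamb
        return balign.SubstitutionMatrix(alpha, alpha, mat)


DEFAULT_SCORING = Scoring()


@dataclass
class SegmentAlignment:
    """One query-vs-germline-segment local alignment."""

    segment_id: str
    score: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    mismatch_positions: list[int]  # reference offsets
    gap_count: int
    identity: float
    ambiguous: bool = False
    # aligned (query, ref) position pairs, gaps excluded; used to map anchors
    pairs_query: np.ndarray = field(default_factory=lambda: np.empty(0, int), repr=False)
    pairs_ref: np.ndarray = field(default_factory=lambda: np.empty(0, int), repr=False)

    @property
    def aligned_ref_length(self) -> int:
        return self.ref_interval[1] - self.ref_interval[0]

    @property
    def aligned_length(self) -> int:
        """Number of gap-free aligned columns."""
        return int(self.pairs_query.size)

    def ref_to_query(self, ref_pos: int) -> int | None:
        """Query coordinate aligned to ``ref_pos``, or None if gapped/outside."""
        idx = np.searchsorted(self.pairs_ref, ref_pos)
        if idx < self.pairs_ref.size and self.pairs_ref[idx] == ref_pos:
            return int(self.pairs_query[idx])
        return None

    def shifted(self, query_offset: int) -> "SegmentAlignment":
        """Same alignment with query coordinates shifted by ``query_offset``.

        Used when a segment was aligned against a slice of the full read.
        """
        return replace(
            self,
            query_interval=(self.query_interval[0] + query_offset,
                            self.query_interval[1] + query_offset),
            pairs_query=self.pairs_query + query_offset,
        )


# Encoding cache: biotite NucleotideSequence construction dominates runtime
# for many small alignments, so sequences are converted once per string.
_SEQ_CACHE: dict[str, bseq.NucleotideSequence] = {}


def _as_seq(s: str) -> bseq.NucleotideSequence:
    seq = _SEQ_CACHE.get(s)
    if seq is None:
        seq = bseq.NucleotideSequence(s)
        if len(_SEQ_CACHE) > 4096:
            _SEQ_CACHE.clear()
        _SEQ_CACHE[s] = seq
    return seq


def align_local(query: str, ref: str, scoring: Scoring = DEFAULT_SCORING,
                segment_id: str = "") -> SegmentAlignment | None:
    """Optimal local alignment of ``query`` against ``ref``.

    Ns in the query are scored as mismatches (they match nothing). Returns
    ``None`` when the best local score is not positive. Among co-optimal
    traces biotite's first is taken, which is deterministic for fixed
    inputs.
    """
    if not query or not ref:
        raise ValueError("align_local requires non-empty sequences")
    # N handling: replace N with a placeholder that mismatches everything.
    # The unambiguous alphabet has no N, and under match/mismatch scoring a
    # base that equals nothing in ref is exactly a mismatch, so substitute a
    # base and post-correct the score/mismatch bookkeeping via recount.
    q_clean = query.upper().replace("N", "A")
    n_positions = {i for i, c in enumerate(query.upper()) if c == "N"}
    alignment = balign.align_optimal(
        _as_seq(q_clean), _as_seq(ref.upper()), scoring.matrix(),
        gap_penalty=(scoring.gap_open, scoring.gap_extend),
        local=True, max_number=1,
    )[0]
    trace = alignment.trace
    if trace.shape[0] == 0:
        return None

    q_col = trace[:, 0]
    r_col = trace[:, 1]
    both = (q_col >= 0) & (r_col >= 0)
    pq = q_col[both]
    pr = r_col[both]
    gap_count = int((~both).sum())

    mismatches = []
    matches = 0
    score = 0
    for qi, ri in zip(pq.tolist(), pr.tolist()):
        if qi in n_positions or q_clean[qi] != ref[ri]:
            mismatches.append(ri)
            score += scoring.mismatch
        else:
            matches += 1
            score += scoring.match
    # gap scoring: open charged on the first position of each gap run
    in_gap = False
    for flag in both.tolist():
        if not flag:
            score += scoring.gap_extend if in_gap else scoring.gap_open
            in_gap = True
        else:
            in_gap = False

    if score <= 0:
        return None
    ref_interval = (int(pr[0]), int(pr[-1]) + 1)
    return SegmentAlignment(
        segment_id=segment_id,
        score=score,
        query_interval=(int(pq[0]), int(pq[-1]) + 1),
        ref_interval=ref_interval,
        mismatch_positions=mismatches,
        gap_count=gap_count,
        identity=matches / (ref_interval[1] - ref_interval[0]),
        pairs_query=pq.astype(int),
        pairs_ref=pr.astype(int),
    )
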