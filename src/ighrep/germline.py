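"""Germline IGHV/IGHD/IGHJ segment database.

The annotation pipeline aligns rearranged heavy-chain reads against a
germline segment reference. This module loads such a reference from a
FASTA file plus a sidecar annotation TSV (region boundaries and CDR3
anchor offsets), validates it, and provides a deterministic synthetic
reference builder used throughout the test suite and the simulator.

Coordinates are 0-based, half-open, on the coding strand. ``segment_id``
may carry an IMGT-style ``*NN`` allele suffix; gene-level collapsing is
string truncation at ``*``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineSegment",
    "GermlineReference",
    "family_of",
    "gene_of",
    "load_germline",
    "write_germline",
    "build_fixture_reference",
]

_ACGT = set("ACGT")
_V_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")
_GENE_RE = re.compile(r"^IGH([VDJ])(\d+)(?:[-/S].*)?$")
_STOPS = {"TAA", "TAG", "TGA"}


def gene_of(segment_id: str) -> str:
    """Collapse an allele-qualified segment id to its gene name.

    >>> gene_of("IGHV1-18*01")
    'IGHV1-18'
    """
    return segment_id.split("*")[0]


def family_of(gene: str) -> str:
    """Map an IGH gene name to its family label, e.g. ``IGHV1-18`` -> ``VH1``.

    The family is the segment-type letter (V/D/J) suffixed with "H" and the
    leading family digits of the gene name (``IGHJ4`` -> ``JH4``).
    """
    m = _GENE_RE.match(gene_of(gene))
    if m is None:
        raise ValueError(f"cannot parse IGH gene name: {gene!r}")
    return f"{m.group(1)}H{int(m.group(2))}"


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J segment with its structural annotations.

    V segments carry framework/CDR region intervals and the offset of the
    conserved 2nd-CYS codon (the 5' anchor of the junction); J segments
    carry the offset of the conserved J-TRP codon (the 3' anchor) and the
    reading-frame offset of the germline J.
    """

    segment_id: str
    segment_type: str  # "V" | "D" | "J"
    sequence: str
    regions: dict[str, tuple[int, int]] | None = None  # V only
    cdr3_anchor: int | None = None  # V only
    j_anchor: int | None = None  # J only
    reading_frame_offset: int | None = None  # J only

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "D", "J"):
            raise ValueError(f"{self.segment_id}: bad segment_type {self.segment_type!r}")
        if not self.sequence or set(self.sequence) - _ACGT:
            raise ValueError(
                f"{self.segment_id}: sequence must be non-empty uppercase ACGT"
            )
        if self.segment_type == "V":
            self._validate_v()
        if self.segment_type == "J":
            if self.j_anchor is None or not (0 <= self.j_anchor < len(self.sequence) - 2):
                raise ValueError(f"{self.segment_id}: j_anchor out of range")
            if self.reading_frame_offset not in (0, 1, 2):
                raise ValueError(f"{self.segment_id}: reading_frame_offset must be 0/1/2")
        # family must be derivable; raises on unparseable names
        family_of(self.segment_id)

    def _validate_v(self) -> None:
        if self.regions is None or set(self.regions) != set(_V_REGIONS):
            raise ValueError(f"{self.segment_id}: V segment needs FR1..FR3 regions")
        prev_end = None
        for name in _V_REGIONS:
            s, e = self.regions[name]
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.segment_id}: region {name} out of bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"{self.segment_id}: region {name} overlaps or disorders predecessor"
                )
            prev_end = e
        if self.cdr3_anchor is None or self.cdr3_anchor < self.regions["FR3"][0]:
            raise ValueError(f"{self.segment_id}: cdr3_anchor must lie in or after FR3")
        if self.cdr3_anchor + 3 > len(self.sequence):
            raise ValueError(f"{self.segment_id}: cdr3_anchor codon exceeds sequence")

    @property
    def gene(self) -> str:
        return gene_of(self.segment_id)

    @property
    def family(self) -> str:
        return family_of(self.segment_id)


@dataclass
class GermlineReference:
    """A validated collection of germline segments."""

    segments: list[GermlineSegment]
    version_tag: str = "unversioned"
    _by_id: dict[str, GermlineSegment] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for seg in self.segments:
            if seg.segment_id in self._by_id:
                raise ValueError(f"duplicate segment_id {seg.segment_id!r}")
            self._by_id[seg.segment_id] = seg
        for t in "VDJ":
            if not self.of_type(t):
                raise ValueError(f"reference has no {t} segment")

    def of_type(self, segment_type: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.segment_type == segment_type]

    def __getitem__(self, segment_id: str) -> GermlineSegment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def __len__(self) -> int:
        return len(self.segments)


def _parse_interval(text: str) -> tuple[int, int]:
    s, e = text.split("..")
    return int(s), int(e)


def _fmt_interval(iv: tuple[int, int]) -> str:
    return f"{iv[0]}..{iv[1]}"


def load_germline(fasta_path: str | Path, annotation_path: str | Path) -> GermlineReference:
    """Load and validate a germline reference from FASTA + annotation TSV.

    The sidecar TSV has columns: segment_id, segment_type, fr1, cdr1, fr2,
    cdr2, fr3 (each ``start..end``, half-open), cdr3_anchor, j_anchor,
    frame. Non-V/J columns are left blank. Every FASTA record must have a
    matching annotation row; violations raise ``ValueError`` naming the
    offending record.
    """
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    ann_by_id = {}
    for _, row in ann.iterrows():
        sid = row["segment_id"]
        if sid in ann_by_id:
            raise ValueError(f"duplicate annotation row for {sid!r}")
        ann_by_id[sid] = row

    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate FASTA record {sid!r}")
        seen.add(sid)
        if sid not in ann_by_id:
            raise ValueError(f"FASTA record {sid!r} has no annotation row")
        row = ann_by_id[sid]
        stype = row["segment_type"]
        seq = str(rec.seq).upper()
        regions = None
        cdr3_anchor = None
        j_anchor = None
        frame = None
        if stype == "V":
            regions = {
                name: _parse_interval(row[name.lower()]) for name in _V_REGIONS
            }
            cdr3_anchor = int(row["cdr3_anchor"])
        elif stype == "J":
            j_anchor = int(row["j_anchor"])
            frame = int(row["frame"])
        segments.append(
            GermlineSegment(
                segment_id=sid,
                segment_type=stype,
                sequence=seq,
                regions=regions,
                cdr3_anchor=cdr3_anchor,
                j_anchor=j_anchor,
                reading_frame_offset=frame,
            )
        )
    missing = set(ann_by_id) - seen
    if missing:
        raise ValueError(f"annotation rows without FASTA records: {sorted(missing)}")
    return GermlineReference(segments=segments)


def write_germline(reference: GermlineReference, fasta_path: str | Path,
                   annotation_path: str | Path) -> None:
    """Write a reference back to FASTA + sidecar TSV (inverse of load)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.segment_id, description="")
        for s in reference.segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for s in reference.segments:
        row = {
            "segment_id": s.segment_id,
            "segment_type": s.segment_type,
            "fr1": "", "cdr1": "", "fr2": "", "cdr2": "", "fr3": "",
            "cdr3_anchor": "", "j_anchor": "", "frame": "",
        }
        if s.segment_type == "V":
            assert s.regions is not None
            for name in _V_REGIONS:
                row[name.lower()] = _fmt_interval(s.regions[name])
            row["cdr3_anchor"] = str(s.cdr3_anchor)
        elif s.segment_type == "J":
            row["j_anchor"] = str(s.j_anchor)
            row["frame"] = str(s.reading_frame_offset)
        rows.append(row)
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n codons drawn uniformly from the 61 sense codons (no stops)."""
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def build_fixture_reference(n_v: int, n_d: int, n_j: int, seed: int) -> GermlineReference:
    """Deterministic synthetic germline reference for tests and simulation.

    V segments are 297 nt: FR1 [0,75) CDR1 [75,99) FR2 [99,150) CDR2
    [150,174) FR3 [174,288), then the 2nd-CYS anchor codon TGT at 288 and
    a short germline CDR3 start (GCGAGA). The open reading frame from FR1
    start is stop-free. J segments are a stop-free head (germline CDR3
    tail; length 15 + 3i, distinct per segment), the J-TRP codon TGG,
    then a fixed FR4-like tail. D segments are 12-30 nt with pairwise
    5-mer-disjoint sequences.

    Families cycle V: 1..7, D: 1..7, J: 1..6 so family-biased draws have
    categories to hit.
    """
    if min(n_v, n_d, n_j) < 1:
        raise ValueError("need at least one segment of each type")
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []

    regions = {
        "FR1": (0, 75), "CDR1": (75, 99), "FR2": (99, 150),
        "CDR2": (150, 174), "FR3": (174, 288),
    }
    for i in range(n_v):
        fam = i % 7 + 1
        body = _random_codons(rng, 96)  # 288 nt, stop-free in frame 0
        seq = body + "TGT" + "GCGAGA"
        segments.append(GermlineSegment(
            segment_id=f"IGHV{fam}-{i + 1}*01",
            segment_type="V",
            sequence=seq,
            regions=dict(regions),
            cdr3_anchor=288,
        ))
    # D segments share no 5-mer (within or across segments), so a trimmed
    # D core of >= 5 nt identifies its segment and position uniquely.
    used_kmers: set[str] = set()
    for i in range(n_d):
        fam = i % 7 + 1
        length = int(rng.integers(12, 31))
        for _ in range(1000):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
            kmers = {seq[k:k + 5] for k in range(length - 4)}
            if len(kmers) == length - 4 and not (kmers & used_kmers):
                used_kmers |= kmers
                break
        else:
            raise RuntimeError("could not draw 5-mer-disjoint D segments")
        segments.append(GermlineSegment(
            segment_id=f"IGHD{fam}-{i + 1}*01",
            segment_type="D",
            sequence=seq,
        ))
    # J heads have distinct lengths (anchors 15, 18, 21, ... all = 0 mod 3)
    # so different J segments never share an alignment diagonal despite the
    # common FR4-like tail.
    j_tail = "GGCCAAGGGACCACGGTCACCGTCTC"  # stop-free after TGG
    for i in range(n_j):
        fam = i % 6 + 1
        anchor = 15 + 3 * i
        head = _random_codons(rng, anchor // 3)  # stop-free in the anchor frame
        seq = head + "TGG" + j_tail
        segments.append(GermlineSegment(
            segment_id=f"IGHJ{fam}*0{i // 6 + 1}",
            segment_type="J",
            sequence=seq,
            j_anchor=anchor,
            reading_frame_offset=0,
        ))
    return GermlineReference(segments=segments, version_tag=f"fixture-seed{seed}")
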