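"""Ground-truthed V(D)J recombination and single-cell repertoire simulator.

Generates IgH reads by the recombination arithmetic the annotator
inverts: ``V[0:len-v3] + n1 + D[d5:len-d3] + n2 + J[j5:]`` with
hotspot-biased somatic hypermutation applied afterward to the
germline-templated positions. Every read carries a full truth record
(segment ids, trims, N inserts, mutated positions, hotspot flags,
productivity), so each pipeline stage can be tested against known
ground truth with no external data.

Cohort simulation reproduces a single-podocyte survey design: 48 cells
split HC 6 / MN 18 / IgAN 15 / IN 9, isotype probabilities proportional
to the observed per-class detection frequencies, co-expressing cells
(each expressed class gets its own rearrangement, since classes in one
cell never share a pattern), extra same-class patterns, shared clones
placed across chosen individuals, and VH-family draw weights in a
VH1-biased "podocyte" preset and a VH3/VH4-weighted "B-cell" preset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import QueryRead
from .germline import GermlineReference, GermlineSegment, build_fixture_reference
from .shm import hotspot_mask

__all__ = [
    "CohortSpec", "SharedCloneSpec", "SimulationConfig", "SimBundle",
    "TruthRecord", "apply_shm", "simulate_rearrangement", "simulate_cohorts",
    "podocyte_config", "bcell_config",
    "PODOCYTE_V_FAMILY_WEIGHTS", "BCELL_V_FAMILY_WEIGHTS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

# VH family draw weights for the two repertoire modes: podocytes VH1 38.5%
# / VH3 39.6%; B cells VH3 52.3% / VH4 25.1% / VH1 12.9%. Remaining mass
# split over the other families present in the reference.
PODOCYTE_V_FAMILY_WEIGHTS = {"VH1": 0.385, "VH3": 0.396, "VH4": 0.12}
BCELL_V_FAMILY_WEIGHTS = {"VH3": 0.523, "VH4": 0.251, "VH1": 0.129}

# Isotype draw probabilities proportional to the per-class detection
# frequencies (IgG 60.4 / IgM 56.3 / IgA 12.5 / IgE 10.4 / IgD 4.2 %).
_DETECT = {"IgG": 0.604, "IgM": 0.563, "IgA": 0.125, "IgE": 0.104, "IgD": 0.042}
DEFAULT_ISOTYPE_PROBS = {k: v / sum(_DETECT.values()) for k, v in _DETECT.items()}

# Per-class SHM targets (substitutions per aligned nt): rare IgD
# mutation, low IgM, high IgA/IgG/IgE.
DEFAULT_SHM_RATES = {"IgD": 0.002, "IgM": 0.01, "IgA": 0.06, "IgG": 0.06,
                     "IgE": 0.05}


@dataclass(frozen=True)
class CohortSpec:
    n_cells: int
    n_individuals: int
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOTYPE_PROBS))
    p_coexpression: float = 0.0
    p_multi_pattern: float = 0.0   # probability of an extra same-class pattern
    shm_scale: float = 1.0         # cohort multiplier on per-class SHM rates


@dataclass(frozen=True)
class SharedCloneSpec:
    """One clone (a single rearrangement) injected into named cells."""
    placements: tuple[tuple[str, str], ...]   # (individual_id, cell_id)
    isotype: str = "IgG"


@dataclass
class SimulationConfig:
    seed: int
    cohorts: dict[str, CohortSpec]
    shm_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHM_RATES))
    hotspot_bias: float = 3.0
    trim_means: dict[str, float] = field(
        default_factory=lambda: {"v3": 2.0, "d5": 2.0, "d3": 2.0, "j5": 3.0})
    n_insert_means: tuple[float, float] = (4.5, 4.5)
    v_family_weights: dict[str, float] | None = None   # None -> uniform
    d_family_weights: dict[str, float] | None = None
    j_family_weights: dict[str, float] | None = None
    cdr3_mode: str = "gaussian_like"   # or "restricted"
    n_restricted_templates: int = 5
    p_productive: float = 0.958
    reads_per_expression: int = 1
    shared_clones: list[SharedCloneSpec] = field(default_factory=list)
    motifs: tuple[str, ...] = ("RGYW", "WRCY")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o).__name__)
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2,
                          sort_keys=True)


@dataclass
class TruthRecord:
    read_id: str
    cell_id: str
    individual_id: str
    group: str
    isotype: str
    v_id: str
    d_id: str
    j_id: str
    v3: int
    d5: int
    d3: int
    j5: int
    n1: str
    n2: str
    junction: str
    cdr3_length: int
    in_frame: bool
    has_stop: bool
    productive: bool
    shm_rate_target: float
    mutated_positions: tuple[int, ...]
    hotspot_flags: tuple[bool, ...]

    @property
    def n_mutations(self) -> int:
        return len(self.mutated_positions)

    @property
    def n_hotspot_mutations(self) -> int:
        return int(sum(self.hotspot_flags))


@dataclass
class SimBundle:
    """Simulated reads plus per-read ground truth and the config echo."""
    reads: list[QueryRead]
    truth: pd.DataFrame
    config: SimulationConfig
    reference: GermlineReference

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """FASTA + metadata TSV (pipeline input dialect), truth TSV with
        extension columns, and the config JSON echo."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reads_fasta": out / "reads.fasta",
            "metadata": out / "metadata.tsv",
            "truth": out / "truth.tsv",
            "config": out / "config.json",
        }
        SeqIO.write(
            [SeqRecord(Seq(r.sequence), id=r.read_id, description="")
             for r in self.reads],
            str(paths["reads_fasta"]), "fasta")
        pd.DataFrame([{
            "read_id": r.read_id, "cell_id": r.cell_id,
            "individual_id": r.individual_id, "group": r.group,
            "isotype": r.isotype,
        } for r in self.reads]).to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["config"].write_text(self.config.to_json())
        return paths


# ---------------------------------------------------------------------------
# SHM

def apply_shm(sequence: str, hotspot_positions, rate: float, bias: float,
              rng: np.random.Generator,
              mutable=None) -> tuple[str, list[int]]:
    """Substitution-only SHM with hotspot bias.

    Per-site substitution probability is ``p`` outside hotspot positions
    and ``bias * p`` inside, with ``p`` calibrated so the expected overall
    rate over mutable positions equals ``rate``. ``mutable`` (default all
    positions) restricts mutation to germline-templated sites. The
    substituted base is drawn uniformly from the three alternatives.
    """
    if rate < 0 or bias < 1:
        raise ValueError("need rate >= 0 and bias >= 1")
    n = len(sequence)
    hot = np.zeros(n, dtype=bool)
    idx = np.asarray(sorted(hotspot_positions), dtype=int)
    if idx.size:
        hot[idx] = True
    if mutable is None:
        mut_ok = np.ones(n, dtype=bool)
    else:
        mut_ok = np.asarray(mutable, dtype=bool)
    if rate == 0:
        return sequence, []
    t = int(mut_ok.sum())
    h = int((hot & mut_ok).sum())
    if t == 0:
        return sequence, []
    p = rate * t / (h * bias + (t - h))
    if bias * p > 1:
        raise ValueError(f"SHM calibration infeasible: bias*p = {bias * p:.3f} > 1")
    probs = np.where(hot, bias * p, p)
    probs[~mut_ok] = 0.0
    hits = np.nonzero(rng.random(n) < probs)[0]
    if hits.size == 0:
        return sequence, []
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    for i in hits:
        alternatives = _BASES[_BASES != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return arr.tobytes().decode(), [int(i) for i in hits]


# ---------------------------------------------------------------------------
# single rearrangement

def _weighted_segment_choice(segments: list[GermlineSegment],
                             family_weights: dict[str, float] | None,
                             rng: np.random.Generator) -> GermlineSegment:
    segments = sorted(segments, key=lambda s: s.segment_id)
    if family_weights is None:
        return segments[rng.integers(0, len(segments))]
    families = sorted({s.family for s in segments})
    named = {f: family_weights.get(f, 0.0) for f in families}
    leftover = max(0.0, 1.0 - sum(named.values()))
    unnamed = [f for f in families if f not in family_weights]
    if unnamed:
        for f in unnamed:
            named[f] = leftover / len(unnamed)
    w = np.array([named[s.family] / sum(1 for x in segments if x.family == s.family)
                  for s in segments])
    if w.sum() <= 0:
        raise ValueError("family weights assign no mass to any present family")
    return segments[rng.choice(len(segments), p=w / w.sum())]


def _geom_len(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0,1,...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _draw_junction_parts(cfg: SimulationConfig, v: GermlineSegment,
                         d: GermlineSegment, j: GermlineSegment,
                         rng: np.random.Generator) -> dict:
    tm = cfg.trim_means
    v3 = min(_geom_len(rng, tm["v3"]), len(v.sequence) - (v.cdr3_anchor + 3))
    # leave >= 6 nt of J head so the J segment stays identifiable
    j5 = min(_geom_len(rng, tm["j5"]), max(j.j_anchor - 6, 0))
    d5 = _geom_len(rng, tm["d5"])
    d3 = _geom_len(rng, tm["d3"])
    if d5 + d3 > len(d.sequence) - 1:   # keep >= 1 nt of D core
        excess = d5 + d3 - (len(d.sequence) - 1)
        take = min(excess, d3)
        d3 -= take
        d5 -= excess - take
    n1 = _random_bases(rng, int(rng.poisson(cfg.n_insert_means[0])))
    n2 = _random_bases(rng, int(rng.poisson(cfg.n_insert_means[1])))
    return {"v3": v3, "d5": d5, "d3": d3, "j5": j5, "n1": n1, "n2": n2}


def _make_templates(cfg: SimulationConfig, reference: GermlineReference,
                    rng: np.random.Generator) -> list[dict]:
    """Junction templates for the 'restricted' CDR3 mode: a small pool of
    fixed (D, J, trims, N-inserts) combinations producing length spikes."""
    v0 = sorted(reference.of_type("V"), key=lambda s: s.segment_id)[0]
    js = sorted(reference.of_type("J"), key=lambda s: s.segment_id)
    ds = sorted(reference.of_type("D"), key=lambda s: s.segment_id)
    templates = []
    lengths_seen: set[int] = set()
    attempts = 0
    while len(templates) < cfg.n_restricted_templates and attempts < 2000:
        attempts += 1
        d = ds[rng.integers(0, len(ds))]
        j = js[rng.integers(0, len(js))]
        parts = _draw_junction_parts(cfg, v0, d, j, rng)
        # pad n2 so the junction is in frame for the fixture geometry
        jl = _junction_length(v0, d, j, parts)
        pad = (-jl) % 3
        parts["n2"] = parts["n2"] + _random_bases(rng, pad)
        if jl + pad in lengths_seen:    # distinct spikes, not one pile
            continue
        seq, _, geom = _assemble(v0, d, j, parts)
        in_frame, has_stop = _productive(seq, geom)
        if in_frame and not has_stop and not _boundary_ambiguous(
                v0, d, j, parts, seq, geom):
            lengths_seen.add(jl + pad)
            templates.append({"d_id": d.segment_id, "j_id": j.segment_id,
                              **parts})
    if len(templates) < cfg.n_restricted_templates:
        raise RuntimeError("could not build stop-free restricted templates")
    return templates


def _junction_length(v, d, j, parts) -> int:
    v_kept = len(v.sequence) - parts["v3"]
    core = len(d.sequence) - parts["d5"] - parts["d3"]
    return ((v_kept - v.cdr3_anchor) + len(parts["n1"]) + core
            + len(parts["n2"]) + (j.j_anchor - parts["j5"]) + 3)


def _assemble(v: GermlineSegment, d: GermlineSegment, j: GermlineSegment,
              parts: dict) -> tuple[str, np.ndarray, dict]:
    """Build the read; returns (sequence, templated-position mask, geometry)."""
    v_kept = v.sequence[:len(v.sequence) - parts["v3"]] if parts["v3"] else v.sequence
    core = d.sequence[parts["d5"]:len(d.sequence) - parts["d3"] or None]
    j_kept = j.sequence[parts["j5"]:]
    seq = v_kept + parts["n1"] + core + parts["n2"] + j_kept
    templated = np.ones(len(seq), dtype=bool)
    n1_start = len(v_kept)
    d_start = n1_start + len(parts["n1"])
    n2_start = d_start + len(core)
    j_start = n2_start + len(parts["n2"])
    templated[n1_start:d_start] = False
    templated[n2_start:j_start] = False
    geom = {
        "cys_q": v.cdr3_anchor,
        "trp_q": j_start + (j.j_anchor - parts["j5"]),
        "d_span": (d_start, n2_start),
        "j_start": j_start,
    }
    return seq, templated, geom


def _productive(seq: str, geom: dict) -> tuple[bool, bool]:
    """(in_frame, has_stop) in the 2nd-CYS frame over the whole read."""
    cys, trp = geom["cys_q"], geom["trp_q"]
    in_frame = (trp - cys) % 3 == 0
    start = cys % 3
    has_stop = any(seq[i:i + 3] in _STOPS for i in range(start, len(seq) - 2, 3))
    return in_frame, has_stop


def _extension_risk(germ: str, quer: str, limit: int = 16) -> bool:
    """Could a local aligner extend from a true boundary into ``quer``?

    True when some prefix of the (germline continuation, query) pairing
    reaches a cumulative score >= 0 under +2/-2 substitution scoring,
    either on the direct diagonal or after a gap of up to 6 nt on either
    side (charged -4 - (len-1)) — i.e. the optimal alignment would (or
    could, on a tie) swallow non-templated bases.
    """
    def risk(g: str, q: str, start: int) -> bool:
        cum = start
        for gc, qc in zip(g[:limit], q[:limit]):
            cum += 2 if gc == qc else -2
            if cum >= 0:
                return True
        return False

    if risk(germ, quer, 0):
        return True
    for shift in range(1, 7):
        open_cost = -4 - (shift - 1)
        if risk(germ[shift:], quer, open_cost) or risk(germ, quer[shift:], open_cost):
            return True
    return False


def _boundary_ambiguous(v: GermlineSegment, d: GermlineSegment,
                        j: GermlineSegment, parts: dict, seq: str,
                        geom: dict) -> bool:
    """Any segment terminus whose trimmed germline continuation could be
    re-absorbed by the aligner, which would shift trims/N inserts."""
    v_end = len(v.sequence) - parts["v3"]
    d_start, d_end = geom["d_span"]
    j_start = geom["j_start"]
    if parts["v3"] and _extension_risk(v.sequence[v_end:], seq[v_end:]):
        return True
    if parts["j5"] and _extension_risk(
            j.sequence[:parts["j5"]][::-1], seq[:j_start][::-1]):
        return True
    if parts["d5"] and _extension_risk(
            d.sequence[:parts["d5"]][::-1], seq[:d_start][::-1]):
        return True
    if parts["d3"] and _extension_risk(
            d.sequence[len(d.sequence) - parts["d3"]:], seq[d_end:]):
        return True
    return False


def _read_hotspot_mask(v, d, j, parts, motifs) -> np.ndarray:
    """Hotspot positions of the read, mapped from the germline masks."""
    pieces = [
        hotspot_mask(v.sequence, motifs)[:len(v.sequence) - parts["v3"] or None],
        np.zeros(len(parts["n1"]), dtype=bool),
        hotspot_mask(d.sequence, motifs)[parts["d5"]:len(d.sequence) - parts["d3"] or None],
        np.zeros(len(parts["n2"]), dtype=bool),
        hotspot_mask(j.sequence, motifs)[parts["j5"]:],
    ]
    return np.concatenate(pieces)


def simulate_rearrangement(reference: GermlineReference, cfg: SimulationConfig,
                           rng: np.random.Generator, shm_rate: float,
                           force_productive: bool | None = None,
                           templates: list[dict] | None = None,
                           max_retries: int = 500) -> tuple[str, dict]:
    """One recombined (and mutated) read plus its truth fields.

    ``force_productive=True`` resamples the junction (and the mutation
    draw) until the post-SHM read is in-frame and stop-free; ``False``
    until it is not productive; ``None`` accepts the first draw. Raises
    after ``max_retries`` failed resamples.
    """
    for _ in range(max_retries):
        v = _weighted_segment_choice(reference.of_type("V"),
                                     cfg.v_family_weights, rng)
        # forced-unproductive draws use free junctions: the template pool
        # is in-frame and stop-free by construction
        if cfg.cdr3_mode == "restricted" and templates and force_productive is not False:
            t = templates[rng.integers(0, len(templates))]
            d = reference[t["d_id"]]
            j = reference[t["j_id"]]
            parts = {k: t[k] for k in ("v3", "d5", "d3", "j5", "n1", "n2")}
        else:
            d = _weighted_segment_choice(reference.of_type("D"),
                                         cfg.d_family_weights, rng)
            j = _weighted_segment_choice(reference.of_type("J"),
                                         cfg.j_family_weights, rng)
            parts = _draw_junction_parts(cfg, v, d, j, rng)
        seq, templated, geom = _assemble(v, d, j, parts)
        if _boundary_ambiguous(v, d, j, parts, seq, geom):
            continue
        hot = _read_hotspot_mask(v, d, j, parts, cfg.motifs)
        mutated, positions = apply_shm(
            seq, np.nonzero(hot)[0], shm_rate, cfg.hotspot_bias, rng,
            mutable=templated)
        in_frame, has_stop = _productive(mutated, geom)
        productive = in_frame and not has_stop
        if force_productive is True and not productive:
            continue
        if force_productive is False and productive:
            continue
        cys, trp = geom["cys_q"], geom["trp_q"]
        junction = mutated[cys:trp + 3]
        truth = {
            "v_id": v.segment_id, "d_id": d.segment_id, "j_id": j.segment_id,
            **{k: parts[k] for k in ("v3", "d5", "d3", "j5")},
            "n1": mutated[len(v.sequence) - parts["v3"]:
                          len(v.sequence) - parts["v3"] + len(parts["n1"])],
            "n2": mutated[geom["d_span"][1]:geom["j_start"]],
            "junction": junction,
            "cdr3_length": len(junction) - 6,
            "in_frame": in_frame, "has_stop": has_stop, "productive": productive,
            "shm_rate_target": shm_rate,
            "mutated_positions": tuple(positions),
            "hotspot_flags": tuple(bool(hot[p]) for p in positions),
        }
        return mutated, truth
    raise RuntimeError(
        f"junction resampling exceeded {max_retries} retries "
        f"(force_productive={force_productive})")


# ---------------------------------------------------------------------------
# cohorts

def _draw_isotype(probs: dict[str, float], rng: np.random.Generator,
                  exclude: set[str] = frozenset()) -> str:
    items = [(k, v) for k, v in sorted(probs.items()) if k not in exclude and v > 0]
    w = np.array([v for _, v in items], dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())][0]


def simulate_cohorts(reference: GermlineReference | None,
                     config: SimulationConfig) -> SimBundle:
    """Full study-design simulation: cells, cohorts, co-expression,
    multi-pattern cells and shared clones, with per-read ground truth.

    Deterministic for a fixed (seed, config); a different seed yields a
    different bundle.
    """
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = build_fixture_reference(
            14, 7, 6, seed=int(rng.integers(0, 2**31 - 1)))
    templates = (_make_templates(config, reference, rng)
                 if config.cdr3_mode == "restricted" else None)

    # lay out cells: individuals round-robin within each cohort
    cells: list[tuple[str, str, str]] = []   # (group, individual_id, cell_id)
    for grp in sorted(config.cohorts):
        spec = config.cohorts[grp]
        counter: dict[str, int] = {}
        for i in range(spec.n_cells):
            ind = f"{grp}{i % spec.n_individuals + 1}"
            counter[ind] = counter.get(ind, 0) + 1
            cells.append((grp, ind, f"{ind}-{counter[ind]}"))
    cell_index = {(ind, cid): (grp, ind, cid) for grp, ind, cid in cells}

    clone_cache: dict[int, tuple[str, dict]] = {}
    for ci, clone in enumerate(config.shared_clones):
        for placement in clone.placements:
            if tuple(placement) not in cell_index:
                raise ValueError(
                    f"shared clone {ci} placed in nonexistent cell {placement}")
        clone_cache[ci] = simulate_rearrangement(
            reference, config, rng,
            shm_rate=0.0, force_productive=True, templates=templates)

    reads: list[QueryRead] = []
    truth_rows: list[dict] = []

    def emit(grp: str, ind: str, cid: str, isotype: str,
             seq: str, truth: dict) -> None:
        k = sum(1 for r in reads if r.cell_id == cid)
        rid = f"{cid}_r{k + 1}"
        for rep in range(config.reads_per_expression):
            read_id = rid if config.reads_per_expression == 1 else f"{rid}.{rep + 1}"
            reads.append(QueryRead(
                read_id=read_id, sequence=seq, cell_id=cid,
                individual_id=ind, group=grp, isotype=isotype))
            truth_rows.append({
                "read_id": read_id, "cell_id": cid, "individual_id": ind,
                "group": grp, "isotype": isotype, **truth,
            })

    for grp, ind, cid in cells:
        spec = config.cohorts[grp]

        def new_rearr(isotype: str) -> tuple[str, dict]:
            rate = config.shm_rates.get(isotype, 0.0) * spec.shm_scale
            force = bool(rng.random() < config.p_productive)
            return simulate_rearrangement(
                reference, config, rng, shm_rate=rate,
                force_productive=force, templates=templates)

        iso1 = _draw_isotype(spec.isotype_probs, rng)
        expressions = [(iso1, *new_rearr(iso1))]
        if rng.random() < spec.p_coexpression and len(spec.isotype_probs) > 1:
            iso2 = _draw_isotype(spec.isotype_probs, rng, exclude={iso1})
            expressions.append((iso2, *new_rearr(iso2)))
        if rng.random() < spec.p_multi_pattern:
            expressions.append((iso1, *new_rearr(iso1)))
        for iso, seq, truth in expressions:
            emit(grp, ind, cid, iso, seq, truth)

    for ci, clone in enumerate(config.shared_clones):
        seq, truth = clone_cache[ci]
        for ind, cid in clone.placements:
            grp, _, _ = cell_index[(ind, cid)]
            emit(grp, ind, cid, clone.isotype, seq, truth)

    truth = pd.DataFrame(truth_rows)
    return SimBundle(reads=reads, truth=truth, config=config,
                     reference=reference)


# ---------------------------------------------------------------------------
# presets encoding the study conditions

def podocyte_config(seed: int, **overrides) -> SimulationConfig:
    """48 cells, HC 6 / MN 18 / IgAN 15 / IN 9, VH1-biased usage,
    restricted CDR3 pool, patient co-expression and extra-pattern rates
    chosen to hit the preset per-cohort multi-pattern fractions."""
    # p_multi_pattern solves 1-(1-pc*q)(1-pm*q) = target multi-pattern
    # fraction per cohort (HC 1/3, MN 11/18, IgAN 6/15, IN 5/9), with
    # pc the co-expression probability and q = 0.958 the productive rate,
    # since each co-expressed class carries its own pattern.
    cohorts = {
        "HC": CohortSpec(n_cells=6, n_individuals=1, p_coexpression=0.0,
                         p_multi_pattern=0.348, shm_scale=0.35),
        "MN": CohortSpec(n_cells=18, n_individuals=3, p_coexpression=1 / 3,
                         p_multi_pattern=0.448),
        "IgAN": CohortSpec(n_cells=15, n_individuals=4, p_coexpression=1 / 3,
                           p_multi_pattern=0.124),
        "IN": CohortSpec(n_cells=9, n_individuals=1, p_coexpression=4 / 9,
                         p_multi_pattern=0.236),
    }
    kw = dict(
        seed=seed, cohorts=cohorts,
        v_family_weights=dict(PODOCYTE_V_FAMILY_WEIGHTS),
        cdr3_mode="restricted",
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def bcell_config(seed: int, n_cells: int = 800, **overrides) -> SimulationConfig:
    """B-cell-like mode: VH3/VH4-weighted usage, Gaussian-like CDR3
    lengths, one pattern per cell."""
    cohorts = {"other": CohortSpec(n_cells=n_cells, n_individuals=1)}
    kw = dict(
        seed=seed, cohorts=cohorts,
        v_family_weights=dict(BCELL_V_FAMILY_WEIGHTS),
        cdr3_mode="gaussian_like",
    )
    kw.update(overrides)
    return SimulationConfig(**kw)
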