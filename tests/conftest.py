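"""Shared fixtures: a small germline reference and pre-annotated simulated
bundles reused across test modules (annotation is the expensive step)."""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ighrep.align import SegmentAlignment
from ighrep.annotate import QueryRead, VDJAssignment, annotate_reads
from ighrep.germline import build_fixture_reference
from ighrep.simulate import CohortSpec, SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def ref10():
    """10 V / 5 D / 4 J synthetic germline reference."""
    return build_fixture_reference(10, 5, 4, seed=11)


def _flat_config(seed, n_cells, rate, d_trim_means=(2.0, 2.0), **kw):
    return SimulationConfig(
        seed=seed,
        cohorts={"other": CohortSpec(n_cells=n_cells, n_individuals=1)},
        shm_rates={k: rate for k in ("IgA", "IgG", "IgM", "IgD", "IgE")},
        trim_means={"v3": 2.0, "d5": d_trim_means[0], "d3": d_trim_means[1],
                    "j5": 3.0},
        **kw,
    )


@dataclass
class AnnotatedBundle:
    bundle: object
    assignments: list
    qc: object

    @property
    def truth(self):
        return self.bundle.truth.set_index("read_id")

    @property
    def reference(self):
        return self.bundle.reference


def _annotated(ref, cfg) -> AnnotatedBundle:
    bundle = simulate_cohorts(ref, cfg)
    assignments, qc = annotate_reads(bundle.reads, bundle.reference)
    return AnnotatedBundle(bundle=bundle, assignments=assignments, qc=qc)


@pytest.fixture(scope="session")
def annotated_shm0(ref10):
    """250 mutation-free reads: junction recovery must be exact."""
    return _annotated(ref10, _flat_config(seed=5, n_cells=250, rate=0.0))


@pytest.fixture(scope="session")
def annotated_shm2(ref10):
    """250 reads at 2% SHM with light D trimming (cores mostly >= 8 nt)."""
    return _annotated(ref10, _flat_config(seed=6, n_cells=250, rate=0.02,
                                          d_trim_means=(1.0, 1.0)))


@pytest.fixture(scope="session")
def annotated_classes(ref10):
    """1000 reads in two isotype classes with distinct SHM targets
    (IgM 1%, IgG 6%), ~500 per class."""
    cfg = SimulationConfig(
        seed=7,
        cohorts={"other": CohortSpec(
            n_cells=1000, n_individuals=1,
            isotype_probs={"IgM": 0.5, "IgG": 0.5})},
        shm_rates={"IgM": 0.01, "IgG": 0.06},
        trim_means={"v3": 2.0, "d5": 1.0, "d3": 1.0, "j5": 3.0},
    )
    return _annotated(ref10, cfg)


@pytest.fixture(scope="session")
def vh1_usage_run(ref10):
    """2000 annotated reads drawn with the VH1-biased family weights
    (VH1 0.385 / VH3 0.396); returns (assignments, configured VH1 weight)."""
    from ighrep.simulate import PODOCYTE_V_FAMILY_WEIGHTS
    cfg = SimulationConfig(
        seed=8,
        cohorts={"other": CohortSpec(n_cells=2000, n_individuals=1)},
        shm_rates={"IgG": 0.02, "IgM": 0.01},
        v_family_weights=dict(PODOCYTE_V_FAMILY_WEIGHTS),
    )
    ann = _annotated(ref10, cfg)
    return ann.assignments, PODOCYTE_V_FAMILY_WEIGHTS["VH1"]


# ---------------------------------------------------------------------------
# lightweight fabricated assignments for statistics tests

def fake_assignment(v_call="IGHV1-18*01", d_call="IGHD2-2*01",
                    j_call="IGHJ4*01", junction="TGTGCGAGATTTGACTACTGG",
                    cell_id="c1", individual_id="i1", group="HC",
                    isotype="IgG", productive=True,
                    read_id=None) -> VDJAssignment:
    """A structurally minimal VDJAssignment for repertoire-statistics tests
    (alignment internals are placeholders)."""
    def seg(sid):
        return SegmentAlignment(
            segment_id=sid, score=100, query_interval=(0, 50),
            ref_interval=(0, 50), mismatch_positions=[], gap_count=0,
            identity=1.0, pairs_query=np.arange(50), pairs_ref=np.arange(50))

    read = QueryRead(
        read_id=read_id or f"{cell_id}_{isotype}_{junction[:8]}",
        sequence="ACGT" * 20, cell_id=cell_id, individual_id=individual_id,
        group=group, isotype=isotype)
    junction_ok = junction if productive is not None else None
    return VDJAssignment(
        read=read, v=seg(v_call), j=seg(j_call),
        d=seg(d_call) if d_call else None,
        n1="", n2="", trims={"v3": 0, "d5": 0, "d3": 0, "j5": 0},
        junction_nt=junction_ok, cdr3_nt=junction_ok[3:-3] if junction_ok else None,
        cdr3_length=len(junction_ok) - 6 if junction_ok else None,
        in_frame=True, has_stop=False, productive=productive)
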