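"""End-to-end pipeline: annotate -> SHM -> repertoire statistics ->
group comparisons -> JSON + Markdown report with a hashed MANIFEST.

The report mirrors the headline quantities of a single-cell IgH
repertoire characterization: functional rate, per-class detection
fractions, V/D/J usage, CDR3 length distribution with Gaussian-fit R^2,
shared rearrangements, co-expression / multi-pattern fractions and
Mann-Whitney SHM comparisons. Percentages are rounded to one decimal
place at report time only; raw ratios are always emitted alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import io as ighio
from .align import Scoring
from .annotate import AnnotateConfig, airr_table, annotate_reads
from .germline import GermlineReference, load_germline
from .shm import mutation_profile, profile_table, shm_by_class
from .simulate import SimulationConfig, simulate_cohorts
from .stats import (build_cells, cdr3_distribution, cell_summaries,
                    compare_shm_groups, find_shared_patterns, usage_frequencies)

__all__ = ["PipelineConfig", "run_pipeline", "detection_fractions"]


@dataclass
class PipelineConfig:
    out_dir: str
    reference_fasta: str | None = None
    reference_annotation: str | None = None
    reads_fasta: str | None = None
    reads_metadata: str | None = None
    airr_input: str | None = None
    seed: int = 0
    scoring: Scoring = field(default_factory=Scoring)
    annotate: AnnotateConfig | None = None
    motifs: tuple[str, ...] = ("RGYW", "WRCY")
    dedup_per_cell: bool = False
    holm_adjust: bool = False
    productive_only_ingest: bool = False
    simulator: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.annotate is None:
            self.annotate = AnnotateConfig(scoring=self.scoring)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Report-style rounding: 56.25 -> 56.3 (not banker's 56.2)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def detection_fractions(cells) -> pd.DataFrame:
    """Per-class positive-cell fractions, as percentages of all cells.

    A cell is positive for a class when any of its sequences carries that
    isotype label. Full-precision percentages; round only for display.
    """
    if not cells:
        raise ValueError("no cells")
    classes = ("IgG", "IgM", "IgA", "IgE", "IgD")
    n = len(cells)
    rows = []
    for cls in classes:
        pos = sum(1 for c in cells if cls in c.isotypes_expressed)
        rows.append({"isotype": cls, "n_positive": pos, "n_cells": n,
                     "percent": 100.0 * pos / n})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.Series,)):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig,
                 reference: GermlineReference | None = None) -> dict:
    """Run every stage and write the output bundle under ``out_dir``.

    Outputs, in order: annotated AIRR TSV (+ QC table), per-read and
    per-class SHM tables, usage tables, CDR3 histogram + fit, shared
    patterns, per-cell summaries, detection fractions, SHM group
    comparisons, then report.json / report.md and a MANIFEST with a
    sha256 per file. Deterministic given inputs and seed. Returns the
    report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"stages_completed": []}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[name] = _sha256(path)

    def checkpoint() -> None:
        (out / "MANIFEST.json").write_text(
            json.dumps({"files": manifest,
                        "stages_completed": report["stages_completed"]},
                       indent=2, sort_keys=True))

    try:
        # ---- ingestion ------------------------------------------------
        if config.simulator is not None:
            bundle = simulate_cohorts(reference, config.simulator)
            reference = bundle.reference
            reads = bundle.reads
            for name, path in bundle.write(out / "simulated").items():
                manifest[f"simulated/{path.name}"] = _sha256(path)
            report["simulated_truth_functional_fraction"] = float(
                bundle.truth["productive"].mean())
        elif config.airr_input is not None:
            reads, _, qc_in = ighio.ingest_airr(
                config.airr_input,
                productive_only=config.productive_only_ingest)
            report["ingest_qc"] = qc_in
        else:
            if not config.reads_fasta or not config.reads_metadata:
                raise ValueError("no input: need reads_fasta+metadata, "
                                 "airr_input or simulator block")
            reads = ighio.read_fasta_with_metadata(
                config.reads_fasta, config.reads_metadata)
        if reference is None:
            if not config.reference_fasta:
                raise ValueError("no germline reference given")
            reference = load_germline(config.reference_fasta,
                                      config.reference_annotation)
        report["n_reads_in"] = len(reads)
        report["stages_completed"].append("ingest")
        checkpoint()

        # ---- annotation ----------------------------------------------
        assignments, qc = annotate_reads(reads, reference, config.annotate)
        table = airr_table(assignments)
        save("rearrangements.airr.tsv",
             lambda p: ighio.write_airr(table, p))
        save("qc_unassignable.tsv", lambda p: qc.to_csv(p, sep="\t", index=False))
        n_called = len(assignments)
        determinate = [a for a in assignments if a.productive is not None]
        n_prod = sum(1 for a in determinate if a.productive)
        report.update({
            "n_assigned": n_called,
            "n_unassignable": len(qc),
            "n_productivity_determinate": len(determinate),
            "n_productive": n_prod,
            "functional_rate_percent": (100.0 * n_prod / len(determinate)
                                        if determinate else None),
        })
        report["stages_completed"].append("annotate")
        checkpoint()

        # ---- SHM ------------------------------------------------------
        profiles = [mutation_profile(a, reference, config.motifs)
                    for a in assignments]
        ptable = profile_table(profiles)
        save("shm_per_read.tsv", lambda p: ptable.to_csv(p, sep="\t", index=False))
        by_class = shm_by_class(profiles)
        save("shm_by_class.tsv", lambda p: by_class.to_csv(p, sep="\t", index=False))
        report["shm_by_class"] = {
            r["isotype"]: {"n": int(r["n"]),
                           "mean_frequency": None if pd.isna(r["mean_frequency"])
                           else float(r["mean_frequency"])}
            for _, r in by_class.iterrows()}
        report["stages_completed"].append("shm")
        checkpoint()

        # ---- repertoire statistics -------------------------------------
        for level in ("family", "gene"):
            usage = usage_frequencies(assignments, level=level,
                                      dedup_per_cell=config.dedup_per_cell)
            save(f"usage_{level}.tsv",
                 lambda p, u=usage: u.to_csv(p, sep="\t", index=False))
            report[f"usage_{level}"] = {
                stype: {row["category"]: float(row["frequency"])
                        for _, row in sub.iterrows()}
                for stype, sub in usage.groupby("segment_type")}

        lengths = [a.cdr3_length for a in assignments
                   if a.productive and a.cdr3_length is not None]
        dist = cdr3_distribution(lengths)
        save("cdr3_histogram.tsv",
             lambda p: dist.lengths.rename_axis("cdr3_length").reset_index()
             .to_csv(p, sep="\t", index=False))
        fit = {"amplitude": dist.amplitude, "mean": dist.mean, "sd": dist.sd,
               "r_squared": dist.r_squared}
        save("cdr3_fit.json",
             lambda p: p.write_text(json.dumps(fit, indent=2, sort_keys=True)))
        report["cdr3"] = {"n": len(lengths), **fit}

        cells = build_cells(assignments)
        shared = find_shared_patterns(cells)
        shared_df = pd.DataFrame([{
            "pattern_key": s.pattern_key,
            "n_cells": len(s.members),
            "members": ";".join(f"{c}@{i}" for c, i in s.members),
            "cross_individual": s.cross_individual,
        } for s in shared])
        save("shared_patterns.tsv",
             lambda p: shared_df.to_csv(p, sep="\t", index=False))
        report["shared_patterns"] = {
            "n_shared": len(shared),
            "n_cross_individual": sum(s.cross_individual for s in shared),
        }

        summary, per_cell = cell_summaries(cells)
        save("cell_summary.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False))
        save("per_cell.tsv", lambda p: per_cell.to_csv(p, sep="\t", index=False))
        report["cells"] = {
            row["group"]: {
                "n_cells": int(row["n_cells"]),
                "coexpression_percent": 100.0 * float(row["fraction_coexpressing"]),
                "multi_pattern_percent": 100.0 * float(row["fraction_multi_pattern"]),
            } for _, row in summary.iterrows()}

        det = detection_fractions(cells)
        save("detection_fractions.tsv",
             lambda p: det.to_csv(p, sep="\t", index=False))
        report["detection_percent"] = {
            row["isotype"]: float(row["percent"]) for _, row in det.iterrows()}
        report["stages_completed"].append("stats")
        checkpoint()

        # ---- group comparisons -----------------------------------------
        values = {}
        prod_ids = {a.read.read_id for a in assignments if a.productive}
        for grp, sub in ptable[ptable["read_id"].isin(prod_ids)].groupby("group"):
            values[grp] = sub["mutation_frequency"].tolist()
        if len(values) >= 2:
            tests = compare_shm_groups(values, holm_adjust=config.holm_adjust)
            save("shm_group_tests.tsv",
                 lambda p: tests.to_csv(p, sep="\t", index=False))
            report["shm_tests"] = [
                {k: (v if not hasattr(v, "item") else v.item())
                 for k, v in row.items()}
                for row in tests.to_dict(orient="records")]
        report["stages_completed"].append("compare")
        checkpoint()

        # ---- report -----------------------------------------------------
        report_json = json.dumps(_jsonable(report), indent=2, sort_keys=True)
        save("report.json", lambda p: p.write_text(report_json))
        save("report.md", lambda p: p.write_text(_markdown_report(report)))
        report["stages_completed"].append("report")
        checkpoint()
    except Exception as err:
        stage = (report["stages_completed"][-1]
                 if report["stages_completed"] else "ingest")
        checkpoint()
        raise RuntimeError(f"pipeline failed after stage '{stage}': {err}") from err
    return report


def _pct(x) -> str:
    return "n/a" if x is None else f"{round_half_up(x)}%"


def _markdown_report(report: dict) -> str:
    lines = ["# IgH repertoire report", ""]
    lines.append(f"- reads in: {report.get('n_reads_in')}; assigned: "
                 f"{report.get('n_assigned')}; unassignable: "
                 f"{report.get('n_unassignable')}")
    lines.append(f"- functional rate: {_pct(report.get('functional_rate_percent'))} "
                 f"({report.get('n_productive')}/"
                 f"{report.get('n_productivity_determinate')})")
    det = report.get("detection_percent", {})
    if det:
        lines.append("- detection: " + ", ".join(
            f"{k} {round_half_up(v)}%" for k, v in det.items()))
    cdr3 = report.get("cdr3", {})
    if cdr3:
        r2 = cdr3.get("r_squared")
        lines.append(f"- CDR3: n={cdr3.get('n')}, Gaussian fit R^2 = "
                     + ("n/a" if r2 is None else f"{r2:.2f}"))
    sp = report.get("shared_patterns", {})
    if sp:
        lines.append(f"- shared rearrangements: {sp.get('n_shared')} "
                     f"({sp.get('n_cross_individual')} cross-individual)")
    for grp, d in report.get("cells", {}).items():
        lines.append(f"- {grp}: n={d['n_cells']}, co-expression "
                     f"{round_half_up(d['coexpression_percent'])}%, "
                     f"multi-pattern {round_half_up(d['multi_pattern_percent'])}%")
    for t in report.get("shm_tests", []):
        lines.append(f"- SHM {t['group_a']} vs {t['group_b']}: "
                     f"U={t['U']:.1f}, p={t['p_two_sided']:.3g} {t['stars']}")
    lines.append("")
    return "\n".join(lines)
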