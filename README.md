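# ighrep

Single-cell immunoglobulin heavy-chain (IgH) repertoire analysis:
germline V(D)J assignment, junction decomposition, productivity calling,
somatic-hypermutation (SHM) and AID hotspot-motif analysis, repertoire
statistics, and a ground-truthed V(D)J recombination simulator.

## The problem

Heavy-chain transcripts amplified from single cells — classically B
cells, but also non-B cells such as kidney podocytes — carry a somatic
V\_H\_DJ\_H rearrangement: one IGHV, one IGHD and one IGHJ germline
segment joined with exonucleolytic trimming of the segment termini and
non-templated (N) nucleotide insertions at the V–D and D–J joins, then
diversified by AID-driven somatic hypermutation. Characterizing such a
repertoire means answering, per sequence and per cell:

* **Which germline segments?** Best-matching V/D/J by local alignment
  (match +2, mismatch −2, gap open −4, gap extend −1; deterministic
  tie-breaking by score, aligned length, then segment id).
* **What junction?** The span from the conserved 2nd-CYS codon of V
  through the J-TRP codon of J; CDR3 is the junction minus both anchor
  codons; trims (v3, d5, d3, j5) and inserts (n1, n2) are read off the
  alignments.
* **Productive?** In-frame (CYS→TRP distance ≡ 0 mod 3) and stop-free.
* **How mutated?** SHM frequency = substitutions per germline-aligned
  nucleotide over FR2→JH; a sequence is *mutated* at ≥ 2% (< 98%
  germline homology). The share of mutations inside RGYW/WRCY hotspot
  4-mers (R=A/G, Y=C/T, W=A/T; scanned on the germline) above 25% is
  the antigen-driven-selection criterion.
* **Repertoire structure?** V/D/J family and gene usage, the CDR3
  length histogram with a least-squares Gaussian fit and its
  R² = 1 − SS_res/SS_tot, identical rearrangements shared between cells
  and individuals, per-cell isotype co-expression and multi-pattern
  counts, and Mann–Whitney U comparisons of SHM between cohorts.

Because single-cell amplicon studies rarely ship raw reads, the package
includes a first-class simulator: it generates reads as
`V[0:len−v3] + n1 + D[d5:len−d3] + n2 + J[j5:]` with hotspot-biased SHM
applied to the templated positions, under configurable cohort structure
(isotype probabilities, per-class SHM targets, co-expressing and
multi-pattern cells, shared clones, family-biased V usage, and a
"restricted" junction-template mode that produces non-Gaussian CDR3
spikes). Every read carries full ground truth, so each pipeline stage is
verifiable without external data.

## Worked example

```python
from ighrep import (build_fixture_reference, annotate_reads,
                    mutation_profile, cdr3_distribution, simulate_cohorts,
                    podocyte_config)

ref = build_fixture_reference(n_v=10, n_d=5, n_j=4, seed=11)
bundle = simulate_cohorts(ref, podocyte_config(seed=4))   # 48 cells
assignments, qc = annotate_reads(bundle.reads, ref)

productive = [a for a in assignments if a.productive]
print(f"{len(assignments)} assigned, "
      f"functional rate {100 * len(productive) / len(assignments):.1f}%")

profiles = [mutation_profile(a, ref) for a in assignments]
mutated = sum(p.is_mutated for p in profiles)
print(f"{mutated} of {len(profiles)} sequences mutated (>= 2%)")

lengths = [a.cdr3_length for a in productive]
print(f"CDR3 Gaussian-fit R^2 = {cdr3_distribution(lengths).r_squared:.2f}")
```

prints

```
75 assigned, functional rate 97.3%
40 of 75 sequences mutated (>= 2%)
CDR3 Gaussian-fit R^2 = 0.00
```

75 sequences come from the 48 cells (co-expressing and multi-pattern
cells contribute more than one), 97.3% are in-frame and stop-free, the
patient cohorts' IgG/IgA sequences push just over half past the ≥ 2%
mutated threshold, and the near-zero R² says the CDR3 length histogram
is far from Gaussian — the restricted-diversity signature, in contrast
to the B-cell-like mode where the same fit returns R² ≈ 0.95.

The same pipeline runs from the shell:

```
ighrep run --config config.json --out-dir out/
```

producing an AIRR rearrangement TSV, per-read and per-class SHM tables,
usage tables, the CDR3 histogram and fit, shared-pattern and per-cell
reports, Mann–Whitney cohort comparisons, and `report.json`/`report.md`
with a hashed MANIFEST. External data can be supplied as FASTA + metadata
TSV, an AIRR rearrangement TSV, or a 10x `filtered_contig_annotations`
CSV (with pass-through of existing V/D/J calls).

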