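# Methods

## Annotation model

Reads are assumed to be coding-strand IgH amplicons spanning (part of)
the V region through the start of FR4. Annotation proceeds V → J → D:

1. **V assignment.** Optimal local alignment (Gotoh affine; match +2,
   mismatch −2, gap open −4, gap extend −1, a length-L gap costing
   4 + (L−1)) of the read against every V in the reference. The winner
   is chosen by score, then gap-free aligned length, then
   lexicographically smallest segment id; a surviving tie sets an
   `ambiguous` flag. A V call requires both ≥ 100 gap-free aligned
   columns and a score of at least `match × 100`: a chance alignment can
   *span* 100 reference nt (scattered matches bridged by gaps) but
   cannot reach the score of 100 cleanly matched positions. If forward
   assignment fails, one reverse-complement rescue pass runs.
2. **J assignment.** Same procedure against every J, restricted to the
   read 3′ of the V alignment end; ≥ 18 aligned columns required.
3. **D assignment.** Ungapped scan of every D over the window strictly
   between V end and J start, exact over all diagonals via prefix sums.
   A D call requires ≥ 5 contiguous exact matches inside the chosen
   segment (configurable); the reported segment is the highest-scoring
   ungapped run-containing stretch. No D is a legal outcome.
4. **Junction decomposition.** n1 = read between V end and D start
   (or the whole window when no D), n2 = read between D end and J
   start; trims v3/d5/d3/j5 are the unaligned germline termini.
5. **Productivity.** The junction runs from the 2nd-CYS codon (mapped
   through the V alignment from the germline `cdr3_anchor`) through the
   J-TRP codon inclusive; CDR3 excludes both anchor codons. In-frame ⇔
   CYS→TRP distance ≡ 0 (mod 3); stop codons are scanned in the CYS
   frame from the first aligned V position to the end of the aligned J;
   productive = in-frame ∧ stop-free. If an anchor falls in a trimmed or
   unaligned region the junction is undefined and productivity is
   *indeterminate* (excluded from functional-rate denominators).

Reads containing N keep N scored as a mismatch (it matches nothing) and
N positions are never counted as mutations. Indels relative to germline
are not modelled as SHM; gapped alignments are annotated but excluded
from the substitution-reconstruction identity.

## SHM and hotspot analysis

SHM is counted over germline-aligned positions from the FR2 start (on
the V) through the end of the aligned J, across V, D (if called) and J.
N-insert positions enter neither numerator nor denominator. If the
alignment starts 3′ of FR2 the profile is flagged partial and starts at
the first aligned position. Thresholds follow the field's convention:
*mutated* at frequency ≥ 2% (inclusive), *antigen-selected* at hotspot
ratio > 25% (strict).

Hotspot windows are the degenerate 4-mers RGYW and WRCY (its
reverse-complement reading), both scanned on the **germline** sequence
of each segment: AID targets the germline motif and a mutation can
destroy the very motif it hit. A position is a hotspot position if any
window covers it. The per-sequence hotspot ratio is (mutations at
hotspot positions)/(all mutations), undefined at zero mutations; a
pooled-across-sequences variant is provided
(`pooled_hotspot_ratio`). A config flag restricts scanning to RGYW
only.

## Repertoire statistics

* **Usage**: per segment type, family- or gene-level (alleles collapsed
  at `*`) counts and frequencies; reads without a D call are excluded
  from the D denominator and reported separately. Default counting is
  per sequence; a dedup flag collapses to unique
  (cell, isotype, pattern).
* **CDR3 length distribution**: integer histogram binned on the lattice
  the data occupy (bin step = gcd of pairwise length differences —
  productive-only repertoires live on the multiple-of-3 lattice, and
  binning at step 1 would let structural zeros dominate the fit).
  Gaussian fit A·exp(−(x−μ)²/2σ²) by nonlinear least squares,
  initialized at (max count, sample mean, sample sd);
  R² = 1 − SS_res/SS_tot against the mean-count baseline. Fewer than 4
  distinct lengths → fit refused (R² undefined), histogram still
  returned. R² is invariant to scaling all counts.
* **Shared rearrangements**: the clone identity is the `pattern_key` —
  gene-level V|D|J plus the exact junction nucleotides; ≥ 2 cells with
  an identical key form a shared pattern, flagged cross-individual when
  they span ≥ 2 individuals. Output order is deterministic (by key) and
  invariant to input order.
* **Per-cell summaries**: co-expression = ≥ 2 distinct isotype labels in
  a cell; multi-pattern = ≥ 2 distinct productive pattern keys. Reported
  per cohort, pooled patients (all non-HC), and overall.
* **Group comparisons**: two-sided Mann–Whitney U with tie midranks;
  exact enumeration when n_a + n_b ≤ 20 with no ties, otherwise the
  normal approximation with tie and continuity correction (the method
  used is reported). All-identical input is degenerate with p = 1. All
  pairwise cohort tests plus pooled patients vs control are reported
  with significance stars at 0.05/0.01/0.001/0.0001. No multiplicity
  adjustment by default (a Holm-corrected column is optional), matching
  the convention of reporting raw U-test stars.

Percentages are rounded half-up to one decimal only at report time
(56.25 → 56.3); raw ratios are always emitted alongside.

## Simulator

Reads are built as `V[0:len−v3] + n1 + D[d5:len−d3] + n2 + J[j5:]`,
then SHM is applied. Distributional choices (all config-exposed):

| parameter | default | note |
|---|---|---|
| trim lengths v3/d5/d3/j5 | geometric, means 2/2/2/3 nt | minimal standard choice |
| N-insert lengths | Poisson, mean 4.5 nt each | |
| per-class SHM targets | IgD 0.002, IgM 0.01, IgA 0.06, IgG 0.06, IgE 0.05 subs/nt | rare IgD, low IgM, high IgA/IgG/IgE |
| hotspot bias b | 3 | per-site probability b·p at hotspot positions |
| p_productive | 0.958 | per-rearrangement probability of forcing a productive junction |

SHM calibration: with T templated positions of which h are hotspots,
the per-site probability is p = rate·T/(h·b + T − h), b·p at hotspots
(error if b·p > 1), so the expected overall rate equals `rate` and the
expected hotspot share of mutations is b·f/(b·f + 1 − f) for hotspot
fraction f. Only germline-templated positions mutate; N inserts are
already random. Forced-productive (or forced-unproductive) draws
resample the junction *and* the mutation draw until the post-SHM read
satisfies the constraint, within a bounded retry budget.

**Identifiability by construction.** Junction draws whose boundary bases
a local aligner could re-absorb — a trimmed germline continuation whose
comparison against the query reaches a cumulative score ≥ 0 under
+2/−2, directly or after a gap shift of up to 6 nt — are rejected and
redrawn; j5 trims are capped to leave ≥ 6 identifying J-head nt. The
synthetic reference reinforces this: fixture D segments share no 5-mer
(within or across segments) and fixture J heads have pairwise-distinct
lengths, so impostor segments cannot tie the true segment's score. This
slightly conditions the trim/N distributions but makes ground-truth
junction recovery exact at SHM 0, which is what the recovery tests
assert. Without these constraints exact recovery is information-
theoretically unattainable (trimmed-base/insert collisions are
genuinely ambiguous).

**Cohorts.** Each cell draws one isotype and one rearrangement; with
probability `p_coexpression` it adds a second, different isotype *with
its own rearrangement* (classes within a cell never share a pattern);
with probability `p_multi_pattern` it adds an extra same-class pattern.
The multi-pattern fraction of a cohort is therefore
1 − (1 − pc·q)(1 − pm·q) with q the productive rate. Shared clones are
generated once and injected into named (individual, cell) slots.
`cdr3_mode="gaussian_like"` draws free junctions (the sum of trim/insert
components yields an approximately discretized-normal CDR3 length;
Gaussian-fit R² ≈ 0.95 at n = 800); `"restricted"` draws from a small
pool of fixed (D, J, trims, inserts) templates with distinct junction
lengths, producing spike histograms (R² ≈ 0–0.2). In restricted mode
identical junctions recur across cells and individuals, so
cross-individual shared patterns arise naturally from the restriction
itself; `shared_clone_spec` exists for placing specific clones in tests.

**Study-condition presets.** `podocyte_config`: 48 cells split
HC 6 / MN 18 / IgAN 15 / IN 9 over 1/3/4/1 individuals; isotype
probabilities proportional to the per-class detection frequencies
(IgG 60.4 / IgM 56.3 / IgA 12.5 / IgE 10.4 / IgD 4.2); VH family
weights VH1 0.385 / VH3 0.396 / VH4 0.12 (rest split); restricted CDR3;
HC SHM scaled by 0.35 so patients exceed controls; co-expression
probabilities HC 0, MN/IgAN 1/3, IN 4/9 and `p_multi_pattern` solved
per cohort so expected multi-pattern fractions are 1/3, 11/18, 6/15 and
5/9. `bcell_config`: one cohort, VH3 0.523 / VH4 0.251 / VH1 0.129,
Gaussian-like CDR3.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis
consumes — junction arithmetic, hotspot-biased substitution SHM, class
labels, cohort contrasts, sharing, co-expression — but not real
sequence biology: no allele-level germline variation, no indel SHM, no
context-dependent mutability beyond the RGYW/WRCY bias, no clonal
expansion or sequencing-error model (fold Sanger error into the rate),
and reads always start at V position 0. Passing recovery tests
therefore demonstrates correctness of the annotation arithmetic and
calibration machinery on in-model data, not robustness to real-data
artefacts such as primer remnants, indels or allele mismatches. Real
germline references (e.g. IMGT exports) load through the same
FASTA + sidecar interface.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (250-read recovery
  bundles, 1000-read class-rate bundle, 2000-read usage bundle, 1000
  oracle reads, 1000 null replicates) are chosen so each check's
  binomial/statistical resolution comfortably exceeds its asserted
  tolerance.
* Co-optimal alignment traces follow biotite's deterministic first
  trace; cross-segment ties are broken by (score, aligned length, id).
* The Gaussian fit can legitimately converge to the flat baseline
  (R² ≈ 0) on symmetric spike histograms, or fail to converge on some
  pathological inputs (fit then reported as refused).
* `mann_whitney_u` delegates to `scipy.stats.mannwhitneyu`; the exact
  path is validated against an independent enumeration oracle in the
  test suite.
* The conserved-anchor fixture geometry (2nd-CYS at V offset 288, TGG
  at J offsets 15+3i) keeps all J anchors in frame 0, so restricted
  templates stay frame-compatible across J choices.
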