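# Methods

## Model and estimands

The package quantifies tissue-specific codon demand in three layers.

**Elongator-codon counting.** A CDS is read in frame; the initiator codon is
always excluded, and the terminal codon is excluded if and only if it is a
stop triplet, so that only codons decoded by elongating tRNAs are counted.
Codons containing ambiguous bases are skipped and removed from the
denominator (guessing at an N would bias frequencies toward whatever
convention resolved it). Counts are stored in a fixed 64-slot vector so the
downstream "divide by the maximum across all 64 codons" step is literal;
stop slots are zero for any clean CDS. On deliberately dirty input
(lenient mode) an internal stop triplet is recorded in its own slot but does
not enter the elongator total, which keeps the invariant
`sum(sense counts) == total_elongator` and the conservation identity
`total = #codons − 1 − terminal stop − ambiguous − internal stops` exact.

**Expression weighting.** Per-tissue usage is
`U_t(c) = Σ_g k̃_gt · f_g(c)`: normalised counts times per-CDS codon
*frequency* (not raw codon counts). Frequency-weighting makes each gene's
contribution independent of its CDS length; with uniform counts the result
is the mean per-CDS frequency, which deliberately differs from the
length-weighted genome aggregate when lengths vary (asserted as an
inequality test). The genome baseline is the unweighted count aggregate
over all longest-isoform CDS — a sequence-level property of the gene set,
not of any expression state.

**Bias ratio.** Both the tissue usage vector and the genome frequency are
max-normalised (peak = 1) before the per-codon ratio is taken. On this
scale the ratio is invariant under any global rescaling of a tissue's
counts, so it is comparable across sequencing depths and library sizes; a
frequency-scale ratio (`on="frequency"`) is available for sensitivity
analysis and agrees in ordering, differing only by the ratio of the two
vectors' peak slots. Codons with zero genome usage get no ratio and are
reported as undefined rather than infinite.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `min_elongator` (ranking) | 50 codons | fractions on shorter CDS are dominated by sampling noise; configurable |
| `focus_set` | {ACT, ACC} | the ACY threonine codons decoded by tRNA-Thr-AGT directly and via wobble |
| `flag_threshold` | 1.1 | a tissue is flagged only when every focus codon exceeds the genome baseline by >10% |
| `max_zero_columns` (size factors) | 0 | reference genes must be detected in every sample; raising it enables a pseudo-reference on sparse matrices |
| isoform tie-break | lexicographic smallest transcript id | deterministic when two isoforms have equal length |

The flag threshold deserves a note: the estimated ratio of an unenriched
tissue is centred at 1 with a few percent of sampling noise (finite CDS
length × finite gene number), so a strict "ratio > 1" rule would flag
roughly a quarter of null datasets by chance. The 10% margin makes the flag
mean "meaningfully above baseline" and calibrates the null to ≲1 flag in 20
replicates at the default simulation size; set `flag_threshold=1.0` for the
strict rule. The reported ratios themselves are never thresholded.

## What the synthetic generator emulates

`SimSpec` draws a gene catalog and a count matrix with known structure:

- Each CDS is `ATG` + i.i.d. sense codons + `TAA`. Codon probabilities are
  amino-acid frequency × within-family synonymous preference. Body length
  is uniform on 300–900 codons (the scale of typical fly CDS). i.i.d.
  draws carry no positional autocorrelation — the simplest structure that
  exercises the pipeline's estimands.
- Baseline amino-acid frequencies follow a typical eukaryotic proteome;
  synonymous preferences use a generic C/G-wobble skew, except the
  threonine family, where ACT/ACC are deliberately the minor codons
  (0.18/0.22 vs ACA 0.35, ACG 0.25) so that a planted ACT/ACC boost is a
  genuine minor-to-major synonymous shift with a stable, non-focus maximum
  slot in the 64-vector.
- A planted enrichment multiplies the focus codons by f ≥ 1 *within their
  synonymous family* and renormalises the family, holding amino-acid
  composition fixed — isolating synonymous bias, the footprint a
  tRNA-modification effect would leave.
- 40% of genes are background (no home tissue, baseline expression
  everywhere, member of no gene list); the rest are split round-robin into
  per-tissue modules. Module genes have mean expression `depth × 8` in
  their home tissue and `depth` elsewhere (`depth` = 1000). Counts are
  negative binomial with size parameter `dispersion` = 10
  (variance = μ + μ²/10, i.e. ~32% biological CV; ∞ recovers Poisson).
  Optional planted per-column scale factors exercise the size-factor stage.
- Everything is driven by one integer seed through independent
  `SeedSequence` streams; catalog, counts and all downstream tables are
  byte-reproducible.

`expected_bias` gives the closed-form expectation of the pipeline's focus
ratios under a spec, by mixture algebra over the preference vectors and
expression weights (module sizes × home-boost weights, or the gene-list
restriction), followed by the same max-normalisations the pipeline applies.
It is the parameter-recovery target for the planted-bias tests.

What the generator does **not** emulate: real codon-order correlation,
splice isoforms, 3'/5' coverage bias, read-level noise, annotation errors,
or correlated expression across tissues. Passing tests therefore show the
*estimator pipeline* is correct and calibrated under its stated noise
model, not that any particular biological dataset will show a bias.

## Numerical and design choices

- Counting is strand-specific on the given CDS; reverse complements are a
  different sequence by design.
- The per-tissue sum defaults to all genes matched between the count matrix
  and the catalog; a per-tissue gene list (e.g. differentially expressed
  genes) restricts it. Rows are resolved by gene id, then transcript id,
  then an optional explicit map; unmatched rows are skipped with a logged
  count rather than raised, since annotation mismatches are routine.
- Ranking ties break by elongator total (desc), then gene id (asc), making
  the table fully deterministic.
- Validation is advisory: flags (frame, start, internal stop, terminal
  stop, ambiguity) are reported per CDS, and only the pipeline's strict
  mode promotes frameshifts/internal stops to errors — counting codons on a
  frameshifted CDS is meaningless, but annotation noise should not kill a
  genome-scale run by default.
- Output tables are written with a fixed `%.12g` float format and sorted
  JSON keys, so reruns on identical inputs are byte-identical.
- Size-factor estimation fails loudly when no row is detected in every
  sample, pointing at the pseudo-reference option instead of silently
  switching estimators.

## Problem sizes

The default simulation (500 genes, 300–900 codon bodies, 3 tissues) runs a
full generate-normalise-weight-compare replicate in ~0.2 s; the acceptance
script's 50-odd replicates complete in well under a minute. At these sizes
the estimated focus ratio carries ~2–4% relative noise, which is why the
planted-bias recovery checks average 10 seeded replicates and compare to
the analytic expectation at 10% tolerance.

## Known limitations

- The bias ratio is descriptive; no significance test is attached (none is
  defined for the estimand), so "flagged" means "exceeds the noise margin",
  not "statistically significant".
- Expression rows that are transcript-keyed while the catalog is gene-keyed
  rely on the id-rule/alias resolution; a wrong mapping silently shrinks
  `n_genes_used` (it is reported precisely so users can notice).
- Max-normalisation ties the whole vector to the single peak slot; if a
  focus codon itself were the peak, its ratio would saturate at 1. With
  realistic amino-acid compositions the peak is a glutamate/lysine codon
  and this does not arise, but it is a structural property of the 0–1
  scaling step worth knowing.
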