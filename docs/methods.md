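# Methods

## Communication model

Expression is assumed log-normalized: counts scaled to 10,000 per cell
and log1p-transformed. Within one condition, each cluster's level of each
gene is Tukey's trimean (Q₁ + 2·Q₂ + Q₃)/4 of these values, with
quantiles by linear interpolation (the type-7 convention). The quantile
convention is stated deliberately: at small cluster sizes different
conventions give different trimeans, and type 7 is what the standard
numerical stacks default to. The trimean is zero whenever all three
quartiles are zero, so a gene expressed in under a quarter of a
cluster's cells contributes nothing — this is what makes the summary
robust to rare-cell noise and what makes compartment-restricted
expression translate into exactly-zero reverse-direction communication.

A heteromeric ligand or receptor takes the geometric mean of its subunit
trimeans, and is zero if any subunit is absent: all parts of a complex
are required. The probability that a sender cluster with ligand level L
signals to a receiver with receptor level R is the saturating
mass-action response L·R/(K_h + L·R). Defaults, all exposed in
`PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| `kh` | 0.5 | Hill half-saturation, on the scale of products of log-normalized levels |
| `min_cells` | 10 | clusters below this size (per condition) are ineligible |
| `alpha` | 0.05 | significance threshold for permutation p-values and padj |
| `n_perm` | 100 | cluster-label permutations |
| `epsilon` | 1e-9 | pseudo-score for the optional finite induction ratios |
| `de_min_pct` | 0.10 | minimum expressing-cell fraction to test a gene |
| `de_lfc_threshold` | 0.25 | minimum \|log2FC\| to test a gene |

`kh`, the geometric-mean complex rule and label permutation with
`n_perm = 100` are the documented defaults of the communication-inference
methodology this scoring layer builds on; agonist/antagonist cofactors
and population-size weighting (options of that methodology) are off and
not implemented.

## Permutation significance

Within one condition, the cluster labels of the condition's cells are
shuffled `n_perm` times and the full tensor recomputed; the p-value of an
entry is (1 + #{P\* ≥ P_obs})/(1 + n_perm). The +1 correction keeps p in
(0, 1] at finite n_perm. Two details are part of the contract:

- **Stream rule.** The permutation RNG is
  `default_rng(SeedSequence([seed, crc32(condition)]))`, and each
  permutation shuffles the integer-coded label vector of the condition's
  eligible-cluster cells in dataset order. This makes p-values
  reproducible bit-for-bit given the seed, and condition-local: labels
  are never shuffled across conditions, since tensors are computed per
  condition.
- **Eligibility.** Cells of ineligible clusters are excluded from the
  permutation pool, not merely masked afterwards. Consequence (tested):
  deleting an ineligible cluster from the input changes no unmasked
  entry.

Under exchangeability every permuted statistic ties the observed one for
constant genes (0 ≥ 0), giving p = 1 rather than spurious significance.

## Crosstalk scoring

Entries with p < `alpha` are summed per pathway over its interactions
and over (sender, receiver) pairs grouped into the four
compartment-direction classes. The total is computed as the sum of the
four class sums, so conservation (classes sum to total) holds exactly,
not to rounding. Crosstalk fractions divide by that total; a pathway
with no significant communication carries zero fractions and a
`zero_total` flag. "Multi-directional" is defined as the sum of the two
cross-compartment classes (stromal→immune + immune→stromal) — the
reading consistent with listing it alongside the two uni-directional
scores — and is therefore ≤ total by construction.

Ranking sorts by crosstalk fraction, breaking ties by directional score
and then pathway name, with zero-total pathways last; the result is a
total order, invariant to input order.

Induction ratios divide a pathway's directional score in an alternate
(injured) condition by the reference (first-listed, "Sham") condition.
Ratios are computed on summed probabilities by default
(`ratio_on_fractions` switches to fractions). Zero-baseline handling is
explicit: reference 0 with alternate > 0 is flagged `infinite`, both
zero `undefined`; with `use_epsilon_ratios` the ratio column instead
holds (alt + ε)/(ref + ε), which totally orders zero-reference pathways
by their injured-condition score — the comparison the recovery analyses
use. Both tables must come from the same database (fingerprint check).

Hierarchy edge lists give, per pathway, the summed significant
probability for every (sender, receiver) pair with a positive sum — the
numeric content of a hierarchy plot where line thickness encodes
communication strength.

## Differential expression and overlap

`wilcoxon_de` follows the standard single-cell marker-test convention:
genes pass if expressed in ≥ `de_min_pct` of either group and
|log2FC| ≥ `de_lfc_threshold`, with log2FC on expm1-scale group means
with pseudocount 1; surviving genes get a two-sided Wilcoxon rank-sum
p-value (normal approximation with tie and continuity correction, via
`scipy.stats.mannwhitneyu`) and BH adjustment over tested genes. The
normal approximation is accurate to a few hundredths against exact
enumeration at group sizes ≤ 10 (tested), and indistinguishable at the
group sizes single-cell clusters provide. The directional overlap takes
the two tables' padj < `alpha` sets and partitions their union into
exclusive and shared genes; "same direction" is the sign of log2FC
alone, with no magnitude floor.

## Synthetic data generator

The generator emulates a Sham / 7-day-injury synovial design: two
conditions, four clusters (lining fibroblasts and pericytes as stroma;
macrophages and T cells as immune) with 100–150 cells per cluster per
condition, 2,000 genes with negative-binomial counts at mean 0.5 and
dispersion 2 (variance μ + μ²/θ), i.e. ≈64% zeros at baseline — sparsity
in the range of real droplet scRNA-seq. Cell numbers per cluster are a
power choice, not a fidelity claim. Planted signals multiply the mean of
their ligand genes in the sender cluster and receptor genes in the
receiver cluster by `fold_effect` in active conditions. `exclusive=True`
additionally silences the planted genes outside their planted cluster
and outside active conditions — the compartment-confined,
injury-induced structure of M-CSF signaling, and the configuration under
which reverse-direction scores are exactly zero. The default
ligand-receptor database holds the planted interactions plus 20
single-interaction decoy pathways on distinct, randomly chosen
background genes, so ranking is non-trivial: decoys are exchangeable
across clusters and reach significance at roughly the nominal 5% rate.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation, cluster-specific library sizes, or
continuous cell states. Passing recovery tests therefore demonstrates
that the scoring layer recovers planted directional signal against
exchangeable noise at realistic sparsity — not that it is robust to the
full failure modes of real tissue data.

One root seed drives everything through `SeedSequence` spawning (count
draws first, then decoy gene choice), so identical configs are
bit-identical.

## Recovery and calibration analyses

The planted-recovery analysis uses the two-ligand CSF structure (Csf1
from fibroblasts and Il34 from pericytes converging on macrophage
Csf1r, fold effects 8 and 6, active only after injury) among 20 decoys,
20 seeds per run. A single-ligand pathway is recoverable as rank 1 but
is a weaker induction-ratio discriminant: because the Hill response
saturates near baseline expression, a decoy that reaches chance
significance in two stromal→immune entries can out-sum one planted
interaction, while the two-edge pathway clears every decoy's attainable
sum. Null calibration uses 200 decoy interactions on signal-free data
(4×100 cells), 5 seeds; the significant fraction sits near the nominal
0.05. Problem sizes throughout (cells per cluster, gene counts, seed
counts) are chosen so the full suite and the acceptance script run in
well under a minute each on one CPU while leaving clear margins on every
property.

## Numerical and degenerate-input policy

- Trimean of an empty vector, unknown genes/clusters/pathways, absent
  conditions, unbound databases, non-covering compartment maps: errors
  naming the offending field.
- A compartment with no eligible cluster is an error naming the
  compartment (crosstalk direction would be undefined).
- Zero library-size cells (possible only at extreme configurations) are
  left as all-zero rows rather than dividing by zero.
- Exceedance uses `P* >= P_obs` with exact float comparison; ties occur
  by construction (identical recomputed values, e.g. all-zero entries)
  and are counted as exceedances, which is what makes constant data give
  p = 1.
- TSV outputs carry `# key=value` provenance headers (seed, alpha, kh,
  n_perm, database fingerprint) and full-precision floats, so re-runs
  are byte-comparable and stage re-runs from files reproduce in-memory
  results.

## Known limitations

- The permutation test calibrates cluster-specificity, not biological
  causality; saturated Hill probabilities make raw scores insensitive to
  expression differences above ~4·K_h.
- Fraction-based ranking can tie unrelated pathways at fraction 1.0 when
  each has a single significant direction; the score tie-break resolves
  this deterministically but the fraction itself carries no strength
  information.
- Multi-condition designs are compared pairwise against the first-listed
  reference only; there is no joint trajectory of induction across
  conditions.
- The DE module implements the default marker-test behavior only (no
  latent-variable covariates, no pseudobulk aggregation).
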