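# Methods notes

## Scope and data model

The package implements the analysis that follows a genome-wide TF-family
screen under a six-step NaCl gradient (T0, T30, T60, T90, T120, T150 mM;
replicated samples, default 3, i.e. 18 samples). Expression is consumed as
a TPM matrix (genes × samples) with a sample→treatment sidecar; genomes as
FASTA + GFF3 (1-based closed coordinates); homology evidence as BLAST
outfmt-6 and HMMER tabular files produced externally. The package does not
run aligners or homology searches, build phylogenies, or call motif
discovery — those stages' tabular outputs are inputs.

## Family identification

Candidates = {ids with an HMM domain hit at E ≤ evalue_max} ∩ {ids with at
least one BLAST row at identity ≥ identity_min and E ≤ evalue_max}.
Both thresholds are inclusive (the convention when a cutoff is quoted
without strictness), and a query with several HSP rows survives if *any*
row passes — the common behaviour of gene-family screens; per-query-best-hit
filtering can be emulated upstream. Renaming orders genes by natural
chromosome sort (chr09 < chr10), then start, then id, and is a bijection
independent of input order.

## Protein properties

GRAVY, the instability index and average molecular weight are computed via
Biopython, which carries the published Kyte–Doolittle and Guruprasad DIWV
tables; the test suite independently re-derives every value from the raw
tables on short peptides. The aliphatic index uses Ikai's coefficients
(a = 2.9, b = 3.9) on mole percents. The pI is the root of the
Henderson–Hasselbalch net charge (positive: N-terminus, K, R, H; negative:
C-terminus, D, E, C, Y), found by bisection on pH ∈ [0, 14] to a 1e-3
tolerance. Because printed pI values depend on the pKa set, the set is a
named, swappable table: `expasy` (Bjellqvist-compatible, default, matching
ProtParam-style tools) and `emboss`. Non-standard residues (X, B, Z, U, …)
are rejected with a clear error rather than silently skipped, so property
values are never computed on partially understood sequences.

## Promoters and cis-regulatory elements

The promoter is the 2000 bp upstream of the annotated gene start:
`[start−2000, start−1]` for plus-strand genes, `[end+1, end+2000]`
reverse-complemented for minus-strand genes, truncated (never padded) at
chromosome boundaries and returned 5′→3′ relative to the gene. Scanning is
plain IUPAC matching compiled to character-class regexes with lookahead, so
overlapping occurrences are all reported; reverse-strand hits are found by
scanning the reverse complement of the pattern on the forward sequence and
are reported at the leftmost forward-strand offset, which makes a
palindromic site appear once per strand — deliberate, since strandedness of
a CRE call is usually reported by scanners and the double count is easy to
collapse downstream.

The shipped 38-element catalog (10 stress, 11 hormone, 17 growth) is the
package's own editable choice of PlantCARE-style elements; analyses of real
genomes should substitute their own scanner's table via the motif TSV. The
family-level summary reports both occurrence totals and distinct element
types per category; percentage shares (1-decimal, half-away-from-zero) are
computed over distinct types, because published three-way splits count
element types while per-gene burdens count occurrences. Elements outside
the three-way map are flagged `other` and excluded from the split.

## Expression filtering and pattern classes

A gene is dropped only if TPM < 1 in *every* sample (one expressed sample
rescues it); filtering is idempotent. Replicate summaries are arithmetic
means per treatment — the conventional choice for TPM and the least
surprising default. Pattern classification works on the 6 treatment means
with a tolerance band τ = rel_tol·(max − min), default rel_tol = 0.1:

1. continuous_down — every step ≤ +τ and last < first − τ;
2. continuous_up — symmetric;
3. biphasic — interior maximum exceeding both endpoints by > τ;
4. reverse_biphasic — interior minimum below both endpoints by > τ;
5. other — flat profiles (max = min) and everything else.

Monotone classes are checked before interior-extremum classes, so a noisy
but essentially monotone profile is not mislabelled biphasic. The band rule
is this package's formalisation — published pattern groupings are usually
made by eye — and rel_tol is exposed everywhere the rule is used.
Classification depends only on the shape relative to τ, so it is invariant
to positive rescaling.

## Concentration-ordered network

Correlations are Pearson coefficients across all per-replicate samples
(18 by default), not across the 6 treatment means: replicate scatter is
informative and the means-based alternative inflates correlations. This is
configurable by passing a means matrix instead. Edges are kept at
PCC ≥ 0.9, inclusive, between TF and non-TF genes (`tf_vs_nontf`);
`tf_vs_all` adds TF–TF pairs, relevant when hub degrees should count
TF–TF co-expression. Only the single positive cutoff is used by default;
the antecedent TO-GCN method's dual positive/negative cutoff scheme is out
of scope here. Constant-profile genes have undefined correlation and are
skipped with a log message rather than treated as zero.

Bait genes seed the hierarchy: mean(T0) strictly maximal, every successive
step decreasing or within τ, and mean(T150) < mean(T0) − τ. With
rel_tol = 0 this reduces to strictly decreasing T0-peaked profiles. Levels
are assigned by multi-source BFS: baits are level 1, every reachable node
gets 1 + its unweighted shortest-path distance to the nearest bait
(verified against Floyd–Warshall in the tests); unreachable nodes stay
unassigned rather than receiving a sentinel. Hub tables sort by degree
descending with gene id as the deterministic tie-break.

Exports: edge-list TSV with a companion node-attribute table (full
round-trip of weights, TF flags and levels), GraphML (full round-trip), and
SIF (topology only, for Cytoscape import).

## Enrichment

The upper tail P(X ≥ k) of Hypergeometric(N, K, n) is summed in log space
(logsumexp over scipy log-pmf terms); tests compare against exact
binomial-coefficient enumeration for all N ≤ 30 to 1e-10. BH adjustment is
the step-up procedure (via statsmodels), input order preserved. Terms with
zero study hits are excluded from the family, so m equals the number of
tested terms; significance is strict (adjusted p < 0.05). Study genes
missing from the background are dropped with a warning. GO and KEGG maps
should be tested as separate families (separate `enrich` calls).

## Synthetic data: what it emulates, and what it does not

The generator's defaults mirror the study design: 6 treatments × 3
replicates, ~500 genes with 30 TFs, five planted co-expression modules,
~10% planted low-expression genes, lognormal multiplicative noise with
σ = 0.1 on the log scale. Module members share one treatment-level
archetype — monotone down (the bait module), monotone up, mid peak, mid
trough, late peak — scaled per gene, so noiseless within-module pairs have
PCC exactly 1 and the bait/pattern keys are analytic. The down archetype's
T0→T30 drop is large relative to replicate noise so the planted bait set is
recovered exactly at the default noise level, by construction rather than
by luck. Background genes are flat-base + jitter profiles rejection-sampled
to |PCC| < 0.7 against every archetype and never peaking at T0; archetypes
were chosen with pairwise positive correlation ≤ 0.65, so no cross-module
or background pair can reach the 0.9 cutoff and the edge answer key is
exact.

The toy genome plants concrete motif instances at recorded
promoter-relative offsets on both strands of strand-alternating genes, with
one promoter per chromosome truncated to 500 bp to exercise boundary
handling. Incidental matches arising from random background sequence are
detected with a naive brute-force matcher (an independent code path from
the regex scanner) and mutated away; rare boundary positions where every
base completes some motif are left in place, and the frozen answer key is
the final naive scan, so key equality is exact. Hit-table fixtures pin one
BLAST row at exactly 30.0% identity and one E-value at exactly 1e-5 to
exercise the inclusive boundaries, and cycle decoys through each failure
mode.

What passing on this fixture does **not** show: TPM compositionality and
library-size effects, correlated (batch) noise, dispersion–mean trends,
partially overlapping modules, negatively co-regulated pairs, repetitive
genomic sequence, or realistic motif densities. Recovery rates on real data
will be lower than the planted rates; the fixture demonstrates correctness
of the operations, not field performance.

## Problem sizes and numerics

Default verification sizes — 500-gene matrices, 3 chromosomes × 8 genes,
1,000 correlation vectors, 100 random graphs ≤ 200 nodes, exhaustive
hypergeometric checks at N ≤ 30 — were chosen so the whole suite and the
acceptance script each complete in well under a minute on a laptop core
while still exercising every code path. Bisection tolerance for pI is
1e-3 pH; correlation values are clipped to [−1, 1] to absorb float error;
manifest determinism is assessed on input/output checksums, which are
independent of where the run directory lives.

## Known limitations

- The four-class pattern rule and the τ-band bait rule are formalisations
  of criteria that published analyses apply informally; boundary profiles
  can switch class as rel_tol changes.
- pI values depend on the pKa table; cross-tool comparisons must name the
  table.
- The level assignment is undirected BFS from baits; no attempt is made to
  orient edges or infer regulatory direction.
- Enrichment treats terms independently (no GO-graph propagation).
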