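# Methods

## Conservation model

The unit of analysis is one reference-species 3′ UTR with aligned
orthologous rows (default panel: human, mouse, rat, dog; FASTA blocks with
`-` gaps). Coordinates are 0-based, half-open, on the ungapped reference
sequence, 5′→3′; the internal alphabet is DNA (patterns given in RNA are
converted on input and rendered back in RNA in reports). `N` never matches
a pattern and always breaks a conservation call.

An occurrence of a k-mer (k = 8 by default, configurable) is **conserved**
when the k alignment columns occupied by its reference nucleotides are, in
every non-reference row, gap-free and identical to the k-mer. This strict
column-exact rule is the default because it is reproducible and
conservative; `find_conserved_instances(..., window=w)` relaxes it to
"the k-mer occurs in the orthologous row within the instance's columns
widened by *w* columns", for sensitivity analyses where local alignment
jitter is a concern. Conservation is a categorical presence call — no
phylogeny, no branch lengths.

Two counting units are emitted per k-mer: UTRs with ≥1 conserved instance
(the ranking unit, matching counts of 3′ UTRs) and total conserved
instances (used by positional profiles).

## Shuffled-control null and the conservation signal

Each k-mer's null is a seeded sample of up to `n_controls` (default 10)
control k-mers drawn from the exhaustively enumerated candidates that
pass **all** filters:

- identical mononucleotide composition (anagrams), or identical
  dinucleotide multiset in `dinucleotide` mode;
- equal overlapping UGUA count (UGUA is the pumilio core, whose own
  conservation would contaminate the null); "similar UGUA composition" is
  hardened to equality because equality is testable;
- no 7-nt substring matching a seed-match list for deeply conserved miRNA
  families (the packaged default list covers ~24 prominent families and is
  meant to be replaced by a project-specific list for serious use);
- no overlap with the polyadenylation signal AAUAAA, the pumilio site
  UGUAHAUA, or the ARE consensus UUAUUUAWW — as substring for patterns up
  to k nt, as containing-string for longer patterns;
- UTR count within `abundance_tolerance` (default 2.0-fold) of the
  source's UTR count.

Exclusion lists apply to controls only; the discovery scan itself covers
every k-mer present in the data. Fewer survivors than requested is a
logged warning; zero survivors is an error at the single-k-mer API and a
`no_controls` flag in the ranking table.

The signal is conserved-UTR count over the mean conserved-UTR count of the
controls, with the denominator floored at **one conserved UTR**. The floor
is a deliberate numerical choice: at realistic divergence most control
means are exactly 0, and any tiny-denominator convention (for instance
1/n_controls) multiplies sparsely conserved k-mers by a large constant and
ranks chance conservation above genuinely conserved elements. With the
floor, k-mers whose controls are unmeasurably conserved rank by their own
conserved count and carry an `unstable` flag meaning "ordering meaningful,
magnitude not". Control means at or above 1 are used as-is, so ratios like
40/20 = 2.0 are exact.

## Motif analyses

IUPAC patterns are expanded to concrete k-mers; scanning reports every
overlapping match with deterministic (utr_id, start) ordering. An
instance's relative position is its midpoint over UTR length (symmetric
for 5′/3′ comparisons); positional profiles use equal-width bins on [0, 1]
(default 20) with per-bin uniform expectation total/n_bins. Regions use a
300-nt window: proximal if start < 300, distal if end > L − 300, else
central; when a short UTR makes an instance both, proximal takes
precedence and the instance is flagged. Multi-copy spacing is the
start-to-start distance between adjacent instance starts within a UTR
(stated in output headers, since "spacing" is otherwise ambiguous).
Variant co-occurrence and DE overlap both use the exact upper-tail
hypergeometric P(X ≥ k). The conservation-position bias test is a pooled
one-sided two-proportion z test (terminal fraction conserved > central).

## Expression enrichment

The gene universe is every gene in the expression table with finite log2
fold change and positive abundance in at least one condition (an FPKM
floor is configurable; the default is any positive signal). `up` means
q < 0.05 and log2FC > 0 (q-threshold configurable); the nominal p < 0.05
coloring used in scatter displays is a reporting flag, not the enrichment
set. CDF comparisons are one-sided two-sample Kolmogorov–Smirnov tests;
"greater" means the sample is shifted toward higher fold changes. Samples
under three genes are computed but flagged low-power; empty strata are
flagged untestable rather than raising.

For shuffled-motif backgrounds, controls are generated per concrete
expansion of the pattern; each control's gene set excludes genes that also
carry the motif (preventing contamination of the background), and both a
motif-vs-control CDF comparison and the control's own up-set enrichment
are reported, giving the enrichment spectrum in which a functional motif
should stand clear of every shuffle. Control p-values are reported raw
(an optional Benjamini–Hochberg column can be added downstream); the
spectrum display is itself the multiplicity control.

Genes may enter several positional strata (one instance terminal, another
central); this is logged, not prevented, because the stratified contrast
asks about instances, not exclusive gene classes. The all-gene background
of the motif CDF excludes motif genes only, not control-sequence genes.

## Synthetic data generator

The generator emulates the shape of the real inputs, not their full
biology:

- **Lengths**: log-normal with arithmetic mean 1700 nt (the typical
  mammalian 3′ UTR length), sigma 0.75 in log space, minimum 100 nt.
- **Composition**: A/C/G/T = 0.30/0.20/0.20/0.30 by default, emulating
  AU-rich mammalian 3′ UTRs. Composition matters: an AU-rich motif's
  anagram controls are naturally of comparable abundance in AU-rich
  sequence, which is what makes 2-fold abundance matching satisfiable, as
  it is in real UTRs. The `neutral-conservation` calibration profile uses
  uniform composition instead so that all 4⁸ k-mers are exchangeable under
  its null.
- **Divergence**: each non-reference species row receives i.i.d.
  per-column substitutions (default 0.3/column) and geometric-length
  indels (rate 0.01/column, split evenly between deletions and
  insertions). Indels live only in non-reference rows so reference
  coordinates stay exact; insertions become species-private gap columns.
- **Planting**: 10% of genes receive one instance (two with probability
  0.1), drawn uniformly or with a terminal(300 nt) bias, variant chosen
  uniformly from the pattern's expansions. Planted footprints are written
  into every species and shielded from divergence, then independently
  *broken* by a single random substitution with probability
  1 − retention_prob (default 0.9) per species; an instance is truly
  conserved iff every species retained it. Chance background occurrences
  of the pattern are detected post hoc and recorded in the truth ledger,
  never suppressed (suppression would distort composition).
- **Expression**: control abundances are log-normal (log2 mean 3, sd 2);
  the treated condition multiplies in-scope genes (all planted genes, or
  only those with a terminal instance under `effect_scope="terminal"`) by
  2^effect (default 0.5 log2 units) plus optional per-gene noise
  (`noise_sd`, default 0 — keeping the null exactly calibrated; raise it
  to study uncontrolled biological heterogeneity). Two replicates per
  condition receive log-normal measurement noise (sd 0.15 log2 units);
  p-values come from a per-gene z test whose dispersion is pooled across
  all genes (the information-sharing spirit of low-replicate DE callers;
  a per-gene Welch t is available as `q_model="welch_t"`), and q-values
  from Benjamini–Hochberg.

Randomness is split into independent streams keyed on the seed (lengths/
sequences/planting; per-gene divergence; instance breaking; insertion
content; expression), so reference sequences are identical whether or not
alignments are generated, and substitution draws are coupled across
divergence-rate grids (conserved counts are exactly monotone in the rate
at fixed seed).

What the generator does **not** model: phylogenetic rate matrices or tree
structure, alternative polyadenylation isoforms, splicing, composition
heterogeneity along the UTR, correlated gene expression, or
sequencing-depth–dependent dispersion. Passing recovery tests on this
model therefore demonstrates that the pipeline's statistics detect the
signal they are designed for under controlled conditions — not that any
particular biological dataset will show that signal.

## Frozen profiles and problem sizes

Fixture profiles are versioned in `utrmotif.simulate.PROFILES`:
`default` (2000 genes, the recovery conditions above), `null-expression`
(effect 0), `terminal-effect` (effect restricted to terminal-instance
genes), `terminal-bias` (terminal planting), `neutral-conservation`
(200 genes, divergence 0.02/column, nothing planted — at this divergence
a typical 8-mer instance survives in all three non-reference species with
probability ≈ 0.62, so conserved counts stay informative and the
normalized signal's null median is near 1), and `tiny` (40 genes for
smoke tests). The acceptance script checks rank recovery on 3 simulations
and enrichment/CDF recovery on 20 expression cohorts; the stratified
contrast reports medians over 5 replicate simulations to damp
single-draw noise in the (null) central stratum.

## Numerical and edge-case conventions

- Duplicate UTR ids are errors; multiple transcripts per gene are reduced
  to the longest UTR (ties: lexicographically smallest utr_id).
- Non-finite fold changes are excluded everywhere by default (logged);
  `keep_nonfinite=True` retains them for universe counting only.
- Hypergeometric configurations with k > min(K, n) or sets larger than the
  universe are errors; genes outside the universe are dropped with a log
  message.
- Sorting of the ranking table: descending signal, ties by k-mer,
  undefined signals last. All samplers are seeded; identical seed, spec
  and data give byte-identical outputs.
- CLI exit codes: 0 success, 2 configuration error, 3 data error,
  4 untestable statistic.

## Known limitations

- The strict column-exact conservation rule undercounts conserved
  instances when the true alignment is locally shifted; the window mode
  exists for that reason but has no principled default width.
- The default miRNA seed-match exclusion list is abridged; supply the
  full list for the miRNA families relevant to your clade.
- With few UTRs (tens), abundance matching leaves many k-mers without
  controls; their rows carry `no_controls` and an undefined signal.
- The discrete hypergeometric p-value is conservative for small sets;
  calibration checks should use its randomized (uniformized) version, as
  the test suite does.
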