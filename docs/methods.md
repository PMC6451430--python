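# Methods

## Scope and model

`panethnet` chains six inference steps, each deliberately simple and
auditable, from replicate protein intensities to process-level statements
about an autophagy-impaired epithelium. The package consumes already
quantified tables: peptide-to-protein inference, intensity normalization,
RNA-seq quantification and differential testing, orthology inference and
the curation of interaction/motif/domain resources all happen upstream and
enter as plain TSV/FASTA inputs.

## Differential abundance

- **Test.** One-factor ANOVA across the two genotype groups; with two
  groups this is exactly the equal-variance two-sample t-test (F = t²),
  which the test suite verifies against an independently coded t-test.
- **Scale.** The ANOVA runs on log2-transformed intensities (configurable
  via `log_transform`). Label-free intensity noise is approximately
  multiplicative, so the log scale stabilizes within-group variance. The
  source analysis does not state the scale; raw-scale testing is retained
  behind the flag.
- **Floor.** Intensities are clipped to a floor before the log transform,
  default half the smallest nonzero intensity in the table — a standard
  detection-limit surrogate that keeps zeros finite without inventing
  signal.
- **Degenerate variance.** Zero within-group variance with equal means
  gives P = 1; with different means P = 0. These conventions make the
  zero-noise separation limit exact and only ever arise on synthetic or
  degenerate data.
- **Fold-change.** Computed on arithmetic means of the (floored) raw
  intensities and stored signed with |FC| ≥ 1: +KO/WT when the knockout
  mean is at least the wild-type mean, −WT/KO otherwise. This makes the
  |FC| ≥ 2 gate and the later 0.7 log2 comparison unambiguous, with
  `log2fc = sign · log2|FC|`.
- **Thresholds.** P < 0.05 strict; |FC| ≥ 2 and unique peptides ≥ 2
  inclusive — the senses exactly as conventionally printed. No
  multiple-testing correction is applied at this stage; the thresholds are
  a joint filter, not a calibrated error rate.

## Orthology mapping

One-to-many mouse→human assignments expand into multiple rows, copying
direction and log2FC (the profile this package models maps 283 mouse
proteins onto 284 human orthologues through exactly one such expansion).
Many-to-one collisions keep the representative with the extreme |log2FC| —
the choice that preserves the "altered" call — and are logged in the
mapping report rather than applied silently. The default confidence cutoff
is 1.0, the InParanoid seed-orthologue score; lower-confidence pairs are
kept out unless the caller relaxes `min_confidence`.

## Target prediction

Three independent evidence channels feed a union:

- **Curated lists** (experimental interactors per receptor; an iLIR-style
  list for LC3) are consumed as membership tables.
- **Motif scanning** reports every overlapping window whose residues fall
  in the per-position alphabets; `X` is tolerated in sequences but never
  satisfies a restricted position. The default LC3 pattern is the extended
  xLIR definition, with the canonical core `[WFY]xx[LIV]` available; both
  are configuration, not code. The p62 recognition pattern has no
  authoritative published regular expression available to this package, so
  the shipped default `[DE][DE][WFY]xx[LIV]` (acidic-flanked LIR-like) is a
  *synthetic working default*, clearly overridable in `PipelineConfig`;
  analyses that depend on p62-motif calls should supply their own pattern.
- **DDI inference** predicts a candidate iff one of its Pfam domains forms
  a known interacting pair (DOMINE-style, canonicalized unordered) with a
  domain annotated on the configured ATG16L1 accession. ATG16L1's query
  domains come from the same domain table, never from code.

The 7-cell Venn partition over {p62, LC3, ATG16L1} is disjoint and
exhaustive by construction; `fraction_multi` is the share of targets hit by
≥ 2 receptors. Statistical enrichment of the targeted set against a
background is possible through the hypergeometric module but is exploratory:
the appropriate background universe is analysis-specific.

## Process trends

The contribution unit is one (protein, process) curated link: a protein
annotated to a process contributes exactly once to that process regardless
of how many receptors target it, and independently to each process it
annotates. This per-protein counting reproduces the reference fractions
(19/25 inhibitory → downregulated; 5/7 stimulatory → upregulated). The
alternative reading — counting receptor→protein edges — is defensible but
does not reproduce those tallies. Sign semantics: (up, activation) and
(down, inhibition) are stimulatory; the mixed combinations inhibitory.

The aggregation rule is strictly >70% for a unidirectional call; an exact
70% split is classified dual, the conservative reading of a rule stated as
"more than 70%" up/down and "less than 70%" dual with equality undefined.
Out-of-context curation rows (`in_context` false) never enter the tallies.

The exported network is strictly tripartite (receptor→protein "targets"
edges, deduplicated per pair; protein→process "activates"/"inhibits"
edges), written as SIF, GraphML and a node-attribute TSV for Cytoscape.

## Cross-omics attribution

Both sides are compared on the signed log2 scale; turnover is called iff
|protein log2FC − transcript log2FC| > 0.7 (strict). The comparison uses
signed values even when directions disagree — a protein up while its
transcript is down inflates the difference, which is the desired behaviour
for a turnover signal — and the choice is recorded here because a
|‖p‖ − ‖t‖| variant would be defensible. Transcripts failing the DE
thresholds (|log2FC| ≥ 1, q ≤ 0.05, inclusive) still enter the delta; the
DE flag is reported separately so both the "44 of 66 DE" style count and
the "40 of 44 turnover" style count can be formed.

## Hypergeometric enrichment

`P(X ≥ k)` is summed in log space from gammaln-based log-PMF terms
(logsumexp), keeping tails at the 1e-57 scale exact; the suite cross-checks
against arbitrary-precision Fraction summation, a Monte-Carlo sampling
oracle and `scipy.stats.hypergeom`. The universe is a required input — all
genes detected in the respective dataset is the sensible default — because
reported marker p-values are irreproducible without knowing it; only the
overlap counts are universe-free.

## Synthetic worlds

The generator emits all eight inputs with bookkeeping sufficient to verify
every stage. Defaults state the experimental world being emulated:
3 replicates per condition; 70% of differential proteins up; 41% of the
human-mapped set targeted; 19% of targets multi-receptor; six processes
with contribution counts (25, 7, 10, 15, 8, 12) whose first two realize
19/25-inhibitory and 5/7-stimulatory tallies; 90% turnover among measured
transcripts (the 40/44-scale fraction) separated by a planted
`turnover_delta` of 1.5 log2 units; an 83-gene marker list with 56 members
planted inside the DE pool. Values the source world does not state were
chosen once as field-plausible and are not tuned: 400 proteins with half
differential (≈ the 283-differential scale while keeping tests fast),
planted |log2FC| ~ U(1.2, 3.5) (comfortably past the |FC| ≥ 2 gate),
replicate noise sd 0.25 on log2 intensities (typical label-free CV ≈ 20%),
base abundances U(20, 28) log2 units, 200-residue sequences, a 500-gene
transcript background with 120 DE.

Motif planting is rejection-sampled: non-target sequences are redrawn until
they contain no xLIR or p62 match, and planted sequences are redrawn until
scanning recovers exactly the planted occurrences, so accidental motifs
cannot corrupt the planted evidence truth. Domain/DDI plants give each
DDI-channel protein a unique partner domain of ATG16L1's WD40 stand-in;
decoy domains are never paired with it. The orthologue table contains
exactly one 1:2 expansion plus low-confidence decoy pairs that the default
threshold excludes.

What a green test does and does not establish: with zero replicate noise
every stage output equals the planted truth exactly (the separation limit);
with default noise the filter obeys its nominal operating characteristics
(false-positive rate ≈ 5% on nulls, high power at the planted effect
sizes) while the downstream deterministic stages remain exact on their
emitted inputs. The generator does not emulate missing-value structure,
intensity-dependent variance, shared peptides, batch effects or correlated
transcript noise, so green tests say nothing about robustness to those
real-data features.

## Determinism and numerics

All generator randomness flows through one seeded NumPy generator; the
pipeline itself is deterministic, writes tables with fixed column order and
sorted rows where order is not meaningful, and serializes floats via
`repr` so reruns are byte-identical and reader/writer pairs round-trip
losslessly. A failed stage leaves an `INCOMPLETE` marker naming the stage
so partial output directories are recognizable.

## Known limitations

- The p62 motif default is a stand-in (above); p62-channel calls on real
  data require a user-supplied pattern.
- Trend calls are unweighted votes; effect sizes, annotation confidence and
  receptor multiplicity do not enter.
- DDI inference treats any one interacting domain pair as sufficient and
  ignores domain architecture or structural context.
- Orthologue expansion can double-count a protein's contribution when both
  human copies are annotated to the same process; the mapping report makes
  expansions visible.
- The hypergeometric test assumes the DE list is an unbiased draw from the
  universe, which detection-biased proteomics/transcriptomics violates in
  practice; p-values should be read comparatively, not literally.
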