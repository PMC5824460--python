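# Methods

This note documents the models and procedures introkit implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data studies do and do not demonstrate.

## Locus QC and partitioning (`seqio_qc`)

Input is one multiple sequence alignment per locus (FASTA; taxon ids as
headers) over {A,C,G,T, IUPAC ambiguity codes, `-`, `N`}. Cleaning applies,
in a fixed order:

1. **Terminal trim** — from each end, drop columns whose non-gap occupancy
   is ≤ `trailing_occupancy_frac` (default 0.30), stopping at the first
   dense column. Interior sparse columns are not "trailing" and are kept.
2. **Short-sequence drop** — remove sequences whose non-gap length is
   ≤ `short_seq_frac` (0.30) of the mean non-gap length.
3. **Coding gap columns** — exclude any coding column containing a gap
   unless the reference taxon is gapped there too. Rationale: in
   reference-based assemblies, insertions absent from the (high-quality)
   reference are overwhelmingly assembly errors, and unlicensed coding gaps
   would imply frameshifts.
4. **Noncoding gap columns** — exclude noncoding insertion columns whose
   residue is present in fewer than `noncoding_gap_frac` (0.50) of the
   retained taxa.

Cleaning is idempotent and never alters residues; only columns and
sequences are removed (and scaffolding inserts `N`s).

Subset assignment: **primary** = ≥ 25 species, ≥ 200 bp, has a coding
region, ambiguity ≤ 3%; **MS** = the same but 15–24 species; **NL** = no
coding region but ≥ 25 species; everything else is discarded. The ambiguity
fraction is IUPAC-ambiguity cells over non-gap cells; `N` counts in the
denominator but never as ambiguity (scaffolding inserts Ns deliberately),
and the 3% rule is strict — a locus at exactly 3.0% is retained.

Coding regions come from a six-frame start-to-stop ORF scan of the
reference sequence (`min_orf_codons` default 100, the TransDecoder
convention; fixtures use 30). The longest ORF defines the codon phase;
further non-overlapping qualifying ORFs define split loci. Coordinates are
0-based half-open; codon position 1 is the first base of the start codon.

Fragmented sequences are scaffolded against reference-transcript
coordinates, bridging inter-fragment gaps with `N`s, and accepted when the
summed fragment length (Ns excluded) reaches the 200 bp cutoff.

## Site patterns (`site_patterns`)

For an ordered quartet (((P1,P2),P3),O) or quintet (((P1,P2),(P3,P4)),O),
each column is reduced to a string over {A,B} with the outgroup allele
labelled A. Sites with gaps, `N`, or ambiguity codes are excluded, as are
invariant and multiallelic sites. Heterozygous IUPAC codes are excluded
rather than resolved, matching the exclusion rule the tests assume.
All-'B'-ingroup patterns (the outgroup carries a private allele) are
counted: they enter the D_FOIL concordant classes. Counting is vectorized
but column-for-column identical to the scalar classifier, which the tests
verify. Loci missing a role's taxon are skipped with a log entry rather
than failing, since occupancy varies across subsets.

## D statistics (`dstats`)

* `patterson_d`: D = (n_ABBA − n_BABA)/(n_ABBA + n_BABA), χ² =
  (n_ABBA − n_BABA)²/(n_ABBA + n_BABA), df = 1, two-sided, no continuity
  correction. Zero discordant sites yields a flagged-undefined result. An
  exact two-sided binomial option exists for small pooled counts, where the
  chi-square approximation is not defensible.
* `bonferroni` / `TestBattery`: the family threshold is α/m over the
  battery; a test is significant iff p < α/m (strict). A 62-test battery at
  α = 0.05 gives the 0.0008 threshold. In the pipeline, a D test counts one
  comparison and a D_FOIL test four (one per component).
* `dfoil`: the four components are normalized left-minus-right contrasts of
  pattern-class sums; the membership table is packaged as
  `data/dfoil_components.tsv` (reviewable data, not hard-coded arithmetic).
  Each component gets a chi-square p-value and a sign in {+,0,−}; the sign
  is 0 unless significant under the battery threshold. In `alt` mode the
  three-derived classes containing a full sister-pair synapomorphy
  (BBBAA/BBABA for D_FO/D_IL, BABBA/ABBBA for D_FI/D_OL) are removed: on
  real assemblies those classes are dominated by homoplasy leaking from the
  large synapomorphic classes. On clean simulated data the opposite holds —
  the standard sums make the chart's zero components cancel exactly, while
  alt mode leaves small biases in the direction polarizers — so
  classification studies here use `standard`; `alt` remains the default
  for empirical pipelines.
* Divergence proxies t12/t34/t1234 are mean pairwise mismatch fractions
  over the sites used, within (P1,P2), within (P3,P4), and across pairs.
  Only the ordering check t12 < t34 < t1234 is consumed (the quintet must
  respect the T12 < T34 convention); strong introgression can legitimately
  break it, which is reported as a flag, not an error.
* `classify_signature`: canonical signatures map to hypotheses via the
  packaged chart `data/dfoil_signatures.tsv` — the none row, two ancestral
  rows ((+,+,0,0) and (−,−,0,0)), eight directional rows, and four
  pair-uncertain rows in which only the two pair-identifying components are
  significant (e.g. (0,−,0,−): D_IL and D_OL both carry P2–P4 sharing, and
  the neutral D_FO/D_FI are exactly the direction polarizers, so the pair
  is identified but the direction is uncertain or reciprocal). Any other
  signature is `complex` — no single event explains it. The chart was
  derived from large-sample pulse-model simulations (4000 loci × 1 kb,
  γ = 0.5, every single-event scenario) and is validated by the recovery
  tests.
* `ghost_direction`: given an excluded-partner test (A with C, omitting B)
  and an included test, a significant A–C signal that shifts to A–B once B
  is present yields "B into A (directional)"; a persisting A–C signal is
  ambiguous; no excluded-test signal, no call.

## Concordance factors (`trees_concordance`)

CFs are estimated empirically: per locus, a clade indicator (one tree per
locus) or a posterior clade frequency (tree sample per locus); the CF is
the mean over loci and the credibility interval is a seeded percentile
bootstrap (2.5/97.5) resampling loci, not trees within loci. This replaces
a full Bayesian concordance MCMC: the downstream logic consumes only CFs
and intervals, and the reference analyses report little sensitivity to the
concordance prior. Clades are evaluated on induced subtrees when taxa are
missing; a restriction that becomes trivial imposes no constraint and
counts as present.

The asymmetry test calls two conflicting CFs different iff their intervals
are disjoint; a shared endpoint counts as overlap (conservative). The
excess-CF admixture estimate subtracts the mean of the supplied alternative
CFs from the focal CF and reports a whole-percent genome fraction; with
several alternatives the mean is used (the single-mirror case reduces to a
plain difference).

The primary concordance tree accepts clades greedily in descending CF
order (ties broken by canonical clade order: smaller side, then
lexicographic), skipping clades incompatible with the accepted set
(four-intersection test), and assembles the tree by containment nesting;
polytomies are allowed.

Bipartition conflicts between two trees are computed on the shared taxon
set: every bipartition with support ≥ `min_support` in one tree that is
incompatible with some bipartition of the other is reported (support read
from internal node labels or bracket comments; an unannotated bipartition
passes any threshold). At `min_support` = 0 the symmetric difference of the
bipartition sets equals the Robinson–Foulds distance, which the tests check
against dendropy. `constraint_skeleton` collapses internal edges below a
support threshold (default 90, the bootstrap-constraint convention) into
polytomies; unlabeled internal nodes count as support 0 with a warning.

## Synthetic data (`synthetic_data`)

Gene trees follow a multispecies coalescent on a quartet (((P1,P2),P3),O)
or quintet (((P1,P2),(P3,P4)),O): one sampled lineage per species, within
each species-tree branch coalescence at rate k(k−1)/2 in coalescent units
(per-branch effective-size multipliers supported). Introgression is a
*pulse*: with per-locus probability γ, every lineage in the recipient
population at time `t_m` jumps to the donor population — the discrete-event
model the signature chart assumes, not continuous migration. `tau_root` is
the ingroup root; the outgroup attaches at `tau_out` (default 2·tau_root).
Sequences evolve under JC69 (uniform root state; per-branch change
probability (3/4)(1 − e^(−4dθ/3))); counting-based statistics see only
shared derived states, so richer substitution models would add nothing
here. Locus i of a scenario draws from an independent stream keyed
[seed, i], with the pulse indicator as the first draw, so truth labels are
recoverable without re-simulation; identical seeds give byte-identical
outputs.

QC fixtures fabricate loci violating exactly one rule each, with truth
labels: clean primary loci, over-ambiguous loci one cell above the 3%
boundary, boundary loci at exactly 3.0% (retained), short loci, sparse
(< 15 taxa) loci, MS-range loci, and ORF-free noncoding loci.

### Canonical study conditions

Two reference scenarios are fixed package-wide:

* **Null scenario** (calibration): quartet, τ12 = 1.0, τ_root = 1.3,
  τ_out = 2.6 coalescent units, 500 loci × 500 bp, θ = 0.00015
  substitutions/site per coalescent unit. The short internal branch gives
  abundant ILS discordance, and the low mutation scale keeps informative
  sites to ≲ 0.1 per locus, which matters: sites within a locus share
  gene-tree branches, so with more mutation per locus the pooled counts
  become blocks of identical patterns and the per-site chi-square is
  overdispersed (anticonservative). At these settings, with the exact
  binomial test for the few dozen pooled discordant sites, the ILS-only
  false-positive rate is at its nominal 5% (measured 4.3% over 300
  replicates).
* **Power scenario** (recovery): quintet, τ12 = 1.0, τ34 = 2.0,
  τ_root = 3.0, τ_out = 6.0, 500 loci, θ = 0.0005, pulses at t_m = 0.1
  (tip events, 500 bp or 1 kb loci) or t_m = 1.05 (ancestral events), with
  γ = 0.3. Measured operating characteristics: signature-class recovery
  (ancestral vs inter-taxon) ≈ 88–96%, ghost-direction recovery ≈ 100%.

What passing these studies shows — and does not. The generator emulates
ILS, pulse introgression, and neutral JC69 evolution with free
recombination between loci and none within; it does not model assembly
error, paralogy, sequencing depth, base composition, rate variation, or
within-locus recombination. Calibration and recovery results therefore
validate the statistics and their implementation under the model the tests
assume, not robustness to those artifacts (the QC stage exists precisely
because real assemblies violate them).

## Pipeline (`pipeline_cli`)

`introkit run --config run.yaml` executes QC → counting → D/D_FOIL battery
→ CF contrasts → tree conflict → consolidated introgression calls, writing
TSV/JSON artifacts at each stage; identical config + seed reproduces
byte-identical outputs. Every significant battery entry lands in exactly
one call (keyed by the implicated taxon pair) or in an `unexplained` list;
ghost-direction verdicts take precedence over a D_FOIL pair-uncertain
label for the same pair. `introkit verify-paper` recomputes the packaged
worked examples (printed pattern counts, CF point estimates and intervals,
battery size) and compares at printed precision; the known inconsistency
between the two printed values for one mirror clade (0.136 in one table,
0.092 in the discussion arithmetic) is resolved in favour of the
discussion's arithmetic, and an interval printed as 0.023–0.055 around a
"0.39" point value is treated as belonging to 0.039.

## Numerical and degenerate-input conventions

Chi-square tests use df = 1 without continuity correction. Zero-denominator
statistics are flagged undefined, never raised. Bootstrap seeds are
required, and all simulation randomness derives from integer seeds below
2³¹. Tie-breaks (equal CFs, equal ORF lengths) are deterministic by
canonical order (clade sort key; ORF start position). Empty alignments
after cleaning are classified `discard` rather than erroring, so batch runs
survive degenerate loci.
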