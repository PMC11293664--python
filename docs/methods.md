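# Methods

## Scope and data model

The package operates on tables of proteolysis-derived stability
measurements: one row per assayed molecule with a wildtype-domain label,
the variant's amino-acid sequence, folding free energy ΔG (kcal/mol)
and/or log10 K50 (the protease concentration at half-maximal cleavage, a
monotone proxy for stability). Sequences are restricted to the 20-letter
amino-acid alphabet; rows with other letters (including `X`) are dropped
with a logged count, because both the aligner's substitution matrix and
the predictors' tokenisers assume the canonical alphabet.

## Curation

Three rules, applied in this order:

1. **Aggregation.** Rows sharing `(domain_id, protein_sequence)` are
   collapsed regardless of DNA-level replicate keys; mean and replicate
   SD of both readouts are recorded. The SD estimator is the sample SD
   (ddof = 1), the conventional replicate-variability estimator; ddof is
   configurable. SD is undefined (absent) for singletons.
2. **SD filter.** An aggregate is removed when SD(ΔG) > 2 kcal/mol *or*
   SD(log K50) > 0.5. The inequalities are strict: records exactly at a
   threshold are retained, and single-replicate records (no SD) pass.
3. **Domain-count filter.** All records of a domain are removed when the
   domain has fewer than 100 measurements. "Measurements" is read as
   unique protein sequences after aggregation by default; a
   `count_mode="raw_measurements"` flag counts pre-aggregation rows
   instead, since the phrase is ambiguous for replicated data.

The chain is monotone (each stage returns a subset), deterministic, and
every drop is counted in the curation summary so the full bookkeeping
from raw rows to curated sequences can be reconstructed from logs.
Records with a missing ΔG (e.g. censored values that fail numeric
parsing) are retained through curation when log K50 is present, but are
excluded from regression targets downstream.

## Splitting

Two layers. First, `floor(0.10 × n_domains)` domains (minimum 1, with a
warning when the floor was 0) are drawn uniformly without replacement;
*all* of their records are labelled `test_only`. Second, records of the
remaining domains are assigned to train/validation/test at 0.8/0.1/0.1.
The assignment is stratified by domain: within each domain the records
are permuted under the seeded RNG and sliced at largest-remainder
counts, with non-zero validation/test ratios guaranteed at least one
record each so per-domain rank statistics remain computable. Domains
with fewer than 3 records fall back to train with a warning. A single
RNG stream seeds both layers and the seed is stored in the assignment
artifact.

`validate_split` audits: no protein sequence labelled train/validation
may also appear in test/test_only; no domain may span the core and
held-out layers; labels must cover the curated set exactly once.
Identical sequences appearing under *different* domain ids (possible for
short designed sequences) are reported as warnings, not merged.

## Sequence identity and matching

Pairwise identity uses optimal local (Smith–Waterman) alignment via
Biopython's `PairwiseAligner`: BLOSUM62, affine gaps costing
11 + (k−1)·1 for a gap of length k. Identity is matches divided by
alignment columns (gaps included) × 100 — the convention that counts
indels against identity. Because co-optimal alignments can differ in
identity, the pair is aligned in a canonical (sorted) orientation so
identity(a, b) = identity(b, a) exactly.

Significance uses Karlin–Altschul gapped statistics
E = K·m·n·exp(−λS) with λ = 0.267, K = 0.041 (the standard constants for
BLOSUM62 with 11/1 gaps) and the total residue count of the training set
as the effective database size. A domain's identity-to-training-set is
the maximum identity over hits with E < 10⁻³; 0% is assigned when no hit
passes. Closest-partner matching prefers the highest-identity sequence
hit (ties broken by score, then lexicographic id); a structural matcher
(e.g. a Foldseek wrapper returning a partner and TM-score) can be
plugged in as a fallback through a callable adapter, and matching
degrades to "none" when the adapter is absent or fails. Structural
alignment itself is out of scope.

## Predictors and training protocol

Both families implement one contract — fit on disjoint train/validation
sets, then deterministic `predict` returning one finite ΔG per sequence:

- **`kmer_ridge`** — ridge regression (α = 1) on counts of character
  k-mers of lengths 1..k (k = 3). Closed-form; the default pipeline
  model.
- **`tiny_transformer`** — a single-block transformer encoder written in
  NumPy (learned token + position embeddings, one self-attention layer,
  ReLU feed-forward, residual connections; d_model = 24, d_ff = 48 by
  default, well under 1M parameters) with a linear regression head
  reading the representation of a start token prepended to the sequence
  — the head placement used when fine-tuning protein language models for
  whole-sequence regression. Trained with Adam on MSE of standardized
  targets. `init_mode="pretrained"` seeds residue embeddings with
  standardized physicochemical descriptors (hydropathy, charge,
  side-chain volume, polarity, helix propensity) as an informative
  prior; `"random"` initialises from scratch.

The shared protocol: a local batch (128) accumulated to a global batch
(2048) per optimizer step; validation loss evaluated every step; training
stops when validation has not improved for `patience_steps` (500)
optimizer steps; the *best-validation* checkpoint, not the last, is
returned (so its validation loss always dominates the final step's).
Loss and early-stopping metric are MSE by default — the protocol leaves
them unspecified upstream, so both are configurable. All randomness
(init, shuffling) derives from the single config seed; the precision
flag is accepted for config compatibility and is a no-op on CPU. An
adapter slot for external pretrained language-model checkpoints exists in
the contract but is not required anywhere.

`train_single_domain_ensemble` trains one predictor per domain on that
domain's own train/validation rows under the same protocol, skipping
domains below a record minimum (default 30) with a log entry.

## Evaluation

Per domain and partition: Spearman's R (Pearson correlation of average
ranks; undefined — NaN with a reason — under zero rank variance) between
predicted and measured ΔG, with the domain's max identity to training
attached (core domains report 100%, their own wildtype being in
training). Domains with fewer than two evaluable records are reported as
skipped rather than silently dropped.

**Collective vs single.** For each held-out domain with a matched
training partner, the pooled model's Spearman is paired with that of the
partner-domain model. The primary test is Wilcoxon's rank-sum between
the two Spearman samples; because the data are structurally paired, the
exact signed-rank p-value is reported alongside — neither is asserted as
the "right" choice. The rank-sum implementation enumerates all
C(m+n, m) assignments of pooled midranks exactly for combined n ≤ 12
(two-sided p = P(|U − mn/2| ≥ |u_obs − mn/2|), valid under ties), and
uses the tie-corrected normal approximation above that.

**Recalibration.** Per domain, measured ΔG is regressed on predicted ΔG
by OLS, so the recalibrated prediction slope·pred + intercept lives in
kcal/mol (the regression direction is a documented choice; the inverse
is a one-line change). RMSE and R² = 1 − SS_res/SS_tot (computed against
the per-domain label mean, never squared-Pearson, so negative values are
representable) are reported before and after. Fitting and evaluating on
the same points means OLS optimality guarantees rmse_after ≤ rmse_before
and r2_after ≥ r2_before; this in-sample usage mirrors how such
recalibrations are usually reported, and callers wanting an honest
generalization estimate should fit on a subset. Zero-variance
predictions yield a flagged intercept-only fit.

## Synthetic data generator

The generator emulates the deposit's *structure*: 40 domains by default
(desk scale), wildtype lengths 40–72 aa, 44% labelled de novo (cosmetic),
120–220 mutants per domain drawn from a substitution/insertion/deletion
spectrum (0.8/0.1/0.1, 1–3 edits), replicate counts {1: 0.3, 2: 0.5,
3: 0.2}, replicate noise SD 0.3 kcal/mol on ΔG, and log K50 as an affine
function of true ΔG (slope 0.55, intercept 1.2, noise 0.05) — only its
monotonicity matters to the pipeline. 2% of variants per domain are
planted with symmetric two-point replicates whose sample SD is exactly
3.0 kcal/mol, guaranteed above the SD threshold, so tests can assert the
filter removes exactly the planted set. Twelve domain pairs are homologs
at controlled identity (45–95%, hit within ±3 points as measured by the
package's own aligner); remaining domains are unrelated random sequences
that score 0% identity under the e-value cutoff.

The ground-truth stability is additive: a global rule on adjacent
residue pairs (a 20×20 kcal/mol table, SD 0.5, shared by all domains)
plus a domain-private per-position substitution table (SD 0.2) and a
per-domain offset pinning the wildtype ΔG into 1–5 kcal/mol. The pair
rule is deliberate: a per-residue composition rule turned out to be
fully learnable from any single domain, which made partner-domain models
*beat* pooled training — the opposite of the effect the comparison is
meant to exhibit. With a pair rule, one domain's mutants sample only its
own backbone's pair contexts, far too sparsely to estimate 400 shared
weights, while pooled training covers the pair space densely; pooling
then genuinely transfers, and the collective-vs-single comparison is
positive by construction (mean Spearman improvement ≈ +0.4, 10/10 seeds
at default settings). An optional pairwise-epistasis noise term exists
and defaults to off.

What the generator does **not** emulate: real thermodynamic coupling,
structure, position-dependent indel energetics, assay-specific unfolded
state effects, or the real relation between ΔG and K50. Passing tests on
synthetic data therefore validate the *pipeline machinery* — filters,
splits, alignment, statistics, protocol — not biophysical accuracy of
any predictor.

## Numerical and design choices

- Floor rounding (minimum 1) for the held-out-domain count; for 461
  domains at 10% this gives 46.
- Spearman ties get average ranks; exact-test conventions are described
  above; identical-multiset rank-sum inputs give p = 1 by the symmetric
  enumeration convention.
- Problem sizes throughout tests and the acceptance script (tens of
  domains, 10²–10⁴ records, 10 seeded replicates for the directional
  comparison) are the package's chosen desk scale; every quantity is
  recomputed at run time from the seeded generator.
- Pipeline artifacts are CSV/JSON/FASTA with SHA-256 checksums in a run
  manifest; reruns under the same config reproduce identical hashes, and
  `resume=True` skips checksum-clean stages.

## Known limitations

- The internal aligner is exact Smith–Waterman without prefiltering;
  all-vs-training scans are O(n²) in sequence count and meant for
  hundreds, not millions, of wildtypes.
- E-values use fixed Karlin–Altschul constants rather than
  sequence-composition-adjusted ones; identities near a decision
  boundary of the e-value cutoff may differ by a few percent from other
  aligners' conventions.
- The tiny transformer is a protocol demonstrator at desk scale; nothing
  about its capacity is representative of large pretrained models, and
  `init_mode="pretrained"` is an informative-descriptor prior, not
  actual pretraining.
- Per-domain recalibration is evaluated in-sample by design (see above).
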