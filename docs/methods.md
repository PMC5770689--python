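# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Differential synthesis model

Each biological replicate contributes one log2(mutant/wt) SILAC ratio per
protein. Isotope labels are reversed in half the replicates ("label swap");
swapped columns store log2(wt/mutant) and are negated by `orient_ratios`
before any statistics, which cancels label-specific bias and makes the
analysis equivariant under a global swap (tested).

Proteins detected in fewer than `min_reps` (default 3) replicates are
filtered out, mirroring standard practice for 4-replicate designs: a
protein absent from two or more replicates is outside the analysis
universe, whatever its effect size.

The test is a two-sided **one-sample t-test** of the oriented log2 ratios
against 0 with df = n−1. A one-sample formulation is the natural model for
ratio data — each replicate already encodes the mutant/wt contrast — and is
a documented choice, since a two-sample reading of the upstream tooling is
also conceivable. Significance is called at raw p < α (default 0.05) with
no multiple-testing correction, matching the screening convention the
pipeline reproduces; a Benjamini–Hochberg FDR column is emitted so users
can apply a stricter criterion. Degenerate rows (n < 2, or zero variance
around a non-zero mean) are reported as such, never silently dropped; the
all-zero row is the exact null (t = 0, p = 1). Missing values are excluded,
never imputed.

Volcano coordinates are x = mean log2 fold change, y = −log10 p; p = 0.05
corresponds to y = −log10(0.05) ≈ 1.301 (the mathematical value).

## Targeting enrichment

SP-targeting = signal peptide ∪ transmembrane domain, counted once
(n_targeting = n_sp + n_tm − n_both). Flags are inputs from upstream
predictors; the package never predicts them from sequence. Percentages are
rounded **half-up** to one decimal to match printed-table conventions
(33.75% → 33.8%); unrounded fractions are also emitted. Enrichment is a
Pearson χ² with 1 df on the 2×2 table of disjoint groups (regulated vs
non-regulated by default — comparing regulated against *all* proteins,
which include the regulated, is the documented alternative and can be
built from the same summaries). Yates continuity correction is exposed but
off by default. Group assignment maps proteins to *sets* of labels, since
groups legitimately overlap (upregulated ⊂ regulated).

## 5′-UTR features

The UTR is bases 1..cds_start−1 of the transcript, normalized to uppercase
RNA (T→U). UTRs shorter than 13 nt are excluded (`reason="min_length"`):
start codons that close to the cap initiate translation poorly, so their
features are uninformative. The boundary is inclusive — 13 nt is analyzed.

A **uORF** is operationally a start codon only: a trinucleotide from
{AUG, CUG, GUG, UUG, ACG} lying entirely within the UTR, with a purine
(A/G) at −3 and G at +4 (positions numbered with the first codon base as
+1). No in-frame stop is required. Decisions worth stating:

* the −3/+4 context applies to all five codons, not only AUG; the
  `UORFRule` object makes the AUG-only alternative a one-line change;
* candidates at positions 1–3 are not counted — their −3 context does not
  exist on the transcript and cannot be evaluated (conservative choice);
* the +4 base may be read from the main ORF when the candidate abuts the
  CDS; the codon itself must be fully upstream;
* every position is scanned in all three frames and overlapping hits all
  count; `N` matches nothing;
* all interface coordinates are 1-based inclusive.

The scanner is validated against an independent brute-force triple-loop
scan, position-exactly, on hundreds of random transcripts.

## RNA folding

Structural stability is summarized by the minimum total pair energy of a
pseudoknot-free secondary structure: Nussinov-style interval dynamic
programming, O(n³) time, with pair energies GC −3, AU −2, GU −1 (model
units) and at least 3 unpaired bases in every hairpin loop. This is a
deliberately simple, fully specified model — not a nearest-neighbor
thermodynamic parameterization. Absolute ΔG values therefore do not match
any external folding tool; only within-run contrasts (regulated vs
non-regulated distributions) are meaningful. The folding backend is
pluggable: `compute_features` accepts any callable returning an object
with `delta_g`, so a thermodynamic folder can be dropped in.

Numerical choices: traceback ties are broken deterministically (3′ base
unpaired preferred, then the 5′-most partner) with a 1e-9 energy
tolerance; sequences longer than a cap (default 5000 nt) are refused, not
truncated; unpairable sequences return ΔG = 0 with an all-dot structure.
An exhaustive enumeration oracle (`brute_force_mfe`, guarded to ≤ 22 nt,
leftmost-base recursion independent of the production DP) backs the tests,
together with the invariants ΔG ≤ 0, subadditivity under concatenation,
and reverse-complement symmetry — the last only for a complement-closed
pair set (GC/AU), because a G:U wobble pair reverse-complements to the
unpairable A:C.

## Group comparison

Features of all mRNA variants of a protein are analyzed with weight 1/k
(k = number of *included* variants), so every protein contributes total
mass 1 and multi-variant proteins do not skew distributions. k is
recomputed after the <13-nt exclusion so weights always sum to 1; counting
excluded variants in the denominator is available via `recompute_k=False`.
Proteins with no included variant are dropped and logged.

Default bins follow the reported conventions: length <150 / 150–550 / >550
nt (both boundary values fall in the middle bin) and uORF counts 0..7 with
a ≥8 tail. Two test modes:

* **permutation** (default): Pearson χ² statistic on the unrounded
  weighted 2×bins table; the null comes from shuffling group labels over
  proteins; p = (1 + #{perm ≥ obs}) / (1 + n_perm). This is the
  statistically proper treatment of non-integer weighted counts.
* **chi-square-rounded**: weights rounded half-up to integers, classical
  asymptotic χ² — provided for comparability with spreadsheet-style
  analyses.

Zero-total bins are dropped from the statistic; a group with zero mass is
an error.

## Metabolite screen

Per-sample median normalization: every sample is scaled so its median over
*detected* (nonzero) metabolites equals the median of the per-sample
medians; the operation is idempotent and an all-zero sample is an error.
(A per-metabolite reading of "median normalization" exists; per-sample is
the standard one and is what is implemented.)

Presence: a metabolite is detected in a genotype at a timepoint when at
least `min_fraction` (default 1.0, "consistently detected") of that
genotype's cell replicates exceed a threshold (default: half the smallest
nonzero normalized intensity, so detection coincides with nonzero under
the defaults and is invariant to global rescaling). The genotype-level
pattern (both / wt-only / mutant-only / neither) requires detection at
*every* timepoint; a flag records whether the per-timepoint patterns
agree. Uptake/secretion: conditioned-medium mean below (above) the
unconditioned-medium mean by a relative margin (default 20%, direction
being the scientifically reported quantity, not a published cutoff) is
consumed (secreted), per genotype.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is tested
under: 1240 quantifiable proteins, 80/1240 regulated with up-bias 0.9
(≈ 72 up : 8 down), effect 1 log2 unit against replicate noise of 0.25
log2 units, 4 replicates of which 2 label-swapped, 10% per-cell
missingness. Regulated-group UTR lengths are log-normal with median ≈ 365
nt against ≈ 148 nt (σ_log = 0.9) — longer regulated UTRs with heavier
tails past 550 nt; planted uORF counts are Poisson with mean 3.5 vs 1.5;
sequences are i.i.d. at 60% GC (a typical 5′-UTR composition) before motif
insertion. Variants per protein follow a truncated geometric (p = 0.5,
max 4) — the variant-count distribution is not derivable from the study
and this is a modeling choice. Annotation flags are Bernoulli per group
with configured SP/TM overlap, or, in fixture mode, an exact study-scale
table (1240 proteins; 237/177/97 SP/TM/both; 80 regulated with 27/24/13;
8 downregulated all-negative). The metabolome plants one mutant-only
metabolite (present in mutant cells at every timepoint, zero in wt) and
two consumed (0.4×) / two secreted (2.5×) medium metabolites around an
unconditioned reference, with 25% log-normal sample noise and 2 replicates
per condition.

Planted uORFs are written by overwriting a 7-nt window (−3..+4) at
non-overlapping positions at least 3 nt from the 5′ end, so every planted
start is guaranteed recoverable by the scanner (tested); incidental
context-valid starts also arise from the random background at roughly one
per 100 nt, as in real sequence.

Determinism: every generator draws from its own named substream
(`SeedSequence(seed, spawn_key=crc32(name))`), so a fixed seed reproduces
each table byte-for-byte and adding a generator never perturbs another's
draws. Missing values are absent cells (NaN), not zeros, because the
detection filter counts presence.

What the generator does *not* emulate: peptide-level quantification and
roll-up, intensity-dependent missingness, correlated replicate structure,
real transcript architecture (introns, alternative TSSs), database
redundancy, or chromatographic artifacts. Passing tests therefore
demonstrate correctness and calibration of the *analysis*, not performance
on any real acquisition.

## Problem sizes used in the validation runs

The test suite and acceptance script run at sizes chosen to make the
statistical checks sharp while staying desk-scale: null calibration at
5000 proteins; parameter recovery at 2000 proteins (effect 1.0, noise
0.25); UTR group detection across 20 independent study-scale replicates
(1240 proteins each); scanner oracle agreement on 500 random transcripts
(13–400 nt); folding oracle agreement on 300 random sequences (8–18 nt)
plus 1000 concatenation pairs. Real-study headline counts (2888 proteins
identified, specific median UTR lengths of a given transcript database)
depend on raw acquisitions and database versions and are out of scope.

## Known limitations

* The folding model ignores stacking and loop entropies; ΔG contrasts are
  qualitative.
* Raw p < 0.05 calling at thousands of tests implies a known
  false-positive load (~5%, verified by the null-calibration test); the
  BH column is the remedy when error control matters.
* The χ²-rounded mode inherits the asymptotic approximation and the
  arbitrariness of rounding; prefer the permutation mode.
* Uptake/secretion calls with 2 replicates per condition and 25%
  multiplicative noise will misclassify some unshifted metabolites at the
  default 20% margin; planted directional shifts are called reliably.
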