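# Methods

This note documents the models, statistical procedures, parameter choices
and known limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Variant consensus

Variants are keyed on (chrom, pos, ref, alt, sample). Single-nucleotide
variants only; indels are dropped with a warning. The five cohort cutoffs
(`ref_reads_normal`, `total_reads_tumor`, `alt_reads_tumor` lower bounds;
`tumor_vaf` lower bound; `normal_vaf` upper bound) are all boundary-
inclusive. Two preset configurations ship: a deep-coverage whole-exome
cohort (8/28/10/0.10/0.05) and a shallower tumor/PDX cohort (8/14/5/0.10/
0.05), each with its hypermutant exclusion list.

**Order of operations.** Whether cutoffs were applied per caller before or
after intersection is genuinely open; the default applies them per caller
record first and intersects the survivors, because the cutoffs are defined
on per-caller output fields and this order is stable under re-merging. The
alternative (`filter_order="consensus_first"`) merges first, taking
per-field maxima of the read evidence, and filters the merged record.

TMB uses the overlap-collapsed (interval-union) length of the supplied BED
regions in megabases; zero-size region sets are an error, not a zero
denominator.

## The 288-class substitution scheme and the permutation null

Each mutation is classified by (flanking context, alternate base): 64
trinucleotide contexts for interior positions, and 16 + 16 boundary
dinucleotide contexts for the first/last base of a UTR, where the absent
flank is marked `.`. With 3 alternate bases each, 96 contexts × 3 = 288
classes. Boundary contexts are interpreted as UTR-terminal positions; this
is the natural reading of "no nucleotide in exclusively the first or third
position" and is asserted structurally (192 full + 96 boundary classes).

The permutation null redraws each observed mutation uniformly, with
replacement, among all UTRome positions whose context matches its class
(same context string, same alternate base). Per-class counts are therefore
preserved exactly in every permutation — the suite checks this by
re-deriving class counts from instrumented draws. A class with no matching
UTRome position is excluded with a warning and the affected count adjusted.
Position collisions within a permutation are allowed; at UTRome scale they
are negligible.

Enrichment per motif category is reported two ways, as the observed count
against `n_perm` background counts:

* a one-sample *t* test of the background vector against the observed count
  (two-sided by default; one-sided available). With a zero-variance
  background the *t* statistic is undefined and only the empirical values
  are reported (p = 1 when the background equals the observed constant);
* empirical p values, `(1 + #{bg ≥ obs})/(1 + n_perm)` for enrichment and
  the mirrored form for depletion.

**Calibration.** Under the null (mutations drawn uniformly over UTRome
positions and alternate bases — the same distribution the permutation uses,
marginalized over classes), the empirical enrichment p is uniform up to the
discreteness of the count distribution. The acceptance study uses 500
simulated datasets of 150 mutations on a shared 12-UTR UTRome with
n_perm = 200, reading out the m⁶A category: RRACH is dense enough
(~1 expected site per 85 nt) that observed counts spread over many values,
keeping the tie-induced conservatism of the `(1+k)/(1+n)` estimator small.
The measured rejection rate at 0.05 sits inside the binomial 99% band.

## Motif scanning

Windows of ±100 nt around the mutation (clipped at UTR ends) are scanned in
WT and mutant form; a site is "lost" if present only in WT, "gained" if only
in the mutant. U and T are equivalent throughout.

* **Fixed patterns.** PAS `AAUAAA` and m⁶A `RRACH` are exact IUPAC substring
  matches (vectorized; verified against regex expansion).
* **miRNA seeds.** A seed (miRNA positions 2–8) matches at the reverse
  complement of positions 2–8 (7mer-m8) or of positions 2–7 followed by A
  (7mer-A1). Only a configured top-expressed subset should be supplied.
* **PWMs.** Log-odds against a background base composition (uniform by
  default; the UTRome composition via `utrome_background`). A position is a
  site when its score reaches `score_threshold` × the motif's maximum
  achievable log-odds; the default fraction is 0.8. Sources give no
  published threshold, so the fraction is explicit and configurable.

## Reporter library design

Inserts are 201 nt: 100 nt of sense-strand flank either side of the mutated
base, mutant differing from WT at exactly that position (asserted at
construction). Mutations within 100 nt of a UTR end use supplied genomic
flank when available; otherwise the window shifts to stay inside the UTR,
keeping length 201 and recording the off-center 1-based edit offset.
Controls (201 nt, three categories: miRNA-seed, repressor/activator,
element-dose) carry no mutation key. Sequence-identical library members are
reported as a warning list, not an error, since nearby mutations genuinely
produce identical WT windows.

## Stability MPRA

Counts are divided by each sample's spike-in count; every downstream
statistic is invariant to rescaling a sample's counts and spike together.
Decay ratios are per-replicate `normalized(t)/normalized(1 h)` for t = 3, 6 h,
compared between mutant and WT with a two-sample *t* test — Welch by
default, since nothing supports equal variances — and summarized as
log₂(mean mutant ratio / mean WT ratio).

The decay model `y(t) = yf + (y0 − yf)·exp(−α·t)` is fitted by
Levenberg–Marquardt least squares (`scipy.optimize.curve_fit`, ≤ 1000
evaluations, 1e-8 tolerances) from starts (0.5, 0, 0.1), jointly over all
replicates' points (30 points for 5 timepoints × 6 replicates) — pooling
stabilizes α at MPRA depths. Before fitting, each insert's curve is scaled
so its replicate-mean 1 h value maps to 0.5, matching the y0 start; scaling
leaves α and the half-life invariant and is switchable off. Constant
(e.g. all-zero) curves, optimizer failures, and fits with α ≤ 0 return
`converged=False` with an undefined half-life rather than raising.
Half-life is ln 2 / α, an exact identity of the stored fields.

Recovery, measured by the acceptance study: noiseless curves refit α to
~1e-9 absolute; with Poisson noise at 400 mean 1 h reads/insert and 6
replicates, the median relative α error over α ∈ [0.05, 0.5] /h is ~4%.

**Significance filters.** A pair is significant iff all of:
(A) summed raw 1 h counts ≥ 24 for both inserts (summed over replicates, as
written; boundary inclusive); (B) p < 0.05 *and* |log₂FC| > 0.3 at 3 h or at
6 h (strict); (C) |log₂(mutant half-life / WT half-life)| > 0.2 (strict;
false when either fit failed). In the size/power study (500 pairs, baseline
α = 0.2 /h ≈ 3.5 h half-life, a typical mRNA), null pairs pass all three at
≪ 5% and pairs with a 0.6 log₂ half-life shift are detected > 99% of the
time; the 6 h comparison carries most of the power because a 0.6 log₂
half-life shift moves the 3 h decay ratio by only ~0.3 log₂ units, exactly
at threshold B.

## Translation MPRA

Counts per fraction are CPM-normalized (pseudocount 0.5 added to counts).
TE per replicate is (low + high polysome CPM)/total CPM (`total_poly`) or
high/total (`high_poly`); the monosome fraction is read but unused, matching
the two TE definitions. Because CPM renormalizes within each sample,
absolute TE carries a per-fraction library-size scale; it cancels in the
mutant-vs-WT ratio of ratios, which is the reported effect. Differential TE
is a two-sample Welch *t* test on replicate log₂-TE values with
Benjamini–Hochberg correction across pairs, significant at FDR < 0.10. This
replicate-level test is deliberately simple and self-contained — it is not
a count-model method like xtail, and the output's `method` tag says so.
Under the global null the call rate stays below the FDR target; a planted
16-fold TE shift at 300 reads/insert is detected with the realized
ratio-of-ratios within ~5% of 16.

RNA expression change (control validation) is log₂(total CPM/plasmid CPM).

## Base-editor feasibility

Only transitions are installable: C→T and G→A by CBE, A→G and T→C by ABE.
The PAM must lie on the strand where the change reads C→T (CBE) or A→G
(ABE), 3′ of the edited base. Distance is the number of nucleotides strictly
between the edited base and the first (protospacer-proximal) PAM base, and
must be 13–18 — placing the edit at protospacer positions ~3–8 of a 20-nt
spacer, the canonical base-editing window. The convention (first PAM base,
both endpoints exclusive of the counted bases) is recorded in the output. A
bystander is any other editable-type base (C for CBE, A for ABE) whose own
distance to the same PAM is also in 13–18; a PAM qualifies only with zero
bystanders. Among qualifying PAMs, priority is NGG, NG, then the engineered
variants (NGAN, NGCG, NNGRRT, NNNRRT), ties broken by smaller distance; the
20 nt 5′ of the PAM is reported as the protospacer.

Note that widening the distance window is *not* monotone for editability:
it adds candidate PAMs but also enlarges the bystander window, so a verdict
can be revoked. The suite therefore checks correctness against exhaustive
enumeration (all strands, substrings, patterns, distances) rather than a
monotonicity property.

## Feature comparisons

Binary features (motif alteration; conservation score strictly > 0.9) use
Pearson chi-square without continuity correction (configurable); continuous
features (GC of the 201-nt WT insert window; externally supplied ΔG in
kcal/mol, e.g. minimum free energy of the insert computed by an RNA-folding
package) use two-tailed unpaired Welch *t* tests. The 201-nt window (not the
full UTR) is used for both GC and ΔG for comparability with the reporter.
Conservation lookups on a bedGraph-like track return missing for uncovered
positions, which are excluded from the conservation comparison only.

## Synthetic data: what it emulates, and what it does not

* **UTRome.** i.i.d. bases at a target GC (default 0.45, typical of human
  3′ UTRs), lengths uniform in a configurable range, one synthetic
  chromosome per UTR (`chrSYN1..N`) to avoid genome-build ambiguity, all on
  the + strand. Motifs can be planted by overwriting non-overlapping
  stretches.
* **Mutations.** Drawn from a 288-class frequency table (default: uniform
  over candidate position×alt pairs, i.e. classes weighted by availability).
  Classes are drawn sequentially and an exhausted class is redrawn, keeping
  mutation positions unique; with a large UTRome the distortion is
  negligible. A requested number of mutations can be placed exactly inside
  planted motif sites, with the rest kept outside.
* **Caller tables.** Read evidence (tumor depth ~ Poisson(100), true VAF
  ~ U(0.2, 0.5), alt reads binomial, normal contamination 0.2%) is drawn
  once per true mutation and shared across callers; each caller reports a
  true mutation with its sensitivity, plus per-caller false positives at
  random UTRome positions.
* **Stability counts.** Expected count of insert i in sample (t, r) is
  `depth · A_i · exp(−α_i (t − t₀)) · f_s`, with A_i unit-mean log-normal
  (σ = 0.5) initial abundances — the library's insert-abundance distribution
  is unpublished, so log-normal is the configurable default — and f_s
  unit-mean log-normal (σ = 0.2) per-sample efficiency factors, which the
  spike-in (constant true abundance × f_s) normalizes away. Anchoring at
  the first timepoint makes mean 1 h counts equal `depth`. Noise is Poisson
  by default; negative-binomial (configurable dispersion) is available
  because real MPRA counts are overdispersed; `noise="none"` returns exact
  expectations for closed-form tests.
* **Polysome counts.** Plasmid and total expectations `depth · A_i`; low and
  high polysome `depth · A_i · TE_i/2` each; monosome `depth · A_i/2`. The
  planted multiplier TE_i is exactly the expected mutant/WT ratio of ratios.

Not emulated: raw reads, alignment artifacts, PCR duplicates, UTR-length and
expression biases of real transcriptomes, correlated caller errors, and
fraction cross-contamination in polysome gradients. Passing tests therefore
demonstrate correctness of the statistics and calling logic under the stated
generative models, not robustness to every artifact of real MPRA data.

## Problem sizes and numerical choices

Acceptance studies use: 1,000 mutations for library geometry; 1,000 inserts
for noisy decay recovery; 500 WT/mutant pairs for stability size/power; 500
simulated datasets × 200 permutations for calibration; 1,000 true mutations
+ 4 × 50 false positives for the consensus oracle; 500 random 80-nt loci for
the editability oracle; 200 pairs for the translation arm. Seeds derive from
a single `--seed` via a child generator; identical seeds give byte-identical
outputs everywhere. Ties in PAM selection break by distance; ties in BH are
handled by the step-up running minimum; degenerate inputs (zero spikes,
zero-count columns, zero-variance vectors, empty groups) are excluded or
reported with reasons rather than raised, except where the input is
structurally invalid (duplicate caller keys, mismatched reference bases,
non-probability PWMs).
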