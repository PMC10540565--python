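# utrmpra

A Python toolkit for analyzing somatic mutations in 3′ untranslated regions
(3′ UTRs) and their functional consequences, built for studies that pair
tumor/normal variant calling with massively parallel reporter assays (MPRAs)
of mRNA stability and translation — the setting of metastatic prostate
cancer cohorts, where 3′ UTR point mutations can rewire post-transcriptional
regulation of oncogenes and tumor suppressors.

The package implements the full desk-side analysis chain:

1. **Variant consensus** (`utrmpra.consensus`) — merge the output tables of
   four somatic SNV callers, apply cohort-specific read-support and VAF
   cutoffs (e.g. `ref_reads_normal ≥ 8`, `total_reads_tumor ≥ 28`,
   `alt_reads_tumor ≥ 10`, `tumor VAF ≥ 0.1`, `normal VAF ≤ 0.05`), retain
   variants reported by ≥ 2 callers, drop hypermutant samples, and compute
   tumor mutational burden (mutations/Mb) over overlap-collapsed BED regions.
2. **Motif enrichment** (`utrmpra.motifs`) — classify each mutation into a
   288-class substitution scheme (64 trinucleotide contexts plus 2×16
   UTR-boundary dinucleotide contexts, × 3 alternate bases), scan paired
   WT/mutant windows for gain and loss of RNA-binding-protein PWM sites,
   miRNA seed matches (7mer-m8 and 7mer-A1), the polyadenylation signal
   AAUAAA, and the m⁶A RRACH consensus, and test enrichment against a
   permutation null that redraws every mutation uniformly among 3′ UTRome
   positions of the *same* context class, preserving base-change and context
   frequencies exactly. Enrichment is scored by a one-sample *t* test of the
   background against the observed count plus empirical *p* values.
3. **Library design** (`utrmpra.design`) — 201-nt WT/mutant reporter insert
   pairs (100 nt of flank either side of the mutation) plus control
   sequences, with FASTA/TSV output.
4. **Stability MPRA** (`utrmpra.stability`) — spike-in normalization of a
   1/3/6/12/24 h time course over 6 replicates, 1→3 h and 1→6 h decay-ratio
   *t* tests, nonlinear least-squares fits of
   `y(t) = yf + (y0 − yf)·exp(−α·t)` (starts y0=0.5, yf=0, α=0.1),
   half-life = ln 2 / α, and a three-filter significance call:
   (A) summed 1 h raw counts ≥ 24 for both inserts, (B) p < 0.05 and
   |log₂FC| > 0.3 at 3 h or 6 h, (C) |log₂FC half-life| > 0.2.
5. **Translation MPRA** (`utrmpra.translation`) — CPM normalization of
   plasmid/total/monosome/low-polysome/high-polysome fractions, translation
   efficiency (TE) as polysome:total CPM ratios, differential TE as the
   log₂ ratio-of-ratios (mutant TE / WT TE) with a replicate-level *t* test
   and Benjamini–Hochberg FDR < 0.10.
6. **CRISPR editability** (`utrmpra.editability`) — base-editor feasibility:
   transitions only (CBE: C→T/G→A, ABE: A→G/T→C), PAM search
   (NGG, NG, NGAN, NGCG, NNGRRT, NNNRRT; NGG/NG prioritized) on the strand
   where the edit reads C→T or A→G, PAM 13–18 nt 3′ of the edited base, and
   zero bystander editable bases in that window.
7. **Feature statistics** (`utrmpra.features`) — functional-vs-passenger
   comparisons of motif overlap and high conservation (phastCons-style score
   > 0.9) by chi-square, and of GC content and supplied folding ΔG by
   two-tailed Welch *t* tests.
8. **Synthetic data** (`utrmpra.synthetic`) — generators for every input the
   pipeline consumes (UTRome, mutations with chosen context frequencies,
   caller tables with configurable sensitivity/false positives, decay
   time-course counts, polysome counts with planted TE shifts), all with
   known ground truth and exact seed reproducibility, so the whole chain is
   testable without controlled-access patient data.

## Worked example

```python
import numpy as np
from utrmpra import synthetic, design, stability

utrome = synthetic.gen_utrome(6, (400, 600), seed=1)
muts, truth = synthetic.gen_mutations(utrome, 4, seed=2)
designs = design.design_library(muts, utrome)
pairs = design.design_pairs_table(designs)

ids = [sid for sid, _ in design.library_sequences(designs)]
alphas = {sid: (0.35 if sid.endswith("_MUT") else 0.2) for sid in ids}
counts, samples = synthetic.gen_stability_counts(ids, [alphas[i] for i in ids],
                                                 depth=400, seed=3)
calls, fits = stability.call_stability(counts, samples, pairs)
print(calls[["mutation_key", "log2fc_decay_6h", "p_6h",
             "log2fc_half_life", "significant"]].round(3).to_string(index=False))
```

Output:

```
   mutation_key  log2fc_decay_6h  p_6h  log2fc_half_life  significant
UTR0002:286:T>A           -0.858 0.001            -0.690         True
UTR0005:287:A>T           -0.947 0.000            -0.708         True
UTR0002:199:C>G           -0.923 0.002            -0.826         True
UTR0001:140:C>G           -0.944 0.000            -0.831         True
```

Each mutant insert decays with α = 0.35 /h against a WT α = 0.2 /h, a true
half-life change of log₂(0.2/0.35) ≈ −0.81. The fitted half-life ratios
(−0.69 to −0.83) recover it to within Poisson counting noise at a mean
depth of 400 reads per insert, the 6 h decay comparison is significant for
every pair, and all three filters pass.

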