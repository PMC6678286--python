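# Methods

This note documents the models and procedures implemented in `repscreen`,
the defaults chosen where the design was open, and what the synthetic-data
generators do and do not emulate.

## Paired cohorts and preprocessing

A cohort is a probeset × sample matrix of positive array intensities with
each patient contributing one tumor and one adjacent-normal sample. All
analysis happens on the log2 scale after a floor step: intensities below 50
(array units) are rounded up to 50, so near-background probes cannot
produce explosive ratios. The floor is applied *before* any ratio is
computed; `floor` is a parameter (default 50).

Per-probe paired statistics are built from the per-patient difference
vector d_k = log2(tumor_k) − log2(normal_k); patients are ordered by sorted
patient id so results are independent of column order.

## Signature selection

**top100.** Probes are gated at |mean log2 ratio| ≥ log2(2) and the 100
largest absolute ratios are kept, counting up- and down-regulated probes
together (both the count and the fold gate are parameters). Ties break by
probe id. A cohort in which no probe changes two-fold raises an error
rather than returning an empty signature.

**Volcano.** A probe is selected when its paired t-test p-value is below
10⁻⁴ *and* it passes the two-fold gate. The fold cutoff is exposed because
only "a fold-change cutoff" is conventionally specified; two-fold was chosen
to match the top-100 gate. Degenerate zero-variance probes are flagged, not
dropped: a probe with identical nonzero differences in every patient gets
p = 0 and is selected iff it also passes the fold gate; all-zero differences
give p = 1. Leave-one-out selection excludes one *patient* (both samples),
which preserves pairing, and emits one signature per excluded patient,
labelled by that patient.

**Paired SAM.** The paired design is analysed as one-class SAM on the
difference vectors: d_i = r_i / (s_i + s0) with r_i the mean difference and
s_i its standard error. s0 is chosen by the percentile rule: candidate
values are the 0, 5, …, 100th percentiles of s; for each candidate the
spread of d (median absolute deviation) is computed in 100 quantile windows
of s, and the candidate minimising the coefficient of variation of those
spreads wins, ties toward the smaller percentile. The null comes from 100
seeded random sign-flips of the patient difference columns, with s
recomputed per flip. Observed order statistics d_(i) are compared with their
permutation expectation d̄_(i); for a half-width Δ the upper cut is the
smallest positive d_(i) with d_(i) − d̄_(i) ≥ Δ (analogously below), and
every probe beyond a cut is called.

The FDR estimate at Δ is the *average* number of permutation statistics
beyond the cuts divided by the observed call count. The average (the
original SAM formulation) rather than the median is the default for a
specific reason: an FDR of exactly 0 should mean "no permutation places a
single statistic beyond the cuts". With a median-based count, FDR 0 is
reached whenever the observed maximum beats the *median* permutation
maximum — a coin flip on pure-null data — and the FDR-0 selection rule
would call one spurious probe in roughly half of null cohorts. The
median variant remains available (`fdr_statistic="median"`).

Selection takes the smallest Δ with FDR ≤ 0 (target exposed), then raises Δ
until the called set is below 1000 probes. Δ candidates are the 512
quantiles of the observed |d_(i) − d̄_(i)| gaps: deterministic, and fine
enough that the selected call set is insensitive to the grid in practice.

Small-sample caveat: with P patients there are only 2^P sign-flip patterns.
Below about 10 patients, permutations that nearly reproduce the observed
labelling occur frequently, and an FDR of exactly 0 becomes unattainable —
SAM then honestly calls nothing. The study-scale default of 24 patients is
comfortably away from this regime.

## Connectivity scoring

The per-instance statistic is the signed two-tail KS statistic over the tag
positions (formulas in the README); the two tag lists combine to
s = ks_up − ks_down when their signs differ and 0 otherwise, and raw scores
are scaled by the extreme positive/negative score across instances.
Signature probes missing from the reference universe are dropped with a
logged count; a signature with no probes left is a query error. Rank
matrices with ties are rejected at load.

Drug-level enrichment orders instances by descending scaled score and
applies the same KS statistic to the drug's instance positions, with a
p-value from 10,000 seeded random draws of position subsets (add-one
corrected, two-sided on |enrichment|). Because raw scores of exactly 0 are
common (any instance whose up- and down-KS share a sign), the ordering
breaks ties with a seeded random permutation. This matters: a deterministic
tie-break (e.g. by instance id) would cluster each drug's instances inside
the tied block and systematically inflate |enrichment| for null drugs,
invalidating the uniform-positions null. The null distribution is cached
per (instance count, total) within a query. A drug owning every instance
has nothing to discriminate and reports p = 1.

## Consensus funnel

Per cohort: one top-100 query, one SAM query, one volcano query per
leave-one-out sub-dataset. A drug's per-method frequency is hits over all
queries of that method pooled across cohorts (the natural alternative —
per-cohort frequencies — is not implemented; pooled was the declared
choice). The 20% rule is strict: frequency must exceed 0.20, so 2 hits in
10 queries do not pass. Final candidates pass all three methods; the report
ranks by (final, mean frequency, more-negative mean enrichment, label).

Leave-one-out queries are *near-duplicates* of one another (two sub-datasets
share all but one patient), so per-method pass counts for null drugs are far
more variable than an independent-queries binomial model predicts: one lucky
decoy tends to hit most volcano queries at once. The acceptance tests
therefore bound the decoy *per-query* hit rate by α (with seed-level
clustering) and apply the binomial envelope only to the one-query-per-cohort
methods; the expected number of decoys surviving the full three-way
intersection stays below one in the screens we run.

## GSEA

Classic weighted-KS running sum: hits advance by |score|^p normalised over
hit weights (p = 1 default; p = 0 gives the unweighted KS limit), misses
retreat by 1/(N − N_hit); ES is the extremum, the leading edge the hit genes
at/before it (after it, for negative ES). The null permutes *gene sets*
(random same-size sets drawn from the profile), not phenotypes — a drug
ranking has no sample replicates to permute. A drug's ranked profile is
built from the reference as n − (mean rank across the drug's instances),
sorted descending; this construction is a package choice.

## Median-effect and combination index

fa/fu = (D/Dm)^m is fitted by ordinary least squares on the linearised
scale; r is the Pearson correlation of that fit and Dm ≡ IC50. Replicate
doses are averaged on the fa scale before linearisation. fa values of 0 or
1 cannot be linearised and are clipped to (10⁻⁶, 1 − 10⁻⁶) with a warning.
The CI uses the mutually exclusive (classic) two-term form — the standard
choice; the nonexclusive third product term is not implemented.
`classify_ci` maps CI < 1 / = 1 / > 1 to synergism / additivity /
antagonism, with an optional tolerance band around 1. Constant-ratio
analysis checks the declared component ratio to 10⁻⁹ relative, fits the
combination on total dose, and evaluates the CI at each *observed*
combination fa.

A published table of combination-index measurements (withaferin A paired
with pemetrexed, cisplatin or gemcitabine across four NSCLC cell lines) is
shipped as package data purely as classification input; the package cannot
recompute those values because the underlying viability measurements are
not available.

## Synthetic-data generators

`generate_paired_cohort` draws per-probe log2 baselines from N(8, 1), a
per-patient baseline shift N(0, 0.5) shared by the patient's two samples
(this is what gives the paired t-test its advantage), independent
per-sample noise N(0, 0.5), and adds ±effect_size (default 1.5, ≈2.8-fold)
to tumor samples of planted probes. Intensities are 2^(log2 value), so a
realistic left tail falls below the floor of 50 — planted *down* probes with
low baselines are partially clipped by the floor, deliberately, which is
why recovery of down probes runs slightly behind up probes. Defaults (24
patients, 5000 probesets, 100 up + 100 down planted) emulate a
lung-adenocarcinoma cohort of 48 paired arrays. `generate_study` reuses one
planted probe set across several cohorts with independent patients and
noise, emulating independent cohorts of the same disease.

`generate_reference` produces 50 drugs × 4 instances of full probe-universe
permutations. For the planted reversal drug, a fraction `reversal_strength`
(default 0.8) of planted tumor-up probes is placed uniformly within the
bottom decile of each instance's ranking, and of tumor-down probes within
the top decile; placing them in a decile rather than at the exact extremes
keeps KS statistics away from the degenerate value 1. Decoy instances are
uniform random permutations.

`generate_dose_response` inverts the median-effect model and adds Gaussian
noise on the log10(fa/(1−fa)) scale, where the model is linear.
`generate_combination` solves the Loewe additivity condition
d1/Dx1(fa) + d2/Dx2(fa) = 1 exactly (Brent root-finding to 10⁻¹⁴) for each
total dose at a constant component ratio; the synergistic/antagonistic
modes evaluate that additive curve at dose × shift (default shift 2), i.e.
the mixture acts as if two-fold more/less potent, pushing CI to ≈1/shift
and ≈shift respectively.

What the generators do *not* emulate: probe-level array processing (CEL
normalisation, platform mapping), correlated probe blocks, batch effects in
the perturbation reference, dose-dependent variance in viability assays.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the stated generative model, not that any particular
real cohort or reference build would yield the same candidate lists.

## Problem sizes in the shipped checks

The acceptance tests and `scripts/acceptance.py` run SAM/volcano
calibration on 20 cohorts of 5000 probes × 24 patients, and the screening
funnel on 20 replicates of 3 cohorts × 24 patients × 5000 probes against a
50-drug, 200-instance reference — the full study-scale conditions; GSEA
null uniformity uses 200 replicates of a 200-gene profile. These sizes were
chosen so the complete check suite runs in a few minutes on one CPU.

## Known limitations

- Probe identifiers are opaque strings end to end: no probe-to-gene
  collapsing or cross-platform mapping.
- The drug-level p-value is a sampling null over instance positions; it is
  a declared construction, not a reimplementation of any specific web
  tool's permuted results.
- Real rank matrices with tied ranks are rejected, not repaired.
- The stemness-module GSEA ships no gene list; any GMT can be supplied, and
  the planted-reversal demonstration uses the generator's ground truth
  instead.
- No NES/multi-set FDR machinery, no isobologram graphics, no
  Bliss-independence alternative.
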