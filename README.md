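# repscreen

Signature-reversal drug repurposing for paired tumor/normal expression
cohorts, as a tested, fully synthetic-data-driven pipeline.

The idea: derive up/down gene signatures that separate tumors from their
adjacent-normal tissue, then search a drug-perturbation reference (a
CMap-style collection of per-instance probe rankings) for compounds whose
perturbation profile *reverses* those signatures — candidate therapeutics.
Candidate lists from three independent signature-selection methods are
consolidated by a frequency rule and a three-way intersection. Two follow-up
analyses round out the workflow: gene set enrichment analysis (GSEA) to test
whether a candidate's profile is the reverse of a gene set of interest
(e.g. a stemness module), and Chou–Talalay median-effect / combination-index
analysis to quantify synergy between a candidate and standard chemotherapy.

## What it computes

**Signatures** (from a floored, log2-scale paired cohort; intensities below
50 are rounded up to 50 first):

- *top100* — the 100 probesets with the largest |mean log2 tumor/normal
  ratio| among those changing at least two-fold;
- *volcano* — paired t-test p < 10⁻⁴ plus the two-fold gate, applied
  leave-one-patient-out to yield one signature per sub-dataset;
- *SAM* — paired significance analysis of microarrays,
  d_i = mean(diff_i)/(s_i + s0), sign-flip permutation null (100
  permutations), selected at estimated FDR 0 with the signature capped below
  1000 probesets.

**Connectivity.** For signature tags at ascending ranks V(j) within an
instance ranking of n probes,

    a = max_j [ j/t − V(j)/n ],  b = max_j [ V(j)/n − (j−1)/t ],
    ks = a  if a > b  else −b

The instance connectivity score is `ks_up − ks_down` when the two statistics
disagree in sign, else 0; scores are scaled to [−1, 1] across instances.
Each drug then gets an enrichment score (the same KS statistic applied to
its instances' positions in the score ordering) and a permutation p-value.
A drug is a **hit** when enrichment < 0 and p < 0.05; drugs hitting strictly
more than 20% of a method's queries pass that method, and the final
candidates pass all three methods.

**GSEA.** Weighted Kolmogorov–Smirnov running sum (hits weighted by
|score|^p, p = 1) with a gene-set permutation null; negative ES = the set
concentrates among the genes the drug down-regulates.

**Synergy.** Median-effect model fa/fu = (D/Dm)^m fitted by least squares on
log10(fa/(1−fa)) vs log10 D (Dm = IC50), and the combination index

    CI = d1/Dx1(fa) + d2/Dx2(fa),  Dx = Dm·(fa/(1−fa))^(1/m)

with CI < 1 synergism, CI = 1 additivity, CI > 1 antagonism.

Every input the pipeline needs can be generated synthetically with known
ground truth: paired cohorts with planted differentially expressed probes, a
perturbation reference with one planted reversal drug, and dose-response /
constant-ratio combination series with known (m, Dm) and interaction mode.

## Worked example

```python
import repscreen as rs
from repscreen.consensus import run_screen, report

cfg = rs.SimulationConfig(n_patients=12, n_probes=1000, n_up=40, n_down=40,
                          effect_size=1.5, noise_sd=0.3, seed=0)
cohorts = rs.generate_study(cfg, n_cohorts=3)
ref = rs.generate_reference(cohorts[0].probe_ids, cohorts[0].planted_up,
                            cohorts[0].planted_down, n_drugs=20,
                            instances_per_drug=4, reversal_strength=0.8, seed=0)
table = run_screen({f"cohort{k}": c for k, c in enumerate(cohorts)}, ref, seed=0)
print(report(table)[["drug", "frequency_top100", "frequency_volcano",
                     "frequency_sam", "mean_enrichment", "final"]].head(4))
```

prints

```
            drug  frequency_top100  frequency_volcano  frequency_sam  mean_enrichment  final
planted-reversal               1.0           1.000000       1.000000        -0.962500   True
        decoy_13               0.0           0.083333       0.666667        -0.415476  False
        decoy_02               0.0           0.000000       0.333333        -0.433631  False
        decoy_08               0.0           0.027778       0.000000        -0.410417  False
```

The planted reversal drug is a significant reversal hit in every query of
all three methods (frequency 1.0 each, mean enrichment −0.96) and is the
only drug to pass the three-way intersection (`final`). The best decoy hits
a few queries by chance but never clears the >20% rule in all three methods.

The same workflow is available from the shell:

```sh
repscreen simulate --out demo --n-patients 12 --n-probes 1000 --seed 0
repscreen screen --config screen.yaml --out results/
repscreen gsea --profile profile.tsv --gmt sets.gmt --set stemness --out results/
repscreen synergy ci --drug1 a.csv --drug2 b.csv --combo combo.csv --ratio 1:10 --out results/
```

## Layout

- `repscreen.synthetic_data` — cohort / reference / dose-response generators
- `repscreen.signatures` — floor preprocessing, top-100, volcano (+ leave-one-out), paired SAM
- `repscreen.connectivity` — KS connectivity scoring and drug enrichment
- `repscreen.consensus` — the frequency/intersection screening funnel
- `repscreen.enrichment` — weighted-KS GSEA
- `repscreen.synergy` — median-effect fits and combination index
- `repscreen.io` / `repscreen.cli` — GCT/GMT/GRP/TSV/CSV readers-writers and the `repscreen` command

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
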