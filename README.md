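# netvuln

Network-vulnerability screening of miRNA biomarkers for platinum
resistance from paired miRNA/mRNA expression profiles.

## Scientific problem

In high-grade serous ovarian cancer, a large share of patients relapse
with platinum-resistant disease, and individual differentially
expressed miRNAs rarely replicate as resistance markers. `netvuln`
implements a network-vulnerability approach: rather than ranking miRNAs
by fold change alone, it asks which miRNAs hold *exclusive* control
over many target genes inside the condition-specific regulatory
network, because removing such a regulator disconnects the largest
number of genes from all regulation.

The pipeline:

1. **Differential expression** of miRNAs and mRNAs between
   platinum-sensitive and platinum-resistant samples, using an
   empirical-Bayes moderated t-statistic with Benjamini–Hochberg FDR
   control and a fold-change filter (FC > 1.5 or < 0.67, adjusted
   p < 0.05).
2. **Condition-specific subnetwork**: the edges of a reference
   miRNA→mRNA regulatory network whose both endpoints are
   differentially expressed.
3. **Topology**: degree, betweenness and closeness centrality; hubs
   and bottlenecks (top 10% with ties); a power-law fit of the degree
   distribution by ordinary least squares on log–log scale.
4. **NSR — number of single-line regulations.** For miRNA $m$ with
   target set $T(m)$ in the subnetwork,

   $$\mathrm{NSR}(m) \;=\; \bigl|\{\, g \in T(m) : \deg_{\text{in}}(g) = 1 \,\}\bigr|,$$

   the number of its targets regulated by *no other* miRNA. Its
   significance is assessed against a degree-preserving permutation
   null: random simple bipartite graphs with the same miRNA
   out-degrees and mRNA in-degrees, with the add-one-smoothed p-value
   $p = (1 + \#\{\mathrm{NSR}^{\text{null}} \ge \mathrm{NSR}^{\text{obs}}\})/(1 + n_{\text{perm}})$.
5. **Knowledge filter**: NPRG, the number of a miRNA's subnetwork
   targets on a user-supplied platinum-resistance gene list. Biomarkers
   are miRNAs with $p_{\mathrm{NSR}} < 0.01$ and $\mathrm{NPRG} \ge 1$.
6. **Evaluation**: ROC/AUC for sensitive-vs-resistant discrimination
   and Kaplan–Meier / log-rank survival comparison splitting patients
   at the upper quartile of biomarker expression; generic
   hypergeometric over-representation analysis of biomarker targets.

A first-class synthetic-data generator produces scale-free bipartite
networks with planted differential expression and planted biomarkers
carrying an excess of single-line targets, plus exponential survival
times with expression-dependent hazard — so every stage can be
validated against known ground truth.

## Worked example

Simulate a study (31 sensitive + 37 resistant samples, 60 miRNAs,
150 mRNAs, 4 planted biomarkers) and run the full pipeline:

```bash
printf 'seed: 7\nn_perm: 1000\n' > config.yaml
netvuln run --config config.yaml --out-dir results
```

Actual output:

```
... netvuln.pipeline INFO DE: 32 miRNAs, 90 mRNAs
... netvuln.pipeline INFO selected biomarkers: ['mir-015', 'mir-006', 'mir-019', 'mir-036']
selected biomarkers: mir-015, mir-006, mir-019, mir-036
report: results/report.json
```

The four selected miRNAs are exactly the four planted biomarkers
recorded in `results/inputs/truth.json`. The NSR table
(`results/nsr.tsv`, top rows):

```
mirna    degree  nsr  p_nsr                 nprg  selected
mir-015  17      11   0.000999000999000999  3     True
mir-006  18      10   0.002997002997002997  3     True
mir-019  17      10   0.000999000999000999  2     True
mir-036  10      10   0.000999000999000999  2     True
mir-003  6       1    0.6693306693306693    0     False
```

Evaluation (`results/evaluation.tsv`): AUCs 0.90–0.97 and log-rank
p-values down to 5.0e-10 (PFS) for the upper-quartile expression
split. The subnetwork has 246 edges over 32 miRNAs and 84 mRNAs, a
log–log degree-distribution fit with slope −1.18 (R² = 0.77), and the
over-representation analysis flags only the planted resistance gene
set as significant.

The same analysis is available stage-by-stage (`netvuln simulate`,
`de`, `network`, `nsr`, `evaluate`, `enrich`) and as a Python API
(`netvuln.run_all`, `netvuln.analyze`). Exit codes: 0 success, 2
input/format errors, 3 degenerate data.

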