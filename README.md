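# superdelta

Differential gene expression testing by robust pairwise differences, for
two-group comparisons on log2 expression matrices (bulk microarray or any
complete, summarized expression data).

## The problem

Expression measurements carry a per-sample technical component: the widely
used mixed-effects model writes the observed log2 expression of gene *i* in
sample *j* of group *a* as

    y_ij^a = mu_i^a + eps_ij^a + alpha_j^a,      alpha_j ~ N(0, eta²),  eps_ij ~ N(0, sigma²)

where `alpha_j` is shared by every gene of sample *j* and is typically much
larger than the residual noise (estimates from breast-cancer microarray
cohorts: eta = 0.873 vs sigma = 0.617). Classical between-array
normalizations (per-sample mean centring, median–IQR location-scale,
quantile mapping, cyclic loess) remove `alpha_j` by borrowing information
across **all** genes — including the differentially expressed ones. When
up- and down-regulation are unbalanced, that borrowing biases every gene by
roughly the mean true effect, inflating the type-I error and depressing
power.

## The method

`superdelta` normalizes each gene against individual baseline genes
instead. For a target gene *i* and baseline *i'*:

1. **delta step** — form per-sample differences
   `delta_ii',j = y_ij − y_i'j`, which cancel `alpha_j` exactly;
2. **test step** — compute the pooled two-sample t-statistic `t_ii'` on the
   delta series (N − 2 df);
3. **summary step** — condense the vector of pairwise statistics with the
   *median fold trim median* (MFTM): fold the vector about its median, drop
   the 20 % of entries deviating most from it (the likely pairings with
   truly DE baselines), and take

       t_i^MFTM = sqrt(2) × Med(t_i^trim).

   The sqrt(2) factor compensates the doubled variance of a difference of
   two i.i.d. errors, so `t_i^MFTM` approximates the *oracle* t-statistic
   one would compute on noise-free data. The baseline attaining the trimmed
   median is gene *i*'s **pairing gene** — its empirically chosen
   housekeeping reference.
4. p-values from the t distribution, Benjamini–Hochberg FDR control, and
   (optionally) a fold-change gate `|log2FC| > log2(1.25)`.

The package also ships the four classical normalizations, the oracle
baseline, a seeded simulator for the mixed-effects model, and a replicated
power / type-I benchmark harness.

## Worked example

Simulate a 2,000-gene, 25 + 25 sample dataset with 160 true DE genes, write
it to TSV, and run both pipelines:

```sh
sdelta test    --in expr.tsv --design design.tsv --summarizer mftm \
               --trim 0.2 --baselines 500 --seed 1 --out sd_result.tsv
# 141 genes at adjusted p < 0.05 -> sd_result.tsv
sdelta classic --in expr.tsv --design design.tsv --normalize quantile --out q_result.tsv
# 139 DEGs -> q_result.tsv
sdelta pairfreq --in sd_result.tsv --min-times 5 --out freq.tsv
# 54 genes paired more than 5 times -> freq.tsv
```

The result table carries, per gene, the representative statistic, the
pairing gene, the effect estimate in log2 units and raw/adjusted p-values:

```
gene_id  statistic  pairing_gene  effect_log2  p_raw     p_adj
g1       3.4193     g1401         0.5908       0.00129   0.0205
g2       2.5499     g1254         0.4229       0.01402   0.1669
g3       4.6296     g553          0.8183       2.81e-05  0.0007
```

Here 141 of the 160 true signals sit in a 2,000-gene background; the
quantile pipeline finds a similar count under this balanced design — the
methods separate under unbalanced DE structure (scenario SIM3 below). The
same operations are available as library calls (`superdelta_test`,
`classic_pipeline`, `run_benchmark`, ...).

In Python, the benchmark behind the numbers below is three lines:

```python
from dataclasses import replace
import superdelta as sd

sc  = sd.sim3_scenario(seed=1)                       # 5,000 genes, 637 down-regulated
cal = sd.calibrate_effect_scale(sc, 89.18)           # oracle hits 89.18 % power
tab = sd.run_benchmark({"sim3": replace(sc, effect_scale=cal.effect_scale)},
                       replicates=20, seed=1)
```

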