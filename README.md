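# gwasint

Integrating GWAS summary statistics with variant functional-annotation
meta-scores — and measuring honestly whether that helps.

Functional meta-scores such as CADD or Eigen summarise dozens of genomic
features into one deleteriousness number per variant.  A natural hope is
that prioritizing GWAS variants by such scores increases discovery power.
`gwasint` implements the four standard ways of folding a per-SNP score
into a GWAS — inverse-variance **meta-analysis** of z-statistics,
**Fisher's method** on p-values, the **weighted p-value** approach
(p_i/w_i with non-negative, mean-one weights built from the scores
alone), and **stratified FDR control** (sFDR: per-stratum q-values at a
common FDR level, with the implied group weights) — together with the
machinery needed to evaluate them: greedy LD clumping into independent
loci, family-wise error rate under the complete null, locus-level
Recall/Precision against a baseline GWAS, power under Bonferroni /
top-k / FDR rejection rules, and rank-based relative efficiency
RE = 1 − R̄_method/R̄_baseline over the truly associated SNPs.

The headline findings the package reproduces at desk scale: all four
methods control the family-wise error under the null; meta-analysis and
Fisher's method are badly non-robust when the scores are partially
informative, uninformative or misleading; the weighting approaches —
sFDR above all — leave the baseline GWAS findings essentially untouched
when the scores carry no signal.

It is a library first (NumPy/SciPy/pandas), with a thin `gwasint` CLI
(`integrate`, `clump`, `evaluate`, `simulate design1|design2|design3`)
for shell use.  Everything is driven by synthetic data generated with
documented statistical structure; see `docs/methods.md` for the models,
parameter meanings and limitations.

## Worked example

Simulate a heritable trait on an LD-block genome, clump it into loci,
then integrate a *permuted* (hence uninformative) phred-score track with
stratified FDR and ask what survived:

```python
import numpy as np
from gwasint import (
    simulate_ld_blocks, simulate_heritable_gwas, simulate_scores,
    permute_scores, sfdr_adjust, greedy_clump, count_significant_loci, eval_loci,
)

skeleton, ld = simulate_ld_blocks(n_blocks=400, block_size=(5, 10), within_r2=0.8, seed=7)
gwas = simulate_heritable_gwas(skeleton, n_causal_blocks=40, ncp=8.0, seed=8)
baseline = greedy_clump(gwas, ld)
print("baseline significant loci:", count_significant_loci(baseline, alpha=5e-8))

scores = permute_scores(simulate_scores(len(gwas), seed=9), seed=10)
p_sfdr, fit = sfdr_adjust(gwas["p"].to_numpy(), scores["phred"].to_numpy(),
                          k=2, top_fraction=0.05, gamma=0.05)
print("group weights:", np.round(fit.w_k, 3))
post = greedy_clump(gwas.assign(p=p_sfdr), ld)
report = eval_loci(baseline, post, alpha=5e-8)
print(f"after sFDR: P={report.P} TP={report.TP} recall={report.recall:.3f} "
      f"new discoveries={report.new_discoveries}")
```

Output:

```
baseline significant loci: 40
group weights: [0.889 1.006]
after sFDR: P=40 TP=40 recall=1.000 new discoveries=0
```

All 40 causal blocks reach genome-wide significance at baseline.  The
permuted scores are noise, so the two sFDR strata (top 5 % of scores vs
the rest) both contain real signals; the derived group weights sit near
1 and every baseline locus is retained with no spurious new ones —
exactly the robustness property that distinguishes sFDR from
meta-analysis or Fisher's method, which reshuffle the ranking whenever
the scores disagree with the GWAS.

The same operations are available from the shell:

```bash
gwasint simulate design1 --m 20000 --replicates 1000 --seed 1 --out fwer.tsv
gwasint integrate --sumstats sumstats.tsv --annotations cadd.tsv --method sfdr --out out.tsv
gwasint clump --sumstats out.tsv --ld ld.tsv --out loci.tsv
```

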