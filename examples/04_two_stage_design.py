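"""Selective genotyping and the two-stage merge.

Stage 1 genotypes the 200 phenotypic extremes at every marker; stage 2 adds
targeted-assay calls at the top markers for the remaining 197 animals. The
merged scan therefore uses n=397 at targeted markers and n=200 elsewhere -
the sample-size discontinuity visible as sudden jumps in real LOD curves -
and the full-sample effect estimate shrinks the extreme-sampling bias.
"""

from ailqtl import (QtlSpec, SimConfig, choose_targeted_markers,
                    effect_summary, merge_two_stage, scan_timeseries,
                    select_extremes, simulate_dataset, top_snp)

cfg = SimConfig(seed=9, n_animals=397, pop_size=100, selective_n=200,
                chromosomes=[("chr1", 100_000_000, 100),
                             ("chr2", 100_000_000, 100)],
                qtls=[QtlSpec("chr1", 50_000_000, additive_effect_g=2.7)])
geno, pheno, truth = simulate_dataset(cfg)

extremes = select_extremes(pheno, n=200)
array_geno = geno.subset_animals(extremes)
targeted_ids = choose_targeted_markers(array_geno, pheno, n_markers=2)
rest = [a for a in geno.animal_ids if a not in set(extremes)]
merged = merge_two_stage(array_geno,
                         geno.subset_markers(targeted_ids).subset_animals(rest))

results = scan_timeseries(merged, pheno)
marker, week, lod = top_snp(results)
t = results[-1].table
print(f"targeted markers: {targeted_ids}")
print("n_used at targeted markers:",
      sorted(set(t.loc[t['marker_id'].isin(targeted_ids), 'n_used'])))
print("n_used elsewhere:",
      sorted(set(t.loc[~t['marker_id'].isin(targeted_ids), 'n_used'])))

g_true = truth.qtl_genotypes[0]
w = pheno.week_values(25)
sel = [a in set(extremes) for a in pheno.animal_ids]
import numpy as np
sel = np.array(sel)
biased = w[sel & (g_true == 2)].mean() - w[sel & (g_true == 0)].mean()
full = w[g_true == 2].mean() - w[g_true == 0].mean()
print(f"\nhomozygote contrast at the true QTL, week 25:")
print(f"  extremes only (n=200): {biased:.2f} g   all animals (n=397): "
      f"{full:.2f} g   (simulated truth: 5.40 g)")
print("The extreme-sampled estimate is inflated; genotyping everyone at the "
      "top markers restores an unbiased effect size.")
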