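"""Screening statistics on a simulated modern corpus.

Draws a cohort with the published per-species biomarker means/SDs
(17 red deer, 22 reindeer), then runs the screening stage: normality check,
Wilcoxon comparisons and PCA.
"""

from cervidct import (
    compare_species,
    load_moments,
    normality_screen,
    pca,
    simulate_cohort,
    summarize_moments,
)

moments = load_moments("modern")
cohort = simulate_cohort(moments, seed=42)
print(f"simulated cohort: {dict(cohort.df.species.value_counts())}")

print("\nWilcoxon rank-sum, red deer vs reindeer:")
for comp in compare_species(cohort):
    flag = "*" if comp.p_value < 0.05 else " "
    print(f"  {comp.biomarker:6s}  red deer {comp.mean_a:7.2f} +- {comp.sd_a:5.2f}   "
          f"reindeer {comp.mean_b:7.2f} +- {comp.sd_b:5.2f}   p = {comp.p_value:.4f} {flag}")

screen = normality_screen(cohort)
failed = screen[~screen.normal]
print(f"\nShapiro-Wilk failures at alpha=0.05: "
      f"{[f'{r.species}/{r.biomarker}' for r in failed.itertuples()] or 'none'}")

res = pca(cohort)
print("\nPCA explained variance: "
      + ", ".join(f"PC{i+1} {v:.1%}" for i, v in
                  enumerate(res.explained_variance_ratio[:3])))

rec = summarize_moments(cohort)
print(f"recovered reindeer Tb.N = {rec.means.loc['reindeer', 'tb_n']:.2f} "
      f"(generator mean 3.51)")
print("\nThe mesh-density biomarkers (Tb.N, Tb.Sp, Tb.Th, Tb.Pf) separate the "
      "species; BV/TV and SMI overlap, matching their isolated p-values.")
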