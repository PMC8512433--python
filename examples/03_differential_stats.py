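"""Feature table -> significant features -> multivariate models.

Processes a compact planted study end to end through alignment and the
statistical screen, then prints the ANOVA/FDR discovery count, PCA variance
and PLS-DA quality metrics with a permutation p-value.
"""

import numpy as np

from vinomix import diffstats, synthio
from vinomix import features as ft
from vinomix.identify import AlkaneLadder
from vinomix.pipeline import _is_feature

recipe = synthio.default_study_recipe(seed=1)
runs, truth = synthio.simulate_study(recipe)

peaks = []
for run in runs:
    peaks.extend(ft.detect_peaks(run))
warps, corrected, _ = ft.correct_rt(peaks, n_runs=len(runs))
feats = ft.group_peaks(corrected, recipe.design)
feats = ft.fill_missing(feats, runs, warps)
feats = ft.average_technical_replicates(feats, recipe.design)
table = ft.features_to_dataframe(feats)
print(f"{len(feats)} aligned features x {table.shape[1]} biological samples")

bio = {m.sample_id: m for m in recipe.design}
is_feat = _is_feature(feats, AlkaneLadder.from_mapping(recipe.ladder), "2-Octanol")
matrix = diffstats.preprocess(diffstats.FeatureMatrix(table.T, bio, "raw"), is_feat.feature_id)

res = diffstats.anova_per_feature(matrix, "rootstock")
sig = res[res["q"] <= 0.05]
print(f"rootstock screen: {len(sig)} features significant at BH q <= 0.05")

model_matrix = matrix.restrict(list(sig["feature_id"]))
pca = diffstats.pca_fit(model_matrix, k=5)
print(f"PCA of significant features: PC1 {100 * pca.var_fraction[0]:.1f} %, "
      f"PC2 {100 * pca.var_fraction[1]:.1f} % of variance")

pls = diffstats.plsda_fit(model_matrix, "rootstock")
perm_p, _, _ = diffstats.permutation_test(model_matrix, "rootstock", B=200, rng=0)
print(f"PLS-DA (2 components): R2Y {pls.R2Y:.2f}, LOOCV Q2 {pls.Q2:.2f}, "
      f"permutation p {perm_p:.3f} (B=200)")
print(f"features with VIP > 1: {int((pls.vip > 1).sum())}")
print("-> a Q2 well above the permutation null confirms that rootstock, not chance,")
print("   drives the separation of the planted volatile shifts.")
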