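"""PCA overview and pairwise OPLS-DA with VIP on the metabolite table.

The discriminant model separates class-predictive from class-orthogonal
variation; R2Y measures fit, Q2 (leave-one-out) predictive ability, and
VIP > 1 flags features carrying more than an average share of the
between-class variance.
"""

import flavoromics as fm
from flavoromics.chemometrics import fit_oplsda, fit_pca, log_intensities
from flavoromics.preprocess import preprocess_table

study = fm.generate_study(fm.SynthConfig(seed=1))
mets, _ = preprocess_table(study.metabolites)

X = log_intensities(mets)
pca = fit_pca(X, k=2)
pc1, pc2 = pca.explained_variance_fraction * 100
print(f"PCA: PC1 explains {pc1:.2f}%, PC2 {pc2:.2f}% of total variance")

sub = mets.subset_groups(("GL", "XZ"))
model = fit_oplsda(
    log_intensities(sub), list(sub.group_labels), n_ortho=1, cv="loo"
)
print(f"OPLS-DA GL vs XZ: R2Y = {model.r2y:.3f}, Q2 = {model.q2:.3f}")
print("top five features by VIP (planted markers should dominate):")
print(model.vip.sort_values(ascending=False).head(5).round(2).to_string())
truth = set(study.truth.planted["metabolite"])
top = set(model.vip.sort_values(ascending=False).head(5).index)
print(f"of those, planted in truth: {len(top & truth)}/5")
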