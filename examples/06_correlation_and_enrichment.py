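"""Link the two platforms: Spearman VOC x metabolite correlation and
hypergeometric pathway over-representation of the differential metabolites.

Correlations use mid-ranks with the t-approximation p; asterisk-level
significance is raw p < 0.05 (BH-adjusted values reported alongside).
Enrichment is the upper-tail hypergeometric test against a declared
universe of detected metabolites.
"""

from itertools import combinations

import flavoromics as fm
from flavoromics.assoc import ora_hypergeometric, spearman_matrix
from flavoromics.chemometrics import log_intensities
from flavoromics.diffscreen import differential_analysis
from flavoromics.preprocess import preprocess_table

study = fm.generate_study(fm.SynthConfig(seed=1))
mets, _ = preprocess_table(study.metabolites)
vocs, _ = preprocess_table(
    study.vocs, peaks=study.voc_peaks, annotations=study.annotations
)

sel_m, sel_v = set(), set()
for pair in combinations(mets.groups, 2):
    sel_m |= set(differential_analysis(mets, pair).selected_features)
    sel_v |= set(differential_analysis(vocs, pair).selected_features)

corr = spearman_matrix(
    log_intensities(mets)[sorted(sel_m)], log_intensities(vocs)[sorted(sel_v)]
)
n_pairs = corr.rho.size
n_sig = int(corr.significant.to_numpy().sum())
print(f"correlation matrix: {corr.rho.shape[0]} metabolites x "
      f"{corr.rho.shape[1]} VOCs = {n_pairs} pairs, {n_sig} with p < 0.05")
strongest = corr.to_long().sort_values("rho", key=abs, ascending=False).iloc[0]
print(f"strongest association: {strongest.metabolite} ~ {strongest.voc} "
      f"(rho = {strongest.rho:.2f}, p = {strongest.p:.3f})")

universe = set(mets.feature_ids)
enr = ora_hypergeometric(sel_m & universe, study.pathways, universe)
print("\ntop pathways by over-representation:")
print(enr.head(3)[["hits", "pathway_size", "p", "p_adjusted"]].to_string())
print(f"truth: enriched pathways planted by the generator = "
      f"{sorted(study.truth.enriched_pathways)}")
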