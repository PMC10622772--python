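"""Cluster accepted biomarkers into metabolic phenotypes.

Biomarkers that identify overlapping participant sets cluster together
(Jaccard distance on positive sets, complete linkage, silhouette-selected
k); clusters are characterized by metabolite fold changes and grouped by
fold-change similarity; each identified participant gets a primary cluster.
"""

import metabophen as mp

cohort = mp.generate_cohort(mp.CohortConfig(seed=1))
records, quant, _ = mp.preprocess_cohort(cohort.records, cohort.quant, cohort.assay)
defs = mp.enumerate_features(quant.metabolites, mp.defaults.LOW_QUANT_METABOLITES)
fm = mp.compute_features(quant, defs)
labels = records["diagnosis"].to_numpy()
result = mp.screen_all(fm, labels, mp.make_strata(records),
                       mp.ScreenParams(repeats=10, n_perm=199, seed=1))
profile = mp.build_profiles(result.definitions, fm)

D = mp.jaccard_distance_matrix(profile)
model = mp.cluster_biomarkers(D)
print(f"{profile.matrix.shape[1]} accepted biomarkers -> k* = {model.k} clusters "
      f"(silhouette-selected)")

summaries = mp.cluster_summaries(model, profile, labels)
fct = mp.fold_changes(model, quant, labels, profile)
names = mp.cluster.name_clusters(model, fct)
summaries["name"] = [names[c] for c in summaries.index]
print("\nper-cluster subpopulation size and purity:")
print(summaries[["name", "n_biomarkers", "pct_asd", "pmp_asd"]].to_string())

groups = mp.group_clusters(fct, n_groups=min(7, model.k))
print("\ncluster groups (by fold-change similarity):", dict(groups))

primary = mp.assign_primary_cluster(profile, model, labels)
print(f"\nidentified participants: {len(primary)}; "
      f"median clusters per identified participant: "
      f"{primary.cluster_count.median():.0f} (range "
      f"{primary.cluster_count.min()}-{primary.cluster_count.max()})")
# pct_asd is the fraction of all cases a cluster identifies; pmp_asd is the
# case fraction among everyone the cluster flags. Auto-generated names show
# the direction of the strongest metabolite fold changes.
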