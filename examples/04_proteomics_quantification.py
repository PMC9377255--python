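"""Quantify GUS proteins from activity-based-probe peptide intensities.

Peptides are mapped onto the catalog by exact substring match (I/L
indistinguishable); only peptides unique to one redundancy cluster
quantify.  Protein intensity is the sum of unique-peptide peak areas,
log2 after summing; class-level intensities feed Welch's t-test between
MMF recipients and healthy donors.
"""
from gusome import discover, generate_cohort
from gusome.proteomics import (
    class_protein_abundance,
    group_tests,
    map_peptides,
    protein_intensity,
    sequence_coverage,
)
from gusome.simulate import make_representatives

reps = make_representatives(core_length=240, fmn_tail=120)
cohort = generate_cohort(seed=1, representatives=reps)
_, clusters = discover(cohort.catalog, reps)

matches = map_peptides(cohort.peptides, cohort.catalog, clusters)
n_unique = sum(m.unique for m in matches)
print(f"{len(matches)} peptide observations, {n_unique} cluster-unique")

rows = protein_intensity(matches, clusters)
print(f"{rows['cluster_id'].nunique()} clusters quantified across "
      f"{rows['sample_id'].nunique()} samples")

by_id = {r.id: r for r in cohort.catalog}
cl = clusters[0]
peps = {m.peptide for m in matches
        if m.unique and m.matched_clusters == (cl.cluster_id,)
        and cl.representative_id in m.matched_proteins}
cov = sequence_coverage(by_id[cl.representative_id], peps)
print(f"coverage of {cl.cluster_id} representative: {100 * cov:.1f}%")

cls_int = class_protein_abundance(rows)
print("\nlog2 class intensities (NaN = undetected):")
print(cls_int.round(2))
tests = group_tests(cls_int, {s.sample_id: s.group for s in cohort.samples})
print("\nWelch's t-test, MMF vs healthy, per class:")
print(tests[["gus_class", "t", "df", "p"]].round(4))
# The planted +2 log2 FMN shift in MMF recipients (and the -2 shift for
# No-Loop enzymes) should surface as the smallest Welch p-values.
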