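"""Marker QC funnel: platform intersection, random imputation, MAF filter.

Mimics merging a high-density training-population array with a
lower-density array used for selection candidates: only overlapping
markers are kept, missing calls are imputed from allele frequencies,
then monomorphic and rare markers are removed.
"""

import numpy as np

from rcgs.genotypes import filter_markers, impute_random, intersect_platforms
from rcgs.simpop import TrainingPopConfig, make_training_population

mm, *_ = make_training_population(
    TrainingPopConfig(n_markers=600, n_chromosomes=7, family_sizes=(40, 40, 40),
                      family_h2_targets=(0.5, 0.5, 0.5)),
    seed=3,
)

# pretend the second platform covers a subset of markers
rng = np.random.default_rng(0)
low_density = mm.subset_markers(np.sort(rng.choice(mm.marker_ids, 450, replace=False)))
mm_a, mm_b = intersect_platforms(mm, low_density)
print(f"platform overlap: {mm_a.n_markers} of {mm.n_markers} markers")

# knock out 5% of calls, then impute from Hardy-Weinberg proportions
dosages = mm_a.dosages.copy()
dosages[rng.random(dosages.shape) < 0.05] = np.nan
mm_missing = type(mm_a)(mm_a.individual_ids, mm_a.marker_ids, dosages)
print(f"missing calls introduced: {mm_missing.n_missing}")
mm_imputed = impute_random(mm_missing, seed=1)
print(f"missing after imputation: {mm_imputed.n_missing}")

mm_qc, report = filter_markers(mm_imputed, maf_threshold=0.05)
print(f"\nQC report: {report.to_dict()}")
print(f"{report.n_retained} markers survive; removed markers are either fixed "
      f"in this material or below 5% minor-allele frequency, where genomic "
      f"relationships are poorly estimated.")
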