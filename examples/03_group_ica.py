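"""Group spatial ICA at desk scale: PCA chain, ICASSO stability, spectra.

Recovers planted spatial sources from a small cohort, reports each
component's ICASSO stability index I_q, and screens a time course's
spectrum with the low-frequency power-ratio criterion.
"""

import numpy as np

from dynconn import SyntheticConfig, generate_cohort
from dynconn.gica import (
    back_reconstruct,
    group_pca_concat,
    icasso_stability,
    match_components,
    spectral_icn_metrics,
    subject_pca,
)

cohort = generate_cohort(
    SyntheticConfig(n_subjects_per_group=4, n_sources=6, n_voxels=300,
                    n_timepoints=150, seed=11)
)

spcas = [subject_pca(s, 20) for s in cohort.subjects]
gpca = group_pca_concat(spcas, 10, seed=0)
result = icasso_stability(gpca, 8, n_runs=6, seed=0)  # 6 planted + 2 surplus
back_reconstruct(result, gpca, spcas, cohort.subjects)

perm, cors = match_components(result.group_maps, cohort.truth.source_maps)
print("matched |spatial correlation| per planted source:", cors.round(3))
print("stability I_q per component:", result.stability_iq.round(3))
print("components retained (I_q > 0.8):", int(result.retained.sum()), "of 8")
print("(the planted sources cluster tightly across ICA restarts; the two "
      "surplus components absorb noise and score lower)")

tc = result.subject_timecourses[cohort.subjects[0].subject_id][:, 0]
m = spectral_icn_metrics(tc, cohort.config.tr_seconds)
print(f"\nfirst component spectrum: power(<0.10 Hz)/power(0.15-0.25 Hz) = "
      f"{m.power_ratio:.2f}; classified as ICN: {m.is_icn}")
print("(the generator's state-driven sources are spectrally flat, so the "
      "low-frequency dominance criterion correctly rejects them; real ICN "
      "time courses concentrate power below 0.10 Hz and score far higher)")
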