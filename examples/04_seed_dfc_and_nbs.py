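"""Seed-based dynamic functional connectivity and the network-based statistic.

Seeds are the ROIs showing local mdALFF group differences; per sliding
window the seed-to-target Pearson correlation is Fisher-Z transformed and
summarised as dFC_mean / dFC_var.  The NBS permutation test then controls
family-wise error over connected components of suprathreshold edges in the
group contrast.  Here three couplings from the FPN seed are weakened in the
SCD group (strong demonstration effects: windowed correlation estimates are
noisy, so edge-level effects attenuate substantially on the dFC_mean scale).
"""

import numpy as np
import pandas as pd

from dynconn import (SimulationSpec, WindowSpec, compute_dfc_cohort,
                     condition_series, filter_defined_networks,
                     simulate_cohort)
from dynconn.cohort import CohortDataset
from dynconn.simulate import DfcEffect
from dynconn.stats import nbs_test

spec = SimulationSpec(
    seed=5, correlation_targets=(),
    dfc_effects=(DfcEffect(194, 15, "mean", -3.0),
                 DfcEffect(194, 23, "mean", -3.0),
                 DfcEffect(194, 130, "mean", -3.0)))
cohort = simulate_cohort(spec, rng=5, update_scores=False)
atlas = filter_defined_networks(cohort.atlas)
conditioned = CohortDataset(
    atlas=atlas, phenotypes=cohort.phenotypes,
    series={sid: condition_series(s) for sid, s in cohort.series.items()})

seeds = [194]   # the FPN ROI the couplings emanate from
dfc = compute_dfc_cohort(conditioned, seeds, spec=WindowSpec(50, 10))
print(f"dFC rows: {len(dfc)} ({len(seeds)} seed x 272 targets x "
      f"{cohort.n_subjects} subjects)")

wide = dfc.pivot_table(index="subject_id", columns=["seed_roi", "target_roi"],
                       values="dfc_mean").loc[cohort.phenotypes["subject_id"]]
edges = [(int(a), int(b)) for a, b in wide.columns]
res = nbs_test(wide.to_numpy(), edges, cohort.phenotypes,
               n_perm=500, primary_p=0.01, rng=5)
print(f"suprathreshold |t| >= {res.primary_threshold:.2f}; "
      f"components found: {len(res.components)}")
for comp, size, p in zip(res.components, res.component_sizes, res.p_fwe):
    marks = [f"{u}-{v}" for u, v in comp]
    print(f"  component of {size} edge(s), p_fwe = {p:.3f}: {', '.join(marks)}")
# p_fwe refers each observed component's edge count to the maximal component
# size under 500 group-label permutations (covariates stay attached to their
# subjects).  With a single seed every suprathreshold edge shares the seed
# ROI, so they merge into one star-shaped component; the injected targets
# (15, 23, 130) appear inside it.
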