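"""Optional real-data demo: the GBSG2 breast-cancer cohort.

Loads the German Breast Cancer Study Group 2 data (686 patients, 299
recurrence-free-survival events; shipped with scikit-survival), fits a
Cox model, and prints the time-averaged permutation importance of each
prognostic factor under the IPCW Brier score, plus the ALE direction for
tumour size.  Real data: expect messier numbers than the simulations.
"""

import numpy as np
import pandas as pd
from sksurv.datasets import load_gbsg2

from survexplain import (CoxModel, SurvivalDataset, TimeGrid, ale,
                         brier_loss, pfi, train_test_split)

Xraw, y = load_gbsg2()
X = Xraw.copy()
for col in X.select_dtypes("category").columns:
    X[col] = X[col].astype(str)
cohort = SurvivalDataset(X, y["time"] / 365.25, y["cens"].astype(int))
print(f"{cohort.n} patients, {cohort.events.sum()} events")

train, test = train_test_split(cohort, 0.3, seed=1)
model = CoxModel().fit(train)
grid = TimeGrid.from_dataset(test, max_points=25)

print("\ntime-averaged PFI (Brier-score increase after permutation):")
for r in pfi(model, test, brier_loss(train), n_repeats=5, seed=2,
             time_grid=grid):
    print(f"  {r.feature:10s} {r.time_average:+.4f}")

eff = ale(model, test, "tsize", n_intervals=15, time_grid=grid)
mid = eff.values[:, len(grid) // 2]
print(f"\nALE(tsize) end-to-end change at the median time: "
      f"{mid[-1] - mid[0]:+.3f} "
      "(larger tumours lower predicted recurrence-free survival)")
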