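"""Reconstruct a small usage panel and derive trends and prefactors.

Shows the panel-side chain on hand-made data: missing-bound fill from the
mean high/low ratio, reference-year interpolation, national summaries,
top-k selection with the mass-coverage factor F_M, and the mapping
prefactors F(t) that scale reference-year maps forward.
"""

import numpy as np
import pandas as pd

from pestmap import (
    compute_prefactors,
    fill_missing_bounds,
    fit_linear_trend,
    interpolate_reference_year,
    rank_and_select,
    summarize_states,
)

rows = []
for year in range(2006, 2017):
    mass = 100.0 + 5.0 * (year - 2015)  # rising use, 105 kg in 2016
    rows.append(("glyphosate", "Corn", 0, year, mass * 1.2, mass * 0.8))
    rows.append(("atrazine", "Corn", 0, year, 40.0 * 1.1, np.nan))  # low bound missing
rows.append(("atrazine", "Corn", 1, 2010, 44.0, 36.0))  # the one complete pair
panel = pd.DataFrame(rows, columns=["ai", "crop", "state", "year", "mass_high", "mass_low"])

log = []
panel = fill_missing_bounds(panel, log=log)
panel = interpolate_reference_year(panel, ref_year=2015)
print(log[0])  # how many single-bound cells were completed

series = summarize_states(panel, years=(2006, 2016))
selection = rank_and_select(series, k=1, ref_year=2015, max_missing_total=10,
                            max_missing_recent=10)
print(f"selected: {selection.selected_pairs()}, F_M = {selection.f_m:.3f}")
# F_M is the mass share of the selected ingredient in 2015; the rest of the
# national mass is reinstated later by the inventory-conditioning factor.

nat = series.national.query("ai == 'glyphosate'")
fit = fit_linear_trend(nat["year"].to_numpy(), nat["median_mass"].to_numpy(),
                       ai="glyphosate", crop="Corn")
pf = compute_prefactors(fit, m_s_ref=100.0)
print(f"trend slope: {fit.slope:.2f} kg/yr per year (R2 = {fit.r2:.3f})")
print("prefactors:", {y: round(f, 3) for y, f in pf.items() if y in (2015, 2020, 2025)})
# F(2025) = 1.5 means the 2015 map is scaled up 50% for the 2025 projection.
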