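"""Generate a synthetic world and inspect its pieces.

The world is the test bed for the whole estimation chain: a lat/lon grid
split into countries (country 0 holds the state-level usage panel),
autocorrelated covariate fields, true application-rate surfaces linear in
a few covariates, and a usage panel integrated from that truth.
"""

import numpy as np

from pestmap import WorldConfig, generate_world

config = WorldConfig(seed=42)
bundle = generate_world(config)

print(f"grid: {bundle.grid_spec.shape}, countries: {config.n_countries}, "
      f"states in reference country: {config.n_states}")
print(f"ingredients: {config.ais}")
print(f"crops: {config.crops}")
print(f"panel rows: {len(bundle.usage_panel)} "
      f"(missing: {bundle.usage_panel['mass_high'].isna().mean():.1%})")

ai, crop = config.ais[0], config.crops[0]
apr = bundle.true_apr[(ai, crop)]
print(f"\ntrue APR of {ai} on {crop}: "
      f"min {apr.min():.3f}, mean {apr.mean():.3f}, max {apr.max():.3f} kg/ha/yr")
used = bundle.true_coefficients.query("ai == @ai and crop == @crop")
print(f"generated from covariates: {[str(c) for c in used['covariate']]}")

total = sum(bundle.faostat_totals.values())
print(f"\ncountry inventory totals sum to {total:,.0f} tonnes/yr "
      f"(perturbed by {config.faostat_perturb_frac:.0%} relative noise)")
# The totals are what the conditioning stage later rescales the maps toward.
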