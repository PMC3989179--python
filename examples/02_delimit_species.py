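"""Delimit species by a barcode-gap prior sweep and the stability rule.

Simulates five species, sweeps the gap partitioning over 20 geometric priors
from 0.001 to 0.2, and selects the smallest group count stable over three or
more successive priors — the primary species hypothesis (PSH).
"""

from gapdelim import (
    SimConfig,
    collapse_haplotypes,
    distance_matrix,
    prior_sweep,
    select_psh,
    simulate_dataset,
    sweep_table,
)

ds = simulate_dataset(SimConfig(sample_sizes=(6, 6, 6, 6, 6)), seed=7)
dm = distance_matrix(collapse_haplotypes(ds.alignment))
sweep = prior_sweep(dm)
print(sweep_table(sweep).round(4).to_string(index=False))

sel = select_psh(sweep)
print(
    f"\nchosen count: {sel.chosen_count} putative species "
    f"(true K = {ds.config.n_species})"
)
print(
    f"stable for priors {sel.stable_prior_min:.4f}..{sel.stable_prior_max:.4f} "
    "- the plateau persists past the intraspecific scale (0.01) and collapses "
    "well before the interspecific scale (0.15), as a genuine barcode gap should."
)
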