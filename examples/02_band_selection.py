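"""Exhaustive two-band index screening of hyperspectral spectra.

Simulates 39 ground samples with 163-band spectra carrying two
informative band pairs (visible-NIR negative, SWIR positive), runs
the 13,203-combination search for each pair index, and prints the
strongest positive and negative combinations.
"""

import numpy as np

import wheatyield as wy

cfg = wy.SceneConfig(seed=3)
y = np.random.default_rng(3).uniform(cfg.yield_min, cfg.yield_max, 39)
table = wy.simulate_hyperspectral_samples(y, cfg)

surface = wy.pairwise_correlation_surface(table, "NDSI")
print(f"{table.n_bands} bands -> {surface.n_unordered_pairs} unordered pairs")

for index_type, ext in wy.select_all_index_types(table).items():
    for label, pair in (("+", ext.positive), ("-", ext.negative)):
        if pair is not None:
            print(f"{index_type} strongest {label}: "
                  f"{pair.i_nm:.0f}-{pair.j_nm:.0f} nm, r = {pair.r:+.3f} "
                  f"(p = {pair.p:.1e})")
print("visible-NIR combinations correlate negatively with yield and SWIR")
print("combinations positively, matching the planted signal structure.")
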