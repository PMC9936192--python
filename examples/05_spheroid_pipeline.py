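"""Distance-layer time series: separate the two gel densification mechanisms.

A synthetic invasion series imposes a fibre-density ramp next to the cells
(band 1) and a slow aggregate-density ramp far from them (band 3).  The
pipeline decomposes each image into distance layers, measures per-layer
histograms and correlation functions, and fits all conditions jointly with
the imaging parameters shared across the series.
"""

import warnings

import numpy as np

import gelstruct as gs

t = np.linspace(0, 1, 4)
cfg = gs.SpheroidSeriesConfig(
    domain=gs.Domain(width=384, height=384, pixel_size=0.59),
    times_min=tuple(720.0 * x for x in t),
    band_edges_um=(0.0, 40.0, 80.0),
    phi_A=tuple((0.8, 0.6 + 0.2 * x) for x in t),   # band 2 ramps phi_A
    phi_F=tuple((0.5 + 0.3 * x, 0.5) for x in t),   # band 1 ramps phi_F
    L_A=8.0,
    spheroid_radius_um=22.0,
    radius_growth_um_per_min=0.005,
    n_sprouts=4,
    sprout_speed_um_per_min=0.05,
    sprout_width_um=6.0,
)
series = gs.simulate_spheroid_series(cfg, 0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    surface = gs.analyze_timeseries(
        series.gel_images, series.cell_masks, 0.59,
        edges=cfg.band_edges_um,
        cfg=gs.FitConfig(n_starts=4, seed=0),
        shared=("b", "Delta", "sigma", "D_F", "L_A"),
        min_band_pixels=5000,
    )

print(surface.table[["time_index", "band", "phi_F", "phi_A", "phi_1", "p90"]].round(3).to_string(index=False))
print("\nshared imaging parameters:", {k: round(v, 2) for k, v in surface.shared.items()})
for band, ramped in ((1, "phi_F"), (2, "phi_A")):
    sub = surface.table[surface.table.band == band].sort_values("time_index")
    print(f"band {band}: {ramped} rises {sub[ramped].iloc[-1] - sub[ramped].iloc[0]:+.3f} "
          f"(imposed ramp lives in {ramped})")
print("\nThe 90th-percentile column (p90) rises only where phi_F rises: more")
print("fibre overlaps extend the grey-tone distribution to higher intensities.")
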