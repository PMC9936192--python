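"""Joint grey-tone fit: histogram + correlation function, seven parameters.

Simulates 8-bit grey-tone images at the spheroid imaging point (background
b=9, per-fibre increment Delta=15, noise sigma=5) and identifies structural
and imaging parameters directly from the unsegmented images.
"""

import numpy as np

import gelstruct as gs

domain = gs.Domain(width=600, height=600, pixel_size=0.59)
truth = gs.GreyToneParams(
    fibre=gs.FibreParams(eta=gs.eta_from_phi_F(0.5), D_F=2.0, L_F=40.0),
    aggregate=gs.AggregateParams(phi_A=0.6, L_A=19.0),
    b=9.0, Delta=15.0, sigma=5.0,
)

curves, hists = [], []
for child in np.random.SeedSequence(0).spawn(6):
    img = gs.simulate_greytone(domain, truth, child, quantize=True)
    hists.append(gs.greytone_histogram(img))
    curves.append(gs.radial_profile(gs.autocorrelation_2d(img.astype(float)), domain.pixel_size))

result = gs.fit_greytone(
    gs.aggregate_replicates(curves), gs.pool_histograms(hists), gs.FitConfig(n_starts=8, seed=0)
)

values = {"eta": truth.fibre.eta, "D_F": 2.0, "phi_A": 0.6, "L_A": 19.0,
          "b": 9.0, "Delta": 15.0, "sigma": 5.0}
print("parameter   truth    fitted")
for name, tv in values.items():
    print(f"  {name:6s}   {tv:6.3f}   {result.params[name]:6.3f}")
print(f"\nnoise from the curve's r=0 jump: {result.diagnostics['sigma_from_c0']:.3f} grey levels")
print("The histogram pins the imaging parameters (b, Delta, sigma) and the")
print("overlap statistics; the correlation function pins the sizes D_F and L_A.")
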