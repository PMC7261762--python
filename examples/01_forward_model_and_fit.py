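"""Forward-simulate one white-matter voxel and recover its composition.

Builds a voxel containing one axonal fiber bundle (70% of the signal,
axial/radial diffusivity 1.7/0.3 um^2/ms) plus 10% cellular (restricted)
water and 20% CSF-like free water, synthesizes its signal under the default
99-direction scheme, and fits the spectrum model back. The printed fractions
match the generating ones to within a few hundredths — the spectral
resolution of a 5-shell protocol — which is what makes the fitted metrics
usable as classifier features.
"""

import numpy as np

import dbsidnn as dd

scheme = dd.make_default_scheme()          # 99 directions + 1 b0, b_max 1500
grid = dd.default_grid()                   # diffusivity spectrum 0..4 um^2/ms

spectrum = np.zeros(grid.n)
for d_value, fraction in [(0.2, 0.10), (3.2, 0.20)]:
    j = int(np.argmin(np.abs(grid.d_values - d_value)))
    spectrum[j] += fraction / grid.weights[j]

truth = dd.DbsiModelParams(
    orientations=np.array([[0.0, 0.0, 1.0]]),
    lambda_par=[1.7],
    lambda_perp=[0.3],
    fractions=[0.70],
    iso_spectrum=spectrum,
    grid=grid,
)
signal = dd.dbsi_forward(truth, scheme)

params, metrics = dd.fit_dbsi_voxel(signal, scheme)
print(f"fiber fraction      {metrics.fiber_fraction:.3f}   (truth 0.700)")
print(f"restricted fraction {metrics.restricted_fraction:.3f}   (truth 0.100)")
print(f"hindered fraction   {metrics.hindered_fraction:.3f}   (truth 0.000)")
print(f"water fraction      {metrics.water_fraction:.3f}   (truth 0.200)")
print(f"fiber AD / RD       {metrics.fiber_ad:.3f} / {metrics.fiber_rd:.3f} um^2/ms "
      "(truth 1.700 / 0.300)")
print(f"fiber FA            {metrics.fiber_fa:.3f}")

dti = dd.fit_dti(signal, scheme)
print(f"\nsingle-tensor (DTI) FA on the same voxel: {dti.fa:.3f} — free water drags "
      "it below the fiber's intrinsic anisotropy, which is why the spectrum "
      "model separates lesion pathology better.")
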