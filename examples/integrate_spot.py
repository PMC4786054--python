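"""Summation-integrate a simulated spot with three error estimates.

Builds a MOSFLM-style measurement box, fits the background plane,
subtracts it from the peak sum and compares the classical
independent-Poisson error estimate with the cascade + pixel-noise
estimate.
"""

import numpy as np

from ptccd import (DetectorConfig, PhotonTable, RadialMap, Window,
                   build_measurement_box, derive_noise_budget, extract_box,
                   generate_flood_photons, generate_spot_photons,
                   simulate_image, summation_integrate, variance_cascade,
                   variance_poisson_mosflm)

cfg = DetectorConfig()
budget = derive_noise_budget(cfg.cascade_params())
rng = np.random.default_rng(7)
radial = RadialMap(cfg)

spot_center = (306.5 * 73.0, 306.5 * 73.0)
sc = radial.face_to_ccd(np.array([spot_center]))[0]
win = Window(int(sc[0] // 30) - 20, int(sc[1] // 30) - 20, 41, 41)

spot = generate_spot_photons(spot_center, 90.0, 1.0e4, rng)
flood = generate_flood_photons(20.0, 289, 289, 35, 35, rng)
img = simulate_image(PhotonTable.concat([spot, flood]), cfg, rng, window=win)

# the reference 23x23 corrected-pixel box, rescaled to the 30 um raw grid
box = build_measurement_box((0, 0), 23, 23, 5, 4, 11).scaled(
    (20, 20), 73.0 / (30.0 * cfg.taper.demag))
raster = extract_box(img.data.astype(float), box)
res = summation_integrate(raster, box, pedestal=cfg.bias_adu)
vp = variance_poisson_mosflm(res, budget.gain_absorbed)
vc = variance_cascade(res, budget)

print(f"box: {box.nx}x{box.ny} raw pixels, M={box.m_peak} peak, "
      f"N={box.n_bg} background")
print(f"I_S = {res.intensity:.0f} ADU "
      f"(expected ~{1e4 * budget.gain_incident:.0f})")
print(f"sigma(I_S), independent-Poisson model : {np.sqrt(vp):6.1f} ADU")
print(f"sigma(I_S), cascade + pixel noise     : {np.sqrt(vc):6.1f} ADU")
print("\nThe Poisson estimate ignores the gain-fluctuation factor "
      f"gamma={budget.gamma:.2f} and the per-pixel read-out/digitization "
      f"noise psi={budget.psi:.2f} ADU^2, so it understates the error "
      f"by ~{np.sqrt(vc / vp):.2f}x here.")
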