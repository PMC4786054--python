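"""Cascade noise budget and detective quantum efficiency.

Folds the stage parameters of the detection chain (phosphor absorption,
scintillation gain, optical transmission, ADC) into the cascade factor
gamma, the pixel factor psi and the two gains, then tabulates the
zero-frequency DQE over signal strengths and region sizes.
"""

from ptccd import DetectorConfig, derive_noise_budget, dqe, expected_signal_adu

cfg = DetectorConfig()
params = cfg.cascade_params()
budget = derive_noise_budget(params)

print("cascade factor gamma      :", round(budget.gamma, 4))
print("pixel factor psi [ADU^2]  :", round(budget.psi, 4))
print("gain G  [ADU/absorbed ph] :", round(budget.gain_absorbed, 4))
print("gain G' [ADU/incident ph] :", round(budget.gain_incident, 4))
print("expected signal for 1e4 incident photons [ADU]:",
      round(expected_signal_adu(1e4, params), 1))
# gamma = 1.54 means every detected photon carries 54% more variance
# than an ideal counter; G' ~ 0.82 ADU/photon sets the ADU scale.

print("\nDQE(n_photons, region size):")
print("n_photons " + "".join(f"{f'{p}x{p}':>9}" for p in (6, 10, 14, 18)))
for n in (100.0, 500.0, 1e3, 1e4, 1e6):
    row = [dqe(n, p * p, budget, cfg.phosphor.q_abs) for p in (6, 10, 14, 18)]
    print(f"{n:9g} " + "".join(f"{v:9.3f}" for v in row))
print("\nWeak signals are pixel-noise limited (DQE falls with region "
      "size); strong signals approach q_abs/gamma =",
      round(cfg.phosphor.q_abs / budget.gamma, 3))
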