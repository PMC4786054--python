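"""A reduced replicate spot ensemble: validate the error estimators.

Simulates replicate spot images in zone A, integrates each by summation
and by profile fitting on both raw and corrected images, and prints the
ensemble summary.  With a few hundred replicates this is a quick look;
the full study uses 1e4.
"""

from ptccd import EnsembleSpec, run_spot_ensemble

spec = EnsembleSpec(n_replicates=500, zone="A", seed=42)
result = run_spot_ensemble(spec, pipeline="both")
print(result.summary().round(2).to_string())
print(
    "\nReading the table: on raw images the mean cascade estimator should\n"
    "track var(I_S) while the Poisson estimator falls short by ~gamma;\n"
    "the profile variance ratio is the factor by which fit-quality error\n"
    "estimates are optimistic (~1.7 raw, ~3.8 corrected at full size)."
)
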