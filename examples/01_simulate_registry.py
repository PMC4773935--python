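"""Generate a synthetic multi-region cancer registry with known truth.

The "stable" scenario emulates a Nordic-style extract: four regions of
one country plus two neighbouring countries, annual incidence and death
counts by sex, site and 5-year age group for 1983-2012, with flat
calendar trends so every estimation method should land near the truth.
"""

from incidest import generate, preset_scenarios

config = preset_scenarios(seed=7)["stable"]
bundle, truth = generate(config)

print(f"scenario: {config.name}; seed {config.seed}")
print(f"incidence strata: {len(bundle.incidence.data):,}")
print(f"datasets: {sorted(bundle.incidence.data['dataset'].unique())}")

national_2010 = truth.national_2010
print("\nexpected national cases in 2010 (the generator's ground truth):")
print(national_2010.to_string(index=False))
# These are the noise-free expectations; the recorded counts in the
# bundle are Poisson draws around them, so an estimator evaluated
# against this truth shows method bias, not sampling luck.
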