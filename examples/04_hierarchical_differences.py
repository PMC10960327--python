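"""Stage 3: hierarchical estimate of the group-level cued-miscued difference.

Simulates a small cohort with a 50 ms orienting gap and fits the hierarchical
model in which non-decision time is unconstrained per condition at the group
level.  The posterior difference should be clearly negative (cued faster).
"""

from gazeddm import HierMCMCConfig, build_hierarchical_model, group_difference, sample_hierarchical
from gazeddm.synth import GenerativeProfile, generate_cohort

profile = GenerativeProfile(
    n_participants=8, trials_per_condition=250,
    mixture={"t0": 1.0}, dt0_ms=(50.0, 1e-9), seed=3,
)
table, _ = generate_cohort(profile)

spec = build_hierarchical_model("t0", table)
chains = sample_hierarchical(spec, cfg=HierMCMCConfig.reduced(seed=9, iterations=600, burn_in=300))
diff = group_difference(chains)

print(f"group-level difference in t0 (cued - miscued): {diff.mean*1000:+.1f} ms")
print(f"95% credible interval: [{diff.ci_low*1000:+.1f}, {diff.ci_high*1000:+.1f}] ms")
print(f"posterior mass in the plausible ({diff.plausible_direction}) direction: "
      f"{diff.plausible_mass:.3f}")
print("An interval excluding zero on the negative side indicates a credible")
print("orienting benefit at the gazed-at location (truth here: -50 ms).")
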