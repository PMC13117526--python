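"""Sample size and operating characteristics of the Bayesian decision rules.

The design assumes a 0.5 log10-unit Lac/NAA reduction with SD 0.4.  The
futility rule stops when the posterior probability of superiority falls to
50% or below; success requires Pr(sup) >= 95% at the final analysis.
"""

from pigtrial.design import DesignSpec, calibrate_threshold, sample_size_two_arm, simulate_oc

sizing = sample_size_two_arm(delta=0.5, sd=0.4, power=0.80, alpha_two_sided=0.05)
print(f"per-group n for 80% power at 5% two-sided alpha: {sizing.n_per_arm} "
      f"(normal approximation {sizing.n_normal_approx:.1f}; "
      f"achieved power {sizing.achieved_power:.1%})")

spec = DesignSpec(delta=0.5, sd=0.4, n_per_arm=12, n_sims=20_000, seed=1)
oc = simulate_oc(spec)
print(f"\nsimulated operating characteristics ({spec.n_sims} trials/condition):")
print(f"  power (Pr_sup >= 0.95 | delta = 0.5):      {oc.power:.1%}")
print(f"  type I error (Pr_sup >= 0.95 | delta = 0): {oc.type1:.1%}")
print(f"  futility stop (Pr_sup <= 0.50 | delta = 0): {oc.p_stop_futility_null:.1%}")
print("  (under the null, Pr_sup is uniform, so the futility rule stops ~50%")
print("   of null trials and the 0.95 threshold gives a 5% one-sided error)")

c = calibrate_threshold(spec, target_alpha=0.025)
print(f"\nthreshold calibrated to a 2.5% one-sided type I error: c = {c:.3f}")
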