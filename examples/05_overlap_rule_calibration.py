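"""Verify the adjusted overlap rule holds its 5% error rate.

Simulates pairs of dependent mean estimates under a true null of equal
means and counts how often the adjusted intervals are disjoint.  With
the formula multiplier the rate sits near alpha; with naive 1.96
intervals the overlap test is far too conservative.
"""
from mcidkit import calibrate_overlap_rule

print(f"{'rho':>5}{'z*':>8}{'disjoint rate':>15}{'95% MC interval':>22}")
for rho in (0.0, 0.25, 0.5, 0.7):
    res = calibrate_overlap_rule(rho, n=100, reps=5000, seed=7)
    print(f"{rho:>5.2f}{res.z_star:>8.3f}{res.rate:>15.4f}"
          f"   ({res.mc_ci[0]:.4f}, {res.mc_ci[1]:.4f})")

naive = calibrate_overlap_rule(0.5, n=100, reps=5000, seed=7, z_star=1.96)
print(f"\nnaive 1.96 intervals at rho=0.5: rate {naive.rate:.4f} "
      "(conservative: far below 0.05)")
# Disjointness of the adjusted intervals is calibrated as a 5% test;
# unadjusted 95% CIs almost never separate under the null.
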