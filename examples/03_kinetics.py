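"""The two closed-form kinetic submodels.

DC recruitment is mass-action in the apoptotic beta-cell count and the
(constant) circulating DC pool; the beta-cell quiescence period shortens
as the apoptotic fraction — a proxy for glucose load — rises.
"""

from t1dsim import dc_recruited, estimate_gamma, quiescence_period

# mass-action recruitment: k_r * beta_AP * DC_c per hour
n = dc_recruited(k_r=0.01, beta_ap=200, dc_c=50, mode="nearest")
print(f"recruitment at k_r=0.01, 200 apoptotic cells, 50 circulating DCs: "
      f"{n} DCs this hour")

# the glucose-metabolism exponent from the literature calibration point:
# a 7-day baseline quiescence shortens to 2 days at 70% apoptotic cells
gamma = estimate_gamma(T0_days=7, target_days=2, apoptotic_fraction=0.7)
print(f"estimated glucose-metabolism exponent gamma = {gamma}")

for frac in (0.0, 0.3, 0.7, 1.0):
    T = quiescence_period(168.0, frac, 1.0, gamma)
    print(f"apoptotic fraction {frac:.1f}: quiescence period {T:6.1f} h "
          f"({T / 24:.1f} days)")
# At 70% apoptotic cells the period is 50.4 h = 2.1 days, i.e. the
# 2-day glucose-stimulated division cycle the exponent was fitted to.
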