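"""Dose-response and time-course reduction: DC50, Dmax, AUC, initial rate.

Generates a noisy 10-point 1:3 titration and a degradation time course
from known truth, then runs the standard reductions.
"""

from ternary_sar import (
    GeneratorSpec,
    auc_trapezoid,
    fit_dose_response,
    fit_time_course,
    generate_degradation_dataset,
)

data = generate_degradation_dataset(GeneratorSpec(seed=7))
truth = data["truth"]

dr = fit_dose_response(data["dose_response_curve"])
print(f"dose response: DC50 = {dr.dc50_label} nM (truth {truth['dc50_nM']:.1f}), "
      f"Dmax = {dr.dmax:.0f}% (truth {truth['dmax']:.0f}), AUC = {dr.auc:.0f}")

flat = auc_trapezoid([100.0] * 10)
print(f"non-degrader reference: flat 100-POC curve over 10 doses -> AUC {flat:.0f}")

tc = data["time_course"]
tfit = fit_time_course(tc["time_min"].to_numpy(), tc["poc"].to_numpy())
print(f"time course: t1/2 = {tfit.t_half_min:.1f} min "
      f"(truth {truth['tc_t_half_min']:.1f}), "
      f"initial rate = {tfit.initial_rate:.2f} %/min "
      f"(truth {truth['initial_rate']:.2f})")

# AUC summarises potency and efficacy without a fit (lower = better
# degrader; 900 is the 10-point no-degradation ceiling).  The initial
# degradation rate is 100 * 0.693 / t_half in %/min.
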