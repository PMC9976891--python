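"""Fit the three kinetic/binding models on simulated data.

Simulates a dipeptide-formation time course, an initiation-rate Arrhenius
series and a toeprint binding titration at published design points (with
mild noise), then re-fits each and prints estimate +/- standard error.
"""

from sdscan import (
    fit_arrhenius,
    fit_binding,
    fit_time_course,
    simulate_arrhenius,
    simulate_binding_curve,
    simulate_time_course,
)

# decoding time course: k = 7.4 min^-1, amplitude 0.6
tc = simulate_time_course(7.4, 0.6, [0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6],
                          noise_sd=0.02, seed=1)
fit = fit_time_course(tc)
print(f"decoding rate: k_app = {fit['k_app']:.2f} +/- {fit.se['k_app']:.2f} min^-1 "
      f"(truth 7.4)")

# initiation Arrhenius series: Ea = 42.9 kcal/mol anchored at k(20C) = 0.008
s = simulate_arrhenius(42.9, 0.008, 293.15, [288.15, 293.15, 298.15, 303.15, 310.15],
                       noise_sd_lnk=0.05, seed=2)
fit = fit_arrhenius(s)
print(f"activation energy: E_a = {fit['E_a']:.1f} +/- {fit.se['E_a']:.1f} kcal/mol "
      f"(truth 42.9)")

# toeprint titration: Fmax = 0.98, KA = 19 uM^-2 at c = 1 uM
curve = simulate_binding_curve(0.98, 19.0, [0.05, 0.1, 0.25, 0.5, 1, 2], 1.0,
                               noise_sd=0.02, seed=3)
fit = fit_binding(curve)
print(f"binding: F_max = {fit['F_max']:.2f} +/- {fit.se['F_max']:.2f}, "
      f"K_A = {fit['K_A']:.0f} +/- {fit.se['K_A']:.0f} uM^-2 (truth 0.98, 19)")
# Standard errors come from the fit covariance; a 'saturated' flag would
# mark titrations that sit on the plateau and constrain K_A only roughly.
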