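"""Quantify a plate: standard curve, sample inversion, citrate synthase.

Builds a small glycogen plate (female adult samples, 1:6 dilution,
8 flies per sample), fits the standard curve, inverts the sample wells,
and evaluates the citrate synthase closed form.
"""

from flymet import (
    AssaySpec,
    CSAssayParams,
    citrate_synthase_activity,
    fit_standard_curve,
    quantify,
)

standards = [(0.0, 0.021), (0.25, 0.148), (0.5, 0.270),
             (1.0, 0.523), (2.0, 1.021), (4.0, 2.018)]
cal = fit_standard_curve(standards)
print(f"standard curve: reading = {cal.slope:.4f}*conc + {cal.intercept:.4f} "
      f"(R^2 = {cal.r_squared:.5f})")

spec = AssaySpec("glycogen", dilution=6, n_animals=8, sample_volume=1.0)
for sid, reading in [("line301_f", 0.412), ("line303_f", 0.958),
                     ("blankish", 0.015)]:
    m = quantify(reading, cal, spec, sample_id=sid)
    if m.below_detection:
        print(f"{sid}: below detection")
    else:
        print(f"{sid}: {m.amount_per_animal:.3f} units/fly")
# amount/fly = (reading - intercept)/slope * 6-fold dilution / 8 flies

act = citrate_synthase_activity(CSAssayParams(dA412_per_min=0.1712))
print(f"citrate synthase at dA412/min = 0.1712: {act:.4f} U/mL")
# (0.1712 * 0.22 mL * 1) / (13.6 mM^-1 cm^-1 * 0.63 cm * 0.02 mL)
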