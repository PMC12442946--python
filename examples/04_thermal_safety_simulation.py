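"""Simulate focused therapeutic ultrasound heating and CEM43 safety.

Runs the axisymmetric bioheat solver on the default five-layer abdominal
stack (skin/muscle/bowel/blood/pancreas, pancreas at 3.5 cm) for a focused
1 MHz, 5 W/cm^2, 50% duty, 3 min sonication and prints per-tissue peak
temperatures, thermal doses and safety verdicts.
"""

import json

from echopanc import (SonicationProtocol, TransducerSpec,
                      default_abdominal_stack, safety_report,
                      simulate_protocol, thermal_dose)

stack = default_abdominal_stack()
protocol = SonicationProtocol(surface_intensity_w_cm2=5.0, duty_factor=0.5,
                              duration_min=3.0)
field = simulate_protocol(stack, TransducerSpec(focal_depth_cm=4.0), protocol)
dose = thermal_dose(field)
report = safety_report(dose, field, stack, protocol=protocol)

for tissue, entry in report["tissues"].items():
    print(f"{tissue:>9}: peak {entry['peak_temp_c']:6.2f} C, "
          f"CEM43 {entry['max_cem43']:10.3g} min -> {entry['verdict']}")
print("overall:", report["overall"],
      "| high-duty avoid flag:", report["high_duty_avoid_flag"])
# CEM43 is the Sapareto-Dewey dose in equivalent minutes at 43 C; the
# pass/fail thresholds are 240 CEM43 in any tissue and a 40 C pancreatic
# peak. Duty factors of 75% or more carry an advisory avoid flag.
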