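"""Light-exposure arithmetic: power, irradiance and dosage.

Converts sample-plane power measurements to irradiance, tabulates the
irradiance ladder with the dosage each step delivers over a 25-minute
exposure, and reproduces the scanned-ROI arithmetic of a confocal
stimulation experiment.
"""

from optoquant import dosage, exposure_table, irradiance_from_power

# Power measured at the sample plane over a scanned 75 x 600 um ROI
for block, power_uW in (("405+445 nm block", 5.6), ("445 nm only block", 2.1)):
    irr = irradiance_from_power(power_uW, 45_000.0, "uW", "um2")
    print(f"{block}: {power_uW} uW over 45,000 um^2 -> {irr:.2f} W/m^2")

# 445 nm dosage over the full 5-minute stimulation at the block-2 irradiance
print(f"dosage at 47.60 W/m^2 for 300 s: {dosage(47.60, 300.0):.2f} J/m^2")

print()
print(exposure_table((0.0, 0.02, 0.05, 0.15, 0.46, 1.39, 4.17, 12.50, 50.00),
                     duration_min=25.0).to_string(index=False))

# Irradiance is power per area (W/m^2); dosage is its time integral
# (J/m^2), the quantity that makes different exposure durations comparable.
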