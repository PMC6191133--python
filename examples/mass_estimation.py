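"""Two routes to the mass of food stores on a hive frame.

Route 1 converts the measured capped-honey surface to grams via the
mass of honey held by 1 cm^2 of capped comb.  Route 2 subtracts the
estimated brood weight and the empty drawn-frame weight from the
weighed frame.  The constants are reference values supplied by the
user (per-apiary calibration); none are baked into the package.
"""

from combquant import MassConstants, food_mass_from_frame_weight, honey_mass_from_area

constants = MassConstants(
    honey_mass_per_cm2=1.1,   # g per cm^2 of capped honey comb
    brood_mass_per_cm2=0.77,  # g per cm^2 of capped brood comb
    empty_frame_mass=560.0,   # g, drawn frame (wood + wax)
)

capped_honey_cm2 = 412.0   # from the photo pipeline
capped_brood_cm2 = 250.0
frame_weight_g = 1230.0    # frame weighed during the hive evaluation

by_area = honey_mass_from_area(capped_honey_cm2, constants)
by_weight = food_mass_from_frame_weight(frame_weight_g, capped_brood_cm2, constants)

print(f"capped honey surface {capped_honey_cm2:.0f} cm^2 "
      f"-> {by_area:.0f} g of honey (area route)")
print(f"frame {frame_weight_g:.0f} g - brood {capped_brood_cm2:.0f} cm^2 "
      f"x {constants.brood_mass_per_cm2} g/cm^2 - empty {constants.empty_frame_mass:.0f} g "
      f"-> {by_weight:.0f} g of food stores (weight route)")
# the weight route also counts uncapped nectar and pollen, so it reads
# higher than the capped-honey area route on active frames
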