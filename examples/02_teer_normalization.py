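"""Normalize raw transwell resistance readings to TEER and recover a dose effect.

TEER (transendothelial electrical resistance) indexes the tightness of the
paracellular pathway.  The analysis multiplies the raw ohm reading by the
insert area (0.33 cm^2) and subtracts the empty coated insert's 70 Ohm cm^2.
Here a sham and a 10 Gy day-2 group are simulated with a 30% true decrease.
"""

from bbbassay import TrueKinetics, compute_teer, compute_teer_table, simulate_permeability_dataset

print("single reading:", compute_teer(1371.5, 0.33, 70.0).teer, "Ohm cm^2")

kinetics = TrueKinetics(teer_between_sd=0.0)
study = simulate_permeability_dataset(
    kinetics, n_inserts=16, noise_cv=0.10, seed=11, doses=(0.0, 10.0), days=(2,)
)
out = compute_teer_table(study.teer_table, area_cm2=0.33, blank=70.0)
means = out.groupby("dose_gy")["teer"].mean()
print(f"sham  day 2: {means[0.0]:6.1f} Ohm cm^2")
print(f"10 Gy day 2: {means[10.0]:6.1f} Ohm cm^2")
print(f"recovered decrease: {100 * (1 - means[10.0] / means[0.0]):.1f}%  (true 30%)")
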