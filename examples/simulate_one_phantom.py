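"""Full Monte Carlo dosimetry of one phantom.

Builds the lowest-BMI female phantom, samples 2e5 Y-90 decays uniformly
in the liver at the mean beta energy, transports them with the CSDA
engine, and converts the liver self-S-value into the total liver dose
for a 3 GBq administration.
"""

import voxdose as vd

phantom = vd.build_phantom(vd.preset("female", 18.6))
record, dosemap, ledger = vd.simulate_phantom(phantom, 200_000, seed=1)

print("S-values (mGy/MBq-s), liver source:")
for organ, s in record.s_values.items():
    print(f"  {organ:<8s}{s:.4e}  (+/- {record.uncertainties[organ]:.1e})")
print(f"energy ledger imbalance: {ledger.imbalance():.1e}")
print(f"unscored bremsstrahlung fraction: "
      f"{ledger.radiative_mev / ledger.emitted_mev:.3%}")

dose = vd.total_dose(record.s_values["liver"], vd.THERAPY_3GBQ)
rate = vd.equivalent_dose_rate(record.s_values["liver"], 100.0)
print(f"\nliver dose for 3 GBq / 64.1 h: {dose:.1f} Gy")
print(f"equivalent-dose rate at 100 MBq: {rate:.3e} mSv/s")
print(
    "\nOnly electrons are transported, so organs beyond the ~4 mm beta\n"
    "range (lungs, kidneys) receive zero dose here; adjacent vertebral\n"
    "marrow picks up a small interface dose.  The reference table's\n"
    "nonzero distant-organ entries come from bremsstrahlung photons,\n"
    "which this engine tallies but does not transport."
)
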