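"""Per-record emission factors: engine load, SFOC, NOx, SOx and CO2.

Builds nothing — just evaluates the factor curves a ship emission inventory
applies to every movement record, and prints the values for a medium-speed
distillate-burning vessel at normal and low engine load.
"""

from shipair import co2_ef, nox_ef, pm_ef, propulsion_load, sfoc_at_load, sox_split

design_speed = 10.0  # m/s
for speed in (10.0, 6.3, 0.0):
    load = float(propulsion_load(speed, design_speed))
    sfoc = float(sfoc_at_load(250.0, load))
    ef_so2, ef_so4s = sox_split(0.005, sfoc, "MDO_MGO")
    print(f"speed {speed:5.1f} m/s -> load {load:5.3f}, SFOC {sfoc:5.1f} g/kWh, "
          f"SO2 {ef_so2:4.2f}, primary-SO4 sulphur {ef_so4s:5.3f}, "
          f"PM {float(pm_ef(0.005, load)):4.2f}, "
          f"CO2 {float(co2_ef('MDO_MGO', sfoc)):5.0f} g/kWh")

print("\nMARPOL NOx tiers for a 514-rpm medium-speed engine (g/kWh):")
for tier in (0, 1, 2, 3):
    print(f"  Tier {tier}: {nox_ef(tier, 'MSD', 514.0):5.1f}")

# The load column shows the cubic propeller law with its 2% hotelling floor;
# SOx factors scale with fuel sulphur times SFOC, and the SO2/sulphate split
# keeps the fuel sulphur mass balance exact.
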