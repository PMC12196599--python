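"""Battery endurance what-ifs for the wearable module.

The linear discharge model C_rem = C_init − I_dis·t on the 2000 mAh pack,
evaluated for the three operating modes: everything on (GNSS tracking +
radio connected, 72 mA), radio idle (20 mA), and wake-on-shake (5 mA).
"""

from fallfsm import PowerSpec, operating_time, remaining_capacity
from fallfsm.power import DEFAULT_CAPACITY_MAH, SCENARIO_PRESETS

cap = DEFAULT_CAPACITY_MAH
for name, current in SCENARIO_PRESETS.items():
    t = operating_time(cap, current)
    print(f"{name:>14}: {current:5.1f} mA -> {t:6.1f} h ({t / 24:5.1f} days)")

res = remaining_capacity(PowerSpec(c_init=cap, i_dis=72, t=10))
print(f"\nafter a 10 h outing with everything on: "
      f"{res.remaining_mah:.0f} mAh left ({res.percent:.0f}%)")
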