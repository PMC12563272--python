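"""Medium-consumption budgets for the perfusion regimens.

Compares constant flow (2 µL/min) with intermittent pulses (10 µL/min for
5 min every 3 h) over a 96 h experiment, and puts chip consumption next to
a conventional 96-well plate.
"""

import wellquant as wq
from wellquant.perfusion import PROTOCOL_PRESETS

constant = PROTOCOL_PRESETS["constant_2ul"]
ibidi = PROTOCOL_PRESETS["intermittent_ibidi"]
pdms = PROTOCOL_PRESETS["intermittent_pdms"]

print(f"intermittent cycle volume (ibidi channel): "
      f"{wq.volume_per_cycle(ibidi):.0f} µL every {ibidi.period_h:g} h")
print(f"intermittent cycle volume (PDMS device):   "
      f"{wq.volume_per_cycle(pdms):.0f} µL every {pdms.period_h:g} h")

horizon = 96.0
print(f"\nover {horizon:.0f} h, one channel:")
print(f"  constant 2 µL/min:  {wq.consumption(constant, horizon) / 1000:.2f} mL")
print(f"  intermittent:       {wq.consumption(ibidi, horizon) / 1000:.2f} mL")
ratio = wq.consumption_ratio(constant, ibidi, horizon)
print(f"  ratio: {ratio:.1f}x — intermittent feeding consumes over "
      f"{int(ratio)}x less medium for comparable growth")

print(f"\nfilling budgets: 96-well plate {wq.plate_budget(96, 200) / 1000:.1f} mL;"
      f" ibidi chip (3 x 45 µL) {wq.plate_budget(3, 45):.0f} µL")

sched = wq.build_schedule(ibidi, imaging_interval_h=3.0, horizon_h=12.0)
print(f"\n12 h schedule: {len(sched.dispense_events)} dispenses at "
      f"{[e[0] for e in sched.dispense_events]} h; imaging at "
      f"{list(sched.imaging_times_h)} h (offset to avoid flow)")
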