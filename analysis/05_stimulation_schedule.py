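#!/usr/bin/env python
"""Shaker-flow parameterization and stochastic schedules.

Reports the tangential flow speeds of the two experimental settings (85 rpm
/ 2 cm for embryos, 105 rpm / 2 cm for choanoflagellate sheets), generates a
2 h stochastic schedule within the 68-99 rpm / 2-9 s / 5-29 min envelope,
and validates the published six-segment sequence against that envelope.
Writes results/schedule.csv and results/flow_speeds.csv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from gastrulaquant.stimulation import (
    PRINTED_STOCHASTIC_SCHEDULE, InstrumentLimits, ShakerSettings,
    flow_speed, generate_schedule, validate_schedule,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for name, rpm in (("embryo", 85.0), ("choanoflagellate", 105.0)):
        s = ShakerSettings(rpm=rpm, radius_cm=2.0, reversal_period_s=2.5)
        peak, mean_abs = flow_speed(s)
        rows.append({"setting": name, "rpm": rpm, "radius_cm": 2.0,
                     "peak_cm_s": round(peak, 2), "mean_abs_cm_s": round(mean_abs, 2)})
    speeds = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    speeds.to_csv(ROOT / "results" / "flow_speeds.csv", index=False)
    print(speeds.to_string(index=False))

    limits = InstrumentLimits()
    sched = generate_schedule(limits, total_min=120.0, seed=1)
    pd.DataFrame([{"rpm": s.rpm, "duration_min": s.duration_min, "period_s": s.period_s}
                  for s in sched.segments]).to_csv(ROOT / "results" / "schedule.csv",
                                                   index=False)
    print(f"\nstochastic schedule: {len(sched.segments)} segments, "
          f"{sched.total_duration_min:.0f} min, all within limits: "
          f"{not validate_schedule(sched, limits)}")

    violations = validate_schedule(PRINTED_STOCHASTIC_SCHEDULE, limits)
    print("published six-segment table vs the 68-99 rpm envelope:",
          violations or "no violations")


if __name__ == "__main__":
    main()
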