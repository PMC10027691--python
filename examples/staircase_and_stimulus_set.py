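"""Simulate the adaptive staircase and build an individualized stimulus set.

A simulated listener with a logistic psychometric function runs a
2-down/1-up transformed staircase; the converged interval estimates the
listener's 70.7%-correct discrimination threshold (the JND, in log2
ripple-velocity units).  The JND then spaces the 17-stimulus pool
(0.5 JND steps from 4 cycles/s) and the 6 item classes (1.5 JND apart).
"""

import wmconn as w
from wmconn.stimuli import staircase_target_proportion

listener = w.LogisticListener(threshold=0.2, slope=0.05)
result = w.run_staircase(
    listener, rule="2d1u", start_interval=1.0,
    stop_reversals=60, averaged_reversals=40, seed=1,
)
target = listener.interval_at(staircase_target_proportion("2d1u"))
print(f"staircase JND estimate: {result.jnd:.3f} log2 units "
      f"(analytic 70.7% point: {target:.3f}, {len(result.track)} trials)")

stimset = w.build_stimulus_set(jnd=result.jnd)
print(f"pool: {len(stimset.pool)} ripple velocities, "
      f"{stimset.pool[0].omega:.1f}-{stimset.pool[-1].omega:.1f} cycles/s")
print("class velocities (cycles/s):",
      [round(stimset.class_spec(c).omega, 2) for c in range(6)])
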