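"""The Monte Carlo threshold algorithm on an analytic double well.

Runs a lid-by-lid threshold walk on E(x,y) = 13.3(x^2-1)^2 + 13.3 y^2 and
compares the lid at which the far basin is first discovered with the true
saddle energy from a brute-force flood fill.
"""
import numpy as np

from crystalmct.fixtures import SurfaceSystem, double_well_2d, flood_fill_saddle
from crystalmct.threshold import LidSchedule, run_threshold

surface = double_well_2d()
saddle = flood_fill_saddle(surface, 0.01, [-1.0, 0.0], [1.0, 0.0])
print(f"flood-fill saddle energy: {saddle:.3f} kJ/mol (analytic: 13.300)")

schedule = LidSchedule.named("S3")  # 1.25 kJ/mol lids, 2000 moves each
print(f"schedule {schedule.scheme_name}: {schedule.n_lids} lids, "
      f"{schedule.total_moves} total moves")

for seed in range(3):
    system = SurfaceSystem(surface)
    record = run_threshold(
        system, np.array([-1.0, 0.0]), schedule, seed=seed,
        stop_condition=lambda found: len(found) >= 2,
    )
    far = [i for i, (m, _) in enumerate(system.minima) if m[0] > 0.5]
    lid = record.first_found[far[0]]
    print(f"seed {seed}: far basin first found at lid {lid:.2f} "
          f"(saddle + {lid - saddle:.2f})")
print()
print("The first-found lid is an upper bound on the true barrier: it can")
print("never undercut the saddle, and with fine lids it lands within one")
print("increment above it.")
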