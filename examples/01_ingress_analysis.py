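"""Follow one ligand from bulk solvent into a buried cavity.

Builds a toy receptor with a 5 A cavity, plants a binding trajectory with
explicit waters, then runs the core ingress readouts: site-distance series,
four-state segmentation, entry events, and the solvation fraction.
"""

import numpy as np

import ligandpath as lp
from ligandpath import synthetic as syn

receptor = syn.make_toy_receptor(900, seed=7)
traj, truth = syn.make_translocation_trajectory(
    receptor, ligand_n_atoms=30, n_waters=120, noise_sd=0.3, seed=1,
    dwell_frames={s: 40 for s in syn.STATE_ORDER})

site = lp.SitePoint(receptor.metadata["cavity_center"])
series = lp.distance_series(traj, "chain L", "chain A", site)
seg = lp.segment_states(series, method="changepoint", n_states=5)
events = lp.detect_entry_events(series)

print("mean site distance per segmented state (A):")
for start, stop, label in seg.segments():
    print(f"  {label:<10s} frames {start:3d}-{stop - 1:3d}  "
          f"{series.distances[start:stop].mean():6.2f}")

bulk = lp.bulk_reference(traj, "chain L", frames=np.arange(40))
solv = lp.solvation_fraction(traj, "chain L", bulk_mean=bulk)
labels = np.array(truth.state_schedule)
print("\nsolvation fraction per planted state (1.0 = bulk shell):")
for state in syn.STATE_ORDER:
    print(f"  {state:<10s} {solv.fraction[labels == state].mean():5.2f}")

print(f"\nentered vestibule: {events.entered_vestibule} "
      f"(first frame {events.first_vestibule_frame}); "
      f"fully bound: {events.fully_bound} "
      f"(first frame {events.first_binding_frame})")
print("The distance staircase and the monotone loss of first-shell waters "
      "together are the signature of stepwise translocation into a buried, "
      "dehydrated binding site.")
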