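"""Ion-surface association curves, peaks, residence times and enrichment.

Builds seeded toy trajectories: ions with planted association shells around
a reference point, plus a background. Recovers the shell radii as peaks,
extracts gap-tolerant residence events, and quantifies how much more a
"mutant" with doubled shell occupancy associates than the "wild type".
"""

import numpy as np

from halodesign import compare_association, find_peaks, rdf_min_distance, residence_events
from halodesign import fixtures as fx

protein = np.zeros((1, 3))

shells = fx.make_ion_trajectory(
    protein, n_ions=40, n_frames=60, shells=[(2.2, 0.5), (4.8, 0.5)], seed=23
)
curve = rdf_min_distance(shells, bin_width=0.08, r_max=8.0, seed=6)
print("association peaks (A):", [round(p, 2) for p in find_peaks(curve, min_height=2.0, min_separation=0.5)])

bound = fx.make_ion_trajectory(protein, n_ions=10, n_frames=50, shells=[(2.7, 1.0)], seed=8)
events = residence_events(bound, contact_cutoff=3.0, gap_tolerance=2)
longest = max(events, key=lambda e: e.duration_frames)
print(f"{len(events)} residence events; longest {longest.duration_frames} frames "
      f"({longest.duration_ps(bound.frame_spacing_ps):.0f} ps at 10 ps/frame)")

base = dict(n_ions=30, n_frames=80, seed=31)
wild = fx.make_ion_trajectory(protein, shells=[(2.7, 0.25)], uniform_weight=0.75, **base)
mutant = fx.make_ion_trajectory(protein, shells=[(2.7, 0.5)], uniform_weight=0.5, **base)
kwargs = dict(bin_width=0.25, r_max=8.0, seed=4)
ratio = compare_association(
    rdf_min_distance(mutant, **kwargs), rdf_min_distance(wild, **kwargs), (2.0, 3.5)
)
print(f"integrated association, mutant/wild in 2.0-3.5 A: {ratio:.2f}")
# The peaks land on the planted 2.2 and 4.8 A shells within one bin; ions
# held on a 2.7 A shell stay "resident" for the whole window; doubling the
# shell weight roughly doubles the integrated association (ratio ~2).
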