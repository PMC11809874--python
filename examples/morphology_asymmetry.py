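"""Dendrite asymmetry index from SWC files and synthetic arbours.

The index measures how far the volume-weighted dendritic centroid lies
from the soma, normalized by the per-coordinate spread: stellate (closed
field) arbours score near 0, polarized (open field) arbours score high,
and the score predicts unitary scalp signal strength.
"""

import tempfile
from pathlib import Path

import numpy as np

from apeeg import asymmetry_index, load_morphology, make_morphology

swc = """\
# toy pyramidal cell: soma at origin, apical trunk along +z, two basals
1 1 0 0 0 5.0 -1
2 4 0 0 200 2.0 1
3 4 0 0 500 1.5 2
4 3 60 0 -40 1.0 1
5 3 -60 0 -40 1.0 1
"""
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "pyramidal.swc"
    path.write_text(swc)
    m = load_morphology(path)
    print(f"SWC toy pyramidal: {m.n_segments} cone segments, "
          f"asymmetry index {asymmetry_index(m):.1f}")

print("\nsynthetic arbours with increasing centroid offset:")
for offset in (0.0, 25.0, 100.0):
    m = make_morphology(asymmetry=offset, n_segments=30, seed=4)
    print(f"  offset {offset:5.0f} um -> index {asymmetry_index(m):8.2f}")
print("a point-symmetric arbour scores exactly 0 (closed field, no far "
      "potential); the index grows with dendritic polarization.")
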