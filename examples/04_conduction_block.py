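"""Conduction block through dense fibrosis (percolation).

Launches single plane waves at a band of uniform fibrosis on a small patch
and reports whether they emerge on the far side.  Around ~41 % the
conducting cluster of myocytes stops spanning the band and propagation
fails for every texture — the level at which fibrotic tissue behaves as
solid scar.  A few minutes of runtime.
"""

from rotoranchor import CellParams
from rotoranchor.protocols import crossing_test

params = CellParams.calibrated()
for level in (30.0, 38.0, 44.0):
    crossed = sum(crossing_test(level, seed=s, n_rows=32, n_cols=120,
                                region_cols=(25, 81), max_time=400.0,
                                params=params)
                  for s in range(3))
    print(f"fibrosis {level:4.0f} %: {crossed}/3 textures conducted")
print("the full 1 %-step threshold sweep lives in scripts/acceptance.py (t6)")
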