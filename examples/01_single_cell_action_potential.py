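"""Single myocyte: action potential and the effect of fibrotic remodeling.

Integrates one TP06 epicardial cell for two paced beats and prints resting
potential, peak overshoot and APD90, then repeats with the ionic remodeling
that a 40 % local fibrosis level imposes (I_Na -62 %, I_Kr -70 %, I_Ks
-80 %).  Remodeled fibrotic tissue repolarizes later — the APD prolongation
that helps seed wave breaks at a scar.
"""

import rotoranchor as ra
from rotoranchor import single_cell as sc


def two_beat_apd(params):
    t, v, y1 = sc.integrate_cell(params, 1000.0, stim_times=[50.0])
    t, v, _ = sc.integrate_cell(params, 1000.0, y0=y1, stim_times=[50.0])
    return t, v, sc.apd90(t, v, 50.0)


base = ra.CellParams.epicardial()
t, v, apd = two_beat_apd(base)
print(f"healthy epicardial cell: V_rest = {v[0]:.1f} mV, "
      f"peak = {v.max():.1f} mV, APD90 = {apd:.0f} ms")

remodeled = ra.apply_remodeling(40.0, base)
s = ra.remodeling_factors(40.0)
print(f"remodeling at f = 40 %: scale factors "
      f"s_Na = {s.s_na:.2f}, s_Kr = {s.s_kr:.2f}, s_Ks = {s.s_ks:.2f}")
t, v, apd_r = two_beat_apd(remodeled)
print(f"remodeled cell:          V_rest = {v[0]:.1f} mV, "
      f"peak = {v.max():.1f} mV, APD90 = {apd_r:.0f} ms "
      f"(+{apd_r - apd:.0f} ms vs healthy)")
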