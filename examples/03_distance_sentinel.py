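"""Distance to the healthy state and the decompensation sentinel.

Simulates a small cohort, pools it for the normalization constants,
builds each animal's self-referenced distance trajectory D_k, runs the
sentinel rule (D > 2.5 for 3 consecutive 20-min windows), and compares
the sentinel time t_D with the decompensation time t_CVD detected from
the arterial-pressure occlusion responses.
"""
import numpy as np

import fhrsentinel as fs

cohort = fs.simulate_cohort(4, master_seed=11)
records = fs.analyze_cohort(cohort)

print("animal   t_D (s)   t_CVD (s)   t_CVD - t_D   t_pH - t_CVD")
for rec, sim in zip(records, cohort):
    t_ph = fs.find_ph_crossing(sim.metabolites)
    cmp = fs.compare_sentinel_to_cvd(rec.sentinel.t_D, rec.t_cvd, t_ph)
    print(f"{rec.animal_id}  {cmp['t_D_s']:8.0f}  {cmp['t_CVD_s']:9.0f}"
          f"   {cmp['cvd_minus_d_hhmm']:>9s}     {cmp['ph_minus_cvd_hhmm']:>6s}")

print("\nThe sentinel anticipates or trails the pressure-based")
print("decompensation time by a few minutes, and both precede the fall of")
print("pH below 7.00 by roughly an hour - the window in which an early")
print("alert is clinically useful.")

traj = records[0].trajectory
base = traj.valid & (traj.t_k < cohort[0].schedule.moderate)
print(f"\nbaseline D fluctuation (first animal): sd = {np.nanstd(traj.D[base]):.2f}"
      " (the normalization makes 1 the natural unit)")
print(f"peak D: {np.nanmax(traj.D):.1f}")
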