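"""Calibrate individual intensity zones from an incremental lactate test.

Simulates one 6x200 m incremental test for a swimmer whose true
threshold speeds at 2/4/6 mmol/L are 1.30/1.40/1.45 m/s, fits the
piecewise log-linear lactate-speed profile, and classifies a few
training speeds into the five intensity levels.
"""

from swimtraj import classify_speed, fit_lactate_profile, simulate_lactate_test

stages = simulate_lactate_test((1.30, 1.40, 1.45), n_stages=6, noise_sd=0.15, seed=7)
print("incremental test stages (speed m/s, lactate mmol/L):")
for speed, lactate in stages:
    print(f"  {speed:.3f}  {lactate:5.2f}")

profile = fit_lactate_profile(stages)
print(f"\nfitted threshold speeds: v2={profile.v2:.3f}  v4={profile.v4:.3f}  "
      f"v6={profile.v6:.3f} m/s")

for speed in (1.20, 1.35, 1.43, 1.50):
    level = classify_speed(speed, profile)
    print(f"training speed {speed:.2f} m/s -> {level}")
print("max-effort sprint ->", classify_speed(1.50, profile, is_max_sprint=True))

# v2/v4/v6 are the speeds at blood lactate 2/4/6 mmol/L; swims below v2
# are easy aerobic work (I1), between v4 and v6 severe (I3), and all-out
# sprints are I5 regardless of speed.
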