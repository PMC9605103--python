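"""Full pipeline on a small synthetic wrist scenario.

Generates one subject, both hands, a reduced wrist protocol with known
ground-truth screw motions, runs registration -> frames -> helical axes
-> statistics, and compares the recovered screw parameters with the
generator's ground truth.
"""

import tempfile

import numpy as np

from wristkin import ScenarioConfig, generate_scenario, run_pipeline

cfg = ScenarioConfig(
    n_subjects=1,
    hands=("L", "R"),
    fe_positions_deg=(0.0, 30.0, -60.0),
    rud_positions_deg=(0.0, -40.0),
    perturb_rot_deg=5.0,
    perturb_trans_mm=5.0,
    vertex_noise_mm=0.0,
    bone_subdivisions=3,
    radius_subdivisions=4,
    seed=42,
)
out = tempfile.mkdtemp(prefix="wristkin_example_")
scenario = generate_scenario(cfg, out)
result = run_pipeline(scenario.manifest_path, out_dir=out + "/results")

print(f"{len(result.records)} kinematics records "
      f"(8 bones x 3 non-neutral positions x 2 hands)")
print()
print(result.records[["subject", "hand", "bone", "position",
                      "ha_angle_deg", "ha_translation_mm", "fe_deg"]].head(8).round(3))

errs = []
for _, r in result.records.iterrows():
    s = scenario.ground_truth.screw(r.subject, r.hand, r.bone, r.motion, r.position_deg)
    errs.append(abs(r.ha_angle_deg - s.angle_deg))
print()
print(f"max |recovered - true| rotation angle: {max(errs):.2e} deg")
print("With no vertex noise the pipeline reproduces every ground-truth")
print(f"screw essentially exactly. Full tables written to {result.out_dir}.")
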