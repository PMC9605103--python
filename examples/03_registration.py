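"""Rigid CPD registration of a displaced radius point cloud.

Takes the synthetic radius surface, down-samples it to ~3000 points,
applies a known rigid transform (a surrogate for scanner/arm placement),
and recovers that transform with rigid coherent point drift.
"""

import numpy as np

from wristkin import PointCloud, cpd_rigid, downsample, make_radius_template
from wristkin.transforms import RigidTransform, rotation_about_axis

mesh, _ = make_radius_template(subdivisions=5)
cloud = downsample(PointCloud(mesh.vertices, "radius"), 3000)
print(f"radius cloud: {len(mesh.vertices)} vertices -> {len(cloud)} points")

truth = RigidTransform(rotation_about_axis([0.3, 1.0, -0.2], 20.0),
                       np.array([5.0, -3.0, 2.0]))
moved = PointCloud(truth.apply(cloud.points), "moved")

result = cpd_rigid(cloud, moved)
err = result.transform @ truth.inverse()

print(f"CPD converged in {result.n_iter} iterations (sigma^2 = {result.sigma2:.2e})")
print(f"rotation error:    {err.rotation_angle_deg():.2e} deg")
print(f"translation error: {np.linalg.norm(err.translation):.2e} mm")
print()
print("Errors at this level mean the recovered transform is numerically")
print("exact; with real scans the residual reflects segmentation noise.")
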