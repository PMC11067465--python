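"""Preprocess raw tracked positions the way experimental data are handled.

Starting from pixel coordinates with occlusion gaps: fill short gaps
with cubic splines, warp the imaged tank corners onto a physical square
(homography), then smooth with a Gaussian kernel (sigma = 2 frames,
truncated at 5 sigma) and differentiate with Gaussian-derivative kernels
to obtain velocities and accelerations.
"""

import numpy as np

import schoolsim as ss
from schoolsim.preprocessing import RawTrack, TankGeometry

# synthetic "camera" data: two fish on known circular paths, imaged
# through a perspective-distorted view of a 100 cm tank
truth = ss.fixtures.circular_mover(radius=20.0, speed=11.0,
                                   n_frames=600, n_individuals=2)
geometry = TankGeometry(
    corners=np.array([[120.0, 80.0], [2620.0, 180.0],
                      [2540.0, 2700.0], [60.0, 2600.0]]),
    side_cm=100.0)
to_image = np.linalg.inv(geometry.homography().params)


def image_coords(xy_cm):
    shifted = xy_cm + 50.0  # circle centered in the tank
    h = np.concatenate([shifted, np.ones(shifted.shape[:-1] + (1,))], -1)
    p = h @ to_image.T
    return p[..., :2] / p[..., 2:]


pixels = image_coords(truth.positions)
pixels[100:104, 0] = np.nan  # a 4-frame occlusion
track = RawTrack(pixels, fps=1.0 / truth.dt)

track = ss.interpolate_gaps(track, max_gap=10)
track = ss.project_to_plane(track, geometry)
traj = ss.smooth_and_differentiate(track, sigma_frames=2.0)

interior = slice(15, -15)
speed = traj.speeds[interior]
omega = ss.turning_rate(traj.velocities[interior],
                        traj.accelerations[interior])
print(f"gap filled, projected to the tank plane, smoothed: "
      f"{traj.n_frames} frames of {traj.n_individuals} fish")
print(f"recovered speed        {speed.mean():7.3f} cm/s   (truth 11.0)")
print(f"recovered |turn rate|  {np.abs(omega).mean():7.3f} rad/s  "
      f"(truth u/R = {11.0 / 20.0:.3f})")
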