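"""Recover 3D world positions from bounding boxes + depth patches.

Synthesizes a detection stream (pixel boxes with jitter, depth patches
with invalid holes) for a walking target seen from a hovering observer,
then runs the localization geometry: ROI contraction, valid-depth
averaging, pinhole back-projection, and the camera->body->world transform
chain.  Prints the recovery error, which is bounded by the injected pixel
jitter.
"""

import numpy as np

from lstmkf.benchmark import (localize_stream, simulate_detection_stream,
                              simulate_trajectory)
from lstmkf.geometry import CameraIntrinsics, ObserverPose

K = CameraIntrinsics(np.array([[400.0, 0, 320], [0, 400.0, 240], [0, 0, 1]]))
observer = ObserverPose(np.eye(3), [-30.0, 0.0, 8.0])  # 30 m behind, 8 m up

_, positions, _, _ = simulate_trajectory([("walking", 20.0)], dt=1 / 10, seed=2)

for jitter in (0.0, 2.0):
    frames = simulate_detection_stream(positions, K, observer, seed=5,
                                       jitter_px=jitter, invalid_frac=0.3)
    recovered = localize_stream(frames, K)
    err = np.linalg.norm(recovered - positions, axis=1)
    print(f"box jitter {jitter:3.1f} px -> mean localization error "
          f"{np.nanmean(err) * 100:.2f} cm over {len(frames)} frames")
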