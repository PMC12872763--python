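"""Derive the five-keypoint centerline of a mask and emit a pose annotation.

The canonical centerline of an elongated mask is five control points:
two endpoints where the midline meets the object boundary and three
interior points at 1/4, 1/2 and 3/4 of the length axis, each midway
between the upper and lower edges.  The quintuplet is serialized as a
single normalized pose-annotation text line (class, box, 5 x (x, y, vis)).
"""

import tempfile
from pathlib import Path

import numpy as np

from stipemorph import (
    bounding_rect,
    canonical_keypoints,
    centerline_length,
    keypoints_to_pose,
)
from stipemorph.io_formats import write_pose_annotation

# a straight 401 x 101 px band placed inside a 1000 x 500 px image
mask = np.zeros((500, 1000), dtype=bool)
mask[100:201, 100:501] = True

kps = canonical_keypoints(mask)
print("keypoints (x, y):", [tuple(map(float, p)) for p in kps.points])
print(f"centerline polyline length: {centerline_length(kps):.1f} px")

pose = keypoints_to_pose(kps, bounding_rect(mask), image_width=1000, image_height=500)
out = Path(tempfile.mkdtemp()) / "pose.txt"
write_pose_annotation(pose, out)
line = out.read_text().strip()
print("pose annotation line:")
print(" ", line)
print()
print("The 20 tokens are: class id, box center x/y, box w/h, then five")
print("(x, y, visibility) triples, all as fractions of the image size.")
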