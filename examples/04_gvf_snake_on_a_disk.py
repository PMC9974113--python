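"""GVF-snake convergence on an analytic disk.

Initializes the contour as a rectangle just inside the block border, far
outside the object, and lets the gradient-vector-flow force carry it onto
the disk boundary. The converged contour is compared point by point with
the true circle of radius 30.
"""

import numpy as np

from lungrepair import GVFConfig, SnakeConfig
from lungrepair.gvf_snake import (
    compute_gvf,
    edge_map,
    evolve,
    init_contour,
    internal_matrix,
    interior_mask,
)

block = np.zeros((101, 101), np.uint8)
rr = np.arange(101)[:, None]
cc = np.arange(101)[None, :]
block[(rr - 50) ** 2 + (cc - 50) ** 2 <= 30**2] = 1

cfg = SnakeConfig()
field = compute_gvf(edge_map(block, cfg.sigma_edge), GVFConfig())
state = init_contour(block.shape, cfg.n_points)
A = internal_matrix(cfg.n_points, cfg.lambda1, cfg.lambda2)

start_gap = np.abs(np.hypot(state.xs - 50, state.ys - 50) - 30)
final = evolve(state, field, A, cfg)
dist = np.abs(np.hypot(final.xs - 50, final.ys - 50) - 30)
interior = interior_mask(final, block.shape)

print(f"initial mean gap to the circle: {start_gap.mean():.1f} px")
print(f"converged after {final.iteration} iterations (mean step {final.mean_step:.4f} px)")
print(f"mean |distance - 30|: {dist.mean():.3f} px, max: {dist.max():.3f} px")
print(f"interior area {int(interior.sum())} px vs pi*30^2 = {np.pi * 900:.0f}")
# The contour travels ~20-40 px from the rectangle to the disk edge under
# the unit-normalized GVF force and settles within a fraction of a pixel.
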