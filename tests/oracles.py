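"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the superposition
oracle minimises RMSD directly over a rotation grid plus simplex
refinement (no SVD), and the contact oracle enumerates periodic images in
explicit Python loops (no vectorised minimum-image arithmetic).
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_grid_rmsd(mobile, reference, n_grid=30):
    """Minimum RMSD over rotations by brute force: an Euler-angle grid
    scan followed by Nelder–Mead refinement of the rotation vector."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    def cost_mat(mats):
        moved = np.einsum("rij,nj->rni", mats, p)
        return np.sqrt(((moved - q) ** 2).sum(axis=2).mean(axis=1))

    a = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    b = np.linspace(0, np.pi, n_grid // 2 + 1)
    g = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    euler = np.array(np.meshgrid(a, b, g, indexing="ij")).reshape(3, -1).T
    rots = Rotation.from_euler("zyz", euler)
    costs = cost_mat(rots.as_matrix())

    def cost_vec(v):
        moved = p @ Rotation.from_rotvec(v).as_matrix().T
        return float(np.sqrt(((moved - q) ** 2).sum(axis=1).mean()))

    # refine the best grid basins; keep the overall minimum
    best = np.inf
    for k in np.argsort(costs)[:15]:
        res = minimize(cost_vec, rots[int(k)].as_rotvec(),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def contact_count_oracle(pa, pb, box, cutoff):
    """All-pairs contact count with explicit ±1 periodic images in X and Y
    (never Z), strict < cutoff."""
    lx, ly = float(box[0]), float(box[1])
    count = 0
    for a in pa:
        for b in pb:
            dmin = np.inf
            for ix in (-1, 0, 1):
                for iy in (-1, 0, 1):
                    dx = a[0] - b[0] - ix * lx
                    dy = a[1] - b[1] - iy * ly
                    dz = a[2] - b[2]
                    dmin = min(dmin, (dx * dx + dy * dy + dz * dz) ** 0.5)
            if dmin < cutoff:
                count += 1
    return count
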