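"""Independent numerical oracles for the analytic forward models.

* EEG: truncated Legendre multipole series for the dipole potential in a
  homogeneous conducting sphere, coded directly from the interior Neumann
  series (independent of the closed-form summation used by the package).
* MEG: Geselowitz surface-integral formula — primary dipole field plus the
  volume-current contribution expressed through the surface potential —
  evaluated by centroid quadrature on a fine icosphere mesh.
"""

import numpy as np
from scipy.special import eval_legendre

from cghbm.constants import BRAIN_CONDUCTIVITY_S_PER_M, MU0


def legendre_prime(n, c, eps=1e-6):
    return (eval_legendre(n, c + eps) - eval_legendre(n, c - eps)) / (2 * eps)


def eeg_potential_series(sensors_m, r0_m, q, radius_m,
                         conductivity=BRAIN_CONDUCTIVITY_S_PER_M, n_max=300):
    """Surface potential of dipole q [Am] at r0 inside a homogeneous sphere."""
    R = radius_m
    r0 = np.linalg.norm(r0_m)
    r_hat = sensors_m / np.linalg.norm(sensors_m, axis=1, keepdims=True)
    if r0 < 1e-12:
        return 3.0 * (r_hat @ q) / (4 * np.pi * conductivity * R**2)
    r0_hat = r0_m / r0
    c = r_hat @ r0_hat
    a = q @ r0_hat
    b = (r_hat - c[:, None] * r0_hat) @ q
    out = np.zeros(len(sensors_m))
    for n in range(1, n_max + 1):
        out += ((2 * n + 1) / n * r0 ** (n - 1) / R ** (n + 1)
                * (n * eval_legendre(n, c) * a + legendre_prime(n, c) * b))
    return out / (4 * np.pi * conductivity)


def meg_field_geselowitz(sensors_m, r0_m, q, radius_m,
                         conductivity=BRAIN_CONDUCTIVITY_S_PER_M,
                         subdivisions=4):
    """B [T] at the sensors: primary dipole field + volume-current surface term.

    B(r) = B_inf(r) - (mu0 sigma / 4 pi) * sum_j V_j A_j n_j x (r - c_j)/|r - c_j|^3,
    with the surface potential V taken from the (series-verified) potential
    model on an icosphere quadrature mesh.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=radius_m)
    centers = mesh.triangles_center
    areas = mesh.area_faces
    normals = mesh.face_normals
    v_surf = eeg_potential_series(centers, r0_m, q, radius_m, conductivity)
    out = np.empty((len(sensors_m), 3))
    for i, rs in enumerate(sensors_m):
        dv = rs - r0_m
        b_inf = MU0 / (4 * np.pi) * np.cross(q, dv) / np.linalg.norm(dv) ** 3
        dd = rs[None, :] - centers
        d3 = np.linalg.norm(dd, axis=1) ** 3
        surf = (np.cross(normals, dd) / d3[:, None]
                * (v_surf * areas)[:, None]).sum(axis=0)
        out[i] = b_inf - MU0 * conductivity / (4 * np.pi) * surf
    return out
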