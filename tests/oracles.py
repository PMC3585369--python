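"""Independent numerical oracles for the analytic solvers.

An axisymmetric finite-volume discretization of the conduction problem
div(sigma grad phi) = -s on a sphere of radius R, on an (r, theta)
grid.  Symmetric configurations (current sources on the polar axis,
radial dipoles on the axis) are exactly axisymmetric, so the 2D solver
provides a fully independent check of the Legendre-series solutions.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve


class FDSphere:
    """Finite-volume Laplace/Poisson solver on an axisymmetric sphere.

    Cells are centred at r_i = (i + 1/2) dr, theta_j = (j + 1/2) dth
    with i < Nr, j < Nth; conductivity is piecewise-constant per
    radial shell.  Exterior boundary is insulating; currents are
    injected via the right-hand side (surface injection goes into the
    outermost cell at the requested angle).
    """

    def __init__(self, radii, sigmas, Nr=64, Nth=128):
        self.radii = np.asarray(radii, dtype=float)
        self.sigmas = np.asarray(sigmas, dtype=float)
        self.R = self.radii[-1]
        self.Nr, self.Nth = Nr, Nth
        self.dr = self.R / Nr
        self.dth = np.pi / Nth
        self.r_c = (np.arange(Nr) + 0.5) * self.dr
        self.th_c = (np.arange(Nth) + 0.5) * self.dth
        self.sig_c = self.sigmas[np.minimum(
            np.searchsorted(self.radii, self.r_c), len(self.radii) - 1)]
        self._build()

    def _idx(self, i, j):
        return i * self.Nth + j

    def _build(self):
        Nr, Nth, dr, dth = self.Nr, self.Nth, self.dr, self.dth
        rows, cols, vals = [], [], []

        def add(i1, j1, i2, j2, g):
            a, b = self._idx(i1, j1), self._idx(i2, j2)
            rows.extend([a, a, b, b])
            cols.extend([a, b, b, a])
            vals.extend([g, -g, g, -g])

        th_f = np.arange(Nth + 1) * dth
        cos_f = np.cos(th_f)
        # radial faces between (i, j) and (i+1, j)
        for i in range(Nr - 1):
            r_f = (i + 1) * dr
            s1, s2 = self.sig_c[i], self.sig_c[i + 1]
            sig_f = 2 * s1 * s2 / (s1 + s2)
            for j in range(Nth):
                area = 2 * np.pi * r_f ** 2 * (cos_f[j] - cos_f[j + 1])
                add(i, j, i + 1, j, sig_f * area / dr)
        # angular faces between (i, j) and (i, j+1)
        for i in range(Nr):
            r_lo, r_hi = i * dr, (i + 1) * dr
            ring = 2 * np.pi * (r_hi ** 2 - r_lo ** 2) / 2.0
            for j in range(Nth - 1):
                sin_f = np.sin(th_f[j + 1])
                area = ring * sin_f
                g = self.sig_c[i] * area / (self.r_c[i] * dth)
                add(i, j, i, j + 1, g)
        n = Nr * Nth
        A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        # pin the first cell to remove the Neumann null space
        A = A.tolil()
        A[0, :] = 0.0
        A[0, 0] = 1.0
        self.A = csr_matrix(A)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = rhs.copy()
        rhs[0] = 0.0
        phi = spsolve(self.A, rhs)
        return phi.reshape(self.Nr, self.Nth)

    # -- source helpers ----------------------------------------------------

    def rhs_surface_poles(self, current: float) -> np.ndarray:
        """+current injected at the north pole, -current at the south
        pole, through the outermost cells touching the axis."""
        rhs = np.zeros(self.Nr * self.Nth)
        rhs[self._idx(self.Nr - 1, 0)] += current
        rhs[self._idx(self.Nr - 1, self.Nth - 1)] -= current
        return rhs

    def rhs_axial_dipole(self, rq: float, moment: float) -> np.ndarray:
        """Radial current dipole on the +z axis at radius ``rq``,
        modeled as two monopoles one cell apart (moment = I * d)."""
        i0 = int(round(rq / self.dr))  # monopoles straddle rq symmetrically
        current = moment / self.dr
        rhs = np.zeros(self.Nr * self.Nth)
        rhs[self._idx(i0, 0)] += current       # + pole at (i0 + 1/2) dr
        rhs[self._idx(i0 - 1, 0)] -= current   # - pole at (i0 - 1/2) dr
        return rhs

    # -- geometry helpers --------------------------------------------------

    def cell_points(self, mask) -> np.ndarray:
        """3D coordinates (in the x-z plane) of cell centers selected by
        a boolean mask of shape (Nr, Nth)."""
        rr, tt = np.meshgrid(self.r_c, self.th_c, indexing="ij")
        pts = np.stack([rr * np.sin(tt), np.zeros_like(rr), rr * np.cos(tt)],
                       axis=-1)
        return pts[mask]

    def interior_mask(self, r_min_frac=0.25, r_max_frac=0.75,
                      axis_margin_deg=10.0) -> np.ndarray:
        """Cells away from boundaries, sources and the polar axis."""
        rr, tt = np.meshgrid(self.r_c, self.th_c, indexing="ij")
        margin = np.radians(axis_margin_deg)
        return ((rr >= r_min_frac * self.R) & (rr <= r_max_frac * self.R)
                & (tt > margin) & (tt < np.pi - margin))
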