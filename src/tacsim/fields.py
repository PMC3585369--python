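"""Quasi-static electric field of scalp current pads in a multi-shell sphere.

At stimulation frequencies the head behaves as a purely resistive
volume conductor, so the potential obeys Laplace's equation inside each
shell with continuity of potential and normal current density across
shell boundaries and an insulating exterior (except at the injection
sites).  For a point current source on the outer surface the solution
separates into a Legendre series; each harmonic order propagates
through the shells with a 2x2 transfer matrix, and the insulating
outer-boundary condition fixes the overall scale.  Stimulation pads
are discretized as grids of such point sources, and fields superpose
linearly.

The quantity that drives the neuronal populations is the component of
the cortical electric field along the local surface normal (parallel to
the pyramidal somato-dendritic axis), averaged per macro-region and
scaled by a calibration constant Lambda into a membrane-potential
offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (CorticalMesh, ElectrodeLayout, InvalidGeometryError,
                       Parcellation, ShellModel)

__all__ = [
    "StimulationConfig",
    "PointSourceSet",
    "FieldMap",
    "RegionFieldCoefficients",
    "FieldFormatError",
    "ConvergenceWarning",
    "pad_sources",
    "potential_multishell",
    "efield_at",
    "normal_field",
    "region_mean_field",
    "save_field_map",
    "load_field_map",
    "save_region_coefficients",
]


class FieldFormatError(ValueError):
    """Malformed field-map or coefficient file."""


class ConvergenceWarning(UserWarning):
    """Legendre series truncation may be insufficient."""


@dataclass(frozen=True)
class StimulationConfig:
    """Two-pad stimulation setup.

    Default: 7 x 5 cm pads centred on PO9 (anode) and PO10 (cathode)
    with 1.12 mA injected, each pad discretized as a 7 x 5 grid of
    point sources (``sources_per_pad`` = 35).
    """

    anode: str = "PO9"
    cathode: str = "PO10"
    current: float = 1.12e-3
    pad_width: float = 0.07
    pad_height: float = 0.05
    sources_per_pad: int = 35

    def __post_init__(self) -> None:
        if self.current <= 0:
            raise ValueError("current must be positive")
        if self.pad_width <= 0 or self.pad_height <= 0:
            raise ValueError("pad dimensions must be positive")
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")
        if self.sources_per_pad < 1:
            raise ValueError("sources_per_pad must be >= 1")


@dataclass
class PointSourceSet:
    """Point current sources on the scalp surface.

    ``currents`` sum to zero (charge conservation); positions lie on
    the outer shell.
    """

    positions: np.ndarray  # (n, 3) m
    currents: np.ndarray   # (n,) A

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.positions) != len(self.currents):
            raise ValueError("positions/currents length mismatch")
        total = np.abs(self.currents).sum()
        if total > 0 and abs(self.currents.sum()) > 1e-12 * total:
            raise ValueError("source currents must sum to zero")


@dataclass
class FieldMap:
    """Electric field vectors (V/m) sampled at cortical barycenters."""

    E: np.ndarray  # (n_triangles, 3)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 2 or self.E.shape[1] != 3:
            raise ValueError("E must be (n, 3)")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("field contains non-finite values")


@dataclass
class RegionFieldCoefficients:
    """Per-region mean normal field and derived membrane offsets.

    ``offsets[k] = lambda_ * mean_normal_field[k]`` with Lambda in
    mV per (V/m); the offsets feed the pyramidal membrane potential.
    """

    mean_normal_field: np.ndarray  # (n_regions,) V/m
    lambda_: float                 # mV per (V/m)
    offsets: np.ndarray            # (n_regions,) mV

    @classmethod
    def from_means(cls, means: np.ndarray, lambda_: float) -> "RegionFieldCoefficients":
        means = np.asarray(means, dtype=float)
        return cls(mean_normal_field=means, lambda_=float(lambda_),
                   offsets=float(lambda_) * means)

    def with_lambda(self, lambda_: float) -> "RegionFieldCoefficients":
        return RegionFieldCoefficients.from_means(self.mean_normal_field, lambda_)


# ---------------------------------------------------------------------------
# pad discretization
# ---------------------------------------------------------------------------


def _pad_grid(n: int, width: float, height: float) -> np.ndarray:
    """Grid offsets (n, 2) covering a width x height rectangle.

    The grid is chosen close to the pad aspect ratio; ``n = 1`` yields
    the pad center.
    """
    if n == 1:
        return np.zeros((1, 2))
    ncols = max(1, int(round(np.sqrt(n * width / height))))
    nrows = int(np.ceil(n / ncols))
    while ncols * nrows < n:
        nrows += 1
    xs = (np.arange(ncols) + 0.5) / ncols - 0.5
    ys = (np.arange(nrows) + 0.5) / nrows - 0.5
    grid = np.array([(x * width, y * height) for y in ys for x in xs])
    return grid[:n]


def pad_sources(config: StimulationConfig, layout: ElectrodeLayout,
                scalp_radius: float) -> PointSourceSet:
    """Discretize the two stimulation pads into weighted point sources.

    Each pad is a ``sources_per_pad``-point grid covering the pad
    footprint in the local tangent plane of its center electrode,
    projected radially onto the scalp sphere.  Anode points carry
    ``+current / sources_per_pad`` each; cathode points the negative.
    """
    positions, currents = [], []
    for name, sign in ((config.anode, +1.0), (config.cathode, -1.0)):
        center = layout.position(name)  # KeyError for unknown labels
        c_hat = center / np.linalg.norm(center)
        # local tangent basis: u along azimuth, v along meridian
        z = np.array([0.0, 0.0, 1.0])
        u = np.cross(z, c_hat)
        nu = np.linalg.norm(u)
        if nu < 1e-12:  # pad at the vertex: any tangent pair works
            u = np.array([1.0, 0.0, 0.0])
        else:
            u = u / nu
        v = np.cross(c_hat, u)
        for dx, dy in _pad_grid(config.sources_per_pad, config.pad_width, config.pad_height):
            p = center + dx * u + dy * v
            p = p / np.linalg.norm(p) * scalp_radius
            positions.append(p)
            currents.append(sign * config.current / config.sources_per_pad)
    return PointSourceSet(positions=np.array(positions), currents=np.array(currents))


# ---------------------------------------------------------------------------
# multi-shell Legendre series
# ---------------------------------------------------------------------------


def _shell_coefficients(shells: ShellModel, order: int) -> np.ndarray:
    """Per-order, per-shell radial coefficients for a unit surface source.

    For harmonic order n the potential in shell j is
    ``a[j] x^n + b[j] x^-(n+1)`` (x = r/R).  Starting from a regular
    solution (1, 0) in the innermost shell, coefficients propagate
    across each interface by continuity of potential and of normal
    current density; the insulating outer boundary with the source's
    surface harmonic fixes the overall scale for injected current
    I = 1 A:  sigma_N (n a_N - (n+1) b_N) = (2n+1) / (4 pi R).

    Returns an array (order, n_shells, 2) of (a, b), orders 1..order.
    """
    radii = np.asarray(shells.radii)
    sig = np.asarray(shells.conductivities)
    R = radii[-1]
    x_if = radii[:-1] / R  # interface radii, normalized
    n_shells = len(radii)
    out = np.empty((order, n_shells, 2))
    for n in range(1, order + 1):
        ab = np.empty((n_shells, 2))
        ab[0] = (1.0, 0.0)
        for j in range(n_shells - 1):
            x = x_if[j]
            a, b = ab[j]
            xn = x ** n
            xm = x ** (-(n + 1))
            # continuity of phi and of sigma * dphi/dr
            phi = a * xn + b * xm
            dphi = sig[j] * (n * a * xn / x - (n + 1) * b * xm / x)
            # solve [xn, xm; sig' n xn/x, -sig' (n+1) xm/x] [a', b'] = [phi, dphi]
            s2 = sig[j + 1]
            m11, m12 = xn, xm
            m21, m22 = s2 * n * xn / x, -s2 * (n + 1) * xm / x
            det = m11 * m22 - m12 * m21
            ab[j + 1, 0] = (phi * m22 - m12 * dphi) / det
            ab[j + 1, 1] = (m11 * dphi - phi * m21) / det
        aN, bN = ab[-1]
        scale = (2 * n + 1) / (4 * np.pi * R) / (sig[-1] * (n * aN - (n + 1) * bN))
        out[n - 1] = ab * scale
    return out


def _locate_shells(shells: ShellModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.linalg.norm(points, axis=1)
    R = shells.outer_radius
    if np.any(r > R * (1 + 1e-9)):
        raise InvalidGeometryError("evaluation point outside the head")
    idx = np.searchsorted(np.asarray(shells.radii), np.minimum(r, R))
    idx = np.minimum(idx, len(shells.radii) - 1)
    return r, idx


def _series_terms(shells: ShellModel, sources: PointSourceSet, points: np.ndarray,
                  order: int):
    """Common setup for potential/field evaluation.

    Yields per-order quantities; checks tail convergence afterwards.
    """
    coeffs = _shell_coefficients(shells, order)  # (order, n_shells, 2)
    r, shell_idx = _locate_shells(shells, points)
    R = shells.outer_radius
    x = r / R
    s_hat = sources.positions / np.linalg.norm(sources.positions, axis=1)[:, None]
    p_hat = np.where(r[:, None] > 0, points / np.maximum(r, 1e-300)[:, None],
                     np.array([0.0, 0.0, 1.0]))
    u = np.clip(p_hat @ s_hat.T, -1.0, 1.0)  # (n_pts, n_src)
    return coeffs, r, shell_idx, x, s_hat, p_hat, u


def _check_tail(term_norms: np.ndarray, tol: float, what: str) -> None:
    total = np.max(np.abs(term_norms).sum(axis=0))
    if total <= 0:
        return
    tail = np.max(np.abs(term_norms[-5:]).sum(axis=0))
    if tail > tol * total:
        warnings.warn(
            f"{what}: Legendre series tail ratio {tail / total:.2e} exceeds "
            f"{tol:.0e}; increase the series order", ConvergenceWarning)


def _radial_factor(a_n: np.ndarray, b_n: np.ndarray, xn: np.ndarray,
                   xm: np.ndarray) -> np.ndarray:
    # b is exactly 0 in the innermost shell, where x^-(n+1) may overflow
    return a_n * xn + np.where(b_n == 0.0, 0.0, b_n * xm)


def potential_multishell(shells: ShellModel, sources: PointSourceSet,
                         points: np.ndarray, order: int = 120,
                         tail_tol: float = 1e-8, zero_mean: bool = True) -> np.ndarray:
    """Electrostatic potential (V) at interior points.

    Truncated Legendre-series solution for surface point current
    sources on a multi-shell sphere, superposed over all sources.  The
    additive gauge is fixed by zero mean over the evaluation points;
    pass ``zero_mean=False`` to keep the raw series value (useful when
    differencing potentials across separate calls).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    coeffs, r, shell_idx, x, s_hat, p_hat, u = _series_terms(shells, sources, points, order)
    n_pts, n_src = u.shape
    phi = np.zeros((n_pts, n_src))
    P_prev = np.ones_like(u)   # P_0
    P_curr = u.copy()          # P_1
    a = coeffs[:, shell_idx, 0]  # (order, n_pts)
    b = coeffs[:, shell_idx, 1]
    tails = np.zeros((order, n_src))
    xn = x.copy()               # x^n
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xm = x ** -2.0          # x^-(n+1); only used where b != 0
        for n in range(1, order + 1):
            f = _radial_factor(a[n - 1], b[n - 1], xn, xm)
            term = f[:, None] * P_curr
            phi += term
            tails[n - 1] = np.abs(term).max(axis=0)
            xn *= x
            xm /= x
            P_next = ((2 * n + 1) * u * P_curr - n * P_prev) / (n + 1)
            P_prev, P_curr = P_curr, P_next
    _check_tail(tails, tail_tol, "potential_multishell")
    out = phi @ sources.currents
    return out - out.mean() if zero_mean else out


def efield_at(shells: ShellModel, sources: PointSourceSet, points: np.ndarray,
              order: int = 120, tail_tol: float = 1e-8) -> FieldMap:
    """Electric field E = -grad(phi) (V/m) at interior points.

    The gradient of each Legendre term is evaluated analytically:
    radial part from the derivative of the radial factor, angular part
    from d P_n(cos gamma)/d gamma, which is free of the 1/sin(gamma)
    singularity when written against the vector (u * r_hat - s_hat).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    coeffs, r, shell_idx, x, s_hat, p_hat, u = _series_terms(shells, sources, points, order)
    n_pts, n_src = u.shape
    R = shells.outer_radius
    E = np.zeros((n_pts, 3))
    P_prev = np.ones_like(u)
    P_curr = u.copy()
    dP_prev = np.zeros_like(u)  # P_0'
    dP_curr = np.ones_like(u)   # P_1'
    a = coeffs[:, shell_idx, 0]
    b = coeffs[:, shell_idx, 1]
    tails = np.zeros((order, n_src))
    xn = x.copy()
    inv_r = 1.0 / np.maximum(r, 1e-300)
    w = sources.currents
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xm = x ** -2.0          # x^-(n+1); only used where b != 0
        for n in range(1, order + 1):
            a_n, b_n = a[n - 1], b[n - 1]
            f = _radial_factor(a_n, b_n, xn, xm)
            fprime = _radial_factor(n * a_n, -(n + 1) * b_n, xn, xm) * inv_r  # d/dr
            # radial component: E_r = -f'(r) P_n(u), summed over sources
            rad = -(fprime[:, None] * P_curr) @ w
            # angular component: E_ang = +(1/r) f(r) P_n'(u) (u r_hat - s_hat)
            gw = (f * inv_r)[:, None] * dP_curr * w  # (n_pts, n_src)
            E += rad[:, None] * p_hat
            E += (gw * u).sum(axis=1)[:, None] * p_hat - gw @ s_hat
            tails[n - 1] = np.abs(fprime[:, None] * P_curr).max(axis=0)
            xn *= x
            xm /= x
            P_next = ((2 * n + 1) * u * P_curr - n * P_prev) / (n + 1)
            dP_next = ((2 * n + 1) * (P_curr + u * dP_curr) - n * dP_prev) / (n + 1)
            P_prev, P_curr = P_curr, P_next
            dP_prev, dP_curr = dP_curr, dP_next
    _check_tail(tails, tail_tol, "efield_at")
    return FieldMap(E=E)


def normal_field(field: FieldMap, mesh: CorticalMesh) -> np.ndarray:
    """Signed normal component E_n,i = E_i . n_hat_i (V/m) per triangle."""
    if len(field.E) != mesh.n_triangles:
        raise ValueError(
            f"field has {len(field.E)} rows but mesh has {mesh.n_triangles} triangles")
    return np.einsum("ij,ij->i", field.E, mesh.normals)


def region_mean_field(E_n: np.ndarray, parcellation: Parcellation,
                      lambda_: float) -> RegionFieldCoefficients:
    """Unweighted per-region mean of the normal field, scaled by Lambda.

    Returns the mean normal field per macro-region (V/m) and the
    membrane offsets Delta_k = Lambda * E_n_mean_k (mV).
    """
    E_n = np.asarray(E_n, dtype=float)
    if len(E_n) != len(parcellation.labels):
        raise ValueError("E_n length does not match parcellation")
    counts = np.bincount(parcellation.labels, minlength=parcellation.n_regions)
    if np.any(counts == 0):
        raise ValueError("parcellation has empty regions")
    sums = np.bincount(parcellation.labels, weights=E_n, minlength=parcellation.n_regions)
    return RegionFieldCoefficients.from_means(sums / counts, lambda_)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_field_map(field: FieldMap, path) -> None:
    """Write a field map as (triangle_index, Ex, Ey, Ez) rows."""
    with open(path, "w") as fh:
        for i, e in enumerate(field.E):
            fh.write(f"{i}\t{e[0]:.12g}\t{e[1]:.12g}\t{e[2]:.12g}\n")


def load_field_map(path) -> FieldMap:
    """Read a delimited field map (triangle_index, Ex, Ey, Ez).

    Indices must be 0-based, contiguous and unique; rows may appear in
    any order.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty files are reported below
            data = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise FieldFormatError(f"cannot parse field map {path}: {exc}") from exc
    if data.size == 0:
        raise FieldFormatError("empty field map file")
    if data.shape[1] != 4:
        raise FieldFormatError("expected 4 columns: index, Ex, Ey, Ez")
    idx = data[:, 0].astype(int)
    if np.any(data[:, 0] != idx):
        raise FieldFormatError("non-integer triangle indices")
    order = np.argsort(idx)
    if not np.array_equal(idx[order], np.arange(len(idx))):
        raise FieldFormatError("triangle indices must be 0-based, unique and gap-free")
    return FieldMap(E=data[order, 1:4])


def save_region_coefficients(coeffs: RegionFieldCoefficients, path) -> None:
    """Write (region_index, mean_normal_field, offset_mV) rows."""
    with open(path, "w") as fh:
        for k, (m, d) in enumerate(zip(coeffs.mean_normal_field, coeffs.offsets)):
            fh.write(f"{k}\t{m:.12g}\t{d:.12g}\n")
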