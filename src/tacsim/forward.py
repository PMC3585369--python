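"""EEG forward model: analytic multi-shell spherical leadfield, X = A * S.

Scalp potentials of cortical current dipoles are computed with the
truncated Legendre-series solution for a current dipole inside
concentric conducting shells (brain / skull / scalp by default).  For
each harmonic order the infinite-medium dipole expansion provides the
outgoing source term in the innermost shell; two independent radial
solutions are propagated across the shell interfaces by continuity of
potential and normal current density, and the insulating outer
boundary closes the system.  Region time courses are expanded onto the
dipole layer (each triangle of a macro-region carries its region's
time course scaled by the triangle's dipole moment) and multiplied by
the leadfield to give the electrode-space EEG record, X = A * S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import ConvergenceWarning
from .geometry import (DipoleLayer, ElectrodeLayout, InvalidGeometryError,
                       Parcellation, ShellModel)
from .neural import SimulationResult

__all__ = [
    "LeadfieldMatrix",
    "EEGRecord",
    "dipole_potential_multishell",
    "leadfield_3shell",
    "project_eeg",
    "rereference",
    "save_leadfield",
    "load_leadfield",
    "save_eeg",
    "load_eeg",
]


@dataclass
class LeadfieldMatrix:
    """Electrodes x dipoles gain matrix (V per A*m)."""

    values: np.ndarray
    electrode_names: tuple[str, ...]
    reference: str = "average"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.electrode_names = tuple(self.electrode_names)
        if self.values.shape[0] != len(self.electrode_names):
            raise ValueError("row count must equal electrode count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("leadfield contains non-finite values")


@dataclass
class EEGRecord:
    """Electrodes x samples EEG matrix (V)."""

    X: np.ndarray
    fs: float
    electrode_names: tuple[str, ...]
    reference: str = "average"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.electrode_names = tuple(self.electrode_names)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.electrode_names):
            raise ValueError("X must be (n_electrodes, n_samples)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("EEG contains non-finite values")

    def channel(self, name: str) -> np.ndarray:
        return self.X[self.electrode_names.index(name)]


# ---------------------------------------------------------------------------
# dipole series
# ---------------------------------------------------------------------------


def _dipole_shell_coefficients(shells: ShellModel, order: int) -> np.ndarray:
    """Per-order radial coefficients of the interior-dipole solution.

    The potential of order n in shell j is written
    ``beta_n (a_j x^n + b_j x^-(n+1))`` with x = r/R and ``beta_n`` the
    infinite-medium source coefficient.  The innermost shell has
    b_1 = 1 (the bare source) plus a regular correction a_1; the
    propagated pair must satisfy the insulating condition
    n a_N = (n+1) b_N at the outer boundary.

    Returns (order, n_shells, 2) of (a_j, b_j).
    """
    radii = np.asarray(shells.radii)
    sig = np.asarray(shells.conductivities)
    R = radii[-1]
    x_if = radii[:-1] / R
    n_shells = len(radii)
    out = np.empty((order, n_shells, 2))
    for n in range(1, order + 1):
        def propagate(ab0: tuple[float, float]) -> np.ndarray:
            ab = np.empty((n_shells, 2))
            ab[0] = ab0
            for j in range(n_shells - 1):
                x = x_if[j]
                a, b = ab[j]
                xn = x ** n
                xm = x ** (-(n + 1))
                phi = a * xn + b * xm
                dphi = sig[j] * (n * a * xn / x - (n + 1) * b * xm / x)
                s2 = sig[j + 1]
                det = xn * (-s2 * (n + 1) * xm / x) - xm * (s2 * n * xn / x)
                ab[j + 1, 0] = (phi * (-s2 * (n + 1) * xm / x) - xm * dphi) / det
                ab[j + 1, 1] = (xn * dphi - phi * (s2 * n * xn / x)) / det
            return ab

        hom = propagate((1.0, 0.0))
        src = propagate((0.0, 1.0))
        aN_h, bN_h = hom[-1]
        aN_s, bN_s = src[-1]
        alpha = -(n * aN_s - (n + 1) * bN_s) / (n * aN_h - (n + 1) * bN_h)
        out[n - 1] = src + alpha * hom
    return out


def dipole_potential_multishell(shells: ShellModel, dip_pos: np.ndarray,
                                dip_moment: np.ndarray, points: np.ndarray,
                                order: int = 60, tail_tol: float = 1e-8) -> np.ndarray:
    """Potential (V) of interior current dipoles, summed over dipoles.

    ``dip_pos``/``dip_moment`` are (m, 3) arrays (meters, A*m); dipoles
    must lie strictly inside the innermost shell.  ``points`` (p, 3)
    may sit anywhere in the head at radius >= every dipole radius (the
    exterior branch of the expansion is used).  Returns a (p, m) matrix
    of per-dipole potentials.
    """
    dip_pos = np.atleast_2d(np.asarray(dip_pos, dtype=float))
    dip_moment = np.atleast_2d(np.asarray(dip_moment, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    radii = np.asarray(shells.radii)
    sig1 = shells.conductivities[0]
    R = shells.outer_radius

    rq = np.linalg.norm(dip_pos, axis=1)
    if np.any(rq >= radii[0]):
        raise InvalidGeometryError("dipoles must lie strictly inside the innermost shell")
    r = np.linalg.norm(points, axis=1)
    if np.any(r > R * (1 + 1e-9)):
        raise InvalidGeometryError("evaluation point outside the head")
    if np.any(r[:, None] < rq[None, :] * (1 - 1e-12)):
        raise InvalidGeometryError("evaluation points must lie outside the dipole radii")
    shell_idx = np.minimum(np.searchsorted(radii, np.minimum(r, R)), len(radii) - 1)

    coeffs = _dipole_shell_coefficients(shells, order)
    q_hat = dip_pos / np.maximum(rq, 1e-300)[:, None]
    p_hat = points / np.maximum(r, 1e-300)[:, None]
    u = np.clip(p_hat @ q_hat.T, -1.0, 1.0)            # (p, m)
    q_r = np.einsum("mj,mj->m", dip_moment, q_hat)     # radial moment
    # w = q . (p_hat - u q_hat): moment component toward the observation point
    w = (dip_moment @ p_hat.T).T - u * q_r[None, :]    # (p, m)

    x = r / R                                          # (p,)
    ratio_R = rq / R                                   # (m,)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_r = np.where(r[:, None] > 0, rq[None, :] / r[:, None], 0.0)  # (p, m)
    ratio_r = np.minimum(ratio_r, 1.0)
    pref = 1.0 / (4.0 * np.pi * sig1 * R * R)

    phi = np.zeros_like(u)
    P_prev = np.ones_like(u)
    P_curr = u.copy()
    dP_prev = np.zeros_like(u)
    dP_curr = np.ones_like(u)
    t1 = x[:, None] * np.ones_like(ratio_R)[None, :]   # (rq/R)^(n-1) x^n
    t2 = np.ones_like(u) / np.maximum(x, 1e-300)[:, None] ** 2  # (rq/r)^(n-1) x^-2
    tails = np.zeros(order)
    a_pts = coeffs[:, shell_idx, 0]                    # (order, p)
    b_pts = coeffs[:, shell_idx, 1]
    for n in range(1, order + 1):
        ang = n * q_r[None, :] * P_curr + w * dP_curr  # (p, m)
        f = a_pts[n - 1][:, None] * t1 + b_pts[n - 1][:, None] * t2
        term = pref * f * ang
        phi += term
        tails[n - 1] = np.abs(term).sum(axis=1).max()
        t1 *= ratio_R[None, :] * x[:, None]
        t2 *= ratio_r
        P_next = ((2 * n + 1) * u * P_curr - n * P_prev) / (n + 1)
        dP_next = ((2 * n + 1) * (P_curr + u * dP_curr) - n * dP_prev) / (n + 1)
        P_prev, P_curr = P_curr, P_next
        dP_prev, dP_curr = dP_curr, dP_next
    total = np.abs(phi).sum(axis=1).max()
    if total > 0 and tails[-5:].max() > tail_tol * total:
        warnings.warn("dipole Legendre series tail not converged; increase order",
                      ConvergenceWarning)
    return phi


def leadfield_3shell(shells3: ShellModel, layout: ElectrodeLayout,
                     dipoles: DipoleLayer, order: int = 150,
                     reference: str = "average") -> LeadfieldMatrix:
    """Analytic spherical leadfield for unit dipoles (V per A*m).

    ``shells3`` is the EEG head model (exactly 3 shells: brain, skull,
    scalp); electrodes are taken at their layout positions on the
    scalp.  Columns correspond to the dipole layer's triangles, for a
    unit-moment dipole along each triangle normal.  Average-referenced
    by default.
    """
    if len(shells3.radii) != 3:
        raise InvalidGeometryError(
            f"EEG head model must have exactly 3 shells, got {len(shells3.radii)}")
    A = dipole_potential_multishell(shells3, dipoles.positions,
                                    dipoles.orientations, layout.positions,
                                    order=order)
    lf = LeadfieldMatrix(values=A, electrode_names=layout.names, reference="raw")
    if reference == "average":
        return rereference(lf, "average")
    return lf


# ---------------------------------------------------------------------------
# projection and referencing
# ---------------------------------------------------------------------------


def project_eeg(A: LeadfieldMatrix, parcellation: Parcellation,
                dipoles: DipoleLayer, sim: SimulationResult) -> EEGRecord:
    """Project region time courses to scalp electrodes: X = A * S_dipole.

    Every triangle of a macro-region carries the region's time course
    scaled by its dipole moment; the expansion collapses to a compact
    (electrodes x regions) matrix before the time-domain product.
    """
    if A.values.shape[1] != len(dipoles):
        raise ValueError("leadfield columns must match dipole count")
    if len(parcellation.labels) != len(dipoles):
        raise ValueError("parcellation triangle count must match dipole count")
    if sim.S.shape[0] != parcellation.n_regions:
        raise ValueError(
            f"simulation has {sim.S.shape[0]} regions, parcellation "
            f"{parcellation.n_regions}")
    weighted = A.values * dipoles.moments[None, :]
    # region gain: sum of moment-weighted leadfield columns per region
    n_el = weighted.shape[0]
    region_gain = np.zeros((n_el, parcellation.n_regions))
    np.add.at(region_gain.T, parcellation.labels, weighted.T)
    X = region_gain @ sim.S
    return EEGRecord(X=X, fs=sim.fs, electrode_names=A.electrode_names,
                     reference=A.reference)


def rereference(data, scheme: str):
    """Re-reference a leadfield or EEG record.

    ``scheme`` is ``"average"`` or an electrode label; subtracts the
    reference signal from every row.  Average referencing is
    idempotent; inter-electrode differences are invariant.
    """
    if isinstance(data, LeadfieldMatrix):
        values = data.values
    elif isinstance(data, EEGRecord):
        values = data.X
    else:
        raise TypeError("expected LeadfieldMatrix or EEGRecord")
    if scheme == "average":
        ref = values.mean(axis=0, keepdims=True)
    else:
        if scheme not in data.electrode_names:
            raise KeyError(f"unknown reference electrode {scheme!r}")
        ref = values[data.electrode_names.index(scheme)][None, :]
    new = values - ref
    if isinstance(data, LeadfieldMatrix):
        return LeadfieldMatrix(values=new, electrode_names=data.electrode_names,
                               reference=scheme)
    return EEGRecord(X=new, fs=data.fs, electrode_names=data.electrode_names,
                     reference=scheme)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_leadfield(lf: LeadfieldMatrix, path) -> None:
    """Delimited matrix with a header row of electrode names (rows =
    electrodes, columns = dipoles)."""
    with open(path, "w") as fh:
        fh.write("\t".join(lf.electrode_names) + "\n")
        fh.write(f"# reference: {lf.reference}\n")
        np.savetxt(fh, lf.values, delimiter="\t")


def load_leadfield(path) -> LeadfieldMatrix:
    with open(path) as fh:
        names = tuple(fh.readline().split())
        second = fh.readline()
        reference = "average"
        if second.startswith("#"):
            reference = second.split(":", 1)[1].strip()
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
        else:
            first_row = np.fromstring(second, sep="\t")
            rest = np.loadtxt(fh, delimiter="\t", ndmin=2)
            values = np.vstack([first_row, rest]) if rest.size else first_row[None, :]
    return LeadfieldMatrix(values=values, electrode_names=names, reference=reference)


def save_eeg(eeg: EEGRecord, path) -> None:
    """Delimited text: header of channel labels, one row per sample (V)."""
    with open(path, "w") as fh:
        fh.write("\t".join(eeg.electrode_names) + "\n")
        fh.write(f"# fs: {eeg.fs} Hz, reference: {eeg.reference}\n")
        np.savetxt(fh, eeg.X.T, delimiter="\t")


def load_eeg(path) -> EEGRecord:
    with open(path) as fh:
        names = tuple(fh.readline().split())
        meta = fh.readline()
        fs = float(meta.split("fs:")[1].split("Hz")[0])
        reference = meta.split("reference:")[1].strip()
        X = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return EEGRecord(X=X, fs=fs, electrode_names=names, reference=reference)
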