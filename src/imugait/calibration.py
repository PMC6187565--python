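"""Sensor calibration by constrained ellipsoid fitting.

A triad with small inter-axis misalignment measures, at rest, a gravity
vector distorted by the non-orthogonality matrix

    E ≈ [[1, 0, alpha],
         [beta, 1, gamma],
         [0, 0, 1]]

so the locus of multi-orientation static accelerometer samples is an
ellipsoid ``(x - b)ᵀ E⁻ᵀE⁻¹ (x - b) = g²`` rather than a sphere of radius
g (b is an additive bias).  Fitting that ellipsoid and factoring its
quadratic form recovers the misalignment angles analytically; the same fit
applied to a figure-eight magnetometer sweep yields the hard-iron offset
(ellipsoid centre) and soft-iron correction (ellipsoid-to-sphere map).

The fit solves the quadric-coefficient least-squares problem under the
ellipsoid-guaranteeing quadratic constraint ``4B - A² = 1`` (A, B the first
two symmetric invariants of the quadratic form), i.e. the generalized
eigenproblem ``CᵀC O = λ M O`` with ``OᵀMO = 1`` — the constraint matrix M
acts on the six second-order coefficients only, so the problem is reduced
to a 6x6 eigenproblem by Schur complement, which is guaranteed to have
exactly one admissible eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import FitError, InvalidInputError

__all__ = [
    "NonOrthoAngles",
    "EllipsoidModel",
    "MagCalibration",
    "AccelCalibration",
    "nonortho_matrix",
    "fit_ellipsoid",
    "ellipsoid_geometry",
    "estimate_nonortho_angles",
    "correct_accel",
    "calibrate_accelerometer",
    "apply_accel_calibration",
    "calibrate_magnetometer",
    "apply_mag_calibration",
]

MAX_NONORTHO_RAD = 0.1  # small-angle validity limit (~5.7 deg)


class NonOrthoAngles(NamedTuple):
    """Small misalignment angles (rad) of the accelerometer triad."""

    alpha: float
    beta: float
    gamma: float


def nonortho_matrix(angles: NonOrthoAngles) -> np.ndarray:
    """Small-angle forward distortion matrix E (true -> measured)."""
    a, b, g = angles
    return np.array([[1.0, 0.0, a], [b, 1.0, g], [0.0, 0.0, 1.0]])


def nonortho_inverse(angles: NonOrthoAngles) -> np.ndarray:
    """Exact inverse of the small-angle E (unit triangular-like structure)."""
    a, b, g = angles
    return np.array([[1.0, 0.0, -a], [-b, 1.0, a * b - g], [0.0, 0.0, 1.0]])


# Quadratic form of the invariant 4B - A^2 on (a, b, c, f, g, h):
# 2(ab+bc+ca) - (a^2+b^2+c^2) - 4(f^2+g^2+h^2)
_M0 = np.array(
    [
        [-1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        [1.0, -1.0, 1.0, 0.0, 0.0, 0.0],
        [1.0, 1.0, -1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, -4.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, -4.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, -4.0],
    ]
)


@dataclass
class EllipsoidModel:
    """10-coefficient quadric  ax²+by²+cz²+2fyz+2gxz+2hxy+2px+2qy+2rz+d = 0.

    ``coeffs`` is ordered (a, b, c, f, g, h, p, q, r, d) and normalised so
    the ellipsoid constraint quadratic form equals one and a+b+c > 0.
    Derived geometry (centre, semi-axis lengths, orthonormal axes) is filled
    by :func:`ellipsoid_geometry`.
    """

    coeffs: np.ndarray
    S: np.ndarray = field(init=False)
    T: np.ndarray = field(init=False)
    center: np.ndarray | None = None
    radii: np.ndarray | None = None
    axes: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        a, b, c, f, g, h, p, q, r, d = self.coeffs
        self.S = np.array([[a, h, g], [h, b, f], [g, f, c]])
        self.T = 2.0 * np.array([p, q, r])

    @property
    def constraint_value(self) -> float:
        """OᵀMO — equals 1 for a fit satisfying the ellipsoid constraint."""
        a1 = self.coeffs[:6]
        return float(a1 @ _M0 @ a1)

    def quadratic_form(self) -> Tuple[np.ndarray, float]:
        """Return (Q, 1) with (x-center)ᵀ Q (x-center) = 1."""
        center, _, _ = ellipsoid_geometry(self)
        bvec = self.T / 2.0
        k = float(self.coeffs[9] + bvec @ center)
        if k >= 0:
            raise FitError("quadric is not a real ellipsoid (non-negative residual constant)")
        return self.S / (-k), 1.0


def _design_matrix(points: np.ndarray) -> np.ndarray:
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return np.column_stack(
        [x * x, y * y, z * z, 2 * y * z, 2 * x * z, 2 * x * y, 2 * x, 2 * y, 2 * z, np.ones_like(x)]
    )


def fit_ellipsoid(points: np.ndarray) -> EllipsoidModel:
    """Constrained least-squares ellipsoid fit to a 3-D point cloud.

    Parameters
    ----------
    points : (n, 3) array, n >= 10, non-coplanar with adequate orientation
        coverage.

    Returns
    -------
    EllipsoidModel with geometry fields populated.

    Raises
    ------
    FitError if the cloud is degenerate or no eigenvector satisfies the
    ellipsoid condition 4B - A² > 0.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise InvalidInputError(f"points must be (n, 3), got {points.shape}")
    if points.shape[0] < 10:
        raise InvalidInputError(f"need at least 10 points, got {points.shape[0]}")
    if not np.all(np.isfinite(points)):
        raise InvalidInputError("points contain non-finite values")

    D = _design_matrix(points)
    G = D.T @ D  # CᵀC of the constraint formulation
    S11 = G[:6, :6]
    S12 = G[:6, 6:]
    S22 = G[6:, 6:]
    try:
        # Schur complement onto the six quadratic coefficients
        T22 = -np.linalg.solve(S22, S12.T)
    except np.linalg.LinAlgError as exc:
        raise FitError("degenerate point cloud: rank-deficient normal equations") from exc
    reduced = np.linalg.solve(_M0, S11 + S12 @ T22)
    eigvals, eigvecs = np.linalg.eig(reduced)

    # The constraint quadratic form 4B - A² is positive only for axis ratios
    # below sqrt(3); wider (but still genuine) ellipsoids appear in the
    # spectrum on the infeasible side of the constraint, with a (near-)zero
    # eigenvalue.  Candidates are therefore screened by the defining
    # ellipsoid property — positive-definite quadratic form — and ranked by
    # normalised algebraic residual; the constraint scaling OᵀMO = 1 is then
    # applied whenever it is feasible (always, in the near-spherical sensor
    # calibration regime).
    best = None
    best_res = np.inf
    for i in range(6):
        if abs(eigvals[i].imag) > 1e-8 * (1.0 + abs(eigvals[i].real)):
            continue
        v = np.real(eigvecs[:, i])
        v = v / np.linalg.norm(v)
        if v[:3].sum() < 0:
            v = -v
        if np.any(np.linalg.eigvalsh(np.array(
            [[v[0], v[5], v[4]], [v[5], v[1], v[3]], [v[4], v[3], v[2]]]
        )) <= 0):
            continue  # quadratic form not PD: not an ellipsoid
        O = np.concatenate([v, T22 @ v])
        res = float(np.linalg.norm(D @ O) / np.linalg.norm(O))
        if res < best_res:
            best_res = res
            best = O
    if best is None:
        raise FitError(
            "no admissible eigenvector: point cloud does not determine an ellipsoid "
            "(coplanar points or insufficient orientation coverage)"
        )
    quad = float(best[:6] @ _M0 @ best[:6])
    if quad > 0:
        best = best / np.sqrt(quad)  # enforce OᵀMO = 1
    model = EllipsoidModel(coeffs=best)
    ellipsoid_geometry(model)  # populate + validate geometry
    return model


def ellipsoid_geometry(model: EllipsoidModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre, semi-axis lengths and orthonormal axes of a fitted quadric.

    The centre is the stationary point ``-S⁻¹ T/2`` of the quadric; radii and
    axes come from the eigendecomposition ``S = N D Nᵀ`` after translating
    the quadric to its centre, which puts it in the standard
    ``x²/a′² + y²/b′² + z²/c′² = 1`` form.  Axes are permuted/sign-fixed to
    the closest-to-identity assignment against the nominal sensor frame
    (misalignments are small by assumption, so this resolves the inherent
    axis-labelling ambiguity deterministically).
    """
    if model.center is not None and model.radii is not None and model.axes is not None:
        return model.center, model.radii, model.axes
    S = model.S
    bvec = model.T / 2.0
    try:
        center = np.linalg.solve(S, -bvec)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular quadratic form: cannot locate ellipsoid centre") from exc
    k = float(model.coeffs[9] + bvec @ center)
    if k >= 0:
        raise FitError("quadric has no real ellipsoid surface")
    lam, N = np.linalg.eigh(S)
    if np.any(lam <= 0):
        raise FitError("quadratic form is not positive definite: not an ellipsoid")
    # closest-to-identity axis assignment (max total |cosine| matching)
    _, perm = linear_sum_assignment(-np.abs(N))
    N = N[:, perm]
    lam = lam[perm]
    signs = np.sign(np.diag(N))
    signs[signs == 0] = 1.0
    N = N * signs
    radii = np.sqrt(-k / lam)
    model.center = center
    model.radii = radii
    model.axes = N
    model.eigenvalues = lam
    return center, radii, model.axes


def estimate_nonortho_angles(model: EllipsoidModel, g_mag: float = 9.81) -> NonOrthoAngles:
    """Extract triad misalignment angles from a fitted static-accel ellipsoid.

    Identifying the fitted quadratic form with the distortion model gives
    ``(g² Q)⁻¹ = E Eᵀ``; with the sparse small-angle structure of E, the
    entries of ``P = E Eᵀ`` (normalised by P[2,2] = 1, which also removes any
    residual gravity-scale error) yield the angles in closed form:
    ``alpha = P[0,2]``, ``gamma = P[1,2]``, ``beta = P[0,1] - alpha·gamma``.
    """
    if g_mag <= 0:
        raise InvalidInputError("gravity magnitude must be positive")
    Q, _ = model.quadratic_form()
    try:
        P = np.linalg.inv(g_mag * g_mag * Q)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular quadratic form in angle extraction") from exc
    P = P / P[2, 2]
    alpha = float(P[0, 2])
    gamma = float(P[1, 2])
    beta = float(P[0, 1] - alpha * gamma)
    angles = NonOrthoAngles(alpha, beta, gamma)
    if max(abs(a) for a in angles) >= MAX_NONORTHO_RAD:
        raise FitError(
            f"extracted angles {tuple(np.degrees(angles))} deg exceed the small-angle "
            "validity limit; calibration data are inconsistent with the misalignment model"
        )
    return angles


def correct_accel(raw: np.ndarray, angles: NonOrthoAngles) -> np.ndarray:
    """Undo triad non-orthogonality: apply E⁻¹ to raw samples ((3,) or (n,3))."""
    raw = np.asarray(raw, dtype=float)
    Einv = nonortho_inverse(angles)
    if raw.ndim == 1:
        return Einv @ raw
    return raw @ Einv.T


@dataclass
class AccelCalibration:
    """Full accelerometer correction: additive bias plus misalignment angles."""

    angles: NonOrthoAngles
    bias: np.ndarray
    g_mag: float = 9.81


def calibrate_accelerometer(points: np.ndarray, g_mag: float = 9.81) -> AccelCalibration:
    """Fit a multi-orientation static cloud and return bias + angles."""
    model = fit_ellipsoid(points)
    center, _, _ = ellipsoid_geometry(model)
    angles = estimate_nonortho_angles(model, g_mag=g_mag)
    return AccelCalibration(angles=angles, bias=center, g_mag=g_mag)


def apply_accel_calibration(raw: np.ndarray, cal: AccelCalibration) -> np.ndarray:
    raw = np.asarray(raw, dtype=float)
    return correct_accel(raw - cal.bias, cal.angles)


@dataclass
class MagCalibration:
    """Hard-iron offset and symmetric positive-definite soft-iron correction."""

    offset: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise InvalidInputError("soft-iron correction matrix must be symmetric")

    @classmethod
    def identity(cls) -> "MagCalibration":
        return cls(offset=np.zeros(3), matrix=np.eye(3))


def calibrate_magnetometer(points: np.ndarray) -> MagCalibration:
    """Hard/soft-iron calibration from a figure-eight orientation sweep.

    The distorted field locus is an ellipsoid; its centre is the hard-iron
    offset and the symmetric square root of its quadratic form, rescaled to
    the mean field magnitude (geometric mean of the semi-axes), maps the
    ellipsoid back onto a sphere.  Choosing the *symmetric* PD square root
    pins down the rotational ambiguity of the soft-iron factorisation.
    """
    model = fit_ellipsoid(points)
    center, radii, _ = ellipsoid_geometry(model)
    Q, _ = model.quadratic_form()
    lam, V = np.linalg.eigh(Q)
    if np.any(lam <= 0):
        raise FitError("magnetometer sweep does not determine an ellipsoid")
    W = V @ np.diag(np.sqrt(lam)) @ V.T  # maps ellipsoid to the unit sphere
    field = float(np.prod(radii) ** (1.0 / 3.0))
    return MagCalibration(offset=center, matrix=field * W)


def apply_mag_calibration(raw: np.ndarray, cal: MagCalibration) -> np.ndarray:
    """matrix · (raw − offset) for a single sample (3,) or a stream (n, 3)."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        return cal.matrix @ (raw - cal.offset)
    return (raw - cal.offset) @ cal.matrix.T
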