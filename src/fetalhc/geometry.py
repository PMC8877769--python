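"""Ellipse geometry: perimeter formulas, conic fitting, rescaling, mm conversion.

Conventions (used everywhere in the package)
--------------------------------------------
* Image coordinates: ``x`` to the right (columns), ``y`` down (rows),
  pixel centers at integer coordinates, 0-based.
* ``EllipseParams.theta`` is the orientation of the major axis measured
  from the +x axis, in degrees, normalized to ``[0, 180)``.  For circles
  (``a == b``) theta is reported as 0 by convention and should not be
  compared.
* Semi-axes satisfy ``a >= b > 0``; the constructor canonicalizes a
  swapped pair by rotating theta by 90 degrees.

The head circumference of an ellipse with semi-axes ``a`` and ``b`` is
approximated by Ramanujan's closed form

    h  = (a - b)^2 / (a + b)^2
    HC = pi (a + b) (1 + 3h / (10 + sqrt(4 - 3h)))

whose relative error is below 1e-6 for axis ratios ``b/a >= 0.2``.  The
exact perimeter (adaptive quadrature of the arc-length integral) is kept
alongside as the reference, so the approximation error stays measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .errors import (
    DegenerateGeometryError,
    InvalidParameterError,
    NonEllipseError,
    TooFewPointsError,
)

__all__ = [
    "EllipseParams",
    "PixelSpacing",
    "ramanujan_circumference",
    "exact_perimeter",
    "fit_ellipse",
    "rescale_ellipse",
    "hc_mm",
    "ellipse_boundary_points",
]


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center (cx, cy), semi-axes a >= b, orientation theta.

    theta is in degrees in [0, 180), measured from the +x axis toward +y
    (clockwise on screen with y pointing down).
    """

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "a", "b", "theta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        a, b, theta = self.a, self.b, self.theta
        if a <= 0 or b <= 0:
            raise InvalidParameterError(f"semi-axes must be positive, got a={a}, b={b}")
        if a < b:
            a, b = b, a
            theta = theta + 90.0
        if a == b:
            theta = 0.0  # orientation undefined for circles
        theta = theta % 180.0
        object.__setattr__(self, "a", float(a))
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "theta", float(theta))
        object.__setattr__(self, "cx", float(self.cx))
        object.__setattr__(self, "cy", float(self.cy))

    # -- conic form ---------------------------------------------------------
    def conic(self) -> np.ndarray:
        """Implicit conic coefficients (A, B, C, D, E, F) with
        A x^2 + B x y + C y^2 + D x + E y + F = 0 and F scaled so the
        quadratic form is normalized (A + C = 1 is *not* imposed; the
        coefficient vector is unique up to scale)."""
        t = math.radians(self.theta)
        c, s = math.cos(t), math.sin(t)
        a2, b2 = self.a**2, self.b**2
        # sum over the two principal directions: (u.x)^2/a^2 + (v.x)^2/b^2 = 1
        A = c * c / a2 + s * s / b2
        C = s * s / a2 + c * c / b2
        B = 2 * c * s * (1 / a2 - 1 / b2)
        # translate center
        D = -2 * A * self.cx - B * self.cy
        E = -2 * C * self.cy - B * self.cx
        F = (
            A * self.cx**2
            + B * self.cx * self.cy
            + C * self.cy**2
            - 1.0
        )
        return np.array([A, B, C, D, E, F], dtype=float)

    def isoclose(self, other: "EllipseParams", tol: float = 1e-9) -> bool:
        """Parameter-wise closeness; theta compared modulo 180 and ignored
        for near-circles."""
        geom = (
            abs(self.cx - other.cx) <= tol
            and abs(self.cy - other.cy) <= tol
            and abs(self.a - other.a) <= tol
            and abs(self.b - other.b) <= tol
        )
        if not geom:
            return False
        if self.a - self.b <= tol * max(1.0, self.a):
            return True
        d = abs(self.theta - other.theta) % 180.0
        return min(d, 180.0 - d) <= tol / max(self.a, 1.0) * 180.0 / math.pi or min(d, 180.0 - d) <= tol


@dataclass(frozen=True)
class PixelSpacing:
    """Physical size of one pixel along x and y, in mm/pixel."""

    sx: float
    sy: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sy = self.sy if self.sy is not None else self.sx
        object.__setattr__(self, "sy", float(sy))
        object.__setattr__(self, "sx", float(self.sx))
        if not (self.sx > 0 and self.sy > 0) or not (
            math.isfinite(self.sx) and math.isfinite(self.sy)
        ):
            raise InvalidParameterError(
                f"pixel spacing must be positive, got sx={self.sx}, sy={self.sy}"
            )

    @property
    def isotropic(self) -> bool:
        return self.sx == self.sy


def _check_axes(a: float, b: float) -> None:
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        raise InvalidParameterError(f"semi-axes must be positive finite, got a={a}, b={b}")


def ramanujan_circumference(a: float, b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter.

    Symmetric in (a, b); exact for circles (returns 2*pi*a when a == b);
    relative error <= 1e-6 for axis ratio >= 0.2.
    """
    _check_axes(a, b)
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def exact_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter by adaptive quadrature of the arc-length integral.

    P = 4 * int_0^{pi/2} sqrt(a^2 cos^2 t + b^2 sin^2 t) dt, evaluated with
    scipy's adaptive quadrature at tight tolerance (relative ~1e-12).
    """
    _check_axes(a, b)
    hi, lo = (a, b) if a >= b else (b, a)
    val, _err = integrate.quad(
        lambda t: math.hypot(hi * math.cos(t), lo * math.sin(t)),
        0.0,
        math.pi / 2.0,
        epsabs=1e-12 * hi,
        epsrel=1e-12,
        limit=200,
    )
    return 4.0 * val


def ellipse_boundary_points(e: EllipseParams, n: int = 360) -> np.ndarray:
    """``n`` points sampled on the ellipse boundary, shape (n, 2), columns (x, y)."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    th = math.radians(e.theta)
    c, s = math.cos(th), math.sin(th)
    u = e.a * np.cos(t)
    v = e.b * np.sin(t)
    x = e.cx + u * c - v * s
    y = e.cy + u * s + v * c
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Direct least-squares conic fitting (Halir & Flusser's numerically stable
# formulation of Fitzgibbon's ellipse-specific fit).
# ---------------------------------------------------------------------------

def _params_from_conic(coef: np.ndarray) -> EllipseParams:
    A, B, C, D, E, F = (float(v) for v in coef)
    disc = B * B - 4.0 * A * C
    if not np.all(np.isfinite(coef)) or disc >= 0:
        raise NonEllipseError(f"conic is not an ellipse (discriminant {disc:g})")
    # center: gradient of the quadratic form vanishes
    M = np.array([[2.0 * A, B], [B, 2.0 * C]])
    cx, cy = np.linalg.solve(M, [-D, -E])
    # constant term after recentering
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    axes2 = -Fc / lam
    if not np.all(axes2 > 0):
        raise NonEllipseError("conic has no real elliptical axes")
    axes = np.sqrt(axes2)
    # major axis corresponds to the larger semi-axis
    i_major = int(np.argmax(axes))
    vx, vy = vec[:, i_major]
    theta = math.degrees(math.atan2(vy, vx)) % 180.0
    a, b = float(np.max(axes)), float(np.min(axes))
    return EllipseParams(cx=float(cx), cy=float(cy), a=a, b=b, theta=theta)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Fit an ellipse to >= 5 points by direct least squares.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Pixel coordinates, columns (x, y).

    Raises
    ------
    TooFewPointsError
        Fewer than 5 points.
    DegenerateGeometryError
        Collinear / rank-deficient point configuration.
    NonEllipseError
        The best-fit conic is not an ellipse (should not happen with the
        ellipse-specific constraint, but guarded against numerically).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError(f"points must have shape (n, 2), got {pts.shape}")
    if pts.shape[0] < 5:
        raise TooFewPointsError(f"need >= 5 points, got {pts.shape[0]}")
    # condition: center and scale
    mean = pts.mean(axis=0)
    centered = pts - mean
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-10:
        raise DegenerateGeometryError("points are collinear or coincident")
    scale = centered.std()
    x = centered[:, 0] / scale
    y = centered[:, 1] / scale

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("degenerate point configuration") from exc
    Mmat = S1 + S2 @ T
    # premultiply by inv(C1), C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    Mred = np.array([Mmat[2] / 2.0, -Mmat[1], Mmat[0] / 2.0])
    eigval, eigvec = np.linalg.eig(Mred)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where(np.isreal(eigval) & (cond > 0))[0]
    if good.size == 0:
        raise NonEllipseError("no ellipse-admissible eigenvector in direct fit")
    a1 = np.real(eigvec[:, good[0]])
    coef_n = np.concatenate([a1, T @ a1])  # (A,B,C,D,E,F) in normalized frame
    # undo scaling: x = (X - mx)/s
    A, B, C, D, E, F = coef_n
    s = scale
    mx, my = mean
    Ao = A / s**2
    Bo = B / s**2
    Co = C / s**2
    Do = -2 * A * mx / s**2 - B * my / s**2 + D / s
    Eo = -2 * C * my / s**2 - B * mx / s**2 + E / s
    Fo = (
        A * mx**2 / s**2
        + B * mx * my / s**2
        + C * my**2 / s**2
        - D * mx / s
        - E * my / s
        + F
    )
    return _params_from_conic(np.array([Ao, Bo, Co, Do, Eo, Fo]))


def rescale_ellipse(e: EllipseParams, fx: float, fy: float) -> EllipseParams:
    """Exact image of ``e`` under the diagonal map (x, y) -> (fx*x, fy*y).

    Used to map an ellipse fitted on a resized grid back to the original
    grid (or to apply anisotropic pixel spacing).  The implicit conic is
    transformed exactly and the geometric parameters re-extracted.
    """
    if not (fx > 0 and fy > 0) or not (math.isfinite(fx) and math.isfinite(fy)):
        raise InvalidParameterError(f"scale factors must be positive, got fx={fx}, fy={fy}")
    A, B, C, D, E, F = e.conic()
    coef = np.array(
        [A / fx**2, B / (fx * fy), C / fy**2, D / fx, E / fy, F]
    )
    return _params_from_conic(coef)


def hc_mm(e: EllipseParams, spacing: PixelSpacing) -> float:
    """Head circumference in mm: Ramanujan perimeter of the physical ellipse.

    Isotropic spacing scales both axes; anisotropic spacing maps the ellipse
    through the exact diagonal transform first (the image of an ellipse under
    an axis-aligned stretch is again an ellipse, generally with a different
    orientation).
    """
    if spacing.isotropic:
        return ramanujan_circumference(e.a * spacing.sx, e.b * spacing.sx)
    phys = rescale_ellipse(e, spacing.sx, spacing.sy)
    return ramanujan_circumference(phys.a, phys.b)
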