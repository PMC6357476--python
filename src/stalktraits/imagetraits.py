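"""Cross-section morphometry: diameter, rind thickness, vascular bundles.

The measurement chain mirrors how scanned internode cross sections are
analysed in stalk phenotyping:

1. segment the stalk (bright foreground on dark background), take the
   outer boundary;
2. stalk diameter = the largest distance between any two boundary points;
3. rind thickness = mean, over radial rays from the centroid, of the depth
   at which brightness first falls below a fixed fraction of the local
   rind-band brightness;
4. vascular bundles = smoothed local brightness maxima in the pith, each
   refined by a 2D-Gaussian least-squares fit; the bundle rim is the level
   set where the fitted surface drops to a fraction ``f`` of its peak, an
   ellipse whose principal radii follow from the covariance eigenvalues as
   ``r_i = sqrt(2 ln(1/f)) * sqrt(lambda_i)`` and whose area is
   ``pi * r1 * r2``;
5. bundle density = bundle count / whole cross-section area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure
from skimage.feature import peak_local_max

__all__ = [
    "CrossSectionImage",
    "StalkBoundary",
    "BundleFit",
    "SectionTraits",
    "MorphometryConfig",
    "SegmentationError",
    "RindMeasurementError",
    "segment_stalk",
    "stalk_diameter",
    "rind_thickness",
    "detect_bundle_centers",
    "fit_bundle_gaussian",
    "bundle_area",
    "ellipse_radii_from_eigenvalues",
    "measure_section",
]


class SegmentationError(RuntimeError):
    """No usable foreground component."""


class RindMeasurementError(RuntimeError):
    """Too few rays produced a rind/pith intensity transition."""


@dataclass(frozen=True)
class CrossSectionImage:
    """A grayscale cross-section scan with its physical pixel size.

    Coordinates are (x, y) = (col, row) * scale_cm_per_px, origin at the
    top-left pixel centre.
    """

    intensities: np.ndarray
    scale_cm_per_px: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 2D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if self.scale_cm_per_px <= 0:
            raise ValueError("scale_cm_per_px must be positive")
        object.__setattr__(self, "intensities", arr)

    @classmethod
    def from_file(cls, path: str | Path, scale_cm_per_px: float) -> "CrossSectionImage":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse any colour channels
            arr = arr.mean(axis=2)
        return cls(intensities=arr, scale_cm_per_px=scale_cm_per_px)

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.intensities), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class StalkBoundary:
    """Closed outer contour of the stalk, in cm, plus the enclosed area."""

    points_cm: np.ndarray  # (n, 2) as (x, y)
    area_cm2: float
    mask: np.ndarray  # boolean stalk mask (pixels), kept for downstream stages
    centroid_cm: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_cm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("boundary needs at least 3 (x, y) points")
        if self.area_cm2 <= 0:
            raise ValueError("enclosed area must be positive")
        object.__setattr__(self, "points_cm", pts)


@dataclass(frozen=True)
class BundleFit:
    """Fitted per-bundle Gaussian with derived rim ellipse.

    ``covariance_cm2`` is the fitted 2x2 Sigma; its eigenvalues
    ``lambda1 >= lambda2`` give the principal rim radii
    ``r_i = sqrt(2 ln(1/f) * lambda_i)`` at rim fraction ``f`` and the
    rim-ellipse area ``pi * r1 * r2``.
    """

    center_cm: tuple[float, float]
    amplitude: float
    baseline: float
    covariance_cm2: np.ndarray
    eigenvalues: tuple[float, float]  # (lambda1, lambda2), descending
    radii_cm: tuple[float, float]  # (r1, r2), descending
    area_cm2: float
    rim_fraction: float
    converged: bool


@dataclass(frozen=True)
class SectionTraits:
    diameter_cm: float
    rind_thickness_cm: float
    bundle_count: int
    bundle_density_per_cm2: float
    mean_bundle_area_cm2: float  # NaN when no converged bundle
    cross_section_area_cm2: float


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunable measurement parameters.

    rim_fraction
        Fraction of the fitted peak amplitude defining the bundle rim;
        0.5 is the full-width-half-maximum convention.
    rind_transition_fraction
        A ray's rind/pith transition is the first point, walking inward,
        whose brightness falls below this fraction of that ray's rind-band
        mean.
    segmentation_threshold
        ``None`` selects an automatic (Otsu) threshold; a number fixes it.
    """

    segmentation_threshold: float | None = None
    rim_fraction: float = 0.5
    fit_window_radius_factor: float = 0.8
    min_bundle_spacing_cm: float = 0.10
    min_amplitude: float = 25.0
    n_rind_rays: int = 72
    rind_transition_fraction: float = 0.7
    smooth_sigma_cm: float = 0.0075
    fit_tol: float = 1e-12
    fit_max_iter: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.rim_fraction < 1:
            raise ValueError("rim_fraction must lie in (0, 1)")
        if not 0 < self.rind_transition_fraction < 1:
            raise ValueError("rind_transition_fraction must lie in (0, 1)")
        if self.fit_window_radius_factor <= 0:
            raise ValueError("fit_window_radius_factor must be positive")
        if self.min_bundle_spacing_cm <= 0:
            raise ValueError("min_bundle_spacing_cm must be positive")
        if self.n_rind_rays < 1:
            raise ValueError("n_rind_rays must be positive")


# ---------------------------------------------------------------------------
# Segmentation and diameter
# ---------------------------------------------------------------------------


def segment_stalk(
    image: CrossSectionImage, config: MorphometryConfig | None = None
) -> StalkBoundary:
    """Threshold, fill holes, keep the largest component, trace its contour.

    Raises :class:`SegmentationError` when there is no foreground or the
    foreground touches the image border (a truncated stalk cannot be
    measured).
    """
    config = config or MorphometryConfig()
    arr = image.intensities
    if config.segmentation_threshold is None:
        if np.ptp(arr) == 0:
            raise SegmentationError("image is uniform; no foreground to segment")
        thr = filters.threshold_otsu(arr)
    else:
        thr = config.segmentation_threshold
    fg = arr > thr
    if not fg.any():
        raise SegmentationError("no foreground pixels above threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
        raise SegmentationError("stalk touches the image border; section truncated")

    contours = measure.find_contours(comp.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) sub-pixel
    s = image.scale_cm_per_px
    pts = np.column_stack([contour[:, 1], contour[:, 0]]) * s  # (x, y) cm

    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    cy, cx = ndimage.center_of_mass(comp)
    return StalkBoundary(
        points_cm=pts, area_cm2=float(area), mask=comp, centroid_cm=(cx * s, cy * s)
    )


def stalk_diameter(boundary: StalkBoundary | np.ndarray) -> float:
    """Largest Euclidean distance between any two boundary points (cm).

    Computed on the convex hull (the diameter of a point set is attained
    on its hull), so it is exact and fast even for long contours.
    """
    pts = boundary.points_cm if isinstance(boundary, StalkBoundary) else np.asarray(boundary, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two boundary points")
    if len(pts) > 3:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear/degenerate input: fall back to all points
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# Rind thickness
# ---------------------------------------------------------------------------


def _ray_profile(
    arr: np.ndarray, start_rc: tuple[float, float], angle: float, radii_px: np.ndarray
) -> np.ndarray:
    rows = start_rc[0] + radii_px * math.sin(angle)
    cols = start_rc[1] + radii_px * math.cos(angle)
    return ndimage.map_coordinates(arr, [rows, cols], order=1, mode="nearest")


def rind_thickness(
    image: CrossSectionImage,
    boundary: StalkBoundary,
    config: MorphometryConfig | None = None,
) -> float:
    """Mean radial depth of the bright rind annulus (cm).

    Rays are cast from the mask centroid. Along each ray the boundary
    radius R is taken from the mask; the rind-band reference brightness is
    the mean over the outermost ~5% of the ray just inside the boundary,
    and the transition is the first sample, walking inward, below
    ``rind_transition_fraction`` x that reference. Rays without a
    transition are dropped; more than 50% dropped raises
    :class:`RindMeasurementError`.
    """
    config = config or MorphometryConfig()
    arr = image.intensities
    s = image.scale_cm_per_px
    cx, cy = boundary.centroid_cm
    start_rc = (cy / s, cx / s)
    mask = boundary.mask.astype(float)

    r_max = np.sqrt(((boundary.points_cm - [cx, cy]) ** 2).sum(axis=1)).max() / s
    step = 0.5  # px
    radii = np.arange(0.0, r_max + 2.0, step)

    thicknesses = []
    for angle in np.linspace(0.0, 2 * math.pi, config.n_rind_rays, endpoint=False):
        inside = _ray_profile(mask, start_rc, angle, radii) > 0.5
        if not inside.any():
            continue
        R_idx = int(np.max(np.nonzero(inside)))
        if R_idx < 4:
            continue
        prof = _ray_profile(arr, start_rc, angle, radii[: R_idx + 1])
        # reference band: just inside the boundary, skipping the mixed edge px
        band_n = max(3, int(round(0.05 * R_idx)))
        hi = max(R_idx - 2, 1)
        lo = max(hi - band_n, 0)
        ref = float(prof[lo : hi + 1].mean())
        cutoff = config.rind_transition_fraction * ref
        below = np.nonzero(prof[: hi + 1] < cutoff)[0]
        if below.size == 0:
            continue  # no transition on this ray
        trans_idx = int(below.max())  # first below-threshold sample walking inward
        thicknesses.append((radii[R_idx] - radii[trans_idx]) * s)

    if len(thicknesses) < 0.5 * config.n_rind_rays:
        raise RindMeasurementError(
            f"only {len(thicknesses)}/{config.n_rind_rays} rays showed a "
            "rind/pith transition"
        )
    return float(np.mean(thicknesses))


# ---------------------------------------------------------------------------
# Bundle detection and Gaussian fitting
# ---------------------------------------------------------------------------


def _pith_mask(
    image: CrossSectionImage, boundary: StalkBoundary, config: MorphometryConfig
) -> np.ndarray:
    """Stalk mask eroded by the measured rind depth (plus a safety margin)."""
    s = image.scale_cm_per_px
    try:
        t_cm = rind_thickness(image, boundary, config)
    except RindMeasurementError:
        # no measurable annulus: fall back to a thin edge margin
        t_cm = 2.0 * s
    erode_px = max(1, int(round(t_cm / s)) + 2)
    dist = ndimage.distance_transform_edt(boundary.mask)
    return dist > erode_px


def detect_bundle_centers(
    image: CrossSectionImage,
    boundary: StalkBoundary,
    config: MorphometryConfig | None = None,
) -> list[tuple[float, float]]:
    """Candidate bundle centres (cm), brightest-first.

    Local maxima of the Gaussian-smoothed image inside the pith, with a
    prominence floor (``min_amplitude`` above the pith median) and a
    minimum pairwise spacing; when two maxima are closer than the spacing
    the more prominent one wins.
    """
    config = config or MorphometryConfig()
    s = image.scale_cm_per_px
    pith = _pith_mask(image, boundary, config)
    if not pith.any():
        return []
    smoothed = ndimage.gaussian_filter(image.intensities, config.smooth_sigma_cm / s)
    baseline = float(np.median(smoothed[pith]))
    spacing_px = config.min_bundle_spacing_cm / s
    # thin with a small square footprint, then enforce the Euclidean
    # spacing greedily (brightest first); peak_local_max's own
    # min_distance is a Chebyshev square and would over-suppress
    # diagonal neighbours right at the spacing limit
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(spacing_px / 3)),
        threshold_abs=baseline + config.min_amplitude,
        labels=pith,
    )
    if peaks.size == 0:
        return []
    order = np.argsort(-smoothed[peaks[:, 0], peaks[:, 1]])
    peaks = peaks[order].astype(float)
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= spacing_px for q in kept):
            kept.append(p)
    return [(float(c) * s, float(r) * s) for r, c in kept]


def ellipse_radii_from_eigenvalues(
    lambda1: float, lambda2: float, rim_fraction: float
) -> tuple[float, float, float]:
    """Principal rim radii and ellipse area from covariance eigenvalues.

    At the rim where the Gaussian drops to ``f`` of its peak,
    ``r_i = sqrt(2 ln(1/f) * lambda_i)`` and ``area = pi * r1 * r2``.
    """
    if lambda2 <= 0 or lambda1 < lambda2:
        raise ValueError("eigenvalues must satisfy lambda1 >= lambda2 > 0")
    if not 0 < rim_fraction < 1:
        raise ValueError("rim_fraction must lie in (0, 1)")
    k = 2.0 * math.log(1.0 / rim_fraction)
    r1 = math.sqrt(k * lambda1)
    r2 = math.sqrt(k * lambda2)
    return r1, r2, math.pi * r1 * r2


def fit_bundle_gaussian(
    image: CrossSectionImage,
    center_cm: tuple[float, float],
    config: MorphometryConfig | None = None,
    support_mask: np.ndarray | None = None,
) -> BundleFit:
    """Least-squares fit of ``baseline + A exp(-0.5 d' Sigma^-1 d)``.

    Sigma is parameterised by its Cholesky factor so every iterate is
    positive definite. The fit window is a disc of radius
    ``fit_window_radius_factor * min_bundle_spacing_cm`` around the seed
    centre; a window extending outside the image is an error. When a
    boolean ``support_mask`` (same shape as the image, e.g. the pith
    region) is given, only pixels inside it enter the fit — bundles near
    the pith edge must not be fitted against the bright rind band.
    """
    config = config or MorphometryConfig()
    s = image.scale_cm_per_px
    arr = image.intensities
    h, w = arr.shape
    win_px = max(4, int(round(config.fit_window_radius_factor * config.min_bundle_spacing_cm / s)))
    c0 = int(round(center_cm[0] / s))
    r0 = int(round(center_cm[1] / s))
    if r0 - win_px < 0 or r0 + win_px >= h or c0 - win_px < 0 or c0 + win_px >= w:
        raise ValueError("fit window extends outside the image")

    window = arr[r0 - win_px : r0 + win_px + 1, c0 - win_px : c0 + win_px + 1]
    xs = (np.arange(c0 - win_px, c0 + win_px + 1)) * s
    ys = (np.arange(r0 - win_px, r0 + win_px + 1)) * s
    X, Y = np.meshgrid(xs, ys)
    win_cm = win_px * s
    # circular support with a mild radial taper keeps neighbouring
    # bundles' tails in the window corners from steering the fit
    dist2 = (X - xs[win_px]) ** 2 + (Y - ys[win_px]) ** 2
    keep = (dist2 <= win_cm**2).ravel()
    if support_mask is not None:
        sup = support_mask[r0 - win_px : r0 + win_px + 1, c0 - win_px : c0 + win_px + 1]
        keep &= sup.astype(bool).ravel()
        if keep.sum() < 32:  # not enough pith pixels to constrain 7 params
            raise ValueError("fit window has too little usable support")
    wgt = np.exp(-0.5 * dist2.ravel()[keep] / (0.6 * win_cm) ** 2)
    sqw = np.sqrt(wgt)
    z = window.ravel()[keep]
    x = X.ravel()[keep]
    y = Y.ravel()[keep]

    base0 = float(np.median(z))
    amp0 = max(float(window[win_px, win_px]) - base0, 1.0)
    # moment-based initial covariance from the positive excess brightness
    excess = np.clip(z - base0, 0.0, None)
    tot = excess.sum()
    if tot > 0:
        mx0 = float((excess * x).sum() / tot)
        my0 = float((excess * y).sum() / tot)
        sxx0 = float((excess * (x - mx0) ** 2).sum() / tot)
        syy0 = float((excess * (y - my0) ** 2).sum() / tot)
    else:
        mx0, my0 = center_cm
        sxx0 = syy0 = (win_cm / 4.0) ** 2
    sigma0 = float(np.sqrt(max(min(sxx0, syy0), (0.5 * s) ** 2)))
    sigma0 = min(sigma0, win_cm / 2.0)

    def model(p: np.ndarray) -> np.ndarray:
        base, amp, mx, my, l11, l21, l22 = p
        # Sigma = L L', L lower-triangular; invert analytically
        det_l = l11 * l22
        sxx = l11 * l11
        sxy = l11 * l21
        syy = l21 * l21 + l22 * l22
        det = det_l * det_l
        dx = x - mx
        dy = y - my
        q = (syy * dx * dx - 2 * sxy * dx * dy + sxx * dy * dy) / det
        return base + amp * np.exp(-0.5 * q)

    def resid(p: np.ndarray) -> np.ndarray:
        return sqw * (model(p) - z)

    p0 = np.array([base0, amp0, center_cm[0], center_cm[1], sigma0, 0.0, sigma0])
    l_min = 0.3 * s  # sub-pixel floor keeps Sigma numerically PD
    lo = [-np.inf, 0.0, xs[0], ys[0], l_min, -win_cm, l_min]
    hi = [np.inf, np.inf, xs[-1], ys[-1], win_cm, win_cm, win_cm]
    try:
        res = optimize.least_squares(
            resid,
            p0,
            bounds=(lo, hi),
            xtol=config.fit_tol,
            ftol=config.fit_tol,
            gtol=config.fit_tol,
            max_nfev=config.fit_max_iter * len(p0),
        )
        ok = bool(res.success)
        p = res.x
    except Exception:
        ok = False
        p = p0

    base, amp, mx, my, l11, l21, l22 = p
    L = np.array([[l11, 0.0], [l21, l22]])
    cov = L @ L.T
    evals = np.linalg.eigvalsh(cov)  # ascending
    lam2, lam1 = float(evals[0]), float(evals[1])
    converged = ok and amp > config.min_amplitude and lam2 > 0
    if lam2 <= 0:
        lam1 = lam2 = float("nan")
        r1 = r2 = area = float("nan")
    else:
        r1, r2, area = ellipse_radii_from_eigenvalues(lam1, lam2, config.rim_fraction)
    return BundleFit(
        center_cm=(float(mx), float(my)),
        amplitude=float(amp),
        baseline=float(base),
        covariance_cm2=cov,
        eigenvalues=(lam1, lam2),
        radii_cm=(r1, r2),
        area_cm2=area,
        rim_fraction=config.rim_fraction,
        converged=converged,
    )


def bundle_area(fit: BundleFit) -> float:
    """Rim-ellipse area ``pi * r1 * r2`` (cm^2) of a converged fit."""
    if not fit.converged:
        raise ValueError("bundle fit did not converge; area undefined")
    r1, r2 = fit.radii_cm
    if not (r1 >= r2 > 0):
        raise ValueError("bundle radii must satisfy r1 >= r2 > 0")
    return math.pi * r1 * r2


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def measure_section(
    image: CrossSectionImage, config: MorphometryConfig | None = None
) -> tuple[SectionTraits, list[BundleFit]]:
    """Run the full measurement chain on one cross-section image.

    Only converged bundle fits count toward bundle_count, density and the
    mean area; a stage failure propagates with the stage named.
    """
    config = config or MorphometryConfig()
    try:
        boundary = segment_stalk(image, config)
    except Exception as exc:
        raise RuntimeError(f"segmentation failed: {exc}") from exc
    diameter = stalk_diameter(boundary)
    try:
        rind = rind_thickness(image, boundary, config)
    except RindMeasurementError as exc:
        raise RuntimeError(f"rind measurement failed: {exc}") from exc
    centers = detect_bundle_centers(image, boundary, config)
    pith = _pith_mask(image, boundary, config)

    fits: list[BundleFit] = []
    for c in centers:
        try:
            fits.append(fit_bundle_gaussian(image, c, config, support_mask=pith))
        except ValueError:
            continue  # window off-image near the rind: treated as no fit
    converged = [f for f in fits if f.converged]
    areas = [f.area_cm2 for f in converged]
    traits = SectionTraits(
        diameter_cm=diameter,
        rind_thickness_cm=rind,
        bundle_count=len(converged),
        bundle_density_per_cm2=len(converged) / boundary.area_cm2,
        mean_bundle_area_cm2=float(np.mean(areas)) if areas else float("nan"),
        cross_section_area_cm2=boundary.area_cm2,
    )
    return traits, fits
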