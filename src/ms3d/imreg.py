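"""Similarity-transform image registration via Fourier phase correlation.

Registers the reflectance imager's grayscale view onto the depth camera's
grayscale view.  Translation is recovered from the phase of the normalized
cross-power spectrum; rotation and scale are recovered by resampling the
high-pass-filtered Fourier magnitude into log-polar coordinates, where a
rotation becomes a circular shift along the angle axis and an isotropic
scaling becomes a shift along the log-radius axis (the Fourier-Mellin
construction).

Coordinate conventions: x = column, y = row, origin at the top-left pixel,
0-based.  A transform ``(dx, dy, theta0, sigma)`` describes the *content*
mapping from the reference image A to the moving image B: a feature at
position p in A appears in B at

    p' = sigma * R(theta0) @ (p - c) + c + (dx, dy)

with c the image center ``((w-1)/2, (h-1)/2)`` and R the rotation matrix in
(x, y).  Parameterizing about the center makes the inverse transform
center-independent: ``inverse = (-R(-theta0) @ d / sigma, -theta0, 1/sigma)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegistrationTransform2D",
    "LogPolarSpectrum",
    "phase_correlation",
    "logpolar_magnitude",
    "estimate_rotation_scale",
    "estimate_similarity",
    "warp_similarity",
    "hann2d",
]

SIGMA_MIN = 0.25
SIGMA_MAX = 4.0
_EPS = 1e-12


class DegenerateImageError(ValueError):
    """Raised when an image has no usable spectral content (e.g. constant)."""


class RegistrationRangeError(ValueError):
    """Raised when an estimated parameter falls outside the trusted range."""


@dataclass(frozen=True)
class RegistrationTransform2D:
    """Similarity transform between two equally-shaped image grids.

    Attributes
    ----------
    dx, dy : float
        Translation in pixels (x = column, y = row).
    theta0 : float
        Rotation angle in degrees, positive from +x toward +y (clockwise on
        screen with y pointing down).
    sigma : float
        Isotropic scale factor, > 0.
    peak_response : float
        Normalized height of the phase-correlation peak in [0, 1]; a
        confidence proxy (1 for an exact circular shift).
    low_confidence : bool
        Set when ``peak_response`` fell below the configured floor.
    """

    dx: float
    dy: float
    theta0: float
    sigma: float
    peak_response: float = 1.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite([self.dx, self.dy, self.theta0, self.sigma]).all():
            raise ValueError("non-finite transform parameters")

    def rotation_matrix(self) -> np.ndarray:
        t = np.deg2rad(self.theta0)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous matrix in (x, y) for a grid of the given shape."""
        h, w = shape
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        sr = self.sigma * self.rotation_matrix()
        t = c - sr @ c + np.array([self.dx, self.dy])
        m = np.eye(3)
        m[:2, :2] = sr
        m[:2, 2] = t
        return m

    def inverse(self) -> "RegistrationTransform2D":
        rinv = self.rotation_matrix().T / self.sigma
        d = -rinv @ np.array([self.dx, self.dy])
        return RegistrationTransform2D(
            dx=float(d[0]),
            dy=float(d[1]),
            theta0=-self.theta0,
            sigma=1.0 / self.sigma,
            peak_response=self.peak_response,
            low_confidence=self.low_confidence,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "dx": self.dx,
                "dy": self.dy,
                "theta0_deg": self.theta0,
                "sigma": self.sigma,
                "peak_response": self.peak_response,
                "low_confidence": self.low_confidence,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegistrationTransform2D":
        d = json.loads(text)
        return cls(
            dx=d["dx"],
            dy=d["dy"],
            theta0=d["theta0_deg"],
            sigma=d["sigma"],
            peak_response=d.get("peak_response", 1.0),
            low_confidence=d.get("low_confidence", False),
        )


@dataclass(frozen=True)
class LogPolarSpectrum:
    """Log-polar resampling of a centered Fourier magnitude spectrum.

    ``values[k, m]`` samples the magnitude at radius ``rho_min * rho_base**k``
    and angle ``m * theta_range_deg / n_theta`` degrees; the angle axis covers
    ``[0, theta_range_deg)`` and is circular with that period.
    """

    values: np.ndarray  # (n_rho, n_theta)
    rho_base: float
    n_rho: int
    n_theta: int
    theta_range_deg: float = 180.0
    rho_min: float = 1.0


def _as_image(img: np.ndarray, min_size: int = 8) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {a.shape}")
    if a.shape[0] < min_size or a.shape[1] < min_size:
        raise ValueError(f"image too small for registration: {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("image contains non-finite values")
    return a


def hann2d(shape: tuple[int, int]) -> np.ndarray:
    """Separable 2D Hann window (suppresses FFT edge wrap-around)."""
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _parabolic_offset(fm1: float, f0: float, fp1: float) -> float:
    denom = fm1 - 2.0 * f0 + fp1
    if abs(denom) < _EPS:
        return 0.0
    off = 0.5 * (fm1 - fp1) / denom
    if abs(off) < 1e-9:  # numerically-zero offsets stay exactly integer
        return 0.0
    return float(np.clip(off, -0.5, 0.5))


#: Std-dev (cycles/pixel) of the Gaussian low-pass applied to the normalized
#: cross-power spectrum.  Pure phase correlation weights every frequency
#: equally, so bins that carry no signal (only interpolation noise) corrupt
#: the surface on band-limited textures; tapering them restores a clean peak
#: while leaving the peak location of an exact circular shift untouched.
LOWPASS_SIGMA = 0.1


def _correlation_surface(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Normalized cross-power correlation surface; peak 1 for an exact shift."""
    fa = np.fft.fft2(img_a)
    fb = np.fft.fft2(img_b)
    cross = fb * np.conj(fa)
    r = cross / (np.abs(cross) + _EPS)
    fy = np.fft.fftfreq(img_a.shape[0])
    fx = np.fft.fftfreq(img_a.shape[1])
    lp = np.exp(-(fx[None, :] ** 2 + fy[:, None] ** 2) / (2 * LOWPASS_SIGMA**2))
    surf = np.real(np.fft.ifft2(r * lp))
    return surf * (surf.size / lp.sum())


def phase_correlation(
    img_a: np.ndarray, img_b: np.ndarray
) -> tuple[float, float, float]:
    """Estimate the translation taking ``img_a``'s content to ``img_b``'s.

    Returns ``(dx, dy, peak_response)`` such that, up to boundary effects,
    ``img_b(x, y) == img_a(x - dx, y - dy)``.  The peak of the inverse FFT of
    the normalized cross-power spectrum is located at the shift; a 3x3
    parabolic fit refines it to subpixel resolution.  For an exact circular
    shift the surface is a discrete delta and the estimate is exact.

    No window is applied here: the primitive operates on the pixels it is
    given so that circular shifts stay exact (callers window beforehand for
    non-circular content; :func:`estimate_similarity` does so internally).
    """
    a = _as_image(img_a)
    b = _as_image(img_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    for name, im in (("img_a", a), ("img_b", b)):
        if np.ptp(im) == 0:
            raise DegenerateImageError(f"{name} is constant (zero spectrum)")

    surf = _correlation_surface(a, b)
    h, w = surf.shape
    iy, ix = np.unravel_index(int(np.argmax(surf)), surf.shape)
    peak = float(surf[iy, ix])

    # subpixel: separable parabolic fit through circular neighbors
    ox = _parabolic_offset(surf[iy, (ix - 1) % w], surf[iy, ix], surf[iy, (ix + 1) % w])
    oy = _parabolic_offset(surf[(iy - 1) % h, ix], surf[iy, ix], surf[(iy + 1) % h, ix])

    dx = ix + ox
    dy = iy + oy
    if dx > w / 2:
        dx -= w
    if dy > h / 2:
        dy -= h
    return float(dx), float(dy), float(np.clip(peak, 0.0, 1.0))


def _highpass(shape: tuple[int, int]) -> np.ndarray:
    # Classic Fourier-Mellin emphasis filter on normalized frequencies.
    y = np.linspace(-0.5, 0.5, shape[0], endpoint=False)
    x = np.linspace(-0.5, 0.5, shape[1], endpoint=False)
    xx = np.cos(np.pi * x)[None, :] * np.cos(np.pi * y)[:, None]
    return (1.0 - xx) * (2.0 - xx)


def logpolar_magnitude(
    img: np.ndarray,
    n_rho: int = 256,
    n_theta: int = 360,
    *,
    window: bool = True,
    theta_range_deg: float = 180.0,
) -> LogPolarSpectrum:
    """Log-polar map of the centered, high-pass-filtered Fourier magnitude.

    A rotation of the input by theta circularly shifts the theta axis by
    theta; an isotropic scaling by sigma shifts the log-rho axis by
    ``-log(sigma) / log(rho_base)`` bins (frequency radii scale inversely
    with spatial scale).  The default theta range [0, 180) uses the point
    symmetry of real-image magnitude spectra.
    """
    if n_rho < 32 or n_theta < 32:
        raise ValueError("n_rho and n_theta must be >= 32")
    a = _as_image(img)
    if window:
        a = a * hann2d(a.shape)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(a)))
    mag *= _highpass(mag.shape)

    h, w = mag.shape
    cy, cx = h / 2.0, w / 2.0  # fftshift puts DC at (h//2, w//2); float ok
    cy, cx = float(h // 2), float(w // 2)
    rho_min = 1.0
    rho_max = min(h, w) / 2.0
    rho_base = float(np.exp(np.log(rho_max / rho_min) / n_rho))
    k = np.arange(n_rho)
    rho = rho_min * rho_base**k
    theta = np.deg2rad(np.arange(n_theta) * theta_range_deg / n_theta)
    tt, rr = np.meshgrid(theta, rho)
    xs = cx + rr * np.cos(tt)
    ys = cy + rr * np.sin(tt)
    vals = ndimage.map_coordinates(mag, [ys, xs], order=1, mode="constant", cval=0.0)
    return LogPolarSpectrum(
        values=vals,
        rho_base=rho_base,
        n_rho=n_rho,
        n_theta=n_theta,
        theta_range_deg=theta_range_deg,
        rho_min=rho_min,
    )


def _logpolar_shift(
    spec_a: LogPolarSpectrum, spec_b: LogPolarSpectrum
) -> tuple[float, float, float]:
    """Phase-correlate two log-polar spectra -> (theta_deg, sigma, peak).

    The rho axis is not periodic, so a Hann taper is applied along rho only;
    the theta axis is genuinely circular with the declared period.
    """
    va = np.log1p(spec_a.values)
    vb = np.log1p(spec_b.values)
    taper = np.hanning(va.shape[0])[:, None]
    dth_bins, drho_bins, peak = phase_correlation(va * taper, vb * taper)
    theta = dth_bins * spec_a.theta_range_deg / spec_a.n_theta
    sigma = spec_a.rho_base ** (-drho_bins)
    return theta, sigma, peak


def _derotate(img: np.ndarray, theta_deg: float, sigma: float) -> np.ndarray:
    """Undo a content rotation/scale about the image center (for candidate
    testing): output(q) = img(sigma * R(theta) @ (q - c) + c)."""
    t = RegistrationTransform2D(0.0, 0.0, theta_deg, sigma)
    h, w = img.shape
    m = t.matrix((h, w))  # (x, y) convention
    p = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    myx = p @ m @ p  # same map in (row, col)
    return ndimage.affine_transform(
        img, myx[:2, :2], offset=myx[:2, 2], order=1, mode="constant", cval=0.0
    )


def estimate_rotation_scale(
    img_a: np.ndarray,
    img_b: np.ndarray,
    n_rho: int = 256,
    n_theta: int = 360,
) -> tuple[float, float]:
    """Estimate rotation (deg) and scale of img_b's content relative to img_a.

    Phase correlation between the two log-polar magnitude spectra yields the
    angle and log-scale shifts.  Because the magnitude spectrum of a real
    image is point-symmetric, theta is only determined modulo 180 degrees;
    both candidates are tested by de-rotating img_b and keeping the one whose
    subsequent translation correlation peaks higher.  Returns theta in
    [-90, 90) and sigma in [1/4, 4].
    """
    a = _as_image(img_a)
    b = _as_image(img_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    spec_a = logpolar_magnitude(a, n_rho, n_theta)
    spec_b = logpolar_magnitude(b, n_rho, n_theta)
    theta, sigma, _ = _logpolar_shift(spec_a, spec_b)
    if not (SIGMA_MIN <= sigma <= SIGMA_MAX):
        raise RegistrationRangeError(
            f"estimated scale {sigma:.4g} outside [{SIGMA_MIN}, {SIGMA_MAX}]"
        )
    theta = ((theta + 90.0) % 180.0) - 90.0  # wrap to [-90, 90)
    best = None
    win = hann2d(a.shape)
    for cand in (theta, theta - 180.0 if theta >= 0 else theta + 180.0):
        b_unrot = _derotate(b, cand, sigma)
        try:
            _, _, peak = phase_correlation(a * win, b_unrot * win)
        except DegenerateImageError:
            continue
        if best is None or peak > best[1]:
            best = (cand, peak)
    if best is None:
        raise DegenerateImageError("both de-rotation candidates degenerate")
    cand = ((best[0] + 90.0) % 180.0) - 90.0
    return float(cand), float(sigma)


def estimate_similarity(
    img_a: np.ndarray,
    img_b: np.ndarray,
    n_rho: int = 256,
    n_theta: int = 360,
    peak_floor: float = 0.03,
) -> RegistrationTransform2D:
    """Full similarity registration of img_b (moving) onto img_a (reference).

    Rotation and scale come first from the Fourier-Mellin stage; img_b is
    then de-rotated/de-scaled about its center and the residual translation
    recovered by windowed phase correlation.  The measured residual shift s
    relates to the content translation d by ``d = sigma * R(theta) @ s``.
    """
    a = _as_image(img_a)
    b = _as_image(img_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    theta, sigma = estimate_rotation_scale(a, b, n_rho, n_theta)
    b_unrot = _derotate(b, theta, sigma)
    win = hann2d(a.shape)
    sx, sy, peak = phase_correlation(a * win, b_unrot * win)
    t = np.deg2rad(theta)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    d = sigma * rot @ np.array([sx, sy])
    return RegistrationTransform2D(
        dx=float(d[0]),
        dy=float(d[1]),
        theta0=float(theta),
        sigma=float(sigma),
        peak_response=peak,
        low_confidence=peak < peak_floor,
    )


def warp_similarity(
    img: np.ndarray,
    t: RegistrationTransform2D,
    out_shape: tuple[int, int] | None = None,
    fill: float = np.nan,
) -> np.ndarray:
    """Resample ``img`` (the moving image) onto the reference grid.

    Each output pixel q is inverse-mapped through t — i.e. sampled at
    ``sigma * R(theta0) @ (q - c) + c + (dx, dy)`` in ``img`` — with bilinear
    interpolation; out-of-domain samples take ``fill``.  With t estimated by
    :func:`estimate_similarity`, the result aligns with the reference image.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2D image")
    if out_shape is None:
        out_shape = a.shape
    m = t.matrix(out_shape)
    p = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    myx = p @ m @ p
    return ndimage.affine_transform(
        a,
        myx[:2, :2],
        offset=myx[:2, 2],
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=fill,
    )


def apply_similarity(
    img: np.ndarray,
    t: RegistrationTransform2D,
    out_shape: tuple[int, int] | None = None,
    fill: float = 0.0,
) -> np.ndarray:
    """Forward-transform content by t (the generator counterpart of
    :func:`warp_similarity`): features at p move to sigma*R(p-c)+c+d."""
    return warp_similarity(img, t.inverse(), out_shape=out_shape, fill=fill)
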