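"""Phase-correlation and Fourier-Mellin registration tests.

Independent oracles: exhaustive spatial-domain normalized cross-correlation
for translations, grid search over angle/scale for the Fourier-Mellin stage,
and scikit-image's phase_cross_correlation as a second opinion on shifts.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from ms3d import imreg
from ms3d.imreg import (
    DegenerateImageError,
    RegistrationTransform2D,
    apply_similarity,
    estimate_rotation_scale,
    estimate_similarity,
    hann2d,
    logpolar_magnitude,
    phase_correlation,
    warp_similarity,
)

from conftest import make_texture


# ---------------------------------------------------------------- oracles

def ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / d) if d > 0 else 0.0


def ncc_shift_oracle(ref, mov, radius=16, step=0.25):
    """Argmax of spatial NCC: coarse integer scan, then 0.25 px refinement."""
    best, arg = -np.inf, (0, 0)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            s = ncc(ref, np.roll(mov, (-dy, -dx), axis=(0, 1)))
            if s > best:
                best, arg = s, (dx, dy)
    cx, cy = arg
    for dy in np.arange(cy - 1, cy + 1 + step / 2, step):
        for dx in np.arange(cx - 1, cx + 1 + step / 2, step):
            shifted = ndimage.shift(mov, (-dy, -dx), order=1, mode="wrap")
            s = ncc(ref, shifted)
            if s > best:
                best, arg = s, (dx, dy)
    return arg


def rotation_oracle(ref, mov, lo=-45.0, hi=45.0):
    """Grid search over rotation maximizing NCC after inverse rotation."""
    def score(th):
        un = warp_similarity(mov, RegistrationTransform2D(0, 0, th, 1.0), fill=0.0)
        return ncc(ref, un)

    coarse = np.arange(lo, hi + 1.0, 1.0)
    th0 = coarse[np.argmax([score(t) for t in coarse])]
    fine = np.arange(th0 - 1.0, th0 + 1.0 + 0.125, 0.25)
    return fine[np.argmax([score(t) for t in fine])]


def scale_oracle(ref, mov, lo=0.5, hi=2.0):
    def score(sg):
        un = warp_similarity(mov, RegistrationTransform2D(0, 0, 0.0, sg), fill=0.0)
        return ncc(ref, un)

    coarse = np.exp(np.arange(np.log(lo), np.log(hi), 0.05))
    s0 = coarse[np.argmax([score(s) for s in coarse])]
    fine = s0 * np.exp(np.arange(-0.05, 0.05, 0.005))
    return fine[np.argmax([score(s) for s in fine])]


# ------------------------------------------------------- phase correlation

def test_identity_image_gives_zero_shift_and_unit_peak(texture):
    dx, dy, peak = phase_correlation(texture, texture)
    assert (dx, dy) == (0.0, 0.0)
    assert peak == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("shift", [(5, -3), (0, 17), (-40, 0), (-11, 29)])
def test_circular_shift_recovered_exactly(texture, shift):
    dx, dy = shift
    moved = np.roll(texture, (dy, dx), axis=(0, 1))
    ex, ey, peak = phase_correlation(texture, moved)
    assert (ex, ey) == (float(dx), float(dy))
    assert peak > 0.9


def test_fifty_random_circular_shifts_exact():
    """Property from the translation-recovery invariant: 50/50 exact."""
    tex = make_texture(7)
    rng = np.random.default_rng(123)
    for _ in range(50):
        dx, dy = (int(v) for v in rng.integers(-60, 61, 2))
        moved = np.roll(tex, (dy, dx), axis=(0, 1))
        ex, ey, _ = phase_correlation(tex, moved)
        assert (ex, ey) == (float(dx), float(dy))


def test_integer_shift_matches_brute_force_ncc_argmax():
    """Equivalence on small instances: FFT estimate equals the spatial
    cross-correlation argmax for integer circular shifts."""
    tex = make_texture(3, shape=(48, 48))
    rng = np.random.default_rng(5)
    for _ in range(5):
        dx, dy = (int(v) for v in rng.integers(-10, 11, 2))
        moved = np.roll(tex, (dy, dx), axis=(0, 1))
        ex, ey, _ = phase_correlation(tex, moved)
        ox, oy = ncc_shift_oracle(tex, moved, radius=12, step=1.0)
        assert (ex, ey) == (float(ox), float(oy))


def test_subpixel_shift_within_half_pixel_of_ncc_oracle(texture):
    t = RegistrationTransform2D(12.25, 4.5, 0.0, 1.0)
    moved = apply_similarity(texture, t)
    win = hann2d(texture.shape)
    ex, ey, _ = phase_correlation(texture * win, moved * win)
    ox, oy = ncc_shift_oracle(texture, moved)
    assert abs(ex - ox) <= 0.5 and abs(ey - oy) <= 0.5
    assert ex == pytest.approx(12.25, abs=0.5)
    assert ey == pytest.approx(4.5, abs=0.5)


def test_agrees_with_skimage_oracle_on_circular_shifts(texture):
    rng = np.random.default_rng(17)
    for _ in range(10):
        dx, dy = (int(v) for v in rng.integers(-30, 31, 2))
        moved = np.roll(texture, (dy, dx), axis=(0, 1))
        ex, ey, _ = phase_correlation(texture, moved)
        (sy, sx), _, _ = phase_cross_correlation(texture, moved)
        # skimage reports the shift to apply to the moving image (negated)
        assert (ex, ey) == (-sx, -sy) == (dx, dy)


def test_constant_image_raises(texture):
    with pytest.raises(DegenerateImageError):
        phase_correlation(texture, np.ones_like(texture))


def test_shape_mismatch_raises(texture):
    with pytest.raises(ValueError, match="shape"):
        phase_correlation(texture, texture[:64, :64])


# ---------------------------------------------------------- log-polar map

def oracle_1d_circular_shift(a2d, b2d, axis):
    """1D phase correlation of detrended axis-profiles (bin-shift oracle)."""
    pa = np.log1p(a2d).sum(axis=1 - axis)
    pb = np.log1p(b2d).sum(axis=1 - axis)
    pa = (pa - pa.mean()) * np.hanning(len(pa))
    pb = (pb - pb.mean()) * np.hanning(len(pb))
    fa, fb = np.fft.fft(pa), np.fft.fft(pb)
    cross = fb * np.conj(fa)
    lp = np.exp(-np.fft.fftfreq(len(pa)) ** 2 / (2 * 0.1**2))
    surf = np.real(np.fft.ifft(cross / (np.abs(cross) + 1e-12) * lp))
    k = int(np.argmax(surf))
    return k - len(pa) if k > len(pa) / 2 else k


def test_logpolar_identity(texture):
    sa = logpolar_magnitude(texture)
    sb = logpolar_magnitude(texture.copy())
    assert np.allclose(sa.values, sb.values)
    assert sa.values.shape == (sa.n_rho, sa.n_theta)


def test_logpolar_rotation_shifts_theta_axis(texture):
    rot = apply_similarity(texture, RegistrationTransform2D(0, 0, 30.0, 1.0))
    sa = logpolar_magnitude(texture)
    sb = logpolar_magnitude(rot)
    shift_bins = oracle_1d_circular_shift(sa.values, sb.values, axis=1)
    expected = 30.0 / (sa.theta_range_deg / sa.n_theta)
    assert abs(shift_bins - expected) <= 1.0


def test_logpolar_scale_shifts_rho_axis(texture):
    scaled = apply_similarity(texture, RegistrationTransform2D(0, 0, 0.0, 1.2))
    sa = logpolar_magnitude(texture)
    sb = logpolar_magnitude(scaled)
    shift_bins = oracle_1d_circular_shift(sa.values, sb.values, axis=0)
    # spatial scale sigma shifts frequency radii by -log(sigma)
    expected = -np.log(1.2) / np.log(sa.rho_base)
    assert abs(shift_bins - expected) <= 1.0


def test_logpolar_rejects_tiny_grids(texture):
    with pytest.raises(ValueError, match=">= 32"):
        logpolar_magnitude(texture, n_rho=16, n_theta=64)


# ------------------------------------------------------- rotation + scale

def test_rotation_scale_identity(texture):
    th, sg = estimate_rotation_scale(texture, texture)
    assert th == pytest.approx(0.0, abs=0.1)
    assert sg == pytest.approx(1.0, abs=0.005)


def test_rotation_within_one_degree_of_grid_search_oracle(texture):
    rot = apply_similarity(texture, RegistrationTransform2D(0, 0, 25.0, 1.0))
    th, sg = estimate_rotation_scale(texture, rot)
    th_oracle = rotation_oracle(texture, rot)
    assert abs(th - th_oracle) <= 1.0
    assert th == pytest.approx(25.0, abs=1.0)
    assert sg == pytest.approx(1.0, abs=0.03)


def test_scale_within_three_percent_of_grid_search_oracle(texture):
    sc = apply_similarity(texture, RegistrationTransform2D(0, 0, 0.0, 1.25))
    th, sg = estimate_rotation_scale(texture, sc)
    sg_oracle = scale_oracle(texture, sc)
    assert abs(sg - sg_oracle) / sg_oracle <= 0.03
    assert sg == pytest.approx(1.25, rel=0.03)
    assert abs(th) <= 1.0


# ------------------------------------------------------- full similarity

def test_similarity_identity(texture):
    t = estimate_similarity(texture, texture)
    assert t.dx == pytest.approx(0.0, abs=0.1)
    assert t.dy == pytest.approx(0.0, abs=0.1)
    assert t.theta0 == pytest.approx(0.0, abs=0.25)
    assert t.sigma == pytest.approx(1.0, abs=0.01)
    assert not t.low_confidence


def test_similarity_recovers_known_transform():
    """Checker+blob image under (10, -6, 15 deg, 1.1): parameters known by
    construction, recovered within (0.5 px, 0.5 px, 1 deg, 3%)."""
    yy, xx = np.mgrid[0:128, 0:128]
    img = ((xx // 16 + yy // 16) % 2).astype(float) * 0.5
    rng = np.random.default_rng(2)
    for _ in range(10):
        cx, cy, r = rng.uniform(20, 108), rng.uniform(20, 108), rng.uniform(4, 12)
        img += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r**2))
    truth = RegistrationTransform2D(10.0, -6.0, 15.0, 1.1)
    moved = apply_similarity(img, truth)
    est = estimate_similarity(img, moved)
    assert est.dx == pytest.approx(10.0, abs=0.5)
    assert est.dy == pytest.approx(-6.0, abs=0.5)
    assert est.theta0 == pytest.approx(15.0, abs=1.0)
    assert est.sigma == pytest.approx(1.1, rel=0.03)


def test_similarity_recovery_rate_20_random_transforms():
    """>= 90% of 20 random transforms recovered within tolerance."""
    rng = np.random.default_rng(42)
    good = 0
    for i in range(20):
        tex = make_texture(100 + i)
        dx, dy = rng.uniform(-15, 15, 2)
        th = rng.uniform(-30, 30)
        sg = rng.uniform(0.8, 1.25)
        moved = apply_similarity(tex, RegistrationTransform2D(dx, dy, th, sg))
        est = estimate_similarity(tex, moved)
        good += (
            abs(est.dx - dx) <= 0.5
            and abs(est.dy - dy) <= 0.5
            and abs(est.theta0 - th) <= 1.0
            and abs(est.sigma - sg) / sg <= 0.03
        )
    assert good >= 18


def test_plant_silhouette_registration(scene):
    """Spectral NIR band vs depth-camera grayscale: the registered band
    should differ from the truth-aligned band only at margins."""
    from ms3d.synth import render_view

    r = render_view(scene, 0.0, noise_seed=9)
    ref = r.rgb.astype(float).mean(axis=2)
    mov = r.cube.plane("nir")
    est = estimate_similarity(ref, mov)
    truth = scene.params.spectral_transform
    assert est.dx == pytest.approx(truth.dx, abs=1.0)
    assert est.dy == pytest.approx(truth.dy, abs=1.0)
    assert est.theta0 == pytest.approx(truth.theta0, abs=1.0)
    assert est.sigma == pytest.approx(truth.sigma, rel=0.03)
    aligned = warp_similarity(mov, est, fill=np.nan)
    target = np.nan_to_num(r.aligned_reflectance["nir"], nan=0.0)
    interior = np.isfinite(aligned)
    interior[:10] = interior[-10:] = False
    interior[:, :10] = interior[:, -10:] = False
    mad = np.nanmean(np.abs(aligned[interior] - target[interior]))
    assert mad < 0.05


# ------------------------------------------------------------------ warps

def test_warp_identity_returns_input(texture):
    out = warp_similarity(texture, RegistrationTransform2D(0, 0, 0, 1.0), fill=0.0)
    assert np.allclose(out, texture, atol=1e-12)


def test_warp_roundtrip_recovers_interior():
    tex = make_texture(1, smooth=4.0)  # band-limited: bilinear error is small
    t = RegistrationTransform2D(5.0, -3.0, 10.0, 1.05)
    there = warp_similarity(tex, t, fill=0.0)
    back = warp_similarity(there, t.inverse(), fill=0.0)
    interior = np.abs(back - tex)[20:-20, 20:-20]
    # double bilinear resampling: sub-gray-level on the 8-bit scale
    assert np.mean(interior) * 255 < 0.5
    assert interior.max() * 255 < 3.0


def test_warp_constant_image_stays_constant():
    img = np.full((64, 64), 0.7)
    t = RegistrationTransform2D(4.0, 2.0, 30.0, 1.2)
    out = warp_similarity(img, t, fill=np.nan)
    inside = np.isfinite(out)
    assert np.allclose(out[inside], 0.7, atol=1e-12)


def test_transform_inverse_composition_is_identity():
    t = RegistrationTransform2D(8.0, -5.0, 4.0, 0.85)
    m = t.matrix((240, 320)) @ t.inverse().matrix((240, 320))
    assert np.allclose(m, np.eye(3), atol=1e-6)


def test_transform_json_roundtrip():
    t = RegistrationTransform2D(1.5, -2.5, 12.0, 1.02, peak_response=0.4)
    t2 = RegistrationTransform2D.from_json(t.to_json())
    assert t == t2


def test_out_of_range_scale_raises(texture, monkeypatch):
    """A measured scale outside [1/4, 4] signals registration failure."""
    monkeypatch.setattr(imreg, "_logpolar_shift", lambda a, b: (0.0, 6.0, 1.0))
    with pytest.raises(imreg.RegistrationRangeError):
        estimate_rotation_scale(texture, texture)
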