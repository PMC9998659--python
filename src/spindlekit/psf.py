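"""Point-spread-function modeling and PSF-based axial position estimation.

With only a few widefield z-slices per frame, the spindle's axial extent is
recovered photometrically: a fluorophore away from the focal plane appears
dimmer following the axial profile of the microscope's PSF. Fitting a
Gaussian to a bead stack gives the axial profile

    I(z) = exp(-((z - z_c) / sigma)^2)

relative to the in-focus peak, which is inverted per pixel to

    z_hat = z_c + sigma * sqrt(-log I)

to assign a z-offset to every sufficiently bright spindle pixel. The resulting
3D point cloud feeds the minimum-volume enclosing ellipsoid fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import j0

__all__ = [
    "GaussianPSFModel",
    "OpticsConfig",
    "PSFFitError",
    "simulate_psf",
    "fit_psf_gaussians",
    "estimate_z",
    "reconstruct_spindle_points",
]


class PSFFitError(RuntimeError):
    """Gaussian PSF fit failed to converge."""


@dataclass
class GaussianPSFModel:
    """Separable Gaussian PSF: a 2D lateral Gaussian (independent sigma_x,
    sigma_y in pixels) times a 1D axial Gaussian (sigma_z in um).

    ``amplitude`` is the height of the Gaussian at its peak.
    """

    amplitude: float
    xy_center: tuple[float, float]
    z_center: float
    sigma_x: float
    sigma_y: float
    sigma_z: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("all sigmas must be positive")

    def axial_intensity(self, z) -> np.ndarray:
        """Normalized axial profile I(z) = exp(-((z - z_c)/sigma_z)^2)."""
        z = np.asarray(z, dtype=float)
        return np.exp(-np.square((z - self.z_center) / self.sigma_z))

    def to_record(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "xy_center": list(self.xy_center),
            "z_center": self.z_center,
            "sigma_x": self.sigma_x,
            "sigma_y": self.sigma_y,
            "sigma_z": self.sigma_z,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "GaussianPSFModel":
        return cls(
            amplitude=rec["amplitude"],
            xy_center=tuple(rec["xy_center"]),
            z_center=rec["z_center"],
            sigma_x=rec["sigma_x"],
            sigma_y=rec["sigma_y"],
            sigma_z=rec["sigma_z"],
        )


@dataclass
class OpticsConfig:
    """Imaging parameters for PSF simulation.

    Defaults describe a 1.42 NA oil-immersion objective imaging a red
    fluorophore, with the emission wavelength in um.
    """

    numerical_aperture: float = 1.42
    emission_wavelength_um: float = 0.61
    immersion_index: float = 1.515
    sample_index: float = 1.38
    pixel_size_um: float = 0.06887
    z_range_um: float = 3.0
    z_samples: int = 31
    lateral_halfwidth_px: int = 16
    model: str = "gaussian"  # "gaussian" or "gibson_lanni"

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < self.immersion_index:
            raise ValueError("numerical aperture must be in (0, immersion index)")
        if self.emission_wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.z_samples < 3 or self.z_range_um <= 0:
            raise ValueError("z sampling must cover a positive range with >= 3 planes")

    @property
    def sigma_xy_um(self) -> float:
        """Gaussian approximation of the lateral PSF width."""
        return 0.21 * self.emission_wavelength_um / self.numerical_aperture

    @property
    def sigma_z_um(self) -> float:
        """Gaussian approximation of the axial PSF width."""
        return 0.66 * self.emission_wavelength_um * self.immersion_index / self.numerical_aperture**2


def _gibson_lanni_stack(optics: OpticsConfig, z: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Scalar diffraction integral over the pupil for an index-mismatched sample.

    I(r, z) = | int_0^1 J0(k NA r rho) exp(i k OPD(rho, z)) rho d rho |^2
    with the defocus + spherical-aberration optical path difference of the
    immersion/sample index mismatch.
    """
    k = 2.0 * np.pi / optics.emission_wavelength_um
    na, ni, ns = optics.numerical_aperture, optics.immersion_index, optics.sample_index
    rho = np.linspace(0.0, 1.0, 128)
    sin_i = np.clip(na * rho / ni, 0.0, 0.999999)
    cos_i = np.sqrt(1.0 - sin_i**2)
    sin_s = np.clip(na * rho / ns, 0.0, 0.999999)
    cos_s = np.sqrt(1.0 - sin_s**2)
    out = np.empty((z.size, r.size))
    bess = j0(k * na * np.multiply.outer(r, rho))  # (nr, nrho)
    for iz, zz in enumerate(z):
        opd = zz * (ns * cos_s - ni * cos_i)  # depth-dependent mismatch defocus
        phase = np.exp(1j * k * opd)
        integrand = bess * (phase * rho)[None, :]
        field = np.trapezoid(integrand, rho, axis=1)
        out[iz] = np.abs(field) ** 2
    return out


def simulate_psf(optics: OpticsConfig) -> np.ndarray:
    """Simulate a 3D PSF stack (z, y, x), normalized so the peak equals 1.

    ``model="gibson_lanni"`` evaluates the scalar diffraction integral with
    the index-mismatch optical path difference; the default ``"gaussian"``
    uses the widefield Gaussian approximation sigma_xy = 0.21 lambda / NA,
    sigma_z = 0.66 lambda n_i / NA^2. Both are circularly symmetric in x/y
    about the stack center.
    """
    hw = optics.lateral_halfwidth_px
    n_lat = 2 * hw + 1
    z = np.linspace(-optics.z_range_um / 2.0, optics.z_range_um / 2.0, optics.z_samples)
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1].astype(float) * optics.pixel_size_um
    rr = np.hypot(yy, xx)
    if optics.model == "gaussian":
        lat = np.exp(-0.5 * (rr / optics.sigma_xy_um) ** 2)
        ax = np.exp(-0.5 * (z / optics.sigma_z_um) ** 2)
        stack = ax[:, None, None] * lat[None, :, :]
    elif optics.model == "gibson_lanni":
        r_unique, inv = np.unique(np.round(rr, 12), return_inverse=True)
        prof = _gibson_lanni_stack(optics, z, r_unique)  # (nz, nr)
        stack = prof[:, inv].reshape(optics.z_samples, n_lat, n_lat)
    else:
        raise ValueError(f"unknown PSF model {optics.model!r}")
    return stack / stack.max()


def _gauss2d(coords, amp, xc, yc, sx, sy):
    x, y = coords
    return amp * np.exp(-((x - xc) ** 2) / (2 * sx**2) - ((y - yc) ** 2) / (2 * sy**2))


def _gauss1d(z, amp, zc, sz):
    return amp * np.exp(-((z - zc) ** 2) / (2 * sz**2))


def fit_psf_gaussians(
    bead_stack: np.ndarray, pixel_size_um: float, z_step_um: float
) -> GaussianPSFModel:
    """Fit the separable Gaussian PSF model to an empirical bead z-stack.

    A 2D Gaussian with independent sigma_x, sigma_y is fitted at the brightest
    slice, and a 1D Gaussian along z through the brightest (x_c, y_c) column.
    Lateral sigmas are in pixels, axial quantities in um.

    Raises
    ------
    PSFFitError
        If either fit fails to converge (the message reports the residual).
    """
    stack = np.asarray(bead_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) stack, got shape {stack.shape}")
    if np.ptp(stack) == 0:
        raise PSFFitError("flat stack: no peak to fit")
    zi, yi, xi = np.unravel_index(int(np.argmax(stack)), stack.shape)
    plane = stack[zi]
    yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]].astype(float)
    p0 = [float(plane.max()), float(xi), float(yi), 2.0, 2.0]
    try:
        popt_xy, _ = curve_fit(
            _gauss2d, (xx.ravel(), yy.ravel()), plane.ravel(), p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        raise PSFFitError(f"lateral Gaussian fit did not converge: {exc}") from exc
    amp, xc, yc, sx, sy = popt_xy
    resid_xy = float(
        np.sqrt(np.mean((plane - _gauss2d((xx, yy), *popt_xy)) ** 2))
    )
    profile = stack[:, int(round(yc)), int(round(xc))]
    z = np.arange(stack.shape[0], dtype=float) * z_step_um
    try:
        popt_z, _ = curve_fit(
            _gauss1d, z, profile, p0=[float(profile.max()), float(zi) * z_step_um, z_step_um], maxfev=20000
        )
    except RuntimeError as exc:
        raise PSFFitError(f"axial Gaussian fit did not converge: {exc}") from exc
    amp_z, zc, sz = popt_z
    if min(sx, sy, sz) <= 0 or amp <= 0:
        raise PSFFitError(
            f"non-physical fit (amp={amp:.3g}, sx={sx:.3g}, sy={sy:.3g}, sz={sz:.3g}); "
            f"lateral rms residual {resid_xy:.3g}"
        )
    return GaussianPSFModel(
        amplitude=float(amp),
        xy_center=(float(xc), float(yc)),
        z_center=float(zc),
        sigma_x=float(abs(sx)),
        sigma_y=float(abs(sy)),
        sigma_z=float(abs(sz)),
    )


def estimate_z(intensity, model: GaussianPSFModel):
    """Invert the axial Gaussian profile to a z-coordinate.

    For intensity I normalized to the reference profile peak,
    z_hat = z_c + sigma_z * sqrt(-log I): the non-negative branch of inverting
    I = exp(-((z - z_c)/sigma_z)^2). Above- vs below-focus cannot be
    distinguished from a single intensity; the non-negative offset is returned.

    Raises
    ------
    ValueError
        If intensity is outside (0, 1].
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0) or np.any(I > 1):
        raise ValueError("intensity must be normalized to (0, 1]")
    out = model.z_center + model.sigma_z * np.sqrt(-np.log(I))
    return float(out) if np.isscalar(intensity) else out


def reconstruct_spindle_points(
    image: np.ndarray,
    mask: np.ndarray,
    model: GaussianPSFModel,
    pixel_size_um: float,
    top_fraction: float = 0.30,
) -> np.ndarray:
    """Lift bright masked spindle pixels into 3D via the axial PSF inverse.

    Keeps the ceil(top_fraction * mask area) brightest pixels inside the mask
    (burning the mask onto the raw image isolates spindle signal), normalizes
    their intensities to the retained maximum (the reference intensity), and
    maps each pixel to (x*pixel_size, y*pixel_size, estimate_z(I)). The
    returned (k, 3) um point cloud is the MVEE input for the spindle ellipsoid.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise ValueError("empty mask: nothing to reconstruct")
    vals = img[rows, cols]
    k = int(np.ceil(top_fraction * rows.size))
    # stable selection: brightest first, ties broken by pixel order
    order = np.argsort(-vals, kind="stable")[:k]
    vals = vals[order]
    rows, cols = rows[order], cols[order]
    ref = vals.max()
    if ref <= 0:
        raise ValueError("retained intensities are non-positive")
    norm = np.clip(vals / ref, np.finfo(float).tiny, 1.0)
    z = estimate_z(norm, model)
    return np.column_stack([cols * pixel_size_um, rows * pixel_size_um, z])
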