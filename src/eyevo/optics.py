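"""Physically based eye model: pupil function, wave-propagated PSF, image
formation, and image/optics metrics.

The eye is modeled as a pupil plane (circular aperture of radius a*L plus a
programmable phase element) a focal distance s in front of a discretized
sensor of side L. A point source at distance z launches a spherical wave;
the field just after the pupil is propagated to the sensor with the angular
spectrum transfer function, and the squared magnitude of the propagated
field — binned onto sensor-pitch cells — is the point spread function (PSF).
The PSF is depth independent by construction (computed once at a reference
source distance) so image formation is a single 2D convolution per eye per
channel:

    I = clip( S( (H * X) * a^2 ) + N, 0, 1 )

where H is the unit-sum blur kernel of size (res_h+1, res_w+1), X the padded
sharp latent scene, a^2 the relative light throughput of the pupil (area
scales with radius squared), S a linear sensor response, and N Gaussian
sensor noise.

Metrics: radially averaged MTF, an image-quality score (MTF area x light
collection), cycles-per-degree acuity, and PSNR/SSIM comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

from .genome import MorphologicalGene, OpticalGene

__all__ = [
    "OpticsConfig",
    "PupilFunction",
    "PSFStack",
    "LatentScene",
    "RetinalImage",
    "latent_padding",
    "latent_shape",
    "build_pupil_function",
    "lens_phase_profile",
    "angular_spectrum_propagate",
    "propagate_pupil",
    "compute_psf",
    "compute_psf_stack",
    "delta_psf_stack",
    "render_retinal_image",
    "compute_mtf",
    "mtf_area",
    "image_quality",
    "compute_cpd",
    "compare_images",
    "save_image_png",
]

#: default per-channel wavelengths (meters), R/G/B
WAVELENGTHS_RGB = (640e-9, 550e-9, 460e-9)


@dataclass(frozen=True)
class OpticsConfig:
    """Physical constants of the imaging model.

    sensor_size and focal_distance are in world units; wavelengths and
    height_scale in meters (the phase element is physically micro-scale
    regardless of the world's macroscopic geometry). The 4x4 phase gene is
    upsampled to psf_grid_upsample samples per side; pad_factor zero-pads
    the propagation FFT to suppress wraparound.
    """

    sensor_size: float = 0.05
    focal_distance: float = 0.05
    source_distance: float = 3.0
    wavelengths: tuple[float, float, float] = WAVELENGTHS_RGB
    height_scale: float = 1.5e-6
    noise_sigma: float = 0.02
    psf_grid_upsample: int = 51
    pad_factor: int = 4
    grid_oversample: int = 1  # extra propagation-grid sampling per 51-cell

    def __post_init__(self):
        for name in ("sensor_size", "focal_distance", "source_distance",
                     "height_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def diffraction_config(**overrides) -> OpticsConfig:
    """An OpticsConfig at a scale where the 51-sample pupil resolves
    diffraction (Airy rings, lens focusing); used by the analytic-limit
    validation suite. The default desk geometry is deep in the geometric
    regime where the Airy core is far below one grid cell."""
    kw = dict(sensor_size=2e-4, focal_distance=3e-2, source_distance=np.inf,
              noise_sigma=0.0, grid_oversample=4, pad_factor=12)
    kw.update(overrides)
    return OpticsConfig(**kw)


@dataclass
class PupilFunction:
    """Sampled pupil: binary circular amplitude and phase (radians)."""

    amplitude: np.ndarray
    phase: np.ndarray
    pitch: float  # grid sample spacing, world units

    def __post_init__(self):
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase grids must share a shape")

    @property
    def field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class PSFStack:
    """Per-channel unit-sum blur kernels of size (res_h+1, res_w+1).

    ``blind`` flags a fully closed pupil (a=0): kernels are all-zero and the
    rendered image is noise only.
    """

    kernels: list[np.ndarray]
    blind: bool = False

    def __post_init__(self):
        shapes = {k.shape for k in self.kernels}
        if len(shapes) != 1:
            raise ValueError("all channels must share a kernel shape")


@dataclass
class LatentScene:
    """Sharp padded scene image plus per-pixel hit distances."""

    image: np.ndarray  # (Hp, Wp, 3) in [0, 1]
    depth: np.ndarray  # (Hp, Wp), world units

    def __post_init__(self):
        if self.image.shape[:2] != self.depth.shape:
            raise ValueError("image and depth spatial shapes differ")


@dataclass
class RetinalImage:
    pixels: np.ndarray  # (res_h, res_w, 3) in [0, 1]


def latent_padding(res: int) -> int:
    """Per-side padding so a (res+1) kernel can blur the full sensor."""
    return int(np.ceil((res + 1) / 2))


def latent_shape(res_h: int, res_w: int) -> tuple[int, int]:
    """Spatial shape of the padded latent scene for a res_h x res_w eye."""
    return (res_h + 2 * latent_padding(res_h), res_w + 2 * latent_padding(res_w))


# ---------------------------------------------------------------------------
# Pupil and PSF


def _pupil_grid(cfg: OpticsConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample coordinates of the pupil plane. The grid spans 2L per side so
    the fully open pupil (radius a*L at a=1) inscribes exactly."""
    n = cfg.psf_grid_upsample * cfg.grid_oversample
    span = 2.0 * cfg.sensor_size
    pitch = span / n
    c = (np.arange(n) - (n - 1) / 2.0) * pitch
    x, y = np.meshgrid(c, c, indexing="xy")
    return x, y, pitch


def build_pupil_function(og: OpticalGene, cfg: OpticsConfig,
                         channel: int = 1) -> PupilFunction:
    """Pupil function P = A exp(i phi) from the optical gene.

    The 4x4 phase mask is bilinearly upsampled to the pupil grid and mapped
    to an optical phase delay (2 pi / lambda) (eta - 1) h_max phi(x, y); the
    amplitude is a binary circle of radius a * L.
    """
    if not 0.0 <= og.aperture_fraction <= 1.0:
        raise ValueError("aperture_fraction must be in [0, 1]")
    lam = cfg.wavelengths[channel]
    x, y, pitch = _pupil_grid(cfg)
    n = x.shape[0]

    # bilinear upsample of the 4x4 gene onto the propagation grid
    src = np.asarray(og.phase_mask, dtype=float)
    coords = np.linspace(0, src.shape[0] - 1, n)
    cy, cx = np.meshgrid(coords, coords, indexing="ij")
    height_frac = ndimage.map_coordinates(src, [cy, cx], order=1, mode="nearest")

    delay = (2 * np.pi / lam) * (og.refractive_index - 1.0) \
        * cfg.height_scale * height_frac
    r = og.aperture_fraction * cfg.sensor_size
    amp = ((x**2 + y**2) <= r**2 + 1e-18).astype(float)
    return PupilFunction(amplitude=amp, phase=delay, pitch=pitch)


def lens_phase_profile(cfg: OpticsConfig, channel: int = 1,
                       z: float | None = None) -> np.ndarray:
    """Ideal thin-lens phase focusing a source at distance z onto the sensor
    (quadratic in radius, 1/f = 1/s + 1/z). Useful as the 'perfect lens'
    endpoint against which evolved phase masks are compared."""
    lam = cfg.wavelengths[channel]
    z = cfg.source_distance if z is None else z
    x, y, _ = _pupil_grid(cfg)
    inv_f = 1.0 / cfg.focal_distance + (0.0 if np.isinf(z) else 1.0 / z)
    return -(np.pi / lam) * inv_f * (x**2 + y**2)


def angular_spectrum_propagate(field: np.ndarray, pitch: float,
                               wavelength: float, distance: float
                               ) -> np.ndarray:
    """Propagate a sampled complex field by the angular spectrum method:
    U_out = IFFT[ FFT(U) H ], with the exact transfer function
    H = exp(i k d sqrt(1 - (lam fx)^2 - (lam fy)^2)) and evanescent
    components suppressed. No padding — the caller embeds the field in
    whatever window suppresses wraparound."""
    k = 2 * np.pi / wavelength
    m = field.shape[0]
    fx = np.fft.fftfreq(m, d=pitch)
    fxx, fyy = np.meshgrid(fx, fx, indexing="xy")
    arg = 1.0 - (wavelength * fxx) ** 2 - (wavelength * fyy) ** 2
    h = np.where(arg > 0,
                 np.exp(1j * k * distance * np.sqrt(np.maximum(arg, 0.0))),
                 0.0)
    return np.fft.ifft2(np.fft.fft2(field) * h)


def propagate_pupil(p: PupilFunction, cfg: OpticsConfig, channel: int = 1,
                    z: float | None = None) -> tuple[np.ndarray, float]:
    """Propagate the post-pupil field to the sensor plane.

    Returns the intensity on the (zero-padded) fine grid and its pitch. The
    incoming field is a spherical wave from a point source at distance z
    (plane wave for z = inf); the pupil field is zero-padded by pad_factor
    before the FFT to suppress wraparound.
    """
    lam = cfg.wavelengths[channel]
    z = cfg.source_distance if z is None else z
    k = 2 * np.pi / lam
    x, y, pitch = _pupil_grid(cfg)

    if np.isinf(z):
        u_in = np.ones_like(x, dtype=complex)
    else:
        u_in = np.exp(1j * k * np.sqrt(x**2 + y**2 + z**2))
    field = p.field * u_in

    n = field.shape[0]
    m = cfg.pad_factor * n
    padded = np.zeros((m, m), dtype=complex)
    lo = (m - n) // 2
    padded[lo:lo + n, lo:lo + n] = field

    out = angular_spectrum_propagate(padded, pitch, lam, cfg.focal_distance)
    return np.abs(out) ** 2, pitch


def _bin_to_kernel(intensity: np.ndarray, pitch: float, res_h: int, res_w: int,
                   cfg: OpticsConfig) -> np.ndarray:
    """Accumulate fine-grid intensity into (res_h+1, res_w+1) sensor-pitch
    cells centered on the optical axis; energy outside is discarded."""
    kh, kw = res_h + 1, res_w + 1
    cell_h = cfg.sensor_size / res_h
    cell_w = cfg.sensor_size / res_w
    m = intensity.shape[0]
    c = (np.arange(m) - (m - 1) / 2.0) * pitch
    ix = np.floor(c / cell_w + kw / 2.0).astype(int)
    iy = np.floor(c / cell_h + kh / 2.0).astype(int)
    kern = np.zeros((kh, kw))
    okx = (ix >= 0) & (ix < kw)
    oky = (iy >= 0) & (iy < kh)
    sub = intensity[np.ix_(oky, okx)]
    np.add.at(kern, (iy[oky][:, None], ix[okx][None, :]), sub)
    return kern


def compute_psf(p: PupilFunction, cfg: OpticsConfig, channel: int,
                res_h: int, res_w: int, z: float | None = None) -> np.ndarray:
    """One unit-sum PSF channel of size (res_h+1, res_w+1).

    A fully closed pupil produces an all-zero kernel (the caller flags the
    eye as blind rather than erroring — evolution must be free to visit it).
    """
    if not np.any(p.amplitude):
        return np.zeros((res_h + 1, res_w + 1))
    intensity, pitch = propagate_pupil(p, cfg, channel, z)
    kern = _bin_to_kernel(intensity, pitch, res_h, res_w, cfg)
    total = kern.sum()
    if total <= 0:
        return np.zeros((res_h + 1, res_w + 1))
    return kern / total


def compute_psf_stack(og: OpticalGene, morph: MorphologicalGene,
                      cfg: OpticsConfig, z: float | None = None) -> PSFStack:
    """Per-channel PSF stack for an eye; delta kernels if optics disabled."""
    if not og.enabled:
        return delta_psf_stack(morph.res_h, morph.res_w)
    if og.aperture_fraction == 0.0:
        return PSFStack(
            kernels=[np.zeros((morph.res_h + 1, morph.res_w + 1))] * 3,
            blind=True)
    kernels = []
    for ch in range(3):
        pupil = build_pupil_function(og, cfg, ch)
        kernels.append(compute_psf(pupil, cfg, ch, morph.res_h, morph.res_w, z))
    return PSFStack(kernels=kernels)


def delta_psf_stack(res_h: int, res_w: int) -> PSFStack:
    """Perfect-lens (no blur) kernels: a centered delta per channel."""
    k = np.zeros((res_h + 1, res_w + 1))
    k[res_h // 2, res_w // 2] = 1.0
    return PSFStack(kernels=[k.copy() for _ in range(3)])


# ---------------------------------------------------------------------------
# Image formation


def render_retinal_image(scene: LatentScene, psf: PSFStack, og: OpticalGene,
                         cfg: OpticsConfig,
                         rng: np.random.Generator | None = None,
                         return_preclip: bool = False):
    """Form the noisy sensor image from a padded latent scene.

    Per channel: valid-mode 2D convolution with the unit-sum kernel, center
    crop to the sensor resolution, scaling by the a^2 relative throughput,
    linear sensor response, additive Gaussian noise, clip to [0, 1].
    """
    kh, kw = psf.kernels[0].shape
    res_h, res_w = kh - 1, kw - 1
    expect = latent_shape(res_h, res_w)
    if scene.image.shape[:2] != expect:
        raise ValueError(
            f"latent scene shape {scene.image.shape[:2]} does not match "
            f"required padded shape {expect} for a {res_h}x{res_w} eye")
    throughput = og.aperture_fraction ** 2
    out = np.empty((res_h, res_w, 3))
    for ch in range(3):
        conv = signal.convolve2d(scene.image[:, :, ch], psf.kernels[ch],
                                 mode="valid")
        oy = (conv.shape[0] - res_h) // 2
        ox = (conv.shape[1] - res_w) // 2
        out[:, :, ch] = conv[oy:oy + res_h, ox:ox + res_w] * throughput
    preclip = out.copy()
    if cfg.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        out = out + rng.normal(0.0, cfg.noise_sigma, size=out.shape)
    img = RetinalImage(pixels=np.clip(out, 0.0, 1.0))
    return (img, preclip) if return_preclip else img


# ---------------------------------------------------------------------------
# Metrics


def compute_mtf(kernel: np.ndarray, n_bins: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged modulation transfer function of one PSF channel.

    Returns (frequencies, mtf) with frequencies normalized so 1.0 is the
    Nyquist limit of the kernel grid; MTF(0) = 1 for any unit-sum kernel.
    """
    k = np.asarray(kernel, dtype=float)
    if k.sum() <= 0:
        freqs = np.linspace(0, 1, n_bins or max(k.shape))
        return freqs, np.zeros_like(freqs)
    otf = np.abs(np.fft.fftshift(np.fft.fft2(k / k.sum())))
    h, w = k.shape
    fy = np.fft.fftshift(np.fft.fftfreq(h)) / 0.5  # Nyquist-normalized
    fx = np.fft.fftshift(np.fft.fftfreq(w)) / 0.5
    rr = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    n_bins = n_bins or max(h, w)
    edges = np.linspace(0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mtf = np.zeros(n_bins)
    for i in range(n_bins):
        sel = (rr >= edges[i]) & (rr < edges[i + 1])
        mtf[i] = otf[sel].mean() if np.any(sel) else np.nan
    # fill empty bins by previous value, anchor DC at 1
    for i in range(n_bins):
        if np.isnan(mtf[i]):
            mtf[i] = mtf[i - 1] if i else 1.0
    mtf = np.clip(mtf, 0.0, None)
    mtf[0] = 1.0
    return centers, np.minimum(mtf, 1.0)


def mtf_area(kernel: np.ndarray) -> float:
    """Area under the radially averaged MTF on the Nyquist-normalized axis,
    normalized so a delta kernel (MTF = 1 everywhere) scores 1."""
    f, m = compute_mtf(kernel)
    return float(np.trapezoid(m, f) / np.trapezoid(np.ones_like(m), f))


def image_quality(psf: PSFStack, og: OpticalGene) -> float:
    """Image quality = spatial precision x light collection.

    Spatial precision is the channel-mean MTF area in [0, 1]; light
    collection is the a^2 relative throughput. A sharp, fully open eye
    scores 1; a sharp pinhole is capped by its tiny throughput; a blurry
    open eye by its low MTF area.
    """
    sharp = float(np.mean([mtf_area(k) for k in psf.kernels]))
    return sharp * og.aperture_fraction ** 2


def compute_cpd(morph: MorphologicalGene) -> float:
    """Visual acuity in cycles per degree: the Nyquist sampling limit
    res_w / (2 fov) of the best eye (all eyes share one morphology, so this
    is the per-eye value)."""
    return morph.res_w / (2.0 * morph.fov_deg)


def compare_images(reference: np.ndarray, test: np.ndarray
                   ) -> tuple[float, float]:
    """(PSNR in dB, SSIM) between two images in [0, 1] of identical shape.
    PSNR is infinite for identical images."""
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("images must share a shape")
    psnr = peak_signal_noise_ratio(reference, test, data_range=1.0)
    side = min(reference.shape[0], reference.shape[1])
    win = min(7, side if side % 2 == 1 else side - 1)
    kw = {"channel_axis": -1} if reference.ndim == 3 else {}
    ssim = structural_similarity(reference, test, data_range=1.0,
                                 win_size=win, **kw)
    return float(psnr), float(ssim)


def save_image_png(path, array: np.ndarray, log_scale: bool = False) -> None:
    """Write an array as an 8-bit PNG (log-scaled for PSF kernels)."""
    import imageio.v3 as iio

    a = np.asarray(array, dtype=float)
    if log_scale:
        a = np.log10(a + 1e-12)
        a = (a - a.min()) / (a.max() - a.min() + 1e-12)
    iio.imwrite(path, (np.clip(a, 0, 1) * 255).astype(np.uint8))
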