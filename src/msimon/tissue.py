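"""Physically based reflectance simulation of three-layer tissue.

Tissue is modelled as three infinitely wide slabs, each described by seven
physiological/optical parameters: blood volume fraction ``v_hb``, hemoglobin
oxygenation ``s``, reduced scattering at 500 nm ``a_mie`` (cm^-1), scattering
power ``b_mie``, Henyey-Greenstein anisotropy ``g``, refractive index ``n``
and thickness ``d`` (cm).  Per wavelength the absorption coefficient follows
from the hemoglobin extinction spectra,

    mu_a(l) = v_hb [s eps_HbO2(l) + (1 - s) eps_Hb(l)] ln(10) * 150 g/l / 64500 g/mol,

and the scattering coefficient from a Mie-type power law anchored at 500 nm,

    mu_s(l) = a_mie / (1 - g) * (l / 500 nm)^(-b_mie).

Diffuse reflectance spectra are obtained by Monte-Carlo photon transport
(see :mod:`msimon._mc_kernel`) and, via the camera model, converted into
16-band measurements for flow pretraining and synthetic patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._mc_kernel import simulate_slab_kernel
from .camera import CameraModel, integrate_bands_batch

__all__ = [
    "ExtinctionTable",
    "LayerOpticalProps",
    "TissueSample",
    "SimulatedSpectrum",
    "SAMPLING_RANGES",
    "HB_CONCENTRATION_G_PER_L",
    "HB_MOLAR_MASS_G_PER_MOL",
    "absorption_coefficient",
    "scattering_coefficient",
    "sample_tissue",
    "simulate_slab",
    "simulate_reflectance",
    "build_pretraining_corpus",
]

HB_CONCENTRATION_G_PER_L = 150.0
HB_MOLAR_MASS_G_PER_MOL = 6.45e4

#: Uniform sampling ranges for each layer parameter.
SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "v_hb": (0.0, 0.30),
    "s": (0.0, 1.0),
    "a_mie": (5.0, 50.0),
    "b_mie": (0.3, 3.0),
    "g": (0.80, 0.95),
    "n": (1.33, 1.54),
    "d": (0.002, 0.2),
}

N_LAYERS = 3
PARAM_NAMES = tuple(SAMPLING_RANGES)


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and Hb per nm.

    Units: liter mol^-1 cm^-1.  The bundled default table is a *synthetic*
    stand-in with the qualitative shape of the real hemoglobin spectra (see
    ``scripts/generate_synthetic_extinction.py``).
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.eps_hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        self.eps_hb = np.asarray(self.eps_hb, dtype=float)
        if self.eps_hbo2.shape != self.wavelengths.shape or self.eps_hb.shape != self.wavelengths.shape:
            raise ValueError("extinction columns must match the wavelength grid")
        if np.any(self.eps_hbo2 < 0) or np.any(self.eps_hb < 0):
            raise ValueError("extinction coefficients must be nonnegative")

    @classmethod
    def default(cls) -> "ExtinctionTable":
        with resources.files("msimon.data").joinpath(
            "synthetic_hb_extinction.csv"
        ).open("rb") as fh:
            data = np.genfromtxt(fh, delimiter=",", names=True)
        return cls(data["wavelength_nm"], data["eps_hbo2"], data["eps_hb"])

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(data["wavelength_nm"], data["eps_hbo2"], data["eps_hb"])

    def _check_range(self, wl: np.ndarray) -> None:
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside extinction table range "
                f"[{self.wavelengths[0]:.0f}, {self.wavelengths[-1]:.0f}] nm"
            )

    def interp(self, wl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(wl, dtype=float)
        self._check_range(wl)
        return (
            np.interp(wl, self.wavelengths, self.eps_hbo2),
            np.interp(wl, self.wavelengths, self.eps_hb),
        )


@dataclass
class LayerOpticalProps:
    """Parameters of a single tissue slab (units noted in the module docstring)."""

    v_hb: float
    s: float
    a_mie: float
    b_mie: float
    g: float
    n: float
    d: float

    def validate(self, strict_ranges: bool = True) -> None:
        if self.d <= 0:
            raise ValueError("layer thickness must be positive")
        if strict_ranges:
            for name in PARAM_NAMES:
                lo, hi = SAMPLING_RANGES[name]
                v = getattr(self, name)
                if not (lo - 1e-12 <= v <= hi + 1e-12):
                    raise ValueError(
                        f"layer parameter {name}={v} outside sampling range [{lo}, {hi}]"
                    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])


@dataclass
class TissueSample:
    """Ordered stack of exactly three layer parameter sets (top first)."""

    layers: list[LayerOpticalProps]

    def __post_init__(self) -> None:
        if len(self.layers) != N_LAYERS:
            raise ValueError("a tissue sample consists of exactly 3 layers")

    def as_array(self) -> np.ndarray:
        return np.stack([layer.as_array() for layer in self.layers])


@dataclass
class SimulatedSpectrum:
    wavelengths: np.ndarray
    reflectance: np.ndarray
    n_photons: int
    rng_seed: int
    transmittance: np.ndarray | None = None
    absorbed: np.ndarray | None = None


def absorption_coefficient(
    v_hb: float, s: float, wl: np.ndarray, tab: ExtinctionTable
) -> np.ndarray:
    """Blood absorption coefficient mu_a in cm^-1 at wavelength(s) ``wl``."""
    eps_hbo2, eps_hb = tab.interp(wl)
    factor = np.log(10.0) * HB_CONCENTRATION_G_PER_L / HB_MOLAR_MASS_G_PER_MOL
    return v_hb * (s * eps_hbo2 + (1.0 - s) * eps_hb) * factor


def scattering_coefficient(
    a_mie: float, b_mie: float, g: float, wl: np.ndarray
) -> np.ndarray:
    """Scattering coefficient mu_s in cm^-1 from the reduced-scattering power law."""
    if g >= 1.0:
        raise ValueError("anisotropy g must be < 1")
    wl = np.asarray(wl, dtype=float)
    return a_mie / (1.0 - g) * (wl / 500.0) ** (-b_mie)


def sample_tissue(
    n: int,
    rng: np.random.Generator | int | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TissueSample]:
    """Draw ``n`` tissue samples with independent uniform layer parameters."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ranges = ranges or SAMPLING_RANGES
    samples = []
    for _ in range(n):
        layers = []
        for _ in range(N_LAYERS):
            draws = {
                name: rng.uniform(*ranges.get(name, SAMPLING_RANGES[name]))
                for name in PARAM_NAMES
            }
            layers.append(LayerOpticalProps(**draws))
        samples.append(TissueSample(layers))
    return samples


def simulate_slab(
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    g: np.ndarray,
    n_idx: np.ndarray,
    d: np.ndarray,
    n_photons: int,
    seed: int,
) -> tuple[float, float, float]:
    """Single-wavelength transport; returns (reflected, transmitted, absorbed).

    Low-level entry point used by the spectrum simulator and by the physics
    tests (energy conservation, Beer-attenuation limits).
    """
    arrs = [np.ascontiguousarray(np.atleast_1d(a), dtype=float) for a in (mu_a, mu_s, g, n_idx, d)]
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise ValueError("optical coefficients must be finite")
    if np.any(arrs[4] <= 0):
        raise ValueError("layer thicknesses must be positive")
    return simulate_slab_kernel(*arrs, int(n_photons), int(seed) % (2**31))


def _layer_arrays(
    sample: TissueSample, wl: np.ndarray, tab: ExtinctionTable
) -> tuple[np.ndarray, ...]:
    L = wl.size
    mu_a = np.empty((N_LAYERS, L))
    mu_s = np.empty((N_LAYERS, L))
    g = np.empty(N_LAYERS)
    n_idx = np.empty(N_LAYERS)
    d = np.empty(N_LAYERS)
    for i, layer in enumerate(sample.layers):
        mu_a[i] = absorption_coefficient(layer.v_hb, layer.s, wl, tab)
        mu_s[i] = scattering_coefficient(layer.a_mie, layer.b_mie, layer.g, wl)
        g[i] = layer.g
        n_idx[i] = layer.n
        d[i] = layer.d
    return mu_a, mu_s, g, n_idx, d


def simulate_reflectance(
    sample: TissueSample,
    wavelengths: np.ndarray | None = None,
    tab: ExtinctionTable | None = None,
    n_photons: int = 10_000,
    seed: int = 0,
    track_energy: bool = False,
) -> SimulatedSpectrum:
    """Monte-Carlo diffuse reflectance spectrum of a three-layer sample.

    Photons are launched normally onto the top layer from an ambient medium
    with n = 1; the reported reflectance is the total fraction of launched
    weight escaping upward (specular + diffuse).  Each wavelength uses an
    independent, deterministically derived substream of the seed.
    """
    if n_photons < 100:
        raise ValueError("n_photons must be >= 100")
    wl = (
        np.arange(300.0, 1000.0 + 1e-9, 2.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    tab = tab or ExtinctionTable.default()
    mu_a, mu_s, g, n_idx, d = _layer_arrays(sample, wl, tab)
    if not (np.all(np.isfinite(mu_a)) and np.all(np.isfinite(mu_s))):
        raise ValueError("non-finite optical coefficients")

    refl = np.empty(wl.size)
    trans = np.empty(wl.size) if track_energy else None
    absd = np.empty(wl.size) if track_energy else None
    for i in range(wl.size):
        sub = (int(seed) + 1_000_003 * i) % (2**31)
        r, t, a = simulate_slab_kernel(
            np.ascontiguousarray(mu_a[:, i]),
            np.ascontiguousarray(mu_s[:, i]),
            g, n_idx, d, int(n_photons), sub,
        )
        refl[i] = r
        if track_energy:
            trans[i] = t
            absd[i] = a
    return SimulatedSpectrum(
        wavelengths=wl,
        reflectance=refl,
        n_photons=n_photons,
        rng_seed=int(seed),
        transmittance=trans,
        absorbed=absd,
    )


def build_pretraining_corpus(
    n_samples: int,
    cam: CameraModel,
    tab: ExtinctionTable | None = None,
    n_photons: int = 10_000,
    seed: int = 0,
    restrict_to_active: bool = True,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a corpus of 16-band tissue spectra for ensemble pretraining.

    Returns ``(bands, params)`` with shapes (n_samples, 16) and
    (n_samples, 3, 7).  With ``restrict_to_active`` the Monte-Carlo loop
    skips wavelengths carrying zero band weight (outside the bandpass),
    which leaves the band integrals unchanged.
    """
    tab = tab or ExtinctionTable.default()
    rng = np.random.default_rng(seed)
    samples = sample_tissue(n_samples, rng, ranges=ranges)
    wl = cam.wavelengths[cam.active_mask()] if restrict_to_active else cam.wavelengths

    spectra = np.empty((n_samples, wl.size))
    params = np.empty((n_samples, N_LAYERS, len(PARAM_NAMES)))
    for i, sample in enumerate(samples):
        spec = simulate_reflectance(
            sample, wl, tab, n_photons=n_photons, seed=int(seed) + 7919 * (i + 1)
        )
        spectra[i] = spec.reflectance
        params[i] = sample.as_array()
    bands = integrate_bands_batch(wl, spectra, cam)
    return bands, params
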