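"""Monte-Carlo photon transport kernel for layered slab tissue.

Single-wavelength weighted-photon transport through a stack of infinitely
wide plane-parallel layers, in the style of the classic multi-layered MC
formulation: exponential step sampling with mu_t = mu_a + mu_s, fractional
weight deposition mu_a/mu_t per interaction, Henyey-Greenstein scattering,
Fresnel reflection/refraction at every refractive-index boundary (ambient
medium n = 1 above and below), and Russian-roulette termination (survival
probability 0.1 below weight 1e-4, weight-conserving in expectation).

The kernel is compiled with numba; it is deterministic for a fixed seed and
single-threaded by design.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_BIG = 1e12


@njit(cache=False, fastmath=False)
def _fresnel(ni: float, nt: float, ci: float) -> float:
    """Unpolarised Fresnel reflectance for incidence cosine ci (>0)."""
    if ni == nt:
        return 0.0
    if ci > 0.99999999:
        r = (nt - ni) / (nt + ni)
        return r * r
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = ni * si / nt
    if st >= 1.0:
        return 1.0  # total internal reflection
    ct = math.sqrt(1.0 - st * st)
    rs = (ni * ci - nt * ct) / (ni * ci + nt * ct)
    rp = (ni * ct - nt * ci) / (ni * ct + nt * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False, fastmath=False)
def simulate_slab_kernel(
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    g: np.ndarray,
    n_idx: np.ndarray,
    d: np.ndarray,
    n_photons: int,
    seed: int,
):
    """Transport ``n_photons`` through the layer stack at one wavelength.

    Returns ``(reflected, transmitted, absorbed)`` as fractions of the
    launched weight.  ``reflected`` includes the specular component at the
    top surface.
    """
    np.random.seed(seed)
    n_layers = mu_a.shape[0]
    bounds = np.empty(n_layers + 1)
    bounds[0] = 0.0
    for i in range(n_layers):
        bounds[i + 1] = bounds[i] + d[i]

    refl = 0.0
    trans = 0.0
    absorbed = 0.0

    for _ in range(n_photons):
        # specular reflection at the ambient/top-layer interface
        r_sp = _fresnel(1.0, n_idx[0], 1.0)
        refl += r_sp
        w = 1.0 - r_sp
        layer = 0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        s_left = 0.0
        alive = True

        while alive:
            mt = mu_a[layer] + mu_s[layer]
            if s_left <= 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                s_left = -math.log(xi)
            step = s_left / mt if mt > 0.0 else _BIG

            if uz > 0.0:
                db = (bounds[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (bounds[layer] - z) / uz
            else:
                db = _BIG

            if db <= step:
                # hit a boundary before completing the step
                s_left -= db * mt
                ni = n_idx[layer]
                going_down = uz > 0.0
                if going_down:
                    z = bounds[layer + 1]
                    nt = n_idx[layer + 1] if layer + 1 < n_layers else 1.0
                else:
                    z = bounds[layer]
                    nt = n_idx[layer - 1] if layer > 0 else 1.0
                ci = abs(uz)
                R = _fresnel(ni, nt, ci)
                if np.random.random() < R:
                    uz = -uz  # internal reflection
                else:
                    # refract
                    ratio = ni / nt
                    si2 = max(0.0, 1.0 - ci * ci)
                    ct = math.sqrt(max(0.0, 1.0 - ratio * ratio * si2))
                    ux *= ratio
                    uy *= ratio
                    uz = ct if going_down else -ct
                    if going_down:
                        if layer + 1 >= n_layers:
                            trans += w
                            alive = False
                        else:
                            layer += 1
                    else:
                        if layer == 0:
                            refl += w
                            alive = False
                        else:
                            layer -= 1
            else:
                # complete the step inside the layer: absorb + scatter
                z += step * uz
                s_left = 0.0
                dw = w * mu_a[layer] / mt
                absorbed += dw
                w -= dw

                gg = g[layer]
                if gg == 0.0:
                    ct = 2.0 * np.random.random() - 1.0
                else:
                    tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                    ct = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                    if ct < -1.0:
                        ct = -1.0
                    elif ct > 1.0:
                        ct = 1.0
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                phi = 2.0 * math.pi * np.random.random()
                cp = math.cos(phi)
                sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux = nux / norm
                    uy = nuy / norm
                    uz = nuz / norm

                if w < WEIGHT_THRESHOLD:
                    if np.random.random() < ROULETTE_SURVIVAL:
                        w /= ROULETTE_SURVIVAL
                    else:
                        alive = False

    inv = 1.0 / n_photons
    return refl * inv, trans * inv, absorbed * inv
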