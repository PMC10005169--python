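"""Beer-Lambert baseline estimation of oxygenation and blood volume.

The classical linearized model relates band absorbance to the hemoglobin
extinction spectra:

    a_k = -log r_k = v_HbO2 * l * eps_HbO2,k + v_Hb * l * eps_Hb,k + g

where ``l`` is the (unknown) optical path length and ``g`` absorbs
wavelength-independent scattering losses.  Because the camera integrates
over comparatively broad filters, the per-nm extinction coefficients are
first averaged over each band's filter response.  The linear system is
solved by ordinary least squares; oxygenation and total hemoglobin follow
as s = v_HbO2 l / (v_HbO2 l + v_Hb l) and v_HbT l = v_HbO2 l + v_Hb l.

Estimates are deliberately *not* clipped to physical ranges: implausible
values (oxygenation above 100 %, negative concentrations) are reported as
such -- they are precisely the failure mode that motivates the
distribution-based ischemia index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .camera import CameraModel
from .flow import evaluate_auroc
from .tissue import ExtinctionTable

__all__ = [
    "BandExtinctions",
    "BeerLambertFit",
    "BeerLambertModel",
    "band_average_extinctions",
    "fit_beer_lambert",
    "classify_by_baseline",
]


@dataclass
class BandExtinctions:
    """Extinction coefficients averaged over each band's filter response."""

    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        self.eps_hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        self.eps_hb = np.asarray(self.eps_hb, dtype=float)
        if np.any(self.eps_hbo2 < 0) or np.any(self.eps_hb < 0):
            raise ValueError("band extinctions must be nonnegative")

    def design_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.eps_hbo2, self.eps_hb, np.ones_like(self.eps_hbo2)]
        )


@dataclass
class BeerLambertFit:
    """OLS solution of the linearized Beer-Lambert system for one spectrum."""

    v_hbo2_l: float
    v_hb_l: float
    scatter_offset: float
    s: float
    v_hbt_l: float
    residual: float


def band_average_extinctions(
    tab: ExtinctionTable, cam: CameraModel
) -> BandExtinctions:
    """Filter-response-weighted mean extinction per camera band."""
    eps_hbo2, eps_hb = tab.interp(cam.wavelengths)
    f = cam.filter_responses
    denom = f.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("a band has zero filter response")
    return BandExtinctions(
        eps_hbo2=(f @ eps_hbo2) / denom,
        eps_hb=(f @ eps_hb) / denom,
    )


def fit_beer_lambert(
    reflectance: np.ndarray, bx: BandExtinctions, cond_limit: float = 1e12
) -> BeerLambertFit:
    """Fit one 16-band reflectance spectrum.

    Raises for non-positive reflectances (absorbance undefined) and for a
    collinear design (extinction spectra proportional to each other).
    """
    r = np.asarray(reflectance, dtype=float).ravel()
    if np.any(r <= 0):
        raise ValueError(
            f"reflectance must be positive in every band to take the log "
            f"(min {r.min():.3g})"
        )
    a = -np.log(r)
    X = bx.design_matrix()
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > cond_limit:
        raise np.linalg.LinAlgError(
            "collinear Beer-Lambert design (extinction spectra are "
            "linearly dependent over the camera bands)"
        )
    coef, _, _, _ = np.linalg.lstsq(X, a, rcond=None)
    v_hbo2_l, v_hb_l, offset = (float(c) for c in coef)
    v_hbt_l = v_hbo2_l + v_hb_l
    s = v_hbo2_l / v_hbt_l if v_hbt_l != 0 else np.nan
    residual = float(np.linalg.norm(a - X @ coef))
    return BeerLambertFit(
        v_hbo2_l=v_hbo2_l,
        v_hb_l=v_hb_l,
        scatter_offset=offset,
        s=s,
        v_hbt_l=v_hbt_l,
        residual=residual,
    )


class BeerLambertModel:
    """Beer-Lambert regression over a stack of ROI-median reflectance spectra.

    statsmodels-style: the model is constructed from the data (an (n, 16)
    matrix of reference-normalized -- *not* l2-normalized -- reflectances
    plus band-averaged extinctions) and ``fit()`` returns a results object
    with per-spectrum parameter estimates.
    """

    def __init__(self, reflectances: np.ndarray, band_extinctions: BandExtinctions):
        self.reflectances = np.atleast_2d(np.asarray(reflectances, dtype=float))
        self.band_extinctions = band_extinctions

    @classmethod
    def from_components(
        cls, reflectances: np.ndarray, tab: ExtinctionTable, cam: CameraModel
    ) -> "BeerLambertModel":
        return cls(reflectances, band_average_extinctions(tab, cam))

    def fit(self) -> "BeerLambertResults":
        fits = [fit_beer_lambert(r, self.band_extinctions) for r in self.reflectances]
        return BeerLambertResults(self, fits)


class BeerLambertResults:
    def __init__(self, model: BeerLambertModel, fits: list[BeerLambertFit]):
        self.model = model
        self.fits = fits

    def __getattr__(self, name):
        if name in ("s", "v_hbt_l", "v_hbo2_l", "v_hb_l", "scatter_offset", "residual"):
            return np.array([getattr(f, name) for f in self.fits])
        raise AttributeError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "s": self.s,
                "v_hbt_l": self.v_hbt_l,
                "v_hbo2_l": self.v_hbo2_l,
                "v_hb_l": self.v_hb_l,
                "offset": self.scatter_offset,
                "residual": self.residual,
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Beer-Lambert regression results",
            f"  n spectra:          {len(self.fits)}",
            f"  oxygenation s:      mean {df['s'].mean():.4f}  "
            f"[{df['s'].min():.4f}, {df['s'].max():.4f}]",
            f"  v_HbT * l:          mean {df['v_hbt_l'].mean():.4e}",
            f"  scatter offset g:   mean {df['offset'].mean():.4e}",
            f"  residual norm:      mean {df['residual'].mean():.4e}",
        ]
        n_implausible = int(((df["s"] < 0) | (df["s"] > 1)).sum())
        lines.append(f"  implausible s (outside [0,1]), reported unclipped: {n_implausible}")
        return "\n".join(lines)


def classify_by_baseline(
    fits_per_frame: list[BeerLambertFit] | BeerLambertResults,
    state_labels: np.ndarray,
    ischemic_sign: float = -1.0,
) -> dict[str, float]:
    """Per-parameter AU-ROC of the Beer-Lambert estimates as ischemia scores.

    ``state_labels`` holds 0 (perfused) / 1 (ischemic) per frame.  Ischemia
    lowers oxygenation and blood volume, so by default the negated estimate
    is used as the score (``ischemic_sign = -1``) such that ischemic frames
    are the positive, higher-scoring class.
    """
    if isinstance(fits_per_frame, BeerLambertResults):
        s = fits_per_frame.s
        v = fits_per_frame.v_hbt_l
    else:
        s = np.array([f.s for f in fits_per_frame])
        v = np.array([f.v_hbt_l for f in fits_per_frame])
    labels = np.asarray(state_labels).astype(bool)
    if labels.shape != s.shape:
        raise ValueError("labels must align with the fitted frames")
    return {
        "auroc_s": evaluate_auroc(ischemic_sign * s[~labels], ischemic_sign * s[labels]),
        "auroc_v_hbt": evaluate_auroc(
            ischemic_sign * v[~labels], ischemic_sign * v[labels]
        ),
    }
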