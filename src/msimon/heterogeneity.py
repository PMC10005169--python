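"""Interpatient-variability analyses of cohort spectra.

Three complementary views of how much spectral variation is attributable to
the patient versus the perfusion state:

* PCA projection of all frame spectra to two dimensions,
* a per-band random-intercept linear mixed model
  ``r_ij = alpha + beta * S_ij + delta_i + eps_ij`` (patient effect
  delta_i ~ N(0, sigma_delta^2), residual eps_ij ~ N(0, sigma_eps^2))
  fitted by REML, from which proportions of explained variability are
  derived, and
* per-state 2-D kernel density estimates of the PCA scores.

The fixed-effect (state) contribution to total variability is computed as
beta^2 * Var(S) over the realised design, normalised together with the two
variance components so the three proportions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpectra",
    "VarianceDecomposition",
    "VarianceDecompositionModel",
    "pca_project",
    "fit_mixed_model",
    "kde_density_2d",
]


@dataclass
class CohortSpectra:
    """Per-frame averaged ROI-median spectra with patient/state labels."""

    spectra: np.ndarray  # (n_frames_total, 16)
    patient: np.ndarray  # patient id per row
    state: np.ndarray  # 0 perfused / 1 ischemic per row

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.patient = np.asarray(self.patient)
        self.state = np.asarray(self.state, dtype=int)
        n = self.spectra.shape[0]
        if self.patient.shape != (n,) or self.state.shape != (n,):
            raise ValueError("every spectrum row needs a patient and a state label")
        if not np.isin(self.state, [0, 1]).all():
            raise ValueError("state labels must be 0 (perfused) or 1 (ischemic)")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.spectra, columns=[f"band_{k:02d}" for k in range(self.n_bands)]
        )
        df.insert(0, "patient", self.patient)
        df.insert(1, "state", self.state)
        return df


@dataclass
class VarianceDecomposition:
    """Per-band explained-variability proportions and component estimates."""

    band: int
    alpha: float
    beta: float
    sigma2_patient: float
    sigma2_residual: float
    state_prop: float
    patient_prop: float
    residual_prop: float
    converged: bool = True


def pca_project(cohort: CohortSpectra) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of all cohort rows.

    Returns ``(scores (n, 2), explained_variance_fractions (2,))``.
    Centering only (no per-band scaling), matching a covariance-based PCA.
    """
    from sklearn.decomposition import PCA

    p = PCA(n_components=2, svd_solver="full")
    scores = p.fit_transform(cohort.spectra)
    return scores, p.explained_variance_ratio_.copy()


def fit_mixed_model(cohort: CohortSpectra, band: int) -> VarianceDecomposition:
    """REML random-intercept model for one band.

    Raises for degenerate designs (single patient, or a single state);
    non-convergence is flagged on the result and the proportions withheld
    (NaN).
    """
    import statsmodels.api as sm

    if np.unique(cohort.patient).size < 2:
        raise ValueError("mixed model needs at least 2 patients")
    if np.unique(cohort.state).size < 2:
        raise ValueError("mixed model needs both perfusion states")
    y = cohort.spectra[:, band]
    X = sm.add_constant(cohort.state.astype(float))
    model = sm.MixedLM(y, X, groups=cohort.patient)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    alpha, beta = float(res.fe_params[0]), float(res.fe_params[1])
    sigma2_patient = float(np.asarray(res.cov_re)[0, 0])
    sigma2_residual = float(res.scale)
    converged = bool(res.converged)
    if converged:
        var_state = beta**2 * np.var(cohort.state.astype(float), ddof=0)
        total = var_state + sigma2_patient + sigma2_residual
        props = (var_state / total, sigma2_patient / total, sigma2_residual / total)
    else:
        props = (np.nan, np.nan, np.nan)
    return VarianceDecomposition(
        band=band,
        alpha=alpha,
        beta=beta,
        sigma2_patient=sigma2_patient,
        sigma2_residual=sigma2_residual,
        state_prop=props[0],
        patient_prop=props[1],
        residual_prop=props[2],
        converged=converged,
    )


class VarianceDecompositionModel:
    """Mixed-model variance decomposition across all bands (Model/Results)."""

    def __init__(self, cohort: CohortSpectra):
        self.cohort = cohort

    def fit(self) -> "VarianceDecompositionResults":
        decomps = [
            fit_mixed_model(self.cohort, k) for k in range(self.cohort.n_bands)
        ]
        return VarianceDecompositionResults(self, decomps)


class VarianceDecompositionResults:
    def __init__(self, model, decomps: list[VarianceDecomposition]):
        self.model = model
        self.decomps = decomps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": [d.band for d in self.decomps],
                "state_prop": [d.state_prop for d in self.decomps],
                "patient_prop": [d.patient_prop for d in self.decomps],
                "residual_prop": [d.residual_prop for d in self.decomps],
                "beta": [d.beta for d in self.decomps],
                "sigma2_patient": [d.sigma2_patient for d in self.decomps],
                "sigma2_residual": [d.sigma2_residual for d in self.decomps],
                "converged": [d.converged for d in self.decomps],
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        n_patient_dominated = int((df["patient_prop"] > df["state_prop"]).sum())
        return "\n".join(
            [
                "Variance decomposition (random-intercept mixed model, REML)",
                f"  bands fitted:                    {len(df)}",
                f"  mean state proportion:           {df['state_prop'].mean():.3f}",
                f"  mean patient proportion:         {df['patient_prop'].mean():.3f}",
                f"  mean residual proportion:        {df['residual_prop'].mean():.3f}",
                f"  bands dominated by patient:      {n_patient_dominated}/{len(df)}",
            ]
        )


def kde_density_2d(
    scores_by_state: dict[str, np.ndarray],
    grid_size: int = 128,
    padding_bandwidths: float = 4.0,
) -> dict:
    """Per-state Gaussian KDE on a shared 2-D grid.

    Silverman-bandwidth product kernel; the grid spans all states' scores
    plus a margin of several bandwidths so each density integrates to ~1.
    Returns ``{"x": ..., "y": ..., "density": {state: (g, g) array}}``.
    """
    from scipy.stats import gaussian_kde

    all_scores = np.vstack(list(scores_by_state.values()))
    if all_scores.shape[1] != 2:
        raise ValueError("scores must be 2-D projections")
    span = all_scores.max(axis=0) - all_scores.min(axis=0)
    pad = padding_bandwidths * np.maximum(
        all_scores.std(axis=0) * all_scores.shape[0] ** (-1 / 6), 0.05 * span + 1e-12
    )
    lo = all_scores.min(axis=0) - pad
    hi = all_scores.max(axis=0) + pad
    x = np.linspace(lo[0], hi[0], grid_size)
    y = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(x, y, indexing="ij")
    positions = np.vstack([gx.ravel(), gy.ravel()])
    densities = {}
    for state, pts in scores_by_state.items():
        pts = np.asarray(pts, dtype=float)
        kde = gaussian_kde(pts.T, bw_method="silverman")
        densities[state] = kde(positions).reshape(grid_size, grid_size)
    return {"x": x, "y": y, "density": densities}


def plot_pca_density(result: dict, out_path, labels: tuple[str, ...] | None = None):
    """Contour plot of the per-state KDE surfaces (visualisation helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (state, dens) in enumerate(result["density"].items()):
        ax.contour(result["x"], result["y"], dens.T, levels=5, linewidths=1.0)
        ax.plot([], [], label=state)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
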