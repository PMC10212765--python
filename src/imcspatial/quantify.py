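"""Per-cell intensity measurement and two-Gaussian marker gating.

Each marker's per-cell intensities are modeled as a mixture of two
Gaussians — background staining and true (foreground) staining.  The
fitted model yields a positivity threshold at the point between the two
component means where the posterior probability of foreground reaches
one half, which is unique for well-separated fits and robust to unequal
component weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from skimage.measure import regionprops_table
from sklearn.mixture import GaussianMixture

from .exceptions import ConfigurationError, DegenerateInputError
from .io import (
    LabelMask,
    MultiplexImage,
    intensity_col,
    positive_col,
    table_markers,
)

ARCSINH_COFACTOR = 5.0


def apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    """identity, or the cytometry-conventional arcsinh with cofactor 5."""
    if transform == "identity":
        return np.asarray(values, dtype=np.float64)
    if transform == "arcsinh":
        return np.arcsinh(np.asarray(values, dtype=np.float64) / ARCSINH_COFACTOR)
    raise ConfigurationError(f"unknown transform {transform!r}")


@dataclass
class MarkerModel:
    """Fitted background/foreground mixture for one marker."""

    marker: str
    w_bg: float
    mu_bg: float
    sd_bg: float
    w_fg: float
    mu_fg: float
    sd_fg: float
    threshold: float
    transform: str = "identity"
    converged: bool = True

    def __post_init__(self) -> None:
        assert abs(self.w_bg + self.w_fg - 1.0) < 1e-9
        assert self.mu_fg > self.mu_bg

    def posterior_fg(self, x) -> np.ndarray:
        """P(foreground | transformed intensity x)."""
        x = np.asarray(x, dtype=np.float64)
        p_bg = self.w_bg * norm.pdf(x, self.mu_bg, self.sd_bg)
        p_fg = self.w_fg * norm.pdf(x, self.mu_fg, self.sd_fg)
        with np.errstate(invalid="ignore"):
            post = p_fg / (p_bg + p_fg)
        # far in either tail the dominant component decides
        far = p_bg + p_fg == 0
        if np.any(far):
            mid = (self.mu_bg + self.mu_fg) / 2
            post = np.where(far, (x > mid).astype(float), post)
        return post


def measure_cells(image: MultiplexImage, mask: LabelMask) -> pd.DataFrame:
    """One row per labeled cell: centroid, area, mean intensity per marker.

    Intensity is the arithmetic mean of each channel over the cell's
    pixels; (x, y) is the mean of member-pixel (column, row) coordinates.
    """
    if mask.shape != image.shape:
        raise ConfigurationError(
            f"mask shape {mask.shape} does not match image {image.shape}")
    if mask.n_cells == 0:
        cols = ["cell_id", "x", "y", "area_px"]
        cols += [intensity_col(m) for m in image.panel]
        return pd.DataFrame(columns=cols)
    stacked = np.moveaxis(image.pixels, 0, -1)  # (H, W, C) for regionprops
    props = regionprops_table(
        mask.labels,
        intensity_image=stacked,
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    table = pd.DataFrame({
        "cell_id": props["label"],
        "x": props["centroid-1"],
        "y": props["centroid-0"],
        "area_px": props["area"].astype(int),
    })
    for ci, marker in enumerate(image.panel):
        table[intensity_col(marker)] = props[f"intensity_mean-{ci}"]
    return table


def fit_marker_gmm(
    values,
    transform: str = "identity",
    seed: int = 0,
    marker: str = "",
    n_init: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MarkerModel:
    """Fit the two-component Gaussian mixture for one marker by EM.

    k-means initialized, seeded, best of ``n_init`` restarts by
    log-likelihood.  Components are ordered so mu_bg < mu_fg and the
    positivity threshold is the smallest point between the means where
    the posterior probability of foreground reaches 0.5.

    Raises
    ------
    DegenerateInputError
        Fewer than 20 finite values, or zero variance.
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if len(values) < 20:
        raise DegenerateInputError(
            f"marker {marker or '?'}: need >= 20 finite values, got {len(values)}")
    if np.var(values) == 0:
        raise DegenerateInputError(f"marker {marker or '?'}: zero variance")
    x = apply_transform(values, transform)

    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        init_params="kmeans",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        reg_covar=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm.fit(x[:, None])
    converged = bool(gmm.converged_)
    if not converged:
        warnings.warn(
            f"EM did not converge for marker {marker or '?'} after "
            f"{max_iter} iterations; returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    mu_bg, mu_fg = means[order]
    sd_bg, sd_fg = sds[order]
    w_bg, w_fg = weights[order]
    w_bg, w_fg = w_bg / (w_bg + w_fg), w_fg / (w_bg + w_fg)

    model = MarkerModel(
        marker=marker, w_bg=float(w_bg), mu_bg=float(mu_bg), sd_bg=float(sd_bg),
        w_fg=float(w_fg), mu_fg=float(mu_fg), sd_fg=float(sd_fg),
        threshold=0.0, transform=transform, converged=converged)
    model.threshold = _posterior_half_crossing(model)
    return model


def _posterior_half_crossing(model: MarkerModel) -> float:
    """Smallest x in (mu_bg, mu_fg) with posterior P(fg | x) >= 0.5."""
    lo, hi = model.mu_bg, model.mu_fg
    grid = np.linspace(lo, hi, 512)
    g = model.posterior_fg(grid) - 0.5
    if g[0] >= 0:
        return float(lo + 1e-12 * max(abs(lo), 1.0))
    idx = np.flatnonzero(np.diff(np.signbit(g)))
    if len(idx) == 0:
        # posterior never reaches 0.5 inside the bracket; fall back to
        # the midpoint (only occurs for near-degenerate overlapping fits)
        return float((lo + hi) / 2)
    i = idx[0]
    f = lambda x: float(model.posterior_fg(x) - 0.5)
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))


def fit_all_markers(
    cells: pd.DataFrame,
    transform: str = "identity",
    seed: int = 0,
    markers: list[str] | None = None,
) -> dict[str, MarkerModel]:
    """Fit one mixture per marker column of a cell table."""
    if markers is None:
        markers = table_markers(cells)
    models = {}
    for i, m in enumerate(markers):
        models[m] = fit_marker_gmm(
            cells[intensity_col(m)].to_numpy(),
            transform=transform,
            seed=seed + i,
            marker=m,
        )
    return models


def call_positivity(
    cells: pd.DataFrame, models: dict[str, MarkerModel]
) -> pd.DataFrame:
    """Add boolean positive_<marker> columns; intensities untouched.

    A cell is positive when its transformed intensity is >= the model's
    threshold (boundary counts as positive).
    """
    out = cells.copy()
    for m in table_markers(cells):
        if m not in models:
            raise ConfigurationError(f"no fitted model for marker {m!r}")
        model = models[m]
        x = apply_transform(out[intensity_col(m)].to_numpy(), model.transform)
        out[positive_col(m)] = x >= model.threshold
    return out


def models_to_frame(models: dict[str, MarkerModel]) -> pd.DataFrame:
    """Serialize fitted models (one row per marker) for the models CSV."""
    rows = [
        {
            "marker": m.marker, "w_bg": m.w_bg, "mu_bg": m.mu_bg, "sd_bg": m.sd_bg,
            "w_fg": m.w_fg, "mu_fg": m.mu_fg, "sd_fg": m.sd_fg,
            "threshold": m.threshold, "transform": m.transform,
        }
        for m in models.values()
    ]
    return pd.DataFrame(rows)


def models_from_frame(df: pd.DataFrame) -> dict[str, MarkerModel]:
    models = {}
    for row in df.itertuples(index=False):
        models[row.marker] = MarkerModel(
            marker=row.marker, w_bg=row.w_bg, mu_bg=row.mu_bg, sd_bg=row.sd_bg,
            w_fg=row.w_fg, mu_fg=row.mu_fg, sd_fg=row.sd_fg,
            threshold=row.threshold, transform=row.transform)
    return models
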