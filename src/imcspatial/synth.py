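"""Synthetic multiplexed-image generator with full ground truth.

Emulates imaging-mass-cytometry acquisition of tissue: a ~1 mm^2 field at
~1 um/pixel, nuclei rendered as Gaussian-blurred disks on a nuclear (DNA)
channel, and one channel per marker whose pixels are drawn from a
two-Gaussian background/foreground mixture according to each cell's
ground-truth positivity.  Lineage labels are apportioned deterministically
from configurable abundance vectors, and spatial placement supports
complete spatial randomness (with an optional hard core), Thomas cluster
processes, and tunable pairwise attraction between chosen cell types —
the knobs every downstream stage is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.segmentation import expand_labels

from .exceptions import ConfigurationError
from .io import LabelMask, MultiplexImage

NUCLEAR_MARKER = "DNA"

#: lineage marker dictionary used by the default simulated panel:
#: each lineage's defining markers stain with high probability, everything
#: else at a low background-positivity rate.
DEFAULT_LINEAGE_PROPORTIONS = {
    "cancer": 0.40,
    "macrophage": 0.15,
    "monocyte": 0.08,
    "cytotoxic T cell": 0.08,
    "helper T cell": 0.08,
    "Treg": 0.04,
    "neutrophil": 0.05,
    "endothelial": 0.06,
    "B cell": 0.06,
}

_DEFINING = {
    "cancer": ["PanCK"],
    "macrophage": ["CD68"],
    "monocyte": ["CD14"],
    "cytotoxic T cell": ["CD3", "CD8"],
    "helper T cell": ["CD3", "CD4"],
    "Treg": ["CD3", "CD4", "FOXP3"],
    "neutrophil": ["MPO"],
    "endothelial": ["CD31"],
    "B cell": ["CD20"],
}

DEFAULT_MARKERS = [
    "PanCK", "CD68", "CD14", "CD3", "CD8", "CD4",
    "FOXP3", "MPO", "CD31", "CD20", "PD-1", "Ox40L",
]

_ON, _OFF = 0.97, 0.02


def default_marker_profiles() -> dict[str, dict[str, float]]:
    """Per-lineage foreground probability for every default marker."""
    profiles: dict[str, dict[str, float]] = {}
    for lineage in DEFAULT_LINEAGE_PROPORTIONS:
        prof = {m: _OFF for m in DEFAULT_MARKERS}
        for m in _DEFINING[lineage]:
            prof[m] = _ON
        profiles[lineage] = prof
    # activation markers carried by specific compartments
    profiles["Treg"]["PD-1"] = 0.95
    profiles["cytotoxic T cell"]["PD-1"] = 0.50
    profiles["cancer"]["Ox40L"] = 0.30
    return profiles


@dataclass(frozen=True)
class MixtureParams:
    """Two-Gaussian pixel model for one marker (background vs foreground)."""

    bg_mean: float = 1.0
    bg_sd: float = 0.3
    fg_mean: float = 20.0
    fg_sd: float = 2.0

    def validate(self, name: str) -> None:
        for f in ("bg_mean", "bg_sd", "fg_mean", "fg_sd"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"mixture_params[{name}].{f} must be > 0")
        if self.fg_mean <= self.bg_mean:
            raise ConfigurationError(
                f"mixture_params[{name}]: fg_mean ({self.fg_mean}) must exceed "
                f"bg_mean ({self.bg_mean})"
            )


@dataclass
class SimulationConfig:
    """Everything needed to draw one synthetic field reproducibly.

    Defaults emulate the acquisition regime of the emulated study: a
    1000x1000 px field at 1 um/px (~1 mm^2), mildly blurred nuclei, Poisson
    count noise, and a marker panel with well-separated foreground and
    background components.
    """

    field_size_px: tuple[int, int] = (1000, 1000)
    um_per_px: float = 1.0
    n_cells: int = 1000
    lineage_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_PROPORTIONS))
    marker_profiles: dict[str, dict[str, float]] = field(
        default_factory=default_marker_profiles)
    mixture_params: dict[str, MixtureParams] = field(
        default_factory=lambda: {m: MixtureParams() for m in DEFAULT_MARKERS})
    nuclear_mixture: MixtureParams = field(
        default_factory=lambda: MixtureParams(bg_mean=1.0, bg_sd=0.3,
                                              fg_mean=50.0, fg_sd=5.0))
    nucleus_radius_um: tuple[float, float] = (4.0, 0.8)
    min_nucleus_radius_px: float = 2.0
    psf_sigma_px: float = 1.0
    noise_model: str = "poisson"          # none | gaussian | poisson
    gaussian_noise_sd: float = 0.2
    placement: str = "csr"                # csr | thomas | paired_attraction
    min_separation_px: float = 10.0
    thomas_n_parents: int = 20
    thomas_offspring_sd_px: float = 30.0
    attraction_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    attraction_sd_px: float = 8.0
    cell_expansion_px: int = 2
    fg_mean_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_size_px
        if h <= 0 or w <= 0:
            raise ConfigurationError("field_size_px must be positive")
        if self.um_per_px <= 0:
            raise ConfigurationError("um_per_px must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be nonnegative")
        total = sum(self.lineage_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"lineage_proportions sum to {total!r}, expected 1.0")
        if any(p < 0 for p in self.lineage_proportions.values()):
            raise ConfigurationError("lineage_proportions must be nonnegative")
        for name, mix in self.mixture_params.items():
            mix.validate(name)
        self.nuclear_mixture.validate(NUCLEAR_MARKER)
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if self.placement not in ("csr", "thomas", "paired_attraction"):
            raise ConfigurationError(f"unknown placement {self.placement!r}")
        for a, b, s in self.attraction_pairs:
            if s < 0:
                raise ConfigurationError(
                    f"attraction strength for ({a}, {b}) must be >= 0")
        if self.psf_sigma_px < 0:
            raise ConfigurationError("psf_sigma_px must be nonnegative")

    @property
    def markers(self) -> list[str]:
        return list(self.mixture_params)

    @property
    def panel(self) -> list[str]:
        """Marker channels plus the shared nuclear channel, in channel order."""
        return [NUCLEAR_MARKER] + self.markers


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_mask: LabelMask
    true_lineage: dict[int, str]
    true_positivity: dict[int, dict[str, bool]]
    true_centroids: dict[int, tuple[float, float]]  # (x, y) px

    @property
    def n_cells(self) -> int:
        return len(self.true_lineage)

    def lineage_fractions(self) -> dict[str, float]:
        n = max(self.n_cells, 1)
        frac: dict[str, float] = {}
        for lin in self.true_lineage.values():
            frac[lin] = frac.get(lin, 0.0) + 1.0 / n
        return frac


# ---------------------------------------------------------------------------
# lineage apportionment and spatial placement


def apportion_lineages(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` cells to lineages.

    Deterministic, so ground-truth cohort fractions equal the configured
    proportions exactly whenever n * p is integral.
    """
    names = list(proportions)
    quotas = np.array([proportions[k] * n for k in names])
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:short]] += 1
    return dict(zip(names, counts.tolist()))


def _place_uniform(n, shape, min_sep, rng, existing=None):
    """Dart-throwing uniform placement with an optional hard core."""
    h, w = shape
    pts = [] if existing is None else list(existing)
    placed = []
    attempts, max_attempts = 0, 2000 * max(n, 1)
    while len(placed) < n:
        if attempts >= max_attempts:
            raise ConfigurationError(
                "n_cells too dense for min_separation_px in this field")
        attempts += 1
        p = rng.uniform((0, 0), (w, h))
        if _clear(p, pts, min_sep):
            pts.append(p)
            placed.append(p)
    return np.array(placed).reshape(n, 2)


def _clear(p, pts, min_sep):
    if min_sep <= 0 or not pts:
        return True
    d2 = np.sum((np.asarray(pts) - p) ** 2, axis=1)
    return bool(d2.min() >= min_sep * min_sep)


def simulate_points(config: SimulationConfig, rng=None):
    """Draw cell centers and lineage labels only (no raster rendering).

    Returns ``(centers, lineages)`` with centers as an (n, 2) array of
    (x, y) pixel coordinates.  Used by :func:`simulate_image` and directly
    by spatial-statistics calibration, where the raster is irrelevant.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    n = config.n_cells
    counts = apportion_lineages(config.lineage_proportions, n)
    lineages = np.array(
        [lin for lin, c in counts.items() for _ in range(c)], dtype=object)
    lineages = lineages[rng.permutation(n)] if n else lineages

    if config.placement == "csr":
        centers = _place_uniform(n, (h, w), config.min_separation_px, rng)
    elif config.placement == "thomas":
        centers = _place_thomas(config, n, (h, w), rng)
    else:
        centers = _place_attraction(config, lineages, (h, w), rng)
    return centers, lineages


def _place_thomas(config, n, shape, rng):
    """Thomas cluster process: Gaussian offspring around uniform parents."""
    h, w = shape
    parents = rng.uniform((0, 0), (w, h), size=(max(config.thomas_n_parents, 1), 2))
    pts: list[np.ndarray] = []
    attempts, max_attempts = 0, 2000 * max(n, 1)
    while len(pts) < n:
        if attempts >= max_attempts:
            raise ConfigurationError("thomas placement too dense for hard core")
        attempts += 1
        parent = parents[rng.integers(len(parents))]
        p = parent + rng.normal(0, config.thomas_offspring_sd_px, 2)
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            continue
        if _clear(p, pts, config.min_separation_px):
            pts.append(p)
    return np.array(pts).reshape(n, 2)


def _place_attraction(config, lineages, shape, rng):
    """Place attracted types near randomly chosen partners.

    Each cell of type B in an (A, B, strength) pair is, with probability
    ``strength``, displaced from a random already-placed A cell by an
    isotropic Gaussian kernel; otherwise placed uniformly.  Gives a
    tunable, monotone interaction signal for the spatial test.
    """
    h, w = shape
    n = len(lineages)
    pair_for_b = {b: (a, s) for a, b, s in config.attraction_pairs}
    is_b = np.array([lin in pair_for_b for lin in lineages])
    order = np.concatenate([np.flatnonzero(~is_b), np.flatnonzero(is_b)])
    centers = np.zeros((n, 2))
    placed: list[np.ndarray] = []
    placed_idx: list[int] = []
    min_sep = config.min_separation_px
    for idx in order:
        lin = lineages[idx]
        attempts, max_attempts = 0, 5000
        while True:
            if attempts >= max_attempts:
                raise ConfigurationError(
                    "paired_attraction placement too dense for hard core")
            attempts += 1
            anchor = None
            if lin in pair_for_b:
                a_type, strength = pair_for_b[lin]
                a_pos = [placed[i] for i, j in enumerate(placed_idx)
                         if lineages[j] == a_type]
                if a_pos and rng.uniform() < strength:
                    anchor = a_pos[rng.integers(len(a_pos))]
            if anchor is not None:
                p = anchor + rng.normal(0, config.attraction_sd_px, 2)
                if not (0 <= p[0] < w and 0 <= p[1] < h):
                    continue
            else:
                p = rng.uniform((0, 0), (w, h))
            if _clear(p, placed, min_sep):
                break
        centers[idx] = p
        placed.append(p)
        placed_idx.append(idx)
    return centers


# ---------------------------------------------------------------------------
# rendering


def _draw_radii(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Truncated-normal nucleus radii (px), lower bound min_nucleus_radius_px."""
    mean, sd = config.nucleus_radius_um
    mean_px, sd_px = mean / config.um_per_px, sd / config.um_per_px
    radii = rng.normal(mean_px, sd_px, n)
    for _ in range(100):
        bad = radii < config.min_nucleus_radius_px
        if not bad.any():
            break
        radii[bad] = rng.normal(mean_px, sd_px, bad.sum())
    return np.maximum(radii, config.min_nucleus_radius_px)


def _paint_nuclei(centers, radii, shape) -> np.ndarray:
    """Rasterize nucleus disks; contested pixels go to the nearest center."""
    h, w = shape
    labels = np.zeros((h, w), dtype=np.int32)
    best_d2 = np.full((h, w), np.inf)
    for i, ((cx, cy), r) in enumerate(zip(centers, radii), start=1):
        r_int = int(np.ceil(r))
        y0, y1 = max(int(cy) - r_int - 1, 0), min(int(cy) + r_int + 2, h)
        x0, x1 = max(int(cx) - r_int - 1, 0), min(int(cx) + r_int + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        take = (d2 <= r * r) & (d2 < best_d2[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][take] = i
        best_d2[y0:y1, x0:x1][take] = d2[take]
    return labels


def _draw_positivity(config, lineages, rng) -> dict[int, dict[str, bool]]:
    pos: dict[int, dict[str, bool]] = {}
    for i, lin in enumerate(lineages, start=1):
        profile = config.marker_profiles.get(lin, {})
        pos[i] = {m: bool(rng.uniform() < profile.get(m, 0.0))
                  for m in config.markers}
    return pos


def simulate_image(config: SimulationConfig) -> tuple[MultiplexImage, GroundTruth]:
    """Render one synthetic multiplexed field with its ground truth.

    Channel 0 is the shared nuclear (DNA) channel; marker channels carry
    whole-cell signal on the nucleus disk dilated by ``cell_expansion_px``.
    Pixels inside a positive cell's region are drawn from that marker's
    foreground Gaussian, everything else from the background Gaussian;
    PSF blur and noise are applied after composition.  Identical
    (config, seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    centers, lineages = simulate_points(config, rng)
    n = config.n_cells

    radii = _draw_radii(config, n, rng)
    nuc_labels = _paint_nuclei(centers, radii, (h, w))
    cell_labels = expand_labels(nuc_labels, config.cell_expansion_px)
    positivity = _draw_positivity(config, lineages, rng)

    channels = np.empty((1 + len(config.markers), h, w), dtype=np.float64)
    nm = config.nuclear_mixture
    channels[0] = rng.normal(nm.bg_mean, nm.bg_sd, (h, w))
    in_nuc = nuc_labels > 0
    channels[0][in_nuc] = rng.normal(nm.fg_mean, nm.fg_sd, int(in_nuc.sum()))

    for ci, marker in enumerate(config.markers, start=1):
        mix = config.mixture_params[marker]
        img = rng.normal(mix.bg_mean, mix.bg_sd, (h, w))
        # group positive cells by their foreground mean (lineage overrides)
        fg_mean_of = np.zeros(n + 1)
        for cid in range(1, n + 1):
            if positivity[cid][marker]:
                lin = lineages[cid - 1]
                fg_mean_of[cid] = config.fg_mean_overrides.get(
                    (lin, marker), mix.fg_mean)
        pos_lut = fg_mean_of > 0
        pos_mask = pos_lut[cell_labels]
        if pos_mask.any():
            means = fg_mean_of[cell_labels[pos_mask]]
            img[pos_mask] = rng.normal(means, mix.fg_sd)
        channels[ci] = img

    np.clip(channels, 0, None, out=channels)
    if config.psf_sigma_px > 0:
        for c in range(channels.shape[0]):
            channels[c] = ndi.gaussian_filter(channels[c], config.psf_sigma_px)
    if config.noise_model == "poisson":
        channels = rng.poisson(channels).astype(np.float64)
    elif config.noise_model == "gaussian":
        channels = channels + rng.normal(0, config.gaussian_noise_sd, channels.shape)
        np.clip(channels, 0, None, out=channels)

    mask = LabelMask(nuc_labels.astype(np.int64))
    centroids = {
        p.label: (float(p.centroid[1]), float(p.centroid[0]))
        for p in regionprops(nuc_labels)
    }
    truth = GroundTruth(
        true_mask=mask,
        true_lineage={i + 1: str(lineages[i]) for i in range(n)},
        true_positivity=positivity,
        true_centroids=centroids,
    )
    image = MultiplexImage(
        pixels=channels, panel=config.panel, um_per_px=config.um_per_px)
    return image, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSample:
    """One simulated tissue field inside a matched cohort."""

    pair_id: str
    condition: str  # "primary" | "recurrent"
    image: MultiplexImage
    truth: GroundTruth
    config: SimulationConfig

    @property
    def sample_id(self) -> str:
        return f"{self.pair_id}_{self.condition}"


def shift_proportions(
    proportions: dict[str, float], shift: dict[str, float]
) -> dict[str, float]:
    """Add ``shift`` to selected lineages; rescale the others to keep sum 1.

    Explicitly shifted lineages receive exactly p + shift (so ground-truth
    paired differences equal the configured shift); the remaining mass is
    split among unshifted lineages in proportion to their original weights.
    """
    for lin in shift:
        if lin not in proportions:
            raise ConfigurationError(f"recurrent_shift names unknown lineage {lin!r}")
    shifted = {lin: proportions[lin] + shift.get(lin, 0.0) for lin in proportions}
    for lin, p in shifted.items():
        if lin in shift and not (0.0 <= p <= 1.0):
            raise ConfigurationError(
                f"shift pushes {lin!r} proportion to {p:.4f}, outside [0, 1]")
    mass_shifted = sum(shifted[lin] for lin in shift)
    mass_others_old = sum(p for lin, p in proportions.items() if lin not in shift)
    mass_others_new = 1.0 - mass_shifted
    if mass_others_new < -1e-12 or (mass_others_old == 0 and mass_others_new > 1e-12):
        raise ConfigurationError("recurrent_shift not renormalizable within [0, 1]")
    scale = mass_others_new / mass_others_old if mass_others_old > 0 else 0.0
    out = {}
    for lin, p in proportions.items():
        out[lin] = shifted[lin] if lin in shift else p * scale
        if out[lin] < -1e-12:
            raise ConfigurationError(
                f"shift pushes {lin!r} proportion below 0 after renormalization")
        out[lin] = max(out[lin], 0.0)
    return out


def simulate_cohort(
    base: SimulationConfig,
    n_pairs: int,
    recurrent_shift: dict[str, float] | None = None,
    mfi_shift: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    recurrent_overrides: dict | None = None,
) -> list[CohortSample]:
    """Simulate matched primary/recurrent tissue pairs.

    Per pair, the recurrent member's lineage proportions equal the primary
    ones plus ``recurrent_shift`` (others renormalized), and foreground
    means for any (lineage, marker) in ``mfi_shift`` are scaled by
    2**shift.  ``recurrent_overrides`` replaces arbitrary config fields in
    the recurrent members only (e.g. placement and attraction_pairs, to
    inject spatial structure at relapse).  Pair identity is recorded for
    downstream paired statistics.
    """
    recurrent_shift = recurrent_shift or {}
    mfi_shift = mfi_shift or {}
    base.validate()
    rec_props = shift_proportions(base.lineage_proportions, recurrent_shift)
    rec_overrides = dict(base.fg_mean_overrides)
    for (lin, marker), lfc in mfi_shift.items():
        if marker not in base.mixture_params:
            raise ConfigurationError(f"mfi_shift names unknown marker {marker!r}")
        if lin not in base.lineage_proportions:
            raise ConfigurationError(f"mfi_shift names unknown lineage {lin!r}")
        fg = base.fg_mean_overrides.get((lin, marker),
                                        base.mixture_params[marker].fg_mean)
        rec_overrides[(lin, marker)] = fg * 2.0 ** lfc

    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_pairs, 2))
    samples = []
    for i in range(n_pairs):
        pair_id = f"pair{i + 1}"
        prim_cfg = replace(base, seed=int(seeds[i, 0]))
        rec_cfg = replace(
            base,
            seed=int(seeds[i, 1]),
            lineage_proportions=rec_props,
            fg_mean_overrides=rec_overrides,
            **(recurrent_overrides or {}),
        )
        for condition, cfg in (("primary", prim_cfg), ("recurrent", rec_cfg)):
            image, truth = simulate_image(cfg)
            samples.append(CohortSample(pair_id, condition, image, truth, cfg))
    return samples


def truth_cell_table(truth: GroundTruth, markers: list[str]):
    """Ground-truth table: cell_id, x, y, lineage, one boolean per marker."""
    import pandas as pd

    rows = []
    for cid in sorted(truth.true_lineage):
        x, y = truth.true_centroids[cid]
        row = {"cell_id": cid, "x": x, "y": y, "lineage": truth.true_lineage[cid]}
        for m in markers:
            row[m] = truth.true_positivity[cid][m]
        rows.append(row)
    cols = ["cell_id", "x", "y", "lineage"] + list(markers)
    return pd.DataFrame(rows, columns=cols)
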