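"""On-disk contracts shared by every pipeline stage.

Images are channel-stacked TIFF (one page per marker channel), masks are
integer-label TIFF, tables are CSV, configs are YAML.  Coordinates are
0-based pixel indices with (x, y) = (column, row); centroids are arithmetic
means of member-pixel coordinates.  Every reader/writer pair is an inverse
on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MultiplexImage:
    """Channel-stacked pixel raster plus the panel naming each channel.

    Parameters
    ----------
    pixels : ndarray, shape (C, H, W)
        Nonnegative intensities, one channel per marker.
    panel : list of str
        Marker name per channel, unique, same length as the channel axis.
    um_per_px : float
        Physical pixel size; IMC acquires at roughly 1 um/px.
    """

    pixels: np.ndarray
    panel: list[str] = field(default_factory=list)
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be (channel, height, width)")
        if len(self.panel) != self.pixels.shape[0]:
            raise FormatError(
                f"panel has {len(self.panel)} names but image has "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.panel)) != len(self.panel):
            raise ValidationError("marker names in panel must be unique")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, marker: str) -> np.ndarray:
        """2-D view of one marker's channel."""
        try:
            idx = self.panel.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in panel") from None
        return self.pixels[idx]


@dataclass
class LabelMask:
    """Integer instance raster: 0 = background, 1..K = cell instances."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if self.labels.min() < 0:
            raise ValidationError("labels must be nonnegative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def compact(self) -> "LabelMask":
        """Relabel to a gapless {1..K}, preserving label order."""
        present = np.unique(self.labels)
        present = present[present > 0]
        lut = np.zeros(int(self.labels.max()) + 1, dtype=np.int64)
        lut[present] = np.arange(1, len(present) + 1)
        return LabelMask(lut[self.labels])


# ---------------------------------------------------------------------------
# images and masks


def write_image(image: MultiplexImage, path) -> None:
    """Write a multichannel image as a float32 multipage TIFF.

    Pixel size is stored in the TIFF resolution tags (pixels per cm) so a
    round trip restores ``um_per_px``.
    """
    px_per_cm = 1.0e4 / image.um_per_px
    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
        planarconfig="separate",
        metadata={"axes": "CYX"},
    )


def read_image(path, panel_path) -> MultiplexImage:
    """Read a TIFF/OME-TIFF channel stack with its panel CSV.

    The panel must have one row per channel (columns ``channel_index``,
    ``marker_name``); channel order follows the panel.  When the file
    carries no pixel-size metadata, ``um_per_px`` defaults to 1.0 with a
    logged warning.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            pixels = tf.asarray()
            page = tf.pages[0]
            um_per_px = _um_per_px_from_tags(page)
    except (OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    panel = read_panel(panel_path)
    if len(panel) != pixels.shape[0]:
        raise FormatError(
            f"panel lists {len(panel)} channels but image {path} has "
            f"{pixels.shape[0]}"
        )
    if um_per_px is None:
        logger.warning("%s carries no pixel-size metadata; assuming 1.0 um/px", path)
        um_per_px = 1.0
    return MultiplexImage(pixels=pixels, panel=panel, um_per_px=um_per_px)


def _um_per_px_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    # RESUNIT: 2 = inch, 3 = centimeter
    cm_per_unit = {2: 2.54, 3: 1.0}.get(int(unit))
    if cm_per_unit is None:
        return None
    px_per_cm = (num / den) / cm_per_unit
    return 1.0e4 / px_per_cm


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask as 16-bit TIFF (32-bit when K > 65535)."""
    dtype = np.uint16 if mask.n_cells <= 65535 else np.uint32
    tifffile.imwrite(path, mask.labels.astype(dtype))


def read_mask(path) -> LabelMask:
    try:
        labels = tifffile.imread(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    return LabelMask(labels.astype(np.int64))


# ---------------------------------------------------------------------------
# panel


def write_panel(panel: list[str], path) -> None:
    pd.DataFrame(
        {"channel_index": np.arange(len(panel)), "marker_name": panel}
    ).to_csv(path, index=False)


def read_panel(path) -> list[str]:
    df = pd.read_csv(path)
    for col in ("channel_index", "marker_name"):
        if col not in df.columns:
            raise FormatError(f"panel CSV {path} lacks column {col!r}")
    df = df.sort_values("channel_index")
    return [str(m) for m in df["marker_name"]]


# ---------------------------------------------------------------------------
# cell tables

#: fixed leading columns of every cell table
CELL_TABLE_INDEX = ["cell_id", "x", "y", "area_px"]
INTENSITY_PREFIX = "intensity_"
POSITIVE_PREFIX = "positive_"


def intensity_col(marker: str) -> str:
    return INTENSITY_PREFIX + marker


def positive_col(marker: str) -> str:
    return POSITIVE_PREFIX + marker


def table_markers(cells: pd.DataFrame) -> list[str]:
    """Markers carried by a cell table, in column order."""
    return [
        c[len(INTENSITY_PREFIX):]
        for c in cells.columns
        if c.startswith(INTENSITY_PREFIX)
    ]


def validate_cell_table(cells: pd.DataFrame) -> None:
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell_id {dup}")
    icols = [c for c in cells.columns if c.startswith(INTENSITY_PREFIX)]
    if icols and not np.isfinite(cells[icols].to_numpy(dtype=float)).all():
        raise ValidationError("non-finite intensity values")


def _ordered_columns(cells: pd.DataFrame) -> list[str]:
    cols = [c for c in CELL_TABLE_INDEX if c in cells.columns]
    cols += [c for c in cells.columns if c.startswith(INTENSITY_PREFIX)]
    cols += [c for c in cells.columns if c.startswith(POSITIVE_PREFIX)]
    for extra in ("lineage", "sample_id"):
        if extra in cells.columns:
            cols.append(extra)
    cols += [c for c in cells.columns if c not in cols]
    return cols


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table CSV with stable column order.

    Order: cell_id, x, y, area_px, intensity columns, positivity columns,
    then lineage/sample columns when present.  Re-reading reproduces the
    table exactly.
    """
    validate_cell_table(cells)
    out = cells[_ordered_columns(cells)]
    out.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path} is not a cell table (no cell_id column)")
    for c in df.columns:
        if c.startswith(POSITIVE_PREFIX):
            df[c] = df[c].astype(bool)
        elif c in ("x", "y") or c.startswith(INTENSITY_PREFIX):
            df[c] = df[c].astype(np.float64)
    validate_cell_table(df)
    return df


# ---------------------------------------------------------------------------
# structured configs


def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, (dict, list)):
        raise FormatError(f"{path}: expected a YAML mapping or list")
    return data


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
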