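"""Per-cell phenotypic feature extraction from multi-channel images.

Inputs are one 16-bit raster per channel (DNA, secondary marker, actin,
whole-cell stain) plus nuclear and cellular label masks in which every
nuclear region lies inside exactly one cellular region and shares its label.
Outputs are one 128-value row per cell (texture, intensity, ratio,
correlation, morphology) with the cell count attached at the condition level
to complete the 129-feature profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops
from skimage.restoration import rolling_ball

from . import catalog as cat
from .texture import haralick_profile, quantize

logger = logging.getLogger(__name__)


@dataclass
class MultiChannelCellImage:
    """One 2-D nonnegative raster per channel, identical shapes."""

    channels: dict[str, np.ndarray]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for k, v in self.channels.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"channel {k!r} contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class SegmentationMask:
    """Nuclear and cellular label rasters; label 0 is background."""

    nuclei: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        if self.nuclei.shape != self.cells.shape:
            raise ValueError("nuclear and cellular masks must share dimensions")

    def labels(self) -> np.ndarray:
        lab = np.unique(self.nuclei)
        return lab[lab > 0]

    def validate(self) -> None:
        """Check that every nucleus lies inside its same-labelled cell."""
        for lab in self.labels():
            inside = self.cells[self.nuclei == lab]
            if not np.all(inside == lab):
                raise ValueError(f"nucleus {lab} extends outside cell {lab}")


def correct_background(raster: np.ndarray, ball_radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction; output clamped at zero.

    The background is the envelope of a ball of the given radius rolled under
    the intensity surface, the classic flat-field correction for non-uniform
    illumination in fluorescence microscopy.
    """
    raster = np.asarray(raster)
    if ball_radius < 1:
        raise ValueError("ball_radius must be >= 1 pixel")
    if ball_radius > max(raster.shape):
        raise ValueError(
            f"ball_radius {ball_radius} exceeds image extent {raster.shape}")
    background = rolling_ball(raster.astype(np.float64), radius=ball_radius)
    return np.clip(raster.astype(np.float64) - background, 0.0, None)


def _region_stats(values: np.ndarray) -> dict[str, float]:
    """mean, total and CV of a pixel-intensity sample; CV is NaN at zero mean."""
    mean = float(values.mean()) if values.size else np.nan
    total = float(values.sum()) if values.size else np.nan
    if values.size and mean != 0:
        cv = float(values.std(ddof=0) / mean)
    else:
        cv = np.nan
    return {"mean": mean, "total": total, "cv": cv}


def intensity_features(image: MultiChannelCellImage, masks: SegmentationMask,
                       label: int) -> dict[str, float]:
    """Per-marker, per-region intensity statistics and ratio features.

    Regions: nuclear, cytoplasmic (cellular minus nuclear) and whole-cell.
    Ratios are formed from total intensities per the catalog's ratio
    definitions; undefined values (zero denominators, empty regions) are NaN
    and logged.
    """
    nuc = masks.nuclei == label
    cell = masks.cells == label
    if not nuc.any():
        raise ValueError(f"empty nuclear mask for cell {label}")
    cyto = cell & ~nuc
    region_masks = {"nuclear": nuc, "cyto": cyto, "cell": cell}

    stats: dict[tuple[str, str], dict[str, float]] = {}
    out: dict[str, float] = {}
    for marker in cat.TEXTURE_MARKERS:
        raster = image.channels[marker]
        for region, mask in region_masks.items():
            s = _region_stats(raster[mask])
            stats[(marker, region)] = s
            for stat_name, v in s.items():
                out[f"{marker}_{region}_{stat_name}"] = v
            if np.isnan(s["cv"]):
                logger.warning("CV undefined for %s/%s of cell %d", marker, region, label)
    wcs_stats = _region_stats(image.channels["wcs"][cell])
    stats[("wcs", "cell")] = wcs_stats
    out["wcs_cell_mean"] = wcs_stats["mean"]
    out["wcs_cell_total"] = wcs_stats["total"]

    for num_m, num_r, den_m, den_r in cat.RATIO_DEFINITIONS:
        if num_m == den_m:
            name = f"{num_m}_{num_r}_to_{den_r}_total_ratio"
        else:
            name = f"{num_m}_to_{den_m}_{den_r}_total_ratio"
        den = stats[(den_m, den_r)]["total"]
        num = stats[(num_m, num_r)]["total"]
        out[name] = num / den if den else np.nan
        if not den:
            logger.warning("ratio %s undefined for cell %d (zero denominator)", name, label)
    return out


def correlation_features(image: MultiChannelCellImage, masks: SegmentationMask,
                         label: int) -> dict[str, float]:
    """Pearson correlation of pixel intensities for the 6 channel pairs."""
    cell = masks.cells == label
    if cell.sum() < 2:
        raise ValueError(f"cell {label} has fewer than 2 pixels")
    pixels = {ch: image.channels[ch][cell].astype(np.float64) for ch in cat.CHANNELS}
    out: dict[str, float] = {}
    for a, b in cat.CORRELATION_PAIRS:
        va, vb = pixels[a], pixels[b]
        sa, sb = va.std(ddof=0), vb.std(ddof=0)
        if sa == 0 or sb == 0:
            out[f"corr_{a}_{b}"] = np.nan
            logger.warning("correlation %s-%s undefined for cell %d (zero variance)", a, b, label)
        else:
            out[f"corr_{a}_{b}"] = float(np.mean((va - va.mean()) * (vb - vb.mean())) / (sa * sb))
    return out


def morphology_features(masks: SegmentationMask, label: int) -> dict[str, float]:
    """Area, perimeter and form factor (4*pi*A/P^2) of nucleus and cell."""
    out: dict[str, float] = {}
    for prefix, raster in (("nuclear", masks.nuclei), ("cell", masks.cells)):
        region = (raster == label).astype(np.uint8)
        props = regionprops(region)
        if not props:
            raise ValueError(f"no {prefix} region for cell {label}")
        p = props[0]
        area = float(p.area)
        # Crofton estimate: unbiased for smooth shapes, so a rasterized disc
        # has form factor ~1 regardless of radius
        perimeter = float(p.perimeter_crofton)
        out[f"{prefix}_area"] = area
        out[f"{prefix}_perimeter"] = perimeter
        out[f"{prefix}_form_factor"] = (
            4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan)
    return out


def texture_features(image: MultiChannelCellImage, masks: SegmentationMask,
                     label: int, n_levels: int = 256,
                     quantization: str = "global") -> dict[str, float]:
    """Haralick statistics per fluorescent marker over the cell bounding box.

    The bounding box of the cellular region is extracted per marker with all
    background (non-cell) pixels set to zero before quantization, so level-0
    transitions include the background ring inside the box.
    """
    cell = masks.cells == label
    rows = np.any(cell, axis=1).nonzero()[0]
    cols = np.any(cell, axis=0).nonzero()[0]
    box = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    out: dict[str, float] = {}
    max_value = 2 ** image.bit_depth - 1
    for marker in cat.TEXTURE_MARKERS:
        raster = np.where(cell, image.channels[marker], 0)[box]
        q = quantize(raster, n_levels=n_levels, mode=quantization, max_value=max_value)
        for key, v in haralick_profile(q, n_levels=n_levels).items():
            out[f"{marker}_glcm_{key}"] = v
    return out


@dataclass
class ExtractionConfig:
    """Knobs of the extraction stage."""

    n_levels: int = 256
    quantization: str = "global"  # or "cell": per-cell min-max rescaling
    ball_radius: int = 50
    background_correct: bool = False
    catalog: pd.DataFrame = field(default_factory=cat.default_catalog)


def extract_cell_features(image: MultiChannelCellImage, masks: SegmentationMask,
                          label: int, config: ExtractionConfig | None = None,
                          ) -> dict[str, float]:
    """The 128 per-cell features for one labelled cell."""
    config = config or ExtractionConfig()
    out: dict[str, float] = {}
    out.update(texture_features(image, masks, label, n_levels=config.n_levels,
                                quantization=config.quantization))
    out.update(intensity_features(image, masks, label))
    out.update(correlation_features(image, masks, label))
    out.update(morphology_features(masks, label))
    return out


def extract_profiles(images: list[MultiChannelCellImage],
                     masks: list[SegmentationMask],
                     config: ExtractionConfig | None = None,
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell feature table plus the condition-level aggregate.

    Returns ``(cells, condition)`` where ``cells`` has one row per cell
    (columns = the 128 per-cell catalog features, plus ``image`` and ``cell``
    bookkeeping columns) and ``condition`` is the mean over cells with the
    cell count appended, i.e. the full 129-entry condition profile.
    """
    config = config or ExtractionConfig()
    if len(images) != len(masks):
        raise ValueError("each image must be paired with exactly one mask")
    rows = []
    for img_idx, (image, mask) in enumerate(zip(images, masks)):
        if image.shape != mask.nuclei.shape:
            raise ValueError(
                f"image {img_idx} shape {image.shape} != mask shape {mask.nuclei.shape}")
        if config.background_correct:
            image = MultiChannelCellImage(
                channels={k: correct_background(v, config.ball_radius)
                          for k, v in image.channels.items()},
                bit_depth=image.bit_depth)
        mask.validate()
        for label in mask.labels():
            row = extract_cell_features(image, mask, int(label), config)
            row["image"] = img_idx
            row["cell"] = int(label)
            rows.append(row)
    cells = pd.DataFrame(rows)
    feature_cols = [c for c in config.catalog["name"] if c in cells.columns]
    cells = cells[["image", "cell"] + feature_cols]
    condition = cells[feature_cols].mean()
    condition["cell_count"] = float(len(cells))
    return cells, condition


def segment_synthetic(image: MultiChannelCellImage) -> SegmentationMask:
    """Threshold-based fallback segmentation for synthetic images.

    Otsu on the DNA channel yields nuclei; cells come from Otsu on the
    whole-cell stain with a nucleus-seeded watershed.  This is a convenience
    for generated data, not a general-purpose segmenter.
    """
    from scipy import ndimage as ndi
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    dna = image.channels["dna"].astype(np.float64)
    wcs = image.channels["wcs"].astype(np.float64)
    nuclei_bin = dna > threshold_otsu(dna)
    nuclei, _ = ndi.label(nuclei_bin)
    cells_bin = wcs > threshold_otsu(wcs)
    distance = ndi.distance_transform_edt(~nuclei_bin)
    cells = watershed(distance, markers=nuclei, mask=cells_bin)
    # nuclei must stay within their cells
    nuclei = np.where(cells == nuclei, nuclei, 0)
    return SegmentationMask(nuclei=nuclei, cells=cells)


def write_image_tiffs(image: MultiChannelCellImage, masks: SegmentationMask,
                      directory, prefix: str = "synthetic") -> list[str]:
    """Write one 16-bit single-channel TIFF per channel plus label masks."""
    import pathlib

    import tifffile

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, raster in image.channels.items():
        path = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(path, raster.astype(np.uint16))
        paths.append(str(path))
    for name, raster in (("nuclei", masks.nuclei), ("cells", masks.cells)):
        path = directory / f"{prefix}_mask_{name}.tif"
        tifffile.imwrite(path, raster.astype(np.uint16))
        paths.append(str(path))
    return paths
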