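"""Catalog of the 129 phenotypic features measured per cell.

The profile combines five feature families computed from four fluorescence
channels (DNA, a secondary marker such as RelA or gH2AX, actin, and a
whole-cell stain used for segmentation):

* 78 Haralick texture features: 13 co-occurrence statistics x {mean, sd over
  the four pixel offsets} x 3 fluorescent markers (the whole-cell stain
  contributes no texture features),
* 29 intensity features (mean / total / coefficient of variation per marker
  and subcellular region),
* 9 intensity-ratio features,
* 6 pairwise marker correlation features,
* 6 morphology features (area, perimeter, form factor of nucleus and cell),
* 1 cell-count feature attached at the condition level.

The exact composition of the intensity and ratio families is configurable;
the default below is a reconstruction consistent with the printed family
counts, not a verbatim copy of any published feature list.
"""

from __future__ import annotations

import pandas as pd

#: channel keys used throughout the package
CHANNELS = ("dna", "secondary", "actin", "wcs")

#: fluorescent markers that contribute texture features
TEXTURE_MARKERS = ("dna", "secondary", "actin")

#: the 13 Haralick statistics, in canonical order
HARALICK_STATS = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

REGIONS = ("nuclear", "cyto", "cell")
INTENSITY_STATS = ("mean", "total", "cv")

GROUP_TEXTURE = "texture"
GROUP_INTENSITY = "intensity"
GROUP_RATIO = "intensity_ratio"
GROUP_CORRELATION = "correlation"
GROUP_MORPHOLOGY = "morphology"
GROUP_COUNT = "count"

FEATURE_GROUPS = (
    GROUP_TEXTURE,
    GROUP_INTENSITY,
    GROUP_RATIO,
    GROUP_CORRELATION,
    GROUP_MORPHOLOGY,
    GROUP_COUNT,
)

#: (numerator marker, numerator region, denominator marker, denominator region)
#: for the 9 total-intensity ratio features; includes the nuclear-to-whole-cell
#: total ratio per marker and the secondary-to-DNA whole-cell total ratio.
RATIO_DEFINITIONS = (
    ("dna", "nuclear", "dna", "cell"),
    ("secondary", "nuclear", "secondary", "cell"),
    ("actin", "nuclear", "actin", "cell"),
    ("dna", "nuclear", "dna", "cyto"),
    ("secondary", "nuclear", "secondary", "cyto"),
    ("actin", "nuclear", "actin", "cyto"),
    ("secondary", "cell", "dna", "cell"),
    ("actin", "cell", "dna", "cell"),
    ("secondary", "nuclear", "dna", "nuclear"),
)

CORRELATION_PAIRS = (
    ("dna", "secondary"),
    ("dna", "actin"),
    ("dna", "wcs"),
    ("secondary", "actin"),
    ("secondary", "wcs"),
    ("actin", "wcs"),
)


def default_catalog() -> pd.DataFrame:
    """Build the default 129-entry feature catalog.

    Returns a DataFrame with columns ``name``, ``marker``, ``group`` and
    ``region``; ``name`` is unique and the row order is the canonical feature
    order used by every table the package produces.
    """
    rows: list[tuple[str, str, str, str]] = []

    for marker in TEXTURE_MARKERS:
        for stat in HARALICK_STATS:
            for agg in ("mean", "sd"):
                rows.append((f"{marker}_glcm_{stat}_{agg}", marker, GROUP_TEXTURE, "cell"))

    # 29 intensity features: 3 fluorescent markers x 3 regions x 3 statistics
    # plus whole-cell-stain mean and total over the cellular region.
    for marker in TEXTURE_MARKERS:
        for region in REGIONS:
            for stat in INTENSITY_STATS:
                rows.append((f"{marker}_{region}_{stat}", marker, GROUP_INTENSITY, region))
    rows.append(("wcs_cell_mean", "wcs", GROUP_INTENSITY, "cell"))
    rows.append(("wcs_cell_total", "wcs", GROUP_INTENSITY, "cell"))

    for num_m, num_r, den_m, den_r in RATIO_DEFINITIONS:
        if num_m == den_m:
            name = f"{num_m}_{num_r}_to_{den_r}_total_ratio"
        else:
            name = f"{num_m}_to_{den_m}_{den_r}_total_ratio"
        rows.append((name, num_m, GROUP_RATIO, num_r))

    for a, b in CORRELATION_PAIRS:
        rows.append((f"corr_{a}_{b}", f"{a}+{b}", GROUP_CORRELATION, "cell"))

    for region_name, region in (("nuclear", "nuclear"), ("cell", "cell")):
        for stat in ("area", "perimeter", "form_factor"):
            rows.append((f"{region_name}_{stat}", "wcs", GROUP_MORPHOLOGY, region))

    rows.append(("cell_count", "none", GROUP_COUNT, "condition"))

    cat = pd.DataFrame(rows, columns=["name", "marker", "group", "region"])
    if len(cat) != 129 or cat["name"].duplicated().any():
        raise AssertionError("default catalog must contain 129 uniquely named features")
    return cat


def validate_catalog(catalog: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a catalog is malformed."""
    required = {"name", "marker", "group", "region"}
    if not required.issubset(catalog.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    if catalog["name"].duplicated().any():
        dupes = catalog.loc[catalog["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate feature names in catalog: {dupes}")
    unknown = set(catalog["group"]) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
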