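"""Gray-level co-occurrence matrices and Haralick texture statistics.

A GLCM at pixel offset (dx, dy) counts, over an image I(x, y) with x the row
and y the column index, how often gray level i at (x, y) co-occurs with gray
level j at (x + dx, y + dy).  Texture is summarized by 13 statistics of the
normalized GLCM (angular second moment, contrast, correlation, variance,
inverse difference moment, sum average/variance/entropy, entropy, difference
variance/entropy, and the two information measures of correlation), computed
at the four standard offsets 0deg (0,1), 45deg (1,1), 90deg (1,0) and
135deg (1,-1) and then aggregated to a mean and standard deviation per
statistic.

Conventions fixed here (they only rescale or shift features and are absorbed
by the downstream log-ratio / [-1,1] normalization):

* gray levels enter the formulas as 1-based values ``1..n_levels`` so the sum
  distribution is indexed ``k = 2..2*n_levels``;
* all entropies use the natural logarithm, with ``0 * log 0 = 0``;
* the offset aggregation uses the population standard deviation (divide by 4).

Marginals follow the convention ``p_x(j) = sum_i p(i, j)`` (column marginal)
and ``p_y(i) = sum_j p(i, j)`` (row marginal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: the four standard offsets: 0, 45, 90 and 135 degrees, as (drow, dcol)
STANDARD_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def quantize(raster: np.ndarray, n_levels: int = 256, mode: str = "global",
             max_value: int | None = None) -> np.ndarray:
    """Quantize a nonnegative raster to ``n_levels`` gray levels (0-based).

    ``mode='global'`` (default) bins the full acquisition range, taken as
    ``0..max_value`` (65535 for 16-bit data unless given); ``mode='cell'``
    rescales the raster's own min..max to the full level range, which makes
    texture statistics invariant to staining gain per cell.
    """
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("cannot quantize an empty raster")
    if np.any(raster < 0):
        raise ValueError("raster values must be nonnegative")
    if mode == "global":
        top = 65535 if max_value is None else max_value
        q = (raster.astype(np.float64) * n_levels / (top + 1)).astype(np.int64)
    elif mode == "cell":
        lo, hi = float(raster.min()), float(raster.max())
        if hi == lo:
            return np.zeros_like(raster, dtype=np.int64)
        q = ((raster.astype(np.float64) - lo) / (hi - lo) * (n_levels - 1)).round().astype(np.int64)
    else:
        raise ValueError(f"unknown quantization mode {mode!r}")
    return np.clip(q, 0, n_levels - 1)


@dataclass(frozen=True)
class GLCMatrix:
    """Co-occurrence counts and derived probability tables at one offset.

    ``counts[i, j]`` uses 0-based array indices for levels ``i+1, j+1``;
    ``p`` is the normalized matrix, ``p_x``/``p_y`` the column/row marginals
    and ``p_sum[k - 2]`` the probability of the level sum ``k = 2..2n``.
    """

    counts: np.ndarray
    offset: tuple[int, int]
    n_levels: int

    @property
    def p(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_sum(self) -> np.ndarray:
        n = self.n_levels
        out = np.zeros(2 * n - 1)
        # entry s of out is the probability that (i+1)+(j+1) == s+2
        idx = np.add.outer(np.arange(n), np.arange(n))
        np.add.at(out, idx.ravel(), self.p.ravel())
        return out

    @property
    def p_diff(self) -> np.ndarray:
        """Probability of the absolute level difference ``k = 0..n-1``."""
        n = self.n_levels
        out = np.zeros(n)
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        np.add.at(out, idx.ravel(), self.p.ravel())
        return out


def compute_glcm(raster: np.ndarray, offset: tuple[int, int],
                 n_levels: int = 256) -> GLCMatrix:
    """Count gray-level co-occurrences at one offset.

    ``raster`` must already be quantized to integer levels ``0..n_levels-1``
    (background pixels of a cell bounding box set to level 0, as produced by
    :func:`quantize` after masking).  The pair (I(x, y), I(x+dx, y+dy)) is
    counted once per pixel whose partner lies inside the image; the matrix is
    directional (not symmetrized).
    """
    raster = np.asarray(raster)
    if raster.ndim != 2 or raster.size == 0:
        raise ValueError("raster must be a nonempty 2-D array of gray levels")
    if not np.issubdtype(raster.dtype, np.integer):
        raise ValueError("raster must be integer-quantized before GLCM computation")
    if raster.min() < 0 or raster.max() >= n_levels:
        raise ValueError(f"raster levels must lie in [0, {n_levels - 1}]")
    dx, dy = offset

    nrow, ncol = raster.shape
    r0 = max(0, -dx)
    r1 = min(nrow, nrow - dx)
    c0 = max(0, -dy)
    c1 = min(ncol, ncol - dy)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"offset {offset} has no valid pixel pairs in a {raster.shape} raster")

    src = raster[r0:r1, c0:c1].ravel()
    dst = raster[r0 + dx: r1 + dx, c0 + dy: c1 + dy].ravel()
    flat = np.bincount(src * n_levels + dst, minlength=n_levels * n_levels)
    counts = flat.reshape(n_levels, n_levels).astype(np.float64)
    return GLCMatrix(counts=counts, offset=(dx, dy), n_levels=n_levels)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the 0 log 0 = 0 convention (natural log)."""
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_features(glcm: GLCMatrix) -> dict[str, float]:
    """Compute the 13 Haralick statistics of one normalized GLCM.

    Gray levels enter as 1-based values; zero-probability terms contribute
    nothing to the entropies.  Degenerate marginals (zero variance) make the
    correlation statistic 0 by convention.
    """
    p = glcm.p
    n = glcm.n_levels
    levels = np.arange(1, n + 1, dtype=np.float64)
    p_x = glcm.p_x  # marginal over rows: p_x(j)
    p_y = glcm.p_y  # marginal over columns: p_y(i)
    p_sum = glcm.p_sum
    p_diff = glcm.p_diff
    ks = np.arange(2, 2 * n + 1, dtype=np.float64)
    ds = np.arange(0, n, dtype=np.float64)

    ii = levels[:, None]
    jj = levels[None, :]

    f: dict[str, float] = {}
    f["asm"] = float(np.sum(p * p))
    f["contrast"] = float(np.sum(ds**2 * p_diff))

    mu_x = float(np.sum(levels * p_x))
    mu_y = float(np.sum(levels * p_y))
    sd_x = float(np.sqrt(np.sum((levels - mu_x) ** 2 * p_x)))
    sd_y = float(np.sqrt(np.sum((levels - mu_y) ** 2 * p_y)))
    if sd_x > 0 and sd_y > 0:
        f["correlation"] = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f["correlation"] = 0.0

    mu = float(np.sum(ii * p))  # grand mean of the row level
    f["variance"] = float(np.sum((ii - mu) ** 2 * p))
    f["idm"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    f["sum_average"] = float(np.sum(ks * p_sum))
    f["sum_variance"] = float(np.sum((ks - f["sum_average"]) ** 2 * p_sum))
    f["sum_entropy"] = float(-np.sum(_xlogx(p_sum)))
    f["entropy"] = float(-np.sum(_xlogx(p)))
    mu_d = float(np.sum(ds * p_diff))
    f["difference_variance"] = float(np.sum((ds - mu_d) ** 2 * p_diff))
    f["difference_entropy"] = float(-np.sum(_xlogx(p_diff)))

    hxy = f["entropy"]
    hx = float(-np.sum(_xlogx(p_x)))
    hy = float(-np.sum(_xlogx(p_y)))
    # product marginal p_x(j) * p_y(i); terms where p(i,j) > 0 always have a
    # positive product, so the log is well defined where it is weighted.
    prod = p_x[None, :] * p_y[:, None]
    with np.errstate(divide="ignore"):
        log_prod = np.where(prod > 0, np.log(np.where(prod > 0, prod, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * log_prod))
    hxy2 = float(-np.sum(prod * log_prod))
    denom = max(hx, hy)
    f["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    f["imc2"] = float(np.sqrt(abs(1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return f


def aggregate_offsets(values: np.ndarray | list[float]) -> tuple[float, float]:
    """Mean and population standard deviation over the 4 offset values."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (4,):
        raise ValueError("expected exactly 4 offset values")
    return float(values.mean()), float(values.std(ddof=0))


def haralick_profile(raster: np.ndarray, n_levels: int = 256,
                     offsets: tuple[tuple[int, int], ...] = STANDARD_OFFSETS,
                     ) -> dict[str, float]:
    """All 13 statistics x {mean, sd} over the standard offsets.

    ``raster`` is a quantized cell bounding box with background pixels at
    level 0.  Keys are ``{stat}_{mean|sd}``.
    """
    per_offset: dict[str, list[float]] = {}
    for off in offsets:
        stats = haralick_features(compute_glcm(raster, off, n_levels=n_levels))
        for k, v in stats.items():
            per_offset.setdefault(k, []).append(v)
    out: dict[str, float] = {}
    for k, vals in per_offset.items():
        m, s = aggregate_offsets(vals)
        out[f"{k}_mean"] = m
        out[f"{k}_sd"] = s
    return out
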