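"""Texture and intensity features of DTCWT sub-images.

Four feature families are computed on the top half, bottom half and
(for low-pass bands) full extent of every sub-image raster:

* statistical — mean, population SD, skewness, excess kurtosis, and the
  Shannon entropy of the sum-normalized intensities;
* GLCM — contrast, correlation, energy, homogeneity, entropy of 8-level
  grey-level co-occurrence matrices at six pixel offsets;
* GLRLM — eleven run-length statistics (SRE, LRE, GLN, RLN, RP, LGRE,
  HGRE, SRLGE, SRHGE, LRLGE, LRHGE) at four directions;
* LBP — the 10-bin rotation-invariant uniform local binary pattern
  histogram (8 neighbours, 3x3 neighbourhood).

The top/bottom split follows the reading of a lung ultrasound frame: the
top half carries the pleural line, the bottom half carries A-line and
B-line content.  The three clinical covariates are appended last and are
never part of texture feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtcwt import SubbandSet, magnitude_subimages
from .phantom import SampleMeta

GLCM_OFFSETS = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 1), (2, 2))
GLRLM_DIRECTIONS = (0, 45, 90, 135)
GLRLM_FEATURE_NAMES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                       "SRLGE", "SRHGE", "LRLGE", "LRHGE")
CLINICAL_NAMES = ("ga_weeks", "cgats_weeks", "dol_days")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature stage (defaults are the study conditions)."""

    quant_levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS
    glrlm_directions: tuple[int, ...] = GLRLM_DIRECTIONS
    #: "image" uses the quantized-ROI mean/variance in GLCM correlation;
    #: "marginal" uses the textbook GLCM marginal means.
    glcm_correlation: str = "image"
    #: "sum" normalizes the ROI to unit sum before the entropy; "hist256"
    #: uses a 256-bin intensity histogram instead.
    entropy_mode: str = "sum"
    #: average GLCM/GLRLM features over offsets/directions instead of
    #: emitting them separately.
    average_directions: bool = False


# ---------------------------------------------------------------------------
# ROI handling
# ---------------------------------------------------------------------------

def split_rois(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(top, bottom, full) views; top gets rows [0, H//2)."""
    h = raster.shape[0]
    if h < 2:
        raise ValueError("raster must have at least 2 rows")
    return raster[: h // 2], raster[h // 2:], raster


# ---------------------------------------------------------------------------
# Statistical features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatFeatures:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    entropy: float
    degenerate: bool = False

    def values(self) -> tuple[float, ...]:
        return (self.mean, self.sd, self.skewness, self.kurtosis, self.entropy)


STAT_NAMES = ("mean", "sd", "skewness", "kurtosis", "entropy")


def statistical_features(roi: np.ndarray,
                         entropy_mode: str = "sum") -> StatFeatures:
    """First four standardized moments plus intensity entropy.

    SD is the population standard deviation (so skewness and excess
    kurtosis are the standard third/fourth standardized moments); a
    zero-variance ROI returns skewness = kurtosis = 0 with the
    ``degenerate`` flag set.  Entropy treats the sum-normalized ROI as a
    distribution with 0*log2(0) := 0.
    """
    x = np.asarray(roi, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    sd = float(np.sqrt(var))
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(np.mean((x - mean) ** 3) / sd ** 3)
        kurt = float(np.mean((x - mean) ** 4) / sd ** 4 - 3.0)

    if entropy_mode == "sum":
        total = x.sum()
        if total <= 0:
            ent = 0.0
            degenerate = True
        else:
            p = x / total
            nz = p[p > 0]
            ent = float(-(nz * np.log2(nz)).sum())
    elif entropy_mode == "hist256":
        hist, _ = np.histogram(x, bins=256)
        p = hist[hist > 0] / x.size
        ent = float(-(p * np.log2(p)).sum())
    else:
        raise ValueError(f"unknown entropy mode {entropy_mode!r}")
    return StatFeatures(mean, sd, skew, kurt, ent, degenerate)


# ---------------------------------------------------------------------------
# Quantization and GLCM
# ---------------------------------------------------------------------------

@dataclass
class QuantizedImage:
    levels: np.ndarray          # int raster, values in 1..L
    L: int
    bin_edges: np.ndarray       # the L-1 interior thresholds


def quantize(roi: np.ndarray, L: int = 8) -> QuantizedImage:
    """Equal-width quantization to levels 1..L over [min(roi), max(roi)]."""
    x = np.asarray(roi, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return QuantizedImage(np.ones(x.shape, dtype=np.int64), L,
                              np.full(L - 1, lo))
    width = (hi - lo) / L
    lv = np.floor((x - lo) / width).astype(np.int64) + 1
    np.clip(lv, 1, L, out=lv)
    edges = lo + width * np.arange(1, L)
    return QuantizedImage(lv, L, edges)


@dataclass
class GLCMatrix:
    counts: np.ndarray          # LxL integer pair counts
    offset: tuple[int, int]
    normalized: np.ndarray      # counts / total pairs


def glcm(q: QuantizedImage, offset: tuple[int, int]) -> GLCMatrix:
    """Directional (non-symmetric) co-occurrence counts for one offset."""
    dr, dc = offset
    lv = q.levels
    h, w = lv.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(f"ROI of shape {lv.shape} smaller than offset {offset}")
    r0 = slice(max(0, -dr), h - max(0, dr))
    c0 = slice(max(0, -dc), w - max(0, dc))
    r1 = slice(max(0, dr), h + min(0, dr))
    c1 = slice(max(0, dc), w + min(0, dc))
    base = lv[r0, c0].ravel() - 1
    nb = lv[r1, c1].ravel() - 1
    counts = np.bincount(base * q.L + nb, minlength=q.L * q.L)
    counts = counts.reshape(q.L, q.L)
    total = counts.sum()
    return GLCMatrix(counts, (dr, dc), counts / total)


GLCM_FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity",
                      "entropy")


def glcm_features(m: GLCMatrix, q: QuantizedImage,
                  correlation: str = "image") -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity and entropy of one GLCM.

    ``correlation="image"`` normalizes by the mean and population
    variance of the quantized ROI itself; ``"marginal"`` uses the
    textbook GLCM marginal statistics.  A zero-variance ROI yields
    correlation 0.
    """
    g = m.normalized
    L = q.L
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, L + 1)[None, :]
    contrast = float(((i - j) ** 2 * g).sum())
    energy = float((g ** 2).sum())
    homogeneity = float((g / (1.0 + (i - j) ** 2)).sum())
    nz = g[g > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if correlation == "image":
        u = float(q.levels.mean())
        var = float(q.levels.var())
        corr = 0.0 if var == 0 else float((((i - u) * (j - u) * g).sum()) / var)
    elif correlation == "marginal":
        pi = g.sum(axis=1)
        pj = g.sum(axis=0)
        ui = float((np.arange(1, L + 1) * pi).sum())
        uj = float((np.arange(1, L + 1) * pj).sum())
        si = float(np.sqrt(((np.arange(1, L + 1) - ui) ** 2 * pi).sum()))
        sj = float(np.sqrt(((np.arange(1, L + 1) - uj) ** 2 * pj).sum()))
        corr = 0.0 if si * sj == 0 else float(
            (((i - ui) * (j - uj) * g).sum()) / (si * sj))
    else:
        raise ValueError(f"unknown correlation mode {correlation!r}")
    return {"contrast": contrast, "correlation": corr, "energy": energy,
            "homogeneity": homogeneity, "entropy": entropy}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@dataclass
class GLRLMatrix:
    runs: np.ndarray            # L x Jmax counts (grey level, run length)
    direction: int
    n_pixels: int


def _lines_for_direction(lv: np.ndarray, direction: int) -> np.ndarray:
    """Stack the direction's parallel scan lines as rows, 0-padded.

    0 is a sentinel (valid levels are 1..L) so runs never span lines.
    """
    h, w = lv.shape
    if direction == 0:
        return lv
    if direction == 90:
        return lv.T
    # shear so diagonals become columns, then transpose
    sheared = np.zeros((h, w + h - 1), dtype=lv.dtype)
    cols = np.arange(w)
    for r in range(h):
        off = r if direction == 45 else h - 1 - r
        sheared[r, off + cols] = lv[r]
    return sheared.T


def glrlm(q: QuantizedImage, direction: int) -> GLRLMatrix:
    """Maximal-run counts along one direction (0, 45, 90 or 135 degrees).

    45 degrees scans the anti-diagonals (up-right), 135 the main
    diagonals (down-right); every pixel belongs to exactly one maximal
    run per direction, so sum(j * R[i, j]) equals the pixel count.
    """
    if direction not in (0, 45, 90, 135):
        raise ValueError(f"unsupported direction {direction}")
    lv = q.levels
    lines = _lines_for_direction(lv, direction)
    # append a sentinel column so runs cannot wrap between lines
    flat = np.concatenate(
        [lines, np.zeros((lines.shape[0], 1), dtype=lv.dtype)], axis=1).ravel()
    starts = np.flatnonzero(np.r_[True, flat[1:] != flat[:-1]])
    lengths = np.diff(np.r_[starts, flat.size])
    values = flat[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    jmax = max(lv.shape[0], lv.shape[1], int(lengths.max(initial=1)))
    runs = np.bincount((values - 1) * jmax + (lengths - 1),
                       minlength=q.L * jmax).reshape(q.L, jmax)
    return GLRLMatrix(runs, direction, int(lv.size))


def glrlm_features(r: GLRLMatrix) -> dict[str, float]:
    """The eleven run-length statistics.

    All are normalized by the total run count except run percentage
    (RP), whose denominator is the ROI pixel count.
    """
    runs = r.runs.astype(float)
    total = runs.sum()
    if total == 0:
        raise ValueError("GLRLM has no runs")
    i2 = (np.arange(1, runs.shape[0] + 1) ** 2)[:, None].astype(float)
    j2 = (np.arange(1, runs.shape[1] + 1) ** 2)[None, :].astype(float)
    return {
        "SRE": float((runs / j2).sum() / total),
        "LRE": float((runs * j2).sum() / total),
        "GLN": float((runs.sum(axis=1) ** 2).sum() / total),
        "RLN": float((runs.sum(axis=0) ** 2).sum() / total),
        "RP": float(total / r.n_pixels),
        "LGRE": float((runs / i2).sum() / total),
        "HGRE": float((runs * i2).sum() / total),
        "SRLGE": float((runs / (i2 * j2)).sum() / total),
        "SRHGE": float((runs * i2 / j2).sum() / total),
        "LRLGE": float((runs * j2 / i2).sum() / total),
        "LRHGE": float((runs * i2 * j2).sum() / total),
    }


# ---------------------------------------------------------------------------
# Rotation-invariant uniform LBP
# ---------------------------------------------------------------------------

# circular neighbour order: E, NE, N, NW, W, SW, S, SE
_LBP_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1),
                (0, -1), (1, -1), (1, 0), (1, 1))


def _lbp_lut() -> np.ndarray:
    """Map each 8-bit pattern to its rotation-invariant uniform bin.

    Uniform patterns (at most two circular 0-1 transitions) map to their
    popcount 0..8; all non-uniform patterns share bin 9.
    """
    lut = np.empty(256, dtype=np.int64)
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        lut[code] = sum(bits) if transitions <= 2 else 9
    return lut


_LBP_LUT = _lbp_lut()


def lbp_histogram(roi: np.ndarray) -> np.ndarray:
    """Normalized 10-bin rotation-invariant uniform LBP histogram.

    Each interior pixel's 3x3 neighbourhood is thresholded against the
    centre (neighbour >= centre sets the bit).  Only interior pixels
    contribute; the histogram sums to 1.
    """
    x = np.asarray(roi, dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("ROI must be at least 3x3 for LBP")
    center = x[1:-1, 1:-1]
    code = np.zeros(center.shape, dtype=np.int64)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = x[1 + dr: x.shape[0] - 1 + dr, 1 + dc: x.shape[1] - 1 + dc]
        code |= (nb >= center).astype(np.int64) << k
    bins = _LBP_LUT[code]
    hist = np.bincount(bins.ravel(), minlength=10).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray
    meta: SampleMeta | None = None


def _region_features(region: np.ndarray, prefix: str,
                     config: FeatureConfig,
                     names: list[str], values: list[float]) -> None:
    stats = statistical_features(region, entropy_mode=config.entropy_mode)
    for n, v in zip(STAT_NAMES, stats.values()):
        names.append(f"{prefix}_stat_{n}")
        values.append(v)

    q = quantize(region, config.quant_levels)
    glcm_acc: dict[str, list[float]] = {n: [] for n in GLCM_FEATURE_NAMES}
    for off in config.glcm_offsets:
        feats = glcm_features(glcm(q, off), q,
                              correlation=config.glcm_correlation)
        if config.average_directions:
            for n in GLCM_FEATURE_NAMES:
                glcm_acc[n].append(feats[n])
        else:
            tag = f"o{off[0]}{off[1]}"
            for n in GLCM_FEATURE_NAMES:
                names.append(f"{prefix}_glcm_{n}_{tag}")
                values.append(feats[n])
    glrlm_acc: dict[str, list[float]] = {n: [] for n in GLRLM_FEATURE_NAMES}
    for d in config.glrlm_directions:
        feats = glrlm_features(glrlm(q, d))
        if config.average_directions:
            for n in GLRLM_FEATURE_NAMES:
                glrlm_acc[n].append(feats[n])
        else:
            for n in GLRLM_FEATURE_NAMES:
                names.append(f"{prefix}_glrlm_{n}_d{d:03d}")
                values.append(feats[n])
    if config.average_directions:
        for n in GLCM_FEATURE_NAMES:
            names.append(f"{prefix}_glcm_{n}_avg")
            values.append(float(np.mean(glcm_acc[n])))
        for n in GLRLM_FEATURE_NAMES:
            names.append(f"{prefix}_glrlm_{n}_avg")
            values.append(float(np.mean(glrlm_acc[n])))

    hist = lbp_histogram(region)
    for b in range(10):
        names.append(f"{prefix}_lbp_b{b}")
        values.append(float(hist[b]))


def extract_features(s: SubbandSet, meta: SampleMeta | None = None,
                     config: FeatureConfig | None = None) -> FeatureVector:
    """Full named feature vector for one decomposed image.

    Every sub-image raster contributes top- and bottom-half features;
    low-pass rasters additionally contribute full-extent features (so
    e.g. ``M2_full_stat_mean`` is the global mean of the level-2
    low-pass band).  The clinical triple is appended last when ``meta``
    is given.
    """
    config = config or FeatureConfig()
    names: list[str] = []
    values: list[float] = []
    for band_name, raster in magnitude_subimages(s):
        top, bottom, full = split_rois(raster)
        _region_features(top, f"{band_name}_top", config, names, values)
        _region_features(bottom, f"{band_name}_bottom", config, names, values)
        if band_name.startswith("M"):
            _region_features(full, f"{band_name}_full", config, names, values)
    if meta is not None:
        for n, v in zip(CLINICAL_NAMES,
                        (meta.ga_weeks, meta.cgats_weeks, meta.dol_days)):
            names.append(n)
            values.append(float(v))
    return FeatureVector(names, np.asarray(values, dtype=float), meta)
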