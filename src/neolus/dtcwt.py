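"""2D dual-tree complex wavelet transform (DTCWT).

Two parallel separable filter-bank trees (four tree combinations in 2D)
compute the real and imaginary parts of six oriented complex subbands per
decomposition level, at orientations (+15, +45, +75, -75, -45, -15)
degrees.  Level 1 uses a near-symmetric biorthogonal pair with a 5-tap
scaling filter and 7-tap wavelet filter; the two trees differ by a
one-sample sampling offset.  Levels >= 2 use the standard 14-tap
quarter-shift orthonormal pair, tree B being the time-reverse of tree A,
which maintains the half-sample delay between trees at every decimated
rate and yields approximate shift invariance of subband magnitudes.

A per-level real low-pass raster ``M_j`` (the average of the four tree
combinations' scaling coefficients) is recorded before each level's
split, so global low-pass features such as the level-2 mean exist for
every level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pywt
from scipy.ndimage import correlate1d

ORIENTATION_LABELS = ("15p", "45p", "75p", "75n", "45n", "15n")

_SQRT2 = np.sqrt(2.0)

# Near-symmetric biorthogonal 5/7 pair (exact rationals), scaled to unit
# DC gain sqrt(2) so all levels share one normalization.
_H0_ODD = _SQRT2 * np.array([-1, 5, 12, 5, -1], dtype=float) / 20.0
_G0_ODD = np.array([-3, -15, 73, 170, 73, -15, -3], dtype=float) / 280.0
# analysis high-pass from the synthesis low-pass by sign alternation
_H1_ODD = _SQRT2 * _G0_ODD * (-1.0) ** np.arange(7)

# 14-tap quarter-shift orthonormal low-pass (tree A), tabulated to eight
# decimals in the standard published design.
_H0A_RAW = np.array([
    0.00325314, -0.00388321, 0.03466035, -0.03887280,
    -0.11720389, 0.27529538, 0.75614564, 0.56881042,
    0.01186609, -0.10671180, 0.02382538, 0.01702522,
    -0.00543948, -0.00455690])


def _polish_qshift(h: np.ndarray) -> np.ndarray:
    """Project tabulated taps onto the exact DC constraints.

    Least-squares nearest filter with sum = sqrt(2) and alternating sum
    = 0, so the derived high-pass annihilates constants to machine
    precision instead of to the table's print precision.
    """
    n = h.size
    alt = (-1.0) ** np.arange(n)
    a = (_SQRT2 - h.sum()) / n
    b = -(h * alt).sum() / n
    return h + a + b * alt


_H0A = _polish_qshift(_H0A_RAW)
_H0B = _H0A[::-1].copy()
_H1A = _H0B * (-1.0) ** np.arange(14)
_H1B = _H1A[::-1].copy()

FILTER_ID = "near-sym-5.7/qshift-14"


@dataclass
class SubbandSet:
    """Result of a multi-level 2D DTCWT decomposition.

    ``lowpass[j-1]`` is the real raster M_j; ``oriented[j-1]`` maps each
    orientation label in :data:`ORIENTATION_LABELS` to a complex raster.
    """

    levels: int
    lowpass: list[np.ndarray]
    oriented: list[dict[str, np.ndarray]]
    filter_id: str = FILTER_ID

    def raster_names(self) -> list[str]:
        """Stable serialization order: M1..MJ then D{orient}{level}."""
        names = [f"M{j}" for j in range(1, self.levels + 1)]
        for j in range(1, self.levels + 1):
            names += [f"D{o}{j}" for o in ORIENTATION_LABELS]
        return names


def _filt_odd(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    """Centred filtering with symmetric boundary extension (odd taps)."""
    return correlate1d(x, h, axis=axis, mode="mirror")


def _filt_even(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    """Filtering with the even-length q-shift taps, symmetric extension."""
    return correlate1d(x, h, axis=axis, mode="mirror")


def _dec(x: np.ndarray, axis: int, phase: int = 0) -> np.ndarray:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(phase, None, 2)
    return x[tuple(sl)]


def _pad_even(x: np.ndarray) -> np.ndarray:
    """Symmetric one-row/col pad so both axes have even length."""
    pr = x.shape[0] % 2
    pc = x.shape[1] % 2
    if pr or pc:
        x = np.pad(x, ((0, pr), (0, pc)), mode="symmetric")
    return x


def _combine(p_aa: np.ndarray, p_ab: np.ndarray,
             p_ba: np.ndarray, p_bb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Form the two oriented complex subbands from four tree combinations.

    Tree A carries the real part and tree B the imaginary part of the 1D
    complex wavelet, so psi(x)psi(y) and psi(x)conj(psi(y)) give the two
    opposite orientations of each band.  The 1/(2*sqrt(2)) scale makes
    total complex-magnitude energy commensurate with input energy.
    """
    sc = 1.0 / (2.0 * _SQRT2)
    z1 = sc * ((p_aa - p_bb) + 1j * (p_ab + p_ba))
    z2 = sc * ((p_aa + p_bb) + 1j * (p_ba - p_ab))
    return z1, z2


# band -> (positive-orientation label, negative-orientation label)
# rows-highpass sees horizontal structure (15 deg); cols-highpass sees
# vertical structure (75 deg); both-highpass sees the diagonals.
_BAND_LABELS = {"hl": ("15p", "15n"), "lh": ("75p", "75n"),
                "hh": ("45p", "45n")}


def dtcwt_forward(image: np.ndarray, levels: int = 5) -> SubbandSet:
    """Decompose ``image`` to ``levels`` scales of oriented complex subbands.

    Raises ``ValueError`` if the image is too small for the requested
    depth (each axis must be at least ``2**levels``).
    """
    x = np.asarray(image, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be a 2D raster")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(x.shape) < 2 ** levels:
        raise ValueError(
            f"image of shape {x.shape} too small for {levels} levels")

    lowpass: list[np.ndarray] = []
    oriented: list[dict[str, np.ndarray]] = []

    # ---- level 1: odd filters, trees differ by decimation phase --------
    x = _pad_even(x)
    lo_full = _filt_odd(x, _H0_ODD, axis=0)
    hi_full = _filt_odd(x, _H1_ODD, axis=0)
    phase = {"a": 0, "b": 1}

    trees_l: dict[tuple[str, str], np.ndarray] = {}
    bands: dict[str, dict[tuple[str, str], np.ndarray]] = {
        "lh": {}, "hl": {}, "hh": {}}
    for rt in ("a", "b"):
        lo_r = _dec(lo_full, axis=0, phase=phase[rt])
        hi_r = _dec(hi_full, axis=0, phase=phase[rt])
        for ct in ("a", "b"):
            trees_l[(rt, ct)] = _dec(_filt_odd(lo_r, _H0_ODD, 1), 1, phase[ct])
            bands["lh"][(rt, ct)] = _dec(_filt_odd(lo_r, _H1_ODD, 1), 1, phase[ct])
            bands["hl"][(rt, ct)] = _dec(_filt_odd(hi_r, _H0_ODD, 1), 1, phase[ct])
            bands["hh"][(rt, ct)] = _dec(_filt_odd(hi_r, _H1_ODD, 1), 1, phase[ct])
    lowpass.append(_average_trees(trees_l))
    oriented.append(_oriented_from_bands(bands))

    # ---- levels >= 2: q-shift filters per tree --------------------------
    h0 = {"a": _H0A, "b": _H0B}
    h1 = {"a": _H1A, "b": _H1B}
    for _ in range(1, levels):
        trees_l = {k: _pad_even(v) for k, v in trees_l.items()}
        new_l: dict[tuple[str, str], np.ndarray] = {}
        bands = {"lh": {}, "hl": {}, "hh": {}}
        for (rt, ct), arr in trees_l.items():
            lo_r = _dec(_filt_even(arr, h0[rt], 0), 0)
            hi_r = _dec(_filt_even(arr, h1[rt], 0), 0)
            new_l[(rt, ct)] = _dec(_filt_even(lo_r, h0[ct], 1), 1)
            bands["lh"][(rt, ct)] = _dec(_filt_even(lo_r, h1[ct], 1), 1)
            bands["hl"][(rt, ct)] = _dec(_filt_even(hi_r, h0[ct], 1), 1)
            bands["hh"][(rt, ct)] = _dec(_filt_even(hi_r, h1[ct], 1), 1)
        trees_l = new_l
        lowpass.append(_average_trees(trees_l))
        oriented.append(_oriented_from_bands(bands))

    return SubbandSet(levels=levels, lowpass=lowpass, oriented=oriented)


def _average_trees(trees: dict[tuple[str, str], np.ndarray]) -> np.ndarray:
    return (trees[("a", "a")] + trees[("a", "b")]
            + trees[("b", "a")] + trees[("b", "b")]) / 4.0


def _oriented_from_bands(
        bands: dict[str, dict[tuple[str, str], np.ndarray]]
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for band, (pos, neg) in _BAND_LABELS.items():
        p = bands[band]
        z1, z2 = _combine(p[("a", "a")], p[("a", "b")],
                          p[("b", "a")], p[("b", "b")])
        out[pos], out[neg] = z1, z2
    return {k: out[k] for k in ORIENTATION_LABELS}


def magnitude_subimages(s: SubbandSet) -> list[tuple[str, np.ndarray]]:
    """Real rasters for feature extraction, in stable name order.

    The J low-pass rasters are passed through with negative values
    clipped to zero (quantization-based features need non-negative
    input); the 6J oriented subbands become element-wise complex
    magnitudes.
    """
    out = [(f"M{j + 1}", np.clip(s.lowpass[j], 0.0, None))
           for j in range(s.levels)]
    for j in range(s.levels):
        for o in ORIENTATION_LABELS:
            out.append((f"D{o}{j + 1}", np.abs(s.oriented[j][o])))
    return out


def save_subbands(s: SubbandSet, directory: str | Path) -> None:
    """Serialize as named 32-bit float rasters (magnitudes for D bands)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in magnitude_subimages(s):
        np.save(directory / f"{name}.npy", arr.astype(np.float32))


def load_subband_magnitudes(directory: str | Path,
                            levels: int = 5) -> list[tuple[str, np.ndarray]]:
    directory = Path(directory)
    names = [f"M{j}" for j in range(1, levels + 1)]
    names += [f"D{o}{j}" for j in range(1, levels + 1)
              for o in ORIENTATION_LABELS]
    return [(n, np.load(directory / f"{n}.npy")) for n in names]


# ---------------------------------------------------------------------------
# Shift-variance probe (DTCWT vs plain critically-sampled DWT)
# ---------------------------------------------------------------------------

# 5-tap filters zero-padded to 7 taps: pywt requires equal filter lengths
_DWT_WAVELET = pywt.Wavelet("nearsym5-7", filter_bank=(
    np.r_[0.0, _H0_ODD, 0.0].tolist(), _H1_ODD.tolist(),
    (_SQRT2 * _G0_ODD).tolist(),
    np.r_[0.0, _SQRT2 * np.array([-1, 5, 12, 5, -1]) / 20.0
          * (-1.0) ** np.arange(5), 0.0].tolist()))


def _level2_magnitudes_dtcwt(image: np.ndarray) -> list[np.ndarray]:
    s = dtcwt_forward(image, levels=2)
    return [np.abs(s.oriented[1][o]) for o in ORIENTATION_LABELS]


def _level2_magnitudes_dwt(image: np.ndarray) -> list[np.ndarray]:
    coeffs = pywt.wavedec2(image, _DWT_WAVELET, level=2, mode="symmetric")
    return [np.abs(d) for d in coeffs[1]]  # the three level-2 detail bands


def shift_variance_metric(image: np.ndarray, shift_px: int,
                          transform: str = "dtcwt") -> float:
    """Mean relative L2 change of level-2 subband magnitudes under a shift.

    The input is circularly shifted ``shift_px`` rows and the magnitude
    rasters of the level-2 subbands are compared in place (decimation
    grids align, so any change reflects shift variance of the transform,
    not resampling).  Returns a value in [0, 2]; 0 for ``shift_px`` = 0.
    """
    if shift_px < 0:
        raise ValueError("shift_px must be >= 0")
    fn = {"dtcwt": _level2_magnitudes_dtcwt,
          "dwt": _level2_magnitudes_dwt}[transform]
    ref = fn(np.asarray(image, dtype=float))
    shifted = fn(np.roll(np.asarray(image, dtype=float), shift_px, axis=0))
    rels = []
    for a, b in zip(ref, shifted):
        denom = np.linalg.norm(a)
        if denom == 0:
            continue
        rels.append(np.linalg.norm(b - a) / denom)
    return float(np.mean(rels)) if rels else 0.0
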