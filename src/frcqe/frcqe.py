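"""Fourier ring correlation quality estimation (FRC-QE) for 3D fluorescence microscopy.

FRC-QE is a no-reference image quality metric for z-stacks of cleared,
fluorescently stained samples (e.g. nuclear-stained organoids).  Classical
Fourier ring correlation (FRC) needs two independent realizations of the same
signal; in a densely sampled stack, adjacent z-slices approximate such a pair.
The per-slice score is built from the FRC curve between slice ``z`` and its
adjacent neighbour, normalized by the FRC against more distant slices (which
share only large-scale structure and artifacts), and reduced to a scalar by
smoothing and integrating the relative curve over spatial-frequency rings.

Scores are in arbitrary units: they do not measure physical resolution and are
only comparable between stacks scored with identical parameters (block, ring
width, z offsets, smoothing, aggregation rule) — all of which are recorded in
every :class:`QualityProfile`.

The module is organised in the order the method runs:

1. errors, logging, defaults
2. ring partition of the centered 2D frequency plane (:func:`build_ring_map`)
3. FRC curves — production path and brute-force oracle (:func:`frc_curve`,
   :func:`frc_curve_bruteforce`)
4. the FRC-QE metric (:func:`relative_frc_curve`, :func:`frc_qe_slice`,
   :func:`frc_qe_profile`) and the two baselines
   (:func:`dct_shannon_entropy`, :func:`mean_intensity`)
5. synthetic organoid stack generator (:class:`SyntheticSpec`,
   :func:`generate_organoid_stack`)
6. TIFF / CSV input-output (:func:`read_stack`, :func:`write_stack`,
   :func:`write_profile`)
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.fft
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "FRC_BOUND_TOL",
    "RING_POWER_REL_TOL",
    "INTEGRATE_RULES",
    "DEGRADATION_MODES",
    "METRIC_NAMES",
    "with_seed",
    "FRCQEError",
    "InvalidParameterError",
    "DepthError",
    "UndefinedScoreError",
    "UnsupportedFormatError",
    "RingMap",
    "FRCCurve",
    "ImageStack",
    "QEParams",
    "QualityProfile",
    "SyntheticSpec",
    "build_ring_map",
    "frc_curve",
    "frc_curve_bruteforce",
    "relative_frc_curve",
    "frc_qe_slice",
    "frc_qe_profile",
    "dct_shannon_entropy",
    "mean_intensity",
    "scoreable_z_range",
    "depth_fraction",
    "applied_blur_sigma",
    "generate_organoid_stack",
    "read_stack",
    "write_stack",
    "write_profile",
    "read_profile",
    "parse_spec_text",
    "spec_to_text",
]

__version__ = "0.1.0"

logger = logging.getLogger("frcqe")

#: Floating tolerance for "value in [-1, 1]" assertions on FRC curves.
FRC_BOUND_TOL = 1e-9

#: A ring is flagged undefined when its power sum falls below this fraction of
#: the image's total spectral power (catches exact zeros and FFT round-off
#: leakage from constant blocks without imputing a silent 0).
RING_POWER_REL_TOL = 1e-20

INTEGRATE_RULES = ("trapz", "mean", "clip")
DEGRADATION_MODES = ("well_cleared", "poorly_cleared", "uniform_blur")
METRIC_NAMES = ("frc_qe", "dct_entropy", "mean_intensity")


class FRCQEError(Exception):
    """Base class for all frcqe errors."""


class InvalidParameterError(FRCQEError, ValueError):
    """A parameter violates its documented invariant (message names the field)."""


class DepthError(FRCQEError, ValueError):
    """The stack has too few slices for the requested z / normalization offsets."""


class UndefinedScoreError(FRCQEError, ValueError):
    """Fewer than two defined frequency rings remain; no score can be formed."""


class UnsupportedFormatError(FRCQEError, ValueError):
    """Input file is not a grayscale TIFF stack."""


def _as_image2d(pixels, name: str = "image") -> np.ndarray:
    """Validate and promote a 2D image to float64 (the Image2D contract)."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidParameterError(f"{name}: expected a 2D array, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InvalidParameterError(f"{name}: height and width must be >= 2, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name}: values must be finite (no NaN/Inf)")
    return arr


# ---------------------------------------------------------------------------
# Ring partition of the centered frequency plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingMap:
    """Assignment of every 2D frequency sample to a concentric radial ring.

    The frequency plane is the full two-sided, centered (DC at ``(h//2, w//2)``,
    i.e. ``fftshift``) discrete grid; sample ``(i, j)`` has integer frequency
    coordinates ``(i - h//2, j - w//2)`` and Euclidean radius in
    frequency-sample units.  Ring ``k`` collects radii in
    ``[k * ring_width, (k+1) * ring_width)``.
    """

    shape: tuple[int, int]
    ring_width: float
    ring_index: np.ndarray  # (h, w) int array, label per frequency sample
    n_rings: int
    ring_radius: np.ndarray  # (n_rings,) bin-center radius
    n_samples: np.ndarray  # (n_rings,) samples per ring


def build_ring_map(shape: tuple[int, int], ring_width: float = 1.0) -> RingMap:
    """Partition the centered frequency plane of a ``shape`` image into rings.

    Supports non-square and odd dimensions directly; the maximum radius is the
    distance to the farthest corner of the centered frequency grid.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 2 or w < 2:
        raise InvalidParameterError(f"shape: height and width must be >= 2, got {(h, w)}")
    if not (ring_width > 0 and math.isfinite(ring_width)):
        raise InvalidParameterError(f"ring_width: must be a positive finite real, got {ring_width}")

    fy = np.arange(h, dtype=np.float64) - h // 2
    fx = np.arange(w, dtype=np.float64) - w // 2
    radius = np.hypot(fy[:, None], fx[None, :])
    ring_index = np.floor(radius / ring_width).astype(np.intp)
    n_rings = int(ring_index.max()) + 1
    n_samples = np.bincount(ring_index.ravel(), minlength=n_rings)
    ring_radius = (np.arange(n_rings, dtype=np.float64) + 0.5) * float(ring_width)
    return RingMap(
        shape=(h, w),
        ring_width=float(ring_width),
        ring_index=ring_index,
        n_rings=n_rings,
        ring_radius=ring_radius,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# FRC curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FRCCurve:
    """Per-ring correlation between two images (or a relative combination).

    ``value`` holds one correlation per ring; rings whose spectral power
    denominator underflows are flagged undefined by ``NaN`` (never imputed as
    0) and exposed through :attr:`defined`.  For ``kind="pair"`` every defined
    value lies in ``[-1 - FRC_BOUND_TOL, 1 + FRC_BOUND_TOL]``.
    """

    radius: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray
    kind: str = "pair"

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of rings carrying a defined correlation value."""
        return ~np.isnan(self.value)

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.value).sum())


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def _spectrum(img: np.ndarray, window: bool) -> np.ndarray:
    """Centered (fftshift) 2D spectrum, optionally raised-cosine apodized."""
    if window:
        img = img * _hann2d(img.shape)
    return np.fft.fftshift(np.fft.fft2(img))


def _frc_from_spectra(f1: np.ndarray, f2: np.ndarray, ring_map: RingMap) -> FRCCurve:
    labels = ring_map.ring_index.ravel()
    n = ring_map.n_rings
    num = np.bincount(labels, weights=np.real(f1 * np.conj(f2)).ravel(), minlength=n)
    p1 = np.bincount(labels, weights=(np.abs(f1) ** 2).ravel(), minlength=n)
    p2 = np.bincount(labels, weights=(np.abs(f2) ** 2).ravel(), minlength=n)
    value = _normalize_frc(num, p1, p2)
    return FRCCurve(radius=ring_map.ring_radius.copy(), value=value,
                    n_samples=ring_map.n_samples.copy(), kind="pair")


def _normalize_frc(num: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Divide ring cross sums by sqrt(power products); NaN where power underflows."""
    tot1, tot2 = p1.sum(), p2.sum()
    defined = (p1 > tot1 * RING_POWER_REL_TOL) & (p2 > tot2 * RING_POWER_REL_TOL)
    if tot1 == 0.0 or tot2 == 0.0:
        defined[:] = False
    value = np.full(num.shape, np.nan)
    value[defined] = num[defined] / np.sqrt(p1[defined] * p2[defined])
    return value


def frc_curve(a, b, ring_map: RingMap | None = None, window: bool = False) -> FRCCurve:
    """Fourier ring correlation curve between two equally sized 2D images.

    Per ring ``r``: ``FRC(r) = Re[sum F1 . conj(F2)] / sqrt(sum |F1|^2 . sum
    |F2|^2)`` with sums over the frequency samples in the ring, using the real
    part of the complex cross-spectrum in the numerator (the standard FRC
    definition).  Properties: symmetric in ``(a, b)``; invariant under
    multiplying either image by a positive scalar; invariant under adding a
    constant to either image on every ring except the one containing DC;
    rings with vanishing spectral power are flagged undefined (NaN).

    Parameters
    ----------
    a, b
        Real 2D images of identical shape, height and width >= 2.
    ring_map
        Precomputed partition; defaults to ``build_ring_map(a.shape, 1.0)``.
    window
        Apply the same raised-cosine (Hann) apodization to both images before
        transforming.  Off by default so the brute-force definition holds
        exactly.
    """
    a = _as_image2d(a, "a")
    b = _as_image2d(b, "b")
    if a.shape != b.shape:
        raise InvalidParameterError(f"a and b must share a shape, got {a.shape} vs {b.shape}")
    if ring_map is None:
        ring_map = build_ring_map(a.shape)
    elif ring_map.shape != a.shape:
        raise InvalidParameterError(
            f"ring_map shape {ring_map.shape} does not match image shape {a.shape}")
    return _frc_from_spectra(_spectrum(a, window), _spectrum(b, window), ring_map)


def frc_curve_bruteforce(a, b, ring_map: RingMap | None = None) -> FRCCurve:
    """Deliberately naive FRC: explicit scalar loops over every frequency sample.

    Identical contract to ``frc_curve(window=False)``; kept alongside the
    production path as a permanent definitional oracle.
    """
    a = _as_image2d(a, "a")
    b = _as_image2d(b, "b")
    if a.shape != b.shape:
        raise InvalidParameterError(f"a and b must share a shape, got {a.shape} vs {b.shape}")
    if ring_map is None:
        ring_map = build_ring_map(a.shape)
    elif ring_map.shape != a.shape:
        raise InvalidParameterError(
            f"ring_map shape {ring_map.shape} does not match image shape {a.shape}")

    f1 = np.fft.fftshift(np.fft.fft2(a))
    f2 = np.fft.fftshift(np.fft.fft2(b))
    h, w = a.shape
    num = [0.0] * ring_map.n_rings
    p1 = [0.0] * ring_map.n_rings
    p2 = [0.0] * ring_map.n_rings
    for i in range(h):
        for j in range(w):
            k = int(ring_map.ring_index[i, j])
            z1 = complex(f1[i, j])
            z2 = complex(f2[i, j])
            num[k] += (z1 * z2.conjugate()).real
            p1[k] += abs(z1) ** 2
            p2[k] += abs(z2) ** 2
    value = _normalize_frc(np.array(num), np.array(p1), np.array(p2))
    return FRCCurve(radius=ring_map.ring_radius.copy(), value=value,
                    n_samples=ring_map.n_samples.copy(), kind="pair")


# ---------------------------------------------------------------------------
# FRC-QE metric and baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageStack:
    """3D intensity stack (z, y, x) with voxel-pitch metadata.

    ``z_spacing`` and ``xy_pitch`` are physical units per step (conventionally
    micrometres); they are metadata only — scores are computed in voxel units
    and are comparable only between stacks acquired with matching spacing.
    """

    voxels: np.ndarray
    z_spacing: float = 1.0
    xy_pitch: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.ndim != 3:
            raise InvalidParameterError(f"voxels: expected 3D (z, y, x), got ndim={arr.ndim}")
        if arr.shape[1] < 2 or arr.shape[2] < 2:
            raise InvalidParameterError(f"voxels: slice shape must be >= 2x2, got {arr.shape[1:]}")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("voxels: values must be finite (no NaN/Inf)")
        object.__setattr__(self, "voxels", arr)

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]


@dataclass(frozen=True)
class QEParams:
    """Parameter set of one FRC-QE computation.

    Scores depend on every field here (block, z offsets, ring width, smoothing,
    aggregation, windowing), so a series of comparisons is valid only when the
    full set is held constant; :class:`QualityProfile` records it verbatim.

    block
        ``(y_offset, x_offset, height, width)`` ROI with 0-based offsets and
        half-open extents, ``"full"`` for the whole slice, or ``None`` for the
        default: the largest centered square that fits the slice.
    dz_adjacent
        Slice offset of the "independent realization" partner (default 1).
    dz_distant
        Offset of the normalization partners; the distant-slice FRC is the
        mean of the curves against ``z - dz_distant`` and ``z + dz_distant``.
    boundary
        ``"one_sided"`` (default) falls back to a single distant partner near
        the stack faces; ``"two_sided"`` requires both, shrinking the
        scoreable z range.
    smooth_window
        Odd width of the centered moving average over rings (shrinks
        symmetrically at curve ends).
    integrate
        Reduction of the smoothed relative curve: ``"trapz"`` (trapezoidal
        integral over ring radius; default), ``"mean"``, or ``"clip"``
        (negative values clipped to 0 before integrating).
    """

    block: tuple[int, int, int, int] | str | None = None
    dz_adjacent: int = 1
    dz_distant: int = 10
    ring_width: float = 1.0
    smooth_window: int = 5
    integrate: str = "trapz"
    window: bool = False
    boundary: str = "one_sided"

    def validate(self, slice_shape: tuple[int, int] | None = None) -> None:
        if not (isinstance(self.dz_adjacent, (int, np.integer)) and self.dz_adjacent >= 1):
            raise InvalidParameterError(f"dz_adjacent: must be an integer >= 1, got {self.dz_adjacent}")
        if not (isinstance(self.dz_distant, (int, np.integer)) and self.dz_distant > self.dz_adjacent):
            raise InvalidParameterError(
                f"dz_distant: must be an integer > dz_adjacent ({self.dz_adjacent}), got {self.dz_distant}")
        if not (self.ring_width > 0 and math.isfinite(self.ring_width)):
            raise InvalidParameterError(f"ring_width: must be a positive finite real, got {self.ring_width}")
        if not (isinstance(self.smooth_window, (int, np.integer))
                and self.smooth_window >= 1 and self.smooth_window % 2 == 1):
            raise InvalidParameterError(
                f"smooth_window: must be an odd positive integer, got {self.smooth_window}")
        if self.integrate not in INTEGRATE_RULES:
            raise InvalidParameterError(
                f"integrate: must be one of {INTEGRATE_RULES}, got {self.integrate!r}")
        if self.boundary not in ("one_sided", "two_sided"):
            raise InvalidParameterError(
                f"boundary: must be 'one_sided' or 'two_sided', got {self.boundary!r}")
        if isinstance(self.block, str) and self.block != "full":
            raise InvalidParameterError(f"block: string value must be 'full', got {self.block!r}")
        if isinstance(self.block, tuple):
            if len(self.block) != 4:
                raise InvalidParameterError(f"block: expected (y0, x0, height, width), got {self.block}")
            y0, x0, bh, bw = self.block
            if min(bh, bw) < 2 or min(y0, x0) < 0:
                raise InvalidParameterError(
                    f"block: offsets must be >= 0 and extents >= 2, got {self.block}")
            if slice_shape is not None:
                if y0 + bh > slice_shape[0] or x0 + bw > slice_shape[1]:
                    raise InvalidParameterError(
                        f"block: {self.block} does not fit inside slice of shape {slice_shape}")

    def resolve_block(self, slice_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Concrete ``(y0, x0, h, w)``: default is the largest centered square."""
        h, w = slice_shape
        if self.block is None:
            side = min(h, w)
            return ((h - side) // 2, (w - side) // 2, side, side)
        if self.block == "full":
            return (0, 0, h, w)
        return tuple(int(v) for v in self.block)  # type: ignore[return-value]

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if isinstance(d["block"], tuple):
            d["block"] = list(d["block"])
        return d


def scoreable_z_range(depth: int, params: QEParams) -> list[int]:
    """All z indices with an adjacent partner and the required distant partner(s)."""
    zs = []
    for z in range(depth):
        if z + params.dz_adjacent >= depth:
            continue
        lo, hi = z - params.dz_distant >= 0, z + params.dz_distant < depth
        ok = (lo and hi) if params.boundary == "two_sided" else (lo or hi)
        if ok:
            zs.append(z)
    return zs


def _crop_block(slice2d: np.ndarray, block: tuple[int, int, int, int]) -> np.ndarray:
    y0, x0, bh, bw = block
    return slice2d[y0:y0 + bh, x0:x0 + bw]


def relative_frc_curve(stack: ImageStack, z: int, params: QEParams = QEParams()) -> FRCCurve:
    """Relative FRC curve of slice ``z``: adjacent-slice FRC minus distant-slice FRC.

    ``FRC_adj`` is the curve between slice ``z`` and ``z + dz_adjacent``;
    ``FRC_dist`` is the mean of the curves against ``z - dz_distant`` and
    ``z + dz_distant`` over whichever exist (one-sided fallback per
    ``params.boundary``).  Rings undefined in any contributing curve are
    undefined in the result.
    """
    params.validate(stack.slice_shape)
    depth = stack.depth
    valid = scoreable_z_range(depth, params)
    if z not in valid:
        interval = f"[{valid[0]}, {valid[-1]}]" if valid else "(empty)"
        raise DepthError(
            f"slice z={z} has no adjacent/distant partners for dz_adjacent={params.dz_adjacent}, "
            f"dz_distant={params.dz_distant}, boundary={params.boundary}; valid z interval: {interval}")

    block = params.resolve_block(stack.slice_shape)
    ring_map = build_ring_map((block[2], block[3]), params.ring_width)

    def spec_of(zi: int) -> np.ndarray:
        return _spectrum(_crop_block(stack.voxels[zi], block), params.window)

    f_z = spec_of(z)
    adj = _frc_from_spectra(f_z, spec_of(z + params.dz_adjacent), ring_map)
    dist_values = []
    for zd in (z - params.dz_distant, z + params.dz_distant):
        if 0 <= zd < depth:
            dist_values.append(_frc_from_spectra(f_z, spec_of(zd), ring_map).value)
    dist = np.mean(dist_values, axis=0)  # NaN in either curve propagates
    return FRCCurve(radius=ring_map.ring_radius.copy(), value=adj.value - dist,
                    n_samples=ring_map.n_samples.copy(), kind="relative")


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, shrinking symmetrically at the ends."""
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        half = min(window // 2, i, n - 1 - i)
        out[i] = values[i - half:i + half + 1].mean()
    return out


def _aggregate_curve(curve: FRCCurve, params: QEParams) -> float:
    mask = curve.defined
    if int(mask.sum()) < 2:
        raise UndefinedScoreError(
            f"only {int(mask.sum())} defined ring(s) after filtering; >= 2 required for a score")
    v = _moving_average(curve.value[mask], params.smooth_window)
    r = curve.radius[mask]
    if params.integrate == "trapz":
        return float(np.trapezoid(v, r))
    if params.integrate == "mean":
        return float(v.mean())
    if params.integrate == "clip":
        return float(np.trapezoid(np.clip(v, 0.0, None), r))
    raise InvalidParameterError(f"integrate: unknown rule {params.integrate!r}")


def frc_qe_slice(stack: ImageStack, z: int, params: QEParams = QEParams()) -> float:
    """FRC-QE score of one slice: smoothed, integrated relative FRC curve.

    The defined values of the relative curve are smoothed with a centered
    moving average of ``params.smooth_window`` rings, then reduced by the
    ``params.integrate`` rule (default: trapezoidal integral over ring radius,
    undefined rings skipped by joining their defined neighbours).  The score is
    in arbitrary units and only supports relative comparison under fixed
    parameters.
    """
    return _aggregate_curve(relative_frc_curve(stack, z, params), params)


@dataclass(frozen=True)
class QualityProfile:
    """Per-slice quality scores for one stack, with the parameters that made them."""

    z_index: np.ndarray
    frc_qe: np.ndarray
    dct_entropy: np.ndarray
    mean_intensity: np.ndarray
    n_undefined_rings: np.ndarray
    params: QEParams

    def __len__(self) -> int:
        return len(self.z_index)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "z_index": self.z_index,
            "frc_qe": self.frc_qe,
            "dct_entropy": self.dct_entropy,
            "mean_intensity": self.mean_intensity,
            "n_undefined_rings": self.n_undefined_rings,
        })


def frc_qe_profile(stack: ImageStack, params: QEParams = QEParams(),
                   metrics: Sequence[str] = METRIC_NAMES) -> QualityProfile:
    """Score every scoreable slice of a stack with FRC-QE and the baselines.

    One row per z that has an adjacent partner and the distant partner(s)
    required by ``params.boundary``, ordered by z.  Metrics not in ``metrics``
    are reported as NaN.  Spectra are computed once per slice and reused across
    the adjacent/distant pairings.
    """
    params.validate(stack.slice_shape)
    for m in metrics:
        if m not in METRIC_NAMES:
            raise InvalidParameterError(f"metrics: unknown metric {m!r}; choose from {METRIC_NAMES}")
    zs = scoreable_z_range(stack.depth, params)
    if not zs:
        need = 2 * params.dz_distant + 1 if params.boundary == "two_sided" else params.dz_distant + 1
        raise DepthError(
            f"stack of depth {stack.depth} admits no scoreable slice for dz_adjacent="
            f"{params.dz_adjacent}, dz_distant={params.dz_distant}, boundary={params.boundary} "
            f"(at least {need} slices required)")

    block = params.resolve_block(stack.slice_shape)
    ring_map = build_ring_map((block[2], block[3]), params.ring_width)
    blocks = [_crop_block(stack.voxels[z], block) for z in range(stack.depth)]
    spectra = [None] * stack.depth

    def spec_of(zi: int) -> np.ndarray:
        if spectra[zi] is None:
            spectra[zi] = _spectrum(blocks[zi], params.window)
        return spectra[zi]

    qe = np.full(len(zs), np.nan)
    ent = np.full(len(zs), np.nan)
    mi = np.full(len(zs), np.nan)
    nundef = np.zeros(len(zs), dtype=np.intp)
    for row, z in enumerate(zs):
        if "frc_qe" in metrics:
            f_z = spec_of(z)
            adj = _frc_from_spectra(f_z, spec_of(z + params.dz_adjacent), ring_map)
            dist_values = [
                _frc_from_spectra(f_z, spec_of(zd), ring_map).value
                for zd in (z - params.dz_distant, z + params.dz_distant)
                if 0 <= zd < stack.depth
            ]
            rel = FRCCurve(radius=ring_map.ring_radius.copy(),
                           value=adj.value - np.mean(dist_values, axis=0),
                           n_samples=ring_map.n_samples.copy(), kind="relative")
            qe[row] = _aggregate_curve(rel, params)
            nundef[row] = rel.n_undefined
        if "dct_entropy" in metrics:
            ent[row] = dct_shannon_entropy(blocks[z])
        if "mean_intensity" in metrics:
            mi[row] = mean_intensity(blocks[z])
    return QualityProfile(z_index=np.asarray(zs, dtype=np.intp), frc_qe=qe,
                          dct_entropy=ent, mean_intensity=mi,
                          n_undefined_rings=nundef, params=params)


def dct_shannon_entropy(img) -> float:
    """Shannon entropy of the L1-normalized magnitudes of the type-II DCT.

    ``d = |DCT-II(img)|``, ``p = d / sum(d)``, ``H = -sum p * log2 p`` with the
    ``0 * log 0 = 0`` convention.  A constant image has a single nonzero (DC)
    coefficient and entropy 0; an all-zero image returns 0 by the same
    convention.  Invariant under positive scaling; bounded by
    ``log2(height * width)``.
    """
    arr = _as_image2d(img, "img")
    d = np.abs(scipy.fft.dctn(arr, type=2))
    total = d.sum()
    if total == 0.0:
        return 0.0
    p = d.ravel() / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mean_intensity(img) -> float:
    """Arithmetic mean of pixel values within the block."""
    return float(np.mean(_as_image2d(img, "img")))


# ---------------------------------------------------------------------------
# Synthetic cleared-organoid stack generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated nuclear-stained organoid stack.

    The defaults emulate a desk-scale analogue of a ~600 um cerebral organoid
    with a nuclear stain: a sphere of Gaussian nuclei imaged as a z-stack whose
    quality either stays constant with depth (``well_cleared``), degrades
    toward the central slices (``poorly_cleared``: depth-ramped blur plus an
    additive haze background that *raises* intensity where quality falls), or
    is uniformly degraded (``uniform_blur``).  The sphere must fit in-plane;
    it may be truncated by the z faces, as when the imaged slab is thinner
    than the organoid.

    Identical spec (including ``seed``) regenerates a bit-identical stack.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    organoid_radius: float = 48.0
    n_nuclei: int = 300
    nucleus_sigma: float = 2.0
    base_intensity: float = 100.0
    degradation_mode: str = "well_cleared"
    blur_sigma_max: float = 3.0
    haze_max: float = 50.0
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 2 for s in self.shape):
            raise InvalidParameterError(f"shape: expected 3 dims each >= 2, got {self.shape}")
        nz, ny, nx = self.shape
        if not (0 < self.organoid_radius <= min(ny, nx) / 2):
            raise InvalidParameterError(
                f"organoid_radius: must be in (0, {min(ny, nx) / 2}] to fit the {ny}x{nx} "
                f"slice in-plane, got {self.organoid_radius}")
        if not (isinstance(self.n_nuclei, (int, np.integer)) and self.n_nuclei >= 1):
            raise InvalidParameterError(f"n_nuclei: must be an integer >= 1, got {self.n_nuclei}")
        for name in ("nucleus_sigma", "blur_sigma_max", "haze_max", "noise_sigma"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise InvalidParameterError(f"{name}: must be a finite real >= 0, got {v}")
        if not (self.base_intensity > 0 and math.isfinite(self.base_intensity)):
            raise InvalidParameterError(
                f"base_intensity: must be a positive finite real, got {self.base_intensity}")
        if self.degradation_mode not in DEGRADATION_MODES:
            raise InvalidParameterError(
                f"degradation_mode: must be one of {DEGRADATION_MODES}, got {self.degradation_mode!r}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["shape"] = list(d["shape"])
        return d


def depth_fraction(depth: int) -> np.ndarray:
    """Normalized depth-from-nearest-z-face, d(z) in [0, 1]: 0 at the faces,
    rising linearly to ~1 at the central slice (a U-shaped degradation driver)."""
    z = np.arange(depth, dtype=np.float64)
    return np.minimum(z, depth - 1 - z) / ((depth - 1) / 2.0)


def _degradation_gain(mode: str, d: np.ndarray) -> np.ndarray:
    if mode == "well_cleared":
        return np.zeros_like(d)
    if mode == "poorly_cleared":
        return d
    if mode == "uniform_blur":
        return np.ones_like(d)
    raise InvalidParameterError(f"degradation_mode: unknown mode {mode!r}")


def applied_blur_sigma(spec: SyntheticSpec) -> np.ndarray:
    """Per-slice blur width sigma(z) = blur_sigma_max * g(d(z)) the generator applies."""
    return spec.blur_sigma_max * _degradation_gain(spec.degradation_mode,
                                                   depth_fraction(spec.shape[0]))


def _nuclei_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the sphere intersected with the stack volume."""
    nz, ny, nx = spec.shape
    center = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    r = spec.organoid_radius
    pts = []
    while len(pts) < spec.n_nuclei:
        cand = rng.uniform(center - r, center + r, size=(4 * spec.n_nuclei, 3))
        inside = np.linalg.norm(cand - center, axis=1) <= r
        inslab = (cand[:, 0] >= 0) & (cand[:, 0] <= nz - 1)
        pts.extend(cand[inside & inslab])
    return np.array(pts[: spec.n_nuclei])


def generate_organoid_stack(spec: SyntheticSpec = SyntheticSpec()) -> ImageStack:
    """Render a seeded synthetic organoid z-stack per ``spec``.

    Pipeline: nuclei centers drawn uniformly inside the (possibly z-truncated)
    sphere -> each rendered as an isotropic 3D Gaussian blob of width
    ``nucleus_sigma`` and peak ``base_intensity`` -> per-slice degradation
    driven by normalized depth d(z): 2D blur of width
    ``blur_sigma_max * g(d)`` and additive haze ``haze_max * g(d)`` shaped by a
    wide (5 * nucleus_sigma) blur of the slice so it raises intensity without
    adding high-frequency structure -> Gaussian read noise added last (after
    the blur, so blur lowers the high-frequency signal-to-noise ratio) ->
    clipped to >= 0.
    """
    spec.validate()
    nz, ny, nx = (int(s) for s in spec.shape)
    rng = np.random.default_rng(spec.seed)
    centers = _nuclei_centers(spec, rng)

    impulses = np.zeros((nz, ny, nx))
    idx = np.clip(np.rint(centers).astype(np.intp), 0, np.array([nz, ny, nx]) - 1)
    # Peak-normalized amplitude: a unit-mass Gaussian of width sigma has peak
    # (2 pi sigma^2)^{-3/2}; scale impulses so each blob peaks near base_intensity.
    amp = spec.base_intensity * (2.0 * np.pi * spec.nucleus_sigma ** 2) ** 1.5 \
        if spec.nucleus_sigma > 0 else spec.base_intensity
    np.add.at(impulses, (idx[:, 0], idx[:, 1], idx[:, 2]), amp)
    clean = gaussian_filter(impulses, spec.nucleus_sigma) if spec.nucleus_sigma > 0 else impulses

    gain = _degradation_gain(spec.degradation_mode, depth_fraction(nz))
    haze_sigma = max(5.0 * spec.nucleus_sigma, 1.0)
    out = np.empty_like(clean)
    for z in range(nz):
        s = clean[z]
        sigma_z = spec.blur_sigma_max * gain[z]
        out[z] = gaussian_filter(s, sigma_z) if sigma_z > 0 else s
        h_z = spec.haze_max * gain[z]
        if h_z > 0:
            haze = gaussian_filter(s, haze_sigma)
            peak = haze.max()
            if peak > 0:
                out[z] = out[z] + h_z * haze / peak

    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return ImageStack(voxels=np.maximum(out, 0.0))


# ---------------------------------------------------------------------------
# I/O: TIFF stacks, CSV profiles, plain-text synthetic specs
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _meta_from_description(description: str | None) -> dict:
    if not description:
        return {}
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}


def read_stack(path) -> ImageStack:
    """Read a grayscale z-stack from a multi-page TIFF or a directory of TIFFs.

    Directory input: identically shaped single-page TIFFs ordered
    lexicographically as z.  Voxels are promoted to float64; z = page order,
    (y, x) = (row, column).  ``z_spacing`` / ``xy_pitch`` metadata written by
    :func:`write_stack` is recovered when present, otherwise defaulted to 1.0
    with a logged warning.  Multi-channel/RGB images and non-TIFF files are
    rejected loudly.
    """
    p = Path(path)
    if p.is_dir():
        tifs = sorted(f for f in p.iterdir() if f.suffix.lower() in _TIFF_SUFFIXES)
        if not tifs:
            others = sorted(f.name for f in p.iterdir() if f.is_file())
            raise UnsupportedFormatError(
                f"{p}: no .tif/.tiff files found (directory contains {others[:5]}); "
                "only TIFF stacks are supported")
        slices = []
        for f in tifs:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise UnsupportedFormatError(
                    f"{f.name}: expected a single-page grayscale TIFF, got shape {arr.shape}; "
                    "select a channel / split pages first")
            if slices and arr.shape != slices[0].shape:
                raise UnsupportedFormatError(
                    f"{f.name}: slice shape {arr.shape} differs from first slice "
                    f"{slices[0].shape}")
            slices.append(arr)
        voxels = np.stack(slices).astype(np.float64)
        with tifffile.TiffFile(tifs[0]) as tf:
            meta = _meta_from_description(tf.pages[0].description)
    else:
        if p.suffix.lower() not in _TIFF_SUFFIXES:
            raise UnsupportedFormatError(
                f"{p}: unsupported format {p.suffix!r}; only multi-page TIFF is supported")
        with tifffile.TiffFile(p) as tf:
            first = tf.pages[0]
            if (first.samplesperpixel or 1) > 1:
                raise UnsupportedFormatError(
                    f"{p}: {first.samplesperpixel} samples per pixel (RGB/multi-channel); "
                    "select a single channel before scoring")
            shape0 = first.shape
            for i, page in enumerate(tf.pages):
                if page.shape != shape0:
                    raise UnsupportedFormatError(
                        f"{p}: page {i} shape {page.shape} differs from page 0 shape {shape0}")
            series = tf.series[0]
            if any(ax in series.axes for ax in ("S", "C")):
                raise UnsupportedFormatError(
                    f"{p}: multi-channel axes {series.axes!r}; select a single channel")
            data = series.asarray()
            meta = _meta_from_description(first.description)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise UnsupportedFormatError(f"{p}: cannot interpret shape {data.shape} as (z, y, x)")
        voxels = data.astype(np.float64)

    z_spacing = meta.get("z_spacing")
    xy_pitch = meta.get("xy_pitch")
    if z_spacing is None or xy_pitch is None:
        logger.warning("%s: no voxel pitch metadata found; defaulting z_spacing and xy_pitch to 1.0", p)
    return ImageStack(voxels=voxels,
                      z_spacing=float(z_spacing) if z_spacing is not None else 1.0,
                      xy_pitch=float(xy_pitch) if xy_pitch is not None else 1.0)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a float64 multi-page grayscale TIFF with pitch metadata."""
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        photometric="minisblack",
        metadata={"z_spacing": stack.z_spacing, "xy_pitch": stack.xy_pitch},
    )


PROFILE_HEADER = "z_index,frc_qe,dct_entropy,mean_intensity,n_undefined_rings"


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest round-trip decimal


def write_profile(profile: QualityProfile, path) -> None:
    """Write a profile as CSV plus an adjacent ``<path>.params.json`` audit file.

    The CSV carries full double precision (round-trip safe, period decimal
    separator); the JSON records every QEParams value and the tool version so
    that comparisons across runs can be audited for matching parameters.
    """
    if len(profile) == 0:
        raise InvalidParameterError("profile: refusing to write an empty profile")
    p = Path(path)
    lines = [PROFILE_HEADER]
    for i in range(len(profile)):
        lines.append(",".join([
            str(int(profile.z_index[i])),
            _fmt(profile.frc_qe[i]),
            _fmt(profile.dct_entropy[i]),
            _fmt(profile.mean_intensity[i]),
            str(int(profile.n_undefined_rings[i])),
        ]))
    p.write_text("\n".join(lines) + "\n")
    meta = {"tool": "frcqe", "version": __version__, "params": profile.params.to_dict()}
    Path(str(p) + ".params.json").write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_profile(path) -> QualityProfile:
    """Parse a CSV written by :func:`write_profile` (params recovered from the audit file)."""
    p = Path(path)
    lines = p.read_text().strip().split("\n")
    if lines[0] != PROFILE_HEADER:
        raise UnsupportedFormatError(f"{p}: unexpected header {lines[0]!r}")
    rows = [ln.split(",") for ln in lines[1:]]
    meta_path = Path(str(p) + ".params.json")
    params = QEParams()
    if meta_path.exists():
        d = json.loads(meta_path.read_text()).get("params", {})
        if isinstance(d.get("block"), list):
            d["block"] = tuple(d["block"])
        params = QEParams(**d)
    return QualityProfile(
        z_index=np.array([int(r[0]) for r in rows], dtype=np.intp),
        frc_qe=np.array([float(r[1]) for r in rows]),
        dct_entropy=np.array([float(r[2]) for r in rows]),
        mean_intensity=np.array([float(r[3]) for r in rows]),
        n_undefined_rings=np.array([int(r[4]) for r in rows], dtype=np.intp),
        params=params,
    )


def parse_spec_text(text: str) -> SyntheticSpec:
    """Parse a plain-text ``key = value`` config into a :class:`SyntheticSpec`.

    Lines starting with ``#`` (and blank lines) are ignored.  ``shape`` is a
    comma-separated triple ``z,y,x``; ``degradation_mode`` is one of
    ``well_cleared``, ``poorly_cleared``, ``uniform_blur``.
    """
    known = {f.name: f for f in fields(SyntheticSpec)}
    kwargs: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidParameterError(f"spec line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise InvalidParameterError(
                f"spec line {lineno}: unknown key {key!r}; known keys: {sorted(known)}")
        if key == "shape":
            parts = [int(v) for v in value.split(",")]
            if len(parts) != 3:
                raise InvalidParameterError(f"spec line {lineno}: shape needs 3 values, got {value!r}")
            kwargs[key] = tuple(parts)
        elif key == "degradation_mode":
            kwargs[key] = value
        elif key in ("n_nuclei", "seed"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    spec = SyntheticSpec(**kwargs)
    spec.validate()
    return spec


def spec_to_text(spec: SyntheticSpec) -> str:
    """Serialize a :class:`SyntheticSpec` to the plain-text key-value format."""
    lines = []
    for f in fields(SyntheticSpec):
        v = getattr(spec, f.name)
        if f.name == "shape":
            v = ",".join(str(int(s)) for s in v)
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a replaced seed."""
    return replace(spec, seed=int(seed))
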