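"""Vegetation-index feature extraction from multispectral plot imagery.

A plot is observed as a five-band reflectance raster (blue, green, red,
rededge, nir).  Canopy pixels are separated from soil/residue background
with an active-contour (Chan–Vese) or NDVI-threshold segmentation, small
noise regions are removed, and seven per-pixel indices are aggregated into
one feature vector per plot:

    CCCI   canopy chlorophyll content index, ((nir-re)/(nir+re)) / NDVI
    MTVI2  modified triangular vegetation index 2
    BNDVI  blue-normalised difference vegetation index, (nir-blue)/(nir+blue)
    GLI    green leaf index, (2g-r-b)/(2g+r+b)
    CI     coloration index, (red-blue)/red
    H      hue angle, atan2(2r-g-b, sqrt(3)*(g-b))
    V      value channel of the RGB->HSV conversion, max(r,g,b)

Indices whose denominator is numerically degenerate are flagged missing
rather than returned as inf/nan surprises; plot aggregation skips flagged
pixels per index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BAND_NAMES = ("blue", "green", "red", "rededge", "nir")
FEATURE_NAMES = ("CCCI", "MTVI2", "BNDVI", "GLI", "CI", "H", "V")

#: denominators with magnitude below this are treated as degenerate
DENOM_EPS = 1e-9

SQRT3 = np.sqrt(3.0)


class SpectralImage:
    """Five co-registered reflectance bands for one plot.

    Parameters
    ----------
    bands : mapping of band name -> 2-D float array
        Keys must be exactly ``blue, green, red, rededge, nir``; all arrays
        must share one shape.  Values are unitless reflectances, expected in
        [0, 1] (a warning is emitted otherwise, but values are kept).
    """

    def __init__(self, bands):
        missing = set(BAND_NAMES) - set(bands)
        if missing:
            raise ValueError(f"missing bands: {sorted(missing)}")
        arrays = [np.asarray(bands[name], dtype=float) for name in BAND_NAMES]
        shape = arrays[0].shape
        if len(shape) != 2:
            raise ValueError("bands must be 2-D arrays")
        for name, arr in zip(BAND_NAMES, arrays):
            if arr.shape != shape:
                raise ValueError("all bands must share one shape")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"band {name!r} contains non-finite values")
        self.data = np.stack(arrays)  # (5, H, W)
        if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
            warnings.warn("reflectance values outside [0, 1]", stacklevel=2)

    @property
    def shape(self):
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        return self.data[BAND_NAMES.index(name)]

    @classmethod
    def from_stack(cls, stack: np.ndarray) -> "SpectralImage":
        """Build from a (5, H, W) array in canonical band order."""
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3 or stack.shape[0] != 5:
            raise ValueError("expected a (5, H, W) stack")
        return cls(dict(zip(BAND_NAMES, stack)))

    def to_tiff(self, path) -> None:
        """Write as a 5-page float TIFF in canonical band order."""
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))

    @classmethod
    def from_tiff(cls, path) -> "SpectralImage":
        import tifffile

        return cls.from_stack(tifffile.imread(path))


def write_mask_tiff(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(bool)


@dataclass(frozen=True)
class FeatureVector:
    """The seven plot-level indices; flagged entries are NaN."""

    CCCI: float
    MTVI2: float
    BNDVI: float
    GLI: float
    CI: float
    H: float
    V: float
    flags: frozenset = field(default_factory=frozenset)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES], dtype=float)

    def __getitem__(self, key: str) -> float:
        if key not in FEATURE_NAMES:
            raise KeyError(key)
        return getattr(self, key)


def ndvi(red, nir):
    """Normalised difference vegetation index with a guarded denominator."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    den = nir + red
    safe = np.abs(den) >= DENOM_EPS
    out = np.where(safe, (nir - red) / np.where(safe, den, 1.0), 0.0)
    return out


def vegetation_index_maps(blue, green, red, rededge, nir):
    """Per-pixel Table-of-seven indices on reflectance arrays.

    Returns ``(values, flags)`` where both are dicts keyed by feature name;
    ``values`` holds float arrays (NaN where flagged) and ``flags`` boolean
    arrays marking degenerate denominators.  Inputs must be non-negative.
    """
    blue, green, red, re, nir = (
        np.asarray(a, dtype=float) for a in (blue, green, red, rededge, nir)
    )
    for name, arr in zip(BAND_NAMES, (blue, green, red, re, nir)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite reflectance in {name!r}")
        if np.any(arr < 0):
            raise ValueError(f"negative reflectance in {name!r}")

    values: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}

    def guarded(num, den):
        bad = np.abs(den) < DENOM_EPS
        val = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
        return val, bad

    ndvi_den = nir + red
    ndvi_bad = np.abs(ndvi_den) < DENOM_EPS
    ndvi_val = np.where(ndvi_bad, np.nan, (nir - red) / np.where(ndvi_bad, 1.0, ndvi_den))

    # CCCI: rededge normalised difference scaled by 1/NDVI
    re_den = nir + re
    ccci_bad = ndvi_bad | (np.abs(re_den) < DENOM_EPS) | (np.abs(ndvi_val) < DENOM_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccci = np.where(
            ccci_bad,
            np.nan,
            ((nir - re) / np.where(np.abs(re_den) < DENOM_EPS, 1.0, re_den))
            / np.where(ccci_bad, 1.0, ndvi_val),
        )
    values["CCCI"], flags["CCCI"] = ccci, ccci_bad

    # MTVI2 with the canonical denominator
    mtvi2_num = 1.5 * (1.2 * (nir - green) - 2.5 * (red - green))
    arg = (2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(red)) - 0.5
    mtvi2_bad = arg <= 0
    den = np.sqrt(np.where(mtvi2_bad, 1.0, arg))
    mtvi2_bad = mtvi2_bad | (np.abs(den) < DENOM_EPS)
    values["MTVI2"] = np.where(mtvi2_bad, np.nan, mtvi2_num / den)
    flags["MTVI2"] = mtvi2_bad

    values["BNDVI"], flags["BNDVI"] = guarded(nir - blue, nir + blue)
    values["GLI"], flags["GLI"] = guarded(
        2.0 * green - red - blue, 2.0 * green + red + blue
    )
    values["CI"], flags["CI"] = guarded(red - blue, red)

    # Hue: two-argument arctangent so the quadrant is defined; flagged at 0/0
    hy = 2.0 * red - green - blue
    hx = SQRT3 * (green - blue)
    h_bad = (np.abs(hy) < DENOM_EPS) & (np.abs(hx) < DENOM_EPS)
    values["H"] = np.where(h_bad, 0.0, np.arctan2(hy, hx))
    flags["H"] = h_bad

    values["V"] = np.clip(np.maximum(np.maximum(red, green), blue), 0.0, 1.0)
    flags["V"] = np.zeros_like(values["V"], dtype=bool)

    return values, flags


def compute_vegetation_indices(blue, green, red, rededge, nir) -> FeatureVector:
    """The seven indices for a single five-band reflectance spectrum."""
    values, flags = vegetation_index_maps(
        np.atleast_1d(blue),
        np.atleast_1d(green),
        np.atleast_1d(red),
        np.atleast_1d(rededge),
        np.atleast_1d(nir),
    )
    flagged = frozenset(k for k in FEATURE_NAMES if bool(flags[k][0]))
    return FeatureVector(
        **{k: float(values[k][0]) for k in FEATURE_NAMES}, flags=flagged
    )


def segment_canopy(image: SpectralImage, method: str = "chan_vese", **params) -> np.ndarray:
    """Segment canopy (foreground) from soil background.

    ``chan_vese`` runs a two-phase piecewise-constant active contour on the
    NDVI channel (the natural vegetation-contrast scalar field), initialised
    from an NDVI > 0.3 mask; ``threshold`` simply marks NDVI above a cutoff.
    A near-constant NDVI channel yields an empty mask with a warning.
    """
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("empty image")
    channel = ndvi(image.band("red"), image.band("nir"))
    if float(np.var(channel)) < 1e-12:
        warnings.warn("near-constant NDVI channel; returning empty mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)

    if method == "threshold":
        cutoff = params.get("cutoff", 0.3)
        return channel > cutoff
    if method != "chan_vese":
        raise ValueError(f"unknown segmentation method {method!r}")

    from skimage.segmentation import chan_vese

    init = np.where(channel > params.get("init_cutoff", 0.3), 1.0, -1.0)
    seg = chan_vese(
        channel,
        mu=params.get("mu", 0.1),
        lambda1=params.get("lambda1", 1.0),
        lambda2=params.get("lambda2", 1.0),
        tol=params.get("tol", 1e-3),
        max_num_iter=params.get("max_num_iter", 200),
        init_level_set=init,
    )
    seg = np.asarray(seg, dtype=bool)
    # the contour's inside/outside assignment is arbitrary: foreground is the
    # phase with the higher mean NDVI
    if seg.any() and (~seg).any():
        if channel[seg].mean() < channel[~seg].mean():
            seg = ~seg
    elif not seg.any():
        return seg
    return seg


def remove_small_regions(mask: np.ndarray, min_area: int = 25) -> np.ndarray:
    """Drop 8-connected foreground components with area below ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    from skimage.measure import label

    mask = np.asarray(mask, dtype=bool)
    labels = label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False  # background
    return keep[labels]


def extract_plot_features(
    image: SpectralImage, mask: np.ndarray, statistic: str = "mean"
) -> FeatureVector:
    """Aggregate per-pixel indices over the canopy mask into one vector.

    Flagged pixels are excluded from the corresponding index's aggregate; an
    index with no valid pixel (or an empty mask) is returned as NaN with a
    flag, never as a silent zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if not mask.any():
        nanvec = {k: float("nan") for k in FEATURE_NAMES}
        return FeatureVector(**nanvec, flags=frozenset(FEATURE_NAMES))

    bands = [image.band(b)[mask] for b in BAND_NAMES]
    values, flags = vegetation_index_maps(*bands)
    agg = np.mean if statistic == "mean" else np.median
    out: dict[str, float] = {}
    flagged = set()
    for name in FEATURE_NAMES:
        valid = ~flags[name]
        if not valid.any():
            out[name] = float("nan")
            flagged.add(name)
        else:
            out[name] = float(agg(values[name][valid]))
    return FeatureVector(**out, flags=frozenset(flagged))
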