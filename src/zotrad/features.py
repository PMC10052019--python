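"""Radiomic feature extraction for tumor and ZOT regions.

A region (3D scalar volume restricted to a binary mask) is summarized by
shape descriptors plus first-order intensity statistics computed on the
original image and on a bank of filtered images (stationary wavelet
subbands and Laplacian-of-Gaussian responses).  Feature names follow the
reporting convention used throughout the package: wavelet features are
prefixed ``W-<subband><level>-``, Laplacian features ``L-<sigma>-``, and
features extracted from the ZOT region carry a final ``(ZOT)`` keyword;
tumor-region features are unmarked.

The extraction engine is pluggable: ``engine="native"`` (default) is the
self-contained backend implemented here; ``engine="external"`` is an
adapter slot for a full radiomics engine and raises an informative error
when no such engine is importable.  The shipped default configuration
yields exactly 1218 named features per region, hence 2436 per patient
(tumor + ZOT).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import re
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .morphology import VoxelMask, extract_zot, make_structuring_element

__all__ = [
    "FeatureName",
    "ExtractionConfig",
    "FeatureTable",
    "DEFAULT_CONFIG",
    "SCREENING_CONFIG",
    "extract_region_features",
    "build_patient_vector",
    "native_backend_features",
    "clean_table",
    "cohort_feature_table",
]

logger = logging.getLogger(__name__)

REGION_TUMOR = "TUMOR"
REGION_ZOT = "ZOT"


# ---------------------------------------------------------------------------
# Feature naming

_NAME_RE = re.compile(
    r"^(?:(?P<filt>W-[LH]{3}\d+|L-[0-9.]+)-)?(?P<base>[A-Za-z][A-Za-z0-9_]*?)"
    r"(?P<zot> \(ZOT\))?$"
)


@dataclass(frozen=True)
class FeatureName:
    """Structured radiomic feature name.

    ``filter_tag`` is ``None`` for features of the unfiltered image,
    ``"W-<subband><level>"`` for wavelet subbands and ``"L-<sigma>"`` for
    Laplacian-of-Gaussian responses.  ``region_tag`` is ``TUMOR`` or
    ``ZOT`` (``None`` while a single-region vector is being built).
    """

    base_name: str
    filter_tag: str | None = None
    region_tag: str | None = None

    def render(self) -> str:
        s = f"{self.filter_tag}-{self.base_name}" if self.filter_tag else self.base_name
        if self.region_tag == REGION_ZOT:
            s += " (ZOT)"
        return s

    @classmethod
    def parse(cls, rendered: str) -> "FeatureName":
        m = _NAME_RE.match(rendered)
        if m is None:
            raise ValueError(f"unparseable feature name: {rendered!r}")
        region = REGION_ZOT if m.group("zot") else REGION_TUMOR
        return cls(base_name=m.group("base"), filter_tag=m.group("filt"), region_tag=region)

    def with_region(self, region: str) -> "FeatureName":
        return FeatureName(self.base_name, self.filter_tag, region)


# ---------------------------------------------------------------------------
# First-order and shape catalogues

#: the minimal documented native set (first-order core + shape)
FIRST_ORDER_CORE = (
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_Variance",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Energy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_Maximum",
    "firstorder_Percentile10",
    "firstorder_Percentile90",
    "firstorder_RobustRange",
)

FIRST_ORDER_EXTENDED = (
    "firstorder_StdDev",
    "firstorder_Range",
    "firstorder_RootMeanSquared",
    "firstorder_TotalEnergy",
    "firstorder_Uniformity",
    "firstorder_Percentile5",
    "firstorder_Percentile25",
    "firstorder_Percentile75",
    "firstorder_Percentile95",
    "firstorder_InterquartileRange",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_MedianAbsoluteDeviation",
    "firstorder_CoefficientOfVariation",
    "firstorder_TrimmedMean10",
)

SHAPE_FEATURES = (
    "shape_VoxelCount",
    "shape_VolumeMm3",
    "shape_SurfaceVoxelCount",
)


def _first_order(values: np.ndarray, bin_width: float, voxel_volume: float) -> dict[str, float]:
    """All 27 first-order statistics of a masked intensity sample."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    mean = float(v.mean())
    var = float(v.var())  # population variance
    sd = float(np.sqrt(var))
    p = np.percentile(v, [5, 10, 25, 50, 75, 90, 95])
    p5, p10, p25, med, p75, p90, p95 = (float(x) for x in p)
    energy = float((v**2).sum())
    if sd > 0:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew = m3 / sd**3
        kurt = m4 / var**2 - 3.0  # excess kurtosis
        cov = sd / mean if abs(mean) > 1e-12 * sd else 0.0
    else:
        skew = kurt = cov = 0.0

    # histogram probabilities at fixed bin width
    lo = np.floor(v.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((v.max() - lo) / bin_width)) or 1)
    hist, _ = np.histogram(v, bins=nbins, range=(lo, lo + nbins * bin_width))
    prob = hist[hist > 0] / n
    entropy = float(-(prob * np.log2(prob)).sum())
    uniformity = float((prob**2).sum())

    robust = v[(v >= p10) & (v <= p90)]
    inner = v[(v >= p25) & (v <= p75)]
    trim = np.sort(v)[int(np.floor(0.1 * n)) : n - int(np.floor(0.1 * n)) or None]
    return {
        "firstorder_Mean": mean,
        "firstorder_Median": med,
        "firstorder_Variance": var,
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Energy": energy,
        "firstorder_Entropy": entropy,
        "firstorder_Minimum": float(v.min()),
        "firstorder_Maximum": float(v.max()),
        "firstorder_Percentile10": p10,
        "firstorder_Percentile90": p90,
        "firstorder_RobustRange": p90 - p10,
        "firstorder_StdDev": sd,
        "firstorder_Range": float(v.max() - v.min()),
        "firstorder_RootMeanSquared": float(np.sqrt(energy / n)),
        "firstorder_TotalEnergy": energy * voxel_volume,
        "firstorder_Uniformity": uniformity,
        "firstorder_Percentile5": p5,
        "firstorder_Percentile25": p25,
        "firstorder_Percentile75": p75,
        "firstorder_Percentile95": p95,
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "firstorder_RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean()
        ),
        "firstorder_MedianAbsoluteDeviation": float(np.median(np.abs(v - med))),
        "firstorder_CoefficientOfVariation": cov,
        "firstorder_TrimmedMean10": float(trim.mean()),
    }


def _shape_features(mask: VoxelMask) -> dict[str, float]:
    count = mask.voxel_count
    cross = make_structuring_element("cross", 3)
    interior = ndimage.binary_erosion(mask.grid, structure=cross, border_value=0)
    surface = int((mask.grid & ~interior).sum())
    return {
        "shape_VoxelCount": float(count),
        "shape_VolumeMm3": count * mask.voxel_volume_mm3,
        "shape_SurfaceVoxelCount": float(surface),
    }


def native_backend_features(values: Sequence[float], mask: VoxelMask) -> dict[FeatureName, float]:
    """The fixed minimal native feature set for one region.

    Twelve first-order statistics of the masked intensities (entropy at
    the default bin width) plus three shape descriptors of the mask.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 1:
        raise ValueError("empty region")
    fo = _first_order(v, DEFAULT_CONFIG.bin_width, mask.voxel_volume_mm3)
    out = {FeatureName(k): fo[k] for k in FIRST_ORDER_CORE}
    out.update({FeatureName(k): val for k, val in _shape_features(mask).items()})
    return out


# ---------------------------------------------------------------------------
# Filter bank

def _wavelet_subbands(
    volume: np.ndarray, wavelet: str, levels: int
) -> list[tuple[str, np.ndarray]]:
    """Undecimated (a trous) 3D wavelet subbands, same grid as the input.

    At level ``j`` the decomposition filters are upsampled by ``2**(j-1)``
    and applied to the approximation (LLL) image of the previous level;
    each level yields the 8 lo/hi combinations along the three axes.
    """
    w = pywt.Wavelet(wavelet)
    dec_lo = np.asarray(w.dec_lo)
    dec_hi = np.asarray(w.dec_hi)
    out: list[tuple[str, np.ndarray]] = []
    approx = volume
    for level in range(1, levels + 1):
        step = 2 ** (level - 1)
        if step > 1:
            lo = np.zeros(len(dec_lo) * step - (step - 1))
            hi = np.zeros_like(lo)
            lo[::step] = dec_lo
            hi[::step] = dec_hi
        else:
            lo, hi = dec_lo, dec_hi
        bands = {"": approx}
        for axis in range(3):
            new = {}
            for tag, img in bands.items():
                new[tag + "L"] = ndimage.convolve1d(img, lo, axis=axis, mode="reflect")
                new[tag + "H"] = ndimage.convolve1d(img, hi, axis=axis, mode="reflect")
            bands = new
        for tag in sorted(bands):
            out.append((f"W-{tag}{level}", bands[tag]))
        approx = bands["LLL"]
    return out


def _sigma_tag(sigma: float) -> str:
    return f"L-{sigma:g}"


def _filter_bank(
    volume: np.ndarray, spacing: tuple[float, float, float], config: "ExtractionConfig"
) -> list[tuple[str | None, np.ndarray]]:
    bank: list[tuple[str | None, np.ndarray]] = [(None, volume)]
    bank += _wavelet_subbands(volume, config.wavelet, config.wavelet_levels)
    for sigma in config.log_sigmas:
        sig_vox = [sigma / s for s in spacing]
        bank.append(
            (_sigma_tag(sigma), ndimage.gaussian_laplace(volume, sigma=sig_vox, mode="reflect"))
        )
    return bank


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class ExtractionConfig:
    """Feature-extraction settings.

    ``wavelet_levels`` stationary-wavelet levels (8 subbands each) and
    ``log_sigmas`` Laplacian-of-Gaussian scales (mm) define the filter
    bank; 27 first-order statistics are computed per image plus 3 shape
    descriptors per region, so a configuration with ``m`` filtered
    images yields ``3 + 27 * (1 + m)`` features per region.  The default
    (3 wavelet levels, 20 sigmas) gives 1218.
    """

    wavelet: str = "coif1"
    wavelet_levels: int = 3
    log_sigmas: tuple[float, ...] = tuple(np.round(np.arange(0.5, 10.01, 0.5), 2))
    bin_width: float = 25.0
    crop_pad: int = 2
    engine: str = "native"

    @property
    def n_images(self) -> int:
        return 1 + 8 * self.wavelet_levels + len(self.log_sigmas)

    @property
    def n_features_per_region(self) -> int:
        return len(SHAPE_FEATURES) + 27 * self.n_images

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, s: str) -> "ExtractionConfig":
        d = json.loads(s)
        d["log_sigmas"] = tuple(d["log_sigmas"])
        return cls(**d)


#: shipped default: 3 + 27 * (1 + 24 + 20) = 1218 features per region
DEFAULT_CONFIG = ExtractionConfig()

#: lean bank for screening experiments on phantom cohorts:
#: 3 + 27 * (1 + 3) = 111 features per region
SCREENING_CONFIG = ExtractionConfig(wavelet_levels=0, log_sigmas=(1.0, 2.0, 3.0))


# ---------------------------------------------------------------------------
# Region extraction

def _crop_to_mask(volume: np.ndarray, grid: np.ndarray, pad: int):
    idx = []
    for axis in range(3):
        proj = grid.any(axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        idx.append(slice(max(0, nz[0] - pad), min(grid.shape[axis], nz[-1] + 1 + pad)))
    sl = tuple(idx)
    return volume[sl], grid[sl]


def extract_region_features(
    volume: np.ndarray, mask: VoxelMask, config: ExtractionConfig = DEFAULT_CONFIG
) -> dict[FeatureName, float]:
    """Named radiomic feature vector for one region (region tag unset).

    The volume is cropped to the mask bounding box plus ``config.crop_pad``
    voxels before filtering, so features depend only on intensities inside
    that padded box.  Deterministic given (volume, mask, config).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if mask.is_empty():
        raise ValueError("empty region mask")
    if config.engine == "external":
        raise ImportError(
            "no external radiomics engine is importable in this environment; "
            "use ExtractionConfig(engine='native')"
        )
    if config.engine != "native":
        raise ValueError(f"unknown engine {config.engine!r}")

    vol_c, grid_c = _crop_to_mask(volume, mask.grid, config.crop_pad)
    voxvol = mask.voxel_volume_mm3
    out: dict[FeatureName, float] = {
        FeatureName(k): val for k, val in _shape_features(mask).items()
    }
    for tag, img in _filter_bank(vol_c, mask.spacing_mm, config):
        fo = _first_order(img[grid_c], config.bin_width, voxvol)
        for base, val in fo.items():
            out[FeatureName(base, filter_tag=tag)] = float(val)
    if len(out) != config.n_features_per_region:
        raise AssertionError("feature count contract violated")
    return out


def build_patient_vector(
    volume: np.ndarray,
    tumor_mask: VoxelMask,
    zot_mask: VoxelMask,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Concatenated tumor + ZOT feature vector, keyed by rendered name.

    Tumor block first, then ZOT block, each ordered lexicographically by
    rendered name.
    """
    tumor_mask.check_geometry(zot_mask, "tumor/ZOT masks")
    vec: dict[str, float] = {}
    for region, m in ((REGION_TUMOR, tumor_mask), (REGION_ZOT, zot_mask)):
        feats = extract_region_features(volume, m, config)
        block = {fn.with_region(region).render(): v for fn, v in feats.items()}
        for name in sorted(block):
            vec[name] = block[name]
    return vec


def default_feature_names(config: ExtractionConfig = DEFAULT_CONFIG) -> list[str]:
    """Rendered names of the full per-patient catalogue, in table order."""
    fo = list(FIRST_ORDER_CORE) + list(FIRST_ORDER_EXTENDED)
    names: list[FeatureName] = [FeatureName(b) for b in SHAPE_FEATURES]
    names += [FeatureName(b) for b in fo]
    for level in range(1, config.wavelet_levels + 1):
        for tag in sorted("".join(c) for c in itertools.product("HL", repeat=3)):
            names += [FeatureName(b, filter_tag=f"W-{tag}{level}") for b in fo]
    for sigma in config.log_sigmas:
        names += [FeatureName(b, filter_tag=_sigma_tag(sigma)) for b in fo]
    out = []
    for region in (REGION_TUMOR, REGION_ZOT):
        out += sorted(n.with_region(region).render() for n in names)
    return out


# ---------------------------------------------------------------------------
# Feature tables

class FeatureTable:
    """Patients x named radiomic features, with binary labels.

    Labels: 0 = RO (benign oncocytoma), 1 = ccRCC (clear-cell carcinoma).
    ``provenance`` records how the table was produced (extraction config
    hash, generator spec, row lineage after subsetting).
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series, provenance: dict | None = None):
        if len(X) != len(y):
            raise ValueError("X and y row counts differ")
        if X.columns.duplicated().any():
            raise ValueError("duplicate feature column names")
        if y.isna().any():
            raise ValueError("label missing for some rows")
        self.X = X
        self.y = y.astype(int)
        self.provenance = dict(provenance or {})

    # -- basic shape -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def row_ids(self) -> list:
        return list(self.X.index)

    def values(self) -> np.ndarray:
        return np.ascontiguousarray(self.X.to_numpy(dtype=np.float64))

    def labels(self) -> np.ndarray:
        return self.y.to_numpy(dtype=np.int64)

    # -- lineage -----------------------------------------------------
    def subset_rows(self, indexer: Sequence) -> "FeatureTable":
        prov = dict(self.provenance)
        prov["parent_rows"] = self.row_ids
        sub = FeatureTable(self.X.iloc[list(indexer)], self.y.iloc[list(indexer)], prov)
        return sub

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X.to_numpy(np.float64)).tobytes())
        h.update(self.labels().tobytes())
        h.update("\x00".join(self.feature_names).encode())
        return h.hexdigest()[:16]

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.y.values)
        df.insert(0, "patient_id", self.X.index)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path)
        pid = df.pop("patient_id")
        y = df.pop("label")
        df.index = pid
        y.index = pid
        return cls(df, y)


def clean_table(table: FeatureTable) -> FeatureTable:
    """Drop feature columns containing non-finite values.

    Constant columns are retained: the selection wrapper may still pick
    them and the fitness of a subset is unaffected by their presence.
    """
    finite = np.isfinite(table.X.to_numpy(dtype=np.float64)).all(axis=0)
    dropped = [c for c, ok in zip(table.X.columns, finite) if not ok]
    for c in dropped:
        logger.warning("dropping non-finite feature column %s", c)
    X = table.X.loc[:, finite]
    if X.shape[1] == 0:
        raise ValueError("cleaning removed every feature column")
    prov = dict(table.provenance)
    prov["dropped_columns"] = dropped
    return FeatureTable(X, table.y, prov)


def cohort_feature_table(
    cohort: Iterable[tuple[np.ndarray, VoxelMask, int]],
    config: ExtractionConfig = DEFAULT_CONFIG,
    element: np.ndarray | None = None,
    iterations: int = 2,
) -> FeatureTable:
    """Extract tumor + ZOT features for every cohort item into one table."""
    rows, labels, ids = [], [], []
    for i, (volume, mask, label) in enumerate(cohort):
        zot = extract_zot(mask, element=element, iterations=iterations).zot
        rows.append(build_patient_vector(volume, mask, zot, config))
        labels.append(int(label))
        ids.append(f"P{i:03d}")
    X = pd.DataFrame(rows, index=ids)
    y = pd.Series(labels, index=ids)
    return FeatureTable(X, y, provenance={"extraction_config": config.config_hash()})
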