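"""Synthetic phantoms and feature tables for pipeline validation.

Real arterial-phase CT of the renal cohort is not redistributable, so
every downstream stage is exercised on synthetic data with the same
statistical structure:

* **Phantoms** — spherical lesions on a uniform parenchyma background.
  A ccRCC-like phantom carries a hypodense rim ("pseudocapsule") just
  outside the tumor mask; an RO-like phantom meets the parenchyma
  directly.  The rim lies strictly outside the tumor mask, so only the
  zone of transition can see it.
* **Feature tables** — iid standard-normal feature matrices with the
  cohort's shape (defaults n=77, class fractions 0.39/0.61 -> 30 RO and
  47 ccRCC) under a null regime (``k_informative=0``) or with
  ``k_informative`` columns shifted by ``effect_size`` in the ccRCC
  class.

Default phantom intensities are plausibility choices for arterial-phase
renal CT (HU): enhancing parenchyma 180, moderately enhancing tumor 110,
hypodense pseudocapsule 50, voxel noise sd 20.  Cohort generation adds
per-patient variation: tumor radius jitter and independent per-tissue
enhancement offsets (sd 40 HU), emulating contrast-timing variability.
None of these values are estimates of any clinical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .features import FeatureTable, default_feature_names, DEFAULT_CONFIG
from .morphology import VoxelMask

__all__ = [
    "RO_LIKE",
    "CCRCC_LIKE",
    "PhantomSpec",
    "TableSpec",
    "PhantomSizingError",
    "ro_like_spec",
    "ccrcc_like_spec",
    "generate_phantom",
    "generate_cohort",
    "generate_feature_table",
]

RO_LIKE = "RO-like"
CCRCC_LIKE = "ccRCC-like"

#: margin (voxels) that must separate the lesion (incl. rim) from the
#: grid border, so that two dilations never touch the boundary
BORDER_MARGIN_VOX = 4


class PhantomSizingError(ValueError):
    """Lesion does not fit in the grid with the required border margin."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity of one synthetic lesion."""

    class_label: str
    tumor_radius_mm: float
    rim_thickness_mm: float
    tumor_intensity: float
    rim_intensity: float
    background_intensity: float
    noise_sd: float
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.class_label not in (RO_LIKE, CCRCC_LIKE):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if (self.rim_thickness_mm == 0) != (self.class_label == RO_LIKE):
            raise ValueError("rim_thickness_mm must be 0 iff the phantom is RO-like")
        if self.tumor_radius_mm <= 0 or self.rim_thickness_mm < 0 or self.noise_sd < 0:
            raise ValueError("invalid sizes")
        self.check_fits()

    def check_fits(self) -> None:
        r_total = self.tumor_radius_mm + self.rim_thickness_mm
        for n, s in zip(self.grid_shape, self.spacing_mm):
            half_extent = (n - 1) / 2  # voxels from center to border
            if np.ceil(r_total / s) + BORDER_MARGIN_VOX > half_extent:
                raise PhantomSizingError(
                    f"lesion radius {r_total} mm does not fit a {self.grid_shape} grid "
                    f"with a {BORDER_MARGIN_VOX}-voxel margin"
                )

    @property
    def label(self) -> int:
        return 0 if self.class_label == RO_LIKE else 1


def ro_like_spec(**overrides) -> PhantomSpec:
    """Default RO-like phantom: direct tumor/parenchyma interface."""
    base = dict(
        class_label=RO_LIKE,
        tumor_radius_mm=12.0,
        rim_thickness_mm=0.0,
        tumor_intensity=110.0,
        rim_intensity=110.0,
        background_intensity=180.0,
        noise_sd=20.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def ccrcc_like_spec(**overrides) -> PhantomSpec:
    """Default ccRCC-like phantom: hypodense pseudocapsule rim."""
    base = dict(
        class_label=CCRCC_LIKE,
        tumor_radius_mm=12.0,
        rim_thickness_mm=2.0,
        tumor_intensity=110.0,
        rim_intensity=50.0,
        background_intensity=180.0,
        noise_sd=20.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, VoxelMask, int]:
    """Render one phantom: scalar volume, tumor mask and class label.

    The tumor mask is the set of voxels within ``tumor_radius_mm``
    (physical distance) of the grid center.  The volume is the
    background intensity everywhere, the tumor intensity inside the
    mask, the rim intensity in the shell of ``rim_thickness_mm`` just
    outside the mask, plus iid Gaussian voxel noise.  Deterministic
    given (spec, seed).

    The rim shell is realized in the same face-connected voxel metric
    used by the ZOT morphology (``round(rim_thickness_mm / spacing)``
    dilation passes with the 7-voxel cross), so a rim of up to
    ``2 * spacing`` is contained in the default two-pass ZOT shell by
    construction.
    """
    from scipy import ndimage

    from .morphology import make_structuring_element
    spec.check_fits()
    center = [(n - 1) / 2 * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    axes = [
        (np.arange(n) * s - c) ** 2
        for n, s, c in zip(spec.grid_shape, spec.spacing_mm, center)
    ]
    dist = np.sqrt(
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    tumor = dist <= spec.tumor_radius_mm
    volume = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    volume[tumor] = spec.tumor_intensity
    if spec.rim_thickness_mm > 0:
        k = max(1, int(round(spec.rim_thickness_mm / min(spec.spacing_mm))))
        cross = make_structuring_element("cross", 3)
        rim = ndimage.binary_dilation(tumor, structure=cross, iterations=k) & ~tumor
        volume[rim] = spec.rim_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    mask = VoxelMask(tumor, spacing_mm=spec.spacing_mm)
    return volume, mask, spec.label


def generate_cohort(
    n_per_class: tuple[int, int],
    phantom_specs: tuple[PhantomSpec, PhantomSpec] | None = None,
    seed: int = 0,
    radius_jitter_mm: float = 3.0,
    intensity_jitter_sd: float = 40.0,
) -> list[tuple[np.ndarray, VoxelMask, int]]:
    """Reproducible labelled phantom cohort.

    ``n_per_class`` is ``(n_RO, n_ccRCC)``.  Per-patient variation is
    added on top of the class specs: tumor radius jittered uniformly in
    ``+-radius_jitter_mm`` and each tissue intensity (tumor, rim,
    background) offset independently by ``N(0, intensity_jitter_sd)`` —
    the contrast-timing variability that keeps single features from
    being trivially perfect class separators.  Per-item seeds derive
    from the master seed, so each phantom is reproducible in isolation.
    """
    if phantom_specs is None:
        phantom_specs = (ro_like_spec(), ccrcc_like_spec())
    items: list[tuple[np.ndarray, VoxelMask, int]] = []
    index = 0
    for spec, n in zip(phantom_specs, n_per_class):
        for _ in range(n):
            rng = np.random.default_rng(derive_seed(seed, "patient", index))
            jittered = replace(
                spec,
                tumor_radius_mm=spec.tumor_radius_mm
                + rng.uniform(-radius_jitter_mm, radius_jitter_mm),
                tumor_intensity=spec.tumor_intensity
                + rng.normal(0.0, intensity_jitter_sd),
                rim_intensity=spec.rim_intensity + rng.normal(0.0, intensity_jitter_sd),
                background_intensity=spec.background_intensity
                + rng.normal(0.0, intensity_jitter_sd),
            )
            items.append(generate_phantom(jittered, derive_seed(seed, "noise", index)))
            index += 1
    return items


# ---------------------------------------------------------------------------
# Feature tables

@dataclass(frozen=True)
class TableSpec:
    """Shape and signal structure of a synthetic radiomic feature table.

    ``k_informative = 0`` is the null regime: labels independent of all
    features.  Otherwise ``k_informative`` randomly chosen columns are
    shifted by ``effect_size`` (standardized units) in class 1.
    Defaults mirror the cohort shape: 77 patients, 39%/61% classes.
    """

    n_samples: int = 77
    n_features: int = 2436
    class_fractions: tuple[float, float] = (0.39, 0.61)
    k_informative: int = 0
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("table too small")
        if self.k_informative > self.n_features:
            raise ValueError("k_informative exceeds n_features")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def _class_counts(n: int, fractions: tuple[float, float]) -> tuple[int, int]:
    n0 = int(np.floor(n * fractions[0] + 0.5))
    return n0, n - n0


def generate_feature_table(spec: TableSpec) -> FeatureTable:
    """Synthetic feature table following the package naming convention.

    Column names are drawn from the default extraction catalogue
    (alternating tumor / ZOT blocks so both region tags are present at
    any width); indices of the informative columns are recorded in the
    table provenance.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "table"))
    n0, n1 = _class_counts(spec.n_samples, spec.class_fractions)
    labels = np.array([0] * n0 + [1] * n1)
    rng.shuffle(labels)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.k_informative, replace=False)
    )
    if spec.k_informative:
        X[np.ix_(labels == 1, informative)] += spec.effect_size

    catalogue = default_feature_names(DEFAULT_CONFIG)
    half = len(catalogue) // 2
    interleaved = [
        name
        for pair in zip(catalogue[:half], catalogue[half:])
        for name in pair
    ]
    names = []
    for j in range(spec.n_features):
        base = interleaved[j % len(interleaved)]
        names.append(base if j < len(interleaved) else f"{base}#{j // len(interleaved)}")
    ids = [f"S{i:03d}" for i in range(spec.n_samples)]
    table = FeatureTable(
        pd.DataFrame(X, columns=names, index=ids),
        pd.Series(labels, index=ids),
        provenance={
            "generator": "synthetic-table",
            "spec": {
                "n_samples": spec.n_samples,
                "n_features": spec.n_features,
                "class_fractions": list(spec.class_fractions),
                "k_informative": spec.k_informative,
                "effect_size": spec.effect_size,
                "seed": spec.seed,
            },
            "informative_columns": [names[j] for j in informative],
        },
    )
    return table
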