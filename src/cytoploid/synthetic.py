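"""Synthetic nucleus-area populations and rendered DAPI fields.

*Caulerpa* thalli are coenocytic: thousands of nuclei share one cytoplasm,
and their DAPI-stained areas (a proxy for DNA content) fall on a doubling
series of size classes.  No raw measurements were deposited with the study
this package models, so this module regenerates populations with the same
statistical structure: truncated-normal mixtures whose class means, spreads
and per-class counts follow the published per-portion summary table, plus a
renderer that paints the corresponding fluorescence scene (homogeneous
nuclei, rim-stained chloroplasts, small bright bacteria) with exact ground
truth for benchmarking the quantification stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ResolutionError, UnknownPresetError, ValidationError

__all__ = [
    "SyntheticSpec",
    "FieldSpec",
    "PRESETS",
    "sample_nuclei",
    "preset_cytotype",
    "preset_names",
    "render_field",
]

#: Default coefficient of variation used for classes whose published SD is
#: missing (single-nucleus classes).
DEFAULT_CV = 0.10

RECORD_COLUMNS = [
    "area_um2",
    "species",
    "portion",
    "individual",
    "location",
    "reproductive",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Mixture specification for one nucleus-area population.

    Parameters
    ----------
    class_centers
        Mean area of each size class, µm², strictly increasing.
    class_weights
        Mixture proportions, summing to 1.
    cv
        Coefficient of variation per class (scalar broadcasts to all
        classes).  The per-class distribution is a normal truncated at
        zero with scale ``cv * center``.
    n
        Total number of nuclei to draw.
    seed
        Seed for the generator; identical specs give identical samples.
    labels
        Metadata stamped onto every record (species, portion, individual,
        location, reproductive flag).
    class_counts
        Optional exact per-class counts (summing to ``n``).  When given,
        class membership is deterministic instead of multinomial; the
        published table presets use this so that rare classes (down to a
        single nucleus) are always represented.
    class_multipliers
        Optional generating truth: the Cx multiplier of each class.
    """

    class_centers: tuple[float, ...]
    class_weights: tuple[float, ...]
    cv: tuple[float, ...]
    n: int
    seed: int = 0
    labels: Mapping[str, object] = field(default_factory=dict)
    class_counts: tuple[int, ...] | None = None
    class_multipliers: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        centers = tuple(float(c) for c in self.class_centers)
        weights = tuple(float(w) for w in self.class_weights)
        cv = self.cv
        if np.isscalar(cv):
            cv = (float(cv),) * len(centers)
        else:
            cv = tuple(float(c) for c in cv)
        object.__setattr__(self, "class_centers", centers)
        object.__setattr__(self, "class_weights", weights)
        object.__setattr__(self, "cv", cv)
        if len(centers) == 0:
            raise ValidationError("at least one size class is required")
        if len(weights) != len(centers) or len(cv) != len(centers):
            raise ValidationError("class_centers, class_weights and cv must align")
        if any(c <= 0 for c in centers):
            raise ValidationError("class centers must be strictly positive")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValidationError("class centers must be strictly increasing")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("class weights must sum to 1 within 1e-9")
        if any(w < 0 for w in weights):
            raise ValidationError("class weights must be non-negative")
        if any(not (0 < c < 1) for c in cv):
            raise ValidationError("cv must lie in (0, 1)")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.class_counts is not None:
            counts = tuple(int(k) for k in self.class_counts)
            object.__setattr__(self, "class_counts", counts)
            if len(counts) != len(centers):
                raise ValidationError("class_counts must align with class_centers")
            if sum(counts) != self.n:
                raise ValidationError("class_counts must sum to n")


@dataclass(frozen=True)
class FieldSpec:
    """Geometry, intensity and noise parameters for a rendered field.

    Intensities are in arbitrary 16-bit camera units.  Chloroplasts are
    drawn larger than nuclei with a bright 2–3 px rim and a dim interior;
    bacteria are small bright dots below the nuclear diameter range.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_scale: float = 0.1  # µm per pixel
    n_chloroplasts: int = 2
    n_bacteria: int = 8
    background: float = 80.0
    nucleus_amplitude: float = 1200.0
    chloroplast_rim_amplitude: float = 1100.0
    chloroplast_core_amplitude: float = 150.0
    bacterium_amplitude: float = 2500.0
    chloroplast_diameter_um: tuple[float, float] = (5.0, 7.0)
    bacterium_diameter_um: tuple[float, float] = (0.25, 0.5)
    amplitude_jitter: float = 0.15
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be > 0")
        if min(self.shape) < 32:
            raise ValidationError("field must be at least 32x32 pixels")
        if self.n_chloroplasts < 0 or self.n_bacteria < 0:
            raise ValidationError("object counts must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Published per-portion summaries used as generator presets.
#
# Each row: species, portion, reproductive flag, per-class nucleus counts,
# per-class mean areas (µm²), per-class SDs (None -> DEFAULT_CV), and the
# generating Cx multipliers.  The 2Cx unit is anchored in gametes, whose G1
# nuclei average 0.49 µm².

_PRESET_TABLE: dict[str, dict] = {
    "prolifera_gametes": dict(
        species="C. prolifera", portion="gamete", reproductive=True,
        location="Majorca/Catalonia",
        counts=(18, 8), means=(0.49, 0.88), sds=(0.08, 0.08),
        multipliers=(2, 4),
    ),
    "prolifera_reproductive_frond": dict(
        species="C. prolifera", portion="frond", reproductive=True,
        location="Majorca/Catalonia",
        counts=(517, 293, 51, 9), means=(0.51, 0.97, 1.96, 3.72),
        sds=(0.10, 0.21, 0.37, 0.75), multipliers=(2, 4, 8, 16),
    ),
    "prolifera_sterile_frond": dict(
        species="C. prolifera", portion="frond", reproductive=False,
        location="Alicante/Catalonia/Majorca/Murcia",
        counts=(389, 38, 22, 3), means=(1.07, 2.29, 3.67, 7.54),
        sds=(0.37, 0.23, 0.30, 1.29), multipliers=(4, 8, 16, 32),
    ),
    "prolifera_sterile_stolon": dict(
        species="C. prolifera", portion="stolon", reproductive=False,
        location="Alicante/Catalonia/Majorca/Murcia",
        counts=(238, 7), means=(0.86, 1.71), sds=(0.23, 0.17),
        multipliers=(4, 8),
    ),
    "prolifera_sterile_rhizoid": dict(
        species="C. prolifera", portion="rhizoid", reproductive=False,
        location="Alicante/Catalonia/Majorca/Murcia",
        counts=(164, 32), means=(1.00, 1.75), sds=(0.28, 0.31),
        multipliers=(4, 8),
    ),
    "racemosa_frond": dict(
        species="C. racemosa var. cylindracea", portion="frond",
        reproductive=False, location="Santa Pola",
        counts=(390, 43, 1), means=(0.70, 1.33, 2.94),
        sds=(0.18, 0.14, None), multipliers=(3, 6, 12),
    ),
    "racemosa_stolon": dict(
        species="C. racemosa var. cylindracea", portion="stolon",
        reproductive=False, location="Santa Pola",
        counts=(380, 29), means=(0.76, 1.47), sds=(0.18, 0.25),
        multipliers=(3, 6),
    ),
    "racemosa_rhizoid": dict(
        species="C. racemosa var. cylindracea", portion="rhizoid",
        reproductive=False, location="Santa Pola",
        counts=(192, 13), means=(0.57, 1.34), sds=(0.16, 0.29),
        multipliers=(3, 6),
    ),
    "taxifolia_frond": dict(
        species="C. taxifolia", portion="frond", reproductive=False,
        location="Villefranche-sur-Mer",
        counts=(123, 29), means=(0.55, 1.12), sds=(0.11, 0.14),
        multipliers=(2, 4),
    ),
    "taxifolia_stolon": dict(
        species="C. taxifolia", portion="stolon", reproductive=False,
        location="Villefranche-sur-Mer",
        counts=(157, 10), means=(0.54, 1.14), sds=(0.15, 0.12),
        multipliers=(2, 4),
    ),
}

_PRESET_ALIASES = {
    "prolifera_frond": "prolifera_sterile_frond",
    "prolifera_stolon": "prolifera_sterile_stolon",
    "prolifera_rhizoid": "prolifera_sterile_rhizoid",
}

PRESETS = tuple(_PRESET_TABLE)


def preset_names() -> tuple[str, ...]:
    """Names of the documented presets (one per published table row)."""
    return PRESETS


def preset_cytotype(name: str, seed: int = 0) -> SyntheticSpec:
    """Return the :class:`SyntheticSpec` for a documented species/portion.

    Class centers are the published per-class mean areas, dispersions are
    the published SDs converted to CVs (``sd/mean``), and the per-class
    counts are the published exact counts, so rare classes are always
    represented at the printed frequency.
    """
    key = _PRESET_ALIASES.get(name, name)
    if key not in _PRESET_TABLE:
        raise UnknownPresetError(
            f"unknown preset {name!r}; choose from {sorted(_PRESET_TABLE)}"
        )
    row = _PRESET_TABLE[key]
    counts = row["counts"]
    n = int(sum(counts))
    means = row["means"]
    cv = tuple(
        (sd / m) if sd is not None else DEFAULT_CV
        for sd, m in zip(row["sds"], means)
    )
    return SyntheticSpec(
        class_centers=means,
        class_weights=tuple(k / n for k in counts),
        cv=cv,
        n=n,
        seed=seed,
        labels=dict(
            species=row["species"],
            portion=row["portion"],
            reproductive=row["reproductive"],
            location=row["location"],
            individual=key,
            preset=key,
        ),
        class_counts=counts,
        class_multipliers=row["multipliers"],
    )


def _draw_class_areas(
    rng: np.random.Generator, n: int, center: float, cv: float
) -> np.ndarray:
    sd = cv * center
    if sd < 1e-12 * center:
        return np.full(n, center)
    a = (0.0 - center) / sd  # truncate at zero
    return sps.truncnorm.rvs(a, np.inf, loc=center, scale=sd, size=n,
                             random_state=rng)


def sample_nuclei(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw a nucleus-area population from a mixture specification.

    Returns a :class:`pandas.DataFrame` with one row per nucleus and the
    columns ``area_um2, species, portion, individual, location,
    reproductive`` plus ``true_class`` (index of the generating class) and,
    when the spec declares them, ``true_cx`` (generating Cx multiplier).
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.class_centers)
    if spec.class_counts is not None:
        counts = np.asarray(spec.class_counts)
    else:
        counts = rng.multinomial(spec.n, spec.class_weights)
    areas = []
    classes = []
    for i in range(k):
        if counts[i] == 0:
            continue
        areas.append(_draw_class_areas(rng, int(counts[i]),
                                       spec.class_centers[i], spec.cv[i]))
        classes.append(np.full(int(counts[i]), i, dtype=int))
    area = np.concatenate(areas)
    cls = np.concatenate(classes)
    order = rng.permutation(area.size)
    area, cls = area[order], cls[order]

    labels = dict(spec.labels)
    df = pd.DataFrame(
        {
            "area_um2": area,
            "species": labels.get("species", "synthetic"),
            "portion": labels.get("portion", "frond"),
            "individual": labels.get("individual", "synthetic-0"),
            "location": labels.get("location", "in silico"),
            "reproductive": bool(labels.get("reproductive", False)),
            "true_class": cls,
        }
    )
    if spec.class_multipliers is not None:
        mult = np.asarray(spec.class_multipliers)
        df["true_cx"] = mult[cls]
    return df


# ---------------------------------------------------------------------------
# Field rendering


def _paint_disk(img: np.ndarray, cy: float, cx: float, r: float,
                amplitude: float) -> None:
    """Add an anti-aliased disk; per-pixel coverage ~ clip(r - d + 1/2)."""
    h, w = img.shape
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    cov = np.clip(r - d + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] += amplitude * cov


def _paint_annulus(img: np.ndarray, cy: float, cx: float, r: float,
                   width: float, amplitude: float) -> None:
    h, w = img.shape
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    outer = np.clip(r - d + 0.5, 0.0, 1.0)
    inner = np.clip((r - width) - d + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] += amplitude * np.clip(outer - inner, 0.0, 1.0)


def _place_objects(rng: np.random.Generator, radii: Sequence[float],
                   shape: tuple[int, int], margin: float = 4.0,
                   max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample non-overlapping centers, away from the border."""
    h, w = shape
    placed: list[tuple[float, float, float]] = []
    centers = np.empty((len(radii), 2))
    for i, r in enumerate(radii):
        lo = r + margin
        if h - 2 * lo <= 1 or w - 2 * lo <= 1:
            raise ValidationError("field too small for requested objects")
        for _ in range(max_tries):
            cy = rng.uniform(lo, h - lo)
            cx = rng.uniform(lo, w - lo)
            if all(np.hypot(cy - py, cx - px) > r + pr + 3.0
                   for py, px, pr in placed):
                placed.append((cy, cx, r))
                centers[i] = (cy, cx)
                break
        else:
            raise ValidationError(
                "could not place objects without overlap; enlarge the field"
            )
    return centers


def render_field(records: pd.DataFrame, fspec: FieldSpec
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic DAPI field for a set of nucleus records.

    Nuclei are compact homogeneously filled disks whose analytic areas equal
    the requested ``area_um2``; chloroplasts are larger, DAPI-bright around
    the periphery and dim inside; bacteria are much smaller bright dots.
    Additive Gaussian camera noise is applied last.

    Returns
    -------
    image : uint16 ndarray
    truth : DataFrame with one row per rendered object
        (category, y/x centroid in pixels, true area µm², radius px).
    """
    scale = fspec.pixel_scale
    areas = np.asarray(records["area_um2"], dtype=float)
    radii_um = np.sqrt(areas / math.pi)
    radii_px = radii_um / scale
    if np.any(areas < scale * scale):
        raise ResolutionError(
            "some nucleus areas fall below one pixel at this pixel scale"
        )

    rng = np.random.default_rng(fspec.seed)
    chl_d = rng.uniform(*fspec.chloroplast_diameter_um, fspec.n_chloroplasts)
    bac_d = rng.uniform(*fspec.bacterium_diameter_um, fspec.n_bacteria)
    chl_r = chl_d / 2.0 / scale
    bac_r = bac_d / 2.0 / scale

    all_r = np.concatenate([chl_r, radii_px, bac_r])  # big ones first
    centers = _place_objects(rng, all_r, fspec.shape)
    nc, nn = len(chl_r), len(radii_px)

    img = np.full(fspec.shape, fspec.background, dtype=float)
    jitter = fspec.amplitude_jitter
    rows = []
    for i in range(nc):
        cy, cx = centers[i]
        amp = fspec.chloroplast_rim_amplitude * rng.uniform(1 - jitter, 1 + jitter)
        core = fspec.chloroplast_core_amplitude * rng.uniform(1 - jitter, 1 + jitter)
        r = all_r[i]
        _paint_disk(img, cy, cx, r - 2.5, core)
        _paint_annulus(img, cy, cx, r, 2.5, amp)
        rows.append(("chloroplast", cy, cx, math.pi * (r * scale) ** 2, r))
    for i in range(nn):
        cy, cx = centers[nc + i]
        amp = fspec.nucleus_amplitude * rng.uniform(1 - jitter, 1 + jitter)
        r = all_r[nc + i]
        _paint_disk(img, cy, cx, r, amp)
        rows.append(("nucleus", cy, cx, areas[i], r))
    for i in range(len(bac_r)):
        cy, cx = centers[nc + nn + i]
        amp = fspec.bacterium_amplitude * rng.uniform(1 - jitter, 1 + jitter)
        r = all_r[nc + nn + i]
        _paint_disk(img, cy, cx, r, amp)
        rows.append(("bacterium", cy, cx, math.pi * (r * scale) ** 2, r))

    if fspec.noise_sd > 0:
        img += rng.normal(0.0, fspec.noise_sd, size=img.shape)
    image = np.clip(img, 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(rows, columns=["category", "y", "x", "area_um2",
                                        "radius_px"])
    return image, truth
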