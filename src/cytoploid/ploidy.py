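"""Gamete-anchored doubling-series inference of ploidy and endopolyploidy.

The DNA content of a nucleus is proxied by its DAPI-stained area.  Within
one sample the areas form a mixture whose modes sit on a doubling series:
the dominant histogram peak is the G1 (unreplicated) population of the
lowest ploidy level present, the next mode at twice its area is G2
(replicated), and further doublings indicate endopolyploidy.  Absolute
ploidy labels come from an external unit: the area equivalent of 1 Cx,
anchored in gametes (whose G1 nuclei are taken as 2Cx, so
``unit = gamete G1 peak / 2``).

The procedure is deliberately boundary-based, mirroring manual histogram
curation: peaks are read off a lightly smoothed histogram, class boundaries
sit at geometric means of adjacent class centers (the log-space midpoint),
records falling in a declared overlap band around a boundary are split
half-and-half between the two classes, and a class is accepted as occupied
only if its membership cannot be explained as tail spill-over from the
class below (or it shows its own histogram mode).  No mixture-model
likelihood is fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import AmbiguityError, UnresolvedCytotypeError, ValidationError

__all__ = [
    "DEFAULT_MULTIPLIERS",
    "Histogram",
    "PloidySeriesModel",
    "SizeClass",
    "CytotypeProfile",
    "PloidyAnalyzer",
    "build_histogram",
    "find_g1_peak",
    "estimate_unit",
    "class_boundaries",
    "assign_classes",
    "split_overlap",
    "infer_cytotype",
]

#: Cx multipliers observed across all cytotypes (eight levels).
DEFAULT_MULTIPLIERS = (2, 3, 4, 6, 8, 12, 16, 32)


# ---------------------------------------------------------------------------
# Histograms and peaks


@dataclass(frozen=True)
class Histogram:
    """Counts over contiguous half-open bins ``[edge[i], edge[i+1])``."""

    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def build_histogram(areas, bin_width: float = 0.1) -> Histogram:
    """Histogram nuclear areas with fixed-width, half-open bins.

    Bin edges start at ``floor(min/width) * width`` and extend one bin past
    the maximum so every observation falls in a half-open bin; counts sum
    to ``len(areas)``.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValidationError("cannot histogram an empty area list")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    lo = math.floor(areas.min() / bin_width) * bin_width
    while lo > areas.min():  # guard against float rounding in the division
        lo -= bin_width
    n_bins = max(int(math.ceil((areas.max() - lo) / bin_width)) + 1, 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(areas, bins=edges)
    return Histogram(counts=counts, edges=edges)


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def _histogram_modes(hist: Histogram, smooth_window: int = 3,
                     min_height: float = 0.5) -> np.ndarray:
    """Centers of local maxima of the smoothed histogram.

    ``min_height`` (in smoothed counts) rejects single-nucleus noise bins:
    a lone straggler contributes 1/window to the smoothed curve, a genuine
    two-nucleus mode at least 2/window.
    """
    sm = _smooth(hist.counts, smooth_window)
    padded = np.concatenate([[0.0], sm, [0.0]])
    peaks, _ = signal.find_peaks(padded, height=min_height)
    return hist.centers[peaks - 1]


def find_g1_peak(hist: Histogram, smooth_window: int = 3) -> float:
    """Center of the dominant (G1) mode of a nuclear-area histogram.

    The histogram is lightly smoothed with a moving average before peak
    picking; when several bins tie for the maximum the smaller area wins
    (G1 precedes G2 in the cell cycle, and most nuclei sit in G1).  The
    sub-bin position is refined by parabolic interpolation through the
    peak bin and its neighbours.

    Raises
    ------
    AmbiguityError
        If the histogram is flat (no mode structure at all).
    """
    sm = _smooth(hist.counts, smooth_window)
    occupied = np.flatnonzero(hist.counts)
    core = sm[occupied[0]:occupied[-1] + 1] if occupied.size else sm
    if core.size > 1 and np.allclose(core, core[0]):
        raise AmbiguityError("flat histogram: no identifiable G1 mode")
    top = sm.max()
    tied = np.flatnonzero(np.isclose(sm, top))
    # tied maxima in separate modes -> warn, resolve to the smaller area
    if tied.size > 1 and np.any(np.diff(tied) > 1):
        warnings.warn(
            "multiple equal histogram modes; taking the smaller-area mode",
            stacklevel=2,
        )
    i = int(tied[0])
    center = hist.centers[i]
    if 0 < i < sm.size - 1:
        denom = sm[i - 1] - 2 * sm[i] + sm[i + 1]
        if denom < 0:
            shift = 0.5 * (sm[i - 1] - sm[i + 1]) / denom
            center += np.clip(shift, -0.5, 0.5) * hist.bin_width
    return float(center)


def _refine_peak(areas: np.ndarray, peak: float, halfwidth_frac: float = 0.3,
                 iters: int = 8) -> float:
    """Refine a peak position by an iterated symmetric local mean.

    The window half-width is fixed at ``halfwidth_frac * peak`` while its
    center tracks the running local mean; for a roughly symmetric mode the
    fixed point is the mode's mean, insensitive to where the initial
    histogram-bin estimate landed.
    """
    areas = np.asarray(areas, dtype=float)
    h = halfwidth_frac * peak
    p = float(peak)
    for _ in range(iters):
        sel = areas[(areas >= p - h) & (areas <= p + h)]
        if sel.size == 0:
            return p
        p = float(sel.mean())
    return p


def estimate_unit(gamete_areas, bin_width: float = 0.1,
                  smooth_window: int = 3) -> float:
    """Area of 1 Cx from gamete nuclei.

    Gametes are taken as unreduced, so their G1 peak corresponds to 2Cx and
    ``unit = G1 peak / 2``.  The peak position is refined by an iterated
    symmetric local mean around the histogram mode.
    """
    areas = np.asarray(gamete_areas, dtype=float)
    if areas.size == 0:
        raise ValidationError(
            "no gamete records: supply the 1 Cx unit explicitly"
        )
    hist = build_histogram(areas, bin_width)
    peak = find_g1_peak(hist, smooth_window)
    return _refine_peak(areas, peak) / 2.0


# ---------------------------------------------------------------------------
# Series model, boundaries, assignment


def class_boundaries(centers) -> np.ndarray:
    """Boundaries for an increasing list of class centers.

    Interior boundaries sit at geometric means of adjacent centers (the
    log-space midpoint, consistent with the multiplicative class
    structure); the outermost bounds extrapolate the geometric ratio to
    the missing neighbour.  A single center yields ``(0, inf)``.
    """
    c = np.asarray(centers, dtype=float)
    if c.size == 0:
        raise ValidationError("at least one class center is required")
    if np.any(c <= 0) or np.any(np.diff(c) <= 0):
        raise ValidationError("centers must be positive and strictly increasing")
    if c.size == 1:
        return np.array([0.0, np.inf])
    inner = np.sqrt(c[:-1] * c[1:])
    lo = c[0] * math.sqrt(c[0] / c[1])
    hi = c[-1] * math.sqrt(c[-1] / c[-2])
    return np.concatenate([[lo], inner, [hi]])


@dataclass(frozen=True)
class PloidySeriesModel:
    """Doubling-series size-class model.

    ``centers = unit * multipliers`` unless explicit (data-anchored)
    centers are supplied; boundaries default to geometric means of
    adjacent centers.
    """

    unit: float
    multipliers: tuple[int, ...] = DEFAULT_MULTIPLIERS
    centers: np.ndarray = None  # type: ignore[assignment]
    boundaries: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unit <= 0:
            raise ValidationError("unit must be > 0")
        mult = tuple(int(m) for m in self.multipliers)
        if any(b <= a for a, b in zip(mult, mult[1:])) or len(mult) == 0:
            raise ValidationError("multipliers must be strictly increasing")
        object.__setattr__(self, "multipliers", mult)
        centers = (np.asarray(self.centers, dtype=float)
                   if self.centers is not None
                   else self.unit * np.asarray(mult, dtype=float))
        if centers.size != len(mult):
            raise ValidationError("centers must align with multipliers")
        object.__setattr__(self, "centers", centers)
        bounds = (np.asarray(self.boundaries, dtype=float)
                  if self.boundaries is not None
                  else class_boundaries(centers))
        if bounds.size != centers.size + 1:
            raise ValidationError("need one more boundary than centers")
        inner = bounds[1:-1]
        if np.any(inner <= centers[:-1]) or np.any(inner >= centers[1:]):
            raise ValidationError("boundaries must lie between adjacent centers")
        if bounds[0] < 0:
            raise ValidationError("lowest boundary must be >= 0")
        object.__setattr__(self, "boundaries", bounds)

    def assign(self, areas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Class index per area (half-open intervals) + out-of-range flag."""
        areas = np.asarray(areas, dtype=float)
        idx = np.digitize(areas, self.boundaries[1:-1], right=False)
        out = (areas < self.boundaries[0]) | (areas >= self.boundaries[-1])
        return idx, out


@dataclass(frozen=True)
class SizeClass:
    """One occupied size class with its membership summary."""

    cx: int
    center: float
    lower: float
    upper: float
    count: int
    mean: float
    sd: float
    refined_center: float


@dataclass(frozen=True)
class CytotypeProfile:
    """Ploidy interpretation of one sample.

    ``base_multiplier`` 2 means a diploid in haplophasic phase, 3 triploid
    haplophasic, 4 tetraploid diplophasic, and so on.  ``endopolyploid`` is
    set when more than two size classes occur in somatic tissue.
    """

    sample_id: str
    base_multiplier: int
    multipliers: tuple[int, ...]
    unit: float
    endopolyploid: bool
    dominant_phase: str
    classes: tuple[SizeClass, ...] = ()
    phases: tuple[tuple[int, str], ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.multipliers)


@dataclass
class ClassifiedPopulation:
    """Records with size-class labels plus per-class summaries."""

    records: pd.DataFrame
    model: PloidySeriesModel
    classes: tuple[SizeClass, ...]

    @property
    def counts(self) -> dict[int, int]:
        return {c.cx: c.count for c in self.classes}


def _mode_in_interval(modes: np.ndarray, hist: Histogram,
                      smooth_window: int, lower: float, upper: float
                      ) -> float | None:
    """The tallest histogram mode inside a class interval, if any."""
    sel = modes[(modes >= lower) & (modes < upper)]
    if sel.size == 0:
        return None
    sm = _smooth(hist.counts, smooth_window)
    heights = [sm[np.argmin(np.abs(hist.centers - m))] for m in sel]
    return float(sel[int(np.argmax(heights))])


def _local_center(pool: np.ndarray, seed: float, window: float) -> float:
    """One-shot local mean in a symmetric window around ``seed``."""
    h = window * seed
    sel = pool[(pool >= seed - h) & (pool <= seed + h)]
    return float(sel.mean()) if sel.size else float(seed)


def _robust_scale(members: np.ndarray, center: float) -> float:
    """Robust upper-tail spread of a class.

    Uses the upper-sided quantile spread (q90 - median, normalized for a
    normal), so the spill-over contamination from the class below -- which
    sits entirely on the low side of the interval -- does not inflate the
    tail estimate."""
    if members.size >= 8:
        q50, q90 = np.percentile(members, [50, 90])
        return max((q90 - q50) / 1.2816, 0.05 * center)
    return 0.2 * center


def _class_stats(areas: np.ndarray, labels: np.ndarray, model: PloidySeriesModel,
                 all_areas: np.ndarray | None = None, window: float = 0.2,
                 hist: Histogram | None = None, modes: np.ndarray | None = None,
                 smooth_window: int = 3) -> tuple[SizeClass, ...]:
    out = []
    pool = all_areas if all_areas is not None else areas
    for k, m in enumerate(model.multipliers):
        members = areas[labels == k]
        if members.size == 0:
            continue
        c = model.centers[k]
        if members.size < 5:
            # too few nuclei for a mode: the member mean is the least
            # biased location (windows anchored on the doubling grid pull
            # toward the model center)
            refined = float(members.mean())
        else:
            seed = None
            if modes is not None and hist is not None:
                seed = _mode_in_interval(modes, hist, smooth_window,
                                         model.boundaries[k],
                                         model.boundaries[k + 1])
            refined = _local_center(
                pool, seed if seed is not None else float(c), window)
        out.append(SizeClass(
            cx=int(m), center=float(c),
            lower=float(model.boundaries[k]),
            upper=float(model.boundaries[k + 1]),
            count=int(members.size), mean=float(members.mean()),
            sd=float(members.std(ddof=1)) if members.size > 1 else 0.0,
            refined_center=refined,
        ))
    return tuple(out)


def assign_classes(records, model: PloidySeriesModel) -> ClassifiedPopulation:
    """Assign every record to exactly one size class by boundary membership.

    Records outside the outermost boundaries are assigned to the nearest
    class (log-space distance, which for geometric-mean boundaries is the
    class they digitize into anyway) and flagged ``out_of_series``.
    """
    df = _as_records(records)
    if len(df) == 0:
        raise ValidationError("no records to classify")
    areas = df["area_um2"].to_numpy(dtype=float)
    idx, out = model.assign(areas)
    df = df.copy()
    df["class_index"] = idx
    df["cx"] = np.asarray(model.multipliers)[idx]
    df["flag"] = np.where(out, "out_of_series", "ok")
    classes = _class_stats(areas, idx, model)
    return ClassifiedPopulation(records=df, model=model, classes=classes)


def split_overlap(classified: ClassifiedPopulation, lower_cx: int,
                  upper_cx: int, overlap_frac: float = 0.1
                  ) -> ClassifiedPopulation:
    """Half-split the declared overlap band between two adjacent classes.

    Records with areas inside ``[b/(1+f), b*(1+f)]`` around the shared
    boundary ``b`` are pooled, sorted by area, and the lower ``floor(n/2)``
    go to the lower class, the rest to the upper class.  Conserves n.
    """
    model = classified.model
    mult = list(model.multipliers)
    if lower_cx not in mult or upper_cx not in mult:
        raise ValidationError("both classes must exist in the model")
    i, j = mult.index(lower_cx), mult.index(upper_cx)
    if j != i + 1:
        raise ValidationError("overlap splitting requires adjacent classes")
    b = model.boundaries[j]
    df = classified.records.copy()
    areas = df["area_um2"].to_numpy(dtype=float)
    in_band = (areas >= b / (1 + overlap_frac)) & (areas <= b * (1 + overlap_frac))
    band_idx = np.flatnonzero(in_band)
    if band_idx.size == 0:
        return classified
    order = band_idx[np.argsort(areas[band_idx], kind="stable")]
    n_lower = order.size // 2
    new_index = df["class_index"].to_numpy().copy()
    new_index[order[:n_lower]] = i
    new_index[order[n_lower:]] = j
    flags = df["flag"].to_numpy(dtype=object)
    flags[order] = np.where(
        new_index[order] == i, "overlap_split_lower", "overlap_split_upper"
    )
    df["class_index"] = new_index
    df["cx"] = np.asarray(model.multipliers)[new_index]
    df["flag"] = flags
    classes = _class_stats(areas, new_index, model)
    return ClassifiedPopulation(records=df, model=model, classes=classes)


def _as_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        if "area_um2" not in records.columns:
            raise ValidationError("records need an 'area_um2' column")
        df = records.reset_index(drop=True)
    else:
        df = pd.DataFrame({"area_um2": np.asarray(records, dtype=float)})
    areas = df["area_um2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
        raise ValidationError("areas must be finite and > 0")
    return df


def _snap_multiplier(ratio: float, allowed, max_log2_offset: float) -> int:
    """Nearest allowed multiplier in log space, within a tolerance band."""
    allowed = np.asarray(sorted(allowed), dtype=float)
    offsets = np.abs(np.log2(ratio / allowed))
    k = int(np.argmin(offsets))
    if offsets[k] > max_log2_offset:
        raise UnresolvedCytotypeError(
            f"G1/unit ratio {ratio:.3f} is not within 2**±{max_log2_offset:.2f} "
            f"of any allowed multiplier {tuple(int(m) for m in allowed)}"
        )
    return int(allowed[k])


def infer_cytotype(classified: ClassifiedPopulation, unit: float,
                   sample_id: str = "sample",
                   allowed=DEFAULT_MULTIPLIERS,
                   max_log2_offset: float = 0.30,
                   somatic: bool = True,
                   base: int | None = None) -> CytotypeProfile:
    """Interpret a classified population as a cytotype.

    The base multiplier is the allowed multiplier nearest (in log space) to
    ``lowest occupied class mean / unit`` — or a known base supplied by the
    caller, e.g. resolved at species level where a portion's G1 sits between
    two multipliers; classes are read as G1/G2 pairs along the doubling
    chain; the endopolyploid flag is set when more than two classes occur
    in somatic tissue.
    """
    occ = [c for c in classified.classes if c.count > 0]
    if not occ:
        raise ValidationError("no occupied classes")
    if base is None:
        base = _snap_multiplier(occ[0].mean / unit, allowed, max_log2_offset)
    mult = tuple(c.cx for c in occ)
    phases = _phase_attribution(mult)
    return CytotypeProfile(
        sample_id=sample_id,
        base_multiplier=base,
        multipliers=mult,
        unit=unit,
        endopolyploid=bool(somatic and len(mult) > 2),
        dominant_phase="G1",
        classes=tuple(occ),
        phases=phases,
    )


def _phase_attribution(multipliers: tuple[int, ...]) -> tuple[tuple[int, str], ...]:
    """(Cx, phase) roles along the doubling chain.

    The lowest class is G1 of the base level; each class at twice a present
    class is its G2 and, when the chain continues past it (endocycle), also
    the G1 of the doubled level.  Every G2 role therefore has a G1 role at
    half its Cx value.
    """
    present = set(multipliers)
    roles: list[tuple[int, str]] = []
    for m in multipliers:
        if m // 2 * 2 == m and m // 2 in present:
            roles.append((m, "G2"))
            if 2 * m in present:
                roles.append((m, "G1"))
        else:
            roles.append((m, "G1"))
    return tuple(roles)


# ---------------------------------------------------------------------------
# The estimator


class PloidyAnalyzer(BaseEstimator):
    """Infer the ploidy series of one nucleus-area population.

    A scikit-learn style estimator: ``fit`` reads the histogram, anchors
    the base ploidy level on the external 1 Cx ``unit``, builds a
    data-anchored doubling series from the sample's own G1 peak, assigns
    every nucleus to a size class, prunes classes explainable as tail
    spill-over, optionally applies the overlap half-split, and summarizes
    the cytotype.  ``predict`` labels new areas with Cx multipliers using
    the fitted boundaries.

    Parameters
    ----------
    unit : float
        Area per 1 Cx (µm²), typically ``estimate_unit(gamete_areas)``.
    multipliers : tuple of int
        Allowed Cx levels; the fitted series is the doubling chain from the
        base restricted to this set.
    bin_width, smooth_window
        Histogram geometry for peak reading.
    overlap_frac : float
        Half-width (multiplicative) of the overlap band around each shared
        boundary; the band is half-split between the two classes.
    apply_overlap_split : bool
        Whether to apply the overlap half-split after assignment.
    max_log2_offset : float
        Acceptance band (in log2 units) when snapping G1/unit to an
        allowed multiplier; beyond it the cytotype is unresolved.
    center_window : float
        Multiplicative half-width of the window used to refine class-center
        estimates and to test for a class's own histogram mode.
    spill_sigma : float
        A class is occupied only if its count exceeds the expected
        spill-over from the class below by this many Poisson sigmas, or it
        shows a histogram mode near its center.
    assume_somatic : bool
        Treat records without portion metadata as somatic tissue when
        setting the endopolyploidy flag.
    base_multiplier : int, optional
        Fix the base Cx level instead of snapping ``G1/unit``.  Used when
        the cytotype is resolved at species level: a rhizoid or stolon G1
        can sit between two multipliers on its own, but every portion of a
        species shares the species cytotype.

    Attributes
    ----------
    g1_ : float
        Refined G1 peak area (µm²).
    base_multiplier_ : int
        Cx level of the G1 population.
    classes_ : ndarray of int
        Occupied Cx multipliers.
    model_ : PloidySeriesModel
        Data-anchored series used for assignment.
    size_classes_ : tuple of SizeClass
    profile_ : CytotypeProfile
    classified_ : DataFrame
        Input records plus ``cx``, ``phase`` and ``flag`` columns.
    """

    def __init__(self, unit: float | None = None,
                 multipliers=DEFAULT_MULTIPLIERS, bin_width: float = 0.1,
                 smooth_window: int = 3, overlap_frac: float = 0.1,
                 apply_overlap_split: bool = True,
                 max_log2_offset: float = 0.30, center_window: float = 0.2,
                 spill_sigma: float = 3.0, assume_somatic: bool = True,
                 base_multiplier: int | None = None,
                 sample_id: str = "sample"):
        self.unit = unit
        self.base_multiplier = base_multiplier
        self.multipliers = multipliers
        self.bin_width = bin_width
        self.smooth_window = smooth_window
        self.overlap_frac = overlap_frac
        self.apply_overlap_split = apply_overlap_split
        self.max_log2_offset = max_log2_offset
        self.center_window = center_window
        self.spill_sigma = spill_sigma
        self.assume_somatic = assume_somatic
        self.sample_id = sample_id

    # -- internals ---------------------------------------------------------

    def _series_from_base(self, base: int) -> list[int]:
        allowed = sorted(int(m) for m in self.multipliers)
        series, m = [], base
        while m <= allowed[-1]:
            if m in allowed:
                series.append(m)
            m *= 2
        return series

    def _expected_spill(self, areas: np.ndarray, labels: np.ndarray,
                        src: int, donor_center: float, bound: float) -> float:
        """Expected count of donor-class nuclei beyond ``bound``.

        The donor's location is its refined (mode-seeded) center and its
        scale a robust IQR-based spread of its members, so neither the
        spill-over contamination at the interval edges nor interval
        truncation distorts the tail estimate badly.
        """
        members = areas[labels == src]
        if members.size == 0:
            return 0.0
        sd = _robust_scale(members, donor_center)
        return members.size * float(sps.norm.sf((bound - donor_center) / sd))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "PloidyAnalyzer":
        if self.unit is None or self.unit <= 0:
            raise ValidationError(
                "a positive 1 Cx unit is required (use estimate_unit on "
                "gamete areas or pass unit= explicitly)"
            )
        df = _as_records(X)
        areas = df["area_um2"].to_numpy(dtype=float)

        hist = build_histogram(areas, self.bin_width)
        try:
            peak = find_g1_peak(hist, self.smooth_window)
        except AmbiguityError:
            if areas.size == 1 or np.ptp(areas) < self.bin_width:
                peak = float(np.median(areas))  # degenerate single-bin sample
            else:
                raise
        g1 = _refine_peak(areas, peak)
        if self.base_multiplier is not None:
            base = int(self.base_multiplier)
            if base not in set(int(m) for m in self.multipliers):
                raise ValidationError("base_multiplier must be an allowed level")
        else:
            base = _snap_multiplier(g1 / self.unit, self.multipliers,
                                    self.max_log2_offset)
        series = self._series_from_base(base)
        centers = g1 * np.asarray(series, dtype=float) / base
        model = PloidySeriesModel(unit=self.unit, multipliers=tuple(series),
                                  centers=centers)
        labels, out = model.assign(areas)

        # prune classes explainable as spill from below
        modes = _histogram_modes(hist, self.smooth_window)
        w = 1 + self.center_window
        keep = [0]
        flags = np.where(out, "out_of_series", "ok").astype(object)
        for k in range(1, len(series)):
            count = int(np.sum(labels == k))
            if count == 0:
                continue
            d = keep[-1]
            d_seed = _mode_in_interval(modes, hist, self.smooth_window,
                                       model.boundaries[d],
                                       model.boundaries[d + 1])
            d_center = _local_center(
                areas, d_seed if d_seed is not None else float(centers[d]),
                self.center_window)
            spill = self._expected_spill(areas, labels, d, d_center,
                                         model.boundaries[k])
            threshold = spill + self.spill_sigma * math.sqrt(spill)
            c = centers[k]
            has_mode = bool(np.any((modes >= c / w) & (modes <= c * w)))
            if count > threshold or has_mode:
                keep.append(k)
            else:
                flags[labels == k] = "pruned_merged"
                labels[labels == k] = keep[-1]

        kept_mult = tuple(series[k] for k in keep)
        kept_centers = centers[keep]
        final = PloidySeriesModel(unit=self.unit, multipliers=kept_mult,
                                  centers=kept_centers)
        # re-index labels into the kept series
        remap = {k: i for i, k in enumerate(keep)}
        labels = np.asarray([remap[k] for k in labels])

        df = df.copy()
        df["class_index"] = labels
        df["cx"] = np.asarray(kept_mult)[labels]
        df["flag"] = flags
        stats_kw = dict(all_areas=areas, window=self.center_window,
                        hist=hist, modes=modes,
                        smooth_window=self.smooth_window)
        pop = ClassifiedPopulation(records=df, model=final,
                                   classes=_class_stats(areas, labels, final,
                                                        **stats_kw))
        if self.apply_overlap_split:
            for lo, hi in zip(kept_mult, kept_mult[1:]):
                pop = split_overlap(pop, lo, hi, self.overlap_frac)
            pop = ClassifiedPopulation(
                records=pop.records, model=final,
                classes=_class_stats(areas,
                                     pop.records["class_index"].to_numpy(),
                                     final, **stats_kw))

        somatic = self.assume_somatic
        if "portion" in df.columns:
            somatic = bool((df["portion"] != "gamete").any())
        profile = infer_cytotype(pop, unit=self.unit, sample_id=self.sample_id,
                                 allowed=self.multipliers,
                                 max_log2_offset=self.max_log2_offset,
                                 somatic=somatic, base=base)

        phase_map = {}
        roles = dict()
        for m, role in profile.phases:
            roles.setdefault(m, []).append(role)
        occupied = profile.multipliers
        for i, m in enumerate(occupied):
            if i == 0:
                phase_map[m] = "G1"
            elif "G2" in roles.get(m, []) and i == 1:
                phase_map[m] = "G2"
            else:
                phase_map[m] = "endo"
        records = pop.records.copy()
        records["phase"] = records["cx"].map(phase_map)
        records["ploidy_class"] = records["cx"].map(lambda m: f"{m}Cx")

        self.g1_ = float(g1)
        self.base_multiplier_ = int(base)
        self.classes_ = np.asarray(occupied, dtype=int)
        self.model_ = final
        self.size_classes_ = pop.classes
        self.profile_ = profile
        self.endopolyploid_ = profile.endopolyploid
        self.classified_ = records
        self.population_ = ClassifiedPopulation(records=records, model=final,
                                                classes=pop.classes)
        return self

    def predict(self, X) -> np.ndarray:
        """Cx multiplier for each area, using the fitted class boundaries."""
        if not hasattr(self, "model_"):
            raise ValidationError("PloidyAnalyzer is not fitted")
        df = _as_records(X)
        idx, _ = self.model_.assign(df["area_um2"].to_numpy(dtype=float))
        return np.asarray(self.model_.multipliers)[idx]

    def fit_predict(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.classified_["cx"].to_numpy()
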