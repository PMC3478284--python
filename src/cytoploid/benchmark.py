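"""Reproducible benchmark harnesses for the inference and imaging stages.

Both the test suite and the reproduction script need the same two
experiments: (1) regenerate every documented per-portion population at its
published size and check that the ploidy inference recovers the generating
cytotype, and (2) render seeded fluorescence fields with confounders and
score nucleus detection against ground truth.  Sampling noise is inherent
at the published sample sizes (several classes hold 1-9 nuclei), so the
recovery experiment runs a small number of replicate seeds and reports the
majority outcome for discrete quantities and the replicate mean for class
centers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ploidy import PloidyAnalyzer, estimate_unit
from .quantify import measure_population
from .synthetic import FieldSpec, preset_cytotype, render_field, sample_nuclei
from .synthetic import _PRESET_TABLE  # generating truth for the presets

__all__ = ["RecoveryResult", "DetectionResult", "preset_recovery",
           "detection_benchmark", "CYTOTYPE_GROUPS"]

#: Which cytotype group (species x life-history phase) each preset belongs
#: to; the base ploidy level is resolved per group, portions share it.
CYTOTYPE_GROUPS = {
    "prolifera_gametes": "gametes C. prolifera",
    "prolifera_reproductive_frond": "reproductive C. prolifera",
    "prolifera_sterile_frond": "sterile C. prolifera",
    "prolifera_sterile_stolon": "sterile C. prolifera",
    "prolifera_sterile_rhizoid": "sterile C. prolifera",
    "racemosa_frond": "sterile C. racemosa var. cylindracea",
    "racemosa_stolon": "sterile C. racemosa var. cylindracea",
    "racemosa_rhizoid": "sterile C. racemosa var. cylindracea",
    "taxifolia_frond": "sterile C. taxifolia",
    "taxifolia_stolon": "sterile C. taxifolia",
}


@dataclass
class RecoveryResult:
    """Per-preset recovery of the generating cytotype."""

    preset: str
    true_base: int
    true_multipliers: tuple[int, ...]
    true_centers: tuple[float, ...]
    modal_base: int = 0
    modal_multipliers: tuple[int, ...] = ()
    mean_centers: dict = field(default_factory=dict)
    n_replicates: int = 0
    n: int = 0

    @property
    def base_recovered(self) -> bool:
        return self.modal_base == self.true_base

    @property
    def classes_recovered(self) -> bool:
        return self.modal_multipliers == self.true_multipliers

    def max_center_error(self) -> float:
        """Worst relative error of the recovered class centers (fraction)."""
        errs = [abs(self.mean_centers[m] - c) / c
                for m, c in zip(self.true_multipliers, self.true_centers)
                if m in self.mean_centers]
        missing = [m for m in self.true_multipliers
                   if m not in self.mean_centers]
        if missing:
            return float("inf")
        return max(errs)


def preset_recovery(master_seed: int = 0, n_replicates: int = 15
                    ) -> tuple[dict[str, RecoveryResult], float]:
    """Regenerate every preset at its published n and re-infer its cytotype.

    Each replicate draws a fresh gamete sample to anchor the 1 Cx unit,
    resolves the base ploidy level per cytotype group from the pooled
    portions, then fits each portion.  Returns per-preset results plus the
    mean estimated unit.
    """
    names = list(_PRESET_TABLE)
    results = {
        name: RecoveryResult(
            preset=name,
            true_base=_PRESET_TABLE[name]["multipliers"][0],
            true_multipliers=tuple(_PRESET_TABLE[name]["multipliers"]),
            true_centers=tuple(_PRESET_TABLE[name]["means"]),
        )
        for name in names
    }
    bases = {name: [] for name in names}
    mult_sets = {name: [] for name in names}
    centers = {name: {} for name in names}
    units = []

    root = np.random.SeedSequence(master_seed)
    for rep_seq in root.spawn(n_replicates):
        seeds = rep_seq.generate_state(len(names) + 1) % (2**31)
        gametes = sample_nuclei(
            preset_cytotype("prolifera_gametes", seed=int(seeds[0])))
        unit = estimate_unit(gametes["area_um2"])
        units.append(unit)
        samples = {
            name: sample_nuclei(preset_cytotype(name, seed=int(seeds[1 + i])))
            for i, name in enumerate(names)
        }
        group_base: dict[str, int] = {}
        for group in sorted(set(CYTOTYPE_GROUPS.values())):
            pooled = pd.concat(
                [df for n, df in samples.items()
                 if CYTOTYPE_GROUPS[n] == group],
                ignore_index=True)
            group_base[group] = PloidyAnalyzer(unit=unit).fit(
                pooled).base_multiplier_
        for name, df in samples.items():
            fit = PloidyAnalyzer(
                unit=unit, base_multiplier=group_base[CYTOTYPE_GROUPS[name]],
                sample_id=name).fit(df)
            bases[name].append(fit.base_multiplier_)
            mult_sets[name].append(tuple(int(m) for m in fit.classes_))
            for c in fit.size_classes_:
                centers[name].setdefault(c.cx, []).append(c.refined_center)
            results[name].n = len(df)

    for name in names:
        r = results[name]
        r.n_replicates = n_replicates
        r.modal_base = Counter(bases[name]).most_common(1)[0][0]
        r.modal_multipliers = Counter(mult_sets[name]).most_common(1)[0][0]
        r.mean_centers = {m: float(np.mean(v))
                         for m, v in centers[name].items()}
    return results, float(np.mean(units))


@dataclass
class DetectionResult:
    """Nucleus detection scored against rendered ground truth."""

    precision: float
    recall: float
    mean_area_error: float  # mean |relative| error over matched nuclei
    n_fields: int
    n_true: int


def detection_benchmark(master_seed: int = 0, n_fields: int = 20,
                        nuclei_per_field: int = 12,
                        pixel_scale: float = 0.1,
                        match_radius_px: float = 5.0) -> DetectionResult:
    """Score detection on seeded fields with chloroplasts and bacteria."""
    root = np.random.SeedSequence([master_seed, 7])
    seeds = root.generate_state(n_fields) % (2**31)
    tp = fp = fn = 0
    errors: list[float] = []
    for s in seeds:
        records = sample_nuclei(
            preset_cytotype("prolifera_reproductive_frond", seed=int(s))
        ).head(nuclei_per_field)
        fspec = FieldSpec(shape=(512, 512), pixel_scale=pixel_scale,
                          n_chloroplasts=2, n_bacteria=6, seed=int(s))
        image, truth = render_field(records, fspec)
        nuclei = truth[truth["category"] == "nucleus"]
        detected = measure_population(image, pixel_scale)
        matched: set = set()
        for _, det in detected.iterrows():
            dist = np.hypot(nuclei["y"] - det["y"], nuclei["x"] - det["x"])
            j = dist.idxmin() if len(dist) else None
            if j is not None and dist[j] < match_radius_px and j not in matched:
                matched.add(j)
                tp += 1
                true_area = nuclei.loc[j, "area_um2"]
                errors.append(abs(det["area_um2"] - true_area) / true_area)
            else:
                fp += 1
        fn += len(nuclei) - len(matched)
    return DetectionResult(
        precision=tp / max(tp + fp, 1),
        recall=tp / max(tp + fn, 1),
        mean_area_error=float(np.mean(errors)) if errors else float("nan"),
        n_fields=n_fields,
        n_true=tp + fn,
    )
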