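"""End-to-end orchestration: simulate/ingest -> classify -> compare -> report.

One :class:`RunConfig` drives the whole analysis; all randomness flows from
a single root seed, every stage logs its record counts, and the
machine-readable report is byte-stable for a given config+seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .io import validate_records, write_records
from .ploidy import DEFAULT_MULTIPLIERS, PloidyAnalyzer, estimate_unit
from .stats import (
    extract_first_level,
    extract_min_genome,
    one_way_anova,
    summarize_groups,
    two_sample_t,
)
from .synthetic import preset_cytotype, preset_names, sample_nuclei

logger = logging.getLogger("cytoploid.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_table1_report"]


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run.

    Exactly one unit source: either ``unit`` is given explicitly or it is
    anchored in the gamete sample (``unit=None`` requires a gamete preset
    or gamete-flagged input records).
    """

    presets: tuple[str, ...] = ()
    input_csvs: tuple[str, ...] = ()
    unit: float | None = None
    bin_width: float = 0.1
    multipliers: tuple[int, ...] = DEFAULT_MULTIPLIERS
    overlap_frac: float = 0.1
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.presets = tuple(self.presets)
        self.input_csvs = tuple(self.input_csvs)
        if not self.presets and not self.input_csvs:
            self.presets = preset_names()

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()
                   if k != "output_dir"}  # where artifacts land is not analytic
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run produced, with provenance."""

    config_hash: str
    seed: int
    version: str
    unit: float
    profiles: dict = field(default_factory=dict)
    class_summary: list = field(default_factory=list)
    anova: dict = field(default_factory=dict)
    ttests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(x):
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in sorted(x.items())}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            if isinstance(x, (np.floating, float)):
                return round(float(x), 6)
            if isinstance(x, np.integer):
                return int(x)
            return x

        return json.dumps(_clean(asdict(self)), sort_keys=True, indent=1)


def _species_group(row) -> str:
    if row["portion"] == "gamete":
        return "gametes C. prolifera"
    if row["species"].startswith("C. prolifera") and row["reproductive"]:
        return "reproductive C. prolifera"
    return f"sterile {row['species']}"


def run_pipeline(config: RunConfig) -> tuple[RunReport, pd.DataFrame]:
    """Execute the full analysis described by ``config``.

    Returns the report plus the concatenated classified record table.
    Idempotent for a given config and seed.
    """
    samples: dict[str, pd.DataFrame] = {}
    rng = np.random.SeedSequence(config.seed)
    child_seeds = rng.generate_state(max(len(config.presets), 1)) % (2**31)
    for name, child in zip(config.presets, child_seeds):
        spec = preset_cytotype(name, seed=int(child))
        df = sample_nuclei(spec)
        samples[name] = df
        logger.info("simulate %s: %d records", name, len(df))
    for path in config.input_csvs:
        from .io import read_records

        df = read_records(path)
        samples[Path(path).stem] = df
        logger.info("ingest %s: %d records", path, len(df))
    if not samples:
        raise ValidationError("nothing to analyze")

    # unit: explicit, else anchored in gametes
    unit = config.unit
    if unit is None:
        gam = pd.concat(
            [df[df["portion"] == "gamete"] for df in samples.values()],
            ignore_index=True,
        )
        if len(gam) == 0:
            raise ValidationError(
                "no gamete records: pass an explicit 1 Cx unit"
            )
        unit = estimate_unit(gam["area_um2"], bin_width=config.bin_width)
        logger.info("unit anchored in %d gametes: %.4f um^2/Cx", len(gam), unit)

    # Resolve the base ploidy level per cytotype group (species x phase):
    # a stolon or rhizoid G1 can sit between two multipliers on its own,
    # but every portion of a species carries the species cytotype.
    group_of = {
        name: _species_group(df.iloc[0]) for name, df in samples.items()
    }
    group_base: dict[str, int] = {}
    for group in sorted(set(group_of.values())):
        pooled = pd.concat(
            [df for name, df in samples.items() if group_of[name] == group],
            ignore_index=True,
        )
        pooled_fit = PloidyAnalyzer(
            unit=unit, multipliers=config.multipliers,
            bin_width=config.bin_width, overlap_frac=config.overlap_frac,
            sample_id=group,
        ).fit(pooled)
        group_base[group] = pooled_fit.base_multiplier_
        logger.info("cytotype group %s: base %dCx (pooled n=%d)",
                    group, pooled_fit.base_multiplier_, len(pooled))

    classified_parts = []
    profiles = {}
    for name, df in samples.items():
        validate_records(df)
        analyzer = PloidyAnalyzer(
            unit=unit, multipliers=config.multipliers,
            bin_width=config.bin_width, overlap_frac=config.overlap_frac,
            base_multiplier=group_base[group_of[name]],
            sample_id=name,
        ).fit(df)
        prof = analyzer.profile_
        profiles[name] = dict(
            group=group_of[name],
            base_multiplier=prof.base_multiplier,
            multipliers=list(prof.multipliers),
            endopolyploid=prof.endopolyploid,
            g1_peak=analyzer.g1_,
            n=len(df),
            class_counts={f"{c.cx}Cx": c.count for c in prof.classes},
            class_means={f"{c.cx}Cx": c.mean for c in prof.classes},
            class_sds={f"{c.cx}Cx": c.sd for c in prof.classes},
        )
        classified_parts.append(analyzer.classified_)
        logger.info("classify %s: %d records, base %dCx, classes %s",
                    name, len(df), prof.base_multiplier, prof.multipliers)
    classified = pd.concat(classified_parts, ignore_index=True)
    if len(classified) != sum(len(df) for df in samples.values()):
        raise ValidationError("records lost between stages")

    classified["group"] = classified.apply(_species_group, axis=1)
    somatic = classified[classified["portion"] != "gamete"]

    summaries = summarize_groups(classified, by=["group", "portion", "cx"])
    min_genome = extract_min_genome(somatic, by="group")
    first_level = extract_first_level(somatic, by="group")

    report = RunReport(
        config_hash=config.digest(), seed=config.seed, version=__version__,
        unit=float(unit), profiles=profiles,
        class_summary=[
            dict(group=list(s.group), n=s.n, mean=s.mean, sd=s.sd)
            for s in summaries
        ],
    )
    report.counts = dict(
        total=int(len(classified)),
        by_group={k: int(v) for k, v in
                  classified.groupby("group").size().items()},
        min_genome={k: int(v.size) for k, v in min_genome.items()},
        first_level={k: int(v.size) for k, v in first_level.items()},
    )

    if len(min_genome) >= 2:
        res = one_way_anova(list(min_genome.values()))
        report.anova["min_genome"] = dict(
            groups=sorted(min_genome), F=res.F, p=res.p,
            df_between=res.df_between, df_within=res.df_within,
            ss_between=res.ss_between, ss_within=res.ss_within,
        )
        groups_all = [g["area_um2"].to_numpy(dtype=float)
                      for _, g in somatic.groupby("group")]
        res_all = one_way_anova(groups_all)
        report.anova["full_data"] = dict(
            F=res_all.F, p=res_all.p, df_between=res_all.df_between,
            df_within=res_all.df_within,
        )

    ref_key = "reproductive C. prolifera"
    if ref_key in first_level:
        ref = first_level[ref_key]
        for key, sample in sorted(first_level.items()):
            if key == ref_key or sample.size < 2:
                continue
            tt = two_sample_t(ref, sample)
            report.ttests[f"{ref_key} vs {key}"] = dict(
                t=tt.t, df=tt.df, p=tt.p, n_ref=int(ref.size),
                n=int(sample.size),
            )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(classified, out / "classified.csv")
        (out / "report.json").write_text(report.to_json())
        write_table1_report(profiles, out / "class_summary.tsv")
        logger.info("wrote artifacts to %s", out)
    return report, classified


def write_table1_report(profiles: dict, path=None) -> pd.DataFrame:
    """Render cytotype profiles as a published-table-shaped report.

    One row per sample; the count cell uses the ``total (a:b:c)`` format
    and per-class ``mean (sd)`` cells are ordered by increasing Cx.
    """
    if not profiles:
        raise ValidationError("no profiles to report")
    all_cx = sorted(
        {int(cx.rstrip("Cx")) for p in profiles.values()
         for cx in p["class_counts"]}
    )
    rows = []
    for name, p in profiles.items():
        counts = p["class_counts"]
        ordered = [f"{cx}Cx" for cx in all_cx if f"{cx}Cx" in counts]
        count_cell = f"{p['n']} ({':'.join(str(counts[c]) for c in ordered)})"
        row = {"sample": name, "base": f"{p['base_multiplier']}Cx",
               "nuclei (per class)": count_cell,
               "endopolyploid": p["endopolyploid"]}
        for cx in all_cx:
            key = f"{cx}Cx"
            if key in counts:
                row[key] = f"{p['class_means'][key]:.2f} ({p['class_sds'][key]:.2f})"
            else:
                row[key] = "-"
        rows.append(row)
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
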