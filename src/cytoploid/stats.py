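"""Group summaries, minimum-genome extraction, one-way ANOVA and t-tests.

These reproduce the comparison machinery used around the ploidy inference:
per-group mean (SD) summaries shaped like the published table, extraction
of the "minimum genome size" subsets (G1 nuclei of the lowest occupied
ploidy class) and the first-level subsets (G1 plus its replicated G2
class), the classical fixed-effects one-way ANOVA decomposition, and the
pooled-variance Student t-test (every published df equals n1+n2-2, which
identifies the pooled form; Welch is available by flag).  The default
significance convention is a conservative alpha of 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TTestResult",
    "SIGNIFICANCE_LEVEL",
    "summarize_groups",
    "extract_min_genome",
    "extract_first_level",
    "one_way_anova",
    "anova_from_components",
    "two_sample_t",
]

#: Conservative significance level used throughout the comparisons.
SIGNIFICANCE_LEVEL = 0.001


@dataclass(frozen=True)
class GroupSummary:
    group: tuple
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    F: float
    p: float

    def to_table(self) -> pd.DataFrame:
        """Delimited-table layout: Sum of squares / Df / Mean square / F / P."""
        return pd.DataFrame(
            {
                "Sum of squares": [self.ss_between, self.ss_within, self.ss_total],
                "Df": [self.df_between, self.df_within, self.df_total],
                "Mean square": [self.ms_between, self.ms_within, np.nan],
                "F": [self.F, np.nan, np.nan],
                "P value": [round(self.p, 4), np.nan, np.nan],
            },
            index=["Between groups", "Within groups", "Total"],
        )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    pooled: bool


def summarize_groups(records: pd.DataFrame, by) -> list[GroupSummary]:
    """Per-group n, mean and SD (denominator n-1) of nuclear areas."""
    if isinstance(by, str):
        by = [by]
    if len(records) == 0:
        raise ValidationError("no records to summarize")
    out = []
    for key, grp in records.groupby(list(by), sort=True, observed=True):
        areas = grp["area_um2"].to_numpy(dtype=float)
        if areas.size == 0:
            warnings.warn(f"empty group {key!r} omitted", stacklevel=2)
            continue
        key = key if isinstance(key, tuple) else (key,)
        sd = float(areas.std(ddof=1)) if areas.size > 1 else 0.0
        out.append(GroupSummary(group=key, n=int(areas.size),
                                mean=float(areas.mean()), sd=sd))
    return out


def _require_phases(records: pd.DataFrame) -> None:
    if "phase" not in records.columns or "cx" not in records.columns:
        raise ValidationError(
            "records lack phase attribution; classify them first"
        )


def extract_min_genome(records: pd.DataFrame, by: str = "species"
                       ) -> dict[str, np.ndarray]:
    """Minimum-genome-size subsets: G1 nuclei of the lowest occupied class.

    For each group (by default the species), returns the areas of the
    nuclei labelled G1, i.e. the lowest occupied ploidy class of each
    analyzed sample.
    """
    _require_phases(records)
    out: dict[str, np.ndarray] = {}
    for key, grp in records.groupby(by, sort=True, observed=True):
        sel = grp.loc[grp["phase"] == "G1", "area_um2"]
        out[key] = sel.to_numpy(dtype=float)
    return out


def extract_first_level(records: pd.DataFrame, by: str = "species"
                        ) -> dict[str, np.ndarray]:
    """First-ploidy-level subsets: the G1 class plus its 2x G2 class."""
    _require_phases(records)
    out: dict[str, np.ndarray] = {}
    for key, grp in records.groupby(by, sort=True, observed=True):
        sel = grp.loc[grp["phase"].isin(["G1", "G2"]), "area_um2"]
        out[key] = sel.to_numpy(dtype=float)
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA over >= 2 groups of areas."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("one-way ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least two observations")
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    ss_total = float(np.sum((all_x - grand) ** 2))
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    df_between = len(arrays) - 1
    df_within = all_x.size - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ms_between == 0 else np.inf
    else:
        f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    return AnovaResult(
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_total,
        df_between=df_between, df_within=df_within,
        df_total=all_x.size - 1,
        ms_between=ms_between, ms_within=ms_within,
        F=float(f), p=max(p, np.finfo(float).tiny),
    )


def anova_from_components(ss_between: float, df_between: int,
                          ss_within: float, df_within: int) -> AnovaResult:
    """Complete an ANOVA table from its printed SS/df components.

    Useful for validating published tables: mean squares, the F ratio and
    the p-value follow arithmetically from the sums of squares and degrees
    of freedom.
    """
    if df_between < 1 or df_within < 1:
        raise ValidationError("degrees of freedom must be >= 1")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        ss_between=float(ss_between), ss_within=float(ss_within),
        ss_total=float(ss_between + ss_within),
        df_between=int(df_between), df_within=int(df_within),
        df_total=int(df_between + df_within),
        ms_between=ms_b, ms_within=ms_w, F=float(f),
        p=max(p, np.finfo(float).tiny),
    )


def two_sample_t(a, b, pooled: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (pooled Student by default).

    With ``pooled=True`` the df is ``n1 + n2 - 2``; ``pooled=False`` gives
    the Welch test with Satterthwaite df.  Two zero-variance samples with
    equal means return t = 0, p = 1 rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            df = a.size + b.size - 2 if pooled else float(a.size + b.size - 2)
            return TTestResult(t=0.0, df=float(df), p=1.0, pooled=pooled)
        return TTestResult(t=np.inf if diff > 0 else -np.inf,
                           df=float(a.size + b.size - 2), p=0.0, pooled=pooled)
    if pooled:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    else:
        sa, sb = va / a.size, vb / b.size
        se = np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    t = diff / se
    p = 2 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df),
                       p=max(p, np.finfo(float).tiny), pooled=pooled)
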