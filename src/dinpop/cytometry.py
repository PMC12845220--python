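"""Flow-cytometry genome-size and ploidy summaries.

Absolute genome size (2C, in pg) follows from the linear relationship between
sample and internal-standard fluorescence; ploidy is inferred by asking which
cytotype would place the monoploid value (1Cx = 2C/ploidy) inside the known
diploid 1Cx envelope.  Population summaries report mean, SD, CV% and min-max
for 2C and 1Cx (pg and Mbp), and among-population differences in 1Cx are
tested with one-way ANOVA plus Tukey HSD after per-population normality
screening and outlier removal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PG_TO_MBP, CytometryRecord, ValidationError

#: Diploid-cytotype monoploid genome-size envelope (pg), the min-max range of
#: 1Cx values observed across diploid populations of the study system.
DEFAULT_1CX_BAND = (0.60, 0.81)


def compute_2c(sample_peak: float, standard_peak: float, standard_2c: float = 1.99) -> float:
    """2C (pg) = standard 2C x sample peak / standard peak."""
    if sample_peak <= 0 or standard_peak <= 0:
        raise ValidationError("fluorescence peaks must be positive")
    return standard_2c * sample_peak / standard_peak


def infer_ploidy(two_c: float, reference_1cx_band: tuple[float, float] = DEFAULT_1CX_BAND) -> int:
    """Assign ploidy 2 or 4 from a 2C value and the diploid 1Cx band.

    Returns the unique p for which ``two_c / p`` falls inside the band;
    raises when neither or both fit, reporting the two quotients.
    """
    lo, hi = reference_1cx_band
    fits = [p for p in (2, 4) if lo <= two_c / p <= hi]
    if len(fits) != 1:
        raise ValidationError(
            f"unassignable 2C={two_c:g} pg: 1Cx would be "
            f"{two_c / 2:g} (2x) or {two_c / 4:g} (4x), band [{lo:g}, {hi:g}]"
        )
    return fits[0]


def _summary(values: np.ndarray) -> dict[str, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    return {
        "mean": mean,
        "sd": sd,
        "cv_pct": 100.0 * sd / mean,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def population_genome_stats(records: list[CytometryRecord]) -> pd.DataFrame:
    """Per-population (and per-cytotype) genome-size summary table.

    One row per (population, ploidy): N, 2C mean/SD/CV%/min-max, 1Cx
    mean/SD/CV%/min-max (pg) and 1Cx mean/SD in Mbp.  A mixed-ploidy
    population yields one row per cytotype with a warning.
    """
    if not records:
        raise ValidationError("no cytometry records")
    by_key: dict[tuple[str, int], list[CytometryRecord]] = {}
    for r in records:
        by_key.setdefault((r.population_id, r.ploidy), []).append(r)
    pops_with_mixture = {
        pop for pop in {r.population_id for r in records}
        if len({r.ploidy for r in records if r.population_id == pop}) > 1
    }
    if pops_with_mixture:
        warnings.warn(
            f"mixed ploidy within population(s) {sorted(pops_with_mixture)}; "
            "statistics computed per cytotype",
            stacklevel=2,
        )
    rows = []
    for (pop, ploidy), recs in sorted(by_key.items()):
        if len(recs) < 2:
            raise ValidationError(
                f"population {pop} ({ploidy}x): need >=2 records for summary"
            )
        two_c = np.array([r.derived_2c for r in recs])
        one_cx = two_c / ploidy
        s2, s1 = _summary(two_c), _summary(one_cx)
        rows.append(
            {
                "population": pop,
                "n": len(recs),
                "ploidy": ploidy,
                "mean_2c_pg": s2["mean"], "sd_2c_pg": s2["sd"],
                "min_2c_pg": s2["min"], "max_2c_pg": s2["max"],
                "cv_2c_pct": s2["cv_pct"],
                "mean_1cx_pg": s1["mean"], "sd_1cx_pg": s1["sd"],
                "min_1cx_pg": s1["min"], "max_1cx_pg": s1["max"],
                "cv_1cx_pct": s1["cv_pct"],
                "mean_1cx_mbp": s1["mean"] * PG_TO_MBP,
                "sd_1cx_mbp": s1["sd"] * PG_TO_MBP,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MonoploidComparison:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    log_transformed: list[str] = field(default_factory=list)
    outliers_removed: dict[str, int] = field(default_factory=dict)
    excluded_populations: list[str] = field(default_factory=list)


def compare_monoploid_sizes(
    records: list[CytometryRecord],
    shapiro_alpha: float = 0.05,
    iqr_factor: float = 3.0,
    min_n: int = 3,
) -> MonoploidComparison:
    """One-way ANOVA + Tukey HSD on per-plant 1Cx values across populations.

    Per population: outliers beyond ``iqr_factor`` x IQR are removed (the
    default 3.0 is Tukey's "far out" fence, which at the typical 8-19 plants
    per population discards only gross measurement errors without disturbing
    the ANOVA's error rate), then a Shapiro-Wilk screen at ``shapiro_alpha``
    flags non-normal populations.
    If any population fails the screen, the whole analysis runs on
    log-transformed values (applying a monotone transform to every group
    keeps the groups comparable; ``log_transformed`` lists the populations
    that triggered it).  Populations left with fewer than ``min_n`` plants
    are excluded with a warning.
    """
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.population_id, []).append(r.derived_1cx)

    cleaned: dict[str, np.ndarray] = {}
    transformed: list[str] = []
    removed: dict[str, int] = {}
    excluded: list[str] = []
    for pop, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        keep = (x >= q1 - iqr_factor * iqr) & (x <= q3 + iqr_factor * iqr)
        if (~keep).sum():
            removed[pop] = int((~keep).sum())
        x = x[keep]
        if len(x) < min_n:
            excluded.append(pop)
            warnings.warn(
                f"population {pop}: <{min_n} plants after outlier removal; excluded",
                stacklevel=2,
            )
            continue
        if np.ptp(x) > 0 and stats.shapiro(x).pvalue < shapiro_alpha:
            transformed.append(pop)
        cleaned[pop] = x
    if transformed:
        cleaned = {pop: np.log(x) for pop, x in cleaned.items()}

    if len(cleaned) < 2:
        raise ValidationError("need >=2 populations with enough plants for ANOVA")
    names = sorted(cleaned)
    samples = [cleaned[p] for p in names]
    anova = stats.f_oneway(*samples)
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "population_a": names[i],
                    "population_b": names[j],
                    "mean_difference": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_value": float(hsd.pvalue[i, j]),
                }
            )
    return MonoploidComparison(
        f_statistic=float(anova.statistic),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(anova.pvalue),
        tukey=pd.DataFrame(rows),
        log_transformed=sorted(transformed),
        outliers_removed=removed,
        excluded_populations=sorted(excluded),
    )
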