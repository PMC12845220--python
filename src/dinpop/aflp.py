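"""Dominant-marker (AFLP-style) quality control and distance analyses.

Scoring error is estimated from replicated profiles of the same biological
sample: over every within-group pair, the mismatch rate among loci scored in
both profiles.  Loci whose per-locus rate exceeds a threshold are excluded,
replicate groups are collapsed to majority-consensus profiles, and genetic
relationships are summarised with Nei-Li/Dice distances, uncorrected
p-distances, and bootstrapped Neighbor-Joining trees (see
:mod:`dinpop.trees`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import BinaryMarkerMatrix, DistanceMatrix, ValidationError
from .trees import bootstrap_support as _bootstrap_support
from .trees import nj_tree  # re-exported for convenience  # noqa: F401

DEFAULT_ERROR_THRESHOLD = 0.10


@dataclass
class ErrorRateReport:
    per_locus: pd.DataFrame     # fragment_id, compared, mismatches, rate, flip_rate
    overall_rate: float
    overall_flip_rate: float
    total_compared: int
    total_mismatches: int
    flagged: list[str]
    threshold: float


def _flip_rate(mismatch_rate: float) -> float:
    """Per-scoring flip rate implied by a replicate-pair mismatch rate.

    Under independent flips with probability e in each of two replicate
    scorings, a locus mismatches with probability 2e(1-e); inverting gives
    e = (1 - sqrt(1 - 2m)) / 2.  Mismatch rates above 0.5 (which the model
    cannot produce) saturate at 0.5.
    """
    if not np.isfinite(mismatch_rate):
        return float("nan")
    if mismatch_rate >= 0.5:
        return 0.5
    return 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * mismatch_rate))


def replicate_error_rate(
    m: BinaryMarkerMatrix, threshold: float = DEFAULT_ERROR_THRESHOLD
) -> ErrorRateReport:
    """Scoring-error estimates from replicate pairs, per locus and overall.

    Every within-group pair of profiles contributes the loci scored in both;
    the mismatch rate = total mismatches / total compared locus-pairs (the
    quantity conventionally quoted as "the error rate" of a dominant-marker
    study), and the flip rate inverts it to the per-scoring error under the
    independent-flip model (see :func:`_flip_rate`).  Loci whose per-locus
    flip rate exceeds ``threshold`` are flagged for exclusion.
    """
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(m.replicate_groups):
        groups.setdefault(g, []).append(i)
    pairs = [
        (a, b)
        for rows in groups.values() if len(rows) >= 2
        for a, b in combinations(rows, 2)
    ]
    if not pairs:
        raise ValidationError("no replicate groups of size >= 2")

    compared = np.zeros(m.n_loci, dtype=int)
    mismatches = np.zeros(m.n_loci, dtype=int)
    for a, b in pairs:
        va, vb = m.values[a], m.values[b]
        both = (va != -1) & (vb != -1)
        compared += both
        mismatches += both & (va != vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(compared > 0, mismatches / np.maximum(compared, 1), np.nan)
    flip_rates = np.array([_flip_rate(r) for r in rates])
    per_locus = pd.DataFrame(
        {
            "fragment_id": m.fragment_ids,
            "compared": compared,
            "mismatches": mismatches,
            "rate": rates,
            "flip_rate": flip_rates,
        }
    )
    flagged = [
        f for f, r in zip(m.fragment_ids, flip_rates)
        if np.isfinite(r) and r > threshold
    ]
    total_c, total_m = int(compared.sum()), int(mismatches.sum())
    return ErrorRateReport(
        per_locus=per_locus,
        overall_rate=total_m / total_c,
        overall_flip_rate=_flip_rate(total_m / total_c),
        total_compared=total_c,
        total_mismatches=total_m,
        flagged=flagged,
        threshold=threshold,
    )


def filter_loci(
    m: BinaryMarkerMatrix,
    report: ErrorRateReport | None = None,
    threshold: float = DEFAULT_ERROR_THRESHOLD,
) -> BinaryMarkerMatrix:
    """Drop inconsistently scored loci and collapse replicates to consensus.

    Flagged loci (from ``report`` or recomputed at ``threshold``) are
    removed; each replicate group becomes one majority-consensus row (ties
    and all-missing loci become missing).
    """
    if report is None:
        report = replicate_error_rate(m, threshold)
    drop = set(report.flagged)
    keep_cols = [j for j, f in enumerate(m.fragment_ids) if f not in drop]

    group_order: list[str] = []
    group_rows: dict[str, list[int]] = {}
    for i, g in enumerate(m.replicate_groups):
        if g not in group_rows:
            group_order.append(g)
        group_rows.setdefault(g, []).append(i)

    out_rows, sample_ids, population_ids = [], [], []
    sub = m.values[:, keep_cols]
    for g in group_order:
        rows = group_rows[g]
        block = sub[rows]
        ones = (block == 1).sum(axis=0)
        zeros = (block == 0).sum(axis=0)
        consensus = np.full(len(keep_cols), -1, dtype=np.int8)
        consensus[ones > zeros] = 1
        consensus[zeros > ones] = 0  # equal non-zero counts stay missing
        out_rows.append(consensus)
        sample_ids.append(g)
        population_ids.append(m.population_ids[rows[0]])
    return BinaryMarkerMatrix(
        sample_ids=sample_ids,
        population_ids=population_ids,
        replicate_groups=sample_ids,
        fragment_ids=[m.fragment_ids[j] for j in keep_cols],
        fragment_sizes=[m.fragment_sizes[j] for j in keep_cols],
        values=np.asarray(out_rows, dtype=np.int8),
    )


def polymorphic_fraction(m: BinaryMarkerMatrix) -> tuple[int, int, float]:
    """(total loci, polymorphic loci, percent polymorphic).

    A locus is polymorphic iff both presence and absence occur among its
    non-missing entries.
    """
    has_one = (m.values == 1).any(axis=0)
    has_zero = (m.values == 0).any(axis=0)
    poly = int((has_one & has_zero).sum())
    total = m.n_loci
    return total, poly, 100.0 * poly / total


def _pairwise(m: BinaryMarkerMatrix, kind: str) -> DistanceMatrix:
    n = m.n_samples
    values = np.zeros((n, n))
    missing_pairs = []
    v = m.values
    for i in range(n):
        for j in range(i + 1, n):
            both = (v[i] != -1) & (v[j] != -1)
            if not both.any():
                values[i, j] = values[j, i] = np.nan
                missing_pairs.append((m.sample_ids[i], m.sample_ids[j]))
                continue
            a = int(((v[i] == 1) & (v[j] == 1) & both).sum())
            b = int(((v[i] == 1) & (v[j] == 0) & both).sum())
            c = int(((v[i] == 0) & (v[j] == 1) & both).sum())
            if kind == "dice":
                denom = 2 * a + b + c
                d = 1.0 - 2 * a / denom if denom > 0 else 0.0
            else:  # uncorrected p-distance; 0/0 agreement counts as match
                d = (b + c) / int(both.sum())
            values[i, j] = values[j, i] = d
    if missing_pairs:
        warnings.warn(
            f"profile pairs with no co-scored loci set to NA: {missing_pairs}",
            stacklevel=3,
        )
    return DistanceMatrix(list(m.sample_ids), values)


def dice_distance(m: BinaryMarkerMatrix) -> DistanceMatrix:
    """Nei-Li/Dice distance d = 1 - 2a/(2a + b + c) over co-scored loci.

    Shared absences (0/0) carry no weight by the formula itself: they enter
    neither a, b nor c.
    """
    return _pairwise(m, "dice")


def p_distance(m: BinaryMarkerMatrix) -> DistanceMatrix:
    """Uncorrected p-distance: mismatches / compared loci (0/0 = agreement)."""
    return _pairwise(m, "p")


def bootstrap_support(
    m: BinaryMarkerMatrix,
    distance_kind: str = "dice",
    reps: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> dict[frozenset[str], float]:
    """NJ bootstrap over loci (columns resampled with replacement).

    Support is the percent of replicate trees containing each non-trivial
    bipartition of the original tree; display conventionally keeps >= 50%.
    """
    if distance_kind not in ("dice", "p"):
        raise ValidationError(f"unknown distance kind {distance_kind!r}")

    def dist_fn(values: np.ndarray, labels: list[str]) -> DistanceMatrix:
        sub = BinaryMarkerMatrix(
            sample_ids=list(labels),
            population_ids=list(labels),
            replicate_groups=list(labels),
            fragment_ids=[f"c{k}" for k in range(values.shape[1])],
            fragment_sizes=[0] * values.shape[1],
            values=values,
        )
        return _pairwise(sub, distance_kind)

    return _bootstrap_support(m.values, list(m.sample_ids), dist_fn,
                              reps=reps, seed=seed)
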