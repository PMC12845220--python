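"""Codominant (microsatellite) diversity statistics.

Per locus and per scope (one population, or the pooled total) the module
computes the detected and effective allele counts (A_N, A_E = 1/sum p_i^2),
rarefied allelic richness, Nei's unbiased expected heterozygosity, observed
heterozygosity, the inbreeding coefficient F = 1 - H_O/H_E, and two ratio
indices aimed at detecting allele-frequency skew:

* R = A_E / A_N, small when a few alleles dominate the locus;
* iMAF = (1/A_N) / MAF, the expected-if-equifrequent allele frequency over
  the observed major allele frequency, small when one allele drifts toward
  fixation.

Both indices carry Monte-Carlo significance: the null resamples the scope's
gene copies from a uniform multinomial over the A_N observed alleles and asks
how often the null statistic is as small as the observed one (add-one
p-value).  All frequencies are over gene copies — two per diploid and four
per tetraploid individual.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeTable, ValidationError


@dataclass
class LocusDiversity:
    locus_id: str
    a_n: int
    a_e: float
    ar: float
    h_e: float
    h_o: float
    f: float
    r: float
    p_r: float
    maf: float
    imaf: float
    p_imaf: float


# ---------------------------------------------------------------------------
# allele counting


def allele_counts(
    table: GenotypeTable, locus: str, population: str | None = None,
    distinct_only: bool = False,
) -> tuple[Counter, int]:
    """Allele copy counts and total gene copies for a locus within a scope.

    ``distinct_only`` is a sensitivity mode for dosage-ambiguous tetraploid
    calls: each distinct allele of an ambiguous call contributes one copy
    instead of its expanded dosage.
    """
    j = table.locus_index(locus)
    counts: Counter = Counter()
    n_copies = 0
    for i in table.individuals_in(population):
        call = table.calls[i][j]
        if call is None:
            continue
        if distinct_only and (i, j) in table.dosage_ambiguous:
            call = tuple(sorted(set(call)))
        counts.update(call)
        n_copies += len(call)
    if n_copies == 0:
        raise ValidationError(
            f"locus {locus}, scope {population or 'total'}: all calls missing"
        )
    return counts, n_copies


def allele_frequencies(
    table: GenotypeTable, locus: str, population: str | None = None,
    distinct_only: bool = False,
) -> dict[str, float]:
    """Gene-copy allele frequencies (sum to 1) for a locus within a scope."""
    counts, n = allele_counts(table, locus, population, distinct_only)
    return {a: c / n for a, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# diversity statistics


def effective_alleles(freqs: dict[str, float] | list[float]) -> float:
    """Effective allele count A_E = 1 / sum p_i^2."""
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    if p.size == 0:
        raise ValidationError("empty frequency map")
    if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-8):
        raise ValidationError(f"frequencies sum to {p.sum():g}, not 1")
    return float(1.0 / np.sum(p**2))


def heterozygosities(
    table: GenotypeTable, locus: str, population: str | None = None
) -> tuple[float, float]:
    """(H_O, H_E) for a locus within a scope.

    H_O is the fraction of (non-missing) individuals carrying at least two
    distinct alleles — the simplest observable notion, which extends to
    tetraploids.  H_E is Nei's unbiased estimator
    (n_c/(n_c-1)) (1 - sum p_i^2) over n_c gene copies.
    """
    j = table.locus_index(locus)
    rows = [i for i in table.individuals_in(population)
            if table.calls[i][j] is not None]
    if len(rows) < 2:
        raise ValidationError(
            f"locus {locus}, scope {population or 'total'}: need >=2 individuals"
        )
    h_o = sum(len(set(table.calls[i][j])) >= 2 for i in rows) / len(rows)
    counts, n_c = allele_counts(table, locus, population)
    sum_p2 = sum((c / n_c) ** 2 for c in counts.values())
    if len(counts) == 1:
        return 0.0, 0.0
    h_e = (n_c / (n_c - 1)) * (1.0 - sum_p2)
    return h_o, h_e


def allelic_richness(
    table: GenotypeTable, locus: str, population: str | None = None,
    g: int | None = None,
) -> float:
    """Rarefied allelic richness: expected allele count in g gene copies.

    AR = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles with copy counts
    N_i out of N total copies.  ``g=None`` uses the full depth (AR = A_N).
    """
    counts, n = allele_counts(table, locus, population)
    if g is None:
        g = n
    if g < 2:
        raise ValidationError("rarefaction depth g must be >= 2")
    if g > n:
        raise ValidationError(f"rarefaction depth g={g} exceeds {n} gene copies")
    denom = math.comb(n, g)
    return float(sum(1.0 - math.comb(n - c, g) / denom for c in counts.values()))


def min_gene_copies(table: GenotypeTable, locus: str) -> int:
    """Smallest per-population gene-copy count at a locus (rarefaction depth)."""
    return min(
        allele_counts(table, locus, pop)[1] for pop in table.populations
    )


def ae_an_ratio(a_e: float, a_n: int) -> float:
    """R = A_E / A_N; NA (nan) for monomorphic loci."""
    if a_n < 2:
        return float("nan")
    return a_e / a_n


def imaf(freqs: dict[str, float] | list[float]) -> tuple[float, float]:
    """(MAF, iMAF) with iMAF = (1/A_N)/MAF; NA for monomorphic loci."""
    p = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    a_n = len(p)
    maf = max(p)
    if a_n < 2:
        return maf, float("nan")
    return maf, (1.0 / a_n) / maf


def inbreeding_f(h_o: float, h_e: float) -> float:
    """F = 1 - H_O/H_E; NA when H_E = 0."""
    if h_e == 0:
        return float("nan")
    return 1.0 - h_o / h_e


# ---------------------------------------------------------------------------
# Monte-Carlo significance for R and iMAF


def _null_statistics(a_n: int, n_copies: int, reps: int, rng: np.random.Generator):
    """Null draws: uniform multinomial over the A_N observed alleles.

    Returns (r_star, imaf_star) arrays; the R denominator stays fixed at A_N
    even when a null draw loses an allele.
    """
    counts = rng.multinomial(n_copies, np.full(a_n, 1.0 / a_n), size=reps)
    sum_sq = (counts.astype(float) ** 2).sum(axis=1)
    a_e_star = n_copies**2 / sum_sq
    r_star = a_e_star / a_n
    maf_star = counts.max(axis=1) / n_copies
    imaf_star = (1.0 / a_n) / maf_star
    return r_star, imaf_star


def _mc_pvalue(star: np.ndarray, obs: float, rng: np.random.Generator) -> float:
    """Add-one Monte-Carlo p-value with randomized tie rank.

    p = (1 + #{star below obs}) / (reps + 1), where null draws exactly tied
    with the observation take a uniform random rank among the ties.  Both
    statistics here are discrete (finite gene-copy counts), and the
    randomized rank is what keeps the p-value uniform under the null rather
    than conservative.
    """
    tol = 1e-12
    less = int(np.sum(star < obs - tol))
    ties = int(np.sum(np.abs(star - obs) <= tol))
    extra = int(rng.integers(0, ties + 1)) if ties else 0
    return (1 + less + extra) / (len(star) + 1)


def ratio_significance(
    table: GenotypeTable, locus: str, population: str | None = None,
    reps: int = 9999, seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo p-value for R: small when the observed A_E/A_N is lower
    than expected for equifrequent alleles (see :func:`_mc_pvalue`)."""
    counts, n = allele_counts(table, locus, population)
    a_n = len(counts)
    if a_n < 2:
        return float("nan")
    r_obs = ae_an_ratio(effective_alleles({a: c / n for a, c in counts.items()}), a_n)
    rng = np.random.default_rng(seed)
    r_star, _ = _null_statistics(a_n, n, reps, rng)
    return _mc_pvalue(r_star, r_obs, rng)


def imaf_significance(
    table: GenotypeTable, locus: str, population: str | None = None,
    reps: int = 9999, seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo p-value for iMAF under the same uniform-multinomial null."""
    counts, n = allele_counts(table, locus, population)
    a_n = len(counts)
    if a_n < 2:
        return float("nan")
    _, imaf_obs = imaf({a: c / n for a, c in counts.items()})
    rng = np.random.default_rng(seed)
    _, imaf_star = _null_statistics(a_n, n, reps, rng)
    return _mc_pvalue(imaf_star, imaf_obs, rng)


# ---------------------------------------------------------------------------
# summary tables


def locus_diversity(
    table: GenotypeTable, locus: str, population: str | None = None,
    g: int | None = None, reps: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> LocusDiversity:
    """All per-locus statistics for one scope; see module docstring."""
    rng = np.random.default_rng(seed)
    counts, n = allele_counts(table, locus, population)
    freqs = {a: c / n for a, c in counts.items()}
    a_n = len(counts)
    a_e = effective_alleles(freqs)
    h_o, h_e = heterozygosities(table, locus, population)
    maf, imaf_val = imaf(freqs)
    return LocusDiversity(
        locus_id=locus,
        a_n=a_n,
        a_e=a_e,
        ar=allelic_richness(table, locus, population, g=g),
        h_e=h_e,
        h_o=h_o,
        f=inbreeding_f(h_o, h_e),
        r=ae_an_ratio(a_e, a_n),
        p_r=ratio_significance(table, locus, population, reps, rng),
        maf=maf,
        imaf=imaf_val,
        p_imaf=imaf_significance(table, locus, population, reps, rng),
    )


_POP_COLUMNS = ["a_n", "a_e", "ar", "r", "p_r", "h_e", "h_o", "f"]
_LOCUS_COLUMNS = ["a_n", "a_e", "ar", "r", "p_r", "h_e", "h_o", "f",
                  "maf", "imaf", "p_imaf"]


def summarize(
    table: GenotypeTable, reps: int = 9999,
    seed: int | np.random.Generator | None = None,
    g: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population and per-locus diversity reports.

    The per-population table holds unweighted means across loci of A_N, A_E,
    AR, R, p(R), H_E, H_O and F; AR is rarefied at ``g`` gene copies
    (default: the smallest per-population depth at each locus, so equal
    sample sizes make AR identical to A_N).  The per-locus table pools all
    populations and adds MAF, iMAF and p(iMAF), with an unweighted Mean row.
    """
    rng = np.random.default_rng(seed)

    pop_rows = []
    for pop in table.populations:
        per_locus = []
        for locus in table.loci:
            depth = g if g is not None else min_gene_copies(table, locus)
            d = locus_diversity(table, locus, pop, g=depth, reps=reps, seed=rng)
            per_locus.append(d)
        row: dict[str, float | str] = {"population": pop}
        for col in _POP_COLUMNS:
            vals = [getattr(d, col) for d in per_locus]
            row[col] = float(np.nanmean(vals))
        pop_rows.append(row)
    per_population = pd.DataFrame(pop_rows)

    locus_rows = []
    for locus in table.loci:
        depth = g if g is not None else min_gene_copies(table, locus)
        d = locus_diversity(table, locus, None, g=depth, reps=reps, seed=rng)
        locus_rows.append({"locus": locus,
                           **{c: getattr(d, c) for c in _LOCUS_COLUMNS}})
    per_locus_df = pd.DataFrame(locus_rows)
    mean_row = {"locus": "Mean",
                **{c: float(np.nanmean(per_locus_df[c])) for c in _LOCUS_COLUMNS}}
    per_locus_df = pd.concat(
        [per_locus_df, pd.DataFrame([mean_row])], ignore_index=True
    )
    return per_population, per_locus_df
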