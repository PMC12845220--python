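"""Population differentiation: Weir-Cockerham F-statistics, pairwise F_ST,
one-level AMOVA, principal coordinates analysis, and Evanno's delta-K
post-processing of external Bayesian-clustering log-likelihoods.

The Weir-Cockerham moment estimators use per-allele variance components
a (among populations), b (among individuals within populations) and c
(within individuals); overall and per-locus values are ratios of summed
components — never means of per-locus ratios:

    theta (F_ST) = sum a / sum (a+b+c)
    f     (F_IS) = 1 - sum c / sum (b+c)
    F     (F_IT) = 1 - sum c / sum (a+b+c)

The estimator is defined for diploids; tetraploid individuals are handled at
the gene-copy level with heterozygosity taken as ">=2 distinct alleles", and
results from mixed-ploidy tables carry an ``approximate_for_tetraploids``
flag.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    ClusterLikelihoodTrace,
    DistanceMatrix,
    GenotypeTable,
    ValidationError,
)


@dataclass
class FStatsResult:
    per_locus: pd.DataFrame       # locus, a, b, c, f_it, f_is, f_st
    f_it: float
    f_is: float
    f_st: float
    approximate_for_tetraploids: bool = False


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None = None
    n_permutations: int = 0


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame     # samples x axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    pct_variance: np.ndarray      # per positive-eigenvalue axis


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components


def _locus_components(table: GenotypeTable, locus: str) -> tuple[float, float, float]:
    """Summed per-allele (a, b, c) components for one locus."""
    j = table.locus_index(locus)
    pops = table.populations
    # per population: individuals with data, allele copy counts, het counts
    n_i: list[int] = []
    copy_counts: list[Counter] = []
    het_counts: list[Counter] = []
    copies_per_ind: list[float] = []
    for pop in pops:
        rows = [i for i in table.individuals_in(pop)
                if table.calls[i][j] is not None]
        if not rows:
            continue
        cc: Counter = Counter()
        hc: Counter = Counter()
        ncop = 0
        for i in rows:
            call = table.calls[i][j]
            cc.update(call)
            ncop += len(call)
            dosage = Counter(call)
            for allele, d in dosage.items():
                if 1 <= d <= len(call) - 1:
                    hc[allele] += 1
        n_i.append(len(rows))
        copy_counts.append(cc)
        het_counts.append(hc)
        copies_per_ind.append(ncop / len(rows))

    r = len(n_i)
    if r < 2:
        raise ValidationError(f"locus {locus}: need >=2 populations with data")
    alleles = sorted(set().union(*[set(c) for c in copy_counts]))
    n = np.asarray(n_i, dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        raise ValidationError(f"locus {locus}: mean sample size <= 1")
    n_c = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)

    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array(
            [cc[allele] / (ni * cpi) for cc, ni, cpi
             in zip(copy_counts, n_i, copies_per_ind)]
        )
        h_i = np.array([hc[allele] / ni for hc, ni in zip(het_counts, n_i)])
        pbar = float(np.sum(n * p_i) / n.sum())
        s2 = float(np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h_i) / n.sum())
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fstats(table: GenotypeTable) -> FStatsResult:
    """Weir-Cockerham F_IT, F_IS, F_ST per locus and overall."""
    if len(table.populations) < 2:
        raise ValidationError("F-statistics need >=2 populations")
    rows = []
    A = B = C = 0.0
    for locus in table.loci:
        a, b, c = _locus_components(table, locus)
        tot = a + b + c
        rows.append(
            {
                "locus": locus, "a": a, "b": b, "c": c,
                "f_st": a / tot if tot > 0 else float("nan"),
                "f_is": 1 - c / (b + c) if (b + c) > 0 else float("nan"),
                "f_it": 1 - c / tot if tot > 0 else float("nan"),
            }
        )
        A += a
        B += b
        C += c
    tot = A + B + C
    mixed = len({ind.ploidy for ind in table.individuals}) > 1 or any(
        ind.ploidy != 2 for ind in table.individuals
    )
    return FStatsResult(
        per_locus=pd.DataFrame(rows),
        f_st=A / tot if tot > 0 else float("nan"),
        f_is=1 - C / (B + C) if (B + C) > 0 else float("nan"),
        f_it=1 - C / tot if tot > 0 else float("nan"),
        approximate_for_tetraploids=mixed,
    )


def pairwise_fst(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta per population pair.

    Negative estimates are reported as computed (flagged via a warning), for
    comparability with published tables.
    """
    pops = table.populations
    n = len(pops)
    values = np.zeros((n, n))
    any_negative = False
    for i in range(n):
        for j in range(i + 1, n):
            theta = wc_fstats(table.subset([pops[i], pops[j]])).f_st
            values[i, j] = values[j, i] = theta
            if theta < 0:
                any_negative = True
    if any_negative:
        warnings.warn("negative pairwise theta estimates present (kept as computed)",
                      stacklevel=2)
    return DistanceMatrix(pops, values)


# ---------------------------------------------------------------------------
# AMOVA


def _locus_count_arrays(table: GenotypeTable):
    """Per locus: (n_individuals x n_alleles) gene-copy count matrix + mask."""
    out = []
    n = table.n_individuals
    for j in range(len(table.loci)):
        calls = [table.calls[i][j] for i in range(n)]
        alleles = sorted(set().union(*[set(c) for c in calls if c is not None]))
        index = {a: k for k, a in enumerate(alleles)}
        counts = np.zeros((n, len(alleles)), dtype=np.int64)
        valid = np.zeros(n, dtype=bool)
        for i, call in enumerate(calls):
            if call is None:
                continue
            valid[i] = True
            for a in call:
                counts[i, index[a]] += 1
        out.append((counts, valid))
    return out


def _amova_components(
    locus_arrays, groups: np.ndarray, r: int
) -> tuple[float, float, float, float, int, int]:
    """Summed gene-copy-level variance components and SS/df across loci.

    Per locus the units are gene copies with the allele-mismatch (0/1)
    squared distance; sums of squared distances reduce to allele-count
    algebra: sum_{i<j} d_ij = (N^2 - sum_a C_a^2) / 2.
    """
    sigma_a = sigma_w = 0.0
    ss_a = ss_w = 0.0
    df_a = df_w = 0
    for counts, valid in locus_arrays:
        pop_counts = np.zeros((r, counts.shape[1]), dtype=np.int64)
        np.add.at(pop_counts, groups[valid], counts[valid])
        n_p = pop_counts.sum(axis=1).astype(float)
        present = n_p > 0
        if present.sum() < 2:
            continue
        pop_counts = pop_counts[present]
        n_p = n_p[present]
        n_total = n_p.sum()
        c_tot = pop_counts.sum(axis=0).astype(float)
        ss_total = (n_total**2 - (c_tot**2).sum()) / (2 * n_total)
        ss_within = float(
            np.sum((n_p**2 - (pop_counts.astype(float) ** 2).sum(axis=1)) / (2 * n_p))
        )
        ss_among = ss_total - ss_within
        k = len(n_p)
        dfa, dfw = k - 1, int(n_total) - k
        if dfw <= 0:
            continue
        ms_among = ss_among / dfa
        ms_within = ss_within / dfw
        n0 = (n_total - (n_p**2).sum() / n_total) / dfa
        sigma_w += ms_within
        sigma_a += (ms_among - ms_within) / n0
        ss_a += ss_among
        ss_w += ss_within
        df_a += dfa
        df_w += dfw
    return sigma_a, sigma_w, ss_a, ss_w, df_a, df_w


def amova(
    table: GenotypeTable,
    n_permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> AmovaResult:
    """One-level AMOVA (among/within populations) at the gene-copy level.

    Units are gene copies with the allele-mismatch squared distance,
    analysed locus by locus with variance components summed across loci
    (so Phi_ST is commensurable with Weir-Cockerham theta).  Significance
    permutes whole individuals among populations;
    p = (1 + #{phi* >= phi_obs}) / (n_permutations + 1).
    Populations of size 1 are excluded with a warning.
    """
    sizes = Counter(ind.population_id for ind in table.individuals)
    singletons = [p for p, c in sizes.items() if c < 2]
    if singletons:
        warnings.warn(f"excluding single-individual population(s) {singletons}",
                      stacklevel=2)
        table = table.subset([p for p in table.populations if p not in singletons])
    pops = table.populations
    if len(pops) < 2:
        raise ValidationError("AMOVA needs >=2 populations of size >=2")

    locus_arrays = _locus_count_arrays(table)
    groups = np.array([pops.index(ind.population_id) for ind in table.individuals])
    r = len(pops)
    sa, sw, ss_a, ss_w, df_a, df_w = _amova_components(locus_arrays, groups, r)
    total = sa + sw
    result = AmovaResult(
        df_among=df_a, df_within=df_w,
        ss_among=ss_a, ss_within=ss_w,
        sigma2_among=sa, sigma2_within=sw,
        pct_among=100 * sa / total if total != 0 else float("nan"),
        pct_within=100 * sw / total if total != 0 else float("nan"),
        phi_st=sa / total if total != 0 else float("nan"),
    )

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        obs = result.phi_st
        hits = 0
        perm = groups.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            psa, psw, *_ = _amova_components(locus_arrays, perm, r)
            ptot = psa + psw
            phi = psa / ptot if ptot != 0 else float("-inf")
            if phi >= obs - 1e-12:
                hits += 1
        result.p_value = (1 + hits) / (n_permutations + 1)
        result.n_permutations = n_permutations
    return result


# ---------------------------------------------------------------------------
# PCoA


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (Gower double-centering of -d^2/2).

    Negative eigenvalues are retained in ``eigenvalues`` but excluded from
    the percent-variance denominator; axes are ordered by eigenvalue.
    """
    d2 = dm.values**2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = 100 * eigvals[pos] / eigvals[pos].sum()
    axes = [f"axis{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=axes),
        eigenvalues=eigvals,
        pct_variance=pct,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(trace: ClusterLikelihoodTrace) -> tuple[pd.DataFrame, int | None]:
    """Evanno's second-order rate of change of L(K).

    delta K(K) = mean over runs of |L(K+1) - 2 L(K) + L(K-1)| divided by the
    SD over runs of L(K); runs are paired by replicate index.  Returns the
    per-K table and the argmax K (None when every interior K is undefined).
    """
    trace.validate_for_delta_k()
    ks = trace.ks()
    n_runs = min(len(trace.runs[k]) for k in ks)
    L = np.array([trace.runs[k][:n_runs] for k in ks])  # (n_K, n_runs)
    rows = []
    for idx in range(1, len(ks) - 1):
        second = L[idx + 1] - 2 * L[idx] + L[idx - 1]
        sd = float(np.std(L[idx], ddof=1))
        if sd == 0:
            warnings.warn(f"K={ks[idx]}: zero SD across runs; delta K undefined",
                          stacklevel=2)
            dk = float("nan")
        else:
            dk = float(np.mean(np.abs(second)) / sd)
        rows.append({"K": ks[idx], "mean_lnL": float(np.mean(L[idx])),
                     "sd_lnL": sd, "delta_k": dk})
    df = pd.DataFrame(rows)
    if df["delta_k"].notna().any():
        best = int(df.loc[df["delta_k"].idxmax(), "K"])
    else:
        best = None
    return df, best
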