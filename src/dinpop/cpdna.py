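"""Chloroplast haplotype inference, diversity/neutrality statistics, and
statistical-parsimony networks.

Aligned spacer sequences are first masked so that only substitution sites
remain (every column containing a gap — and, by default, an N — is treated
as missing and excluded).  Sequences identical on the kept columns collapse
into haplotypes; from the kept columns the module computes segregating
sites S, mean pairwise differences pi, Watterson's theta, Tajima's D, and
Fu's Fs (via the Ewens sampling distribution of the haplotype count), and
builds a statistical-parsimony network in which haplotype pairs join in
order of increasing mutational distance up to the parsimony connection
limit, multi-step connections passing through hypothetical intermediate
nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .datamodel import (
    DistanceMatrix,
    HaplotypeAlignment,
    HaplotypeNetwork,
    NetworkNode,
    ValidationError,
)
from .trees import Tree, bootstrap_support as _bootstrap_support, nj_tree

BASES = ("A", "C", "G", "T")


@dataclass
class HaplotypeSet:
    haplotype_ids: list[str]
    representatives: np.ndarray            # (k, n_kept) kept-column sequences
    frequencies: list[int]
    members: dict[str, list[str]]          # haplotype -> individual ids
    populations: dict[str, list[str]]      # haplotype -> population ids (per seq)
    variable_positions: list[int]          # 1-based, concatenated coordinates

    @property
    def k(self) -> int:
        return len(self.haplotype_ids)

    def private_flags(self) -> dict[str, bool]:
        """True for haplotypes confined to a single population."""
        return {h: len(set(pops)) == 1 for h, pops in self.populations.items()}


@dataclass
class NeutralityResult:
    n: int
    s: int
    pi: float
    theta_w: float
    tajimas_d: float
    fus_fs: float
    k_haplotypes: int


# ---------------------------------------------------------------------------
# masking and haplotype collapsing


def mask_indel_sites(aln: HaplotypeAlignment, mask_n: bool = True) -> HaplotypeAlignment:
    """Exclude every column containing >=1 gap (and, by default, >=1 N).

    Returns a new alignment whose column mask keeps only pure-substitution
    columns; downstream statistics see kept columns only.
    """
    bad = (aln.sequences == "-").any(axis=0)
    if mask_n:
        bad |= (aln.sequences == "N").any(axis=0)
    mask = aln.column_mask & ~bad
    return HaplotypeAlignment(
        aln.sequences.copy(), list(aln.labels), list(aln.regions), mask
    )


def variable_sites(aln: HaplotypeAlignment) -> list[int]:
    """1-based concatenated positions of kept columns with >=2 distinct bases."""
    positions = []
    for col in np.flatnonzero(aln.column_mask):
        column = aln.sequences[:, col]
        states = set(column) & set(BASES)
        if len(states) >= 2:
            positions.append(int(col) + 1)
    return positions


def collapse_haplotypes(aln: HaplotypeAlignment) -> HaplotypeSet:
    """Group sequences identical on kept columns; ids H1.. by first occurrence."""
    if aln.n_sequences == 0:
        raise ValidationError("empty alignment")
    kept = aln.kept()
    keys: dict[str, int] = {}
    ids: list[str] = []
    reps: list[np.ndarray] = []
    freqs: list[int] = []
    members: dict[str, list[str]] = {}
    pops: dict[str, list[str]] = {}
    for row, (ind, pop) in zip(kept, aln.labels):
        key = "".join(row)
        if key not in keys:
            keys[key] = len(ids)
            hid = f"H{len(ids) + 1}"
            ids.append(hid)
            reps.append(row.copy())
            freqs.append(0)
            members[hid] = []
            pops[hid] = []
        idx = keys[key]
        freqs[idx] += 1
        members[ids[idx]].append(ind)
        pops[ids[idx]].append(pop)
    return HaplotypeSet(
        haplotype_ids=ids,
        representatives=np.asarray(reps),
        frequencies=freqs,
        members=members,
        populations=pops,
        variable_positions=variable_sites(aln),
    )


# ---------------------------------------------------------------------------
# nucleotide diversity and neutrality tests


def pairwise_differences(aln: HaplotypeAlignment) -> np.ndarray:
    """Counts of differing kept columns for every sequence pair."""
    kept = aln.kept()
    n = kept.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (kept[i] != kept[i + 1:]).sum(axis=1)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return d


def nucleotide_stats(aln: HaplotypeAlignment) -> NeutralityResult:
    """n, S, pi, Watterson's theta, Tajima's D and Fu's Fs for an alignment.

    pi is the mean pairwise difference count over kept columns; theta_W =
    S / a1 with a1 = sum_{i<n} 1/i.  Fu's Fs uses theta = pi (the standard
    practice for this statistic).
    """
    n = aln.n_sequences
    if n < 2:
        raise ValidationError("need >=2 sequences")
    s = len(variable_sites(aln))
    d = pairwise_differences(aln)
    pi = float(d[np.triu_indices(n, 1)].mean())
    a1 = sum(1.0 / i for i in range(1, n))
    theta_w = s / a1 if n > 1 else float("nan")
    k = collapse_haplotypes(aln).k
    d_taj = tajimas_d(n, s, pi) if (s >= 1 and n >= 4) else float("nan")
    fs = fus_fs(n, pi, k) if (k > 1 and pi > 0) else float("nan")
    return NeutralityResult(n=n, s=s, pi=pi, theta_w=theta_w,
                            tajimas_d=d_taj, fus_fs=fs, k_haplotypes=k)


def tajimas_d(n: int, s: int, pi: float) -> float:
    """Tajima's D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 for sample
    size n.  Undefined (nan) for S = 0 or n < 4.
    """
    if n < 4:
        raise ValidationError("Tajima's D needs n >= 4")
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1) |s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grown = row + math.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        shifted = np.concatenate(([-np.inf], row[:-1]))
        new = np.logaddexp(grown, shifted)
        row = new
    return row


def fus_fs(n: int, pi: float, k_obs: int) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta = pi).

    The haplotype-count distribution is Ewens':
    P(K = k) = |s(n, k)| theta^k / (theta)_n, evaluated in log space.
    Returns -inf when S' underflows to 1 from below is impossible; emits nan
    for the undefined cases k_obs = 1 or pi = 0.
    """
    if n < 2:
        raise ValidationError("Fu's Fs needs n >= 2")
    if k_obs <= 1 or pi <= 0:
        return float("nan")
    if k_obs > n:
        raise ValidationError(f"k_obs={k_obs} exceeds n={n}")
    log_s = _log_stirling_row(n)
    ks = np.arange(n + 1)
    log_theta = math.log(pi)
    log_terms = log_s + ks * log_theta
    log_denom = sum(math.log(pi + i) for i in range(n))
    log_sp = logsumexp(log_terms[k_obs:]) - log_denom
    # complement via the lower tail for accuracy when S' ~ 1
    log_one_minus = logsumexp(log_terms[1:k_obs]) - log_denom
    if log_sp >= 0.0 or not np.isfinite(log_one_minus):
        return float("-inf")
    return float(log_sp - log_one_minus)


def fus_fs_exact(n: int, theta: float | Fraction, k_obs: int) -> float:
    """Exact-rational evaluation of Fu's Fs (big-int Stirling numbers).

    Slower than :func:`fus_fs`; intended as an independent high-precision
    route for verification and for extreme tails.
    """
    if k_obs <= 1:
        return float("nan")
    th = Fraction(theta)
    if th <= 0:
        return float("nan")
    row = [1]  # |s(0,0)|
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (m - 1) * (row[k] if k < len(row) else 0) + row[k - 1]
        row = new
    denom = Fraction(1)
    for i in range(n):
        denom *= th + i
    upper = sum(Fraction(row[k]) * th**k for k in range(k_obs, n + 1)) / denom
    if upper >= 1:
        return float("-inf")
    return float(math.log(upper) - math.log(1 - upper))


# ---------------------------------------------------------------------------
# statistical parsimony network


def parsimony_probability(j: int, seq_len: int) -> float:
    """Probability that j observed differences reflect exactly j substitutions.

    Model: substitutions hit the ``seq_len`` sites as independent
    Poisson(d) processes with d the Jukes-Cantor distance matching the
    observed per-site difference p = j/m; a connection is parsimonious iff
    every differing site was hit exactly once and no other site was hit at
    all.  Conditioning on j visible differences gives

        P(j) = (d e^-d / p)^j  x  (e^-d / (1 - p))^(m - j)

    which is 1 at j = 0 and non-decreasing in m for fixed j.
    """
    m = seq_len
    if m < 2:
        raise ValidationError("need sequence length >= 2")
    if j == 0:
        return 1.0
    p = j / m
    if p >= 0.75:
        return 0.0
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    log_p = j * (math.log(d) - d - math.log(p)) \
        + (m - j) * (-d - math.log1p(-p))
    return math.exp(log_p)


def parsimony_connection_limit(seq_len: int, confidence: float = 0.95) -> int:
    """Largest number of steps j whose parsimony probability >= confidence."""
    if seq_len < 2:
        raise ValidationError("need sequence length >= 2")
    j = 0
    while j + 1 < seq_len and parsimony_probability(j + 1, seq_len) >= confidence:
        j += 1
    return j


def build_tcs_network(hs: HaplotypeSet, limit: int) -> HaplotypeNetwork:
    """Statistical-parsimony network by agglomerative joining.

    Haplotype pairs are considered in order of increasing Hamming distance
    (on kept columns), up to ``limit`` steps; ties break toward the pair
    with the higher total frequency, then lexicographic ids.  A d-step
    connection inserts d-1 hypothetical nodes so every edge spans exactly
    one mutational step; pairs already connected through earlier joins are
    skipped, and components unreachable within the limit stay disconnected.
    """
    if hs.k == 0:
        raise ValidationError("empty haplotype set")
    ids = hs.haplotype_ids
    freq = dict(zip(ids, hs.frequencies))
    dist: dict[tuple[str, str], int] = {}
    for (i, a), (j, b) in combinations(enumerate(ids), 2):
        d = int((hs.representatives[i] != hs.representatives[j]).sum())
        dist[(a, b)] = d

    candidates = sorted(
        (pair for pair, d in dist.items() if d <= limit),
        key=lambda pair: (dist[pair], -(freq[pair[0]] + freq[pair[1]]), pair),
    )

    parent = {h: h for h in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    nodes = [
        NetworkNode(
            node_id=h,
            frequency=freq[h],
            members=tuple(hs.members[h]),
            populations=tuple(sorted(set(hs.populations[h]))),
            observed=True,
        )
        for h in ids
    ]
    edges: list[tuple[str, str]] = []
    hypo_count = 0
    for a, b in candidates:
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        d = dist[(a, b)]
        chain = [a]
        for _ in range(d - 1):
            hypo_count += 1
            mid = f"m{hypo_count}"
            nodes.append(NetworkNode(node_id=mid, frequency=0, observed=False))
            chain.append(mid)
        chain.append(b)
        edges.extend(zip(chain[:-1], chain[1:]))
    return HaplotypeNetwork(nodes=nodes, edges=edges, connection_limit=limit)


# ---------------------------------------------------------------------------
# NJ tree on sequence p-distances


def sequence_p_distance(aln: HaplotypeAlignment) -> DistanceMatrix:
    """Uncorrected p-distance (proportion of differing kept columns)."""
    kept = aln.kept()
    if kept.shape[1] == 0:
        raise ValidationError("no kept columns")
    d = pairwise_differences(aln) / kept.shape[1]
    labels = [ind for ind, _ in aln.labels]
    return DistanceMatrix(labels, d)


def nj_from_pdistance(
    aln: HaplotypeAlignment, boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """NJ tree on sequence p-distances with bootstrap over kept columns."""
    tree = nj_tree(sequence_p_distance(aln))
    labels = [ind for ind, _ in aln.labels]

    def dist_fn(cols: np.ndarray, lbls: list[str]) -> DistanceMatrix:
        n = cols.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            diff = (cols[i] != cols[i + 1:]).sum(axis=1) / cols.shape[1]
            d[i, i + 1:] = diff
            d[i + 1:, i] = diff
        return DistanceMatrix(lbls, d)

    support = _bootstrap_support(aln.kept(), labels, dist_fn, reps=boot, seed=seed)
    return tree, support
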