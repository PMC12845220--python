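"""Synthetic-data generators with the statistical structure the analyses
assume, so every stage of the toolkit is testable at desk scale.

The default configuration mirrors the study design the toolkit targets:
15 demes of 20 genotyped individuals, diploid throughout except one
autotetraploid deme; four codominant loci differentiated to F ~ 0.12 under
the Balding-Nichols model (deme frequencies Dirichlet-distributed around the
ancestral frequencies with concentration (1-F)/F, giving closed-form expected
F_ST); ~800 dominant fragments scored in quadruplicate with a ~6% flip
error; 61 chloroplast sequences of 1650 positions carrying 28 infinite-sites
mutations on a random genealogy (Kingman coalescent, or star-like to emulate
expansion); and per-cytotype flow-cytometry records around 2C of 1.37 pg
(diploid) and 2.74 pg (tetraploid).

Every generator is a pure function of (config, seed) and returns a truth
record sufficient to recompute the downstream statistics by brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .datamodel import (
    BinaryMarkerMatrix,
    CytometryRecord,
    GenotypeTable,
    HaplotypeAlignment,
    Individual,
    ValidationError,
)

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimConfig:
    seed: int = 0
    n_demes: int = 15
    n_individuals: int = 20
    tetraploid_demes: tuple[int, ...] = (1,)   # 0-based; deme 1 = "population 2"
    n_ssr_loci: int = 4
    n_alleles: int = 9
    fst: float = 0.12
    n_dominant_loci: int = 818
    scoring_error: float = 0.0593
    n_replicates: int = 4
    n_aflp_per_deme: int = 4
    n_sequences: int = 61
    seq_length: int = 1650
    n_mutations: int = 28
    genealogy: str = "coalescent"              # or "star"
    n_gap_columns: int = 0
    fcm_mean_2c: dict[int, float] = field(default_factory=lambda: {2: 1.37, 4: 2.74})
    fcm_sd_2c: dict[int, float] = field(default_factory=lambda: {2: 0.05, 4: 0.11})
    fcm_plants_per_deme: int = 10
    fcm_standard_2c: float = 1.99
    fcm_standard_peak: float = 200.0

    def __post_init__(self) -> None:
        positives = {
            "n_demes": self.n_demes, "n_individuals": self.n_individuals,
            "n_ssr_loci": self.n_ssr_loci, "n_alleles": self.n_alleles,
            "n_dominant_loci": self.n_dominant_loci,
            "n_replicates": self.n_replicates,
            "n_aflp_per_deme": self.n_aflp_per_deme,
            "n_sequences": self.n_sequences, "seq_length": self.seq_length,
            "fcm_plants_per_deme": self.fcm_plants_per_deme,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if not 0.0 < self.fst < 1.0:
            raise ValidationError(f"fst must be in (0, 1), got {self.fst}")
        if not 0.0 <= self.scoring_error < 0.5:
            raise ValidationError(
                f"scoring_error must be in [0, 0.5), got {self.scoring_error}"
            )
        if self.genealogy not in ("coalescent", "star"):
            raise ValidationError(f"unknown genealogy {self.genealogy!r}")
        if self.n_mutations < 0 or self.n_gap_columns < 0:
            raise ValidationError("mutation and gap counts must be >= 0")
        if self.n_mutations + self.n_gap_columns > self.seq_length:
            raise ValidationError("mutations + gap columns exceed sequence length")

    def ploidy_of_deme(self, d: int) -> int:
        return 4 if d in self.tetraploid_demes else 2


def _rng(cfg: SimConfig, seed: int | np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# codominant loci


def simulate_ssr(cfg: SimConfig, seed: int | np.random.Generator | None = None):
    """Balding-Nichols codominant genotypes.

    Ancestral frequencies are Dirichlet(1, ..., 1); deme frequencies are
    Dirichlet(p (1-F)/F), so E[F_ST] = F.  Each individual draws ``ploidy``
    gene copies multinomially from its deme's frequencies.

    Returns ``(GenotypeTable, truth)`` with truth carrying the target F and
    all frequency vectors.
    """
    rng = _rng(cfg, seed)
    scale = (1.0 - cfg.fst) / cfg.fst
    ancestral = []
    deme_freqs = []
    for _ in range(cfg.n_ssr_loci):
        p = rng.dirichlet(np.ones(cfg.n_alleles))
        ancestral.append(p)
        deme_freqs.append(
            np.vstack([
                rng.dirichlet(np.clip(p * scale, 1e-9, None))
                for _ in range(cfg.n_demes)
            ])
        )
    individuals: list[Individual] = []
    calls: list[list[tuple[str, ...] | None]] = []
    labels = [f"a{k}" for k in range(cfg.n_alleles)]
    for d in range(cfg.n_demes):
        ploidy = cfg.ploidy_of_deme(d)
        pop = f"P{d + 1}"
        # draw all gene copies of the deme at once, one locus at a time
        per_locus = [
            rng.choice(cfg.n_alleles, size=(cfg.n_individuals, ploidy),
                       p=deme_freqs[l][d])
            for l in range(cfg.n_ssr_loci)
        ]
        for i in range(cfg.n_individuals):
            row: list[tuple[str, ...] | None] = [
                tuple(sorted(labels[c] for c in per_locus[l][i]))
                for l in range(cfg.n_ssr_loci)
            ]
            individuals.append(Individual(f"ind{d + 1}_{i + 1}", pop, ploidy))
            calls.append(row)
    table = GenotypeTable(individuals, [f"L{l + 1}" for l in range(cfg.n_ssr_loci)],
                          calls)
    truth: dict[str, Any] = {
        "fst": cfg.fst,
        "ancestral_frequencies": ancestral,
        "deme_frequencies": deme_freqs,
    }
    return table, truth


# ---------------------------------------------------------------------------
# dominant loci


def simulate_aflp(cfg: SimConfig, seed: int | np.random.Generator | None = None):
    """Dominant presence/absence profiles with replicate scoring error.

    Per locus, the presence-allele frequency follows Balding-Nichols on a
    biallelic locus (Beta(p (1-F)/F, (1-p) (1-F)/F) around ancestral p);
    a diploid individual shows the fragment with probability 1 - (1-q)^2.
    Each individual contributes ``n_replicates`` profiles whose entries are
    flipped independently with probability ``scoring_error``.

    Returns ``(BinaryMarkerMatrix, truth)``.
    """
    rng = _rng(cfg, seed)
    scale = (1.0 - cfg.fst) / cfg.fst
    p = rng.uniform(0.05, 0.95, size=cfg.n_dominant_loci)
    q = rng.beta(
        np.clip(p * scale, 1e-9, None)[None, :].repeat(cfg.n_demes, axis=0),
        np.clip((1 - p) * scale, 1e-9, None)[None, :].repeat(cfg.n_demes, axis=0),
    )
    presence_prob = 1.0 - (1.0 - q) ** 2

    sizes = rng.choice(np.arange(100, 501), size=cfg.n_dominant_loci, replace=True)
    sample_ids, population_ids, groups, rows = [], [], [], []
    true_profiles = []
    for d in range(cfg.n_demes):
        pop = f"P{d + 1}"
        for i in range(cfg.n_aflp_per_deme):
            true = (rng.random(cfg.n_dominant_loci) < presence_prob[d]).astype(np.int8)
            true_profiles.append(true)
            gid = f"ind{d + 1}_{i + 1}"
            for r in range(cfg.n_replicates):
                flips = rng.random(cfg.n_dominant_loci) < cfg.scoring_error
                profile = np.where(flips, 1 - true, true).astype(np.int8)
                sample_ids.append(f"{gid}_r{r + 1}")
                population_ids.append(pop)
                groups.append(gid)
                rows.append(profile)
    matrix = BinaryMarkerMatrix(
        sample_ids=sample_ids,
        population_ids=population_ids,
        replicate_groups=groups,
        # ids end with the size in bp, the convention the reader parses
        fragment_ids=[f"frag{k}_{s}" for k, s in enumerate(sizes)],
        fragment_sizes=[int(s) for s in sizes],
        values=np.asarray(rows, dtype=np.int8),
    )
    truth = {
        "scoring_error": cfg.scoring_error,
        "presence_prob": presence_prob,
        "true_profiles": np.asarray(true_profiles),
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# chloroplast sequences


def _kingman_genealogy(n: int, rng: np.random.Generator):
    """Random Kingman coalescent: returns (parent, branch_length) arrays.

    Nodes 0..n-1 are leaves; node 2n-2 is the root.  Times are in coalescent
    units (pairwise coalescence rate 1 per pair).
    """
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    blen = np.zeros(2 * n - 1)
    for v in range(2 * n - 2):
        blen[v] = node_time[parent[v]] - node_time[v]
    return parent, blen


def _star_genealogy(n: int):
    """Star tree: every leaf hangs from the root by a unit branch."""
    parent = np.full(n + 1, -1, dtype=int)
    parent[:n] = n
    blen = np.zeros(n + 1)
    blen[:n] = 1.0
    return parent, blen


def simulate_cpdna(cfg: SimConfig, seed: int | np.random.Generator | None = None):
    """Haplotype sequences on a random genealogy under infinite sites.

    ``cfg.n_mutations`` mutations are placed multinomially in proportion to
    branch length, each on its own alignment column (infinite sites), with
    the derived base differing from the ancestral one.  With
    ``genealogy="star"`` the tree is star-like, emulating a sudden-expansion
    history.  Optional gap columns (a '-' in one random row each) exercise
    indel masking without touching mutated columns.

    Returns ``(HaplotypeAlignment, truth)``; truth records the genealogy,
    mutation columns, the per-leaf mutation sets and the implied haplotype
    partition.
    """
    rng = _rng(cfg, seed)
    n = cfg.n_sequences
    if cfg.genealogy == "coalescent":
        parent, blen = _kingman_genealogy(n, rng)
    else:
        parent, blen = _star_genealogy(n)
    n_nodes = len(parent)
    root = n_nodes - 1

    # place mutations on branches ~ multinomial(branch length)
    probs = blen[:root] / blen[:root].sum()
    mut_branch = rng.choice(root, size=cfg.n_mutations, p=probs)

    positions = rng.choice(cfg.seq_length, size=cfg.n_mutations + cfg.n_gap_columns,
                           replace=False)
    mut_cols = positions[:cfg.n_mutations]
    gap_cols = positions[cfg.n_mutations:]

    ancestral = BASES[rng.integers(0, 4, size=cfg.seq_length)]
    seqs = np.tile(ancestral, (n, 1))

    # leaves below each branch
    children: dict[int, list[int]] = {}
    for v in range(root):
        children.setdefault(int(parent[v]), []).append(v)

    def leaves_below(v: int) -> list[int]:
        if v < n:
            return [v]
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.extend(children.get(u, []))
        return out

    mut_sets: list[set[int]] = [set() for _ in range(n)]
    for m, (branch, col) in enumerate(zip(mut_branch, mut_cols)):
        old = ancestral[col]
        new = rng.choice([b for b in BASES if b != old])
        for leaf in leaves_below(int(branch)):
            seqs[leaf, col] = new
            mut_sets[leaf].add(m)

    for col in gap_cols:
        row = rng.integers(0, n)
        seqs[row, col] = "-"

    labels = [(f"seq{i + 1}", f"P{i % cfg.n_demes + 1}") for i in range(n)]
    aln = HaplotypeAlignment(seqs, labels, [("sim", 1, cfg.seq_length)])

    partition: dict[frozenset[int], list[int]] = {}
    for leaf, ms in enumerate(mut_sets):
        partition.setdefault(frozenset(ms), []).append(leaf)
    truth = {
        "parent": parent,
        "branch_lengths": blen,
        "mutation_columns": mut_cols,
        "gap_columns": gap_cols,
        "mutation_sets": mut_sets,
        "n_haplotypes": len(partition),
        "segregating_sites": sum(
            0 < len(leaves_below(int(b))) < n for b in mut_branch
        ),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# flow cytometry


def simulate_fcm(cfg: SimConfig, seed: int | np.random.Generator | None = None):
    """Per-plant cytometry records: 2C ~ Normal(cytotype mean, SD), > 0.

    Fluorescence peaks are backed out of the simulated 2C against the
    internal standard, so :func:`dinpop.cytometry.compute_2c` recovers the
    generated value exactly.
    """
    rng = _rng(cfg, seed)
    records: list[CytometryRecord] = []
    for d in range(cfg.n_demes):
        ploidy = cfg.ploidy_of_deme(d)
        mean = cfg.fcm_mean_2c[ploidy]
        sd = cfg.fcm_sd_2c[ploidy]
        pop = f"P{d + 1}"
        for i in range(cfg.fcm_plants_per_deme):
            two_c = -1.0
            while two_c <= 0:
                two_c = rng.normal(mean, sd) if sd > 0 else mean
            records.append(
                CytometryRecord(
                    plant_id=f"plant{d + 1}_{i + 1}",
                    population_id=pop,
                    sample_peak_mean=cfg.fcm_standard_peak * two_c / cfg.fcm_standard_2c,
                    standard_peak_mean=cfg.fcm_standard_peak,
                    standard_2c=cfg.fcm_standard_2c,
                    ploidy=ploidy,
                )
            )
    return records
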