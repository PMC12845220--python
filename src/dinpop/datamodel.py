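"""Shared domain types for the multi-marker toolkit.

The containers here are deliberately thin: validated dataclasses around numpy
arrays and plain Python structures, shaped after the four marker systems the
toolkit analyses (codominant microsatellites with mixed ploidy, dominant
presence/absence fingerprints with replicates, aligned chloroplast spacers,
and flow-cytometry fluorescence records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING_TOKENS = {"", "?", "NA", "na", "-", "."}

#: picograms -> megabase pairs (1 pg of double-stranded DNA ~ 978 Mbp)
PG_TO_MBP = 978.0


class ValidationError(ValueError):
    """Malformed input data; the message locates the offending row/column."""


@dataclass(frozen=True)
class PopulationSample:
    """Sampling-site metadata with per-marker-system sample sizes."""

    population_id: int
    locality: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    altitude: float = float("nan")
    sample_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.sample_counts.items():
            if n < 0:
                raise ValidationError(f"negative sample count {n} for {key}")


@dataclass(frozen=True)
class Individual:
    individual_id: str
    population_id: str
    ploidy: int

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValidationError(
                f"individual {self.individual_id}: ploidy must be 2 or 4, "
                f"got {self.ploidy}"
            )


@dataclass
class GenotypeTable:
    """Codominant genotypes: individuals x loci, multiset allele calls.

    ``calls[i][j]`` is a sorted tuple of allele labels with length equal to the
    individual's ploidy, or ``None`` for missing.  Allele labels are opaque
    strings (fragment sizes) compared by exact equality.  Tetraploid cells
    whose written genotype listed fewer than four alleles are expanded to four
    copies upstream; the (row, column) pairs affected are recorded in
    ``dosage_ambiguous`` so frequency estimation can flag or reweight them.
    """

    individuals: list[Individual]
    loci: list[str]
    calls: list[list[tuple[str, ...] | None]]
    dosage_ambiguous: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.individuals):
            raise ValidationError("calls row count != number of individuals")
        for i, (ind, row) in enumerate(zip(self.individuals, self.calls)):
            if len(row) != len(self.loci):
                raise ValidationError(
                    f"row {ind.individual_id}: {len(row)} calls for "
                    f"{len(self.loci)} loci"
                )
            for j, call in enumerate(row):
                if call is not None and len(call) != ind.ploidy:
                    raise ValidationError(
                        f"row {ind.individual_id}, locus {self.loci[j]}: "
                        f"call has {len(call)} alleles, ploidy is {ind.ploidy}"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population_id, None)
        return list(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def individuals_in(self, population: str | None) -> list[int]:
        """Row indices of a population, or all rows when ``population=None``."""
        if population is None:
            return list(range(self.n_individuals))
        idx = [
            i for i, ind in enumerate(self.individuals)
            if ind.population_id == population
        ]
        if not idx:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def subset(self, populations: Sequence[str]) -> "GenotypeTable":
        keep = [
            i for i, ind in enumerate(self.individuals)
            if ind.population_id in set(populations)
        ]
        remap = {i: k for k, i in enumerate(keep)}
        amb = frozenset(
            (remap[i], j) for (i, j) in self.dosage_ambiguous if i in remap
        )
        return GenotypeTable(
            individuals=[self.individuals[i] for i in keep],
            loci=list(self.loci),
            calls=[self.calls[i] for i in keep],
            dosage_ambiguous=amb,
        )


@dataclass
class BinaryMarkerMatrix:
    """Dominant presence/absence matrix with replicate grouping.

    ``values`` is an int8 array: 1 present, 0 absent, -1 missing.  Rows carry
    (sample_id, population_id, replicate_group_id); replicate groups tie the
    repeated profiles of one biological sample together for error estimation.
    """

    sample_ids: list[str]
    population_ids: list[str]
    replicate_groups: list[str]
    fragment_ids: list[str]
    fragment_sizes: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = self.values.shape
        if not (len(self.sample_ids) == len(self.population_ids)
                == len(self.replicate_groups) == n):
            raise ValidationError("row metadata lengths disagree with values")
        if not (len(self.fragment_ids) == len(self.fragment_sizes) == m):
            raise ValidationError("column metadata lengths disagree with values")
        bad = ~np.isin(self.values, (-1, 0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary value at row {self.sample_ids[i]}, "
                f"fragment {self.fragment_ids[j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


@dataclass
class HaplotypeAlignment:
    """Aligned sequences over {A,C,G,T,-,N} with a kept-column mask.

    ``sequences`` is an (n, L) array of single characters.  ``column_mask`` is
    True for columns retained for analysis; indel/ambiguity masking flips it.
    ``regions`` records per-region provenance as (region_id, start, end) in
    1-based closed coordinates of the concatenated alignment.
    """

    sequences: np.ndarray
    labels: list[tuple[str, str]]  # (individual_id, population_id)
    regions: list[tuple[str, int, int]]
    column_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="<U1")
        if self.sequences.ndim != 2:
            raise ValidationError("sequences must be a 2-D character matrix")
        n, L = self.sequences.shape
        if len(self.labels) != n:
            raise ValidationError("label count disagrees with sequence count")
        if self.column_mask is None:
            self.column_mask = np.ones(L, dtype=bool)
        self.column_mask = np.asarray(self.column_mask, dtype=bool)
        if self.column_mask.shape != (L,):
            raise ValidationError("column_mask length disagrees with alignment")
        cov = np.zeros(L, dtype=int)
        for _, start, end in self.regions:
            if not (1 <= start <= end <= L):
                raise ValidationError(f"region interval ({start},{end}) outside 1..{L}")
            cov[start - 1:end] += 1
        if self.regions and not (cov == 1).all():
            raise ValidationError("regions must tile the alignment exactly once")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def kept(self) -> np.ndarray:
        """The (n, n_kept) sub-matrix of retained columns."""
        return self.sequences[:, self.column_mask]

    def region_of(self, column: int) -> tuple[str, int]:
        """Map a 1-based concatenated column to its (region_id, region column)."""
        for region_id, start, end in self.regions:
            if start <= column <= end:
                return region_id, column - start + 1
        raise KeyError(f"column {column} not covered by any region")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape disagrees with labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            atol=1e-12,
        ):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass
class ClusterLikelihoodTrace:
    """Replicate log-likelihoods L(K) from an external Bayesian clustering run."""

    runs: dict[int, list[float]]

    def ks(self) -> list[int]:
        return sorted(self.runs)

    def validate_for_delta_k(self) -> None:
        ks = self.ks()
        if len(ks) < 3:
            raise ValidationError("Evanno dK needs >=3 consecutive K values")
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValidationError(f"K values not consecutive: {ks}")
        for k, vals in self.runs.items():
            if len(vals) < 2:
                raise ValidationError(f"K={k}: Evanno dK needs >=2 runs per K")


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    frequency: int
    members: tuple[str, ...] = ()
    populations: tuple[str, ...] = ()
    observed: bool = True


@dataclass
class HaplotypeNetwork:
    """Statistical-parsimony network: observed + hypothetical nodes, 1-step edges."""

    nodes: list[NetworkNode]
    edges: list[tuple[str, str]]
    connection_limit: int

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValidationError("duplicate node ids in network")
        for u, v in self.edges:
            if u not in ids or v not in ids:
                raise ValidationError(f"edge ({u},{v}) references unknown node")

    @property
    def observed_frequency_total(self) -> int:
        return sum(n.frequency for n in self.nodes if n.observed)


@dataclass
class CytometryRecord:
    """One plant's flow-cytometry measurement against an internal standard."""

    plant_id: str
    population_id: str
    sample_peak_mean: float
    standard_peak_mean: float
    standard_2c: float = 1.99
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.sample_peak_mean <= 0 or self.standard_peak_mean <= 0:
            raise ValidationError(
                f"plant {self.plant_id}: fluorescence peaks must be positive"
            )
        if self.ploidy not in (2, 4):
            raise ValidationError(f"plant {self.plant_id}: ploidy must be 2 or 4")

    @property
    def derived_2c(self) -> float:
        return self.standard_2c * self.sample_peak_mean / self.standard_peak_mean

    @property
    def derived_1cx(self) -> float:
        return self.derived_2c / self.ploidy

    @property
    def derived_1cx_mbp(self) -> float:
        return self.derived_1cx * PG_TO_MBP
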