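"""Readers and writers for the delimited-text, FASTA, Newick, NEXUS and
GraphML formats the toolkit consumes and produces.

All readers reject malformed input with errors that name the offending
row/column; all writers round-trip (re-reading reproduces the structure).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    MISSING_TOKENS,
    BinaryMarkerMatrix,
    ClusterLikelihoodTrace,
    DistanceMatrix,
    GenotypeTable,
    HaplotypeAlignment,
    HaplotypeNetwork,
    Individual,
    ValidationError,
)

log = logging.getLogger(__name__)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


# ---------------------------------------------------------------------------
# codominant genotypes


def _expand_dosage(alleles: list[str], ploidy: int) -> tuple[str, ...]:
    """Expand 1..ploidy listed alleles to exactly ``ploidy`` copies.

    Copies are distributed as evenly as possible; the remainder goes to the
    earliest-listed alleles (largest-remainder rule), which makes the
    expansion deterministic given the written order.
    """
    k = len(alleles)
    base, rem = divmod(ploidy, k)
    out: list[str] = []
    for i, a in enumerate(alleles):
        out.extend([a] * (base + (1 if i < rem else 0)))
    return tuple(sorted(out))


def read_genotype_table(path: str | Path, ploidy_map: dict[str, int]) -> GenotypeTable:
    """Read a delimited genotype table (header: id, population, then loci).

    Cells hold '/'-separated allele labels.  Diploid cells must list exactly
    two alleles; tetraploid cells may list one to four distinct alleles
    (electropherograms cannot resolve dosage) and are expanded to four copies
    by the largest-remainder rule, with the cell flagged dosage-ambiguous
    whenever fewer than four were written.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    if len(header) < 3:
        raise ValidationError(f"{path}: header must be id, population, loci...")
    loci = header[2:]

    individuals: list[Individual] = []
    calls: list[list[tuple[str, ...] | None]] = []
    ambiguous: set[tuple[int, int]] = set()
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{row_no}: {len(fields)} fields, expected {len(header)}"
            )
        ind_id, pop = fields[0], fields[1]
        if pop not in ploidy_map:
            raise ValidationError(
                f"{path}:{row_no}: unknown population {pop!r} (not in ploidy map)"
            )
        ploidy = ploidy_map[pop]
        i = len(individuals)
        row: list[tuple[str, ...] | None] = []
        for j, cell in enumerate(fields[2:]):
            if cell in MISSING_TOKENS:
                row.append(None)
                continue
            alleles = [a for a in cell.split("/") if a]
            if ploidy == 2:
                if len(alleles) != 2:
                    raise ValidationError(
                        f"{path}:{row_no} (individual {ind_id}), locus "
                        f"{loci[j]}: {len(alleles)} alleles for diploid call"
                    )
                row.append(tuple(sorted(alleles)))
            else:
                if not 1 <= len(alleles) <= 4:
                    raise ValidationError(
                        f"{path}:{row_no} (individual {ind_id}), locus "
                        f"{loci[j]}: {len(alleles)} alleles for tetraploid call"
                    )
                if len(alleles) < 4:
                    ambiguous.add((i, j))
                row.append(_expand_dosage(alleles, 4))
        individuals.append(Individual(ind_id, pop, ploidy))
        calls.append(row)
    return GenotypeTable(individuals, loci, calls, frozenset(ambiguous))


def write_genotype_table(table: GenotypeTable, path: str | Path, delim: str = ",") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delim.join(["individual", "population", *table.loci]) + "\n")
        for ind, row in zip(table.individuals, table.calls):
            cells = ["?" if c is None else "/".join(c) for c in row]
            fh.write(delim.join([ind.individual_id, ind.population_id, *cells]) + "\n")


# ---------------------------------------------------------------------------
# dominant presence/absence matrix


def read_binary_matrix(
    path: str | Path, min_bp: int = 100, max_bp: int = 500
) -> BinaryMarkerMatrix:
    """Read a dominant marker matrix; drop fragments outside [min_bp, max_bp].

    Header: sample, population, replicate_group, then fragment columns whose
    names end in the fragment size in bp (e.g. ``frag_150`` or ``150``).
    Values in {0, 1, ?}.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(delim)]
    if len(header) < 4:
        raise ValidationError(
            f"{path}: header must be sample, population, replicate_group, fragments..."
        )
    frag_names = header[3:]
    sizes: list[int] = []
    for name in frag_names:
        m = re.search(r"(\d+)\s*$", name)
        if not m:
            raise ValidationError(f"{path}: fragment column {name!r} has no size")
        sizes.append(int(m.group(1)))
    keep = [i for i, s in enumerate(sizes) if min_bp <= s <= max_bp]
    dropped = len(sizes) - len(keep)
    if dropped:
        log.info("read_binary_matrix: dropped %d fragments outside [%d, %d] bp",
                 dropped, min_bp, max_bp)

    sample_ids, population_ids, groups, rows = [], [], [], []
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != len(header):
            raise ValidationError(
                f"{path}:{row_no}: {len(fields)} fields, expected {len(header)}"
            )
        sample_ids.append(fields[0])
        population_ids.append(fields[1])
        groups.append(fields[2])
        vals = []
        for j in keep:
            cell = fields[3 + j]
            if cell in MISSING_TOKENS:
                vals.append(-1)
            elif cell in ("0", "1"):
                vals.append(int(cell))
            else:
                raise ValidationError(
                    f"{path}:{row_no}, fragment {frag_names[j]}: "
                    f"non-binary value {cell!r}"
                )
        rows.append(vals)
    values = np.asarray(rows, dtype=np.int8)
    all_missing = (values == -1).all(axis=0)
    if all_missing.any():
        log.warning("read_binary_matrix: %d all-missing fragment columns retained",
                    int(all_missing.sum()))
    return BinaryMarkerMatrix(
        sample_ids=sample_ids,
        population_ids=population_ids,
        replicate_groups=groups,
        fragment_ids=[frag_names[i] for i in keep],
        fragment_sizes=[sizes[i] for i in keep],
        values=values,
    )


def write_binary_matrix(m: BinaryMarkerMatrix, path: str | Path, delim: str = ",") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delim.join(["sample", "population", "replicate_group",
                             *m.fragment_ids]) + "\n")
        for i in range(m.n_samples):
            cells = ["?" if v == -1 else str(int(v)) for v in m.values[i]]
            fh.write(delim.join([m.sample_ids[i], m.population_ids[i],
                                 m.replicate_groups[i], *cells]) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments


def _parse_fasta_label(raw: str) -> tuple[str, str]:
    """Split ``individual|population`` record ids; population defaults to NA."""
    if "|" in raw:
        ind, pop = raw.split("|", 1)
        return ind, pop
    return raw, "NA"


def read_fasta_alignment(paths: list[str | Path]) -> HaplotypeAlignment:
    """Read one aligned FASTA per region and concatenate in the given order.

    Region ids are file stems.  All sequences within a region must have equal
    length, and every region must contain the same set of sequence labels;
    rows are ordered by the first region's label order.
    """
    if not paths:
        raise ValidationError("no FASTA paths given")
    regions: list[tuple[str, dict[str, str]]] = []
    for p in paths:
        p = Path(p)
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(p), "fasta")}
        if not records:
            raise ValidationError(f"{p}: no sequences")
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"{p}: unequal sequence lengths within region: {sorted(lengths)}"
            )
        regions.append((p.stem, records))

    ref_labels = list(regions[0][1])
    ref_set = set(ref_labels)
    for region_id, records in regions[1:]:
        if set(records) != ref_set:
            only = sorted(set(records) ^ ref_set)
            raise ValidationError(
                f"region {region_id}: label sets differ; unmatched labels: {only}"
            )

    region_spans: list[tuple[str, int, int]] = []
    pos = 0
    rows = {label: [] for label in ref_labels}
    for region_id, records in regions:
        L = len(next(iter(records.values())))
        region_spans.append((region_id, pos + 1, pos + L))
        pos += L
        for label in ref_labels:
            rows[label].append(records[label])

    seq_matrix = np.array(
        [list("".join(rows[label])) for label in ref_labels], dtype="<U1"
    )
    labels = [_parse_fasta_label(l) for l in ref_labels]
    return HaplotypeAlignment(seq_matrix, labels, region_spans)


# ---------------------------------------------------------------------------
# trees, networks, distance matrices


def write_tree(tree, path: str | Path | None = None, support: dict | None = None,
               min_support: float = 50.0) -> str:
    """Serialise a tree to Newick; supports below ``min_support`` % are hidden.

    ``tree`` is a :class:`dinpop.trees.Tree`; ``support`` maps bipartitions
    (frozensets of leaf labels) to percentages.
    """
    newick = tree.to_newick(support=support, min_support=min_support)
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


def write_network(net: HaplotypeNetwork, path_prefix: str | Path | None = None):
    """Export a haplotype network as node/edge tables plus GraphML.

    Returns ``(nodes_df, edges_df)``; with ``path_prefix`` given, writes
    ``<prefix>_nodes.csv``, ``<prefix>_edges.csv`` and ``<prefix>.graphml``.
    """
    import networkx as nx

    if not net.nodes:
        raise ValidationError("cannot export an empty network")
    nodes_df = pd.DataFrame(
        {
            "node_id": [n.node_id for n in net.nodes],
            "frequency": [n.frequency for n in net.nodes],
            "observed": [n.observed for n in net.nodes],
            "members": [";".join(n.members) for n in net.nodes],
            "populations": [";".join(n.populations) for n in net.nodes],
        }
    )
    edges_df = pd.DataFrame(net.edges, columns=["source", "target"])
    if path_prefix is not None:
        prefix = Path(path_prefix)
        nodes_df.to_csv(prefix.with_name(prefix.name + "_nodes.csv"), index=False)
        edges_df.to_csv(prefix.with_name(prefix.name + "_edges.csv"), index=False)
        g = nx.Graph(connection_limit=net.connection_limit)
        for n in net.nodes:
            g.add_node(n.node_id, frequency=n.frequency, observed=n.observed,
                       members=";".join(n.members),
                       populations=";".join(n.populations))
        g.add_edges_from(net.edges)
        nx.write_graphml(g, prefix.with_suffix(".graphml"))
    return nodes_df, edges_df


def write_nexus_distances(dm: DistanceMatrix, path: str | Path | None = None) -> str:
    """Render a NEXUS Distances block (lower-triangle with diagonal).

    The output feeds external split-network software; round-trips through
    :func:`read_nexus_distances`.
    """
    n = dm.n
    lines = [
        "#NEXUS",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={n};",
        "TAXLABELS",
        *[f"  [{i + 1}] '{label}'" for i, label in enumerate(dm.labels)],
        ";",
        "END;",
        "BEGIN Distances;",
        f"DIMENSIONS ntax={n};",
        "FORMAT labels=left diagonal triangle=lower;",
        "MATRIX",
    ]
    for i in range(n):
        row = " ".join(format(dm.values[i, j], ".17g") for j in range(i + 1))
        lines.append(f"  '{dm.labels[i]}' {row}")
    lines += [";", "END;"]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_nexus_distances(source: str | Path) -> DistanceMatrix:
    """Parse the NEXUS Distances block written by :func:`write_nexus_distances`."""
    text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
    labels: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.upper().startswith("MATRIX"):
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                break
            m = re.match(r"'([^']*)'\s*(.*)$", stripped)
            if not m:
                raise ValidationError(f"unparseable distance row: {stripped!r}")
            labels.append(m.group(1))
            rows.append([float(x) for x in m.group(2).split()])
    n = len(labels)
    values = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValidationError(f"row {labels[i]}: expected {i + 1} entries")
        for j, v in enumerate(row):
            values[i, j] = values[j, i] = v
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# external clustering logs


_LNPROB_RE = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?[\d.]+)")
_K_RE = re.compile(r"(\d+)\s+populations assumed")


def read_cluster_runs(paths: list[str | Path]) -> ClusterLikelihoodTrace:
    """Collect L(K) from external clustering result files.

    Each file must contain the standard summary lines ``N populations
    assumed`` and ``Estimated Ln Prob of Data = ...``.
    """
    runs: dict[int, list[float]] = {}
    for p in paths:
        text = Path(p).read_text()
        k_match = _K_RE.search(text)
        l_match = _LNPROB_RE.search(text)
        if not k_match or not l_match:
            raise ValidationError(f"{p}: missing K or Ln Prob summary line")
        runs.setdefault(int(k_match.group(1)), []).append(float(l_match.group(1)))
    return ClusterLikelihoodTrace(runs)


def read_cluster_table(path: str | Path) -> ClusterLikelihoodTrace:
    """Read a two-column delimited table K, lnP (one row per replicate run)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need columns K, lnP")
    runs: dict[int, list[float]] = {}
    for k, lnp in zip(df.iloc[:, 0], df.iloc[:, 1]):
        runs.setdefault(int(k), []).append(float(lnp))
    return ClusterLikelihoodTrace(runs)
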