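"""Readers and writers for every external representation the pipeline touches.

Formats handled: TSV expression matrices with time-encoding headers, simple
edge-list TSV and PSI-MI TAB 2.5/2.7 interaction files, node-label tables,
GMT gene-set collections, event-annotation TSV (one genomic interval per
row) and BED6 output for splicing events.

Genomic coordinates are 0-based half-open everywhere internally; BED is
emitted natively and any 1-based inputs must be converted at the boundary.
Node identifiers are opaque strings: no Entrez/symbol mapping is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseMatrix",
    "LabelledNetwork",
    "GeneSetCollection",
    "GenomicInterval",
    "EventAnnotation",
    "FormatError",
    "read_timecourse",
    "write_timecourse",
    "read_network",
    "write_network",
    "read_gmt",
    "read_event_annotations",
    "read_event_quantifications",
    "write_event_quantifications",
    "write_events_bed",
]


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeCourseMatrix:
    """Genes x ordered sampling times, log2 expression values.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers.
    times_h : ndarray
        Strictly increasing sampling times in hours, one per column.
    values : ndarray
        log2 expression, shape ``(len(gene_ids), len(times_h))``.
    """

    gene_ids: list
    times_h: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {', '.join(map(str, dupes))}")
        if self.times_h.ndim != 1 or len(self.times_h) == 0:
            raise ValueError("times_h must be a non-empty 1-D sequence")
        if not np.all(np.diff(self.times_h) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.values.shape != (len(self.gene_ids), len(self.times_h)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.times_h)} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"T{t:02g}" for t in self.times_h]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass
class LabelledNetwork:
    """Undirected deduplicated interaction network with node-set labels.

    Wraps a :class:`networkx.Graph`; each node carries a ``labels``
    attribute, a frozenset drawn from the configured label vocabulary
    (typically SF / NCRG / ASG). Self-loops are dropped at construction.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        labels: Mapping[str, Iterable[str]] | None = None,
        extra_nodes: Iterable[str] = (),
    ) -> "LabelledNetwork":
        g = nx.Graph()
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
        for n in extra_nodes:
            g.add_node(n)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        labels = labels or {}
        for n in g.nodes:
            g.nodes[n]["labels"] = frozenset(labels.get(n, ()))
        for n in labels:
            if n not in g:
                logger.warning("label for absent node %r ignored", n)
        return cls(g)

    def labels_of(self, node: str) -> frozenset:
        return self.graph.nodes[node]["labels"]

    def nodes_with_label(self, label: str) -> set:
        return {n for n, d in self.graph.nodes(data=True) if label in d["labels"]}

    def labels_present(self) -> set:
        out: set = set()
        for _, d in self.graph.nodes(data=True):
            out |= set(d["labels"])
        return out

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-style)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def span(self) -> int:
        return self.end - self.start


@dataclass
class EventAnnotation:
    """Structure of one alternative-splicing event.

    The inclusion and exclusion paths are alternative sets of exonic
    intervals; ``flank_intervals`` are shared by both paths. Intervals are
    kept in genomic order regardless of strand.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    path_inclusion: list
    path_exclusion: list
    flank_intervals: list

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for iv in [*self.path_inclusion, *self.path_exclusion, *self.flank_intervals]:
            if iv.chrom != self.chrom:
                raise ValueError(
                    f"interval chrom {iv.chrom} differs from event chrom {self.chrom}"
                )
        self.path_inclusion = sorted(self.path_inclusion)
        self.path_exclusion = sorted(self.path_exclusion)
        self.flank_intervals = sorted(self.flank_intervals)
        if set(self.path_inclusion) == set(self.path_exclusion):
            raise ValueError(
                f"event {self.event_id}: inclusion and exclusion paths are identical"
            )

    def span(self) -> GenomicInterval:
        ivs = [*self.path_inclusion, *self.path_exclusion, *self.flank_intervals]
        return GenomicInterval(self.chrom, min(i.start for i in ivs), max(i.end for i in ivs))


# ---------------------------------------------------------------------------
# Time-course matrices
# ---------------------------------------------------------------------------

DEFAULT_TIME_PATTERN = r"T(\d+(?:\.\d+)?)"


def _parse_time_header(header: str, pattern: str) -> float:
    m = re.fullmatch(pattern, header)
    if m is None:
        raise FormatError(
            f"column header {header!r} does not match time pattern {pattern!r}"
        )
    return float(m.group(1))


def read_timecourse(path, time_header_pattern: str = DEFAULT_TIME_PATTERN) -> TimeCourseMatrix:
    """Read a TSV expression matrix whose column headers encode hours.

    The first column holds gene identifiers; every remaining header must
    match ``time_header_pattern`` with the hour value in group 1 (e.g.
    ``T06`` ... ``T30``). Columns are sorted by parsed time.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene-id column plus time columns")
    gene_col = df.columns[0]
    times = [_parse_time_header(c, time_header_pattern) for c in df.columns[1:]]
    order = np.argsort(times)
    time_cols = [df.columns[1:][i] for i in order]
    gene_ids = df[gene_col].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicated gene id(s): {', '.join(dupes)}")
    values = np.empty((len(gene_ids), len(time_cols)))
    for j, col in enumerate(time_cols):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row}"
            ) from exc
    return TimeCourseMatrix(gene_ids, np.asarray(times)[order], values)


def write_timecourse(matrix: TimeCourseMatrix, path, gene_col: str = "gene_id") -> None:
    """Write a TimeCourseMatrix as TSV with ``T<hh>`` headers (full precision)."""
    headers = [gene_col] + [_format_time_header(t) for t in matrix.times_h]
    with open(path, "w") as fh:
        fh.write("\t".join(headers) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def _format_time_header(t: float) -> str:
    if float(t).is_integer():
        return f"T{int(t):02d}"
    return f"T{t}"


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_PSIMITAB_ID = re.compile(r"^[^:]+:(.+)$")


def _psimitab_identifier(fieldval: str) -> str:
    """Strip the namespace prefix from a PSI-MI TAB identifier field."""
    fieldval = fieldval.strip()
    primary = fieldval.split("|")[0]
    m = _PSIMITAB_ID.match(primary)
    if m is None:
        raise FormatError(f"malformed PSI-MI TAB identifier field: {fieldval!r}")
    return m.group(1).strip('"')


def _read_edge_lines(path, dialect: str):
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "simple_tsv":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
                edges.append((fields[0].strip(), fields[1].strip()))
            else:  # psimitab
                if fields[0].startswith(("ID(", "#ID", "ID interactor")):
                    continue  # header line of MITAB 2.5/2.7 exports
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected >=2 PSI-MI TAB columns")
                edges.append(
                    (_psimitab_identifier(fields[0]), _psimitab_identifier(fields[1]))
                )
    return edges


def read_node_labels(path) -> dict:
    """Read a node-label TSV: ``node<TAB>label[,label...]`` per line."""
    labels: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'node<TAB>labels'")
            node = fields[0].strip()
            labs = {l.strip() for l in re.split(r"[,|]", fields[1]) if l.strip()}
            labels.setdefault(node, set()).update(labs)
    return labels


def read_network(
    edges_path,
    labels_path=None,
    dialect: str = "simple_tsv",
    keep_unlabelled: bool = True,
) -> LabelledNetwork:
    """Load an undirected, deduplicated network with node-set labels.

    Parameters
    ----------
    edges_path
        Two-column TSV (``simple_tsv``) or PSI-MI TAB 2.5/2.7 file
        (``psimitab``; only interactor columns 1-2 are used).
    labels_path
        Optional node → label(s) TSV. Labels for absent nodes produce a
        warning, never an error.
    keep_unlabelled
        If False, nodes without any label are dropped (count logged).
    """
    if dialect not in {"simple_tsv", "psimitab"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    edges = _read_edge_lines(edges_path, dialect)
    labels = read_node_labels(labels_path) if labels_path is not None else {}
    net = LabelledNetwork.from_edges(edges, labels)
    if not keep_unlabelled:
        bare = [n for n in net.graph.nodes if not net.graph.nodes[n]["labels"]]
        if bare:
            logger.info("dropped %d unlabelled node(s)", len(bare))
            net.graph.remove_nodes_from(bare)
    return net


def write_network(net: LabelledNetwork, edges_path, labels_path=None) -> None:
    """Write edges as two-column TSV (canonical order) and labels as TSV."""
    with open(edges_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for n in sorted(net.graph.nodes):
                labs = sorted(net.graph.nodes[n]["labels"])
                if labs:
                    fh.write(f"{n}\t{','.join(labs)}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, members, tab-separated."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Event annotations and probe-level quantifications
# ---------------------------------------------------------------------------


def read_event_annotations(path) -> dict:
    """Read event-annotation TSV, one interval per row.

    Columns: event_id, gene_id, chrom, strand, path (incl/excl/flank),
    start, end. Returns ``{event_id: EventAnnotation}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"event_id", "gene_id", "chrom", "strand", "path", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    out: dict = {}
    for event_id, grp in df.groupby("event_id", sort=False):
        paths: dict = {"incl": [], "excl": [], "flank": []}
        for _, row in grp.iterrows():
            if row["path"] not in paths:
                raise FormatError(
                    f"{path}: event {event_id}: path must be incl/excl/flank, "
                    f"got {row['path']!r}"
                )
            paths[row["path"]].append(
                GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            )
        out[event_id] = EventAnnotation(
            event_id=event_id,
            gene_id=grp["gene_id"].iloc[0],
            chrom=grp["chrom"].iloc[0],
            strand=grp["strand"].iloc[0],
            path_inclusion=paths["incl"],
            path_exclusion=paths["excl"],
            flank_intervals=paths["flank"],
        )
    return out


def read_event_quantifications(path, time_header_pattern: str = DEFAULT_TIME_PATTERN):
    """Read probe-level event quantifications.

    TSV columns: event_id, path (incl/excl), probe_id, then one log2
    intensity column per sample with a time-encoding header. Returns
    ``(DataFrame, times_h)`` with time columns sorted ascending.
    """
    df = pd.read_csv(path, sep="\t")
    meta = ["event_id", "path", "probe_id"]
    missing = set(meta) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    sample_cols = [c for c in df.columns if c not in meta]
    times = [_parse_time_header(c, time_header_pattern) for c in sample_cols]
    order = np.argsort(times)
    df = df[meta + [sample_cols[i] for i in order]]
    return df, np.asarray(times, dtype=float)[order]


def write_event_quantifications(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------


def write_events_bed(results: Sequence, path) -> None:
    """Write splicing-event results as BED6.

    One line per event: interval, ``name = gene:event_id:type``,
    ``score = round(1000 * min(1, |max ΔPSI|))``, strand. Events without a
    genomic interval are skipped with a warning. An empty result list still
    produces a file with the header comment.
    """
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for res in results:
            interval = getattr(res, "interval", None)
            if interval is None:
                logger.warning("event %s has no genomic interval; skipped", res.event_id)
                continue
            dpsi_max = max((abs(d) for d in res.delta_psi), default=0.0)
            score = int(round(1000 * min(1.0, dpsi_max)))
            name = f"{res.gene_id}:{res.event_id}:{res.event_type}"
            strand = getattr(res, "strand", ".")
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\t"
                f"{name}\t{score}\t{strand}\n"
            )
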