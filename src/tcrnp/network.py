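"""Clonotype similarity networks and per-cluster graph properties.

A patient's TCR repertoire is a set of unique CDR3 amino-acid sequences
(clonotypes) with abundance counts.  Sequences are connected in an
undirected network whenever their Levenshtein distance is at most
``max_dist`` (default 1, i.e. a single amino-acid difference), and the
connected components with at least two nodes are the *clusters*.  For
each cluster eleven scalar properties are evaluated; these are the raw
material for the per-patient feature extraction in :mod:`tcrnp.features`.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical property order used everywhere downstream (feature schema order).
PROPERTY_ORDER = (
    "node_count",
    "count_baseline",
    "count_post",
    "diameter_length",
    "assortativity",
    "transitivity",
    "density",
    "degree_centralization",
    "closeness_centralization",
    "eigen_centrality_value",
    "central_eigen",
)

#: Properties that can be undefined (NA) for degenerate cluster shapes.
NA_PROPERTIES = frozenset(
    {"assortativity", "transitivity", "closeness_centralization", "central_eigen"}
)

#: Properties treated as causal in the simulation studies.
CAUSAL_PROPERTIES = (
    "count_baseline",
    "diameter_length",
    "eigen_centrality_value",
    "central_eigen",
)

# Column-name dialects accepted out of the box.  AIRR rearrangement naming
# plus the two count-naming dialects used for pre/post treatment samples.
DEFAULT_SEQUENCE_COLUMNS = (
    "junction_aa",
    "cdr3_aa",
    "CDR3.aa",
    "aminoAcid",
    "sequence",
)
DEFAULT_BASELINE_COLUMNS = (
    "count_baseline",
    "Count_baseline",
    "count_pre_infusion",
    "duplicate_count",
    "count",
)
DEFAULT_POST_COLUMNS = (
    "count_post",
    "Count_post_treatment",
    "count_dose_2",
    "count_post_treatment",
)


class RepertoireFormatError(ValueError):
    """Input table does not conform to the expected repertoire format."""


@dataclass(frozen=True)
class Clone:
    """One unique clonotype: CDR3 amino-acid sequence plus abundance counts."""

    sequence: str
    count_baseline: int = 0
    count_post: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("clone sequence must be nonempty")
        if self.count_baseline < 0 or self.count_post < 0:
            raise ValueError(f"negative count for clone {self.sequence!r}")


@dataclass
class Repertoire:
    """One patient's clonotypes, with unique sequences."""

    patient_id: str
    clones: list[Clone]

    def __post_init__(self):
        if not self.clones:
            raise ValueError(f"repertoire {self.patient_id!r} has no clones")
        seqs = [c.sequence for c in self.clones]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"repertoire {self.patient_id!r} has duplicate sequences")

    def counts(self) -> dict[str, tuple[int, int]]:
        return {c.sequence: (c.count_baseline, c.count_post) for c in self.clones}

    def __len__(self) -> int:
        return len(self.clones)


@dataclass
class TCRNetwork:
    """Undirected clonotype similarity graph with its component labels."""

    graph: nx.Graph
    max_dist: int
    cluster_ids: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class ClusterPropertyRecord:
    """The eleven per-cluster network properties; NaN encodes NA."""

    cluster_id: int
    node_count: int
    count_baseline: float
    count_post: float
    diameter_length: float
    assortativity: float
    transitivity: float
    density: float
    degree_centralization: float
    closeness_centralization: float
    eigen_centrality_value: float
    central_eigen: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PROPERTY_ORDER}


@dataclass
class ClusterPropertyTable:
    """Per-cluster property records for one patient, in stable order."""

    patient_id: str
    records: list[ClusterPropertyRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": self.patient_id, "cluster_id": r.cluster_id, **r.as_dict()}
            for r in self.records
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "cluster_id", *PROPERTY_ORDER]
        )

    def property_values(self, name: str) -> list[float]:
        if name not in PROPERTY_ORDER:
            raise KeyError(name)
        return [getattr(r, name) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def read_repertoire(
    path: str | Path,
    patient_id: str | None = None,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
    allow_x: bool = True,
) -> Repertoire:
    """Read a clonotype table (TSV/CSV) into a :class:`Repertoire`.

    ``column_map`` may name the columns explicitly with keys ``sequence``,
    ``count_baseline`` and ``count_post``; otherwise common dialects
    (AIRR ``junction_aa``/``duplicate_count``, pre-infusion/dose-2 naming)
    are auto-detected.  Rows sharing a sequence are merged by summing each
    count column.  A missing second count column yields ``count_post=0``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})

    def resolve(key: str, candidates) -> str | None:
        if key in column_map:
            col = column_map[key]
            if col not in df.columns:
                raise RepertoireFormatError(
                    f"{path.name}: mapped column {col!r} for {key!r} not present"
                )
            return col
        for cand in candidates:
            if cand in df.columns:
                return cand
        return None

    seq_col = resolve("sequence", DEFAULT_SEQUENCE_COLUMNS)
    if seq_col is None:
        raise RepertoireFormatError(
            f"{path.name}: no sequence column found (looked for "
            f"{', '.join(DEFAULT_SEQUENCE_COLUMNS)})"
        )
    base_col = resolve("count_baseline", DEFAULT_BASELINE_COLUMNS)
    post_col = resolve("count_post", DEFAULT_POST_COLUMNS)
    if post_col is None:
        logger.warning("%s: no post-treatment count column; using 0", path.name)

    merged: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    alphabet = AA_ALPHABET | ({"X"} if allow_x else set())
    for _, row in df.iterrows():
        seq = str(row[seq_col]).strip().upper()
        if not seq or seq == "NAN":
            raise RepertoireFormatError(f"{path.name}: empty sequence entry")
        bad = set(seq) - alphabet
        if bad:
            raise RepertoireFormatError(
                f"{path.name}: sequence {seq!r} has non-amino-acid characters {sorted(bad)}"
            )
        for slot, col in enumerate((base_col, post_col)):
            if col is None:
                continue
            val = row[col]
            count = 0 if pd.isna(val) else int(val)
            if count < 0:
                raise ValueError(f"{path.name}: negative count for {seq!r}")
            merged[seq][slot] += count

    clones = [Clone(s, b, p) for s, (b, p) in merged.items()]
    return Repertoire(patient_id or path.stem, clones)


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character edits transforming ``a`` into ``b``."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _within_dist(a: str, b: str, max_dist: int) -> bool:
    if abs(len(a) - len(b)) > max_dist:
        return False
    return levenshtein(a, b) <= max_dist


def build_network(rep: Repertoire, max_dist: int = 1) -> TCRNetwork:
    """Connect sequences at Levenshtein distance <= ``max_dist``.

    Pairs whose lengths differ by more than ``max_dist`` are pruned before
    the DP; the edge set equals the exhaustive all-pairs result.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not rep.clones:
        raise ValueError("empty repertoire")
    seqs = [c.sequence for c in rep.clones]
    g = nx.Graph()
    g.add_nodes_from(seqs)
    by_length: dict[int, list[str]] = defaultdict(list)
    for s in seqs:
        by_length[len(s)].append(s)
    lengths = sorted(by_length)
    for L in lengths:
        bucket = sorted(by_length[L])
        for i, s in enumerate(bucket):
            for t in bucket[i + 1 :]:
                if _within_dist(s, t, max_dist):
                    g.add_edge(s, t)
        for L2 in lengths:
            if L < L2 <= L + max_dist:
                for s in by_length[L]:
                    for t in by_length[L2]:
                        if _within_dist(s, t, max_dist):
                            g.add_edge(s, t)

    cluster_ids: dict[str, int] = {}
    for label, comp in enumerate(_stable_components(g)):
        for node in comp:
            cluster_ids[node] = label
    return TCRNetwork(graph=g, max_dist=max_dist, cluster_ids=cluster_ids)


def _stable_components(g: nx.Graph) -> list[set[str]]:
    comps = list(nx.connected_components(g))
    # descending size, ties by lexicographically smallest member
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def find_clusters(net: TCRNetwork, min_size: int = 2) -> list[set[str]]:
    """Connected components with at least ``min_size`` nodes, in stable order."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [c for c in _stable_components(net.graph) if len(c) >= min_size]


def _freeman_centralization(scores: dict, tmax: float) -> float:
    """Freeman graph centralization: sum of (max - score) over the
    theoretical maximum ``tmax``; NA when ``tmax`` is 0 and the numerator
    is nonzero-undefined (0/0 with all-equal scores yields 0 only for the
    degree convention; callers decide)."""
    vals = np.asarray(list(scores.values()), dtype=float)
    num = float(np.sum(vals.max() - vals))
    if tmax <= 0:
        return math.nan
    return num / tmax


def cluster_properties(
    cluster: set[str], net: TCRNetwork, rep: Repertoire, cluster_id: int = 0
) -> ClusterPropertyRecord:
    """Evaluate the eleven properties on one cluster (a connected component).

    NA (NaN) arises exactly when a property's definitional normalizer is
    undefined: constant degrees for assortativity, no connected triple for
    transitivity, and a zero theoretical-maximum centralization -- which at
    n = 2 is the case for closeness and eigenvector centralization.  Degree
    centralization of a 2-node cluster is 0 (its numerator is exactly 0).
    """
    sub = net.graph.subgraph(cluster)
    n = sub.number_of_nodes()
    if n < 2:
        raise ValueError("cluster must have at least 2 nodes")
    if not nx.is_connected(sub):
        raise ValueError("node set is not a connected component")

    counts = rep.counts()
    count_base = sum(counts[s][0] for s in cluster if s in counts)
    count_post = sum(counts[s][1] for s in cluster if s in counts)

    m = sub.number_of_edges()
    density = m / (n * (n - 1) / 2)
    diameter = nx.diameter(sub)  # longest geodesic, in edges

    degrees = dict(sub.degree())
    deg_vals = set(degrees.values())
    if len(deg_vals) == 1:
        assort = math.nan  # degree-degree correlation undefined for regular graphs
    else:
        assort = float(nx.degree_assortativity_coefficient(sub))

    # global transitivity: 3 * triangles / connected triples; NA when no triple
    triples = sum(d * (d - 1) / 2 for d in degrees.values())
    if triples == 0:
        trans = math.nan
    else:
        triangles = sum(nx.triangles(sub).values()) / 3
        trans = 3 * triangles / triples

    if n == 2:
        deg_centr = 0.0
    else:
        deg_centr = _freeman_centralization(degrees, (n - 1) * (n - 2))

    closeness = nx.closeness_centrality(sub)  # normalized: (n-1)/sum(dist)
    clo_tmax = (n - 1) * (n - 2) / (2 * n - 3)
    clo_centr = _freeman_centralization(closeness, clo_tmax)

    A = nx.to_numpy_array(sub, nodelist=sorted(cluster))
    eigvals, eigvecs = np.linalg.eigh(A)
    lead = float(eigvals[-1])
    vec = np.abs(eigvecs[:, -1])
    vec = vec / vec.max() if vec.max() > 0 else vec
    # star graph attains the theoretical maximum for eigenvector centralization
    star_tmax = (n - 1) * (1 - 1 / math.sqrt(n - 1)) if n > 1 else 0.0
    eig_centr = _freeman_centralization(dict(enumerate(vec)), star_tmax)

    return ClusterPropertyRecord(
        cluster_id=cluster_id,
        node_count=n,
        count_baseline=count_base,
        count_post=count_post,
        diameter_length=float(diameter),
        assortativity=assort,
        transitivity=trans,
        density=density,
        degree_centralization=deg_centr,
        closeness_centralization=clo_centr,
        eigen_centrality_value=lead,
        central_eigen=eig_centr,
    )


def repertoire_properties(
    rep: Repertoire, max_dist: int = 1, min_size: int = 2
) -> ClusterPropertyTable:
    """Full per-patient pipeline: network -> clusters -> property table."""
    net = build_network(rep, max_dist=max_dist)
    clusters = find_clusters(net, min_size=min_size)
    records = [
        cluster_properties(c, net, rep, cluster_id=i) for i, c in enumerate(clusters)
    ]
    return ClusterPropertyTable(patient_id=rep.patient_id, records=records)


def write_property_table(table: ClusterPropertyTable, path: str | Path) -> None:
    """Tidy CSV with NA rendered as empty fields."""
    table.to_frame().to_csv(path, index=False, na_rep="")


def write_edge_list(net: TCRNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("from\tto\n")
        for a, b in sorted(net.graph.edges()):
            fh.write(f"{a}\t{b}\n")
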