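"""Core data types for the differential-proteomics pipeline.

The central container is :class:`AbundanceDataset`, a protein x sample
matrix of log abundances (already log-transformed upstream, e.g. by
MSstats-style quantification; the log base is treated as opaque) with an
explicit missing-value mask and a two-group sample design. Protein-protein
interaction networks, ontology annotations and gene-disease association
records get light validated wrappers around the obvious containers
(networkx graph, pandas DataFrame, dataclass records).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ONTOLOGIES = frozenset({"GO-CC", "GO-BP", "GO-MF", "KOG"})
DISEASE_CHANNELS = frozenset({"knowledge", "experimental", "textmining"})
_DOID_RE = re.compile(r"^DOID:\d+$")


class FormatError(ValueError):
    """A tabular input violates the expected dialect."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (matrix vs metadata) do not."""


@dataclass
class AbundanceDataset:
    """Protein x sample log-abundance matrix with a two-group design.

    Parameters
    ----------
    protein_ids : list of str
        Unique accessions, one per matrix row.
    sample_ids : list of str
        Unique sample names, one per matrix column; order is meaningful.
    group_of : dict
        Maps every sample id to exactly one of exactly two group labels.
    values : ndarray (n_proteins, n_samples)
        Log abundances; missing cells hold NaN and are additionally
        tracked in ``mask``.
    gene_symbols : list of str, optional
        Per-protein gene symbols (used to join annotations / networks).
    """

    protein_ids: list[str]
    sample_ids: list[str]
    group_of: dict[str, str]
    values: np.ndarray
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if any(not p for p in self.protein_ids):
            raise FormatError("empty protein id")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise FormatError("duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if set(self.group_of) != set(self.sample_ids):
            raise ConsistencyError(
                "sample ids in matrix and metadata do not match"
            )
        groups = self.groups
        if len(groups) != 2:
            raise ConsistencyError(
                f"exactly two groups required, found {len(groups)}: {groups}"
            )
        for g in groups:
            if len(self.samples_in_group(g)) < 2:
                raise ConsistencyError(f"group {g!r} has fewer than 2 samples")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if self.gene_symbols is not None and len(self.gene_symbols) != len(
            self.protein_ids
        ):
            raise FormatError("gene_symbols length mismatch")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def groups(self) -> list[str]:
        """The two group labels, in order of first appearance by sample."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        """Integer column indices of the samples belonging to ``group``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group],
            dtype=int,
        )

    def subset_proteins(self, keep_ids: list[str]) -> "AbundanceDataset":
        """Row-subset preserving input order of ``keep_ids``."""
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [index[p] for p in keep_ids]
        return AbundanceDataset(
            protein_ids=list(keep_ids),
            sample_ids=list(self.sample_ids),
            group_of=dict(self.group_of),
            values=self.values[rows].copy(),
            gene_symbols=(
                [self.gene_symbols[i] for i in rows] if self.gene_symbols else None
            ),
        )

    def copy(self) -> "AbundanceDataset":
        return AbundanceDataset(
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            group_of=dict(self.group_of),
            values=self.values.copy(),
            gene_symbols=list(self.gene_symbols) if self.gene_symbols else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame (proteins x samples, NaN = missing)."""
        return pd.DataFrame(
            self.values, index=self.protein_ids, columns=self.sample_ids
        )


class PpiNetwork:
    """Undirected simple protein-protein interaction graph.

    Nodes are gene symbols; every edge carries a confidence ``score`` in
    [0, 1]. Backed by a :class:`networkx.Graph`; duplicate pairs collapse
    to the maximum score and self-loops are rejected at insertion.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str, float]], nodes: list[str] | None = None
    ) -> "PpiNetwork":
        net = cls()
        if nodes:
            net.graph.add_nodes_from(nodes)
        for a, b, score in edges:
            net.add_edge(a, b, score)
        return net

    def add_edge(self, a: str, b: str, score: float = 1.0) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"edge score {score} outside [0, 1]")
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        prev = self.graph.get_edge_data(a, b)
        if prev is None or score > prev["score"]:
            self.graph.add_edge(a, b, score=score)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, d["score"]))
        return sorted(out)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PpiNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass
class AnnotationTable:
    """Protein/gene -> ontology-category assignments.

    One record per (id, ontology, category); exact duplicates are
    dropped, and every ontology label must come from the closed set
    GO-CC / GO-BP / GO-MF / KOG.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "ontology", "category"])
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=["id", "ontology", "category"])
        bad = set(df["ontology"]) - ONTOLOGIES
        if bad:
            raise ValueError(f"unknown ontology labels: {sorted(bad)}")
        self.records = df.drop_duplicates(ignore_index=True)

    def for_ontology(self, ontology: str) -> pd.DataFrame:
        if ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {ontology!r}")
        return self.records[self.records["ontology"] == ontology]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DiseaseAssociation:
    """One gene-disease evidence record with a channel-specific confidence."""

    gene: str
    disease_id: str
    disease_name: str
    channel: str
    score: float

    def __post_init__(self) -> None:
        if not _DOID_RE.match(self.disease_id):
            raise ValueError(f"malformed disease id {self.disease_id!r}")
        if self.channel not in DISEASE_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.score < 0:
            raise ValueError(f"negative confidence score {self.score}")
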