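"""Undirected bipartite drug-protein interaction networks.

A drug-protein interaction (DPI) dataset is modelled as a bipartite graph:
drugs on one side, proteins on the other, and an edge for every known
interaction.  The graph is equivalently the binary biadjacency matrix ``X``
with ``X[i, j] = 1`` iff drug ``i`` interacts with protein ``j``.  All
scoring and evaluation code in this package works on :class:`BipartiteGraph`.

Identifiers are opaque strings; which side a node belongs to is determined
purely by column position in the edge list, never by the identifier text.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteGraph",
    "DegreeSummary",
    "EdgeListError",
    "load_edge_list",
    "write_edge_list",
    "degree_summary",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


Edge = tuple[str, str]


@dataclass(frozen=True)
class BipartiteGraph:
    """A bipartite drug-protein graph with ordered node sets.

    Parameters
    ----------
    drugs, proteins:
        Node identifiers in a fixed order (first-appearance order when the
        graph is built from an edge list).  Zero-degree nodes are permitted.
    edge_indices:
        Frozen set of ``(drug_index, protein_index)`` pairs.
    """

    drugs: tuple[str, ...]
    proteins: tuple[str, ...]
    edge_indices: frozenset[tuple[int, int]]

    # index maps, built once per instance
    _drug_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _protein_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug identifiers")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        for di, pj in self.edge_indices:
            if not (0 <= di < len(self.drugs) and 0 <= pj < len(self.proteins)):
                raise ValueError(f"edge index out of range: {(di, pj)}")
        object.__setattr__(self, "_drug_index", {d: i for i, d in enumerate(self.drugs)})
        object.__setattr__(self, "_protein_index", {p: j for j, p in enumerate(self.proteins)})

    # ------------------------------------------------------------------ build
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Edge],
        drugs: Sequence[str] | None = None,
        proteins: Sequence[str] | None = None,
    ) -> "BipartiteGraph":
        """Build a graph from ``(drug, protein)`` pairs.

        Node order is first-appearance order unless explicit node lists are
        given (which may declare zero-degree nodes).  Duplicate pairs
        collapse to a single edge.
        """
        drug_order: dict[str, int] = {d: i for i, d in enumerate(drugs)} if drugs else {}
        prot_order: dict[str, int] = {p: j for j, p in enumerate(proteins)} if proteins else {}
        idx_edges: set[tuple[int, int]] = set()
        for d, p in edges:
            if d not in drug_order:
                if drugs is not None:
                    raise ValueError(f"edge references undeclared drug {d!r}")
                drug_order[d] = len(drug_order)
            if p not in prot_order:
                if proteins is not None:
                    raise ValueError(f"edge references undeclared protein {p!r}")
                prot_order[p] = len(prot_order)
            idx_edges.add((drug_order[d], prot_order[p]))
        return cls(
            drugs=tuple(drug_order),
            proteins=tuple(prot_order),
            edge_indices=frozenset(idx_edges),
        )

    # ------------------------------------------------------------------ sizes
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edge_indices)

    @property
    def n_possible_pairs(self) -> int:
        """Size of the full drug x protein grid."""
        return self.n_drugs * self.n_proteins

    @property
    def n_candidate_pairs(self) -> int:
        """Number of unconnected drug-protein pairs."""
        return self.n_possible_pairs - self.n_edges

    @property
    def positive_fraction(self) -> float:
        """Fraction of the grid occupied by known interactions."""
        if self.n_possible_pairs == 0:
            return 0.0
        return self.n_edges / self.n_possible_pairs

    # ------------------------------------------------------------------ lookup
    def drug_id(self, name: str) -> int:
        return self._drug_index[name]

    def protein_id(self, name: str) -> int:
        return self._protein_index[name]

    def has_edge(self, drug: str, protein: str) -> bool:
        di = self._drug_index.get(drug)
        pj = self._protein_index.get(protein)
        if di is None or pj is None:
            return False
        return (di, pj) in self.edge_indices

    def edges(self) -> list[Edge]:
        """Edges as name pairs, sorted by (drug order, protein order)."""
        return [
            (self.drugs[di], self.proteins[pj])
            for di, pj in sorted(self.edge_indices)
        ]

    # ------------------------------------------------------------------ degrees
    def _edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (drug_index, protein_index) arrays of the edge set."""
        cached = getattr(self, "_edge_arr", None)
        if cached is None:
            if self.edge_indices:
                rows, cols = zip(*sorted(self.edge_indices))
            else:
                rows, cols = (), ()
            cached = (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))
            object.__setattr__(self, "_edge_arr", cached)
        return cached

    def drug_degrees(self) -> np.ndarray:
        rows, _ = self._edge_arrays()
        return np.bincount(rows, minlength=self.n_drugs).astype(np.int64)

    def protein_degrees(self) -> np.ndarray:
        _, cols = self._edge_arrays()
        return np.bincount(cols, minlength=self.n_proteins).astype(np.int64)

    def drug_neighbors(self, drug: str) -> frozenset[str]:
        """Proteins adjacent to ``drug`` (the set Γ of the drug)."""
        di = self._drug_index[drug]
        return frozenset(
            self.proteins[pj] for d, pj in self.edge_indices if d == di
        )

    def protein_neighbors(self, protein: str) -> frozenset[str]:
        """Drugs adjacent to ``protein``."""
        pj = self._protein_index[protein]
        return frozenset(
            self.drugs[di] for di, p in self.edge_indices if p == pj
        )

    def protein_two_step(self, protein: str) -> frozenset[str]:
        """Proteins reachable from ``protein`` in exactly two edges, excluding itself.

        This is the two-step neighbourhood Γ' used by the Jaccard baseline and
        by the length-3 path scorers.
        """
        out: set[str] = set()
        for drug in self.protein_neighbors(protein):
            out.update(self.drug_neighbors(drug))
        out.discard(protein)
        return frozenset(out)

    # ------------------------------------------------------------------ matrix
    def biadjacency(self) -> sp.csr_matrix:
        """Binary drugs x proteins incidence matrix in CSR form."""
        cached = getattr(self, "_biadj", None)
        if cached is None:
            rows, cols = self._edge_arrays()
            data = np.ones(len(rows), dtype=np.float64)
            cached = sp.csr_matrix(
                (data, (rows, cols)), shape=(self.n_drugs, self.n_proteins)
            )
            object.__setattr__(self, "_biadj", cached)
        return cached.copy()

    # ------------------------------------------------------------------ edits
    def remove_edges(self, edges: Iterable[Edge]) -> "BipartiteGraph":
        """Return a copy without the given edges; node sets are preserved.

        Used to build per-fold training graphs, so that held-out interactions
        contribute nothing to degrees or neighbourhoods.
        """
        drop = set()
        for d, p in edges:
            key = (self._drug_index[d], self._protein_index[p])
            if key not in self.edge_indices:
                raise KeyError(f"edge not in graph: {(d, p)}")
            drop.add(key)
        return BipartiteGraph(
            drugs=self.drugs,
            proteins=self.proteins,
            edge_indices=self.edge_indices - drop,
        )

    def add_edges(self, edges: Iterable[Edge]) -> "BipartiteGraph":
        """Return a copy with the given edges added (endpoints must exist)."""
        new = set(self.edge_indices)
        for d, p in edges:
            new.add((self._drug_index[d], self._protein_index[p]))
        return BipartiteGraph(self.drugs, self.proteins, frozenset(new))

    # ------------------------------------------------------------------ pairs
    def candidate_pairs(self) -> Iterator[Edge]:
        """Yield every non-edge ``(drug, protein)`` in drug-major order."""
        for di, pj in itertools.product(range(self.n_drugs), range(self.n_proteins)):
            if (di, pj) not in self.edge_indices:
                yield (self.drugs[di], self.proteins[pj])


@dataclass(frozen=True)
class DegreeSummary:
    """Per-side degree histograms and the headline skew statistics."""

    drug_histogram: dict[int, int]
    protein_histogram: dict[int, int]
    frac_drugs_degree_below_10: float
    frac_proteins_degree_1: float


def degree_summary(g: BipartiteGraph) -> DegreeSummary:
    """Summarise the degree distributions of both sides of the network.

    DPI networks are typically sparse and right-skewed: most proteins bind a
    single drug while drugs bind up to tens of proteins.  The two fractions
    reported here capture exactly that asymmetry.
    """
    ddeg = g.drug_degrees()
    pdeg = g.protein_degrees()
    dhist = dict(sorted(Counter(ddeg.tolist()).items()))
    phist = dict(sorted(Counter(pdeg.tolist()).items()))
    fd = float(np.mean(ddeg < 10)) if g.n_drugs else 0.0
    fp = float(np.mean(pdeg == 1)) if g.n_proteins else 0.0
    return DegreeSummary(dhist, phist, fd, fp)


def load_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    header: bool = False,
    drugs: Sequence[str] | None = None,
    proteins: Sequence[str] | None = None,
) -> BipartiteGraph:
    """Read a two-column delimited edge list into a :class:`BipartiteGraph`.

    The first column is the drug, the second the protein; extra columns are
    ignored.  Lines starting with ``#`` are comments.  ``delimiter=None``
    splits on any whitespace.  With ``header=True`` the first non-comment
    line is skipped.  Duplicate rows collapse to one edge; the number of
    collapsed duplicates is logged as a warning.

    Raises
    ------
    EdgeListError
        If a non-comment line has fewer than two fields (the message names
        the 1-based line number), or if the file contains no edges at all.
    """
    path = Path(path)
    edges: list[Edge] = []
    seen: set[Edge] = set()
    duplicates = 0
    skipped_header = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header and not skipped_header:
                skipped_header = True
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise EdgeListError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            pair = (fields[0], fields[1])
            if pair in seen:
                duplicates += 1
                continue
            seen.add(pair)
            edges.append(pair)
    if not edges:
        raise EdgeListError(f"{path}: no edges found (empty graph)")
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, duplicates)
    return BipartiteGraph.from_edges(edges, drugs=drugs, proteins=proteins)


def write_edge_list(g: BipartiteGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the edge set in the same two-column format the loader reads."""
    path = Path(path)
    with path.open("w") as fh:
        for d, p in g.edges():
            fh.write(f"{d}{delimiter}{p}\n")
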