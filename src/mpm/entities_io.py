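"""Entity registries and tabular IO.

All pipeline inputs are plain TSV files (tab-delimited, header row, UTF-8):

* a directed protein-functional-interaction edge list
  (``source  target  relation``) where ``binding`` is symmetric and the
  one-way relations (inhibits / activates / regulates / catalyzes) yield a
  single directed edge;
* miRNA-PCG and disease-PCG association tables (binary or scored);
* known miRNA-disease associations;
* a MESH-like disease ontology as ``disease_id  tree_code`` records, the
  hierarchy being implied by dot-delimited positional codes;
* a miRNA -> family mapping.

Identifiers are opaque strings; no nomenclature normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: relation label -> True when the edge is symmetric (binding), False for the
#: one-way functional relations.
RELATION_SEMANTICS: dict[str, bool] = {
    "binding": True,
    "inhibits": False,
    "activates": False,
    "regulates": False,
    "catalyzes": False,
}


class ParseError(ValueError):
    """Raised for malformed input tables; carries the offending line number."""


# ---------------------------------------------------------------------------
# registries
# ---------------------------------------------------------------------------


@dataclass
class EntityRegistry:
    """Bijective mapping between external identifiers and dense 0-based indices.

    Parameters
    ----------
    kind:
        One of ``"miRNA"``, ``"disease"``, ``"PCG"`` (informational only).
    """

    kind: str
    id_to_index: dict[str, int] = field(default_factory=dict)
    index_to_id: list[str] = field(default_factory=list)

    @classmethod
    def from_ids(cls, kind: str, ids) -> "EntityRegistry":
        reg = cls(kind)
        for i in ids:
            reg.add(i)
        return reg

    def add(self, entity_id: str) -> int:
        """Register ``entity_id`` (idempotent) and return its index."""
        idx = self.id_to_index.get(entity_id)
        if idx is None:
            idx = len(self.index_to_id)
            self.id_to_index[entity_id] = idx
            self.index_to_id.append(entity_id)
        return idx

    def index(self, entity_id: str) -> int:
        try:
            return self.id_to_index[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id: {entity_id!r}") from None

    def id(self, index: int) -> str:
        return self.index_to_id[index]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.id_to_index

    def __len__(self) -> int:
        return len(self.index_to_id)

    @property
    def ids(self) -> list[str]:
        return list(self.index_to_id)


# ---------------------------------------------------------------------------
# directed PCG interaction network
# ---------------------------------------------------------------------------


@dataclass
class DirectedInteractionNetwork:
    """Directed PCG-PCG functional interaction graph.

    ``edges`` is a set of ordered ``(source_index, target_index)`` pairs;
    the same ordered pair is never stored twice.  Isolated nodes (registered
    PCGs with no edge) are permitted.
    """

    pcg_registry: EntityRegistry
    edges: set[tuple[int, int]] = field(default_factory=set)

    @property
    def n_pcgs(self) -> int:
        return len(self.pcg_registry)

    def add_edge(self, source: str, target: str) -> None:
        s = self.pcg_registry.add(source)
        t = self.pcg_registry.add(target)
        self.edges.add((s, t))

    def in_degree(self) -> np.ndarray:
        d = np.zeros(self.n_pcgs, dtype=np.int64)
        for _, t in self.edges:
            d[t] += 1
        return d

    def out_degree(self) -> np.ndarray:
        d = np.zeros(self.n_pcgs, dtype=np.int64)
        for s, _ in self.edges:
            d[s] += 1
        return d

    def parents(self, node: int) -> list[int]:
        """In-neighbours of ``node`` (message sources)."""
        return sorted(s for s, t in self.edges if t == node)

    def adjacency(self) -> sparse.csr_matrix:
        """Binary adjacency A with A[s, t] = 1 for each directed edge s->t."""
        n = self.n_pcgs
        if not self.edges:
            return sparse.csr_matrix((n, n))
        rows, cols = zip(*self.edges)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def restricted_undirected(self, nodes: list[int]) -> np.ndarray:
        """Symmetric 0/1 adjacency over ``nodes``: edge iff either direction exists."""
        pos = {n: i for i, n in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for s, t in self.edges:
            if s in pos and t in pos and s != t:
                a[pos[s], pos[t]] = 1.0
                a[pos[t], pos[s]] = 1.0
        return a


def read_edge_list(path, directed_semantics: dict[str, bool] | None = None,
                   registry: EntityRegistry | None = None) -> DirectedInteractionNetwork:
    """Load a directed PCG interaction network from a TSV edge list.

    Binding rows yield both ``(s, t)`` and ``(t, s)``; the one-way relations
    yield ``(s, t)`` only.  Duplicated ordered pairs collapse.
    """
    semantics = RELATION_SEMANTICS if directed_semantics is None else directed_semantics
    df = _read_tsv(path, ["source", "target", "relation"])
    if df.empty:
        raise ParseError(f"{path}: empty edge list")
    net = DirectedInteractionNetwork(registry or EntityRegistry("PCG"))
    for row_number, (s, t, rel) in enumerate(
            zip(df["source"], df["target"], df["relation"]), start=2):
        if rel not in semantics:
            raise ParseError(f"{path}:{row_number}: unknown relation {rel!r}")
        net.add_edge(str(s), str(t))
        if semantics[rel]:
            net.add_edge(str(t), str(s))
    return net


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------


@dataclass
class AssociationTable:
    """Weighted bipartite associations between two entity kinds.

    ``records`` maps ``(left_id, right_id)`` to a weight in [0, 1].
    Duplicate pairs collapse to the maximum weight (strongest evidence).
    """

    left_kind: str
    right_kind: str
    records: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, left: str, right: str, weight: float = 1.0) -> None:
        key = (left, right)
        self.records[key] = max(weight, self.records.get(key, 0.0))

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.records)

    def left_ids(self) -> list[str]:
        return sorted({left for left, _ in self.records})

    def right_ids(self) -> list[str]:
        return sorted({right for _, right in self.records})

    def to_matrix(self, left_registry: EntityRegistry,
                  right_registry: EntityRegistry) -> np.ndarray:
        """Dense left x right weight matrix over the given registries."""
        m = np.zeros((len(left_registry), len(right_registry)))
        for (left, right), w in self.records.items():
            m[left_registry.index(left), right_registry.index(right)] = w
        return m

    def __len__(self) -> int:
        return len(self.records)


def read_association_table(path, left_kind: str, right_kind: str,
                           weight_mode: str = "binary") -> AssociationTable:
    """Load a 2-column (binary) or 3-column (scored) association TSV.

    In ``score`` mode the scores are min-max rescaled to [0, 1] when any
    score lies outside that range; scores already in range pass through.
    """
    if weight_mode not in ("binary", "score"):
        raise ValueError(f"weight_mode must be 'binary' or 'score', got {weight_mode!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = AssociationTable(left_kind, right_kind)
    if weight_mode == "binary":
        for left, right in zip(df.iloc[:, 0], df.iloc[:, 1]):
            table.add(str(left), str(right), 1.0)
        return table
    if df.shape[1] < 3:
        raise ParseError(f"{path}: score mode requires a third (score) column")
    try:
        scores = df.iloc[:, 2].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric score: {exc}") from None
    for left, right, score in zip(df.iloc[:, 0], df.iloc[:, 1], scores):
        table.add(str(left), str(right), float(score))
    weights = np.array(list(table.records.values()))
    if weights.size and (weights.min() < 0.0 or weights.max() > 1.0):
        lo, hi = weights.min(), weights.max()
        span = hi - lo if hi > lo else 1.0
        table.records = {k: (w - lo) / span for k, w in table.records.items()}
    return table


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------


@dataclass
class OntologyTree:
    """Disease ontology with dot-delimited positional tree codes.

    A node may occupy several tree positions (multiple codes), so the
    structure is a DAG over nodes even though each code chain is a tree.
    Prefix codes without an explicit owner are synthesised as implicit
    category nodes whose id equals the code itself.
    """

    node_codes: dict[str, list[str]] = field(default_factory=dict)
    code_to_node: dict[str, str] = field(default_factory=dict)

    def add(self, node_id: str, code: str) -> None:
        segments = code.split(".")
        if any(not seg for seg in segments):
            raise ParseError(f"malformed tree code {code!r} (empty segment)")
        self.node_codes.setdefault(node_id, [])
        if code not in self.node_codes[node_id]:
            self.node_codes[node_id].append(code)
        self.code_to_node[code] = node_id

    def close(self) -> None:
        """Synthesise implicit nodes for every missing prefix code."""
        for code in list(self.code_to_node):
            for prefix in code_prefixes(code)[:-1]:
                if prefix not in self.code_to_node:
                    self.add(prefix, prefix)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.node_codes

    def codes(self, node_id: str) -> list[str]:
        return sorted(self.node_codes.get(node_id, []))

    def roots(self) -> list[str]:
        return sorted(c for c in self.code_to_node if "." not in c)


def code_prefixes(code: str) -> list[str]:
    """All dot-prefixes of ``code`` from root to the code itself."""
    segments = code.split(".")
    return [".".join(segments[: i + 1]) for i in range(len(segments))]


def read_ontology(path) -> OntologyTree:
    """Load ``disease_id<TAB>tree_code`` records; implicit parents are closed over."""
    df = _read_tsv(path, ["disease_id", "tree_code"])
    tree = OntologyTree()
    for node_id, code in zip(df["disease_id"], df["tree_code"]):
        tree.add(str(node_id), str(code))
    tree.close()
    return tree


# ---------------------------------------------------------------------------
# family map
# ---------------------------------------------------------------------------

UNKNOWN_FAMILY = "unknown"


@dataclass
class FamilyMap:
    """Total miRNA -> family mapping; unmapped miRNAs fall back to "unknown"."""

    mapping: dict[str, str] = field(default_factory=dict)

    def family(self, mirna_id: str) -> str:
        return self.mapping.get(mirna_id, UNKNOWN_FAMILY)

    def __len__(self) -> int:
        return len(self.mapping)


def read_family_map(path) -> FamilyMap:
    df = _read_tsv(path, ["mirna_id", "family"])
    return FamilyMap({str(m): str(f) for m, f in zip(df["mirna_id"], df["family"])})


# ---------------------------------------------------------------------------
# score-table output
# ---------------------------------------------------------------------------


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write a prediction table as TSV with a deterministic rank column.

    Rows are ordered by score descending, ties broken by
    (miRNA_id, disease_id) lexicographically; rank is 1-based.
    """
    required = {"miRNA_id", "disease_id", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    vals = scores["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("scores must be finite and in [0, 1]")
    out = scores.sort_values(
        by=["score", "miRNA_id", "disease_id"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _read_tsv(path, required_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df
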