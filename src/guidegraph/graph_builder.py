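"""Convert guide records into graphs with typed edges and node features.

Each guide becomes one graph: a node per nucleotide, undirected *sequential*
edges between backbone neighbours and undirected *structural* edges between
base-paired positions. Undirected edges are realized as two reciprocal arcs
because the downstream attention/convolution operators consume directed arcs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .structure_core import (
    CANONICAL_RULES,
    PairingRules,
    SecondaryStructure,
    predict_structure,
)

__all__ = [
    "GuideRecord",
    "GraphBuildConfig",
    "GuideGraph",
    "BuildFailure",
    "BuildResult",
    "SEQUENTIAL",
    "STRUCTURAL",
    "normalize_sequence",
    "one_hot_features",
    "load_embedding_features",
    "write_embedding_features",
    "build_edges",
    "build_graph",
    "build_dataset",
    "strip_structural_arcs",
]

SEQUENTIAL = 0
STRUCTURAL = 1

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_AMBIGUITY = set("RYSWKMBDHVN")


def normalize_sequence(seq: str) -> str:
    """Upper-case and map DNA T to RNA U. Does not resolve ambiguity codes."""
    return seq.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class GuideRecord:
    """One guide RNA: id, 5'->3' sequence, optional label and structure."""

    id: str
    sequence: str
    efficiency: float | None = None
    structure: SecondaryStructure | None = None

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", seq)
        if self.efficiency is not None and not (0.0 <= self.efficiency <= 100.0):
            raise ValueError(
                f"record {self.id!r}: efficiency {self.efficiency} outside [0, 100]"
            )
        if self.structure is not None and self.structure.length != len(seq):
            raise ValueError(
                f"record {self.id!r}: structure length {self.structure.length} "
                f"!= sequence length {len(seq)}"
            )


@dataclass(frozen=True)
class GraphBuildConfig:
    mode: str = "spacer_only"  # or "extended"
    ambiguity_policy: str = "strict"  # or "uniform"
    feature_provider: str = "one_hot"  # or "embedding"

    def __post_init__(self) -> None:
        if self.mode not in ("spacer_only", "extended"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.ambiguity_policy not in ("strict", "uniform"):
            raise ValueError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")
        if self.feature_provider not in ("one_hot", "embedding"):
            raise ValueError(f"unknown feature_provider {self.feature_provider!r}")


@dataclass
class GuideGraph:
    """Node feature matrix plus typed arcs; one graph per guide.

    ``arc_src``/``arc_dst``/``arc_type`` are parallel int arrays; every
    undirected edge appears as two reciprocal arcs. ``arc_type`` is
    :data:`SEQUENTIAL` or :data:`STRUCTURAL`.
    """

    node_features: np.ndarray
    arc_src: np.ndarray
    arc_dst: np.ndarray
    arc_type: np.ndarray
    label: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.node_features.shape[0])

    @property
    def n_arcs(self) -> int:
        return int(self.arc_src.shape[0])

    @property
    def feature_dim(self) -> int:
        return int(self.node_features.shape[1])

    def arcs(self) -> list[tuple[int, int, int]]:
        """Arcs as ``(src, dst, type)`` tuples."""
        return list(
            zip(self.arc_src.tolist(), self.arc_dst.tolist(), self.arc_type.tolist())
        )


def one_hot_features(seq: str, ambiguity_policy: str = "strict") -> np.ndarray:
    """One-hot node features, fixed column order A, C, G, U.

    Under the ``uniform`` policy IUPAC ambiguity codes become rows of 0.25;
    under ``strict`` they raise.
    """
    seq = normalize_sequence(seq)
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    for p, nt in enumerate(seq):
        idx = _NT_INDEX.get(nt)
        if idx is not None:
            mat[p, idx] = 1.0
        elif nt in _AMBIGUITY:
            if ambiguity_policy == "strict":
                raise ValueError(
                    f"ambiguity code {nt!r} at position {p} (strict policy)"
                )
            mat[p, :] = 0.25
        else:
            raise ValueError(f"invalid nucleotide {nt!r} at position {p}")
    return mat


_EMB_HEADER = re.compile(r"^>(\S+)\s+(\d+)\s+(\d+)\s*$")


def write_embedding_features(matrices: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-id embedding matrices as text blocks with shape headers."""
    with open(path, "w") as fh:
        for rid, mat in matrices.items():
            mat = np.asarray(mat, dtype=np.float64)
            fh.write(f">{rid} {mat.shape[0]} {mat.shape[1]}\n")
            for row in mat:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_embedding_features(
    path: str | Path,
    ids: Sequence[str],
    lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Load per-nucleotide embedding matrices for the requested ids.

    The file holds one block per id: a header line ``><id> <rows> <cols>``
    followed by ``rows`` whitespace-separated numeric lines. When ``lengths``
    is given, each matrix's row count is checked against the record's
    sequence length.
    """
    ids = list(ids)
    if not ids:
        return {}
    available: dict[str, np.ndarray] = {}
    wanted = set(ids)
    with open(path) as fh:
        line = fh.readline()
        while line:
            m = _EMB_HEADER.match(line)
            if m is None:
                raise ValueError(f"malformed embedding header line: {line!r}")
            rid, rows, cols = m.group(1), int(m.group(2)), int(m.group(3))
            block = []
            for _ in range(rows):
                row_line = fh.readline()
                if not row_line:
                    raise ValueError(f"truncated embedding block for {rid!r}")
                block.append(np.array(row_line.split(), dtype=np.float64))
            mat = np.vstack(block) if block else np.zeros((0, cols))
            if mat.shape != (rows, cols):
                raise ValueError(
                    f"embedding block for {rid!r} has shape {mat.shape}, "
                    f"header declares {(rows, cols)}"
                )
            if rid in wanted:
                available[rid] = mat
            line = fh.readline()
    missing = [rid for rid in ids if rid not in available]
    if missing:
        raise KeyError(f"embedding file missing ids: {missing}")
    if lengths is not None:
        for rid in ids:
            expected = lengths[rid]
            if available[rid].shape[0] != expected:
                raise ValueError(
                    f"record {rid!r}: embedding has {available[rid].shape[0]} rows "
                    f"but sequence length is {expected}"
                )
    return {rid: available[rid] for rid in ids}


def build_edges(
    length: int, s: SecondaryStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arc arrays for a guide of ``length`` nucleotides with structure ``s``.

    Sequential edges link consecutive positions; one structural edge per base
    pair. Each undirected edge is emitted as two reciprocal arcs. Arc order
    is bit-stable: all sequential arcs sorted by (src, dst), then structural
    arcs sorted by (src, dst). A base pair that coincides with a backbone
    edge is not emitted a second time.
    """
    if s.length != length:
        raise ValueError(f"structure length {s.length} != {length}")
    arcs: list[tuple[int, int, int]] = []
    for p in range(length - 1):
        arcs.append((p, p + 1, SEQUENTIAL))
        arcs.append((p + 1, p, SEQUENTIAL))
    struct_arcs: list[tuple[int, int, int]] = []
    for i, j in s.pairs:
        if not (0 <= i < length and 0 <= j < length):
            raise ValueError(f"pair ({i}, {j}) out of range for length {length}")
        if abs(j - i) == 1:  # duplicate of a backbone edge
            continue
        struct_arcs.append((i, j, STRUCTURAL))
        struct_arcs.append((j, i, STRUCTURAL))
    arcs.sort(key=lambda a: (a[0], a[1]))
    struct_arcs.sort(key=lambda a: (a[0], a[1]))
    arcs.extend(struct_arcs)
    if arcs:
        src, dst, typ = (np.array(v, dtype=np.int64) for v in zip(*arcs))
    else:
        src = dst = typ = np.zeros(0, dtype=np.int64)
    return src, dst, typ


def build_graph(
    rec: GuideRecord,
    cfg: GraphBuildConfig,
    features: np.ndarray,
    s: SecondaryStructure,
) -> GuideGraph:
    """Assemble one :class:`GuideGraph` from a record, features and structure."""
    n = len(rec.sequence)
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] != n:
        raise ValueError(
            f"record {rec.id!r}: feature matrix has {features.shape[0] if features.ndim == 2 else '?'} "
            f"rows, sequence has {n} nucleotides"
        )
    if s.length != n:
        raise ValueError(
            f"record {rec.id!r}: structure length {s.length} != sequence length {n}"
        )
    if not np.all(np.isfinite(features)):
        raise ValueError(f"record {rec.id!r}: non-finite feature values")
    src, dst, typ = build_edges(n, s)
    return GuideGraph(
        node_features=features,
        arc_src=src,
        arc_dst=dst,
        arc_type=typ,
        label=rec.efficiency,
        meta={
            "id": rec.id,
            "mode": cfg.mode,
            "feature_provider": cfg.feature_provider,
        },
    )


@dataclass(frozen=True)
class BuildFailure:
    record_id: str
    error: str


@dataclass
class BuildResult:
    graphs: list[GuideGraph]
    failures: list[BuildFailure]
    n_sequential_edges: int
    n_structural_edges: int


def build_dataset(
    records: Iterable[GuideRecord],
    cfg: GraphBuildConfig = GraphBuildConfig(),
    structure_source: Callable[[GuideRecord], SecondaryStructure] | None = None,
    feature_source: Callable[[GuideRecord], np.ndarray] | None = None,
    on_error: str = "raise",
    rules: PairingRules = CANONICAL_RULES,
) -> BuildResult:
    """Build one graph per record, order-preserving.

    ``structure_source`` defaults to the record's own structure, falling back
    to :func:`~guidegraph.structure_core.predict_structure`. ``feature_source``
    defaults to one-hot. ``on_error`` is ``"raise"`` or ``"skip"`` (skip the
    failing record and report it in the result).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"unknown on_error policy {on_error!r}")

    def default_structure(rec: GuideRecord) -> SecondaryStructure:
        if rec.structure is not None:
            return rec.structure
        return predict_structure(rec.sequence, rules)

    def default_features(rec: GuideRecord) -> np.ndarray:
        return one_hot_features(rec.sequence, cfg.ambiguity_policy)

    structure_source = structure_source or default_structure
    feature_source = feature_source or default_features

    graphs: list[GuideGraph] = []
    failures: list[BuildFailure] = []
    n_seq = n_struct = 0
    for rec in records:
        try:
            s = structure_source(rec)
            feats = feature_source(rec)
            g = build_graph(rec, cfg, feats, s)
        except Exception as exc:  # noqa: BLE001 - reported per record
            if on_error == "raise":
                raise type(exc)(f"record {rec.id!r}: {exc}") from exc
            failures.append(BuildFailure(record_id=rec.id, error=str(exc)))
            continue
        n_seq += int(np.sum(g.arc_type == SEQUENTIAL)) // 2
        n_struct += int(np.sum(g.arc_type == STRUCTURAL)) // 2
        graphs.append(g)
    return BuildResult(
        graphs=graphs,
        failures=failures,
        n_sequential_edges=n_seq,
        n_structural_edges=n_struct,
    )


def strip_structural_arcs(g: GuideGraph) -> GuideGraph:
    """Copy of ``g`` with structural arcs removed (edge-ablation switch)."""
    keep = g.arc_type == SEQUENTIAL
    return GuideGraph(
        node_features=g.node_features.copy(),
        arc_src=g.arc_src[keep].copy(),
        arc_dst=g.arc_dst[keep].copy(),
        arc_type=g.arc_type[keep].copy(),
        label=g.label,
        meta={**g.meta, "ablation": "no_structural_edges"},
    )
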