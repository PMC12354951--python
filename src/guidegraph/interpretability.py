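"""Aggregate attention weights into per-position importance scores.

For each spacer position three scores are reported: attention *received*
(sum over incoming arcs), attention *emitted* (sum over outgoing arcs), and
a *combined* hub score — the product of the normalized received and emitted
scores, renormalized. Heads are averaged; the final attention layer is used.
Self-loop arcs contribute to both the received and emitted score of their
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .gnn_model import TrainedModel, forward
from .graph_builder import GuideGraph

__all__ = [
    "AttentionProfile",
    "extract_attention",
    "position_importance",
    "rank_positions",
    "write_profile",
    "plot_profile",
]


@dataclass(frozen=True)
class AttentionProfile:
    incoming: np.ndarray
    outgoing: np.ndarray
    combined: np.ndarray
    incoming_normalized: np.ndarray
    outgoing_normalized: np.ndarray
    combined_normalized: np.ndarray

    @property
    def length(self) -> int:
        return int(self.incoming.shape[0])


def extract_attention(
    model: TrainedModel, graphs: Sequence[GuideGraph]
) -> list[dict]:
    """Per-graph arc attention from the final attention layer, head-averaged.

    Returns one dict per graph with ``src``, ``dst`` (self-loops included)
    and ``weights`` (one value per arc); each node's incoming weights sum
    to 1.
    """
    if model.config.attention_layers < 1:
        raise ValueError("model has no attention layer")
    out = []
    for g in graphs:
        _, layers = forward(model, g, return_attention=True)
        last = layers[-1]
        out.append(
            {
                "src": last["src"],
                "dst": last["dst"],
                "weights": last["weights"].mean(axis=1),
            }
        )
    return out


def _normalize(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        return np.full_like(v, 1.0 / len(v))
    return v / total


def position_importance(attn: Sequence[dict], length: int) -> AttentionProfile:
    """Mean per-position received/emitted attention over a set of graphs.

    All graphs must share ``length`` (spacer-only mode). The combined hub
    score is the product of the normalized received and emitted scores,
    renormalized to sum to 1.
    """
    if not attn:
        raise ValueError("no attention data")
    incoming = np.zeros(length)
    outgoing = np.zeros(length)
    for a in attn:
        src, dst, w = a["src"], a["dst"], a["weights"]
        n_nodes = int(max(src.max(), dst.max())) + 1
        if n_nodes != length:
            raise ValueError(
                f"graph has {n_nodes} positions, expected {length} (mixed lengths?)"
            )
        np.add.at(incoming, dst, w)
        np.add.at(outgoing, src, w)
    incoming /= len(attn)
    outgoing /= len(attn)
    inc_n = _normalize(incoming)
    out_n = _normalize(outgoing)
    combined = inc_n * out_n
    return AttentionProfile(
        incoming=incoming,
        outgoing=outgoing,
        combined=combined,
        incoming_normalized=inc_n,
        outgoing_normalized=out_n,
        combined_normalized=_normalize(combined),
    )


def rank_positions(profile: AttentionProfile) -> dict[str, list[int]]:
    """Positions in descending score order per score type.

    Stable: ties are broken by ascending position index.
    """
    def order(scores: np.ndarray) -> list[int]:
        return sorted(range(len(scores)), key=lambda p: (-scores[p], p))

    return {
        "incoming": order(profile.incoming),
        "outgoing": order(profile.outgoing),
        "combined": order(profile.combined),
    }


def write_profile(profile: AttentionProfile, path: str | Path) -> None:
    ranks = rank_positions(profile)
    inv = {k: np.argsort(v) for k, v in {k: np.array(v) for k, v in ranks.items()}.items()}
    lines = [
        "position\tincoming\toutgoing\tcombined\t"
        "incoming_rank\toutgoing_rank\tcombined_rank"
    ]
    for p in range(profile.length):
        lines.append(
            f"{p}\t{profile.incoming[p]:.6f}\t{profile.outgoing[p]:.6f}\t"
            f"{profile.combined[p]:.6f}\t{inv['incoming'][p]}\t"
            f"{inv['outgoing'][p]}\t{inv['combined'][p]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def plot_profile(profile: AttentionProfile, path: str | Path) -> None:
    """Optional bar-chart export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    pos = np.arange(profile.length)
    for ax, scores, title in zip(
        axes,
        (profile.incoming, profile.outgoing, profile.combined),
        ("received", "emitted", "combined (hub)"),
    ):
        ax.bar(pos, scores)
        ax.set_ylabel(title)
    axes[-1].set_xlabel("position (5'->3', 0-based)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
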