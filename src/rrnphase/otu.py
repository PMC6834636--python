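"""Greedy centroid OTU clustering at an identity threshold.

Sequences are scanned in order of decreasing abundance; each joins the
first existing centroid whose global identity (matches / alignment
columns, terminal gaps excluded) reaches the threshold, otherwise it
founds a new centroid.  No chimera filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .alignment import global_identity


@dataclass
class OtuSet:
    """Greedy clustering result: centroids and member assignments."""

    identity_threshold: float
    centroid_ids: list[str] = field(default_factory=list)
    centroids: list[str] = field(default_factory=list)
    membership: dict[str, int] = field(default_factory=dict)
    member_identity: dict[str, float] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "member_id": list(self.membership),
            "otu": [self.centroid_ids[i] for i in self.membership.values()],
            "identity_to_centroid":
                [self.member_identity[m] for m in self.membership],
        })


def cluster_otus(sequences: Sequence[tuple[str, str]],
                 identity: float,
                 abundances: Sequence[int] | None = None) -> OtuSet:
    """Cluster de-replicated ``(id, sequence)`` pairs greedily.

    ``abundances`` orders the scan (descending, stable); without them
    the input order is kept, matching the upstream convention of
    sorting de-replicated sequences by size.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    items = list(sequences)
    if abundances is not None:
        if len(abundances) != len(items):
            raise ValueError("one abundance per sequence required")
        order = sorted(range(len(items)), key=lambda i: -abundances[i])
        items = [items[i] for i in order]
    out = OtuSet(identity_threshold=identity)
    for seq_id, seq in items:
        for ci, centroid in enumerate(out.centroids):
            ident = global_identity(seq, centroid)
            if ident >= identity:
                out.membership[seq_id] = ci
                out.member_identity[seq_id] = ident
                break
        else:
            out.centroid_ids.append(seq_id)
            out.centroids.append(seq)
            out.membership[seq_id] = len(out.centroids) - 1
            out.member_identity[seq_id] = 1.0
    return out
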