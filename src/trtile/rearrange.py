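"""Reordering of aligned alleles so that similar alleles sit adjacently.

The default reorders rows by average-linkage hierarchical clustering on the
per-column disagreement fraction between aligned rows (a gap opposite a
symbol counts as a difference).  Alternative orders: ascending motif count,
ungapped length, lexicographic id, or a caller-supplied manual permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .align import EncodedAlignment
from .encode import GAP_SYMBOL

__all__ = ["RowOrder", "METHODS", "rearrange"]

METHODS = ("clustering", "motif_count", "length", "lexicographic", "manual")


@dataclass(frozen=True)
class RowOrder:
    order: tuple[str, ...]
    method: str

    def __iter__(self):
        return iter(self.order)

    def __len__(self):
        return len(self.order)


def _cluster_order(alignment: EncodedAlignment) -> list[str]:
    ids = alignment.ids
    n = len(ids)
    if n == 1:
        return list(ids)
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for _, r in alignment.rows]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = float(np.mean(rows[i] != rows[j]))
    Z = linkage(squareform(dist, checks=False), method="average")
    # deterministic leaf order: at each merge the smaller subtree comes
    # first; size ties go to the subtree holding the lexicographically
    # smallest id
    leaves: dict[int, list[str]] = {i: [ids[i]] for i in range(n)}
    for k, (ca, cb, _, _) in enumerate(Z):
        a = leaves.pop(int(ca))
        b = leaves.pop(int(cb))
        if (len(a), min(a)) <= (len(b), min(b)):
            leaves[n + k] = a + b
        else:
            leaves[n + k] = b + a
    return leaves[2 * n - 2]


def rearrange(
    alignment: EncodedAlignment,
    method: str = "clustering",
    manual_order=None,
) -> RowOrder:
    """Compute a display order for the alignment's rows.

    ``manual_order`` must be a permutation of the alignment ids and is only
    consulted when ``method == "manual"``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown rearrangement method {method!r}")
    ids = alignment.ids
    if method == "manual":
        if manual_order is None:
            raise ValueError("manual rearrangement requires manual_order")
        manual_order = list(manual_order)
        missing = sorted(set(ids) - set(manual_order))
        extra = sorted(set(manual_order) - set(ids))
        if missing or extra or len(manual_order) != len(ids):
            raise ValueError(
                f"manual_order is not a permutation of the alignment ids; "
                f"missing={missing}, extra={extra}"
            )
        return RowOrder(tuple(manual_order), method)
    if method == "clustering":
        return RowOrder(tuple(_cluster_order(alignment)), method)
    if method in ("motif_count", "length"):
        # at the symbol level both sort by the number of non-gap symbols
        key = lambda rid: (  # noqa: E731
            len(alignment.degapped(rid)),
            rid,
        )
        return RowOrder(tuple(sorted(ids, key=key)), method)
    return RowOrder(tuple(sorted(ids)), "lexicographic")


def write_order(order: RowOrder, path) -> None:
    with open(path, "w") as fh:
        for rid in order:
            fh.write(rid + "\n")


def read_order(path, method: str = "manual") -> RowOrder:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"no ids in {path}")
    return RowOrder(tuple(ids), method)
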