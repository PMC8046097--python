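"""Divisive analysis (DIANA) hierarchical clustering.

Implements the classical Kaufman & Rousseeuw divisive algorithm: start with
all objects in one cluster and repeatedly split the cluster with the largest
diameter.  A split seeds a splinter group with the object of maximal average
dissimilarity to its cluster mates, then iteratively moves over every object
whose average dissimilarity to the remaining group exceeds its average
dissimilarity to the splinter group (largest positive difference first),
until no such object remains.

The recorded height of each split is the diameter of the cluster being
split, so split heights are non-increasing along the division sequence and
cutting the tree at height h is the same as applying every split with
height > h.

The divisive coefficient (DC) summarises clustering structure: for each
object i let d(i) be the diameter of the last cluster it belongs to before
being split off as a singleton, divided by the diameter of the whole data
set; DC = mean(1 - d(i)).  Values near 1 indicate tight, well-separated
clusters.

Ties (equal diameters, equal average dissimilarities) are broken by the
smallest object index so the tree is invariant to input order up to the
documented id ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DianaTree", "diana"]


@dataclass
class DianaTree:
    """Result of a divisive clustering run.

    ``splits`` holds, in division order, (members_before_split, left, right,
    height) with member lists of integer indices; heights are non-increasing.
    """

    n: int
    splits: list = field(default_factory=list)
    dc: float = 0.0
    diameter: float = 0.0

    def cut_k(self, k: int) -> np.ndarray:
        """Partition into k clusters by applying the first k-1 splits."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} outside [1, {self.n}]")
        return self._labels(self.splits[:k - 1])

    def cut_height(self, height: float) -> np.ndarray:
        """Partition induced by undoing no split at or below ``height``."""
        applied = [s for s in self.splits if s[3] > height]
        return self._labels(applied)

    def _labels(self, applied) -> np.ndarray:
        clusters = [list(range(self.n))]
        for members, left, right, _h in applied:
            for ci, c in enumerate(clusters):
                if c == members:
                    clusters[ci:ci + 1] = [left, right]
                    break
        labels = np.empty(self.n, dtype=int)
        # deterministic labels: clusters ordered by smallest member
        for lab, c in enumerate(sorted(clusters, key=lambda c: c[0])):
            labels[c] = lab
        return labels


def _diameter(d: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = d[np.ix_(members, members)]
    return float(sub.max())


def diana(dist: np.ndarray) -> DianaTree:
    """Run divisive clustering on a square symmetric dissimilarity matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dist must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dist must be symmetric")
    n = d.shape[0]
    tree = DianaTree(n=n)
    if n == 1:
        return tree
    tree.diameter = _diameter(d, list(range(n)))

    # last-cluster diameter per object, for the divisive coefficient
    last_diam = np.full(n, tree.diameter)

    active = [list(range(n))]
    while active:
        # split the active cluster with the largest diameter
        diams = [_diameter(d, c) for c in active]
        best = int(np.argmax(diams))
        height = diams[best]
        cluster = active.pop(best)
        if height == 0.0 or len(cluster) < 2:
            # all remaining objects coincide; finish without recording splits
            for c in [cluster] + active:
                for i in c:
                    last_diam[i] = 0.0
            break

        members = sorted(cluster)
        for i in members:
            last_diam[i] = height

        # seed splinter with the object of max average dissimilarity
        rest = list(members)
        sub = d[np.ix_(rest, rest)]
        avg = sub.sum(axis=1) / (len(rest) - 1)
        seed = rest[int(np.argmax(avg))]
        splinter = [seed]
        rest.remove(seed)

        while len(rest) > 1:
            a = np.array([d[i, rest].sum() - d[i, i]
                          for i in rest])  # d[i,i]=0; sum over others
            a = a / (len(rest) - 1)
            b = np.array([d[i, splinter].mean() for i in rest])
            gain = a - b
            j = int(np.argmax(gain))
            if gain[j] <= 0:
                break
            splinter.append(rest.pop(j))

        splinter.sort()
        rest.sort()
        tree.splits.append((members, splinter, rest, height))
        for part in (splinter, rest):
            if len(part) > 1:
                active.append(part)
            else:
                last_diam[part[0]] = min(last_diam[part[0]], height)

    if tree.diameter > 0:
        tree.dc = float(np.mean(1.0 - last_diam / tree.diameter))
    else:
        tree.dc = 0.0
    return tree
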