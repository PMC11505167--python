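"""Approximate nearest neighbours via a forest of random projection trees.

Each tree recursively splits the data with a hyperplane equidistant from two
randomly chosen points (the classic two-means-style split used by
Spotify-style RP forests); queries descend all trees at once with a shared
priority queue ordered by margin distance, so raising the candidate budget
(``search_k``) trades speed for accuracy. With ``search_k >= n`` every leaf
is visited and results are exact, which is how the oracle tests pin this
index against brute-force search.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

_INF = float("inf")


@dataclass
class _Node:
    # leaf: items is not None; internal: hyperplane (w, threshold) + children
    items: np.ndarray | None = None
    w: np.ndarray | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None


class RPForest:
    """Random-projection-tree index over an (n, d) point set, Euclidean metric."""

    def __init__(self, X: np.ndarray, n_trees: int = 15, leaf_size: int = 16, seed: int = 0):
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        if self.X.ndim != 2 or len(self.X) == 0:
            raise ValueError("X must be a non-empty 2-D array")
        self.n_trees = n_trees
        self.leaf_size = leaf_size
        rng = np.random.default_rng(seed)
        all_idx = np.arange(len(self.X))
        self.trees = [self._build(all_idx, rng, depth=0) for _ in range(n_trees)]

    def _build(self, idx: np.ndarray, rng: np.random.Generator, depth: int) -> _Node:
        if idx.size <= self.leaf_size or depth > 60:
            return _Node(items=idx)
        # hyperplane equidistant from two random distinct points
        for _ in range(5):
            a, b = rng.choice(idx, size=2, replace=False)
            w = self.X[a] - self.X[b]
            norm = np.linalg.norm(w)
            if norm > 0:
                break
        else:  # all sampled pairs identical: give up splitting
            return _Node(items=idx)
        w = w / norm
        threshold = float(w @ (self.X[a] + self.X[b]) / 2.0)
        side = self.X[idx] @ w < threshold
        if side.all() or not side.any():  # degenerate split: stop here
            return _Node(items=idx)
        return _Node(
            w=w,
            threshold=threshold,
            left=self._build(idx[side], rng, depth + 1),
            right=self._build(idx[~side], rng, depth + 1),
        )

    # ----------------------------------------------------------------- search

    def _candidates(self, q: np.ndarray, search_k: int) -> np.ndarray:
        """Union of leaf items reached by margin-ordered descent of all trees."""
        heap: list[tuple[float, int, _Node]] = []
        counter = 0  # tie-break so nodes never compare
        for tree in self.trees:
            heap.append((-_INF, counter, tree))
            counter += 1
        heapq.heapify(heap)
        seen: list[np.ndarray] = []
        n_collected = 0
        while heap and n_collected < search_k:
            neg_priority, _, node = heapq.heappop(heap)
            if node.items is not None:
                seen.append(node.items)
                n_collected += node.items.size
                continue
            margin = float(q @ node.w - node.threshold)
            near, far = (node.left, node.right) if margin < 0 else (node.right, node.left)
            priority = -neg_priority
            heapq.heappush(heap, (-min(priority, abs(margin)), counter, far))
            counter += 1
            heapq.heappush(heap, (-priority, counter, near))
            counter += 1
        return np.unique(np.concatenate(seen)) if seen else np.empty(0, dtype=np.int64)

    def query(self, i_or_point, k: int, search_k: int | None = None,
              exclude_self: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """k nearest neighbours of a stored point index or a raw vector.

        Returns (indices, distances) sorted by distance. ``exclude_self``
        removes that stored index from the result.
        """
        q = self.X[i_or_point] if np.isscalar(i_or_point) else np.asarray(i_or_point)
        if search_k is None:
            search_k = max(k * self.n_trees * 50, k + 1)
        cand = self._candidates(q, search_k)
        if exclude_self is not None:
            cand = cand[cand != exclude_self]
        dists = np.linalg.norm(self.X[cand] - q, axis=1)
        order = np.argsort(dists, kind="stable")[:k]
        return cand[order], dists[order]

    def query_radius(self, i_or_point, radius: float, search_k: int,
                     ) -> np.ndarray:
        """Stored-point indices within ``radius`` of the query (self included)."""
        q = self.X[i_or_point] if np.isscalar(i_or_point) else np.asarray(i_or_point)
        cand = self._candidates(q, search_k)
        dists = np.linalg.norm(self.X[cand] - q, axis=1)
        return cand[dists <= radius]
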