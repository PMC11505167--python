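"""Self-parameterizing DBSCAN over fused contig features.

DBSCAN needs two parameters a user would otherwise guess: the neighbourhood
radius Eps and the core-point threshold MinPts. Both are chosen from the
data here: Eps from the knee of the sorted k-distance curve (distances to
each point's k-th nearest neighbour, found with the random-projection-tree
index), and MinPts by grid search scored with the mean silhouette of the
non-noise points. The final clustering reuses the same index for its radius
queries; an exact brute-force mode backs the oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .ann import RPForest
from .io import NOISE_LABEL

DEFAULT_MINPTS_GRID = (5, 10, 15, 20, 25)
DEFAULT_N_TREES = 15
DEFAULT_KDIST_K = 15  # ~ the DBSCAN heuristic k ≈ MinPts (median of the grid)


@dataclass
class ClusterParams:
    """Everything the adaptive selection decided, kept for the record."""

    eps: float
    min_pts: int
    k: int = DEFAULT_KDIST_K
    n_trees: int = DEFAULT_N_TREES
    grid: tuple[int, ...] = DEFAULT_MINPTS_GRID
    k_distance_curve: np.ndarray | None = None


@dataclass
class BinningResult:
    """Contig-to-bin labels; ``-1`` is the reserved noise label."""

    contig_ids: list[str]
    labels: np.ndarray
    params: ClusterParams | None = None
    quality: float = float("nan")

    @property
    def assignments(self) -> dict[str, int]:
        return {cid: int(lab) for cid, lab in zip(self.contig_ids, self.labels)}

    @property
    def n_bins(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE_LABEL])))


def k_distance_curve(
    X: np.ndarray,
    k: int = DEFAULT_KDIST_K,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    search_k: int | None = None,
    exact: bool = False,
) -> np.ndarray:
    """Sorted distances from every point to its k-th nearest neighbour.

    Self is excluded as its own neighbour. ``exact=True`` uses brute-force
    neighbour search instead of the RP-forest index.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    if exact:
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(X)
        dists, _ = nn.kneighbors(X)
        kth = dists[:, k]
    else:
        forest = RPForest(X, n_trees=n_trees, seed=seed)
        kth = np.empty(n)
        for i in range(n):
            _, d = forest.query(i, k=k, search_k=search_k, exclude_self=i)
            kth[i] = d[-1]
    return np.sort(kth)


def select_eps(curve: Sequence[float] | np.ndarray) -> float:
    """Knee of the sorted k-distance curve, Kneedle-style.

    Both axes are normalized to [0, 1] and the point with maximum vertical
    distance to the chord joining the endpoints is returned (as a distance
    value). A flat curve has no knee and raises.
    """
    y = np.asarray(curve, dtype=np.float64)
    if y.size < 3:
        raise ValueError("curve must have at least 3 points")
    span = y[-1] - y[0]
    if span <= 0:
        raise ValueError("no knee in a constant k-distance curve; supply eps manually")
    x_norm = np.linspace(0.0, 1.0, y.size)
    y_norm = (y - y[0]) / span
    knee = int(np.argmax(np.abs(y_norm - x_norm)))
    return float(y[knee])


def dbscan_labels(
    X: np.ndarray,
    eps: float,
    min_pts: int,
    forest: RPForest | None = None,
    search_k: int | None = None,
    exact: bool = False,
) -> np.ndarray:
    """Standard density-reachability DBSCAN with −1 for noise.

    Neighbourhood queries go through the RP-forest index unless ``exact``.
    The point itself counts toward its neighbourhood size, matching the
    common reference implementations.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if exact:
        nn = NearestNeighbors(radius=eps, algorithm="brute").fit(X)
        neighborhoods = nn.radius_neighbors(X, return_distance=False)
    else:
        if forest is None:
            forest = RPForest(X)
        if search_k is None:
            search_k = max(min_pts * forest.n_trees * 50, n // 4)
        neighborhoods = [forest.query_radius(i, eps, search_k=search_k) for i in range(n)]

    is_core = np.array([len(nb) >= min_pts for nb in neighborhoods])
    labels = np.full(n, NOISE_LABEL, dtype=np.int64)
    current = 0
    for i in range(n):
        if labels[i] != NOISE_LABEL or not is_core[i]:
            continue
        stack: list[int] = []
        j = i
        while True:
            if labels[j] == NOISE_LABEL:
                labels[j] = current
                if is_core[j]:
                    for q in neighborhoods[j]:
                        if labels[q] == NOISE_LABEL:
                            stack.append(int(q))
            if not stack:
                break
            j = stack.pop()
        current += 1
    return labels


def select_minpts(
    X: np.ndarray,
    eps: float,
    grid: Sequence[int] = DEFAULT_MINPTS_GRID,
    forest: RPForest | None = None,
    search_k: int | None = None,
    exact: bool = False,
) -> tuple[int, np.ndarray, float]:
    """Grid-search MinPts at fixed Eps, scored by clustering quality.

    The score is the mean silhouette over non-noise points minus the noise
    fraction: silhouette alone slightly rewards trimming cluster fringes
    into noise, so discarded points are charged against the configuration.
    A candidate scores -inf if it yields fewer than 2 clusters or declares
    more than 90% of the points noise. Ties go to the smallest MinPts.
    """
    if not grid:
        raise ValueError("empty MinPts grid")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    best: tuple[float, int, np.ndarray] | None = None
    for min_pts in sorted(grid):
        labels = dbscan_labels(X, eps, min_pts, forest=forest, search_k=search_k, exact=exact)
        keep = labels != NOISE_LABEL
        n_clusters = len(set(labels[keep]))
        noise_frac = 1.0 - keep.mean()
        if n_clusters < 2 or noise_frac > 0.9 or keep.sum() <= n_clusters:
            score = -np.inf
        else:
            score = float(silhouette_score(X[keep], labels[keep])) - noise_frac
        if np.isfinite(score) and (best is None or score > best[0]):
            best = (score, min_pts, labels)
    if best is None:
        raise ValueError(
            "every MinPts candidate scored -inf (too few clusters or >90% noise); "
            "re-select eps or supply parameters manually"
        )
    score, min_pts, labels = best
    return min_pts, labels, score


def cluster(
    X: np.ndarray,
    contig_ids: Sequence[str] | None = None,
    k: int = DEFAULT_KDIST_K,
    n_trees: int = DEFAULT_N_TREES,
    grid: Sequence[int] = DEFAULT_MINPTS_GRID,
    eps: float | None = None,
    seed: int = 0,
    search_k: int | None = None,
    exact: bool = False,
) -> BinningResult:
    """Full adaptive clustering: k-distance curve -> Eps knee -> MinPts grid.

    ``eps`` overrides knee detection when supplied. Records the chosen
    parameters and the silhouette of the winning configuration.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if contig_ids is None:
        contig_ids = [str(i) for i in range(len(X))]
    forest = None if exact else RPForest(X, n_trees=n_trees, seed=seed)
    curve = k_distance_curve(
        X, k=k, n_trees=n_trees, seed=seed, search_k=search_k, exact=exact
    )
    chosen_eps = float(eps) if eps is not None else select_eps(curve)
    min_pts, labels, quality = select_minpts(
        X, chosen_eps, grid=grid, forest=forest, search_k=search_k, exact=exact
    )
    params = ClusterParams(
        eps=chosen_eps, min_pts=min_pts, k=k, n_trees=n_trees,
        grid=tuple(sorted(grid)), k_distance_curve=curve,
    )
    return BinningResult(
        contig_ids=list(contig_ids), labels=labels, params=params, quality=quality
    )


def plot_k_distance(curve: np.ndarray, eps: float | None, out_path) -> None:
    """Render the sorted k-distance curve (and the chosen Eps) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(curve)), curve, lw=1.5)
    if eps is not None:
        ax.axhline(eps, color="crimson", ls="--", label=f"eps = {eps:.4g}")
        ax.legend()
    ax.set_xlabel("points sorted by k-distance")
    ax.set_ylabel("distance to k-th nearest neighbour")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
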