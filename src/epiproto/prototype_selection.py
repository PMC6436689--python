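"""A-priori selection of prototype disease models.

Rather than letting the data pick a best-fitting disease model for every
SNP pair, the screening method restricts candidates to a small set of
*prototypes* chosen before seeing any phenotype: the 143 canonical
non-trivial models are clustered under the population-calibrated
directional distance, and one representative (the incremental center) is
kept per cluster.

Clustering uses the incremental "global K-means" strategy: centers are
added one at a time, each new center being the candidate that minimizes
the total within-cluster (nearest-center) distance.  With K=1 this is
exactly the medoid.  Because the distance depends on minor-allele
frequencies, a library holds one prototype set per pair of MAF bins on
the grid {0.05, 0.1, 0.2, 0.3, 0.4, 0.45} (36 entries); at screening
time each SNP's control-sample MAF is snapped to the nearest grid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__ as _pkg_version
from .disease_models import DiseaseModel, reduced_set
from .model_metric import PopulationContext, distance_matrix, feasible_mask

__all__ = [
    "DEFAULT_BIN_GRID",
    "GlobalKMeans",
    "global_kmeans",
    "assign_bin",
    "LibraryEntry",
    "PrototypeLibrary",
    "build_library",
    "ClassicalMDS",
    "mds_embed",
]

DEFAULT_BIN_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.45)


class GlobalKMeans(BaseEstimator):
    """Incremental (global) K-means on a precomputed distance table.

    Parameters
    ----------
    n_clusters : int
        Number of centers to select.

    Notes
    -----
    ``fit`` expects ``D`` of shape (n, n) where ``D[i, j]`` is the
    *directional* cost of representing member ``j`` by center ``i``.
    Centers are chosen greedily: at each step every non-center ``i`` is
    scored by the total nearest-center distance if ``i`` were added, and
    the minimizer joins the center set.  Ties break toward the smallest
    index, so results are deterministic given the input ordering.

    Attributes
    ----------
    center_indices_ : ndarray of shape (n_clusters,)
        Selected centers, in order of selection.
    labels_ : ndarray of shape (n,)
        Index into ``center_indices_`` of each member's nearest center
        (first-added wins ties).
    inertia_path_ : ndarray of shape (n_clusters,)
        Total within-cluster distance after each addition; non-increasing.
    inertia_ : float
        Final total within-cluster distance.
    """

    def __init__(self, n_clusters: int = 7):
        self.n_clusters = n_clusters

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square distance table")
        if not np.isfinite(D).all():
            raise ValueError("distances must be finite")
        n = D.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {self.n_clusters}")

        centers: list[int] = []
        inertia_path: list[float] = []
        best = np.full(n, np.inf)  # nearest-center distance per member
        in_set = np.zeros(n, dtype=bool)
        for _ in range(self.n_clusters):
            # candidate i: members move to i when D[i, :] beats current best
            cand_cost = np.minimum(D, best[None, :]).sum(axis=1)
            cand_cost[in_set] = np.inf
            new = int(np.argmin(cand_cost))  # argmin takes the first minimum
            centers.append(new)
            in_set[new] = True
            best = np.minimum(best, D[new])
            inertia_path.append(float(best.sum()))

        centers_arr = np.array(centers)
        dist_to_centers = D[centers_arr, :]  # (k, n)
        self.labels_ = np.argmin(dist_to_centers, axis=0)
        self.center_indices_ = centers_arr
        self.inertia_path_ = np.array(inertia_path)
        self.inertia_ = inertia_path[-1]
        return self


def global_kmeans(models: Sequence[DiseaseModel], dist: np.ndarray,
                  k: int) -> tuple[list[DiseaseModel], np.ndarray, np.ndarray]:
    """Select ``k`` prototype models from a directional distance table.

    ``dist[i, j]`` must be the distance of candidate-center ``models[i]``
    to member ``models[j]``.  Returns the prototypes in selection order,
    the per-member cluster assignment (index into the prototype list),
    and the within-cluster-distance path.
    """
    if k > len(models):
        raise ValueError(f"cannot select {k} prototypes from {len(models)} models")
    gkm = GlobalKMeans(n_clusters=k).fit(dist)
    protos = [models[i] for i in gkm.center_indices_]
    return protos, gkm.labels_, gkm.inertia_path_


def assign_bin(maf: float, grid: Sequence[float] = DEFAULT_BIN_GRID) -> float:
    """Snap a MAF to the nearest grid value (midpoints round down)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    grid = sorted(grid)
    diffs = [abs(maf - g) for g in grid]
    # first minimum = smaller grid value on exact midpoints
    return grid[int(np.argmin(diffs))]


@dataclass(frozen=True)
class LibraryEntry:
    """Prototype set for one (MAF-bin, MAF-bin) combination."""

    prototype_ids: tuple[str, ...]          # in selection order
    member_ids: tuple[str, ...]             # clustered models (feasible subset)
    labels: tuple[int, ...]                 # cluster index per member
    excluded_ids: tuple[str, ...] = ()      # infeasible at this bin pair

    def prototypes(self) -> list[DiseaseModel]:
        return [DiseaseModel.from_id(i) for i in self.prototype_ids]


@dataclass(frozen=True)
class PrototypeLibrary:
    """Per-MAF-bin-pair prototype model sets plus build parameters."""

    bin_grid: tuple[float, ...]
    k: int
    prevalence: float
    heritability: float
    sample_ratio: float
    entries: Mapping[tuple[float, float], LibraryEntry]
    version: str = _pkg_version

    def entry(self, bin_a: float, bin_b: float) -> LibraryEntry:
        key = (bin_a, bin_b)
        if key not in self.entries:
            raise KeyError(f"library has no entry for MAF bins {key}")
        return self.entries[key]

    def prototypes_for(self, maf_a: float, maf_b: float) -> list[DiseaseModel]:
        """Prototype models for a SNP pair, binning each MAF to the grid."""
        ba = assign_bin(maf_a, self.bin_grid)
        bb = assign_bin(maf_b, self.bin_grid)
        return self.entry(ba, bb).prototypes()

    def validate(self) -> None:
        expected = {(a, b) for a in self.bin_grid for b in self.bin_grid}
        missing = expected - set(self.entries)
        if missing:
            raise ValueError(f"library missing entries for bin pairs {sorted(missing)}")
        for key, entry in self.entries.items():
            if len(entry.prototype_ids) != self.k:
                raise ValueError(
                    f"entry {key} has {len(entry.prototype_ids)} prototypes, "
                    f"expected {self.k}"
                )

    def to_dict(self) -> dict:
        return {
            "format": "epiproto-prototype-library",
            "version": self.version,
            "params": {
                "bin_grid": list(self.bin_grid),
                "k": self.k,
                "prevalence": self.prevalence,
                "heritability": self.heritability,
                "sample_ratio": self.sample_ratio,
            },
            "entries": {
                f"{a:g},{b:g}": {
                    "prototypes": list(e.prototype_ids),
                    "members": list(e.member_ids),
                    "labels": list(e.labels),
                    "excluded": list(e.excluded_ids),
                }
                for (a, b), e in sorted(self.entries.items())
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PrototypeLibrary":
        if data.get("format") != "epiproto-prototype-library":
            raise ValueError("not a prototype library file")
        params = data["params"]
        entries = {}
        for key, e in data["entries"].items():
            a_str, b_str = key.split(",")
            for mid in list(e["prototypes"]) + list(e["members"]):
                if len(mid) != 9 or set(mid) - {"0", "1"}:
                    raise ValueError(f"malformed model id {mid!r} in entry {key}")
            entries[(float(a_str), float(b_str))] = LibraryEntry(
                prototype_ids=tuple(e["prototypes"]),
                member_ids=tuple(e["members"]),
                labels=tuple(int(x) for x in e["labels"]),
                excluded_ids=tuple(e.get("excluded", ())),
            )
        lib = cls(
            bin_grid=tuple(params["bin_grid"]),
            k=int(params["k"]),
            prevalence=float(params["prevalence"]),
            heritability=float(params["heritability"]),
            sample_ratio=float(params["sample_ratio"]),
            entries=entries,
            version=str(data.get("version", "unknown")),
        )
        lib.validate()
        return lib


def build_library(bins: Sequence[float] = DEFAULT_BIN_GRID, k: int = 7,
                  prevalence: float = 0.02, heritability: float = 0.02,
                  sample_ratio: float = 1.0) -> PrototypeLibrary:
    """Cluster the canonical model set at every MAF-bin pair.

    For each of the ``len(bins)**2`` bin combinations, the directional
    distance table over the canonical 143-model set is computed (rows =
    candidate prototypes, columns = members) and incremental K-means
    selects ``k`` prototypes.  Models whose implied penetrances are
    invalid at a bin pair (risk mass too extreme for the prevalence /
    heritability) are dropped from that entry and recorded.
    """
    if not bins:
        raise ValueError("bins must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    models = reduced_set()
    entries: dict[tuple[float, float], LibraryEntry] = {}
    for a in bins:
        for b in bins:
            ctx = PopulationContext(maf_a=a, maf_b=b, prevalence=prevalence,
                                    heritability=heritability,
                                    sample_ratio=sample_ratio)
            ok = feasible_mask(models, ctx)
            feasible = [m for m, f in zip(models, ok) if f]
            excluded = tuple(m.id for m, f in zip(models, ok) if not f)
            if len(feasible) < k:
                raise ValueError(
                    f"only {len(feasible)} feasible models at bins ({a}, {b}); "
                    f"cannot select {k} prototypes"
                )
            dist = distance_matrix(feasible, ctx)
            protos, labels, _ = global_kmeans(feasible, dist, k)
            entries[(a, b)] = LibraryEntry(
                prototype_ids=tuple(m.id for m in protos),
                member_ids=tuple(m.id for m in feasible),
                labels=tuple(int(x) for x in labels),
                excluded_ids=excluded,
            )
    return PrototypeLibrary(bin_grid=tuple(bins), k=k, prevalence=prevalence,
                            heritability=heritability, sample_ratio=sample_ratio,
                            entries=entries)


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and embeds on the top
    eigenvectors.  Exact for configurations that are genuinely Euclidean
    in ``n_components`` dimensions.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    eigenvalues_ : ndarray
        All eigenvalues of the double-centered matrix, descending.
    explained_fraction_ : float
        Share of the positive eigenvalue mass captured by the kept
        components.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        n = D.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (D ** 2) @ j
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        k = self.n_components
        pos = np.clip(vals[:k], 0.0, None)
        self.embedding_ = vecs[:, :k] * np.sqrt(pos)
        self.eigenvalues_ = vals
        total_pos = vals[vals > 0].sum()
        self.explained_fraction_ = float(pos.sum() / total_pos) if total_pos > 0 else 0.0
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_


def mds_embed(ds: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, float]:
    """Classical-scaling coordinates and explained-variation fraction."""
    mds = ClassicalMDS(n_components=n_components).fit(ds)
    return mds.embedding_, mds.explained_fraction_
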