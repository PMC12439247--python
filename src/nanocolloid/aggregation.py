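"""Aggregation-state analysis: contact clustering and dual size histograms.

Aggregates are defined by touching: two particles closer than a contact
cutoff belong to the same aggregate, and membership is transitive
(single-linkage connected components).  The census reports the aggregate
size distribution in both conventions used for dispersion work:

* percentage — particle-weighted: a size-s aggregate contributes s particles,
  so "30% monomers" means 30 out of 100 particles are monomeric;
* mole fraction — entity-weighted: a size-s aggregate counts as one entity.

The default cutoff is 1.2 x the ~7 nm core+shell contact distance,
configurable because segmentation pipelines differ in their touching
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .simulate import Box, ParticleConfiguration

__all__ = [
    "ClusterAssignment",
    "ClusterCensus",
    "find_clusters",
    "census",
    "pooled_census",
    "monomer_fraction",
    "DEFAULT_CUTOFF_FACTOR",
]

DEFAULT_CUTOFF_FACTOR = 1.2


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of particles into contact clusters at a given cutoff."""

    labels: np.ndarray     # per-particle cluster id, 0..n_clusters-1
    cutoff: float          # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def cluster_sizes(self) -> np.ndarray:
        """Multiset of cluster sizes (indexed by cluster id)."""
        return np.bincount(self.labels, minlength=self.n_clusters)


def _contact_pairs(positions: np.ndarray, box: Box, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i<j, with minimum-image distance strictly < cutoff."""
    n = len(positions)
    if n < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if all(box.periodic):
        tree = cKDTree(np.mod(positions, box.lengths), boxsize=box.lengths)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        delta = box.min_image(positions[pairs[:, 0]] - positions[pairs[:, 1]])
        d = np.sqrt(np.einsum("ij,ij->i", delta, delta))
        keep = d < cutoff  # query_pairs includes d == r; the contact rule is strict
        return pairs[keep, 0], pairs[keep, 1]
    if not any(box.periodic):
        tree = cKDTree(positions)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        keep = d < cutoff
        return pairs[keep, 0], pairs[keep, 1]
    # mixed boundaries (slab): brute-force minimum-image pass
    iu, ju = np.triu_indices(n, k=1)
    delta = box.min_image(positions[iu] - positions[ju])
    d = np.sqrt(np.einsum("ij,ij->i", delta, delta))
    keep = d < cutoff
    return iu[keep], ju[keep]


def find_clusters(config: ParticleConfiguration, cutoff: float) -> ClusterAssignment:
    """Single-linkage contact clusters: components of the graph with edges
    between pairs at distance < cutoff (minimum image on periodic axes).

    Labels are deterministic: clusters are numbered by their lowest member
    index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = config.n_particles
    ii, jj = _contact_pairs(config.positions, config.box, cutoff)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, raw = connected_components(graph, directed=False)
    # renumber by lowest member index for determinism
    order = np.full(raw.max() + 1 if n else 0, -1, dtype=int)
    nxt = 0
    labels = np.empty(n, dtype=int)
    for i in range(n):
        c = raw[i]
        if order[c] < 0:
            order[c] = nxt
            nxt += 1
        labels[i] = order[c]
    return ClusterAssignment(labels=labels, cutoff=cutoff)


@dataclass(frozen=True)
class ClusterCensus:
    """Dual aggregate-size histograms.

    ``size_classes[k]`` is the aggregate size; when ``pooled_top`` is True the
    last class collects every aggregate of that size or larger.  ``percentage``
    is particle-weighted (sums to 100), ``mole_fraction`` entity-weighted
    (sums to 1).
    """

    size_classes: np.ndarray
    percentage: np.ndarray
    mole_fraction: np.ndarray
    counts: np.ndarray         # aggregates per class
    n_particles: int
    pooled_top: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_classes", np.asarray(self.size_classes, dtype=int))
        object.__setattr__(self, "percentage", np.asarray(self.percentage, dtype=float))
        object.__setattr__(self, "mole_fraction", np.asarray(self.mole_fraction, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        if abs(self.percentage.sum() - 100.0) > 1e-9:
            raise ValueError("percentage histogram must sum to 100")
        if abs(self.mole_fraction.sum() - 1.0) > 1e-12:
            raise ValueError("mole-fraction histogram must sum to 1")

    @property
    def n_entities(self) -> int:
        return int(self.counts.sum())

    def percentage_of(self, size: int) -> float:
        """Particle-weighted percentage of a size class (0 if absent)."""
        hit = np.nonzero(self.size_classes == size)[0]
        return float(self.percentage[hit[0]]) if len(hit) else 0.0

    def mole_fraction_of(self, size: int) -> float:
        hit = np.nonzero(self.size_classes == size)[0]
        return float(self.mole_fraction[hit[0]]) if len(hit) else 0.0


def census(assignment: ClusterAssignment, max_class: int = 6) -> ClusterCensus:
    """Aggregate-size census with percentage and mole-fraction histograms.

    With c_s aggregates of size s and N particles total,
    percentage_s = 100 * s * c_s / N and mole_s = c_s / sum(c_s); classes at
    or above ``max_class`` are pooled into a single top class.
    """
    if assignment.n_particles == 0:
        raise ValueError("empty assignment")
    return _census_from_sizes(assignment.cluster_sizes, max_class)


def pooled_census(assignments: list[ClusterAssignment], max_class: int = 6) -> ClusterCensus:
    """Census pooled over several frames (aggregates concatenated)."""
    if not assignments or all(a.n_particles == 0 for a in assignments):
        raise ValueError("empty assignments")
    sizes = np.concatenate([a.cluster_sizes for a in assignments])
    return _census_from_sizes(sizes, max_class)


def _census_from_sizes(sizes: np.ndarray, max_class: int) -> ClusterCensus:
    if max_class < 2:
        raise ValueError("max_class must be >= 2")
    n = int(sizes.sum())
    max_size = int(sizes.max())
    c_s = np.bincount(sizes)      # c_s[s] = number of aggregates of size s
    total_entities = len(sizes)

    classes, counts, pct, mole = [], [], [], []
    top = min(max_class, max_size)
    for s in range(1, top):
        classes.append(s)
        counts.append(int(c_s[s]) if s < len(c_s) else 0)
        pct.append(100.0 * s * counts[-1] / n)
        mole.append(counts[-1] / total_entities)
    # top class (pooled if anything at or above it exists in pooled mode)
    pooled = max_size >= max_class
    s_top = top
    count_top = int(c_s[s_top:].sum())
    particles_top = int(sum(s * c_s[s] for s in range(s_top, len(c_s))))
    classes.append(s_top)
    counts.append(count_top)
    pct.append(100.0 * particles_top / n)
    mole.append(count_top / total_entities)
    return ClusterCensus(
        size_classes=np.array(classes), percentage=np.array(pct),
        mole_fraction=np.array(mole), counts=np.array(counts),
        n_particles=n, pooled_top=pooled)


def monomer_fraction(census_: ClusterCensus) -> float:
    """Particle-weighted monomer percentage — the headline stability statistic."""
    return census_.percentage_of(1)
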