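"""Primary-tumor vs PDX-lineage heterogeneity analysis.

Purity is estimated as twice the mode of the somatic VAF distribution in
copy-neutral regions (clonal heterozygous variants in a diploid tumor sit at
VAF = purity/2).  Matched samples are joined into a presence/absence panel
(Euler regions), per-mutation cellular prevalences are computed with a
closed-form diploid-contamination model at multiplicity 1,

    cp = vaf * (purity * CN_local + (1 - purity) * 2) / purity,

and mutations are grouped into clonal clusters by seeded k-means with
silhouette model selection.  Candidate clone trees are enumerated and kept
when every parent's prevalence covers the sum of its children's in every
sample (the sum rule).  This is a deliberately simplified, deterministic
stand-in for Dirichlet-process clustering (PyClone) and full clone-tree
search (ClonEvol).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import AllelicSegment, SampleProfile, SomaticVariant

__all__ = [
    "LineagePanel",
    "CloneCluster",
    "CloneTree",
    "estimate_purity",
    "build_panel",
    "euler_regions",
    "cellular_prevalence",
    "cluster_prevalences",
    "infer_clone_tree",
]


def _variant_key(v: SomaticVariant) -> str:
    return v.id or f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def estimate_purity(variants: list[SomaticVariant],
                    segments: list[AllelicSegment] | None = None,
                    min_depth: int = 30, min_variants: int = 50,
                    bandwidth: float = 0.03) -> float:
    """Purity = min(1, 2 x mode of the filtered VAF distribution).

    Variants are filtered to depth >= min_depth and, when segments are
    supplied, to copy-neutral (total CN 2) regions.  The mode is located by
    a Gaussian kernel density (fixed bandwidth 0.03) evaluated on a grid
    over [0.02, 1].
    """
    vafs = []
    for v in variants:
        if v.depth < min_depth:
            continue
        if segments is not None:
            neutral = None
            for s in segments:
                if s.chrom == v.chrom and s.start_bp <= v.pos <= s.end_bp:
                    neutral = s.total_cn == 2
                    break
            if neutral is False:
                continue
        vafs.append(v.vaf)
    if len(vafs) < min_variants:
        raise ValueError(
            f"insufficient variants for purity estimation "
            f"({len(vafs)} < {min_variants})")
    vafs_arr = np.asarray(vafs)
    grid = np.linspace(0.02, 1.0, 981)
    dens = np.exp(-0.5 * ((grid[:, None] - vafs_arr[None, :]) / bandwidth) ** 2).sum(axis=1)
    mode = float(grid[int(np.argmax(dens))])
    return min(1.0, 2.0 * mode)


@dataclass
class LineagePanel:
    """Matched samples of one patient with a joint detection matrix."""

    samples: list[SampleProfile]
    mutation_universe: tuple[str, ...]
    presence: np.ndarray  # bool, (n_samples, n_mutations)
    variant_lookup: dict[tuple[str, str], SomaticVariant] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def build_panel(samples: list[SampleProfile], detect_vaf: float = 0.05,
                detect_depth: int = 10) -> LineagePanel:
    """Join matched samples over the union of their somatic variants.

    A mutation counts as detected in a sample iff its VAF >= detect_vaf and
    its depth >= detect_depth there.
    """
    if len(samples) < 2:
        raise ValueError("a lineage panel needs at least two samples")
    universe: dict[str, None] = {}
    lookup: dict[tuple[str, str], SomaticVariant] = {}
    for s in samples:
        for v in s.variants:
            key = _variant_key(v)
            universe.setdefault(key, None)
            lookup[(s.sample_id, key)] = v
    keys = tuple(universe)
    idx = {k: j for j, k in enumerate(keys)}
    presence = np.zeros((len(samples), len(keys)), dtype=bool)
    for i, s in enumerate(samples):
        for v in s.variants:
            if v.vaf >= detect_vaf and v.depth >= detect_depth:
                presence[i, idx[_variant_key(v)]] = True
    return LineagePanel(samples=list(samples), mutation_universe=keys,
                        presence=presence, variant_lookup=lookup)


def euler_regions(panel: LineagePanel) -> dict[tuple[str, ...], int]:
    """Mutation counts per presence pattern (keyed by the tuple of sample ids
    the mutations are detected in); counts sum to the universe size."""
    ids = panel.sample_ids
    out: dict[tuple[str, ...], int] = {}
    for j in range(panel.presence.shape[1]):
        pattern = tuple(ids[i] for i in range(len(ids)) if panel.presence[i, j])
        out[pattern] = out.get(pattern, 0) + 1
    return out


def cellular_prevalence(vaf: float, purity: float, local_total_cn: int = 2) -> float:
    """Closed-form cellular prevalence at mutation multiplicity 1, clamped to
    [0, 1]."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    if local_total_cn < 1:
        raise ValueError("local total copy number must be >= 1")
    cp = vaf * (purity * local_total_cn + (1.0 - purity) * 2.0) / purity
    return min(1.0, max(0.0, cp))


def _local_cn(sample: SampleProfile, v: SomaticVariant) -> int | None:
    for s in sample.segments:
        if s.chrom == v.chrom and s.start_bp <= v.pos <= s.end_bp:
            return s.total_cn
    return 2


@dataclass
class CloneCluster:
    cluster_id: int
    members: tuple[str, ...]
    prevalence: dict[str, float]  # sample_id -> mean cellular prevalence
    fraction_of_substitutions: float
    minor: bool = False  # True when fraction < the >=5% reporting rule


def cluster_prevalences(panel: LineagePanel, purities: dict[str, float],
                        min_fraction: float = 0.05, k_max: int = 8,
                        seed: int = 0, n_restarts: int = 10,
                        variance_floor: float = 1e-3) -> list[CloneCluster]:
    """Group mutations by their per-sample cellular-prevalence vectors.

    Undetected mutations enter with prevalence 0 (absence is the signal for
    lineage-private clones).  k is chosen over 1..k_max by maximum mean
    silhouette (k = 1 only when the total prevalence variance falls below the
    variance floor).  Clusters holding < min_fraction of all substitutions
    are flagged minor; the rest are the reported "top" clusters, ordered by
    size.
    """
    n_mut = len(panel.mutation_universe)
    if n_mut < 20:
        raise ValueError("too few mutations to cluster")
    ids = panel.sample_ids
    cp = np.zeros((n_mut, len(ids)))
    for i, s in enumerate(panel.samples):
        purity = purities[s.sample_id]
        for j, key in enumerate(panel.mutation_universe):
            if not panel.presence[i, j]:
                continue
            v = panel.variant_lookup.get((s.sample_id, key))
            if v is None:
                continue
            cn = _local_cn(s, v)
            if cn == 0:
                continue  # no copies: prevalence undefined, excluded
            cp[j, i] = cellular_prevalence(v.vaf, purity, cn)
    total_var = float(cp.var(axis=0).sum())
    if total_var < variance_floor:
        labels = np.zeros(n_mut, dtype=int)
        best_k = 1
    else:
        best_k, best_sil, labels = 1, -np.inf, np.zeros(n_mut, dtype=int)
        for k in range(2, min(k_max, n_mut - 1) + 1):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            lab = km.fit_predict(cp)
            if len(set(lab)) < 2:
                continue
            sil = silhouette_score(cp, lab)
            if sil > best_sil:
                best_k, best_sil, labels = k, sil, lab
    clusters = []
    order = sorted(range(best_k), key=lambda c: -(labels == c).sum())
    for rank, c in enumerate(order):
        members = tuple(panel.mutation_universe[j] for j in np.flatnonzero(labels == c))
        if not members:
            continue
        prev = {ids[i]: float(cp[labels == c, i].mean()) for i in range(len(ids))}
        frac = len(members) / n_mut
        clusters.append(CloneCluster(
            cluster_id=rank, members=members, prevalence=prev,
            fraction_of_substitutions=frac, minor=frac < min_fraction))
    return clusters


@dataclass
class CloneTree:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]  # (parent, child)
    root: int
    slack: float  # total unexplained prevalence across samples/parents

    def children(self, node: int) -> list[int]:
        return [c for p, c in self.edges if p == node]


def _sum_rule_ok(parents: dict[int, int], clusters: dict[int, CloneCluster],
                 sample_ids: list[str], root: int, root_prev: dict[str, float],
                 tolerance: float) -> tuple[bool, float]:
    slack = 0.0
    kids: dict[int, list[int]] = {}
    for c, p in parents.items():
        kids.setdefault(p, []).append(c)
    for node, ch in kids.items():
        prev = root_prev if node == root else clusters[node].prevalence
        for sid in sample_ids:
            child_sum = sum(clusters[c].prevalence[sid] for c in ch)
            gap = prev[sid] - child_sum
            if gap < -tolerance:
                return False, 0.0
            slack += max(0.0, gap)
    return True, slack


def infer_clone_tree(clusters: list[CloneCluster],
                     tolerance: float = 0.05) -> list[CloneTree]:
    """Enumerate rooted trees over the clusters and keep those satisfying the
    sum rule in every sample; results are ordered by total slack (tightest
    first).  The root must be the cluster with maximal prevalence in every
    sample."""
    if len(clusters) > 8:
        raise ValueError("tree enumeration supports at most 8 clusters")
    by_id = {c.cluster_id: c for c in clusters}
    sample_ids = sorted(clusters[0].prevalence)
    # root candidate: maximal worst-case prevalence; it must dominate every
    # other cluster in every sample up to the sum-rule tolerance
    cand = max(clusters, key=lambda c: min(c.prevalence[s] for s in sample_ids))
    if all(cand.prevalence[s] >= by_id[o].prevalence[s] - tolerance
           for o in by_id for s in sample_ids):
        root = cand.cluster_id
    else:
        raise ValueError("no valid root: no cluster dominates in all samples")
    others = [c.cluster_id for c in clusters if c.cluster_id != root]
    trees = []
    if not others:
        return [CloneTree(nodes=(root,), edges=(), root=root, slack=0.0)]
    choices = [ [p for p in by_id if p != c] for c in others ]
    for combo in itertools.product(*choices):
        parents = dict(zip(others, combo))
        # reject cycles: every node must reach the root
        ok = True
        for start in others:
            seen = set()
            node = start
            while node != root:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parents[node]
            if not ok:
                break
        if not ok:
            continue
        valid, slack = _sum_rule_ok(parents, by_id, sample_ids, root,
                                    by_id[root].prevalence, tolerance)
        if valid:
            edges = tuple(sorted((p, c) for c, p in parents.items()))
            trees.append(CloneTree(nodes=tuple(sorted(by_id)), edges=edges,
                                   root=root, slack=slack))
    trees.sort(key=lambda t: (t.slack, t.edges))
    return trees
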