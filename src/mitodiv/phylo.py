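"""Pairwise distances and UPGMA clustering with bootstrap support.

Distances are computed with pairwise deletion of gap/N columns under the
p-distance, Tamura-Nei 1993 (TN93) or Tamura 1992 3-parameter (T92) models,
optionally gamma-rate-corrected.  Trees are built by average-linkage (UPGMA)
agglomeration with a deterministic smallest-index tie-break, yielding
ultrametric rooted trees; bootstrap support is the fraction of
column-resampled replicate trees containing each clade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from sklearn.base import BaseEstimator

from .genome_model import Msa

logger = logging.getLogger(__name__)

MODELS = ("p-distance", "tn93", "t92")


class SaturationWarning(UserWarning):
    """A pairwise distance hit the model's log singularity."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named taxa."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for t, row in zip(self.taxa, self.d):
            lines.append(t + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def _gamma_term(coef: float, w: float, a: float | None) -> float:
    """Contribution -coef*ln(w), or its gamma-rates analogue with shape a."""
    if a is None:
        return -coef * np.log(w)
    return coef * a * (w ** (-1.0 / a) - 1.0)


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, np.ndarray]:
    """Compared sites, A<->G, C<->T, transversion counts and pooled base counts."""
    valid = np.isin(x, list("ACGT")) & np.isin(y, list("ACGT"))
    xs, ys = x[valid], y[valid]
    n = xs.size
    diff = xs != ys
    pair_ag = diff & (np.isin(xs, ("A", "G")) & np.isin(ys, ("A", "G")))
    pair_ct = diff & (np.isin(xs, ("C", "T")) & np.isin(ys, ("C", "T")))
    tv = diff & ~pair_ag & ~pair_ct
    pooled = np.concatenate([xs, ys])
    base_counts = np.array([(pooled == b).sum() for b in "ACGT"], dtype=float)
    return n, int(pair_ag.sum()), int(pair_ct.sum()), int(tv.sum()), base_counts


def _tn93(P1: float, P2: float, Q: float, freqs: np.ndarray, a: float | None) -> float:
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
    w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise FloatingPointError("saturated")
    d = 0.0
    if k1 > 0:
        d += _gamma_term(k1, w1, a)
    if k2 > 0:
        d += _gamma_term(k2, w2, a)
    d += _gamma_term(k3, w3, a)
    return d


def _t92(P: float, Q: float, theta: float, a: float | None) -> float:
    h = 2 * theta * (1 - theta)
    w1 = 1 - P / h - Q if h > 0 else 1.0
    w2 = 1 - 2 * Q
    if min(w1, w2) <= 0:
        raise FloatingPointError("saturated")
    d = 0.0
    if h > 0:
        d += _gamma_term(h, w1, a)
    d += _gamma_term(0.5 * (1 - h), w2, a)
    return d


def pairwise_distance(
    msa: Msa,
    model: str = "p-distance",
    gamma: float | None = None,
    ceiling: float = 5.0,
) -> DistanceMatrix:
    """Pairwise distances under the chosen substitution model.

    Columns where either sequence has a gap or N are deleted per pair
    (pairwise deletion).  ``gamma`` is the gamma-rate shape parameter (e.g.
    0.18 for control-region alignments); saturated pairs are set to
    ``ceiling`` with a warning.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    arr = msa.as_array()
    n = msa.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nc, nag, nct, ntv, bases = _pair_counts(arr[i], arr[j])
            if nc == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            P1, P2, Q = nag / nc, nct / nc, ntv / nc
            try:
                if model == "p-distance":
                    dist = P1 + P2 + Q
                elif model == "tn93":
                    dist = _tn93(P1, P2, Q, bases / bases.sum(), gamma)
                else:
                    theta = (bases[1] + bases[2]) / bases.sum()  # GC content
                    dist = _t92(P1 + P2, Q, theta, gamma)
            except FloatingPointError:
                warnings.warn(
                    f"saturated pair {msa.ids[i]}/{msa.ids[j]}; distance set to {ceiling}",
                    SaturationWarning,
                )
                dist = ceiling
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree with node heights and optional clade support."""

    tree: dendropy.Tree
    heights: dict[int, float]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clades(self) -> set[frozenset[str]]:
        """Leaf-label sets of all non-trivial internal nodes."""
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(leaves) < len(self.tree.taxon_namespace):
                out.add(leaves)
        return out

    def leaf_root_distances(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out


def upgma(dm: DistanceMatrix) -> UpgmaTree:
    """Average-linkage agglomeration; join height = d/2; deterministic
    smallest-(i, j) tie-break on the current cluster ordering."""
    n = len(dm.taxa)
    ns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        nodes.append(node)
    heights = [0.0] * n
    sizes = [1] * n
    d = dm.d.astype(float).copy()
    active = list(range(n))
    heights_by_id: dict[int, float] = {id(nd): 0.0 for nd in nodes}
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                dij = d[active[ai], active[aj]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, ai, aj)
        dij, ai, aj = best
        i, j = active[ai], active[aj]
        h = dij / 2.0
        parent = dendropy.Node()
        for child_idx in (i, j):
            child = nodes[child_idx]
            parent.add_child(child)
            child.edge.length = max(0.0, h - heights[child_idx])
        nodes.append(parent)
        heights.append(h)
        sizes.append(sizes[i] + sizes[j])
        heights_by_id[id(parent)] = h
        # Lance-Williams average-linkage update against all other clusters
        new_row = np.zeros(len(nodes))
        for ak in range(len(active)):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    tree.seed_node = nodes[-1]
    return UpgmaTree(tree=tree, heights=heights_by_id)


def bootstrap_support(
    msa: Msa,
    model: str = "p-distance",
    n_reps: int = 100,
    seed: int = 0,
    gamma: float | None = None,
) -> tuple[UpgmaTree, dict[frozenset[str], float]]:
    """UPGMA tree with clade supports from column-resampled replicates.

    Support is the fraction of replicate trees containing each internal
    clade; supports are written onto the internal node labels as percentages.
    Reproducible under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = upgma(pairwise_distance(msa, model=model, gamma=gamma))
    counts: dict[frozenset[str], int] = {c: 0 for c in base.clades()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = upgma(pairwise_distance(msa.resample_columns(idx), model=model, gamma=gamma))
        for clade in rep.clades():
            if clade in counts:
                counts[clade] += 1
    supports = {c: n / n_reps for c, n in counts.items()}
    for node in base.tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if leaves in supports:
            node.label = f"{100 * supports[leaves]:.0f}"
    return base, supports


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


class UpgmaTreeBuilder(BaseEstimator):
    """Distance-matrix + UPGMA tree estimator over an alignment.

    Parameters
    ----------
    model : 'p-distance' | 'tn93' | 't92'
    gamma : gamma-rate shape (None for uniform rates)
    n_bootstrap : bootstrap replicates (0 disables support values)
    seed : resampling seed
    ceiling : distance assigned to saturated pairs

    Attributes
    ----------
    distance_matrix_ : DistanceMatrix
    tree_ : UpgmaTree
    supports_ : dict clade -> support fraction (empty without bootstrap)
    """

    def __init__(self, model: str = "p-distance", gamma: float | None = None,
                 n_bootstrap: int = 0, seed: int = 0, ceiling: float = 5.0):
        self.model = model
        self.gamma = gamma
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        self.ceiling = ceiling

    def fit(self, msa: Msa, y=None) -> "UpgmaTreeBuilder":
        self.distance_matrix_ = pairwise_distance(
            msa, model=self.model, gamma=self.gamma, ceiling=self.ceiling
        )
        if self.n_bootstrap > 0:
            self.tree_, self.supports_ = bootstrap_support(
                msa, model=self.model, n_reps=self.n_bootstrap,
                seed=self.seed, gamma=self.gamma,
            )
        else:
            self.tree_ = upgma(self.distance_matrix_)
            self.supports_ = {}
        return self
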