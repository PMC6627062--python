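"""ISG ratio matrix, Ward clustering, and High/Low MLT-int subject grouping.

For each interferon-stimulated gene (ISG) in a configurable panel, the
Post14d/Pre ratio (expression 14 days after induction over baseline) is
computed per subject. Subjects are then clustered with Ward's method on
squared Euclidean distances via the Lance-Williams recurrence; merge
heights are the increase in within-cluster error sum of squares (ESS),
the classical Ward objective.

Separately, each subject's representative MLT-int expression is the mean
of its values at the three timepoints (pre, 24 h post, 14 d post); the
mean of these representatives over subjects is the threshold splitting
subjects into "High MLT-int" (representative >= threshold; ties go High)
and "Low MLT-int" groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

TIMEPOINTS = ("pre", "post24h", "post14d")


def build_ratio_matrix(
    fpkm_pre: pd.DataFrame,
    fpkm_post14d: pd.DataFrame,
    panel: list[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Elementwise Post14d/Pre expression ratios for a gene panel.

    Inputs are gene x subject FPKM matrices. Panel genes missing from
    either matrix are dropped with a warning; subjects are intersected
    (order of ``fpkm_pre`` preserved) and must be non-empty.
    """
    subjects = [s for s in fpkm_pre.columns if s in set(fpkm_post14d.columns)]
    if not subjects:
        raise ValueError("no common subjects between pre and post14d matrices")
    genes = []
    for gene in panel:
        if gene in fpkm_pre.index and gene in fpkm_post14d.index:
            genes.append(gene)
        else:
            warnings.warn(f"panel gene {gene} missing from input; dropped",
                          stacklevel=2)
    if not genes:
        raise ValueError("no panel genes present in both matrices")
    pre = fpkm_pre.loc[genes, subjects].astype(float) + pseudocount
    post = fpkm_post14d.loc[genes, subjects].astype(float) + pseudocount
    if (pre.to_numpy() <= 0).any():
        raise ValueError("non-positive pre expression; supply a pseudocount")
    return post / pre


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` holds (step, cluster_a, cluster_b, height) with scipy-style
    cluster ids: leaves are 0..n-1 in ``labels`` order and the merge at
    step s creates cluster n+s. The height of a merge is the Ward
    objective (ESS) increase caused by that merge.
    """

    labels: list[str]
    merges: list[tuple[int, int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for step, a, b, _ in self.merges:
            members[self.n_leaves + step] = members[a] + members[b]
        return members

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (0..k-1) obtained by undoing the last k-1 merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [1, {self.n_leaves}]")
        members = self._members()
        active = set(range(self.n_leaves))
        for step, a, b, _ in self.merges[: self.n_leaves - k]:
            active -= {a, b}
            active.add(self.n_leaves + step)
        assignment: dict[str, int] = {}
        for cluster_index, cid in enumerate(sorted(active)):
            for leaf in members[cid]:
                assignment[self.labels[leaf]] = cluster_index
        return pd.Series(assignment).reindex(self.labels)

    def to_newick(self) -> str:
        """Newick string; branch length = parent merge height - child height."""
        node: dict[int, tuple[str, float]] = {
            i: (label, 0.0) for i, label in enumerate(self.labels)
        }
        top = self.n_leaves - 1 if not self.merges else None
        for step, a, b, height in self.merges:
            (sa, ha), (sb, hb) = node[a], node[b]
            node[self.n_leaves + step] = (
                f"({sa}:{height - ha:g},{sb}:{height - hb:g})",
                height,
            )
            top = self.n_leaves + step
        return node[top][0] + ";"


def ward_cluster(matrix: pd.DataFrame, axis: str = "subjects") -> Dendrogram:
    """Ward's-method agglomerative clustering on squared Euclidean distance.

    ``matrix`` is gene x subject; ``axis`` chooses which margin is
    clustered (subjects, i.e. columns, by default). Implemented with the
    Lance-Williams update

        D(ij,k) = [(n_i+n_k) D(i,k) + (n_j+n_k) D(j,k) - n_k D(i,j)]
                  / (n_i + n_j + n_k)

    starting from pairwise squared Euclidean distances, under which the
    merge cost D(i,j) equals twice the ESS increase; reported heights are
    the ESS increase itself. Ties break on the smallest (id_a, id_b) pair.
    """
    if axis == "subjects":
        data = matrix.T
    elif axis == "genes":
        data = matrix
    else:
        raise ValueError(f"unknown axis {axis!r}")
    labels = [str(x) for x in data.index]
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN entries")
    n = X.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 items")

    dist: dict[tuple[int, int], float] = {}
    sq = squareform(pdist(X, metric="sqeuclidean"))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(sq[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, int, float]] = []

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    for step in range(n - 1):
        best = min(
            ((d(a, b), a, b) for a in active for b in active if a < b),
            key=lambda t: (t[0], t[1], t[2]),
        )
        cost, a, b = best
        new = n + step
        merges.append((step, a, b, cost / 2.0))
        for k in active:
            if k in (a, b):
                continue
            na, nb, nk = size[a], size[b], size[k]
            dist[(min(k, new), max(k, new))] = (
                (na + nk) * d(a, k) + (nb + nk) * d(b, k) - nk * cost
            ) / (na + nb + nk)
        active -= {a, b}
        active.add(new)
        size[new] = size[a] + size[b]
    return Dendrogram(labels=labels, merges=merges)


@dataclass
class MltGrouping:
    """High/Low grouping of subjects by representative MLT-int expression."""

    table: pd.DataFrame  # subject-indexed: representative, label
    threshold: float


def mlt_grouping(mlt_rpkm: pd.DataFrame) -> MltGrouping:
    """Group subjects by mean MLT-int expression over the three timepoints.

    ``mlt_rpkm`` is subject x timepoint with columns pre, post24h, post14d.
    Representative = row mean; threshold = mean of representatives; label
    High iff representative >= threshold (tie goes High).
    """
    missing_cols = [t for t in TIMEPOINTS if t not in mlt_rpkm.columns]
    if missing_cols:
        raise ValueError(f"missing timepoint column(s): {missing_cols}")
    values = mlt_rpkm[list(TIMEPOINTS)].astype(float)
    bad = values.index[values.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing timepoint value for subject(s) {list(bad)}")
    representative = values.mean(axis=1)
    threshold = float(representative.mean())
    labels = np.where(representative >= threshold, "High", "Low")
    table = pd.DataFrame(
        {"representative": representative, "label": labels}, index=values.index
    )
    return MltGrouping(table=table, threshold=threshold)
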