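"""Morphology classification: per-sample averaging, average-linkage clustering
and assignment against a labeled reference panel.

Per-sample mean descriptor vectors are compared by hierarchical agglomerative
clustering with Euclidean distance and average linkage (UPGMA): the distance
between two clusters is the mean over all cross pairs of member distances.
The agglomeration is written out explicitly rather than delegated so that
tie-breaking is fully specified (among equal minimal distances, merge the
pair with lexicographically smallest cluster ids) and therefore identical
across platforms; scipy's implementation is used as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "sample_mean_fd",
    "hcluster",
    "cut_tree",
    "classify_samples",
    "export_newick",
    "silhouette_report",
]


def _descriptor_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("D") and c[1:].isdigit()]
    if not cols:
        raise ValueError("no descriptor columns (D1, D2, ...) found")
    return sorted(cols, key=lambda c: int(c[1:]))


def sample_mean_fd(vessel_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean descriptor vector per sample.

    Input is a per-vessel table with a sample_id column and D1..DK columns
    (as produced by :func:`vesselmorph.efd_core.descriptor_table`). Returns
    one row per sample with the mean descriptors and the vessel count; rows
    with missing descriptor values are rejected.
    """
    cols = _descriptor_columns(vessel_table)
    if vessel_table[cols].isna().any().any():
        raise ValueError("descriptor table contains missing values")
    grouped = vessel_table.groupby("sample_id", sort=True)
    out = grouped[cols].mean()
    out["n_vessels"] = grouped.size()
    return out.reset_index()


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form.

    ``merges`` is an (n-1, 4) array; row s merges cluster ids i and j (leaves
    are 0..n-1, the cluster created by step s gets id n+s) at average-linkage
    height ``merges[s, 2]``, producing a cluster of ``merges[s, 3]`` leaves.
    """

    merges: np.ndarray
    ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hcluster(m: pd.DataFrame, id_col: str = "sample_id") -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration on Euclidean distances.

    Deterministic: among pairs at the minimal distance the pair with the
    lexicographically smallest (id, id) is merged first. Merge heights are
    asserted non-decreasing (average linkage is monotone).
    """
    ids = [str(v) for v in m[id_col].tolist()]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate row ids in descriptor matrix")
    if len(ids) < 2:
        raise ValueError("clustering needs at least 2 rows")
    x = m[_descriptor_columns(m)].to_numpy(dtype=float)
    n = len(ids)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = np.empty((n - 1, 4), dtype=float)
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                dij = dist[(i, j)]
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        h, i, j = best
        new = n + step
        ni, nj = active.pop(i), active.pop(j)
        for k in sorted(active):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(k, new)] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(i, j)]
        active[new] = ni + nj
        merges[step] = (i, j, h, ni + nj)
    if np.any(np.diff(merges[:, 2]) < -1e-12):
        raise AssertionError("average-linkage merge heights must be non-decreasing")
    return Dendrogram(merges=merges, ids=ids)


def _leaf_sets(dend: Dendrogram) -> list[set[int]]:
    """Leaf membership of every cluster id (leaves then internal nodes)."""
    n = dend.n_leaves
    sets: list[set[int]] = [{i} for i in range(n)]
    for i, j, _, _ in dend.merges:
        sets.append(sets[int(i)] | sets[int(j)])
    return sets

def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Partition the leaves into k clusters by undoing the k-1 last merges.

    Ties in merge height are resolved by merge order: earlier merges stay
    merged. Returns a Series mapping leaf id to a cluster number (0-based,
    numbered by first appearance in leaf order).
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        i, j, _, _ = dend.merges[step]
        root = n + step
        parent[find(int(i))] = root
        parent[find(int(j))] = root
    roots = [find(i) for i in range(n)]
    renumber: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in renumber:
            renumber[r] = len(renumber)
        labels.append(renumber[r])
    return pd.Series(labels, index=dend.ids, name="cluster")


def _centroids(panel: pd.DataFrame, label_col: str) -> pd.DataFrame:
    return panel.groupby(label_col)[_descriptor_columns(panel)].mean()


def classify_samples(
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    method: str = "centroid",
    label_col: str = "label",
    id_col: str = "sample_id",
) -> pd.DataFrame:
    """Assign each sample row a morphology label from a labeled reference panel.

    centroid: nearest reference-class centroid in descriptor space.
    cocluster: samples and panel rows are clustered jointly (average linkage);
    the tree is cut at the largest k at which every cluster still contains at
    least one panel member, and each sample takes the majority panel label of
    its cluster. Samples landing with no panel member (cannot happen at that
    k, but kept as a guard for degenerate inputs) fall back to the centroid
    rule and are flagged.

    Returns a DataFrame with sample_id, label, distance (Euclidean distance
    to the assigned class centroid), method and fallback flag.
    """
    cols = _descriptor_columns(samples)
    if cols != _descriptor_columns(panel):
        raise ValueError("samples and panel have different descriptor columns")
    cents = _centroids(panel, label_col)

    def centroid_label(row: np.ndarray) -> tuple[str, float]:
        dists = np.sqrt(((cents.to_numpy() - row) ** 2).sum(axis=1))
        best = int(np.argmin(dists))
        return str(cents.index[best]), float(dists[best])

    x = samples[cols].to_numpy(dtype=float)
    rows = []
    if method == "centroid":
        for sid, row in zip(samples[id_col], x):
            label, dd = centroid_label(row)
            rows.append(
                {id_col: sid, "label": label, "distance": dd,
                 "method": "centroid", "fallback": False}
            )
    elif method == "cocluster":
        joint = pd.concat(
            [
                samples[[id_col] + cols].assign(_role="sample"),
                panel.rename(columns={label_col: "_panel_label"}).assign(
                    _role="panel",
                    **{id_col: [f"panel::{i}" for i in range(len(panel))]},
                )[[id_col, "_panel_label", "_role"] + cols],
            ],
            ignore_index=True,
        )
        dend = hcluster(joint, id_col=id_col)
        panel_mask = (joint["_role"] == "panel").to_numpy()
        chosen = None
        for k in range(len(joint), 0, -1):
            part = cut_tree(dend, k).to_numpy()
            if all(panel_mask[part == c].any() for c in np.unique(part)):
                chosen = part
                break
        panel_labels = joint["_panel_label"].to_numpy()
        for idx in np.nonzero(~panel_mask)[0]:
            cluster = chosen[idx]
            members = panel_mask & (chosen == cluster)
            if members.any():
                counts = pd.Series(panel_labels[members]).value_counts()
                label = str(counts.index[0])
                dd = float(
                    np.sqrt(((cents.loc[label].to_numpy() - x[idx]) ** 2).sum())
                ) if label in cents.index else np.nan
                fallback = False
            else:  # degenerate guard
                label, dd = centroid_label(x[idx])
                fallback = True
                warnings.warn(
                    f"sample {joint[id_col].iloc[idx]!r}: cluster without panel "
                    "members, fell back to centroid rule",
                    stacklevel=2,
                )
            rows.append(
                {id_col: joint[id_col].iloc[idx], "label": label, "distance": dd,
                 "method": "cocluster", "fallback": fallback}
            )
    else:
        raise ValueError("method must be 'centroid' or 'cocluster'")
    return pd.DataFrame(rows)


def export_newick(dend: Dendrogram) -> str:
    """Newick text of the merge tree; branch lengths are height differences.

    Leaves sit at height 0, so a pair of leaves merged at height h becomes
    "(A:h,B:h);".
    """
    n = dend.n_leaves
    heights = np.concatenate([np.zeros(n), dend.merges[:, 2]])

    def esc(name: str) -> str:
        # underscores are quoted too: unquoted they read back as spaces
        if any(ch in name for ch in " _():,;'\t\n"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def render(node: int, parent_h: float) -> str:
        length = parent_h - heights[node]
        if node < n:
            return f"{esc(dend.ids[node])}:{length:g}"
        i, j, _, _ = dend.merges[node - n]
        inner = f"({render(int(i), heights[node])},{render(int(j), heights[node])})"
        return f"{inner}:{length:g}"

    root = 2 * n - 2
    i, j, _, _ = dend.merges[-1]
    h = heights[root]
    return f"({render(int(i), h)},{render(int(j), h)});"


def silhouette_report(
    m: pd.DataFrame, dend: Dendrogram, k_range: range = range(2, 7)
) -> pd.DataFrame:
    """Mean silhouette width of the dendrogram cut at each k, to guide k."""
    from sklearn.metrics import silhouette_score

    x = m[_descriptor_columns(m)].to_numpy(dtype=float)
    rows = []
    for k in k_range:
        if not 2 <= k <= len(x) - 1:
            continue
        labels = cut_tree(dend, k).to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        rows.append({"k": k, "mean_silhouette": silhouette_score(x, labels)})
    return pd.DataFrame(rows)
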