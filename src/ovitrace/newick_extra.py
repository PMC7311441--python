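"""Terminal-branch affinity analysis of labelled phylogenies.

Large intraspecific trees cluster by haplogroup, which hides the
relationships between populations.  The idea implemented here is to read
the tree only at its terminal level: for each leaf, its *level-1
neighbours* are the other leaves of the smallest clade (>= 2 leaves)
containing it — the sister leaf of a cherry, or all co-members of a
terminal polytomy.  Counting, for every focal breed, how often each
partner breed appears among its leaves' neighbours yields an asymmetric
breed-connection matrix; row-normalised percentages quantify each breed's
affinity profile, and can be aggregated from breeds to geographic regions.

The module also provides matrix concordance (Pearson correlation over
paired cells, used to compare tree-derived and network-derived connection
matrices) and a deterministic neighbour-joining builder as plumbing for
simulated data.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "parse_newick",
    "write_newick",
    "level1_neighbors",
    "affinity_matrix",
    "to_percent",
    "aggregate_regions",
    "matrix_concordance",
    "nj_tree",
]


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (multifurcations allowed) into a tree.

    Unary internal nodes are suppressed so that every internal node has at
    least two children; duplicate leaf labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse newick: {exc}") from exc
    tree.suppress_unifurcations()
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def _leaf_labels(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def level1_neighbors(tree: dendropy.Tree, leaf_label: str) -> set[str]:
    """Other leaves of the smallest >=2-leaf clade containing the focal leaf.

    For a cherry this is the sister leaf; under a terminal polytomy it is
    every co-member.  The relation is asymmetric: in ((M1,I1),(M2,(M3,I2)))
    the neighbours of M2 are {M3, I2} while the neighbours of M3 are {I2}.
    """
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == leaf_label:
            node = lf
            break
    if node is None:
        raise NewickError(f"leaf {leaf_label!r} not in tree")
    anc = node.parent_node
    if anc is None:
        raise NewickError("single-leaf tree has no neighbours")
    labels = set(_leaf_labels(anc))
    labels.discard(leaf_label)
    if not labels:
        raise NewickError("tree contains an unresolved unary node")
    return labels


def affinity_matrix(
    tree: dendropy.Tree,
    breed_of: Mapping[str, str],
    include_self: bool = True,
    percent: bool = False,
) -> pd.DataFrame:
    """Asymmetric breed-connection matrix from level-1 neighbour counts.

    ``counts[b, b']`` sums, over all leaves of breed ``b``, the occurrences
    of breed ``b'`` among their level-1 neighbours.  With ``percent=True``
    rows are normalised to sum to 100.  ``include_self=False`` zeroes
    within-breed connections before normalisation.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for lf in leaves:
        if lf not in breed_of:
            raise NewickError(f"leaf {lf!r} has no breed label")
    breeds = sorted(set(breed_of[lf] for lf in leaves))
    M = pd.DataFrame(0, index=breeds, columns=breeds, dtype=float)
    for lf in leaves:
        focal = breed_of[lf]
        for nb in level1_neighbors(tree, lf):
            M.loc[focal, breed_of[nb]] += 1
    if not include_self:
        np.fill_diagonal(M.values, 0.0)
    if percent:
        return to_percent(M)
    return M


def to_percent(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a count matrix to percentages (rows sum to 100)."""
    sums = counts.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("cannot normalise a row with zero total")
    return counts.div(sums, axis=0) * 100.0


def aggregate_regions(
    counts: pd.DataFrame,
    region_of: Mapping[str, str],
    percent: bool = False,
) -> pd.DataFrame:
    """Sum partner-breed columns into regions (e.g. Moroccan / Iberian /
    Italian / Oriental), keeping focal breeds as rows."""
    missing = [b for b in counts.columns if b not in region_of]
    if missing:
        raise ValueError(f"breeds without region: {missing}")
    regions = sorted(set(region_of[b] for b in counts.columns))
    out = pd.DataFrame(0.0, index=counts.index, columns=regions)
    for b in counts.columns:
        out[region_of[b]] += counts[b]
    if percent:
        return to_percent(out)
    return out


def matrix_concordance(
    m1: pd.DataFrame | np.ndarray, m2: pd.DataFrame | np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation between two matrices over paired cells.

    Returns ``(r, p, N)`` where N is the number of paired cells and p is
    the two-sided p-value from the t transform.  Raises if either matrix
    has zero variance.
    """
    x = np.asarray(m1, dtype=float).ravel()
    y = np.asarray(m2, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("matrices differ in shape")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), x.size


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Plumbing for simulated data: taxa are canonicalised to sorted order so
    the result is deterministic, and the saitou-nei agglomeration is
    delegated to scikit-bio.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    D = distances
    ids = sorted(D.index)
    D = D.loc[ids, ids]
    arr = np.asarray(D, dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(arr, ids=ids)
    tn = _skbio_nj(dm)
    return parse_newick(str(tn))
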