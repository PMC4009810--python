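"""Phylogenetic diversity (PD) of tip subsets and derived spatial indices.

PD here follows the rooted convention: the PD of a set of tips is the total
length of all branches on the union of their root-to-tip paths, including a
stem above the root when one is present.  The deep branch subtending a clade
is therefore counted as long as *any* member survives — which is what makes
the loss of a clade's last member a phylogenetic tipping point.

The spatial indices treat a branch as "represented" in a locality whenever
the branch lies on the root path of a tip occurring there; equivalently, the
branch's geographic range is the union of its descendant tips' locality sets.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .tree import Node, PhyloTree, TipMetadata

__all__ = [
    "pd_value",
    "pd_loss",
    "pd_endemism",
    "pd_dissimilarity",
    "dissimilarity_matrix",
    "hpd1",
    "tip_localities",
    "branch_range",
]


def _check_tips(tree: PhyloTree, tips: Iterable[str]) -> frozenset[str]:
    tips = frozenset(tips)
    known = set(tree.tip_labels)
    unknown = tips - known
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    return tips


def pd_value(tree: PhyloTree, tips: Iterable[str] | None = None, rooted: bool = True) -> float:
    """PD of a tip subset: summed length of branches connecting it to the root.

    With ``rooted=False`` the path is taken only to the subset's most recent
    common ancestor (MRCA-spanning PD); all worked examples in this package
    use the rooted form, which is the default.
    """
    if tips is None:
        tips = tree.tip_labels
    subset = _check_tips(tree, tips)
    if not subset:
        return 0.0
    covered = [b for b in tree.branches() if b.tipset & subset]
    if rooted:
        return float(sum(b.length for b in covered))
    # unrooted variant: drop branches ancestral to the whole subset
    return float(sum(b.length for b in covered if not subset <= b.tipset))


def pd_loss(tree: PhyloTree, lost_tips: Iterable[str]) -> float:
    """PD lost when ``lost_tips`` go extinct.

    Equals ``pd(all) - pd(survivors)``: the total length of branches whose
    entire descendant-tip set is lost.
    """
    lost = _check_tips(tree, lost_tips)
    return float(sum(b.length for b in tree.branches() if b.tipset <= lost)) if lost else 0.0


# ---------------------------------------------------------------------------
# Occupancy-based indices


def tip_localities(occupancy: Mapping[str, TipMetadata] | Mapping[str, frozenset]) -> dict[str, frozenset[str]]:
    """Normalise an occupancy source to ``tip -> frozenset(localities)``.

    Accepts either a metadata map or a plain ``tip -> set`` mapping.  Tips
    with empty locality sets are treated as present nowhere (with a warning),
    so they never make a branch "represented" anywhere.
    """
    out: dict[str, frozenset[str]] = {}
    empty = []
    for tip, value in occupancy.items():
        locs = value.localities if isinstance(value, TipMetadata) else frozenset(value)
        if not locs:
            empty.append(tip)
        out[tip] = frozenset(locs)
    if empty:
        warnings.warn(
            f"{len(empty)} tip(s) have no recorded localities and are treated "
            f"as present nowhere: {sorted(empty)[:5]}",
            stacklevel=2,
        )
    return out


def branch_range(branch: Node, localities: Mapping[str, frozenset[str]]) -> frozenset[str]:
    """Geographic range of a branch: union of descendant-tip locality sets."""
    out: set[str] = set()
    for tip in branch.tipset:
        out.update(localities.get(tip, frozenset()))
    return frozenset(out)


def pd_endemism(
    tree: PhyloTree,
    occupancy: Mapping[str, TipMetadata] | Mapping[str, frozenset],
    locality_set: Iterable[str],
) -> float:
    """Total length of branches whose whole geographic range lies in ``locality_set``.

    Branches occurring nowhere (range empty) are excluded; an empty target
    set yields 0 with a warning.
    """
    target = frozenset(locality_set)
    if not target:
        warnings.warn("empty locality set: PD-endemism is 0 by convention", stacklevel=2)
        return 0.0
    locs = tip_localities(occupancy)
    total = 0.0
    for b in tree.branches():
        rng = branch_range(b, locs)
        if rng and rng <= target:
            total += b.length
    return float(total)


def _represented(tree: PhyloTree, locs: Mapping[str, frozenset[str]], locality: str) -> set[Node]:
    present = {tip for tip, s in locs.items() if locality in s}
    return {b for b in tree.branches() if b.tipset & present}


def pd_dissimilarity(
    tree: PhyloTree,
    occupancy: Mapping[str, TipMetadata] | Mapping[str, frozenset],
    locality_i: str,
    locality_j: str,
    weighted: bool = True,
) -> float:
    """Branch-based PD dissimilarity DPD(i, j) between two localities.

    Counts branches represented in exactly one of the two localities —
    summed by length (default) or as a bare count (``weighted=False``),
    mirroring a Jaccard-style unshared-branch measure.
    """
    locs = tip_localities(occupancy)
    all_locs = set().union(*locs.values()) if locs else set()
    for loc in (locality_i, locality_j):
        if loc not in all_locs:
            raise KeyError(f"unknown locality: {loc!r}")
    bi = _represented(tree, locs, locality_i)
    bj = _represented(tree, locs, locality_j)
    diff = bi ^ bj
    return float(sum(b.length for b in diff)) if weighted else float(len(diff))


def dissimilarity_matrix(
    tree: PhyloTree,
    occupancy: Mapping[str, TipMetadata] | Mapping[str, frozenset],
    weighted: bool = True,
) -> pd.DataFrame:
    """Symmetric DPD matrix over every locality in the occupancy data."""
    locs = tip_localities(occupancy)
    names = sorted(set().union(*locs.values())) if locs else []
    reps = {name: _represented(tree, locs, name) for name in names}
    n = len(names)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            diff = reps[names[a]] ^ reps[names[b]]
            val = sum(br.length for br in diff) if weighted else len(diff)
            mat[a, b] = mat[b, a] = val
    return pd.DataFrame(mat, index=names, columns=names)


def hpd1(
    tree: PhyloTree,
    occupancy: Mapping[str, TipMetadata] | Mapping[str, frozenset],
    weighted: bool = True,
) -> float:
    """Regional PD heterogeneity: mean DPD over all unordered locality pairs.

    Falls as localities share more of the tree (biotic homogenization); needs
    at least two localities.
    """
    mat = dissimilarity_matrix(tree, occupancy, weighted=weighted)
    n = len(mat)
    if n < 2:
        raise ValueError("HPD1 needs at least two localities")
    upper = mat.values[np.triu_indices(n, k=1)]
    return float(upper.mean())
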