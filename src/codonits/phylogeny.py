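"""IUPAC-aware p-distances, neighbor joining, bootstrap, clade queries.

The thirteen ITS haplotypes (nine cultivar types plus four pure lines)
are gap-free, pre-aligned 655-nt sequences differing at no more than four
sites, so the uncorrected p-distance is adequate; a Jukes-Cantor
correction is available behind a flag for completeness. Ambiguity codes
contribute fractionally: the per-site mismatch between base sets A and B
is 1 - |A ∩ B| / max(|A|, |B|), so e.g. C vs Y counts half a difference.

Trees are built by Saitou-Nei neighbor joining (via scikit-bio, negative
branch-length estimates clamped to zero) with site-resampling bootstrap
supports expressed in percent.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .iupac import expand

logger = logging.getLogger(__name__)


def site_mismatch(code_a: str, code_b: str) -> float:
    """Fractional mismatch between two IUPAC codes."""
    a, b = expand(code_a), expand(code_b)
    return 1.0 - len(a & b) / max(len(a), len(b))


def pairwise_distance(seq_a: str, seq_b: str, model: str = "p") -> float:
    """Mean per-site fractional mismatch between two aligned sequences.

    ``model='jc69'`` applies the Jukes-Cantor correction
    d = -3/4 ln(1 - 4p/3) to the p-distance.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if not seq_a:
        raise ValueError("empty sequences")
    p = sum(site_mismatch(a, b) for a, b in zip(seq_a, seq_b)) / len(seq_a)
    if model == "p":
        return p
    if model == "jc69":
        if p >= 0.75:
            raise ValueError("JC69 undefined for p-distance >= 0.75")
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown distance model {model!r}")


def _mismatch_tensor(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Per-site mismatch array of shape (n_sites, n, n) for fast resampling."""
    labels = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    (L,) = lengths
    n = len(labels)
    M = np.zeros((L, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            col = np.fromiter(
                (site_mismatch(a, b) for a, b in zip(seqs[labels[i]],
                                                     seqs[labels[j]])),
                dtype=float, count=L)
            M[:, i, j] = M[:, j, i] = col
    return labels, M


def distance_matrix(seqs: dict[str, str], model: str = "p") -> DistanceMatrix:
    """Symmetric pairwise distance matrix over a label -> sequence mapping."""
    labels = list(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[labels[i]],
                                                  seqs[labels[j]], model=model)
    return DistanceMatrix(d, labels)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("distance matrix contains non-finite entries")
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.any(dm.data < 0):
        logger.warning("negative input distances clamped to 0")
    tree = nj(dm, neg_as_zero=True)
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (internal edges), canonicalized.

    Each internal edge splits the leaf set in two; the side that is
    lexicographically smaller after sorting (with size as the first key)
    represents the bipartition.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric-difference (RF) distance between two unrooted trees."""
    tips_a = {t.name for t in tree_a.tips()}
    tips_b = {t.name for t in tree_b.tips()}
    if tips_a != tips_b:
        raise ValueError("trees must share one leaf set; differ by "
                         f"{sorted(tips_a ^ tips_b)}")
    ba, bb = bipartitions(tree_a), bipartitions(tree_b)
    return len(ba ^ bb)


def bootstrap_support(seqs: dict[str, str], replicates: int = 1000,
                      seed: int = 0, model: str = "p",
                      ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Site-resampling bootstrap of the NJ tree.

    Returns the NJ tree of the full alignment with internal nodes labelled
    by percent support, plus the support of every internal bipartition of
    that tree (percent of replicate trees containing it).
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    labels, M = _mismatch_tensor(seqs)
    L = M.shape[0]
    full_d = M.mean(axis=0)
    tree = nj_tree(DistanceMatrix(full_d, labels))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        d = M[idx].mean(axis=0)
        rep_bps = bipartitions(nj_tree(DistanceMatrix(d, labels)))
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    all_tips = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, all_tips - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in support:
            node.name = f"{support[canon]:.0f}"
    return tree, support


def clade_partition(tree: TreeNode, reference_labels: set[str],
                    ) -> tuple[set[str], set[str]]:
    """Split the leaf set at the internal edge best isolating the references.

    The inside is the smallest internal-edge side containing every
    reference label; if no single side contains them all, the side
    maximizing (references inside - non-references inside) is used.
    Errors on an empty or exhaustive reference set.
    """
    refs = set(reference_labels)
    all_tips = {t.name for t in tree.tips()}
    if not refs:
        raise ValueError("reference_labels must be non-empty")
    if not refs <= all_tips:
        raise ValueError(f"unknown reference labels: {sorted(refs - all_tips)}")
    if refs == all_tips:
        raise ValueError("reference_labels must not cover every leaf")
    sides: list[frozenset[str]] = []
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = frozenset(all_tips) - side
        if len(side) >= 2 and len(other) >= 2:
            sides.extend((side, other))
    containing = [s for s in sides if refs <= s]
    if containing:
        inside = min(containing, key=lambda s: (len(s), tuple(sorted(s))))
    else:
        inside = max(sides,
                     key=lambda s: (len(refs & s) - len(s - refs),
                                    -len(s), tuple(sorted(s))))
        logger.warning("reference labels are not contained in any single "
                       "internal-edge side; returning best-agreement side")
    return set(inside), all_tips - set(inside)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label in dm.ids:
            row = " ".join(f"{v:.6f}" for v in dm[label])
            fh.write(f"{label:<10s} {row}\n")
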