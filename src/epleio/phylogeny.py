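"""Distance-based protein phylogeny: Poisson-corrected p-distances and
neighbor joining, for runs where the user supplies no tree.

The Poisson correction d = -ln(1 - p) puts branch lengths in expected
substitutions per site, the same units as the tree length T consumed by the
multiple-hit correction of the site-change profile.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import InputError, SaturationError
from .io import Alignment, is_missing

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise InputError("non-finite distances")
        if np.any(self.d < 0) or np.any(np.diag(self.d) != 0):
            raise InputError("distances must be >= 0 with a zero diagonal")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")


def pairwise_pdistance(aln: Alignment, i: str, j: str) -> tuple[float, int]:
    """Proportion of differing residues between two taxa.

    Only columns where both taxa carry a non-missing residue are compared;
    returns ``(p, n_comparable)``.
    """
    for t in (i, j):
        if t not in aln.taxa:
            raise InputError(f"taxon {t!r} not in alignment")
    a = aln.data[aln.taxa.index(i)]
    b = aln.data[aln.taxa.index(j)]
    vmiss = np.vectorize(is_missing)
    ok = ~vmiss(a) & ~vmiss(b)
    n = int(ok.sum())
    if n == 0:
        raise InputError(f"no comparable columns between {i!r} and {j!r}")
    return float((a[ok] != b[ok]).mean()), n


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = -ln(1 - p), in substitutions/site."""
    if not 0 <= p < 1:
        raise SaturationError(
            f"p-distance {p} is saturated; use more closely related sequences"
        )
    return float(-np.log1p(-p))


def distance_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs Poisson-corrected distances for an alignment."""
    n = aln.n_taxa
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            p, _ = pairwise_pdistance(aln, aln.taxa[a], aln.taxa[b])
            d[a, b] = d[b, a] = poisson_correct(p)
    return DistanceMatrix(taxa=list(aln.taxa), d=d)


def _newick_label(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Fully deterministic: ties in the Q criterion resolve to the first
    (row-major) minimum, so identical inputs give byte-identical trees.
    The unrooted result is returned with an arbitrary trifurcating root
    (legitimate here because the parsimony counts downstream are invariant
    to root placement).
    """
    if len(dm.taxa) < 4:
        raise InputError("neighbor joining requires at least 4 taxa")
    d = dm.d.astype(float).copy()
    frags = [_newick_label(t) for t in dm.taxa]
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return float(x)

    while len(frags) > 3:
        n = len(frags)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp(li), clamp(lj)
        new_row = 0.5 * (d[i] + d[j] - d[i, j])
        frag = f"({frags[i]}:{li!r},{frags[j]}:{lj!r})"
        keep = [k for k in range(n) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = new_row[keep]
        frags = [frags[k] for k in keep] + [frag]
    l0 = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    l1 = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    l2 = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    newick = (
        f"({frags[0]}:{l0!r},{frags[1]}:{l1!r},{frags[2]}:{l2!r});"
    )
    if n_clamped:
        logger.warning("clamped %d negative NJ branch lengths to 0", n_clamped)
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (substitutions/site)."""
    return float(
        sum(e.length for e in tree.preorder_edge_iter() if e.length is not None)
    )
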