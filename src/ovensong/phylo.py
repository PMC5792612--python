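"""Phylogenies and the covariance structures they imply.

A tree enters the comparative analysis only through the species-by-species
covariance matrix ``V`` of a Brownian-motion (BM) trait evolving along it:
``V[i, j]`` is the length of the root-to-tip path shared by tips *i* and
*j* (the depth of their most recent common ancestor) and ``V[i, i]`` is the
root-to-tip depth of tip *i*.  Alternative models of trait evolution are
realized as transformations of this matrix (or of the branch lengths it is
built from):

``lambda``
    multiplies every off-diagonal entry by ``lam`` in ``[0, 1]`` — the
    classic measure of phylogenetic signal (0 = star phylogeny, 1 = BM).
``kappa``
    raises each individual branch length to the power ``kappa`` in
    ``[0, 3]`` before building ``V``; ``kappa = 0`` turns every branch into
    unit length (speciational/punctuated change).
``delta``
    raises each entry of ``V`` (each node depth) to the power ``delta`` in
    ``[0, 3]``; ``delta > 1`` accelerates and ``delta < 1`` decelerates
    apparent change through time.
``OU``
    a single-optimum Ornstein-Uhlenbeck process with the ancestor at the
    optimum: ``V[i, j] = exp(-alpha * d[i, j]) * (1 - exp(-2 alpha t[i, j]))
    / (2 alpha)`` with ``d`` the patristic (tip-to-tip) distance and ``t``
    the MRCA depth; as ``alpha -> 0`` this recovers the BM matrix, and the
    process variance is absorbed into the residual variance of whatever
    model consumes the matrix.

Matrices are always ordered alphabetically by tip label; downstream joins
are by label, never by position.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

FAMILIES = ("BM", "lambda", "kappa", "delta", "OU")

#: default bounds for the transform parameters; the OU rate upper bound is
#: expressed per unit tree height and resolved against the actual tree.
DEFAULT_BOUNDS = {
    "lambda": (0.0, 1.0),
    "kappa": (0.0, 3.0),
    "delta": (0.0, 3.0),
    "OU": (1e-8, 50.0),  # upper bound interpreted as 50 / tree height
}

_RIDGE = 1e-10


class NewickError(ValueError):
    """Raised when a Newick string cannot be turned into a usable tree."""


@dataclasses.dataclass(frozen=True)
class CovarianceModel:
    """A branch-length transformation realized as a species covariance matrix.

    Attributes
    ----------
    family : str
        One of :data:`FAMILIES`.
    parameter : float or None
        The transform parameter (``None`` for plain BM).
    labels : tuple of str
        Species labels, alphabetical; row/column order of ``matrix``.
    matrix : ndarray
        Symmetric positive-(semi)definite species x species covariance.
    """

    family: str
    parameter: float | None
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-10, rtol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.labels)

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(d, d)

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor; adds a tiny documented ridge if needed.

        Zero-length terminal branches can make the matrix singular to
        machine precision; in that case a ridge of ``1e-10 * mean(diag)``
        is added (and logged) before refactorizing.
        """
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            ridge = _RIDGE * float(np.mean(np.diag(self.matrix)))
            logger.info(
                "covariance (%s) not positive definite; adding ridge %g",
                self.family, ridge,
            )
            return np.linalg.cholesky(
                self.matrix + ridge * np.eye(self.n)
            )


def _format_length(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


_NEWICK_SPECIAL = set("():,;[]' \t\n")


class Phylogeny:
    """A rooted tree with branch lengths, wrapping a :class:`dendropy.Tree`.

    Validates on construction: unique tip labels, branch lengths present
    and nonnegative on every non-root edge.  Ultrametry is checkable via
    :meth:`is_ultrametric` but not required.
    """

    def __init__(self, tree: dendropy.Tree):
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise NewickError("tree must have at least 2 tips")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"missing branch length above node {name!r}")
            if node.edge.length < 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickError(f"negative branch length above node {name!r}")
        self._tree = tree
        self.tip_labels: tuple[str, ...] = tuple(sorted(labels))
        self._struct: dict | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy error hierarchy is wide
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with full float precision (round-trips exactly)."""

        def label_of(node: dendropy.Node) -> str:
            lab = node.taxon.label
            if set(lab) & _NEWICK_SPECIAL:
                return "'" + lab.replace("'", "''") + "'"
            return lab

        def rec(node: dendropy.Node) -> str:
            if node.is_leaf():
                body = label_of(node)
            else:
                body = "(" + ",".join(rec(c) for c in node.child_nodes()) + ")"
            if node.edge.length is not None:
                body += ":" + _format_length(node.edge.length)
            return body

        return rec(self._tree.seed_node) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- structure ---------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _structure(self) -> dict:
        """Edge incidence decomposition: V = A diag(b) A'.

        ``A[i, e]`` is 1 when edge *e* lies on the root-to-tip path of tip
        *i*; rebuilding V under transformed branch lengths is then a single
        matrix product.
        """
        if self._struct is not None:
            return self._struct
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        n = self.n_tips
        edges: list[float] = []
        edge_idx: dict[int, int] = {}
        seed = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is seed:
                # a root edge (e.g. the stem retained when pruning to a
                # subset) is variance shared by every tip; trees read from
                # plain Newick normally carry none, so whole-tree matrices
                # match the ape::vcv convention
                if node.edge.length:
                    edge_idx[id(node)] = len(edges)
                    edges.append(float(node.edge.length))
                continue
            edge_idx[id(node)] = len(edges)
            edges.append(float(node.edge.length))
        A = np.zeros((n, len(edges)))
        for leaf in self._tree.leaf_node_iter():
            i = index[leaf.taxon.label]
            node = leaf
            while node is not None:
                e = edge_idx.get(id(node))
                if e is not None:
                    A[i, e] = 1.0
                node = node.parent_node
        b = np.asarray(edges)
        V = (A * b) @ A.T
        depths = np.diag(V).copy()
        D = depths[:, None] + depths[None, :] - 2.0 * V
        np.fill_diagonal(D, 0.0)
        self._struct = {
            "A": A, "b": b, "V": V, "depths": depths, "D": D,
            "height": float(depths.max()),
        }
        return self._struct

    @property
    def height(self) -> float:
        return self._structure()["height"]

    def depths(self) -> np.ndarray:
        """Root-to-tip path lengths, alphabetical tip order."""
        return self._structure()["depths"].copy()

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self._structure()["depths"]
        return float(d.max() - d.min()) <= rel_tol * max(float(d.max()), 1e-300)

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_internal_node_iter()
        )

    def subset(self, labels: Iterable[str]) -> "Phylogeny":
        """Prune to the given tips (unifurcations collapsed, lengths summed)."""
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        if labels == set(self.tip_labels):
            return self
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        return Phylogeny(sub)

    # -- covariance --------------------------------------------------------

    def covariance(self) -> CovarianceModel:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        return CovarianceModel("BM", None, self.tip_labels,
                               self._structure()["V"].copy())

    def patristic_matrix(self) -> np.ndarray:
        """Tip-to-tip path-length distances, alphabetical order."""
        return self._structure()["D"].copy()

    def transform(self, family: str, parameter: float | None = None,
                  bounds: dict | None = None) -> CovarianceModel:
        """Build the covariance matrix under one transformation family."""
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
        s = self._structure()
        if family == "BM":
            return CovarianceModel("BM", None, self.tip_labels, s["V"].copy())
        if parameter is None:
            raise ValueError(f"family {family!r} requires a parameter")
        lo, hi = self.parameter_bounds(family, bounds)
        if not (lo <= parameter <= hi):
            raise ValueError(
                f"{family} parameter {parameter} outside bounds [{lo}, {hi}]"
            )
        p = float(parameter)
        if family == "lambda":
            V = s["V"].copy()
            off = V - np.diag(np.diag(V))
            V = np.diag(np.diag(V)) + p * off
        elif family == "kappa":
            A, b = s["A"], s["b"]
            V = (A * b ** p) @ A.T
        elif family == "delta":
            V = s["V"] ** p
        else:  # OU: exp(-a d_ij) (1 - exp(-2 a t_ij)) / (2a), t = MRCA depth
            V = np.exp(-p * s["D"]) * (-np.expm1(-2.0 * p * s["V"])) / (2.0 * p)
        return CovarianceModel(family, p, self.tip_labels, V)

    def parameter_bounds(self, family: str,
                         bounds: dict | None = None) -> tuple[float, float]:
        """Resolved (lo, hi) for a family; OU's upper bound scales 1/height."""
        table = dict(DEFAULT_BOUNDS)
        if bounds:
            table.update(bounds)
        if family == "BM":
            raise ValueError("BM has no parameter")
        lo, hi = table[family]
        if family == "OU" and "OU" not in (bounds or {}):
            hi = hi / self.height
        return float(lo), float(hi)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, height {self.height:.4g}>"


@dataclasses.dataclass
class TreeSet:
    """An ordered sample of trees over one tip set (e.g. a posterior sample)."""

    trees: list[Phylogeny]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSet must be nonempty")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {i} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.trees[0].tip_labels

    @classmethod
    def read(cls, path: str | Path) -> "TreeSet":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls([Phylogeny.from_newick(ln) for ln in lines if ln])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(t.to_newick() + "\n" for t in self.trees)
        )


# -- thin functional wrappers (the operation surface) ------------------------

def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def phylo_covariance(tree: Phylogeny) -> CovarianceModel:
    """Brownian-motion phylogenetic covariance matrix of a tree."""
    return tree.covariance()


def apply_transform(tree: Phylogeny, family: str,
                    parameter: float | None = None,
                    bounds: dict | None = None) -> CovarianceModel:
    """Covariance under one of the five branch-length transformations."""
    return tree.transform(family, parameter, bounds=bounds)
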