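"""Chronogram handling: reading dated trees, node ages, crown age, and
counting tips that diverged within a recent time window.

A chronogram is a rooted tree whose branch lengths are in millions of
years (Myr), so every root-to-tip path has the same length (the crown
age) up to the rounding noise that dating software leaves behind.  All
age-based operations validate ultrametricity first and express node ages
in Ma before present: tips sit at 0, the root at the crown age.

The "Pleistocene count" asks, for each terminal taxon, whether the node
at which it diverged from its closest sampled relative (its parent node
in the chronogram) is younger than a threshold age — by default 2.58 Ma,
the base of the Pleistocene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Tuple

import dendropy

from .errors import ChronogramError, UltrametricityError

#: Base of the Pleistocene, Ma.
PLEISTOCENE_BOUNDARY_MA = 2.58

#: Default relative tolerance for ultrametricity (fraction of crown age).
DEFAULT_ULTRAMETRIC_TOL = 1e-6


@dataclass
class Chronogram:
    """A rooted, dated phylogenetic tree with branch lengths in Myr.

    Wraps a :class:`dendropy.Tree`.  Construction validates structure
    (unique non-empty tip labels, >=2 tips, branch lengths present and
    non-negative); ultrametricity is checked lazily by the age-based
    operations so that :func:`check_ultrametric` stays a pure predicate.
    """

    tree: dendropy.Tree
    #: speciation event times recorded by a simulator, ascending (Ma after
    #: origin); empty for trees read from files.
    event_times: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        leaves = self.tree.leaf_nodes()
        if len(leaves) < 2:
            raise ChronogramError(
                f"chronogram needs >= 2 tips, got {len(leaves)}"
            )
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise ChronogramError("every tip must carry a non-empty label")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ChronogramError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise ChronogramError(
                    "missing branch length on edge leading to "
                    f"{_describe(node)}"
                )
            if node.edge.length < 0:
                raise ChronogramError(
                    f"negative branch length ({node.edge.length}) on edge "
                    f"leading to {_describe(node)}"
                )

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def tip_labels(self) -> List[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_nodes()]

    def as_newick(self, precision: int = 6) -> str:
        """Serialize to a Newick string with fixed-precision branch lengths."""
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=f".{precision}f",
        )
        return s.strip() + "\n"

    def write(self, path, schema: str = "newick", precision: int = 6) -> None:
        if schema == "newick":
            with open(path, "w") as fh:
                fh.write(self.as_newick(precision=precision))
        elif schema == "nexus":
            self.tree.write(
                path=str(path),
                schema="nexus",
                suppress_rooting=False,
                real_value_format_specifier=f".{precision}f",
            )
        else:
            raise ValueError(f"unknown schema: {schema!r}")


def _describe(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"internal node above tips {sorted(tips)[:4]}"


# ----------------------------------------------------------------------
# reading


def read_chronogram(path, schema: str = "newick") -> Chronogram:
    """Read a chronogram from a Newick or NEXUS file.

    Plain Newick trees are treated as rooted at their basal node (the
    convention for dated MCC trees); trees explicitly flagged unrooted
    (``[&U]``) are rejected.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"schema must be 'newick' or 'nexus', got {schema!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema=schema,
            rooting="default-rooted",
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise ChronogramError(f"could not parse {path} as {schema}: {exc}") from exc
    if not tree.is_rooted:
        raise ChronogramError(f"{path}: unrooted tree rejected; chronograms must be rooted")
    return Chronogram(tree)


def chronogram_from_string(text: str, schema: str = "newick") -> Chronogram:
    """Parse a chronogram from an in-memory string (mostly for tests/examples)."""
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema=schema, rooting="default-rooted"
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise ChronogramError(f"could not parse tree string as {schema}: {exc}") from exc
    if not tree.is_rooted:
        raise ChronogramError("unrooted tree rejected; chronograms must be rooted")
    return Chronogram(tree)


# ----------------------------------------------------------------------
# ages


def _tip_depths(
    chron: Chronogram,
) -> Tuple[Dict[dendropy.Node, float], Dict[dendropy.Node, float]]:
    """Return (leaf -> depth, node -> depth) root-to-node path lengths."""
    depths: Dict[dendropy.Node, float] = {}
    for node in chron.tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return {n: d for n, d in depths.items() if n.is_leaf()}, depths


def check_ultrametric(
    chron: Chronogram, tol: float | None = None
) -> Tuple[bool, float]:
    """Test whether all root-to-tip depths agree within ``tol``.

    ``tol`` is absolute (Myr); when None it defaults to
    ``DEFAULT_ULTRAMETRIC_TOL`` times the maximum depth, since dating
    software emits rounding noise proportional to tree height.

    Returns ``(is_ultrametric, max_deviation)``.
    """
    leaf_depths, _ = _tip_depths(chron)
    vals = list(leaf_depths.values())
    deviation = max(vals) - min(vals)
    if tol is None:
        tol = DEFAULT_ULTRAMETRIC_TOL * max(max(vals), 1.0)
    return deviation <= tol, deviation


def node_ages(
    chron: Chronogram, tol: float | None = None
) -> Dict[dendropy.Node, float]:
    """Map every node to its age in Ma before present (tips -> 0).

    The tree must be ultrametric within ``tol``; ages are computed as
    crown depth minus root-to-node depth, with tips clamped to exactly 0.
    """
    ok, deviation = check_ultrametric(chron, tol=tol)
    if not ok:
        raise UltrametricityError(
            f"tree is not ultrametric: root-to-tip depth spread = {deviation:g} Myr",
            max_deviation=deviation,
        )
    leaf_depths, depths = _tip_depths(chron)
    height = max(leaf_depths.values())
    ages = {}
    for node, depth in depths.items():
        ages[node] = 0.0 if node.is_leaf() else height - depth
    return ages


def crown_age(chron: Chronogram, tol: float | None = None) -> float:
    """Age of the root (most recent common ancestor of all tips), Ma."""
    ages = node_ages(chron, tol=tol)
    return max(ages.values())


# ----------------------------------------------------------------------
# Pleistocene counting


def count_pleistocene_tips(
    chron: Chronogram,
    threshold: float = PLEISTOCENE_BOUNDARY_MA,
    boundary: Literal["strict", "inclusive"] = "strict",
    tol: float | None = None,
) -> Tuple[int, int]:
    """Count tips whose divergence from their parent node is younger than
    ``threshold`` Ma.

    Each tip's divergence age is the age of its parent node in the
    chronogram (children of a polytomy all use the polytomy's age).
    ``boundary='strict'`` counts parent age < threshold — "within the
    last 2.58 Myr" read as strictly younger; ``'inclusive'`` uses <=.

    Returns ``(k, n)``: the count and the total number of tips.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if boundary not in ("strict", "inclusive"):
        raise ValueError(f"boundary must be 'strict' or 'inclusive', got {boundary!r}")
    ages = node_ages(chron, tol=tol)
    k = 0
    n = 0
    for leaf in chron.tree.leaf_nodes():
        n += 1
        parent_age = ages[leaf.parent_node]
        if (parent_age < threshold) if boundary == "strict" else (parent_age <= threshold):
            k += 1
    return k, n
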