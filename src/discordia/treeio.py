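"""Phylogenetic tree data model and Newick I/O.

Trees are stored as mutable node structures with branch lengths and
per-edge support values in [0, 1].  Support is interpreted as a property of
the edge above a node and is only meaningful on internal edges; bootstrap
percentages found in Newick internal-node labels are rescaled to fractions.

The operations here mirror the preprocessing applied to anchored-enrichment
gene trees before discordance profiling: optimal rooting on an ordered
outgroup priority list, collapsing of poorly supported branches into
polytomies, pruning to a focal clade, and taxon-occupancy computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import (
    DegenerateTreeError,
    NewickParseError,
    TreeValidationError,
    UnrootableError,
)

__all__ = [
    "TaxonSet",
    "Node",
    "PhyloTree",
    "parse_newick",
    "write_newick",
    "root_with_outgroups",
    "collapse_low_support",
    "prune_to_taxa",
    "clade_occupancy",
    "read_tree_file",
    "write_tree_file",
    "read_clade_table",
    "write_clade_table",
]


@dataclass(frozen=True)
class TaxonSet:
    """An ordered universe of unique tip labels with a label -> index map."""

    labels: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise TreeValidationError("duplicate labels in TaxonSet")
        if any(not lab for lab in self.labels):
            raise TreeValidationError("empty label in TaxonSet")
        object.__setattr__(self, "index", {lab: i for i, lab in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index


class Node:
    """A tree node; ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("parent", "children", "length", "support", "label")

    def __init__(self, label: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.support = support
        self.label = label

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length} sup={self.support}>"


class PhyloTree:
    """A rooted or unrooted tree over labelled tips.

    The structure is always stored with a top node (``root``); the
    ``rooted`` flag records whether that node is a meaningful root or just
    an arbitrary anchoring of an unrooted topology.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dup}")
        for n in self.preorder():
            if n.length is not None and n.length < 0:
                raise TreeValidationError("negative branch length")
            if n.support is not None and not (0.0 <= n.support <= 1.0):
                raise TreeValidationError("support outside [0, 1]")

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def taxa(self) -> TaxonSet:
        return TaxonSet(tuple(sorted(self.tip_labels())))

    def n_tips(self) -> int:
        return sum(1 for _ in self.leaves())

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        nodes = [n for n in self.preorder() if not n.is_leaf]
        if exclude_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            c = Node(n.label, n.length, n.support)
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # -- convenience -------------------------------------------------------
    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tips (rooted view)."""
        want = set(labels)
        missing = want - set(self.tip_labels())
        if missing:
            raise TreeValidationError(f"tips not in tree: {sorted(missing)}")
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.label}
            else:
                below[id(n)] = set().union(*(below[id(c)] for c in n.children))
            if want <= below[id(n)]:
                return n
        raise TreeValidationError("mrca not found")  # pragma: no cover

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {self.n_tips()} tips rooted={self.rooted}>"


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("();,:[]'\t\n ")


class _Cursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws(self) -> None:
        while self.peek() and self.peek() in " \t\r\n":
            self.pos += 1


def _read_label(cur: _Cursor) -> str:
    cur.skip_ws()
    if cur.peek() == "'":
        cur.next()
        out = []
        while True:
            ch = cur.next()
            if ch == "":
                raise NewickParseError("unterminated quoted label", cur.pos)
            if ch == "'":
                if cur.peek() == "'":  # escaped quote
                    out.append("'")
                    cur.next()
                    continue
                break
            out.append(ch)
        return "".join(out)
    out = []
    while cur.peek() and cur.peek() not in _LABEL_FORBIDDEN:
        out.append(cur.next())
    return "".join(out)


def _read_number(cur: _Cursor, what: str) -> float:
    cur.skip_ws()
    start = cur.pos
    while cur.peek() and cur.peek() not in _LABEL_FORBIDDEN:
        cur.pos += 1
    token = cur.text[start:cur.pos]
    try:
        return float(token)
    except ValueError:
        raise NewickParseError(f"invalid {what} {token!r}", start) from None


def _parse_clade(cur: _Cursor) -> Node:
    cur.skip_ws()
    node = Node()
    if cur.peek() == "(":
        cur.next()
        while True:
            node.add_child(_parse_clade(cur))
            cur.skip_ws()
            ch = cur.peek()
            if ch == ",":
                cur.next()
                continue
            if ch == ")":
                cur.next()
                break
            raise NewickParseError("unbalanced parentheses", cur.pos)
        label = _read_label(cur)
        if label:
            node.label = label  # may later be reinterpreted as support
    else:
        label = _read_label(cur)
        if not label:
            raise NewickParseError("expected a tip label", cur.pos)
        node.label = label
    cur.skip_ws()
    if cur.peek() == ":":
        cur.next()
        node.length = _read_number(cur, "branch length")
        if node.length < 0:
            raise TreeValidationError("negative branch length in Newick")
    return node


def parse_newick(text: str, support_scale: str = "auto") -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal-node labels that parse as numbers are interpreted as edge
    supports.  Under ``support_scale='auto'`` a single value greater than 1
    anywhere switches interpretation to bootstrap percentages (all values
    divided by 100); ``'percent'`` and ``'fraction'`` force the scale.
    """
    if support_scale not in ("auto", "fraction", "percent"):
        raise TreeValidationError(f"unknown support_scale {support_scale!r}")
    cur = _Cursor(text)
    cur.skip_ws()
    root = _parse_clade(cur)
    cur.skip_ws()
    if cur.peek() != ";":
        raise NewickParseError("expected ';' terminating the tree", cur.pos)
    cur.next()
    cur.skip_ws()
    if cur.peek():
        raise NewickParseError("trailing characters after ';'", cur.pos)

    # reinterpret numeric internal labels as raw supports
    raw: list[tuple[Node, float]] = []
    for n in _preorder(root):
        if n.children and n.label is not None:
            try:
                val = float(n.label)
            except ValueError:
                continue
            n.label = None
            if n.parent is not None:  # a root label has no edge to support
                raw.append((n, val))
    values = [v for _, v in raw]
    if values:
        if any(v < 0 or v > 100 for v in values):
            raise TreeValidationError("support outside [0, 100]")
        percent = support_scale == "percent" or (
            support_scale == "auto" and any(v > 1 for v in values)
        )
        if support_scale == "fraction" and any(v > 1 for v in values):
            raise TreeValidationError("support > 1 under support_scale='fraction'")
        for n, v in raw:
            n.support = v / 100.0 if percent else v
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def _preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _fmt(x: float) -> str:
    s = format(x, ".10g")
    return s


def _needs_quoting(label: str) -> bool:
    return any(ch in _LABEL_FORBIDDEN for ch in label)


def write_newick(tree: PhyloTree, support_scale: str = "fraction") -> str:
    """Serialize a tree to Newick; supports become internal-node labels."""
    if support_scale not in ("fraction", "percent"):
        raise TreeValidationError(f"unknown support_scale {support_scale!r}")

    def emit(n: Node) -> str:
        if n.is_leaf:
            lab = n.label
            if _needs_quoting(lab):
                lab = "'" + lab.replace("'", "''") + "'"
            out = lab
        else:
            out = "(" + ",".join(emit(c) for c in n.children) + ")"
            if n.support is not None and n.parent is not None:
                v = n.support * 100.0 if support_scale == "percent" else n.support
                out += _fmt(v)
            elif n.label:
                out += n.label
        if n.length is not None:
            out += ":" + _fmt(n.length)
        return out

    return emit(tree.root) + ";"


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _below_sets(tree: PhyloTree) -> dict[int, frozenset[str]]:
    below: dict[int, frozenset[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
    return below


def _reroot_on_edge(tree: PhyloTree, v: Node) -> PhyloTree:
    """Place a new root at the midpoint of the edge above ``v`` (in place)."""
    u = v.parent
    assert u is not None
    new_root = Node()
    if v.length is not None:
        half = v.length / 2.0
        v.length = half
        carry_len: float | None = half
    else:
        carry_len = None
    carry_sup = v.support  # the reversed half-edge bounds the same split
    u.children.remove(v)
    new_root.add_child(v)

    prev = new_root
    node: Node | None = u
    while node is not None:
        parent = node.parent
        if parent is not None:
            parent.children.remove(node)
        next_len, next_sup = node.length, node.support
        node.length, node.support = carry_len, carry_sup
        node.parent = None
        prev.add_child(node)
        prev = node
        carry_len, carry_sup = next_len, next_sup
        node = parent

    # the old root may be left with a single child: suppress it
    old = prev
    if len(old.children) == 1:
        child = old.children[0]
        gp = old.parent
        assert gp is not None
        gp.children.remove(old)
        if child.length is not None or old.length is not None:
            child.length = (child.length or 0.0) + (old.length or 0.0)
        sups = [s for s in (child.support, old.support) if s is not None]
        child.support = min(sups) if sups else None
        if child.is_leaf:
            child.support = None
        gp.add_child(child)
    tree.root = new_root
    tree.rooted = True
    return tree


def root_with_outgroups(tree: PhyloTree,
                        priority: Sequence[Iterable[str]]) -> PhyloTree:
    """Root on the edge subtending the smallest clade holding an outgroup set.

    ``priority`` is scanned in order; the first set with at least one member
    present in the tree is used.  If the smallest "clade" containing all its
    present members is the entire tree, that set fails and the scan
    continues.  Raises :class:`UnrootableError` when every set fails.
    """
    if not priority:
        raise TreeValidationError("priority list must be non-empty")
    if tree.n_tips() < 3:
        raise DegenerateTreeError("rooting requires >= 3 tips")
    tips = set(tree.tip_labels())
    work = tree.copy()
    below = _below_sets(work)
    all_tips = frozenset(tips)
    for pset in priority:
        present = frozenset(pset) & tips
        if not present:
            continue
        best: tuple[int, Node, bool] | None = None  # (size, node, side_is_below)
        for n in work.preorder():
            if n is work.root:
                continue
            b = below[id(n)]
            if present <= b:
                cand = (len(b), n, True)
            elif not (present & b):
                cand = (len(all_tips) - len(b), n, False)
            else:
                continue
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None or best[0] == len(all_tips):
            continue
        _, node, side_is_below = best
        # root so the chosen clade hangs off one side of the new root; the
        # edge above `node` is the subtending edge either way
        return _reroot_on_edge(work, node)
    raise UnrootableError("no outgroup taxon present in the tree, or the "
                          "smallest containing clade is the whole tree")


# ---------------------------------------------------------------------------
# Collapsing / pruning / occupancy
# ---------------------------------------------------------------------------

def collapse_low_support(tree: PhyloTree, threshold: float) -> PhyloTree:
    """Contract internal edges with support strictly below ``threshold``.

    Edges lacking a support value and pendant edges are always retained,
    so supports attached only near estimation errors remove exactly those
    error-prone edges.  The comparison is a strict ``<``: an edge exactly at
    the threshold survives.
    """
    if not (0.0 <= threshold <= 1.0):
        raise TreeValidationError("threshold must lie in [0, 1]")
    out = tree.copy()
    for n in list(out.postorder()):
        if n.is_leaf or n.parent is None:
            continue
        if n.support is not None and n.support < threshold:
            parent = n.parent
            idx = parent.children.index(n)
            for c in n.children:
                c.parent = parent
            parent.children[idx:idx + 1] = n.children
    return out


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep``, suppressing unary nodes.

    Branch lengths along a suppressed path are summed so tip-to-tip path
    lengths among kept tips are preserved; the merged edge takes the
    minimum of the merged supports (confidence is never inflated).
    """
    keep = set(keep)
    surviving = keep & set(tree.tip_labels())
    if len(surviving) < 2:
        raise DegenerateTreeError(
            f"pruning leaves {len(surviving)} < 2 tips")
    out = tree.copy()
    internal_ids = {id(n) for n in out.preorder() if n.children}
    # drop unwanted leaves, then clean up bottom-up
    for n in list(out.postorder()):
        if n.is_leaf and n.label not in keep and n.parent is not None:
            n.parent.children.remove(n)
    changed = True
    while changed:
        changed = False
        for n in list(out.postorder()):
            if n.parent is None:
                continue
            if not n.children and id(n) in internal_ids:  # emptied internal node
                n.parent.children.remove(n)
                changed = True
            elif len(n.children) == 1:  # unary: merge
                child = n.children[0]
                if child.length is not None or n.length is not None:
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                sups = [s for s in (child.support, n.support) if s is not None]
                child.support = min(sups) if sups else None
                if child.is_leaf:
                    child.support = None
                parent = n.parent
                idx = parent.children.index(n)
                child.parent = parent
                parent.children[idx] = child
                changed = True
    while len(out.root.children) == 1:
        out.root = out.root.children[0]
        out.root.parent = None
        out.root.length = None
        out.root.support = None
    return PhyloTree(out.root, rooted=out.rooted)


def clade_occupancy(tree: PhyloTree, clade_taxa: Iterable[str]) -> float:
    """Fraction of ``clade_taxa`` present among the tree's tips."""
    clade = set(clade_taxa)
    if not clade:
        raise TreeValidationError("clade_taxa must be non-empty")
    return len(clade & set(tree.tip_labels())) / len(clade)


# ---------------------------------------------------------------------------
# File-level helpers (one Newick per line; '#' comments may name loci)
# ---------------------------------------------------------------------------

def read_tree_file(path, support_scale: str = "auto") -> list[tuple[str, PhyloTree]]:
    """Read a multi-tree Newick file into (locus_id, tree) pairs.

    A comment line ``# name`` names the tree on the following line;
    unnamed trees get ``locus_<i>``.
    """
    out: list[tuple[str, PhyloTree]] = []
    pending: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                pending = line.lstrip("#").strip() or None
                continue
            name = pending if pending else f"locus_{len(out)}"
            out.append((name, parse_newick(line, support_scale)))
            pending = None
    return out


def write_tree_file(path, trees: Iterable[tuple[str, PhyloTree]],
                    support_scale: str = "fraction") -> None:
    with open(path, "w") as fh:
        for name, tree in trees:
            fh.write(f"# {name}\n{write_newick(tree, support_scale)}\n")


def read_clade_table(path) -> dict[str, str]:
    """Read a two-column TSV ``tip<TAB>clade``; '#' comments allowed."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise TreeValidationError(
                    f"clade table line {i}: expected 'tip<TAB>clade'")
            if parts[0] in out:
                raise TreeValidationError(
                    f"clade table line {i}: duplicate tip {parts[0]!r}")
            out[parts[0]] = parts[1]
    return out


def write_clade_table(path, clade_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for tip in sorted(clade_map):
            fh.write(f"{tip}\t{clade_map[tip]}\n")
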