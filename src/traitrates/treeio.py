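"""Tree and trait-table data model and I/O.

Trees are rooted, may contain polytomies, and are kept exactly as read:
no rerooting, no suppression of unifurcations beyond what the Newick
grammar implies.  Branch lengths may be absent in the input; computation
substitutes 1.0 for absent lengths (with a warning) but the raw ``None``
is preserved for round-tripping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy

logger = logging.getLogger(__name__)

#: Default phenotype alphabet (alphabetical order).
DEFAULT_ALPHABET: tuple[str, ...] = ("CI", "FI", "MK", "O", "PI")


class TreeError(ValueError):
    """Invalid tree structure or tree/trait mismatch."""


class NewickParseError(TreeError):
    """Malformed Newick input.

    Attributes
    ----------
    offset : int or None
        Character offset (0-based, within the offending line) of the
        error when the underlying parser reports one.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class TraitError(ValueError):
    """Invalid trait table."""


class Node:
    """A node of a rooted tree."""

    __slots__ = ("name", "label", "length", "children", "parent")

    def __init__(self, name=None, label=None, length=None):
        self.name: str | None = name          # leaf name
        self.label: str | None = label        # internal label (e.g. support); ignored by computation
        self.length: float | None = length    # branch length to parent; None = absent
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def effective_length(self, default: float = 1.0) -> float:
        """Branch length used by computation; absent lengths become *default*."""
        return default if self.length is None else self.length

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name or self.label or '*'}:{self.length})"


class PhyloTree:
    """Rooted phylogeny with branch lengths; polytomies permitted."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- traversal -------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        names = []
        seen: set[int] = set()
        for node in self.postorder():
            if id(node) in seen:
                raise TreeError("node appears twice in the tree")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("child/parent pointers inconsistent")
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length}")
            if node.is_leaf:
                if not node.name:
                    raise TreeError("leaf without a name")
                names.append(node.name)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf names: {sorted(dupes)}")

    # -- derived quantities ----------------------------------------------

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf (absent lengths count as 1.0)."""
        out: dict[str, float] = {}

        def walk(node: Node, acc: float) -> None:
            if node.is_leaf:
                out[node.name] = acc
            for child in node.children:
                walk(child, acc + child.effective_length())

        walk(self.root, 0.0)
        return out

    def total_length(self) -> float:
        return sum(
            n.effective_length() for n in self.postorder() if n is not self.root
        )

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def has_missing_lengths(self) -> bool:
        return any(n.length is None for n in self.postorder() if n is not self.root)

    def __repr__(self):  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"


@dataclass
class TraitData:
    """Mapping leaf name -> state index over an ordered state alphabet."""

    states: dict[str, int]
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET

    def __post_init__(self):
        self.alphabet = tuple(self.alphabet)
        k = len(self.alphabet)
        for taxon, idx in self.states.items():
            if not 0 <= idx < k:
                raise TraitError(f"state index {idx} for {taxon!r} outside alphabet")

    @classmethod
    def from_labels(cls, mapping: dict[str, str], alphabet=DEFAULT_ALPHABET) -> "TraitData":
        alphabet = tuple(alphabet)
        index = {s: i for i, s in enumerate(alphabet)}
        states = {}
        for taxon, lab in mapping.items():
            if lab not in index:
                raise TraitError(f"phenotype {lab!r} for taxon {taxon!r} not in alphabet {alphabet}")
            states[taxon] = index[lab]
        return cls(states, alphabet)

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def label_of(self, taxon: str) -> str:
        return self.alphabet[self.states[taxon]]

    def check_tree(self, tree: PhyloTree) -> None:
        tree_names = set(tree.leaf_names())
        trait_names = set(self.states)
        if tree_names != trait_names:
            missing = sorted(tree_names - trait_names)
            extra = sorted(trait_names - tree_names)
            raise TraitError(
                f"tree/trait leaf sets differ (missing traits: {missing[:5]}, "
                f"extra traits: {extra[:5]})"
            )

    def permuted(self, order: Sequence[int]) -> "TraitData":
        """Trait values reassigned to taxa according to an index permutation."""
        taxa = sorted(self.states)
        values = [self.states[t] for t in taxa]
        return TraitData(
            {taxa[i]: values[order[i]] for i in range(len(taxa))}, self.alphabet
        )


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; writing is ours so that
# absent lengths and label round-trips stay under our control)
# ---------------------------------------------------------------------------


def _convert(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(name=name, length=dnode.edge.length)
    else:
        node = Node(label=dnode.label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
    return node


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` (with a character offset when the
    parser reports one) on malformed input and :class:`TreeError` on
    duplicate leaf names.
    """
    if not text.strip():
        raise NewickParseError("empty Newick string", offset=0)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from exc
    root = _convert(dtree.seed_node)
    root.length = None  # the root has no branch
    tree = PhyloTree(root)
    if tree.has_missing_lengths():
        logger.warning(
            "tree has branches without lengths; computation will use 1.0 for those"
        )
    return tree


def _write_node(node: Node, parts: list[str]) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _write_node(child, parts)
        parts.append(")")
        if node.label:
            parts.append(node.label)
    else:
        parts.append(node.name or "")
    if node.length is not None and node.parent is not None:
        parts.append(f":{node.length!r}")


def write_newick(tree: PhyloTree) -> str:
    parts: list[str] = []
    _write_node(tree.root, parts)
    parts.append(";")
    return "".join(parts)


def read_newick_file(path) -> list[PhyloTree]:
    """Read a Newick file: one tree per non-empty line."""
    trees = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    if not trees:
        raise NewickParseError("no trees in file", offset=0)
    return trees


def write_newick_file(trees: Iterable[PhyloTree], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def read_trait_table(stream, alphabet=DEFAULT_ALPHABET) -> TraitData:
    """Read a TSV trait table (header ``taxon<TAB>phenotype``).

    *stream* may be a path or an open text file.  Unknown phenotype
    labels are rejected unless covered by a custom *alphabet*.
    """
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream, "rt", encoding="utf-8") as fh:
            return read_trait_table(fh, alphabet)

    header = stream.readline().rstrip("\n")
    cols = header.split("\t")
    if cols[:2] != ["taxon", "phenotype"]:
        raise TraitError(f"expected header 'taxon\\tphenotype', got {header!r}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TraitError(f"row {lineno}: expected 2 tab-separated fields, got {line!r}")
        taxon, phenotype = fields[0], fields[1]
        if taxon in mapping:
            raise TraitError(f"row {lineno}: duplicate taxon {taxon!r}")
        if phenotype not in alphabet:
            raise TraitError(
                f"row {lineno}: phenotype {phenotype!r} for taxon {taxon!r} "
                f"not in alphabet {tuple(alphabet)}"
            )
        mapping[taxon] = phenotype
    return TraitData.from_labels(mapping, alphabet)


def write_trait_table(traits: TraitData, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("taxon\tphenotype\n")
        for taxon in sorted(traits.states):
            fh.write(f"{taxon}\t{traits.label_of(taxon)}\n")


# ---------------------------------------------------------------------------
# Star tree and MRCA
# ---------------------------------------------------------------------------


def make_star_tree(tree: PhyloTree, pendant_length: float | None = None) -> PhyloTree:
    """Collapse *tree* to a star: every leaf attached directly to the root.

    Pendant branch lengths default to the mean root-to-leaf path length
    of the input tree, which preserves average depth so that rate scales
    stay comparable between the star and the original tree.
    """
    leaves = tree.leaf_names()
    if len(leaves) < 2:
        raise TreeError("star tree needs at least 2 leaves")
    if pendant_length is None:
        depths = tree.depths()
        pendant_length = sum(depths.values()) / len(depths)
    if pendant_length <= 0:
        raise TreeError("all root-to-leaf paths are zero; star tree is degenerate")
    root = Node()
    for name in leaves:
        root.add_child(Node(name=name, length=pendant_length))
    return PhyloTree(root)


def mrca(tree: PhyloTree, taxa) -> Node:
    """Deepest node whose leaf descendants include all of *taxa*."""
    taxa = set(taxa)
    if not taxa:
        raise TreeError("mrca requires a nonempty taxon set")
    known = set(tree.leaf_names())
    unknown = taxa - known
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    descendants: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            descendants[id(node)] = {node.name}
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= descendants[id(child)]
            descendants[id(node)] = acc
        if taxa <= descendants[id(node)]:
            return node
    raise TreeError("unreachable: root must cover all taxa")  # pragma: no cover
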