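"""Clade hierarchies over genomes and marker-specificity inference.

A :class:`CladeTree` represents the nested taxonomy (class / order / family
/ ...) of the genomes under comparison.  Given the set of genomes in which a
marker (a signature indel or a signature protein) is present,
:func:`infer_specificity` finds the smallest clade the marker "defines":
the smallest taxon whose members carry the marker, up to a coverage
tolerance for incomplete assemblies and an exception budget for isolated
out-of-clade carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence


class TaxonomyError(ValueError):
    """Structural problem in a clade-tree definition."""


@dataclass(frozen=True)
class SpecificityResult:
    """Outcome of specificity inference for one marker.

    Attributes
    ----------
    clade:
        Name of the smallest qualifying clade, or ``None`` when no clade
        satisfies the coverage / exception constraints.
    coverage:
        Fraction of the clade's genomes found in the presence set
        (0.0 when ``clade`` is ``None``).
    external_exceptions:
        Genomes outside the clade (including genomes unknown to the tree)
        that nevertheless carry the marker.
    """

    clade: Optional[str]
    coverage: float
    external_exceptions: frozenset[str] = field(default_factory=frozenset)

    @property
    def qualified(self) -> bool:
        return self.clade is not None


class CladeTree:
    """Rooted tree of named clades with genomes attached to leaves.

    Parameters
    ----------
    nodes:
        Mapping ``clade_name -> parent_name`` with exactly one root
        (``parent is None``).
    memberships:
        Mapping ``genome_id -> leaf clade_name``.
    """

    def __init__(self, nodes: Mapping[str, Optional[str]],
                 memberships: Mapping[str, str]):
        self._parent: dict[str, Optional[str]] = dict(nodes)
        self._children: dict[str, list[str]] = {n: [] for n in self._parent}
        roots = [n for n, p in self._parent.items() if p is None]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root clade, found {len(roots)}")
        self.root: str = roots[0]
        for name, parent in self._parent.items():
            if parent is None:
                continue
            if parent not in self._parent:
                raise TaxonomyError(f"clade {name!r} has unknown parent {parent!r}")
            self._children[parent].append(name)
        # cycle / reachability check
        order = self._preorder()
        if len(order) != len(self._parent):
            unreachable = set(self._parent) - set(order)
            raise TaxonomyError(f"clades not reachable from root: {sorted(unreachable)}")
        self.memberships: dict[str, str] = dict(memberships)
        for genome, leaf in self.memberships.items():
            if leaf not in self._parent:
                raise TaxonomyError(f"genome {genome!r} attached to unknown clade {leaf!r}")
        # cache genomes under each clade
        self._genomes: dict[str, frozenset[str]] = {}
        by_leaf: dict[str, set[str]] = {}
        for genome, leaf in self.memberships.items():
            by_leaf.setdefault(leaf, set()).add(genome)
        for name in reversed(order):  # postorder accumulation
            acc = set(by_leaf.get(name, ()))
            for child in self._children[name]:
                acc |= self._genomes[child]
            self._genomes[name] = frozenset(acc)
        self._depth: dict[str, int] = {}
        for name in order:
            parent = self._parent[name]
            self._depth[name] = 0 if parent is None else self._depth[parent] + 1

    def _preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        seen: set[str] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                raise TaxonomyError(f"cycle detected at clade {node!r}")
            seen.add(node)
            out.append(node)
            stack.extend(reversed(self._children[node]))
        return out

    # -- queries ---------------------------------------------------------
    def clades(self) -> list[str]:
        """All clade names in deterministic preorder."""
        return self._preorder()

    def parent(self, clade: str) -> Optional[str]:
        return self._parent[clade]

    def children(self, clade: str) -> tuple[str, ...]:
        return tuple(self._children[clade])

    def depth(self, clade: str) -> int:
        return self._depth[clade]

    def genomes_under(self, clade: str) -> frozenset[str]:
        """All genomes attached at or below ``clade``."""
        try:
            return self._genomes[clade]
        except KeyError:
            raise TaxonomyError(f"unknown clade {clade!r}") from None

    @property
    def genomes(self) -> frozenset[str]:
        return self._genomes[self.root]

    def is_ancestor(self, ancestor: str, clade: str) -> bool:
        """True when ``ancestor`` is ``clade`` or lies on its root path."""
        node: Optional[str] = clade
        while node is not None:
            if node == ancestor:
                return True
            node = self._parent[node]
        return False

    def __contains__(self, clade: str) -> bool:
        return clade in self._parent

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"CladeTree(root={self.root!r}, {len(self._parent)} clades, "
                f"{len(self.memberships)} genomes)")


def build_clade_tree(rows: Iterable[tuple[str, Sequence[str]]]) -> CladeTree:
    """Build a :class:`CladeTree` from ``(genome_id, lineage)`` rows.

    Each lineage is a root-to-leaf path of clade names.  Paths must be
    prefix-consistent: a clade name always appears under the same parent.

    Raises
    ------
    TaxonomyError
        On duplicate genome ids, empty lineages, or a clade name used
        under two different parents (the error names the offending genome).
    """
    parent: dict[str, Optional[str]] = {}
    memberships: dict[str, str] = {}
    for genome_id, lineage in rows:
        if not genome_id:
            raise TaxonomyError("empty genome_id")
        lineage = list(lineage)
        if not lineage or any(not name for name in lineage):
            raise TaxonomyError(f"genome {genome_id!r}: empty lineage element")
        if genome_id in memberships:
            raise TaxonomyError(f"duplicate genome {genome_id!r}")
        prev: Optional[str] = None
        for name in lineage:
            if name in parent:
                if parent[name] != prev:
                    raise TaxonomyError(
                        f"genome {genome_id!r}: clade {name!r} placed under "
                        f"{prev!r} but previously under {parent[name]!r}")
            else:
                parent[name] = prev
            prev = name
        memberships[genome_id] = lineage[-1]
    if not memberships:
        raise TaxonomyError("no genomes in taxonomy definition")
    return CladeTree(parent, memberships)


def read_taxonomy(path) -> CladeTree:
    """Read a tab-separated taxonomy file.

    Format: ``genome_id<TAB>lineage`` with the lineage as ``;``-joined
    root-to-leaf clade names; ``#`` comment lines and blank lines ignored.
    """
    rows: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TaxonomyError(f"{path}:{lineno}: expected 2 tab-separated "
                                    f"columns, got {len(parts)}")
            genome_id, lineage = parts
            rows.append((genome_id.strip(),
                         [p.strip() for p in lineage.split(";")]))
    return build_clade_tree(rows)


def write_taxonomy(tree: CladeTree, path) -> None:
    """Write the tree back as a ``genome_id<TAB>lineage`` table."""
    with open(path, "w") as fh:
        for genome in sorted(tree.memberships):
            leaf = tree.memberships[genome]
            path_names: list[str] = []
            node: Optional[str] = leaf
            while node is not None:
                path_names.append(node)
                node = tree.parent(node)
            fh.write(f"{genome}\t{';'.join(reversed(path_names))}\n")


def infer_specificity(presence: Iterable[str], tree: CladeTree,
                      min_coverage: float = 0.75,
                      max_exceptions: int = 0) -> SpecificityResult:
    """Find the smallest clade a presence pattern defines.

    A clade ``C`` qualifies when the presence set covers at least
    ``min_coverage`` of ``C``'s genomes and at most ``max_exceptions``
    presence genomes fall outside ``C``.  Genomes unknown to the tree are
    counted as external exceptions, never as coverage.  Among qualifying
    clades the one with the fewest genomes wins; residual ties (possible
    only when ``max_exceptions > 0``) break by greater depth, then name.

    The default ``min_coverage=0.75`` tolerates markers undetected in up
    to a quarter of the clade's genomes, the typical shortfall when part
    of the clade is represented by incomplete metagenome-assembled
    genomes; ``max_exceptions`` defaults to 0 (strict taxon specificity).
    """
    presence_set = frozenset(presence)
    if not presence_set:
        raise ValueError("presence set must be non-empty")
    best: Optional[tuple[int, int, str, float, frozenset[str]]] = None
    for clade in tree.clades():
        members = tree.genomes_under(clade)
        if not members:
            continue
        inside = presence_set & members
        coverage = len(inside) / len(members)
        external = presence_set - members
        if coverage >= min_coverage and len(external) <= max_exceptions:
            key = (len(members), -tree.depth(clade), clade)
            if best is None or key < (best[0], best[1], best[2]):
                best = (len(members), -tree.depth(clade), clade,
                        coverage, frozenset(external))
    if best is None:
        return SpecificityResult(None, 0.0, frozenset())
    return SpecificityResult(best[2], best[3], best[4])
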