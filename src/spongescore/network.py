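"""Bipartite miRNA-target networks and degree-based single-line operators.

A miRNA regulatory network is modelled as an undirected bipartite graph with
miRNAs on one side and targets (mRNAs or lncRNAs, never mixed) on the other.
Every downstream statistic in this package — shared-miRNA overlap tests,
NSR scoring — is built from two primitives defined here: node degree and the
*single-line* target set of a miRNA, i.e. the targets whose only regulator
in the network is that miRNA.  Single-line edges are the structurally
vulnerable sites of the network: losing the miRNA leaves the target
unregulated.

Networks are immutable; ``restrict`` returns a new network induced by the
surviving edges (nodes with no surviving edge are dropped, so degree
statistics are never diluted by phantom nodes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Iterable, Mapping


class TargetClass(str, Enum):
    """Class of the target side of a bipartite regulatory network."""

    MRNA = "mRNA"
    LNCRNA = "lncRNA"


class Side(str, Enum):
    """Which side of the bipartite graph a node lives on."""

    MIRNA = "miRNA"
    TARGET = "target"


@dataclass(frozen=True)
class BipartiteNetwork:
    """Immutable bipartite miRNA-target network.

    Parameters
    ----------
    edges
        Frozen set of ``(mirna_id, target_id)`` pairs.
    target_class
        Whether the target side holds mRNAs or lncRNAs.

    Node sets are derived from the edge set, so the invariant "every edge
    endpoint is a declared node, and no isolated declared nodes" holds by
    construction.
    """

    edges: frozenset[tuple[str, str]]
    target_class: TargetClass
    # cached_property needs a __dict__; field() keeps dataclass machinery happy
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], target_class: TargetClass | str
    ) -> "BipartiteNetwork":
        return cls(
            edges=frozenset((str(m), str(t)) for m, t in edges),
            target_class=TargetClass(target_class),
        )

    # -- derived node sets -------------------------------------------------

    @cached_property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)

    @cached_property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    @cached_property
    def _mirna_targets(self) -> Mapping[str, frozenset[str]]:
        """miRNA -> set of its targets."""
        d: dict[str, set[str]] = {}
        for m, t in self.edges:
            d.setdefault(m, set()).add(t)
        return {m: frozenset(ts) for m, ts in d.items()}

    @cached_property
    def _target_regulators(self) -> Mapping[str, frozenset[str]]:
        """target -> set of miRNAs regulating it."""
        d: dict[str, set[str]] = {}
        for m, t in self.edges:
            d.setdefault(t, set()).add(m)
        return {t: frozenset(ms) for t, ms in d.items()}

    @cached_property
    def target_degrees(self) -> Mapping[str, int]:
        return Counter(t for _, t in self.edges)

    # -- operators ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.edges)

    def targets_of(self, mirna: str) -> frozenset[str]:
        try:
            return self._mirna_targets[mirna]
        except KeyError:
            raise KeyError(f"unknown miRNA node: {mirna!r}") from None

    def regulators_of(self, target: str) -> frozenset[str]:
        try:
            return self._target_regulators[target]
        except KeyError:
            raise KeyError(f"unknown target node: {target!r}") from None

    def degree(self, node: str, side: Side | str) -> int:
        """Number of edges incident to ``node`` on the stated side."""
        side = Side(side)
        if side is Side.MIRNA:
            return len(self.targets_of(node))
        return len(self.regulators_of(node))

    def single_line_targets(self, mirna: str) -> frozenset[str]:
        """Targets regulated by ``mirna`` and by no other miRNA.

        The degree is counted within *this* network: restricting the network
        first (e.g. to a condition-specific subnetwork) changes the answer,
        which is intentional.
        """
        deg = self.target_degrees
        return frozenset(t for t in self.targets_of(mirna) if deg[t] == 1)

    def restrict(
        self, keep_mirnas: Iterable[str], keep_targets: Iterable[str]
    ) -> "BipartiteNetwork":
        """Subnetwork induced by edges with both endpoints kept."""
        km, kt = set(keep_mirnas), set(keep_targets)
        return BipartiteNetwork(
            edges=frozenset((m, t) for m, t in self.edges if m in km and t in kt),
            target_class=self.target_class,
        )


def build_network(pairs, target_class: TargetClass | str | None = None) -> BipartiteNetwork:
    """Build a :class:`BipartiteNetwork` from RegulatoryPair records.

    All pairs must share one target class; duplicates collapse into a single
    edge.  ``target_class`` is only needed to type an empty pair list.
    """
    pairs = list(pairs)
    classes = {TargetClass(p.target_class) for p in pairs}
    if len(classes) > 1:
        raise ValueError(f"pairs mix target classes: {sorted(c.value for c in classes)}")
    if classes:
        inferred = classes.pop()
        if target_class is not None and TargetClass(target_class) != inferred:
            raise ValueError(
                f"pairs have target class {inferred.value}, not {TargetClass(target_class).value}"
            )
        target_class = inferred
    elif target_class is None:
        target_class = TargetClass.MRNA
    return BipartiteNetwork.from_edges(
        ((p.regulator_id, p.target_id) for p in pairs), target_class
    )
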