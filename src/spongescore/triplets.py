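"""Global lncRNA-miRNA-mRNA (ceRNA) network inference.

Under the ceRNA hypothesis, a lncRNA and an mRNA compete for a shared pool
of miRNAs.  For every (lncRNA, mRNA) pair that shares at least one miRNA
regulator we test whether the overlap of their regulator sets is larger
than expected by chance under a hypergeometric null: from a universe of N
miRNAs, the lncRNA is bound by K and the mRNA by n; the upper-tail
probability of observing k or more shared miRNAs is

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K, i) C(N-K, n-i) / C(N, n).

Raw p-values are Benjamini-Hochberg adjusted over the family of all tested
pairs (pairs with zero shared miRNAs are never tested: they cannot form
triplets and would only dilute the FDR family).  Each significant pair
contributes one (lncRNA, miRNA, mRNA) triplet per shared miRNA, so the
triplet count equals the sum of k over significant pairs.

The universe N defaults to the union of the miRNA node sets of the two
source networks; ``intersection`` or a fixed integer are available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import BipartiteNetwork, TargetClass


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``N`` miRNAs in the universe, ``K`` of them bind the lncRNA, ``n`` are
    drawn as the mRNA's regulators, ``k`` is the observed overlap.
    """
    if N < 1:
        raise ValueError(f"universe size N must be >= 1, got {N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TripletTestResult:
    """Shared-miRNA overlap test for one (lncRNA, mRNA) pair."""

    lncrna_id: str
    mrna_id: str
    K: int  #: miRNAs binding the lncRNA
    n: int  #: miRNAs binding the mRNA
    k: int  #: shared miRNAs
    N: int  #: miRNA universe size
    p_value: float
    adj_p_value: float


@dataclass(frozen=True)
class CeRNANetwork:
    """A set of lncRNA-miRNA-mRNA triplets with their pair-level evidence.

    ``pair_results`` holds the significant (lncRNA, mRNA) tests, sorted
    lexicographically; every triplet inherits its pair's significance.
    """

    triplets: frozenset[tuple[str, str, str]]  #: (lncRNA, miRNA, mRNA)
    pair_results: tuple[TripletTestResult, ...] = ()
    n_pairs_tested: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.triplets)

    @cached_property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _, _ in self.triplets)

    @cached_property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for _, m, _ in self.triplets)

    @cached_property
    def mrnas(self) -> frozenset[str]:
        return frozenset(g for _, _, g in self.triplets)

    def mrna_projection(self) -> BipartiteNetwork:
        """Deduplicated miRNA-mRNA edges induced by the triplets."""
        return BipartiteNetwork.from_edges(
            ((m, g) for _, m, g in self.triplets), TargetClass.MRNA
        )

    def lncrna_projection(self) -> BipartiteNetwork:
        """Deduplicated miRNA-lncRNA edges induced by the triplets."""
        return BipartiteNetwork.from_edges(
            ((m, l) for l, m, _ in self.triplets), TargetClass.LNCRNA
        )


def infer_triplets(
    mrna_net: BipartiteNetwork,
    lncrna_net: BipartiteNetwork,
    alpha: float = 0.01,
    universe: str | int = "union",
) -> CeRNANetwork:
    """Infer the global ceRNA network from the two source networks.

    Tests every (lncRNA, mRNA) pair with >= 1 shared miRNA, BH-adjusts over
    exactly that family, and emits one triplet per shared miRNA of each
    pair with adj.P < ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if mrna_net.target_class != TargetClass.MRNA:
        raise ValueError("mrna_net must have target_class mRNA")
    if lncrna_net.target_class != TargetClass.LNCRNA:
        raise ValueError("lncrna_net must have target_class lncRNA")

    union = mrna_net.mirnas | lncrna_net.mirnas
    if universe == "union":
        population = union
        N = len(population)
    elif universe == "intersection":
        population = mrna_net.mirnas & lncrna_net.mirnas
        N = len(population)
    else:
        N = int(universe)
        population = union
        if N < len(union):
            raise ValueError(
                f"fixed universe N={N} smaller than the {len(union)} observed miRNAs"
            )
    if N == 0 or not population:
        raise ValueError("empty miRNA universe")

    # regulator sets restricted to the universe
    reg_l = {
        t: lncrna_net.regulators_of(t) & population for t in lncrna_net.targets
    }
    reg_g = {t: mrna_net.regulators_of(t) & population for t in mrna_net.targets}

    # candidate pairs via shared miRNAs only (k >= 1 by construction)
    shared: dict[tuple[str, str], set[str]] = {}
    for m in (mrna_net.mirnas & lncrna_net.mirnas) & population:
        for l in lncrna_net.targets_of(m):
            for g in mrna_net.targets_of(m):
                shared.setdefault((l, g), set()).add(m)

    keys = sorted(shared)  # deterministic family order
    p_raw = [
        hypergeom_upper_tail(len(shared[l, g]), len(reg_l[l]), len(reg_g[g]), N)
        for l, g in keys
    ]
    adj = bh_adjust(p_raw)

    sig_results: list[TripletTestResult] = []
    triplets: set[tuple[str, str, str]] = set()
    for (l, g), p, q in zip(keys, p_raw, adj):
        if q < alpha:
            sig_results.append(
                TripletTestResult(
                    lncrna_id=l,
                    mrna_id=g,
                    K=len(reg_l[l]),
                    n=len(reg_g[g]),
                    k=len(shared[l, g]),
                    N=N,
                    p_value=p,
                    adj_p_value=float(q),
                )
            )
            for m in shared[l, g]:
                triplets.add((l, m, g))
    return CeRNANetwork(
        triplets=frozenset(triplets),
        pair_results=tuple(sig_results),
        n_pairs_tested=len(keys),
    )
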