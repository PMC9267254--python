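"""Single-line regulation (NSR) scoring and candidate biomarker calls.

The model's central statistic is the *number of single-line regulations*
(NSR) of a miRNA in the condition-specific ceRNA network:

* ``nsr_mrna``   — mRNAs whose only miRNA partner (in the network's
  miRNA-mRNA projection) is this miRNA;
* ``nsr_lncrna`` — likewise in the miRNA-lncRNA projection;
* ``nsr_sponge`` = nsr_mrna + nsr_lncrna (definitional).

Single-line edges are the vulnerable sites of the network: a miRNA with
many exclusive partners exerts regulation no other miRNA can buffer, and
such miRNAs are the biomarker candidates.  Significance of each count is
assessed against the other miRNAs in the same network with a one-sided
Wilcoxon signed-rank test on the paired differences NSR_m - NSR_j (exact,
tie-aware, for <= 25 nonzero differences; tie-corrected normal
approximation above), or with a transparent empirical upper-tail rank as a
cross-check.  A miRNA is a candidate when all three metrics are
significant at the chosen alpha (raw p; the filter is deliberately
uncorrected across metrics and miRNAs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .triplets import CeRNANetwork

#: largest number of nonzero differences for which the signed-rank null is
#: enumerated exactly (sign-flip distribution over doubled midranks)
EXACT_SIGNED_RANK_LIMIT = 25


@dataclass(frozen=True)
class NSRProfile:
    """Per-miRNA single-line regulation counts with significance."""

    mirna_id: str
    nsr_mrna: int
    nsr_lncrna: int
    nsr_sponge: int
    p_mrna: float | None = None
    p_lncrna: float | None = None
    p_sponge: float | None = None
    is_candidate: bool | None = None

    def __post_init__(self):
        if min(self.nsr_mrna, self.nsr_lncrna, self.nsr_sponge) < 0:
            raise ValueError("NSR counts must be >= 0")
        if self.nsr_sponge != self.nsr_mrna + self.nsr_lncrna:
            raise ValueError(
                f"{self.mirna_id}: nsr_sponge ({self.nsr_sponge}) != "
                f"nsr_mrna + nsr_lncrna ({self.nsr_mrna} + {self.nsr_lncrna})"
            )


def extract_condition_specific(
    global_net: CeRNANetwork, de_mirnas: Iterable[str], de_mrnas: Iterable[str]
) -> CeRNANetwork:
    """Condition-specific subnetwork: triplets with a DE miRNA and a DE mRNA.

    lncRNAs are not filtered by expression — whatever lncRNAs survive are
    the inferred functional lncRNAs of the condition.
    """
    if not global_net.triplets:
        raise ValueError("global ceRNA network is empty")
    dm, dg = set(de_mirnas), set(de_mrnas)
    kept = frozenset(
        (l, m, g) for l, m, g in global_net.triplets if m in dm and g in dg
    )
    if not kept:
        warnings.warn(
            "condition-specific extraction produced an empty network",
            stacklevel=2,
        )
    surviving_pairs = {(l, g) for l, _, g in kept}
    return CeRNANetwork(
        triplets=kept,
        pair_results=tuple(
            r
            for r in global_net.pair_results
            if (r.lncrna_id, r.mrna_id) in surviving_pairs
        ),
        n_pairs_tested=global_net.n_pairs_tested,
    )


def compute_nsr(specific_net: CeRNANetwork) -> list[NSRProfile]:
    """NSR counts for every miRNA of the network (no p-values yet).

    The triplet set is projected onto deduplicated miRNA-mRNA and
    miRNA-lncRNA bipartite networks; single-line counts are taken within
    those projections.
    """
    if not specific_net.triplets:
        raise ValueError("cannot compute NSR on an empty network")
    mrna_proj = specific_net.mrna_projection()
    lnc_proj = specific_net.lncrna_projection()
    profiles = []
    for m in sorted(specific_net.mirnas):
        n_mrna = len(mrna_proj.single_line_targets(m)) if m in mrna_proj.mirnas else 0
        n_lnc = len(lnc_proj.single_line_targets(m)) if m in lnc_proj.mirnas else 0
        profiles.append(
            NSRProfile(
                mirna_id=m,
                nsr_mrna=n_mrna,
                nsr_lncrna=n_lnc,
                nsr_sponge=n_mrna + n_lnc,
            )
        )
    return profiles


def signed_rank_greater_p(diffs: Sequence[float]) -> float:
    """One-sided Wilcoxon signed-rank p for "median difference > 0".

    Zero differences are dropped (Wilcoxon convention).  For n <=
    ``EXACT_SIGNED_RANK_LIMIT`` nonzero differences the null distribution
    of W+ is enumerated exactly by dynamic programming over doubled
    midranks, which stays exact under ties in |d| (scipy's exact path does
    not allow ties).  Larger n uses the tie-corrected normal approximation.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks; may be half-integers
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_LIMIT:
        r2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(np.rint(2 * w_plus))
        return float(dist[w2:].sum())
    mean = n * (n + 1) / 4.0
    # tie correction on the variance: sum(t^3 - t)/48 over tied groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(stats.norm.sf(z))


_METRIC_FIELDS = {
    "mrna": ("nsr_mrna", "p_mrna"),
    "lncrna": ("nsr_lncrna", "p_lncrna"),
    "sponge": ("nsr_sponge", "p_sponge"),
}


def nsr_significance(
    profiles: Sequence[NSRProfile],
    metric: str,
    method: str = "signed_rank",
) -> list[NSRProfile]:
    """Fill one metric's p-values: is each miRNA's NSR high vs the rest?

    ``signed_rank`` pairs miRNA m's count against every other miRNA's count
    and tests "median difference > 0".  ``empirical`` is the upper-tail
    rank p = (1 + #{j != m : NSR_j >= NSR_m}) / (number of miRNAs).
    """
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"unknown metric: {metric!r}")
    if method not in ("signed_rank", "empirical"):
        raise ValueError(f"unknown method: {method!r}")
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 profiles, got {len(profiles)}")
    value_field, p_field = _METRIC_FIELDS[metric]
    values = np.array([getattr(p, value_field) for p in profiles], dtype=float)
    if np.all(values == values[0]):
        warnings.warn(
            f"all {metric} NSR values identical; no miRNA can be significant",
            stacklevel=2,
        )
        return [replace(p, **{p_field: 1.0}) for p in profiles]
    out = []
    n_total = len(values)
    for i, prof in enumerate(profiles):
        others = np.delete(values, i)
        if method == "signed_rank":
            p = signed_rank_greater_p(values[i] - others)
        else:
            p = (1 + int((others >= values[i]).sum())) / n_total
        out.append(replace(prof, **{p_field: float(p)}))
    return out


def score_profiles(
    profiles: Sequence[NSRProfile], method: str = "signed_rank"
) -> list[NSRProfile]:
    """Fill p-values for all three metrics."""
    for metric in ("mrna", "lncrna", "sponge"):
        profiles = nsr_significance(profiles, metric, method)
    return list(profiles)


def select_candidates(
    profiles: Sequence[NSRProfile], alpha: float = 0.05
) -> list[NSRProfile]:
    """Flag candidates (all three metrics significant at ``alpha``).

    Output is sorted by nsr_sponge descending, ties broken by miRNA ID.
    """
    for p in profiles:
        if p.p_mrna is None or p.p_lncrna is None or p.p_sponge is None:
            raise ValueError(f"{p.mirna_id}: p-values not filled")
    flagged = [
        replace(
            p,
            is_candidate=bool(
                p.p_mrna < alpha and p.p_lncrna < alpha and p.p_sponge < alpha
            ),
        )
        for p in profiles
    ]
    return sorted(flagged, key=lambda p: (-p.nsr_sponge, p.mirna_id))


def score_nsr(
    specific_net: CeRNANetwork,
    alpha: float = 0.05,
    method: str = "signed_rank",
) -> list[NSRProfile]:
    """Full NSR stage: counts, significance, candidate flags."""
    return select_candidates(score_profiles(compute_nsr(specific_net), method), alpha)
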