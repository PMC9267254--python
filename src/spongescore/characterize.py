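"""Topological and evaluative companion analyses.

Covers the descriptive statistics that situate the NSR model: LMC-miRNA
classification (miRNAs competed by both lncRNAs and mRNAs), the
Group I/II/III partition by single-line regulatory power, two-sample
distribution comparisons (Kolmogorov-Smirnov), biomarker-proportion trend
tests (Pearson chi-squared), Spearman rank correlation, functional
gene-set fractions of miRNA targets, and rank-based ROC/AUC evaluation of
candidate miRNAs on expression data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .de import ExpressionMatrix
from .netio import GeneSet
from .network import BipartiteNetwork
from .nsr import NSRProfile


@dataclass(frozen=True)
class MiRNAClassification:
    """Per-miRNA topological classification."""

    mirna_id: str
    group: str  #: "I" (no single-line power), "II" (one side), "III" (both)
    is_lmc: bool | None = None
    is_reported_biomarker: bool | None = None
    biomarker_scope: str = "none"  #: none | specific | universal


@dataclass(frozen=True)
class RocResult:
    """Orientation-resolved AUC for one feature."""

    mirna_id: str
    auc: float
    direction: str  #: down_in_case | up_in_case


def classify_lmc(
    mrna_net: BipartiteNetwork, lncrna_net: BipartiteNetwork
) -> frozenset[str]:
    """miRNAs present in both source networks (lncRNA/mRNA-competed)."""
    return frozenset(mrna_net.mirnas & lncrna_net.mirnas)


def assign_groups(profiles: Sequence[NSRProfile]) -> list[MiRNAClassification]:
    """Partition miRNAs by where their single-line power lies.

    Group I: none; Group II: solely mRNAs or solely lncRNAs; Group III: both.
    """
    out = []
    for p in profiles:
        has_m, has_l = p.nsr_mrna > 0, p.nsr_lncrna > 0
        group = "III" if (has_m and has_l) else ("II" if (has_m or has_l) else "I")
        out.append(MiRNAClassification(mirna_id=p.mirna_id, group=group))
    return out


def compare_distributions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test: (D, p)."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def proportion_trend_test(
    counts: Mapping[str, tuple[int, int]]
) -> tuple[float, float]:
    """Pearson chi-squared on a groups x {biomarker, other} table.

    ``counts`` maps group label -> (number of biomarkers, group total).
    No continuity correction is applied.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    table = []
    for name, (bio, total) in counts.items():
        if total <= 0:
            raise ValueError(f"group {name!r} has zero total")
        if not 0 <= bio <= total:
            raise ValueError(f"group {name!r}: biomarkers exceed total")
        table.append([bio, total - bio])
    obs = np.asarray(table, dtype=float)
    if np.any(obs.sum(axis=0) == 0):  # all-biomarker or no-biomarker margin
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (tie-aware): (rho, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def functional_fraction(
    target_sets: Mapping[str, set[str]],
    gene_set: GeneSet,
    classes: Mapping[str, str] | None = None,
    mode: str = "union",
) -> dict[str, float | None]:
    """Fraction of a miRNA class's targets that fall in a functional set.

    ``classes`` maps miRNA -> class label (all one class when omitted).
    ``union`` pools each class's targets before taking the fraction;
    ``per_mirna_mean`` averages per-miRNA fractions instead.  Classes whose
    target union is empty report ``None``.
    """
    if mode not in ("union", "per_mirna_mean"):
        raise ValueError(f"unknown mode: {mode!r}")
    if classes is None:
        classes = {m: "all" for m in target_sets}
    by_class: dict[str, list[set[str]]] = {}
    for m, targets in target_sets.items():
        by_class.setdefault(classes.get(m, "other"), []).append(set(targets))
    out: dict[str, float | None] = {}
    for label, sets in by_class.items():
        if mode == "union":
            union = set().union(*sets)
            out[label] = len(union & gene_set.members) / len(union) if union else None
        else:
            fracs = [
                len(s & gene_set.members) / len(s) for s in sets if s
            ]
            out[label] = float(np.mean(fracs)) if fracs else None
    return out


def compute_auc(
    expr: ExpressionMatrix, feature: str, orientation: str = "auto"
) -> RocResult:
    """Rank-based AUC (Mann-Whitney concordance, ties count 1/2).

    The raw statistic is P(case > reference).  ``auto`` reports
    max(a, 1 - a) with the implied direction; ``fixed`` orients by the
    sign of the feature's log2FC (case minus reference means).
    """
    if orientation not in ("auto", "fixed"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    ref, case = expr.group_values(feature)
    if ref.size == 0 or case.size == 0:
        raise ValueError(f"{feature}: a group is empty")
    combined = np.concatenate([case, ref])
    ranks = stats.rankdata(combined)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    auc_up = float(u / (case.size * ref.size))  # P(case > ref), ties 1/2
    if orientation == "auto":
        if auc_up >= 0.5:
            return RocResult(feature, auc_up, "up_in_case")
        return RocResult(feature, 1.0 - auc_up, "down_in_case")
    lfc = case.mean() - ref.mean()
    if lfc < 0:
        return RocResult(feature, 1.0 - auc_up, "down_in_case")
    return RocResult(feature, auc_up, "up_in_case")


def mean_auc(results: Sequence[RocResult] | Sequence[float]) -> float:
    """Arithmetic mean AUC over a set of ROC results (or raw AUC values)."""
    if len(results) == 0:
        raise ValueError("no ROC results")
    values = [r.auc if isinstance(r, RocResult) else float(r) for r in results]
    return float(np.mean(values))
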