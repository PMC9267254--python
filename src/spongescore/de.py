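"""Two-group differential expression on log2 expression matrices.

The DE step gates the condition-specific network extraction: features with
adjusted P < alpha and |log2FC| above a threshold (both strict) are called
differentially expressed.  log2FC is defined as case mean minus reference
mean, so features lower in the case group have negative fold change.

Two engines are provided.  ``welch`` is the unequal-variance two-sample
t-test.  ``moderated`` is an empirical-Bayes moderated t in the limma
style: per-feature pooled variances are shrunk toward a prior variance
s0^2 with prior degrees of freedom d0, both estimated by method of moments
on the log variances, and the t statistic uses the posterior variance

    s_post^2 = (d0 s0^2 + d s^2) / (d0 + d)

with d + d0 degrees of freedom.  The engine is interchangeable — a
precomputed DE table can be supplied instead (``de_results_from_table``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .triplets import bh_adjust


@dataclass(frozen=True)
class ExpressionMatrix:
    """log2 expression values (features x samples) with two-group labels."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: Mapping[str, str]
    reference: str
    case: str
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {v.shape} does not match {len(self.feature_ids)} "
                f"features x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        groups = {self.labels[s] for s in self.sample_ids}
        if not groups <= {self.reference, self.case}:
            raise ValueError(f"unknown group labels: {sorted(groups)}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, labels: Mapping[str, str],
                       reference: str, case: str) -> "ExpressionMatrix":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            labels=dict(labels),
            reference=reference,
            case=case,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @cached_property
    def _group_columns(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([self.labels[s] == self.reference for s in self.sample_ids])
        case = np.array([self.labels[s] == self.case for s in self.sample_ids])
        return np.flatnonzero(ref), np.flatnonzero(case)

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """(reference values, case values) for one feature."""
        try:
            i = self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature: {feature!r}") from None
        ref_idx, case_idx = self._group_columns
        return self.values[i, ref_idx], self.values[i, case_idx]


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression call."""

    feature_id: str
    log2_fc: float
    p_value: float
    adj_p_value: float
    is_de: bool
    degenerate: bool = False  #: zero within-group variance (p by convention)


def differential_expression(
    expr: ExpressionMatrix,
    method: str = "welch",
    alpha_de: float = 0.05,
    lfc_threshold: float = 1.0,
) -> list[DEResult]:
    """Per-feature two-sided test of group mean difference, BH-adjusted.

    DE calls use strict inequalities: adj.P < ``alpha_de`` and
    |log2FC| > ``lfc_threshold``.
    """
    ref_idx, case_idx = expr._group_columns
    if len(ref_idx) < 2 or len(case_idx) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(ref_idx)} reference / "
            f"{len(case_idx)} case"
        )
    ref = expr.values[:, ref_idx]
    case = expr.values[:, case_idx]
    lfc = case.mean(axis=1) - ref.mean(axis=1)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(case, ref, axis=1, equal_var=False)
        p = np.asarray(p, dtype=float)
        degenerate = (ref.var(axis=1) == 0) & (case.var(axis=1) == 0)
        # zero variance in both groups: p=1 when means agree, else p->0
        p[degenerate & (lfc == 0)] = 1.0
        p[degenerate & (lfc != 0)] = np.finfo(float).tiny
    elif method == "moderated":
        p, degenerate = _moderated_t_pvalues(ref, case, lfc)
    else:
        raise ValueError(f"unknown DE method: {method!r}")

    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_adjust(p)
    return [
        DEResult(
            feature_id=f,
            log2_fc=float(l),
            p_value=float(pi),
            adj_p_value=float(qi),
            is_de=bool(qi < alpha_de and abs(l) > lfc_threshold),
            degenerate=bool(d),
        )
        for f, l, pi, qi, d in zip(expr.feature_ids, lfc, p, adj, degenerate)
    ]


def _moderated_t_pvalues(ref: np.ndarray, case: np.ndarray, lfc: np.ndarray):
    """Empirical-Bayes moderated t (variance shrinkage, method of moments)."""
    n1, n2 = ref.shape[1], case.shape[1]
    d = n1 + n2 - 2
    s2 = (ref.var(axis=1, ddof=1) * (n1 - 1) + case.var(axis=1, ddof=1) * (n2 - 1)) / d
    degenerate = s2 == 0
    d0, s0_sq = _fit_variance_prior(s2[~degenerate], d)
    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df = d + d0
    else:  # no excess variability: all features share the prior variance
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    s2_post = np.where(degenerate, s0_sq if s0_sq > 0 else 1.0, s2_post)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = lfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df if np.isfinite(df) else 1e9)
    return p, degenerate


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Moments of log variances: if s^2 ~ s0^2 * d0/d * F(d, d0) then
    var(log s^2) = trigamma(d/2) + trigamma(d0/2); d0 solves that equation
    (Newton on the trigamma inverse) and s0^2 follows from the mean.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
    excess = z.var(ddof=1) - special.polygamma(1, d / 2.0)
    if excess <= 1e-8:
        return np.inf, float(np.exp(e.mean()))
    # invert trigamma(d0/2) = excess by Newton iteration
    x = 0.5 + 1.0 / excess  # starting value from trigamma(x) ~ 1/x
    for _ in range(50):
        f = special.polygamma(1, x) - excess
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * x:
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0_sq = np.exp(e.mean() + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def de_sets(
    results: Sequence[DEResult], alpha_de: float = 0.05, lfc_threshold: float = 1.0
) -> tuple[set[str], set[str]]:
    """(up-regulated, down-regulated) DE feature sets at the given thresholds."""
    up, down = set(), set()
    for r in results:
        if r.adj_p_value < alpha_de and abs(r.log2_fc) > lfc_threshold:
            (up if r.log2_fc > 0 else down).add(r.feature_id)
    return up, down


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "log2FC": [r.log2_fc for r in results],
            "p": [r.p_value for r in results],
            "adj_p": [r.adj_p_value for r in results],
            "is_de": [r.is_de for r in results],
        }
    )


def de_results_from_table(
    path_or_frame, alpha_de: float = 0.05, lfc_threshold: float = 1.0
) -> list[DEResult]:
    """Adopt a precomputed DE table (feature, log2FC, p, adj_p columns).

    Lets an external engine (e.g. a limma fit) replace the built-in tests;
    the DE call is re-derived from the stated thresholds.  A ``p`` column is
    optional when ``adj_p`` is present.
    """
    frame = (
        path_or_frame
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame, sep="\t")
    )
    required = {"feature", "log2FC", "adj_p"}
    if not required <= set(frame.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    p_col = frame["p"] if "p" in frame.columns else frame["adj_p"]
    out = []
    for feat, lfc, p, q in zip(frame["feature"], frame["log2FC"], p_col, frame["adj_p"]):
        out.append(
            DEResult(
                feature_id=str(feat),
                log2_fc=float(lfc),
                p_value=float(p),
                adj_p_value=float(q),
                is_de=bool(q < alpha_de and abs(lfc) > lfc_threshold),
            )
        )
    return out
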