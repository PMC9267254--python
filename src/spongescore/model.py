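"""Model/Results interface tying the pipeline stages together.

:class:`CeRNABiomarkerModel` holds the data (two miRNA-target networks and,
optionally, miRNA/mRNA expression or precomputed DE tables) plus the
analysis thresholds; :meth:`CeRNABiomarkerModel.fit` runs

    differential expression -> global ceRNA (triplet) inference ->
    condition-specific extraction -> NSR scoring -> candidate selection

and returns a :class:`CeRNABiomarkerResults` carrying every intermediate
product, with ``summary()``, ``roc()`` and ``plot_nsr()`` attached.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import characterize as chz
from .de import DEResult, ExpressionMatrix, de_sets, differential_expression
from .network import BipartiteNetwork
from .nsr import (
    NSRProfile,
    compute_nsr,
    extract_condition_specific,
    score_profiles,
    select_candidates,
)
from .triplets import CeRNANetwork, infer_triplets


class CeRNABiomarkerModel:
    """NSR biomarker model over a lncRNA-miRNA-mRNA ceRNA network.

    Parameters
    ----------
    mrna_net, lncrna_net
        The two source bipartite networks (reference interactome).
    mirna_expr, mrna_expr
        Two-group log2 expression matrices used for the DE gate (and for
        ROC evaluation of candidates).  Either matrix may be replaced by a
        precomputed DE result list (``de_mirna_results`` /
        ``de_mrna_results``), e.g. from an external limma fit.
    alpha_triplet
        Adjusted-P threshold for the pair-overlap test (default 0.01).
    alpha_de, lfc_threshold
        DE thresholds: adj.P < alpha_de and |log2FC| > lfc_threshold
        (defaults 0.05 and 1.0, both strict).
    de_method
        ``welch`` or ``moderated`` (empirical-Bayes variance shrinkage).
    universe
        Hypergeometric universe policy: ``union`` (default),
        ``intersection``, or a fixed integer.
    """

    def __init__(
        self,
        mrna_net: BipartiteNetwork,
        lncrna_net: BipartiteNetwork,
        mirna_expr: ExpressionMatrix | None = None,
        mrna_expr: ExpressionMatrix | None = None,
        *,
        de_mirna_results: Sequence[DEResult] | None = None,
        de_mrna_results: Sequence[DEResult] | None = None,
        alpha_triplet: float = 0.01,
        alpha_de: float = 0.05,
        lfc_threshold: float = 1.0,
        de_method: str = "welch",
        universe: str | int = "union",
    ):
        if mirna_expr is None and de_mirna_results is None:
            raise ValueError("need mirna_expr or de_mirna_results")
        if mrna_expr is None and de_mrna_results is None:
            raise ValueError("need mrna_expr or de_mrna_results")
        self.mrna_net = mrna_net
        self.lncrna_net = lncrna_net
        self.mirna_expr = mirna_expr
        self.mrna_expr = mrna_expr
        self.de_mirna_results = de_mirna_results
        self.de_mrna_results = de_mrna_results
        self.alpha_triplet = alpha_triplet
        self.alpha_de = alpha_de
        self.lfc_threshold = lfc_threshold
        self.de_method = de_method
        self.universe = universe

    @classmethod
    def from_synthetic(cls, dataset, **kwargs) -> "CeRNABiomarkerModel":
        """Build the model from a :class:`~spongescore.simulate.SyntheticDataset`."""
        return cls(
            dataset.mrna_net,
            dataset.lncrna_net,
            mirna_expr=dataset.expr_mirna,
            mrna_expr=dataset.expr_mrna,
            **kwargs,
        )

    def _de(self, expr, precomputed) -> list[DEResult]:
        if precomputed is not None:
            return list(precomputed)
        return differential_expression(
            expr, self.de_method, self.alpha_de, self.lfc_threshold
        )

    def fit(self, alpha: float = 0.05, method: str = "signed_rank"):
        """Run the pipeline; returns a :class:`CeRNABiomarkerResults`.

        ``alpha`` is the per-metric NSR significance cut for candidate
        calls; ``method`` is ``signed_rank`` or ``empirical``.
        """
        de_mirna = self._de(self.mirna_expr, self.de_mirna_results)
        de_mrna = self._de(self.mrna_expr, self.de_mrna_results)
        mi_up, mi_down = de_sets(de_mirna, self.alpha_de, self.lfc_threshold)
        g_up, g_down = de_sets(de_mrna, self.alpha_de, self.lfc_threshold)

        global_net = infer_triplets(
            self.mrna_net, self.lncrna_net, self.alpha_triplet, self.universe
        )
        if global_net.triplets:
            specific = extract_condition_specific(
                global_net, mi_up | mi_down, g_up | g_down
            )
        else:
            warnings.warn("global ceRNA network is empty", stacklevel=2)
            specific = CeRNANetwork(frozenset(), (), global_net.n_pairs_tested)

        if specific.triplets:
            profiles = compute_nsr(specific)
            if len(profiles) >= 3:
                profiles = select_candidates(score_profiles(profiles, method), alpha)
            else:
                warnings.warn(
                    f"only {len(profiles)} miRNAs in the condition-specific "
                    "network; significance not testable, no candidates called",
                    stacklevel=2,
                )
                profiles = [
                    NSRProfile(
                        p.mirna_id, p.nsr_mrna, p.nsr_lncrna, p.nsr_sponge,
                        p_mrna=1.0, p_lncrna=1.0, p_sponge=1.0, is_candidate=False,
                    )
                    for p in profiles
                ]
        else:
            profiles = []

        return CeRNABiomarkerResults(
            model=self,
            de_mirna=de_mirna,
            de_mrna=de_mrna,
            global_network=global_net,
            specific_network=specific,
            profiles=profiles,
            alpha=alpha,
            method=method,
        )


class CeRNABiomarkerResults:
    """Fitted pipeline products with reporting helpers."""

    def __init__(self, model, de_mirna, de_mrna, global_network,
                 specific_network, profiles, alpha, method):
        self.model = model
        self.de_mirna = de_mirna
        self.de_mrna = de_mrna
        self.global_network = global_network
        self.specific_network = specific_network
        self.profiles = profiles
        self.alpha = alpha
        self.method = method

    # -- derived views -----------------------------------------------------

    @property
    def de_mirna_sets(self) -> tuple[set[str], set[str]]:
        return de_sets(self.de_mirna, self.model.alpha_de, self.model.lfc_threshold)

    @property
    def de_mrna_sets(self) -> tuple[set[str], set[str]]:
        return de_sets(self.de_mrna, self.model.alpha_de, self.model.lfc_threshold)

    @property
    def candidates(self) -> list[NSRProfile]:
        return [p for p in self.profiles if p.is_candidate]

    @property
    def candidate_ids(self) -> list[str]:
        return [p.mirna_id for p in self.candidates]

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna": [p.mirna_id for p in self.profiles],
                "nsr_mrna": [p.nsr_mrna for p in self.profiles],
                "p_mrna": [p.p_mrna for p in self.profiles],
                "nsr_lncrna": [p.nsr_lncrna for p in self.profiles],
                "p_lncrna": [p.p_lncrna for p in self.profiles],
                "nsr_sponge": [p.nsr_sponge for p in self.profiles],
                "p_sponge": [p.p_sponge for p in self.profiles],
                "is_candidate": [p.is_candidate for p in self.profiles],
            }
        )

    # -- evaluation --------------------------------------------------------

    def roc(self, orientation: str = "auto",
            features: Sequence[str] | None = None) -> list[chz.RocResult]:
        """AUC of each candidate miRNA (or the given features) on expression."""
        if self.model.mirna_expr is None:
            raise ValueError("no miRNA expression attached to the model")
        if features is None:
            features = self.candidate_ids
        return [
            chz.compute_auc(self.model.mirna_expr, f, orientation) for f in features
        ]

    def mean_auc(self, orientation: str = "auto") -> float:
        return chz.mean_auc(self.roc(orientation))

    # -- reporting ---------------------------------------------------------

    def summary(self) -> "Summary":
        m = self.model
        mi_up, mi_down = self.de_mirna_sets
        g_up, g_down = self.de_mrna_sets
        g, s = self.global_network, self.specific_network
        lines = [
            "ceRNA single-line regulation (NSR) biomarker model",
            "=" * 66,
            f"miRNA-mRNA source network:   {len(m.mrna_net.mirnas):>5} miRNAs, "
            f"{len(m.mrna_net.targets):>5} mRNAs, {len(m.mrna_net.edges):>6} edges",
            f"miRNA-lncRNA source network: {len(m.lncrna_net.mirnas):>5} miRNAs, "
            f"{len(m.lncrna_net.targets):>5} lncRNAs, {len(m.lncrna_net.edges):>6} edges",
            f"DE miRNAs: {len(mi_up) + len(mi_down)} "
            f"(up {len(mi_up)}, down {len(mi_down)}); "
            f"DE mRNAs: {len(g_up) + len(g_down)} "
            f"(up {len(g_up)}, down {len(g_down)})"
            f"  [adj.P < {m.alpha_de}, |log2FC| > {m.lfc_threshold}]",
            f"Global ceRNA network:  {len(g):>7} triplets "
            f"({len(g.mirnas)} miRNAs, {len(g.lncrnas)} lncRNAs, "
            f"{len(g.mrnas)} mRNAs; {g.n_pairs_tested} pairs tested, "
            f"adj.P < {m.alpha_triplet})",
            f"Condition-specific:    {len(s):>7} triplets "
            f"({len(s.mirnas)} miRNAs, {len(s.lncrnas)} lncRNAs, "
            f"{len(s.mrnas)} mRNAs)",
            f"Candidates: {len(self.candidates)} of {len(self.profiles)} "
            f"profiled miRNAs (P < {self.alpha}, {self.method})",
        ]
        if self.candidates:
            frame = self.profiles_frame()
            frame = frame[frame["is_candidate"]].drop(columns="is_candidate")
            with pd.option_context("display.float_format", "{:.3g}".format):
                lines += ["", frame.to_string(index=False)]
        return Summary("\n".join(lines))

    def plot_nsr(self, ax=None):
        """Bar chart of NSR-mRNA/NSR-lncRNA per profiled miRNA (candidates marked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        frame = self.profiles_frame().sort_values(
            "nsr_sponge", ascending=False
        )
        x = np.arange(len(frame))
        ax.bar(x, frame["nsr_mrna"], label="NSR-mRNA")
        ax.bar(x, frame["nsr_lncrna"], bottom=frame["nsr_mrna"], label="NSR-lncRNA")
        ax.set_xticks(x)
        ax.set_xticklabels(
            [
                f"{m}*" if c else m
                for m, c in zip(frame["mirna"], frame["is_candidate"])
            ],
            rotation=90,
            fontsize=7,
        )
        ax.set_ylabel("single-line regulations")
        ax.legend()
        ax.figure.tight_layout()
        return ax


class Summary:
    """Plain-text summary block (statsmodels-style)."""

    def __init__(self, text: str):
        self._text = text

    def __str__(self) -> str:
        return self._text

    def __repr__(self) -> str:
        return self._text
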