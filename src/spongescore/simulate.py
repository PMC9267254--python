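"""Synthetic ceRNA-network and expression data with planted biomarkers.

The generator emulates the statistical structure the NSR model assumes:

* two bipartite source networks (miRNA-mRNA, miRNA-lncRNA) with sparse
  Erdos-Renyi background edges;
* ``n_planted`` biomarker miRNAs, each given exclusive mRNA and lncRNA
  partners.  Each partner is co-targeted by a shared pool of *support*
  miRNAs that are never differentially expressed: the co-targeting makes
  every (partner lncRNA, partner mRNA) pair strongly significant under the
  hypergeometric overlap test, while after DE-based extraction the support
  miRNAs drop out and the partner is single-line to its planted miRNA.
  Single-line structure is therefore planted at the condition-specific
  level, which is where the model measures it;
* ``n_decoy_de`` decoy miRNAs that are differentially expressed but share a
  jointly co-regulated block of DE mRNAs/lncRNAs, giving them network
  membership with zero single-line power — the background the per-miRNA
  significance test needs;
* two-group log2 expression (Gaussian noise around a baseline): planted and
  decoy miRNAs, their partner mRNAs and the decoy block mRNAs are shifted
  *down* by ``effect_size`` in the case group (candidate biomarkers are
  down-regulated in the condition).

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .netio import write_edge_list, write_expression
from .network import BipartiteNetwork, TargetClass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator (defaults are the study design)."""

    n_mirnas: int = 50
    n_mrnas: int = 400
    n_lncrnas: int = 200
    density: float = 0.01  #: background edge probability, each bipartite side
    n_planted: int = 5
    planted_single_line_mrna: int = 8
    planted_single_line_lncrna: int = 8
    n_support: int = 10  #: shared pool of non-DE co-regulators of planted partners
    n_decoy_de: int = 15  #: DE miRNAs with no single-line structure
    decoy_block_mrnas: int = 6
    decoy_block_lncrnas: int = 6
    n_samples: int = 15  #: per group
    effect_size: float = 2.0  #: log2 down-shift of planted/decoy DE features
    noise_sd: float = 0.5
    baseline: float = 7.0  #: mean log2 expression
    seed: int = 1

    def __post_init__(self):
        counts = (
            self.n_mirnas, self.n_mrnas, self.n_lncrnas, self.n_planted,
            self.planted_single_line_mrna, self.planted_single_line_lncrna,
            self.n_support, self.n_decoy_de, self.decoy_block_mrnas,
            self.decoy_block_lncrnas, self.n_samples,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.density <= 1:
            raise ValueError("density must lie in [0, 1]")
        if self.n_planted + self.n_decoy_de + self.n_support > self.n_mirnas:
            raise ValueError("planted + decoy + support miRNAs exceed n_mirnas")
        if (self.n_planted * self.planted_single_line_mrna
                + self.decoy_block_mrnas > self.n_mrnas):
            raise ValueError("planted mRNA partners + decoy block exceed n_mrnas")
        if (self.n_planted * self.planted_single_line_lncrna
                + self.decoy_block_lncrnas > self.n_lncrnas):
            raise ValueError("planted lncRNA partners + decoy block exceed n_lncrnas")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated networks + expression + planted truth."""

    config: SimulationConfig
    mrna_net: BipartiteNetwork
    lncrna_net: BipartiteNetwork
    expr_mirna: ExpressionMatrix
    expr_mrna: ExpressionMatrix
    truth: frozenset[str]  #: planted biomarker miRNA IDs
    planted_partners: Mapping[str, Mapping[str, frozenset[str]]]
    support_mirnas: frozenset[str]
    decoy_mirnas: frozenset[str]
    seed: int


def _mirna_name(i: int) -> str:
    return f"miR-sim{i + 1:03d}"


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset under ``config`` (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    c = config

    mirnas = [_mirna_name(i) for i in range(c.n_mirnas)]
    mrnas = [f"G{i + 1:04d}" for i in range(c.n_mrnas)]
    lncrnas = [f"LNC{i + 1:04d}" for i in range(c.n_lncrnas)]

    planted = mirnas[: c.n_planted]
    decoys = mirnas[c.n_planted: c.n_planted + c.n_decoy_de]
    support = mirnas[c.n_planted + c.n_decoy_de:
                     c.n_planted + c.n_decoy_de + c.n_support]

    # -- structural edges --------------------------------------------------
    mrna_edges: set[tuple[str, str]] = set()
    lnc_edges: set[tuple[str, str]] = set()
    planted_partners: dict[str, dict[str, frozenset[str]]] = {}
    for i, m in enumerate(planted):
        gs = mrnas[i * c.planted_single_line_mrna:
                   (i + 1) * c.planted_single_line_mrna]
        ls = lncrnas[i * c.planted_single_line_lncrna:
                     (i + 1) * c.planted_single_line_lncrna]
        planted_partners[m] = {
            "mRNA": frozenset(gs), "lncRNA": frozenset(ls),
        }
        for g in gs:
            mrna_edges.add((m, g))
            mrna_edges.update((s, g) for s in support)
        for l in ls:
            lnc_edges.add((m, l))
            lnc_edges.update((s, l) for s in support)

    block_g = mrnas[c.n_planted * c.planted_single_line_mrna:
                    c.n_planted * c.planted_single_line_mrna + c.decoy_block_mrnas]
    block_l = lncrnas[c.n_planted * c.planted_single_line_lncrna:
                      c.n_planted * c.planted_single_line_lncrna
                      + c.decoy_block_lncrnas]
    if decoys:
        mrna_edges.update((d, g) for d in decoys for g in block_g)
        lnc_edges.update((d, l) for d in decoys for l in block_l)

    # -- background edges --------------------------------------------------
    bg_m = rng.random((c.n_mirnas, c.n_mrnas)) < c.density
    bg_l = rng.random((c.n_mirnas, c.n_lncrnas)) < c.density
    mrna_edges.update((mirnas[i], mrnas[j]) for i, j in zip(*np.nonzero(bg_m)))
    lnc_edges.update((mirnas[i], lncrnas[j]) for i, j in zip(*np.nonzero(bg_l)))

    mrna_net = BipartiteNetwork.from_edges(mrna_edges, TargetClass.MRNA)
    lncrna_net = BipartiteNetwork.from_edges(lnc_edges, TargetClass.LNCRNA)

    # -- expression --------------------------------------------------------
    samples = [f"ref{i + 1:02d}" for i in range(c.n_samples)] + [
        f"case{i + 1:02d}" for i in range(c.n_samples)
    ]
    labels = {s: ("reference" if s.startswith("ref") else "case") for s in samples}
    case_cols = slice(c.n_samples, 2 * c.n_samples)

    mi_values = rng.normal(c.baseline, c.noise_sd, (c.n_mirnas, 2 * c.n_samples))
    de_mirnas = set(planted) | set(decoys)
    for i, m in enumerate(mirnas):
        if m in de_mirnas:
            mi_values[i, case_cols] -= c.effect_size

    g_values = rng.normal(c.baseline, c.noise_sd, (c.n_mrnas, 2 * c.n_samples))
    de_mrnas = set(block_g)
    for partners in planted_partners.values():
        de_mrnas |= partners["mRNA"]
    for j, g in enumerate(mrnas):
        if g in de_mrnas:
            g_values[j, case_cols] -= c.effect_size

    expr_mirna = ExpressionMatrix(
        feature_ids=tuple(mirnas), sample_ids=tuple(samples), values=mi_values,
        labels=labels, reference="reference", case="case",
    )
    expr_mrna = ExpressionMatrix(
        feature_ids=tuple(mrnas), sample_ids=tuple(samples), values=g_values,
        labels=labels, reference="reference", case="case",
    )

    return SyntheticDataset(
        config=c,
        mrna_net=mrna_net,
        lncrna_net=lncrna_net,
        expr_mirna=expr_mirna,
        expr_mrna=expr_mrna,
        truth=frozenset(planted),
        planted_partners={m: dict(p) for m, p in planted_partners.items()},
        support_mirnas=frozenset(support),
        decoy_mirnas=frozenset(decoys),
        seed=c.seed,
    )


def collision_report(ds: SyntheticDataset) -> pd.DataFrame:
    """Planted partners touched by edges beyond their designed regulators.

    A partner's designed regulator set is its planted miRNA plus the shared
    support pool.  Extra regulators come from background edges; only extras
    that are themselves DE miRNAs (``extra_de_regulator``) can break the
    partner's single-line status in the condition-specific network.
    """
    designed = ds.support_mirnas
    de_mirnas = ds.truth | ds.decoy_mirnas
    rows = []
    for owner, partners in ds.planted_partners.items():
        for cls, net in (("mRNA", ds.mrna_net), ("lncRNA", ds.lncrna_net)):
            for partner in sorted(partners[cls]):
                extras = net.regulators_of(partner) - designed - {owner}
                if extras:
                    rows.append(
                        {
                            "partner_id": partner,
                            "target_class": cls,
                            "owner_mirna": owner,
                            "n_extra_regulators": len(extras),
                            "extra_de_regulator": bool(extras & de_mirnas),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "partner_id", "target_class", "owner_mirna",
            "n_extra_regulators", "extra_de_regulator",
        ],
    )


def recovery_metrics(predicted, truth) -> tuple[float, float]:
    """(precision, recall) of a predicted candidate set against the truth.

    Precision of an empty prediction is 1.0 by convention (nothing wrongly
    called); recall of an empty truth is 1.0.
    """
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write pair lists, expression, labels and the truth table as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(ds.mrna_net, outdir / "mrna_pairs.tsv")
    write_edge_list(ds.lncrna_net, outdir / "lncrna_pairs.tsv")
    write_expression(ds.expr_mirna, outdir / "expr_mirna.tsv", outdir / "labels.tsv")
    write_expression(ds.expr_mrna, outdir / "expr_mrna.tsv", outdir / "labels.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        for m in sorted(ds.truth):
            fh.write(f"{m}\n")
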