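"""File formats, identifier normalization and deterministic reports.

No science lives here.  Everything is plain TSV:

* pair lists — ``regulator<TAB>target[<TAB>source[<TAB>support]]``
* gene sets — one symbol per line, or two-column ``set-name<TAB>symbol``
* expression — first column feature ID, remaining columns samples;
  labels — ``sample<TAB>group``
* reports — any record table, written with a fixed column order and rows
  sorted by primary key so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .network import TargetClass

_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-")


def normalize_mirna_id(raw: str, strip_species_prefix: bool = True) -> str:
    """Canonicalize a miRNA symbol.

    Strips a three-letter species prefix (``hsa-miR-23b-3p`` -> ``miR-23b-3p``)
    when ``strip_species_prefix`` is on, and normalizes the family token's
    case to the ``miR-``/``let-`` convention (``MIR-21`` -> ``miR-21``).
    """
    s = raw.strip()
    # "mir-"/"let-" are family tokens, not species prefixes like "hsa-"
    if (strip_species_prefix and _SPECIES_PREFIX.match(s)
            and s[:3].lower() not in ("mir", "let")):
        s = s[4:]
    if not s:
        raise ValueError(f"empty miRNA symbol after normalization: {raw!r}")
    head, sep, rest = s.partition("-")
    low = head.lower()
    if low == "mir":
        head = "miR"
    elif low == "let":
        head = "let"
    return head + sep + rest


@dataclass(frozen=True)
class RegulatoryPair:
    """One miRNA -> target regulation with its evidence."""

    regulator_id: str
    target_id: str
    target_class: TargetClass
    sources: frozenset[str] = frozenset()
    support_count: int = 1

    def __post_init__(self):
        if not self.regulator_id or not self.target_id:
            raise ValueError("regulator_id and target_id must be non-empty")
        if self.support_count < 0:
            raise ValueError("support_count must be >= 0")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (TF, essential, house-keeping, ...)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def load_pairs(
    path: str | Path,
    target_class: TargetClass | str,
    min_support: int = 1,
    normalize: bool = True,
    strip_species_prefix: bool = True,
) -> list[RegulatoryPair]:
    """Read a TSV pair list and return merged, filtered, sorted pairs.

    Duplicate (regulator, target) rows are merged — sources unioned, support
    counts summed — and the ``min_support`` filter is applied *after*
    merging.  Rows without a support column count as one supporting
    experiment.  Output is sorted by (regulator, target), so the result is
    invariant under row permutation of the input file.
    """
    path = Path(path)
    target_class = TargetClass(target_class)
    merged: dict[tuple[str, str], tuple[set[str], int]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if not 2 <= len(fields) <= 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2-4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            reg, tgt = fields[0].strip(), fields[1].strip()
            if not reg or not tgt:
                raise ValueError(f"{path}: line {lineno}: empty regulator or target")
            if normalize:
                reg = normalize_mirna_id(reg, strip_species_prefix)
            src = fields[2].strip() if len(fields) >= 3 else ""
            if len(fields) == 4:
                try:
                    support = int(fields[3])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: support column is not an "
                        f"integer: {fields[3]!r}"
                    ) from None
            else:
                support = 1
            n_rows += 1
            sources, total = merged.setdefault((reg, tgt), (set(), 0))
            if src:
                sources.add(src)
            merged[(reg, tgt)] = (sources, total + support)
    if n_rows == 0:
        raise ValueError(f"{path}: empty pair file")
    return [
        RegulatoryPair(reg, tgt, target_class, frozenset(sources), support)
        for (reg, tgt), (sources, support) in sorted(merged.items())
        if support >= min_support
    ]


def load_gene_sets(paths: Sequence[str | Path]) -> dict[str, GeneSet]:
    """Read gene-set files into a name -> :class:`GeneSet` collection.

    A file whose rows carry two columns is read as (set-name, symbol);
    otherwise the file stem names a single set.  Duplicate symbols collapse;
    duplicate set names across files are an error.
    """
    sets: dict[str, set[str]] = {}
    for path in paths:
        path = Path(path)
        file_sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = [f.strip() for f in line.split("\t")]
                if len(fields) == 1:
                    file_sets.setdefault(path.stem, set()).add(fields[0])
                elif len(fields) == 2:
                    file_sets.setdefault(fields[0], set()).add(fields[1])
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 1 or 2 columns"
                    )
        if not file_sets:
            raise ValueError(f"empty gene-set file: {path}")
        for name, members in file_sets.items():
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} (file {path})")
            sets[name] = members
    return {name: GeneSet(name, frozenset(members)) for name, members in sets.items()}


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)


def write_report(records, path: str | Path, format: str = "tsv") -> None:
    """Write a result table deterministically (sorted by its first column).

    ``records`` may be a DataFrame, a list of dataclasses, or a list of
    dicts.  Repeated calls with the same input produce byte-identical files.
    An empty record list yields a header-only file (TSV) or ``[]`` (JSON).
    """
    frame = _to_frame(records)
    if len(frame) and len(frame.columns):
        frame = frame.sort_values(by=list(frame.columns)[0], kind="mergesort")
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        # frozensets/enums are not JSON types; stringify them
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            return str(o)

        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1, default=default)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_report`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown report format: {format!r}")


def write_edge_list(net, path: str | Path) -> None:
    """Serialize a bipartite network as a pair-list TSV (sorted)."""
    with open(Path(path), "w") as fh:
        for m, t in sorted(net.edges):
            fh.write(f"{m}\t{t}\n")


def read_expression(expr_path: str | Path, labels_path: str | Path,
                    reference: str | None = None, case: str | None = None):
    """Read an expression TSV plus a sample-label TSV into an ExpressionMatrix.

    Group names are taken from the label file; with exactly two groups the
    reference/case roles may be stated explicitly or default to the sorted
    order (first = reference).
    """
    from .de import ExpressionMatrix  # local import: de depends on numpy only

    frame = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels: dict[str, str] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2:
                raise ValueError(f"{labels_path}: line {lineno}: expected 2 columns")
            labels[fields[0]] = fields[1]
    groups = sorted(set(labels.values()))
    if reference is None or case is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly 2 groups, found {groups}")
        reference, case = groups
    return ExpressionMatrix.from_dataframe(frame, labels, reference=reference, case=case)


def write_expression(expr, expr_path: str | Path, labels_path: str | Path) -> None:
    """Write an ExpressionMatrix as expression + label TSVs."""
    expr.to_dataframe().to_csv(expr_path, sep="\t")
    with open(labels_path, "w") as fh:
        for sample in expr.sample_ids:
            fh.write(f"{sample}\t{expr.labels[sample]}\n")


# -- analysis configuration ------------------------------------------------

@dataclass
class Config:
    """Pipeline thresholds and switches (key=value file loadable)."""

    alpha_triplet: float = 0.01
    alpha_de: float = 0.05
    lfc: float = 1.0
    alpha_nsr: float = 0.05
    normalize_ids: bool = True
    strip_species_prefix: bool = True
    auc_orientation: str = "auto"  # auto | fixed
    universe: str = "union"  # union | intersection | <int>
    de_method: str = "welch"  # welch | moderated


def load_config(path: str | Path) -> Config:
    """Parse a ``key=value`` config file (unknown keys are an error)."""
    cfg = Config()
    valid = {f.name: f.type for f in dataclasses.fields(Config)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes", "on"))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            else:
                setattr(cfg, key, value)
    return cfg
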