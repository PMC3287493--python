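"""Drug-by-feature fact matrices and the merged ADR-class label vector.

The central exchange object is :class:`FactsMatrix`: drugs as rows, features
(protein targets or GO terms) as columns, non-negative integer cells. Built
directly from a drug-target relation the matrix is binary; network expansion
and GO aggregation turn cells into integer multiplicity weights.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ADRIcdMap, DrugADRMap, DrugTargetMap

logger = logging.getLogger(__name__)

_CATEGORY = re.compile(r"^[A-Z]\d{2}$")


@dataclass
class FactsMatrix:
    """Drug x feature integer matrix with ordered, unique row/column ids."""

    drug_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_kind: str = "target"  # "target" | "go_term"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if (self.values < 0).any():
            raise ValueError("negative cell values")

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids,
                            columns=self.feature_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "drug_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, feature_kind: str = "target") -> "FactsMatrix":
        df = pd.read_csv(path, sep="\t", index_col="drug_id")
        return cls(drug_ids=[str(d) for d in df.index],
                   feature_ids=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=np.int64),
                   feature_kind=feature_kind)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, FactsMatrix)
                and self.drug_ids == other.drug_ids
                and self.feature_ids == other.feature_ids
                and self.feature_kind == other.feature_kind
                and np.array_equal(self.values, other.values))


@dataclass
class ADRClassLabels:
    """Per-drug binary indicator of membership in one merged ADR class."""

    drug_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.drug_ids),):
            raise ValueError("labels length does not match drug_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"drug_id": self.drug_ids, "label": self.labels}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ADRClassLabels":
        df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "label": np.int64})
        return cls(drug_ids=list(df["drug_id"]), labels=df["label"].to_numpy())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ADRClassLabels)
                and self.drug_ids == other.drug_ids
                and np.array_equal(self.labels, other.labels))


def build_target_facts(targets: DrugTargetMap,
                       drug_universe: Sequence[str]) -> FactsMatrix:
    """Binary drug x target matrix over a fixed ordered drug universe.

    Columns are the union of targets of universe drugs, sorted lexically;
    cell (n, k) is 1 iff drug n docks target k. Pairs whose drug is outside
    the universe are ignored (logged); drugs without any target get an
    all-zero row.
    """
    if not len(drug_universe):
        raise ValueError("drug_universe must be non-empty")
    universe = list(drug_universe)
    uni_set = set(universe)
    kept = [(d, p) for d, p in targets.pairs if d in uni_set]
    skipped = len(targets.pairs) - len(kept)
    if skipped:
        logger.info("ignored %d drug-target pair(s) outside the drug universe",
                    skipped)
    features = sorted({p for _, p in kept})
    col = {p: j for j, p in enumerate(features)}
    row = {d: i for i, d in enumerate(universe)}
    values = np.zeros((len(universe), len(features)), dtype=np.int64)
    for d, p in kept:
        values[row[d], col[p]] = 1
    empty = int((values.sum(axis=1) == 0).sum())
    if empty:
        logger.info("%d drug(s) in the universe have no targets", empty)
    return FactsMatrix(universe, features, values, feature_kind="target")


def build_adr_class_labels(adrs: DrugADRMap, icd: ADRIcdMap,
                           code_range: tuple[str, str],
                           drug_universe: Sequence[str]) -> ADRClassLabels:
    """Merge all ADRs mapping into an ICD-10 category range into one label.

    A drug is labeled 1 iff at least one of its ADR names maps to an ICD-10
    code whose 3-character category falls in ``[low, high]`` (decimal
    sub-codes ignored; range entries like "I30-I52" use the lower bound).
    ADRs absent from the map contribute 0.
    """
    low, high = code_range
    if not (_CATEGORY.match(low) and _CATEGORY.match(high)
            and low[0] == high[0] and low <= high):
        raise ValueError(f"invalid ICD-10 category range {code_range!r}")
    labels = np.zeros(len(drug_universe), dtype=np.int64)
    by_drug: dict[str, set[str]] = {}
    for d, a in adrs.pairs:
        by_drug.setdefault(d, set()).add(a)
    for i, drug in enumerate(drug_universe):
        for adr in by_drug.get(drug, ()):
            cat = icd.category(adr)
            if cat is not None and low <= cat <= high:
                labels[i] = 1
                break
    return ADRClassLabels(list(drug_universe), labels)
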