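"""Fold-change differential calling and preactivated-set constructions.

Calling is purely threshold based: a gene is "up" in a contrast when the
difference of mean log2 expression between the two groups exceeds
log2(fold_threshold), strictly.  The preactivated construct is the
intersection of the stress-induced set in differentiated cells with the
set already up-regulated in de-differentiated cells at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "ContrastSpec",
    "mean_log_expression",
    "log2_fold_changes",
    "up_regulated_set",
    "differential_set",
    "preactivated_set",
    "uniquely_induced_set",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint sample groups and a linear fold-change threshold (>1)."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    fc_threshold: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if not self.group_a or not self.group_b:
            raise ValueError("both contrast groups must be non-empty")
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise ValueError(f"contrast groups overlap: {sorted(overlap)}")
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(self.group_b, self.group_a, self.fc_threshold)


def mean_log_expression(mat: ExpressionMatrix, group: Sequence[str]) -> pd.Series:
    """Arithmetic per-gene mean of log2 expression over the group's columns."""
    group = list(group)
    if not group:
        raise ValueError("sample group is empty")
    missing = [s for s in group if s not in mat.values.columns]
    if missing:
        raise KeyError(f"unknown sample ids: {missing}")
    return mat.values[group].mean(axis=1)


def log2_fold_changes(mat: ExpressionMatrix, contrast: ContrastSpec) -> pd.Series:
    """Per-gene log2 fold change: mean(group_a) − mean(group_b)."""
    return mean_log_expression(mat, contrast.group_a) - mean_log_expression(
        mat, contrast.group_b
    )


def up_regulated_set(
    mat: ExpressionMatrix, contrast: ContrastSpec, name: str = "up"
) -> GeneSet:
    """Genes whose mean log2 difference strictly exceeds log2(fc_threshold)."""
    fc = log2_fold_changes(mat, contrast)
    cut = np.log2(contrast.fc_threshold)
    members = frozenset(fc.index[fc > cut])
    return GeneSet(name=name, members=members)


def differential_set(
    mat: ExpressionMatrix, contrast: ContrastSpec, name: str = "differential"
) -> tuple[GeneSet, GeneSet]:
    """(up, down) at the same threshold; down is up with groups swapped."""
    up = up_regulated_set(mat, contrast, name=f"{name}_up")
    down = up_regulated_set(mat, contrast.swapped(), name=f"{name}_down")
    return up, down


def preactivated_set(
    ros_induced_in_differentiated: GeneSet,
    up_in_dedifferentiated: GeneSet,
    name: str = "preactivated",
) -> GeneSet:
    """Stress-inducible genes already up at baseline in de-differentiated cells.

    The exact intersection of the two input sets.
    """
    members = ros_induced_in_differentiated.members & up_in_dedifferentiated.members
    return GeneSet(name=name, members=members)


def uniquely_induced_set(
    induced_in_diff: GeneSet,
    induced_in_dediff: GeneSet,
    preactivated: GeneSet,
    name: str = "uniquely_induced",
) -> GeneSet:
    """Preactivated genes not induced by stress in de-differentiated cells.

    Requires preactivated ⊆ induced_in_diff (the preactivated construct is
    drawn from the differentiated cells' induced set).
    """
    stray = preactivated.members - induced_in_diff.members
    if stray:
        raise ValueError(
            "preactivated set is not a subset of the induced set in "
            f"differentiated cells; offending ids: {sorted(stray)[:10]}"
        )
    members = preactivated.members - induced_in_dediff.members
    return GeneSet(name=name, members=members)
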