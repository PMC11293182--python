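"""Clustering performance metrics: Adjusted Rand Index and rare-cell
detection accuracy, both implemented from first principles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = ["LabeledPartition", "adjusted_rand_index", "rare_accuracy"]


@dataclass
class LabeledPartition:
    """A per-cell assignment with optional ground truth and rare-type name."""

    labels: np.ndarray
    reference: Optional[np.ndarray] = None
    rare_type: Optional[object] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=object)
            if len(self.reference) != len(self.labels):
                raise ValueError("reference length does not match labels")
            if self.rare_type is not None and self.rare_type not in set(
                self.reference
            ):
                raise ValueError(
                    f"rare_type {self.rare_type!r} absent from reference"
                )

    @property
    def truth(self) -> np.ndarray:
        return self.reference if self.reference is not None else self.labels


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Standard permutation-model ARI from the contingency table:
    (sum_ij C(n_ij,2) - E) / (max - E) where E is the expected index under
    random pairing of the two marginals.  1 for identical partitions, ~0 for
    independent ones; invariant to relabeling and symmetric in (a, b).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("partitions must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    table = _contingency(a, b)
    sum_comb = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    n_pairs = _comb2(np.array(len(a)))
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial (all-singletons etc.)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def rare_accuracy(
    predicted: Sequence,
    truth: Union[LabeledPartition, Sequence],
    rare_type: Optional[object] = None,
    strict: bool = False,
) -> float:
    """Fraction of ground-truth rare cells correctly recognized.

    A rare cell counts as recognized iff the predicted cluster it belongs to
    has the rare type as the unique majority of its ground-truth composition
    (so pure rare clusters and rare-dominated mixed clusters score as hits,
    while rare cells absorbed into abundant clusters do not).  With
    ``strict=True`` the cell's cluster must consist exclusively of rare cells.
    """
    if isinstance(truth, LabeledPartition):
        if rare_type is None:
            rare_type = truth.rare_type
        truth_labels = truth.truth
    else:
        truth_labels = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted)
    if len(predicted) != len(truth_labels):
        raise ValueError("predicted and truth must have equal length")
    if rare_type is None:
        raise ValueError("rare_type must be given")

    is_rare = truth_labels == rare_type
    n_rare = int(is_rare.sum())
    if n_rare == 0:
        raise ValueError(f"no cells of rare type {rare_type!r} in truth")

    hits = 0
    for cluster in np.unique(predicted[is_rare]):
        members = predicted == cluster
        rare_in_cluster = int((members & is_rare).sum())
        if strict:
            ok = rare_in_cluster == int(members.sum())
        else:
            types, counts = np.unique(truth_labels[members], return_counts=True)
            top = counts.max()
            # unique majority: rare type strictly outnumbers every other type
            ok = (
                counts[types == rare_type][0] == top
                and (counts == top).sum() == 1
            )
        if ok:
            hits += rare_in_cluster
    return hits / n_rare
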