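"""Multi-model classification fusion: consensus, else posterior averaging.

Pixels where every model assigns the same class keep that class (consensus).
Elsewhere the per-model class-membership probability vectors are combined by
a weighted arithmetic mean — the model-averaging reading of posterior
integration — and the fused label is the argmax, ties broken by the lowest
class code.  Weights are equal by default, or proportional to supplied
overall accuracies, normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: method_flag values per pixel
CONSENSUS, AVERAGED = 0, 1


@dataclass
class ClassifierOutput:
    """One model's label grid plus per-class membership probabilities.

    ``probabilities`` is (n_classes, rows, cols) in ``class_codes`` order;
    per-pixel vectors must sum to 1 and labels must equal the per-pixel
    argmax (lowest code on ties).
    """

    labels: np.ndarray
    probabilities: np.ndarray
    class_codes: tuple[int, ...]
    model_id: str = ""
    overall_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.class_codes = tuple(int(c) for c in self.class_codes)
        k = len(self.class_codes)
        if self.probabilities.shape != (k,) + self.labels.shape:
            raise ValueError(
                f"probabilities shape {self.probabilities.shape} does not match "
                f"{k} classes over grid {self.labels.shape}"
            )
        sums = self.probabilities.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("per-pixel probabilities must sum to 1 (tol 1e-6)")
        argmax_code = _argmax_lowest_code(self.probabilities, self.class_codes)
        if not np.array_equal(argmax_code, self.labels):
            raise ValueError(f"labels of {self.model_id or 'model'} are not the probability argmax")


@dataclass
class FusionResult:
    """Fused labels with provenance: per-pixel method flag and tie count."""

    labels: np.ndarray
    probabilities: np.ndarray  # fused per-class stack, class_codes order
    method_flag: np.ndarray  # CONSENSUS / AVERAGED per pixel
    class_codes: tuple[int, ...]
    n_ties: int
    weights: tuple[float, ...]

    @property
    def consensus_fraction(self) -> float:
        return float((self.method_flag == CONSENSUS).mean())


def _argmax_lowest_code(probs: np.ndarray, class_codes: Sequence[int]) -> np.ndarray:
    """Argmax over the class axis, breaking exact ties by lowest class code."""
    order = np.argsort(class_codes, kind="stable")
    codes_sorted = np.asarray(class_codes)[order]
    # np.argmax returns the first max, i.e. the lowest code after sorting
    return codes_sorted[np.argmax(probs[order], axis=0)]


def fuse(
    outputs: Sequence[ClassifierOutput],
    weights: Sequence[float] | None = None,
) -> FusionResult:
    """Fuse co-registered classifier outputs.

    Parameters
    ----------
    outputs
        At least two co-registered models over the same class codes.
    weights
        Optional per-model weights; default is equal weighting unless every
        output carries an ``overall_accuracy``, in which case accuracies are
        used.  Weights are normalized to sum to 1.

    Returns
    -------
    FusionResult
        Consensus pixels keep the agreed label (method_flag CONSENSUS);
        others take the argmax of the weighted mean probability vector
        (method_flag AVERAGED), exact ties resolved to the lowest class code
        and counted in ``n_ties``.
    """
    if len(outputs) < 2:
        raise ValueError(f"need at least 2 classifier outputs, got {len(outputs)}")
    first = outputs[0]
    for o in outputs[1:]:
        if o.labels.shape != first.labels.shape:
            raise ValueError("classifier outputs are not co-registered (label shapes differ)")
        if o.class_codes != first.class_codes:
            raise ValueError("classifier outputs use different legends")

    if weights is None:
        accs = [o.overall_accuracy for o in outputs]
        weights = accs if all(a is not None for a in accs) else [1.0] * len(outputs)
    w = np.asarray(weights, dtype=np.float64)
    if w.size != len(outputs):
        raise ValueError(f"{w.size} weights for {len(outputs)} models")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    fused_probs = np.tensordot(w, np.stack([o.probabilities for o in outputs]), axes=(0, 0))

    label_stack = np.stack([o.labels for o in outputs])
    consensus = (label_stack == label_stack[0]).all(axis=0)

    averaged_labels = _argmax_lowest_code(fused_probs, first.class_codes)
    labels = np.where(consensus, first.labels, averaged_labels)
    method_flag = np.where(consensus, CONSENSUS, AVERAGED).astype(np.uint8)

    pmax = fused_probs.max(axis=0)
    tied = ((fused_probs == pmax).sum(axis=0) > 1) & ~consensus
    return FusionResult(
        labels=labels,
        probabilities=fused_probs,
        method_flag=method_flag,
        class_codes=first.class_codes,
        n_ties=int(tied.sum()),
        weights=tuple(float(x) for x in w),
    )
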