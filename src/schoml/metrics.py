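"""External clustering indices for benchmarking against ground truth."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score


def _check_pair(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth).ravel()
    predicted = np.asarray(predicted).ravel()
    if truth.shape != predicted.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape[0]} vs {predicted.shape[0]}"
        )
    if truth.size == 0:
        raise ValueError("empty label vectors")
    return truth, predicted


def ari(truth, predicted) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement.

    1 for identical partitions (up to relabeling); ~0 for random labelings.
    """
    truth, predicted = _check_pair(truth, predicted)
    return float(adjusted_rand_score(truth, predicted))


def nmi(truth, predicted, average_method: str = "arithmetic") -> float:
    """Normalized mutual information, in [0, 1].

    ``average_method`` chooses the entropy normalization
    ({"arithmetic", "geometric", "min", "max"}); arithmetic is the default.
    """
    truth, predicted = _check_pair(truth, predicted)
    return float(
        normalized_mutual_info_score(truth, predicted, average_method=average_method)
    )
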