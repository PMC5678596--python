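"""Small validation metrics: mask overlap and area error."""

from __future__ import annotations

import numpy as np

__all__ = ["dice", "mape"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / float(denom)


def mape(estimate, truth) -> float:
    """Mean absolute percentage error of estimates against ground truth (%)."""
    est = np.asarray(estimate, dtype=np.float64).ravel()
    tru = np.asarray(truth, dtype=np.float64).ravel()
    if est.shape != tru.shape:
        raise ValueError("estimate and truth differ in length")
    if (tru == 0).any():
        raise ValueError("ground truth contains zeros")
    return float(np.mean(np.abs(est - tru) / np.abs(tru)) * 100.0)
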