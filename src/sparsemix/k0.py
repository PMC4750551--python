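"""Estimating the number of mixture components from occupancy traces.

Each retained sweep contributes the count ``K0 = K - #{k : N_k = 0}`` of
non-empty components; the relative frequencies of these counts estimate
``Pr(K0 = h | y)`` for ``h = 1..K``, and the posterior mode is the point
estimate of the number of data clusters.  The full distribution is always
reported: it is typically right-skewed, which makes mean-type estimators
unstable, whereas the mode is indifferent to the degree of overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .sampler import Trace

__all__ = ["K0Posterior", "count_nonempty", "k0_posterior"]


@dataclass
class K0Posterior:
    """Histogram of the per-sweep non-empty component counts."""

    counts: Dict[int, int]
    mode: int
    M0: int

    def as_probabilities(self) -> Dict[int, float]:
        total = sum(self.counts.values())
        return {h: c / total for h, c in sorted(self.counts.items())}


def count_nonempty(Nk: np.ndarray) -> int:
    """K minus the number of empty components in one sweep."""
    Nk = np.asarray(Nk)
    if np.any(Nk < 0):
        raise ValueError("occupancy counts must be non-negative")
    return int(Nk.shape[0] - np.sum(Nk == 0))


def k0_posterior(trace: Trace) -> K0Posterior:
    """Posterior of K0 from the trace; ties broken toward the smaller count
    (parsimony)."""
    values, freq = np.unique(np.asarray(trace.K0), return_counts=True)
    best = int(values[np.argmax(freq)])  # np.argmax takes the first (smallest) tie
    counts = {int(v): int(c) for v, c in zip(values, freq)}
    return K0Posterior(counts=counts, mode=best, M0=counts[best])
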