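"""Temporary removal of highly correlated variables before canonical analysis.

Canonical correlation needs well-conditioned within-block covariance, so
variables correlated above a threshold (|r| > 0.7 by default) are removed in
a single greedy pass over the input feature order, each recording the
retained representative it is correlated with. Removal is temporary in the
sense that the report lets downstream ranking re-attach removed genes to
their representatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import OmicsBlock

__all__ = ["FilterReport", "prefilter_correlated", "CONSTANT_SENTINEL"]

CONSTANT_SENTINEL = "constant"


@dataclass
class FilterReport:
    """Outcome of a correlation prefilter pass.

    ``removed`` maps each removed feature to ``(representative, r)`` where
    ``r`` is the Pearson correlation with the retained representative of
    largest |r| (NaN with the ``"constant"`` sentinel for zero-variance
    features). ``retained`` preserves input order.
    """

    removed: dict[str, tuple[str, float]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)
    threshold: float = 0.7

    def to_rows(self) -> list[tuple[str, str, float]]:
        return [(f, rep, r) for f, (rep, r) in self.removed.items()]


def prefilter_correlated(
    block: OmicsBlock,
    threshold: float = 0.7,
    scope_features: list[str] | None = None,
) -> tuple[OmicsBlock, FilterReport]:
    """Greedily drop features whose |Pearson r| with an already-retained
    feature exceeds ``threshold``.

    The pass runs in input feature order (first-wins): a feature is retained
    unless its absolute correlation with some retained feature exceeds the
    threshold, in which case its representative is the retained feature of
    largest |r|. Zero-variance features are removed with the ``"constant"``
    sentinel and an undefined (NaN) correlation, with a warning.

    With ``scope_features`` the pass only considers that subset (in block
    order); other features are excluded from the output entirely.
    """
    if block.n_samples < 3:
        raise ValueError("prefilter needs at least 3 samples")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if scope_features is not None:
        scope = set(scope_features)
        order = [f for f in block.feature_ids if f in scope]
        work = block.subset(order)
    else:
        work = block
    X = work.values
    sd = X.std(axis=0, ddof=1)
    retained_idx: list[int] = []
    removed: dict[str, tuple[str, float]] = {}
    for j, fid in enumerate(work.feature_ids):
        if sd[j] == 0.0 or not math.isfinite(sd[j]):
            warnings.warn(
                f"feature {fid!r} has zero variance; removed", stacklevel=2
            )
            removed[fid] = (CONSTANT_SENTINEL, float("nan"))
            continue
        best_r, best_rep = 0.0, None
        xj = X[:, j]
        for i in retained_idx:
            r = float(np.corrcoef(xj, X[:, i])[0, 1])
            if abs(r) > abs(best_r):
                best_r, best_rep = r, work.feature_ids[i]
        if best_rep is not None and abs(best_r) > threshold:
            removed[fid] = (best_rep, best_r)
        else:
            retained_idx.append(j)
    retained_ids = [work.feature_ids[i] for i in retained_idx]
    reduced = OmicsBlock(
        list(work.sample_ids), retained_ids, X[:, retained_idx].copy()
    )
    report = FilterReport(removed=removed, retained=retained_ids, threshold=threshold)
    return reduced, report
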