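"""Randomized-group null: is a functional group better than a random one?

A functional group's statistic (CCA aggregate redundancy or PLS LV1
explained variance) is compared against groups of the same gene/metabolite
proportions drawn uniformly at random from the measured feature pools. The
resampling is repeated B times (1000 by default) and the observed value is
compared with the null sample by a one-sample t-test of the null values
against the observed value as hypothesized mean, plus an empirical upper
percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import OmicsBlock
from .multivariate import compute_cca, compute_pls, redundancy_index
from .prefilter import prefilter_correlated
from .prior_grouping import FunctionalGroup

__all__ = ["NullDistribution", "randomized_group_null", "null_significance", "STATISTICS"]

STATISTICS = (
    "cca_redundancy_y_given_x",
    "cca_redundancy_x_given_y",
    "pls_explained_variance_lv1",
)

DEFAULT_B = 1000


@dataclass
class NullDistribution:
    """Null sample for one group/statistic with its significance summary."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    B: int
    t_p_value: float
    empirical_p: float
    seed: int

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)) if self.B > 1 else 0.0,
            "t_p_value": self.t_p_value,
            "empirical_p": self.empirical_p,
            "B": self.B,
            "seed": self.seed,
        }


def _group_statistic(
    X: OmicsBlock,
    Y: OmicsBlock,
    statistic: str,
    threshold: float,
    min_y: int = 2,
) -> float:
    """Prefilter both blocks and evaluate the requested statistic.

    ``min_y`` is 2 for resampled replicates (the redraw rule) but 1 for the
    observed group: a group whose collinear metabolites collapse to a single
    retained column is still analyzable (q = 1).
    """
    Xr, _ = prefilter_correlated(X, threshold)
    Yr, _ = prefilter_correlated(Y, threshold)
    if Xr.n_features < 2 or Yr.n_features < min_y:
        raise ValueError("too few retained features on one side")
    if statistic in ("cca_redundancy_y_given_x", "cca_redundancy_x_given_y"):
        res = compute_cca(Xr.values, Yr.values)
        direction = statistic.removeprefix("cca_redundancy_")
        return redundancy_index(res, direction)
    if statistic == "pls_explained_variance_lv1":
        res = compute_pls(Xr.values, Yr.values, n_components=1, mode="canonical")
        return float(res.explained_variance_x[0])
    raise ValueError(f"unknown statistic {statistic!r}")


def randomized_group_null(
    X_all: OmicsBlock,
    Y_all: OmicsBlock,
    group: FunctionalGroup,
    statistic: str = "cca_redundancy_y_given_x",
    B: int = DEFAULT_B,
    seed: int = 0,
    threshold: float = 0.7,
) -> NullDistribution:
    """Draw B random groups of the same size and collect the statistic.

    Each replicate samples ``|group genes|`` genes and ``|group
    metabolites|`` metabolites without replacement from the full measured
    pools, applies the same correlation prefilter, and evaluates the
    statistic; the observed value is computed identically on the actual
    group. A replicate whose retained counts fall below 2 on either side is
    redrawn (up to 10*B redraws in total, then an error). Reproducible given
    ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    genes = sorted(set(group.gene_ids) & set(X_all.feature_ids))
    mets = sorted(set(group.metabolite_ids) & set(Y_all.feature_ids))
    n_genes, n_mets = len(genes), len(mets)
    if n_genes > X_all.n_features or n_mets > Y_all.n_features:
        raise ValueError("group larger than the measured pools")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = _group_statistic(
            X_all.subset(genes), Y_all.subset(mets), statistic, threshold, min_y=1
        )
    rng = np.random.default_rng(seed)
    gene_pool = np.array(X_all.feature_ids)
    met_pool = np.array(Y_all.feature_ids)
    null_values = np.empty(B)
    draws = 0
    i = 0
    while i < B:
        if draws >= 10 * B:
            raise RuntimeError(
                "redraw cap exceeded: random groups keep collapsing under the prefilter"
            )
        draws += 1
        gsel = sorted(rng.choice(gene_pool, size=n_genes, replace=False))
        msel = sorted(rng.choice(met_pool, size=n_mets, replace=False))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                null_values[i] = _group_statistic(
                    X_all.subset(gsel), Y_all.subset(msel), statistic, threshold
                )
        except (ValueError, np.linalg.LinAlgError):
            continue
        i += 1
    dist = NullDistribution(
        statistic_name=statistic,
        observed=float(observed),
        null_values=null_values,
        B=B,
        t_p_value=np.nan,
        empirical_p=np.nan,
        seed=seed,
    )
    dist.t_p_value, dist.empirical_p = null_significance(dist)
    return dist


def null_significance(dist: NullDistribution) -> tuple[float, float]:
    """Two-sided one-sample t-test of the null values against the observed
    value as hypothesized mean, plus the empirical upper percentile
    (1 + #{null >= observed}) / (B + 1).

    A degenerate null (sd = 0) has no t statistic: the t p-value is 1 if the
    observed equals the constant and 0 otherwise, with a warning.
    """
    if dist.B < 2:
        raise ValueError("need B >= 2")
    null = np.asarray(dist.null_values, dtype=float)
    empirical_p = float((1 + np.sum(null >= dist.observed)) / (dist.B + 1))
    sd = float(np.std(null, ddof=1))
    if sd == 0.0:
        warnings.warn("null distribution is constant; t-test undefined", stacklevel=2)
        t_p = 1.0 if float(null[0]) == dist.observed else 0.0
    else:
        t_p = float(stats.ttest_1samp(null, popmean=dist.observed).pvalue)
    return t_p, empirical_p
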