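"""Count normalization and per-gene IQR outlier statistics.

Normalization is the median-of-ratios scheme: each donor's size factor is the
median, over genes expressed in every donor, of the ratio of that donor's
count to the gene's geometric-mean count across donors. Only this
normalization step of the negative-binomial differential-expression framework
is reproduced; dispersion estimation and Wald testing are out of scope.

Expression deviations are measured per gene in units of the interquartile
range across the donor scope: ``(value - median) / IQR``. A donor is a
*primary* outlier for a gene when its absolute deviation exceeds
``k_primary`` (default 2) IQR and its normalized expression exceeds
``min_norm_expr`` (default 10); the *recurrence* threshold is the same test
at ``k_recurrence`` (default 1) IQR. All inequalities are strict.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    """No reference gene with strictly positive counts in every donor."""


@dataclass
class CountMatrix:
    """Raw integer counts, genes x donors, with unique IDs on both axes."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene IDs: {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated donor IDs: {dup}")
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Counts divided elementwise per donor column by that donor's size factor."""

    values: pd.DataFrame
    size_factors: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.values.columns)


def median_of_ratios(cm: CountMatrix) -> NormalizedMatrix:
    """Median-of-ratios size factors and the normalized matrix.

    Reference genes are those with strictly positive counts in all donors;
    all genes (including all-zero ones) appear in the normalized output.
    A single-donor matrix gets size factor 1.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] == 1:
        sf = pd.Series([1.0], index=counts.columns)
        return NormalizedMatrix(values=counts.copy(), size_factors=sf)

    positive = (counts.values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene with strictly positive counts in every donor; "
            "median-of-ratios reference set is empty (pseudo-reference "
            "fallback is not enabled)"
        )
    ref = counts.values[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    # ratio of each donor's count to the per-gene geometric mean
    log_ratios = np.log(ref) - log_geomean[:, None]
    sf = pd.Series(np.exp(np.median(log_ratios, axis=0)), index=counts.columns)
    values = counts / sf
    return NormalizedMatrix(values=values, size_factors=sf)


def gene_stats(norm: NormalizedMatrix, donor_scope: Iterable[str]) -> pd.DataFrame:
    """Per-gene median and IQR of normalized expression over a donor scope.

    Quantiles use linear interpolation between closest order statistics.
    Returns a frame indexed by gene with columns ``median``, ``iqr``,
    ``n_donors_used``.
    """
    scope = list(dict.fromkeys(donor_scope))
    missing = set(scope) - set(norm.values.columns)
    if missing:
        raise ValueError(f"donor scope not in matrix: {sorted(missing)}")
    if len(scope) < 4:
        raise ValueError(f"donor scope must contain >= 4 donors, got {len(scope)}")
    sub = norm.values[scope].values
    q1, med, q3 = np.percentile(sub, [25, 50, 75], axis=1, method="linear")
    return pd.DataFrame(
        {"median": med, "iqr": q3 - q1, "n_donors_used": len(scope)},
        index=pd.Index(norm.values.index, name="gene_id"),
    )


def call_outliers(
    norm: NormalizedMatrix,
    stats: pd.DataFrame,
    k_primary: float = 2.0,
    k_recurrence: float = 1.0,
    min_norm_expr: float = 10.0,
    donor_scope: Iterable[str] | None = None,
    directional: bool = False,
) -> pd.DataFrame:
    """Score every (gene, donor) pair against the IQR thresholds.

    ``deviation_iqr`` is signed. With a zero IQR the deviation is ±inf when
    the value differs from the median and 0 when it equals it. With
    ``directional=True`` only upward deviations count.

    Returns a long-format frame with columns gene_id, donor_id,
    normalized_value, deviation_iqr, passes_primary, passes_recurrence.
    """
    if k_primary < k_recurrence:
        raise ValueError("k_primary must be >= k_recurrence")
    donors = (
        list(dict.fromkeys(donor_scope)) if donor_scope is not None
        else list(norm.values.columns)
    )
    genes = stats.index
    values = norm.values.loc[genes, donors].values
    med = stats["median"].values[:, None]
    iqr = stats["iqr"].values[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (values - med) / iqr
    dev = np.where((iqr == 0) & (values == med), 0.0, dev)

    magnitude = dev if directional else np.abs(dev)
    expressed = values > min_norm_expr
    primary = (magnitude > k_primary) & expressed
    recurrence = (magnitude > k_recurrence) & expressed

    gene_idx, donor_idx = np.meshgrid(
        np.arange(len(genes)), np.arange(len(donors)), indexing="ij"
    )
    return pd.DataFrame(
        {
            "gene_id": np.asarray(genes)[gene_idx.ravel()],
            "donor_id": np.asarray(donors)[donor_idx.ravel()],
            "normalized_value": values.ravel(),
            "deviation_iqr": dev.ravel(),
            "passes_primary": primary.ravel(),
            "passes_recurrence": recurrence.ravel(),
        }
    )
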