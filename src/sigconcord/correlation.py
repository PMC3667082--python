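"""Correlation of per-sample fold-change profiles against inducer profiles,
and mean |log2 FC| summaries of gene sets per sample group.

The "expression signature of a sample" is its per-sample log2 fold-change
vector against a reference-group mean, and an inducer profile is the
induced-vs-control mean log2 fold change.  Pearson correlations between the
two, computed over the genes shared by both datasets, quantify how closely
each tumor sample recapitulates each induced program; group-wise averages
summarize the grid per subtype and per inducer.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "correlate_profiles",
    "GroupedCorrelation",
    "group_average",
    "mean_absfc_summary",
]


def correlate_profiles(fc_samples: pd.DataFrame, fc_inducers: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every sample profile and every inducer profile.

    Correlations are computed over the intersection of the two gene sets
    (at least 3 genes).  A zero-variance profile has no defined correlation
    and is an error.
    """
    shared = fc_samples.index.intersection(fc_inducers.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    a = fc_samples.loc[shared].to_numpy(dtype=float)
    b = fc_inducers.loc[shared].to_numpy(dtype=float)
    for mat, frame in ((a, fc_samples), (b, fc_inducers)):
        sd = mat.std(axis=0)
        if (sd == 0).any():
            name = frame.columns[int(np.argmax(sd == 0))]
            raise ValueError(f"profile {name!r} has zero variance over the shared genes")
    az = (a - a.mean(axis=0)) / a.std(axis=0)
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    grid = az.T @ bz / len(shared)
    return pd.DataFrame(grid, index=fc_samples.columns, columns=fc_inducers.columns)


@dataclass
class GroupedCorrelation:
    """Group-wise averages of a sample x inducer correlation grid."""

    by_pair: pd.DataFrame  # sample-group x inducer-group mean r
    by_sample_group: pd.Series  # mean over all inducers
    by_inducer_group: pd.Series  # mean over all samples


def _as_series(groups: Mapping[str, str] | pd.Series, axis_values: pd.Index, what: str) -> pd.Series:
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = axis_values.difference(groups.index)
    if len(missing):
        raise ValueError(f"{what} groups do not cover: {missing.tolist()[:5]}")
    groups = groups.loc[axis_values]
    counts = groups.value_counts()
    if (counts == 0).any():
        raise ValueError(f"empty {what} group")
    return groups


def group_average(
    grid: pd.DataFrame,
    sample_groups: Mapping[str, str] | pd.Series,
    inducer_groups: Mapping[str, str] | pd.Series | None = None,
) -> GroupedCorrelation:
    """Average a correlation grid within sample groups (and, optionally,
    inducer groups; by default each inducer is its own group)."""
    sg = _as_series(sample_groups, grid.index, "sample")
    if inducer_groups is None:
        ig = pd.Series(grid.columns, index=grid.columns)
    else:
        ig = _as_series(inducer_groups, grid.columns, "inducer")
    by_pair = grid.groupby(sg, observed=True).mean().T.groupby(ig, observed=True).mean().T
    by_sample_group = grid.groupby(sg, observed=True).mean().mean(axis=1)
    by_inducer_group = grid.T.groupby(ig, observed=True).mean().mean(axis=1)
    return GroupedCorrelation(
        by_pair=by_pair,
        by_sample_group=by_sample_group,
        by_inducer_group=by_inducer_group,
    )


def mean_absfc_summary(
    fc: pd.DataFrame,
    gene_set: Iterable[str],
    sample_groups: Mapping[str, str] | pd.Series,
    *,
    signed: bool = False,
) -> pd.Series:
    """Per-group mean log2 fold change over a gene set.

    The mean is taken over all (gene, sample) cells of ``gene_set`` x group
    samples.  By default the absolute value of that signed mean is returned
    — the display convention for down-regulated sets, whose magnitude is of
    interest; pass ``signed=True`` for the raw mean.
    """
    genes = fc.index.intersection(pd.Index(list(gene_set)))
    if len(genes) == 0:
        raise ValueError("gene_set does not intersect the fold-change matrix")
    sg = _as_series(sample_groups, fc.columns, "sample")
    means = fc.loc[genes].T.groupby(sg, observed=True).mean().mean(axis=1)
    means.name = "mean_log2fc"
    return means.abs() if not signed else means
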