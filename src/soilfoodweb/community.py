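"""Amplicon community metrics: rarefaction, Bray-Curtis, phylum profiles.

The pipeline starts from an OTU count table (rows = samples, columns =
OTUs) with a phylum-level taxonomy; upstream read QC, clustering and
taxonomy assignment are out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def _check_counts(table: pd.DataFrame) -> np.ndarray:
    arr = table.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative entries in OTU table")
    return arr


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Multivariate-hypergeometric (urn) subsampling, the standard
    rarefaction model.  Samples with fewer than ``depth`` total reads are
    dropped with a warning; deterministic for a given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    arr = _check_counts(table).astype(np.int64)
    totals = arr.sum(axis=1)
    keep = totals >= depth
    dropped = table.index[~keep].tolist()
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    rows = [rng.multivariate_hypergeometric(row, depth) for row in arr[keep]]
    return pd.DataFrame(
        np.array(rows), index=table.index[keep], columns=table.columns
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  Zero-total samples have
    undefined dissimilarities and get NaN rows/columns with a warning.
    """
    arr = _check_counts(table).astype(float)
    totals = arr.sum(axis=1)
    ok = totals > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 samples with positive totals")
    if (~ok).any():
        warnings.warn(
            f"zero-total sample(s) {table.index[~ok].tolist()}: "
            "dissimilarities undefined"
        )
    D = np.full((len(table), len(table)), np.nan)
    sub = squareform(pdist(arr[ok], metric="braycurtis"))
    ix = np.where(ok)[0]
    D[np.ix_(ix, ix)] = sub
    np.fill_diagonal(D, np.where(ok, 0.0, np.nan))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def phylum_relative_abundance(
    table: pd.DataFrame, taxonomy: pd.Series
) -> pd.DataFrame:
    """Per-sample phylum proportions (rows sum to 1).

    ``taxonomy`` maps every OTU column to a phylum label (use an explicit
    label such as 'Unclassified' for unassigned OTUs).
    """
    _check_counts(table)
    missing = [o for o in table.columns if o not in taxonomy.index]
    if missing:
        raise ValueError(f"taxonomy missing for OTUs: {missing[:10]}")
    phyla = taxonomy.loc[table.columns]
    agg = table.T.groupby(phyla.values).sum().T
    totals = agg.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = agg.div(totals, axis=0)
    return out
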