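"""Community responses: Shannon diversity and per-effort abundance.

Count tables are long-format DataFrames with columns
``site_id, taxon, session, count`` (non-negative integers).  Counts are
pooled across sessions and life stages before computing responses, so each
site contributes a single value per response.

Two response families are produced:

* ``shannon`` — the Shannon index H = -sum p_i ln p_i over the taxon
  proportions at a site (natural log).
* ``abundance:<taxon>`` — total individuals of a taxon at a site divided by
  the site's sampling effort (number of larval habitats plus CO2-baited
  traps over all sessions).

Rare taxa carry too few individuals per site for stable regressions; the
common-taxa filter keeps the shortest prefix of taxa, in decreasing order of
total abundance, whose cumulative share of all individuals reaches a
threshold (default 97%).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError, UndefinedResponseError

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["site_id", "taxon", "session", "count"]


def validate_counts(df: pd.DataFrame, source: str = "counts") -> pd.DataFrame:
    """Validate a long-format count table and coerce dtypes."""
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing columns {missing}")
    df = df.copy()
    for col in ("site_id", "taxon", "session"):
        df[col] = df[col].astype(str)
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        bad = df.index[counts.isna()][0]
        raise ParseError(f"{source}: non-numeric count at row {bad}")
    if (counts < 0).any() or (counts != counts.round()).any():
        raise ParseError(f"{source}: counts must be non-negative integers")
    df["count"] = counts.astype(int)
    return df[COUNT_COLUMNS].reset_index(drop=True)


def read_counts(path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path), source=str(path))


def site_taxon_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Site x taxon matrix of counts pooled over sessions."""
    return counts.pivot_table(
        index="site_id", columns="taxon", values="count", aggfunc="sum", fill_value=0
    )


def shannon_index(counts: Mapping[str, int] | pd.Series | Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i of one site's taxon totals.

    Zero-count taxa contribute nothing; all-zero input raises
    :class:`UndefinedResponseError` (proportions are undefined).
    """
    if isinstance(counts, Mapping):
        vals = np.asarray(list(counts.values()), dtype=float)
    else:
        vals = np.asarray(counts, dtype=float)
    if vals.size == 0 or (vals < 0).any():
        raise InvalidArgumentError("counts must be a non-empty set of values >= 0")
    total = vals.sum()
    if total == 0:
        raise UndefinedResponseError("Shannon index undefined for all-zero counts")
    p = vals[vals > 0] / total
    return float(-(p * np.log(p)).sum())


def abundance_rate(count_total: float, effort: float) -> float:
    """Total individuals divided by sampling effort (effort >= 1)."""
    if effort < 1:
        raise InvalidArgumentError(f"effort must be >= 1, got {effort}")
    if count_total < 0:
        raise InvalidArgumentError("count must be non-negative")
    return float(count_total) / float(effort)


def shannon_response(counts: pd.DataFrame) -> pd.Series:
    """Per-site Shannon index; sites with all-zero counts are dropped.

    Dropped sites are logged as warnings so a pipeline run records them.
    """
    totals = site_taxon_totals(counts)
    values = {}
    for site, row in totals.iterrows():
        try:
            values[site] = shannon_index(row)
        except UndefinedResponseError:
            logger.warning("site %s has no individuals; excluded from shannon", site)
    return pd.Series(values, name="shannon", dtype=float)


def abundance_response(
    counts: pd.DataFrame, sites: pd.DataFrame, taxon: str
) -> pd.Series:
    """Per-site abundance of one taxon: pooled count / sampling effort."""
    totals = site_taxon_totals(counts)
    effort = sites.set_index("site_id")["effort"]
    if taxon in totals.columns:
        taxon_totals = totals[taxon]
    else:
        taxon_totals = pd.Series(0, index=totals.index)
    vals = {
        site: abundance_rate(taxon_totals.get(site, 0), effort[site])
        for site in effort.index
    }
    return pd.Series(vals, name=f"abundance:{taxon}", dtype=float)


def filter_common_taxa(counts: pd.DataFrame, min_fraction: float = 0.97) -> list[str]:
    """Shortest decreasing-abundance prefix reaching ``min_fraction`` of individuals.

    Taxa are ordered by decreasing total count with ties broken
    alphabetically, so the result is deterministic.
    """
    if not 0 < min_fraction <= 1:
        raise InvalidArgumentError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if counts.empty:
        raise InvalidArgumentError("count table is empty")
    totals = counts.groupby("taxon")["count"].sum()
    totals = totals[totals > 0]
    if totals.empty:
        raise InvalidArgumentError("count table holds no individuals")
    order = totals.sort_index().sort_values(ascending=False, kind="stable")
    cum = order.cumsum() / order.sum()
    n_keep = int(np.searchsorted(cum.values, min_fraction - 1e-12)) + 1
    return list(order.index[:n_keep])


def subset_sessions(counts: pd.DataFrame, keep: Iterable[str]) -> pd.DataFrame:
    """Restrict the count table to a subset of sampling sessions.

    An empty subset is an error: it would silently produce all-zero
    responses downstream.
    """
    keep = list(dict.fromkeys(str(s) for s in keep))
    if not keep:
        raise InvalidArgumentError("session subset must not be empty")
    known = set(counts["session"].unique())
    unknown = [s for s in keep if s not in known]
    if unknown:
        raise InvalidArgumentError(
            f"unknown session label(s) {unknown}; table has {sorted(known)}"
        )
    return counts[counts["session"].isin(keep)].reset_index(drop=True)


def mean_per_site(counts: pd.DataFrame) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of per-site total counts."""
    totals = counts.groupby("site_id")["count"].sum()
    if len(totals) < 2:
        raise InvalidArgumentError("need at least 2 sites for a mean +/- SD")
    return float(totals.mean()), float(totals.std(ddof=1))
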