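"""Normalisation, rarefaction, rank aggregation and alpha diversity for taxon tables."""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import AbundanceTable, DiversityResult, taxon_at_rank

__all__ = [
    "to_relative",
    "rarefy",
    "aggregate_rank",
    "shannon",
    "alpha_diversity",
    "top_n_summary",
    "group_mean_table",
    "diversity_group_test",
]


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to relative abundances (columns sum to 1).

    A proportions-mode table is returned unchanged (idempotent). An
    all-zero sample cannot be normalised and is a hard error.
    """
    if table.mode == "proportions":
        return table
    sums = table.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s) cannot be normalised: {list(zero.index)}")
    return AbundanceTable(
        values=table.values.div(sums, axis=1),
        metadata=table.metadata,
        mode="proportions",
    )


def rarefy(
    table: AbundanceTable,
    depth: Union[int, str] = "min",
    seed: int = 0,
) -> AbundanceTable:
    """Subsample each sample's counts to a common depth, without replacement.

    ``depth="min"`` uses the smallest column sum (every sample kept). The
    draw is a multivariate hypergeometric per sample — the standard
    rarefaction model — and is deterministic for a given seed. A depth
    exceeding any column total is a hard error rather than a silent
    sample drop.
    """
    if table.mode != "counts":
        raise ValueError("rarefaction requires a counts-mode table")
    counts = table.values.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    col_sums = counts.sum(axis=0)
    if depth == "min":
        depth_i = int(col_sums.min())
    else:
        depth_i = int(depth)
    if depth_i < 1:
        raise ValueError(f"depth must be >= 1, got {depth_i}")
    too_shallow = [
        s for s, tot in zip(table.values.columns, col_sums) if tot < depth_i
    ]
    if too_shallow:
        raise ValueError(
            f"depth {depth_i} exceeds total counts of sample(s): {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth_i)
    return AbundanceTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        metadata=table.metadata,
        mode="counts",
    )


def aggregate_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxon rows within the named rank (``phylum`` or ``genus``).

    Taxa whose identifier does not carry the requested rank prefix are
    pooled into an ``unclassified`` row so column sums are conserved
    (compositional closure); dropping them would silently destroy mass.
    """
    groups: dict[str, list[str]] = {}
    n_matched = 0
    for taxon in table.values.index:
        name = taxon_at_rank(taxon, rank)
        if name is not None:
            groups.setdefault(name, []).append(taxon)
            n_matched += 1
        else:
            groups.setdefault("unclassified", []).append(taxon)
    if n_matched == 0:
        raise ValueError(f"no taxon identifier carries rank {rank!r}")
    rows = {name: table.values.loc[members].sum(axis=0) for name, members in groups.items()}
    agg = pd.DataFrame(rows).T.loc[list(groups)]
    if "unclassified" in agg.index and float(agg.loc["unclassified"].sum()) == 0.0:
        agg = agg.drop(index="unclassified")
    return AbundanceTable(values=agg, metadata=table.metadata, mode=table.mode)


def shannon(counts_or_props: Iterable[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log) of one sample.

    Scale-invariant: raw counts and proportions give the same value
    because the vector is normalised first. Zeros contribute nothing;
    an all-zero vector is a hard error.
    """
    v = np.asarray(list(counts_or_props), dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an all-zero vector")
    # scipy normalises and uses natural log by default
    return float(stats.entropy(v))


def alpha_diversity(table: AbundanceTable) -> list[DiversityResult]:
    """Shannon index and richness for every sample in the table."""
    out = []
    for s in table.values.columns:
        col = table.values[s].to_numpy(dtype=float)
        out.append(
            DiversityResult(
                sample_id=str(s),
                shannon=shannon(col),
                richness=int((col > 0).sum()),
            )
        )
    return out


def group_mean_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-group mean abundance (equal sample weights), ordered by concentrate fraction.

    Returns a taxa x group DataFrame; the column order follows increasing
    concentrate fraction. Attaches each group's fraction via ``.attrs['fractions']``.
    """
    labels = table.group_labels()
    fracs = table.fractions()
    group_frac = (
        pd.DataFrame({"g": labels.values, "x": fracs.values})
        .groupby("g")["x"].mean().sort_values()
    )
    cols = {}
    for g in group_frac.index:
        members = [s for s, lab in labels.items() if lab == g]
        cols[g] = table.values[members].mean(axis=1)
    out = pd.DataFrame(cols)
    out.attrs["fractions"] = group_frac.to_dict()
    return out


def top_n_summary(table: AbundanceTable, n: int) -> pd.DataFrame:
    """The n most abundant taxa (by overall mean proportion) with per-group means.

    Remaining taxa are pooled into an ``Other`` row so each group column
    still sums to 1. Requires a proportions-mode table.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if table.mode != "proportions":
        raise ValueError("top_n_summary requires a proportions-mode table")
    overall = table.values.mean(axis=1).sort_values(ascending=False, kind="stable")
    top = list(overall.index[:n])
    rest = list(overall.index[n:])
    means = group_mean_table(table)
    summary = means.loc[top]
    if rest:
        summary.loc["Other"] = means.loc[rest].sum(axis=0)
    else:
        summary.loc["Other"] = 0.0
    summary.attrs["fractions"] = means.attrs["fractions"]
    return summary


def diversity_group_test(table: AbundanceTable) -> dict[str, float]:
    """Kruskal-Wallis test of Shannon diversity across diet groups.

    A thin convenience around the routine group comparison; returns the H
    statistic and p-value. Needs >= 2 groups with >= 1 sample each.
    """
    div = {d.sample_id: d.shannon for d in alpha_diversity(table)}
    labels = table.group_labels()
    groups = [
        [div[s] for s in labels.index[labels == g]]
        for g in pd.unique(labels)
    ]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a diversity comparison")
    h, p = stats.kruskal(*groups)
    return {"H": float(h), "p_value": float(p)}
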