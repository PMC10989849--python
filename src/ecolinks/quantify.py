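"""Collapse a (biotic-filtered) signed network to per-taxon connectedness and
per-sample community-level association strengths."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, ValidationError
from .network import AssociationNetwork

__all__ = [
    "ConnectednessProfile",
    "CommunityAssociationStrength",
    "zero_counts",
    "connectedness",
    "community_strength",
]

log = logging.getLogger(__name__)


@dataclass
class ConnectednessProfile:
    """Per-taxon mean positive / mean negative edge weights and link counts."""

    table: pd.DataFrame  # index taxon; pos_connectedness, neg_connectedness,
    # n_pos_links, n_neg_links, n_zeros

    def __post_init__(self) -> None:
        if (self.table["pos_connectedness"] < 0).any():
            raise ValidationError("positive connectedness must be >= 0")
        if (self.table["neg_connectedness"] > 0).any():
            raise ValidationError("negative connectedness must be <= 0")

    @property
    def taxa(self) -> list:
        return list(self.table.index)

    @property
    def pos(self) -> pd.Series:
        return self.table["pos_connectedness"]

    @property
    def neg(self) -> pd.Series:
        return self.table["neg_connectedness"]


@dataclass
class CommunityAssociationStrength:
    """Per-sample positive (>= 0) and negative (<= 0) association strengths."""

    table: pd.DataFrame  # index sample; positive_strength, negative_strength

    def __post_init__(self) -> None:
        if (self.table["positive_strength"] < -1e-12).any():
            raise ValidationError("positive strength must be >= 0")
        if (self.table["negative_strength"] > 1e-12).any():
            raise ValidationError("negative strength must be <= 0")


def zero_counts(table: AbundanceTable) -> pd.Series:
    """Number of samples in which each taxon is absent (abundance exactly 0)."""
    return (table.data == 0).sum(axis=0).rename("n_zeros")


def connectedness(
    net: AssociationNetwork,
    taxa=None,
    table: AbundanceTable | None = None,
    average_over_all: bool = False,
) -> ConnectednessProfile:
    """Mean positive and mean negative incident edge weight per taxon.

    Taxa with no positive (negative) edges get 0.  By default the mean runs
    over a taxon's existing links only; ``average_over_all`` divides by
    |taxa| - 1 instead (cohesion-style variant).  Passing ``table`` fills the
    per-taxon zero counts; a plain taxon list leaves them at 0.
    """
    if table is not None:
        taxa = table.taxa
        zeros = zero_counts(table)
    else:
        if taxa is None:
            taxa = net.taxa
        zeros = pd.Series(0, index=list(taxa))
    taxa = list(taxa)
    missing = [t for t in net.taxa if t not in set(taxa)]
    if missing:
        raise ValidationError(f"network taxa absent from taxon list: {missing[:5]}")
    pos_sum = {t: 0.0 for t in taxa}
    neg_sum = {t: 0.0 for t in taxa}
    n_pos = {t: 0 for t in taxa}
    n_neg = {t: 0 for t in taxa}
    for a, b, d in net.edges():
        w = d["weight"]
        if w > 0:
            for t in (a, b):
                pos_sum[t] += w
                n_pos[t] += 1
        else:
            for t in (a, b):
                neg_sum[t] += w
                n_neg[t] += 1
    denom_all = max(len(taxa) - 1, 1)
    rows = []
    for t in taxa:
        if average_over_all:
            pos = pos_sum[t] / denom_all
            neg = neg_sum[t] / denom_all
        else:
            pos = pos_sum[t] / n_pos[t] if n_pos[t] else 0.0
            neg = neg_sum[t] / n_neg[t] if n_neg[t] else 0.0
        rows.append(
            {
                "pos_connectedness": pos,
                "neg_connectedness": neg,
                "n_pos_links": n_pos[t],
                "n_neg_links": n_neg[t],
                "n_zeros": int(zeros.get(t, 0)),
            }
        )
    df = pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"))
    return ConnectednessProfile(df)


def community_strength(
    table: AbundanceTable,
    profile: ConnectednessProfile,
) -> CommunityAssociationStrength:
    """Abundance-weighted connectedness per sample.

    positive_strength(s) = sum_j relabund(s, j) * pos_connectedness(j), and
    symmetrically for the negative side.  Count tables are converted to
    relative abundance automatically (logged).
    """
    if set(table.taxa) != set(profile.taxa):
        raise ValidationError("profile taxa do not match abundance table taxa")
    A = table.data[profile.taxa].to_numpy(dtype=float)
    if not table.is_relative:
        log.info("count table passed to community_strength; converting to relative abundance")
        sums = A.sum(axis=1)
        # all-zero samples get zero strengths rather than an error
        A = np.divide(A, np.where(sums > 0, sums, 1.0)[:, None])
    pos = A @ profile.pos.to_numpy()
    neg = A @ profile.neg.to_numpy()
    df = pd.DataFrame(
        {"positive_strength": pos, "negative_strength": neg},
        index=pd.Index(table.samples, name="sample_id"),
    )
    return CommunityAssociationStrength(df)
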