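"""Core typed containers and delimited-text readers/writers.

All downstream stages share a canonical orientation: abundance matrices are
stored samples x taxa.  Containers validate their invariants on construction
so later stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "TaxonomyTable",
    "GeoTable",
    "EnvTable",
    "DistanceMatrix",
    "read_abundance",
    "write_abundance",
    "read_geo",
    "read_env",
    "to_relative",
    "filter_taxa",
]

#: Fixed taxonomic rank order used by :class:`TaxonomyTable`.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """An input violates a container invariant."""


def _check_unique(labels, what: str) -> None:
    index = pd.Index(labels)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dups}")


@dataclass
class AbundanceTable:
    """Sample x taxon non-negative abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as index and taxon identifiers as
        columns.  Values are counts or relative abundances; no missing
        entries are allowed.
    is_relative
        If True, every row must sum to 1 (within 1e-9).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance table contains non-numeric values")
        if np.isnan(values).any():
            raise ValidationError("abundance table contains missing values")
        if (values < 0).any():
            raise ValidationError("abundance table contains negative values")
        if self.is_relative:
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValidationError(
                    "relative abundance rows do not sum to 1 for samples: "
                    f"{[self.data.index[i] for i in bad[:5]]}"
                )

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


@dataclass
class TaxonomyTable:
    """Taxon identifier -> ordered rank strings (missing ranks empty)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon")
        # normalise to the fixed rank order, padding absent ranks
        cols = [c for c in RANKS if c in self.data.columns]
        extra = [c for c in self.data.columns if c not in RANKS]
        if extra:
            raise ValidationError(f"unknown taxonomy rank column(s): {extra}")
        out = pd.DataFrame("", index=self.data.index, columns=list(RANKS))
        out.loc[:, cols] = self.data[cols].fillna("").astype(str)
        self.data = out

    def ranks_for(self, taxon) -> tuple:
        return tuple(self.data.loc[taxon])


@dataclass
class GeoTable:
    """Per-sample longitude/latitude (decimal degrees) and optional elevation (m)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("longitude", "latitude"):
            if col not in self.data.columns:
                raise ValidationError(f"geographic table missing column {col!r}")
        lat = self.data["latitude"].to_numpy(dtype=float)
        lon = self.data["longitude"].to_numpy(dtype=float)
        if np.isnan(lat).any() or np.isnan(lon).any():
            raise ValidationError("geographic table contains missing coordinates")
        if (np.abs(lat) > 90).any():
            raise ValidationError("latitude out of range [-90, 90]")
        if (np.abs(lon) > 180).any():
            raise ValidationError("longitude out of range [-180, 180]")

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def has_elevation(self) -> bool:
        return "elevation" in self.data.columns and self.data["elevation"].notna().all()


@dataclass
class EnvTable:
    """Per-sample named numeric environmental variables."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("environmental table contains non-numeric values")

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def require_complete(self, variables) -> None:
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise ValidationError(f"environmental variable(s) not found: {missing}")
        if self.data[list(variables)].isna().any().any():
            raise ValidationError("missing values among selected environmental variables")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        _check_unique(self.labels, "distance-matrix label")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric within 1e-12")
        if (np.diag(self.values) != 0).any():
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if (self.values < 0).any():
            raise ValidationError("distance matrix has negative entries")

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels) -> "DistanceMatrix":
        """Return a copy restricted/reordered to *labels*."""
        labels = list(labels)
        missing = [s for s in labels if s not in self.labels]
        if missing:
            raise ValidationError(f"labels not in distance matrix: {missing[:5]}")
        idx = [self.labels.index(s) for s in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_frame(path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    _check_unique(df.index, "row")
    _check_unique(df.columns, "column")
    return df


def read_abundance(
    path,
    orientation: str = "samples_as_rows",
    delimiter: str = "\t",
) -> AbundanceTable:
    """Read a delimited abundance table into the canonical samples x taxa form.

    Parameters
    ----------
    path
        Delimited text file; first column holds row identifiers, header holds
        column identifiers, and the body is numeric.
    orientation
        ``"samples_as_rows"`` or ``"taxa_as_rows"``.  Never guessed.
    delimiter
        Field separator (tab by default).
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_frame(path, delimiter)
    body = {}
    for col in raw.columns:
        try:
            body[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()][col]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric cell at row {row!r}, column {col!r}: {exc}"
            ) from None
    df = pd.DataFrame(body, index=raw.index)
    if orientation == "taxa_as_rows":
        df = df.T
    df.index.name = "sample_id"
    return AbundanceTable(df)


def write_abundance(
    table: AbundanceTable,
    path,
    orientation: str = "samples_as_rows",
    delimiter: str = "\t",
) -> None:
    df = table.data if orientation == "samples_as_rows" else table.data.T
    df = df.copy()
    df.index.name = "sample_id" if orientation == "samples_as_rows" else "taxon_id"
    df.to_csv(path, sep=delimiter)


def read_geo(path, delimiter: str = "\t") -> GeoTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return GeoTable(df)


def read_env(path, delimiter: str = "\t") -> EnvTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return EnvTable(df)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Row-normalise abundances so each sample sums to 1.

    Raises
    ------
    ValidationError
        If any sample has zero total abundance (names the sample).
    """
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(
            f"cannot normalise zero-sum sample(s): {zero.index.tolist()[:5]}"
        )
    return AbundanceTable(table.data.div(sums, axis=0), is_relative=True)


def filter_taxa(
    table: AbundanceTable,
    min_occurrence_frac: float = 0.25,
    min_relabund: float = 1e-5,
    abundance_stat: str = "mean",
    strict_occurrence: bool = True,
) -> AbundanceTable:
    """Drop low-ubiquity and low-abundance taxa before network inference.

    A taxon is retained iff its occurrence fraction (samples with abundance
    > 0) exceeds ``min_occurrence_frac`` (strictly, by default) AND its
    ``abundance_stat`` ("mean" or "max") relative abundance across samples is
    >= ``min_relabund``.  The defaults implement the >25% occurrence,
    >=0.001% mean relative abundance criterion.  Returned values are the
    original (unnormalised) abundances of the surviving taxa.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValidationError("cannot filter an empty table")
    if abundance_stat not in ("mean", "max"):
        raise ValueError(f"unknown abundance_stat {abundance_stat!r}")
    rel = to_relative(table).data
    occ = (table.data > 0).mean(axis=0)
    stat = rel.mean(axis=0) if abundance_stat == "mean" else rel.max(axis=0)
    if strict_occurrence:
        keep = (occ > min_occurrence_frac) & (stat >= min_relabund)
    else:
        keep = (occ >= min_occurrence_frac) & (stat >= min_relabund)
    kept = table.data.columns[keep]
    if len(kept) == 0:
        raise ValidationError(
            "all taxa removed by filtering; relax min_occurrence_frac "
            f"(={min_occurrence_frac}) or min_relabund (={min_relabund})"
        )
    # subsetting columns breaks the row-sum invariant of a relative table
    return AbundanceTable(table.data[kept].copy(), is_relative=False)
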