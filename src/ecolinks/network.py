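"""Signed association network construction from abundance tables.

Correlation matrices with t-transform p-values, Benjamini-Hochberg control,
hard |r|/q thresholding, and an eigenvalue-spacing (random-matrix) scan for
choosing the correlation cut-off.  Externally inferred networks (e.g. from
covariance-based tools) enter through :func:`import_network`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .data_model import AbundanceTable, ValidationError

__all__ = [
    "AssociationNetwork",
    "RmtScanResult",
    "correlation_matrix",
    "fdr_adjust",
    "fdr_adjust_matrix",
    "threshold_network",
    "eigenvalue_spacings",
    "unfold_eigenvalues",
    "poisson_spacing_fit",
    "rmt_threshold",
    "import_network",
    "write_network",
    "extract_subnetwork",
]

_TINY = np.finfo(float).tiny


@dataclass
class AssociationNetwork:
    """Undirected signed weighted graph over taxa.

    Edges carry ``weight`` (signed association strength), ``p`` and ``q``
    attributes; ``method`` records how the network was built (method name,
    thresholds, sample count).
    """

    graph: nx.Graph
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on taxon {u!r}")
            w = d.get("weight", 0.0)
            if w == 0:
                raise ValidationError(f"zero-weight edge {u!r}-{v!r}")
            for key in ("p", "q"):
                val = d.setdefault(key, 0.0)
                if not (0.0 <= val <= 1.0):
                    raise ValidationError(f"edge {u!r}-{v!r} has {key}={val} outside [0, 1]")

    @property
    def taxa(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list:
        """Edges as (taxon_a, taxon_b, attrs), lexicographic by pair."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            out.append((a, b, d))
        return sorted(out, key=lambda e: (e[0], e[1]))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b, "weight": d["weight"], "p": d["p"], "q": d["q"]}
            for a, b, d in self.edges()
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "p", "q"])

    @classmethod
    def from_edges(cls, taxa, edge_records, method=None) -> "AssociationNetwork":
        """Build from (taxon_a, taxon_b, weight[, p[, q]]) records."""
        g = nx.Graph()
        g.add_nodes_from(taxa)
        for rec in edge_records:
            a, b, w = rec[0], rec[1], float(rec[2])
            p = float(rec[3]) if len(rec) > 3 else 0.0
            q = float(rec[4]) if len(rec) > 4 else 0.0
            if g.has_edge(a, b):
                raise ValidationError(f"duplicate edge {a!r}-{b!r}")
            g.add_edge(a, b, weight=w, p=p, q=q)
        return cls(g, dict(method or {}))


def correlation_matrix(table: AbundanceTable, method: str = "pearson"):
    """Taxon x taxon correlation matrix with two-sided t-transform p-values.

    Returns ``(R, P)`` DataFrames indexed by taxa.  P's diagonal is reported
    as 0 and is excluded downstream.  Zero-variance taxa get r = 0, p = 1
    against every partner (with a warning), never NaN.
    """
    if table.n_samples < 4:
        raise ValidationError("correlation requires at least 4 samples")
    if table.n_taxa < 2:
        raise ValidationError("correlation requires at least 2 taxa")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    X = table.values
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
    n = X.shape[0]
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(
            f"{flat.size} zero-variance taxa; their correlations set to 0 (p=1)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    if flat.size:
        R[flat, :] = 0.0
        R[:, flat] = 0.0
    np.fill_diagonal(R, 1.0)
    # two-sided p from the t transform with n-2 degrees of freedom
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = np.abs(R) * np.sqrt(df / np.maximum(1.0 - R * R, _TINY))
    P = 2.0 * stats.t.sf(t, df)
    P = np.clip(P, _TINY, 1.0)
    if flat.size:
        P[flat, :] = 1.0
        P[:, flat] = 1.0
    np.fill_diagonal(P, 0.0)
    taxa = table.taxa
    return (
        pd.DataFrame(R, index=taxa, columns=taxa),
        pd.DataFrame(P, index=taxa, columns=taxa),
    )


def fdr_adjust(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    if method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_adjust_matrix(P: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Adjust the upper-triangle of a symmetric p-value matrix; mirror back."""
    vals = P.to_numpy()
    n = vals.shape[0]
    iu = np.triu_indices(n, k=1)
    q = fdr_adjust(vals[iu], method=method)
    Q = np.zeros_like(vals)
    Q[iu] = q
    Q = Q + Q.T
    return pd.DataFrame(Q, index=P.index, columns=P.columns)


def threshold_network(
    R: pd.DataFrame,
    P: pd.DataFrame,
    Q: pd.DataFrame,
    r_min: float = 0.6,
    q_max: float = 0.05,
    method_name: str = "correlation",
    n_samples: int | None = None,
) -> AssociationNetwork:
    """Retain edge (i, j) iff |R_ij| > r_min AND Q_ij < q_max.

    Edge weight is R_ij with sign preserved.  An empty network is allowed.
    """
    taxa = list(R.index)
    r = R.to_numpy()
    p = P.to_numpy()
    q = Q.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(taxa)
    iu, ju = np.triu_indices(len(taxa), k=1)
    keep = (np.abs(r[iu, ju]) > r_min) & (q[iu, ju] < q_max)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(taxa[i], taxa[j], weight=float(r[i, j]), p=float(p[i, j]), q=float(q[i, j]))
    meta = {
        "method": method_name,
        "r_threshold": r_min,
        "q_threshold": q_max,
        "n_samples": n_samples,
    }
    return AssociationNetwork(g, meta)


# ---------------------------------------------------------------------------
# random-matrix threshold scan
# ---------------------------------------------------------------------------

@dataclass
class RmtScanResult:
    """Per-threshold eigenvalue-spacing scan and the chosen cut-off."""

    scan: pd.DataFrame  # threshold, n_eigenvalues, n_offdiag, chi2, p_value
    chosen: float | None
    min_eigenvalues: int
    p_threshold: float

    @property
    def found(self) -> bool:
        return self.chosen is not None


def eigenvalue_spacings(eigenvalues) -> np.ndarray:
    """Nearest-neighbour spacings of sorted eigenvalues (before unfolding)."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    return np.diff(lam)


def unfold_eigenvalues(eigenvalues, dedup_decimals: int = 8, smoothing: float | None = None):
    """Unfold a spectrum with a cubic smoothing spline of its cumulative density.

    Degenerate eigenvalues are collapsed before fitting (standard practice for
    thresholded sparse matrices, whose null space would otherwise dominate the
    spacing distribution).  Returns unfolded eigenvalues with unit mean spacing.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    uniq = np.unique(np.round(lam, dedup_decimals))
    m = uniq.size
    if m < 8:
        raise ValidationError(f"too few distinct eigenvalues to unfold ({m})")
    cumulative = np.arange(1, m + 1, dtype=float)
    s = float(m) if smoothing is None else smoothing
    spline = UnivariateSpline(uniq, cumulative, k=3, s=s)
    return np.asarray(spline(uniq), dtype=float)


def poisson_spacing_fit(spacings, n_bins: int | None = None, s_max: float = 3.0):
    """Chi-square goodness of fit of unit-mean spacings against Exp(1).

    Spacings are rescaled to unit mean, binned on [0, s_max] with ceil(sqrt(n))
    equal-width bins plus an overflow bin, and compared with the exponential
    law e^(-s).  Returns ``(chi2, p_value)``.
    """
    s = np.asarray(spacings, dtype=float)
    s = s[s > 0]
    if s.size < 20:
        raise ValidationError(f"too few positive spacings for the fit ({s.size})")
    s = s / s.mean()
    n = s.size
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n))
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(s, bins=edges)
    obs = np.append(obs, np.sum(s >= s_max))
    cdf = 1.0 - np.exp(-edges)
    probs = np.append(np.diff(cdf), np.exp(-s_max))
    expected = probs * n
    mask = expected > 0
    chi2 = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    dof = int(mask.sum()) - 2  # one constraint + fitted mean
    p = float(stats.chi2.sf(chi2, max(dof, 1)))
    return chi2, p


def rmt_threshold(
    R: pd.DataFrame | np.ndarray,
    grid_start: float = 0.3,
    grid_stop: float = 0.95,
    grid_step: float = 0.01,
    min_eigenvalues: int = 50,
    p_threshold: float = 0.05,
    s_max: float = 3.0,
    n_bins: int | None = None,
) -> RmtScanResult:
    """Scan correlation cut-offs for Poisson nearest-neighbour spacing statistics.

    For each candidate t the matrix is hard-thresholded (|R_ij| < t zeroed,
    diagonal kept), its eigenvalues unfolded, and the spacing distribution
    tested against the exponential law.  The chosen threshold is the smallest
    t whose fit p-value exceeds ``p_threshold`` with at least
    ``min_eigenvalues`` distinct eigenvalues retained; if none qualifies the
    result is flagged and the caller falls back to a fixed cut-off.
    """
    M0 = np.asarray(R, dtype=float) if not isinstance(R, pd.DataFrame) else R.to_numpy()
    n = M0.shape[0]
    if M0.shape != (n, n) or not np.allclose(M0, M0.T, atol=1e-10):
        raise ValidationError("R must be a symmetric square matrix")
    if n < 50:
        raise ValidationError(f"need >= 50 taxa for a meaningful spectrum (got {n})")
    grid = np.round(np.arange(grid_start, grid_stop + grid_step / 2, grid_step), 10)
    rows = []
    chosen = None
    for t in grid:
        M = np.where(np.abs(M0) < t, 0.0, M0)
        np.fill_diagonal(M, np.diag(M0))
        n_offdiag = int(np.count_nonzero(M) - np.count_nonzero(np.diag(M)))
        eig = np.linalg.eigvalsh(M)
        n_eig = np.unique(np.round(eig, 8)).size
        chi2 = np.nan
        p = np.nan
        if n_eig >= min_eigenvalues:
            try:
                unfolded = unfold_eigenvalues(eig)
                chi2, p = poisson_spacing_fit(np.diff(unfolded), n_bins=n_bins, s_max=s_max)
            except ValidationError:
                pass
        rows.append(
            {
                "threshold": float(t),
                "n_eigenvalues": n_eig,
                "n_offdiag": n_offdiag,
                "chi2": chi2,
                "p_value": p,
            }
        )
        if chosen is None and np.isfinite(p) and p > p_threshold and n_eig >= min_eigenvalues:
            chosen = float(t)
    scan = pd.DataFrame(rows)
    if chosen is None:
        warnings.warn(
            "no threshold in the grid satisfies the Poisson spacing fit; "
            "fall back to a fixed r_min",
            stacklevel=2,
        )
    return RmtScanResult(scan, chosen, min_eigenvalues, p_threshold)


# ---------------------------------------------------------------------------
# import / export / subsetting
# ---------------------------------------------------------------------------

def import_network(path, delimiter: str = "\t") -> AssociationNetwork:
    """Read an edge list (taxon_a, taxon_b, weight[, p[, q]]) into a network.

    Missing p/q columns default to 0 (edges treated as pre-validated).
    Self-loops, duplicate pairs, and zero weights are rejected.
    """
    df = pd.read_csv(path, sep=delimiter)
    required = ["taxon_a", "taxon_b", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"edge list missing column(s): {missing}")
    g = nx.Graph()
    for _, row in df.iterrows():
        a, b = str(row["taxon_a"]), str(row["taxon_b"])
        if a == b:
            raise ValidationError(f"self-loop on taxon {a!r}")
        w = float(row["weight"])
        if w == 0:
            raise ValidationError(f"zero-weight edge {a!r}-{b!r} rejected")
        if g.has_edge(a, b):
            raise ValidationError(f"duplicate edge {a!r}-{b!r}")
        p = float(row["p"]) if "p" in df.columns and pd.notna(row.get("p")) else 0.0
        q = float(row["q"]) if "q" in df.columns and pd.notna(row.get("q")) else 0.0
        g.add_edge(a, b, weight=w, p=p, q=q)
    return AssociationNetwork(g, {"method": "imported", "source": str(path)})


def write_network(net: AssociationNetwork, path, delimiter: str = "\t") -> None:
    """Write the edge list as TSV plus a JSON metadata sidecar."""
    net.edge_table().to_csv(path, sep=delimiter, index=False)
    meta_path = str(path) + ".meta.json"
    with open(meta_path, "w") as fh:
        json.dump(net.method, fh, indent=2, sort_keys=True)
        fh.write("\n")


def extract_subnetwork(net: AssociationNetwork, table: AbundanceTable, samples) -> AssociationNetwork:
    """Induced subgraph on taxa with nonzero abundance in the sample subset."""
    samples = list(samples)
    if not samples:
        raise ValidationError("empty sample subset")
    missing = [s for s in samples if s not in table.data.index]
    if missing:
        raise ValidationError(f"samples not in table: {missing[:5]}")
    totals = table.data.loc[samples].sum(axis=0)
    present = set(totals[totals > 0].index)
    keep = [t for t in net.taxa if t in present]
    sub = net.graph.subgraph(keep).copy()
    meta = dict(net.method)
    meta["subnetwork_samples"] = len(samples)
    return AssociationNetwork(sub, meta)
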