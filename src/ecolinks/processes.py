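"""Assign assembly processes to network edges via per-edge link tests.

Each significant edge is tested, through Mantel correlations, against
geographic and environmental distance matrices computed from sample
metadata.  Edges explained by neither factor are the putative biotic
associations that the quantification stage consumes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    AbundanceTable,
    DistanceMatrix,
    EnvTable,
    GeoTable,
    ValidationError,
    to_relative,
)
from .network import AssociationNetwork, fdr_adjust

__all__ = [
    "MantelResult",
    "EdgeProcessAssignment",
    "PROCESS_CLASSES",
    "geo_distance",
    "env_distance",
    "screen_env_covariance",
    "pair_abundance_distance",
    "mantel_test",
    "assign_processes",
    "process_fractions",
]

PROCESS_CLASSES = (
    "dispersal_limitation",
    "environmental_selection",
    "overlap",
    "biotic",
)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def geo_distance(
    geo: GeoTable,
    mode: str = "haversine",
    include_elevation: bool = False,
) -> DistanceMatrix:
    """Pairwise geographic distance between samples, in km.

    ``haversine`` uses great-circle distance on a sphere of radius 6371 km;
    ``euclidean`` treats coordinates as planar.  With ``include_elevation``
    the elevation difference (in km) enters as an extra Euclidean component.
    """
    if mode not in ("haversine", "euclidean"):
        raise ValueError(f"unknown geographic mode {mode!r}")
    lon = geo.data["longitude"].to_numpy(dtype=float)
    lat = geo.data["latitude"].to_numpy(dtype=float)
    if mode == "haversine":
        phi = np.radians(lat)
        lam = np.radians(lon)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
        horizontal = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    else:
        dx = lon[:, None] - lon[None, :]
        dy = lat[:, None] - lat[None, :]
        horizontal = np.sqrt(dx * dx + dy * dy)
    if include_elevation:
        if not geo.has_elevation:
            raise ValidationError("elevation requested but not present for all samples")
        elev_km = geo.data["elevation"].to_numpy(dtype=float) / 1000.0
        dz = elev_km[:, None] - elev_km[None, :]
        d = np.sqrt(horizontal**2 + dz * dz)
    else:
        d = horizontal
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # kill floating asymmetry
    return DistanceMatrix(geo.samples, d)


def env_distance(env: EnvTable, variables=None, standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (optionally z-scored) environmental variables."""
    variables = list(variables) if variables is not None else env.variables
    env.require_complete(variables)
    X = env.data[variables].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValidationError(
                f"zero-variance environmental variable(s): {[variables[i] for i in flat]}"
            )
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(env.samples, d)


def screen_env_covariance(env: EnvTable, rho_max: float = 0.5, order=None) -> list:
    """Greedy covariance screen: keep variables whose |Spearman rho| with every
    previously retained variable stays below ``rho_max``, scanning in the
    caller-given priority order (table order by default)."""
    order = list(order) if order is not None else env.variables
    env.require_complete(order)
    retained: list = []
    for var in order:
        ok = True
        for prev in retained:
            rho = stats.spearmanr(env.data[var], env.data[prev]).statistic
            if np.isnan(rho):
                rho = 0.0
            if abs(rho) >= rho_max:
                ok = False
                break
        if ok:
            retained.append(var)
    return retained


def pair_abundance_distance(
    table: AbundanceTable,
    taxon_i,
    taxon_j,
    metric: str = "braycurtis",
) -> DistanceMatrix:
    """Sample x sample distance computed from one taxon pair's abundances.

    Bray-Curtis between two samples whose pair abundances are both all-zero
    is defined as 0.
    """
    for t in (taxon_i, taxon_j):
        if t not in table.data.columns:
            raise ValidationError(f"taxon {t!r} not found in abundance table")
    if metric not in ("braycurtis", "euclidean"):
        raise ValueError(f"unknown pair metric {metric!r}")
    sub = table.data[[taxon_i, taxon_j]].to_numpy(dtype=float)
    diff = np.abs(sub[:, None, :] - sub[None, :, :]).sum(axis=2)
    if metric == "euclidean":
        delta = sub[:, None, :] - sub[None, :, :]
        d = np.sqrt((delta * delta).sum(axis=2))
    else:
        tot = (sub[:, None, :] + sub[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(table.samples, d)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    exact: bool = False

    def __iter__(self):
        return iter((self.r, self.p))


def _condensed_under_permutation(values: np.ndarray, perms: np.ndarray, iu) -> np.ndarray:
    """Upper-triangle vectors of values[perm][:, perm] for each permutation row."""
    rows = perms[:, iu[0]]
    cols = perms[:, iu[1]]
    return values[rows, cols]


def _corr_rows(V: np.ndarray, w: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of V with w."""
    if method == "spearman":
        V = stats.rankdata(V, axis=1)
        w = stats.rankdata(w)
    Vc = V - V.mean(axis=1, keepdims=True)
    wc = w - w.mean()
    denom = np.sqrt((Vc * Vc).sum(axis=1) * (wc * wc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc @ wc) / denom
    return np.where(np.isfinite(r), r, 0.0)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) permutation Mantel test between two distance matrices.

    The statistic is the correlation of the upper-triangle entries.  The
    permutation p-value includes the identity permutation:
    p = (1 + #{perm: r_perm >= r_obs}) / (1 + n_perm).  When all label
    permutations number at most n_perm + 1, the full permutation group is
    enumerated instead and the result is flagged ``exact`` (p = k / n!).
    """
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices have mismatched labels")
    n = len(d1.labels)
    if n < 3:
        raise ValidationError("Mantel test requires at least 3 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown Mantel method {method!r}")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        warnings.warn("zero variance in a distance matrix; Mantel r undefined", stacklevel=2)
        return MantelResult(0.0, 1.0, 0, False)
    r_obs = float(_corr_rows(v1[None, :], v2, method)[0])
    tol = 1e-12
    n_fact = math.factorial(n)
    if n_fact - 1 <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        V = _condensed_under_permutation(d1.values, perms, iu)
        r_perm = _corr_rows(V, v2, method)
        count = int(np.sum(r_perm >= r_obs - tol))
        return MantelResult(r_obs, count / n_fact, n_fact - 1, True)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    V = _condensed_under_permutation(d1.values, perms, iu)
    r_perm = _corr_rows(V, v2, method)
    count = int(np.sum(r_perm >= r_obs - tol))
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm, False)


# ---------------------------------------------------------------------------
# edge classification
# ---------------------------------------------------------------------------

@dataclass
class EdgeProcessAssignment:
    """Per-edge assembly-process labels with the underlying link-test statistics.

    ``table`` columns: taxon_a, taxon_b, weight, r_geo, p_geo, r_env, p_env,
    process.  The four classes are mutually exclusive and exhaustive.
    """

    table: pd.DataFrame
    alpha: float
    n_permutations: int

    def biotic_edges(self) -> pd.DataFrame:
        return self.table[self.table["process"] == "biotic"].reset_index(drop=True)

    def biotic_network(self, net: AssociationNetwork) -> AssociationNetwork:
        """Restrict *net* to its biotic-classified edges (same node set)."""
        import networkx as nx

        keep = {(row.taxon_a, row.taxon_b) for row in self.biotic_edges().itertuples()}
        g = nx.Graph()
        g.add_nodes_from(net.taxa)
        for a, b, d in net.edges():
            if (a, b) in keep:
                g.add_edge(a, b, **d)
        meta = dict(net.method)
        meta["filtered"] = "biotic"
        return AssociationNetwork(g, meta)


def _classify(geo_sig: bool, env_sig: bool) -> str:
    if geo_sig and env_sig:
        return "overlap"
    if geo_sig:
        return "dispersal_limitation"
    if env_sig:
        return "environmental_selection"
    return "biotic"


def assign_processes(
    net: AssociationNetwork,
    table: AbundanceTable,
    geo_d: DistanceMatrix,
    env_d: DistanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    pair_metric: str = "braycurtis",
    mantel_method: str = "pearson",
    bh_correct: bool = False,
) -> EdgeProcessAssignment:
    """Classify every edge by its 2x2 geographic/environmental significance pattern.

    For each edge the pair-abundance distance matrix is Mantel-tested against
    the geographic and environmental distances.  A factor explains the edge
    when p < alpha AND r > 0 (distance-decay direction).  Geo-only ->
    dispersal_limitation, env-only -> environmental_selection, both ->
    overlap, neither -> biotic.  Deterministic given ``seed``.
    """
    rel = table if table.is_relative else to_relative(table)
    geo_d = geo_d.reorder(rel.samples)
    env_d = env_d.reorder(rel.samples)
    edges = net.edges()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(edges)) if edges else []
    rows = []
    for k, (a, b, d) in enumerate(edges):
        pair_d = pair_abundance_distance(rel, a, b, metric=pair_metric)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            geo_res = mantel_test(
                pair_d, geo_d, method=mantel_method, n_perm=n_perm,
                seed=children[2 * k],
            )
            env_res = mantel_test(
                pair_d, env_d, method=mantel_method, n_perm=n_perm,
                seed=children[2 * k + 1],
            )
        rows.append(
            {
                "taxon_a": a,
                "taxon_b": b,
                "weight": d["weight"],
                "r_geo": geo_res.r,
                "p_geo": geo_res.p,
                "r_env": env_res.r,
                "p_env": env_res.p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["taxon_a", "taxon_b", "weight", "r_geo", "p_geo", "r_env", "p_env"],
    )
    if len(df):
        p_geo = df["p_geo"].to_numpy()
        p_env = df["p_env"].to_numpy()
        if bh_correct:
            p_geo = fdr_adjust(p_geo)
            p_env = fdr_adjust(p_env)
        geo_sig = (p_geo < alpha) & (df["r_geo"].to_numpy() > 0)
        env_sig = (p_env < alpha) & (df["r_env"].to_numpy() > 0)
        df["process"] = [_classify(g, e) for g, e in zip(geo_sig, env_sig)]
    else:
        df["process"] = pd.Series(dtype=str)
    return EdgeProcessAssignment(df, alpha, n_perm)


def process_fractions(assignment: EdgeProcessAssignment) -> dict:
    """Fraction of edges in each of the four assembly-process classes."""
    n = len(assignment.table)
    if n == 0:
        raise ValidationError("cannot compute fractions of an empty assignment")
    counts = assignment.table["process"].value_counts()
    return {cls: float(counts.get(cls, 0)) / n for cls in PROCESS_CLASSES}
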