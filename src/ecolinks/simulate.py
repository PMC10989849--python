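"""Synthetic communities with planted assembly structure.

Generates an abundance table plus matching geographic/environmental metadata
and ground-truth edge labels: pairs of taxa driven by an environmental
gradient, pairs driven by a smooth spatial field, positively or negatively
coupled "biotic" pairs independent of both, and independent noise taxa.
Every pipeline stage is testable against the planted truth, offline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AbundanceTable,
    EnvTable,
    GeoTable,
    ValidationError,
    write_abundance,
)

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticCommunity", "generate_community", "write_fixture", "read_fixture"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted community generator."""

    n_samples: int = 60
    n_noise_taxa: int = 100
    n_env_pairs: int = 0
    n_space_pairs: int = 0
    n_biotic_pos_pairs: int = 0
    n_biotic_neg_pairs: int = 0
    env_effect: float = 2.0
    space_effect: float = 2.0
    biotic_rho: float = 0.9
    biotic_sigma: float = 1.0
    noise_sigma: float = 0.1
    base_abundance_logmean: float = -3.0
    base_abundance_logsd: float = 1.0
    # planted pairs sit this far below the noise base so that gradient-driven
    # taxa cannot dominate sample totals (renormalisation would otherwise leak
    # the gradients into every taxon's relative abundance)
    planted_logmean_offset: float = -2.0
    sparsity_quantile: float = 0.3
    env_space_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_noise_taxa",
            "n_env_pairs",
            "n_space_pairs",
            "n_biotic_pos_pairs",
            "n_biotic_neg_pairs",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (-1.0 < self.biotic_rho < 1.0):
            raise ValidationError("biotic_rho must lie in (-1, 1)")
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be > 0")
        if not (0.0 <= self.sparsity_quantile < 1.0):
            raise ValidationError("sparsity_quantile must lie in [0, 1)")
        if not (-1.0 <= self.env_space_corr <= 1.0):
            raise ValidationError("env_space_corr must lie in [-1, 1]")

    @property
    def n_taxa(self) -> int:
        return self.n_noise_taxa + 2 * (
            self.n_env_pairs
            + self.n_space_pairs
            + self.n_biotic_pos_pairs
            + self.n_biotic_neg_pairs
        )


@dataclass
class GroundTruth:
    """Planted pair labels: taxon_a, taxon_b, true_class, sign."""

    table: pd.DataFrame

    def pairs(self, true_class: str | None = None) -> list:
        df = self.table
        if true_class is not None:
            df = df[df["true_class"] == true_class]
        return [(r.taxon_a, r.taxon_b) for r in df.itertuples()]


@dataclass
class SyntheticCommunity:
    table: AbundanceTable
    geo: GeoTable
    env: EnvTable
    truth: GroundTruth
    spec: SyntheticSpec = field(repr=False, default=None)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_community(spec: SyntheticSpec) -> SyntheticCommunity:
    """Generate (AbundanceTable, GeoTable, EnvTable, GroundTruth) from a spec.

    Samples sit on a 2-D plane with an environmental gradient independent of
    the spatial field (optionally confounded via ``env_space_corr``).
    Planted pairs follow the gradient, the field, or a latent Gaussian copula;
    noise taxa are i.i.d. log-normal.  Log-abundances are exponentiated,
    sparsified by per-taxon quantile truncation, and row-renormalised.
    Deterministic given the spec seed.
    """
    if spec.n_taxa < 2:
        raise ValidationError("spec generates fewer than 2 taxa")
    if spec.n_samples < 4:
        raise ValidationError("need at least 4 samples")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    # coordinates (small patch of valid lon/lat) and latent axes
    x = rng.uniform(0.0, 1.0, n)
    y = rng.uniform(0.0, 1.0, n)
    theta = rng.uniform(0.0, 2 * np.pi)
    G = _standardize(np.cos(theta) * x + np.sin(theta) * y)
    latent = rng.uniform(0.0, 1.0, n)
    E = _standardize(latent + 0.05 * rng.standard_normal(n))
    if spec.env_space_corr:
        c = spec.env_space_corr
        E = _standardize(c * G + np.sqrt(1 - c * c) * E)

    cols = {}
    truth_rows = []

    def planted_pair(prefix, idx, log_a, log_b, true_class, sign):
        a, b = f"{prefix}{idx}a", f"{prefix}{idx}b"
        cols[a], cols[b] = log_a, log_b
        truth_rows.append(
            {"taxon_a": a, "taxon_b": b, "true_class": true_class, "sign": sign}
        )

    base = spec.base_abundance_logmean + spec.planted_logmean_offset
    for i in range(spec.n_env_pairs):
        la = base + spec.env_effect * E + spec.noise_sigma * rng.standard_normal(n)
        lb = base + spec.env_effect * E + spec.noise_sigma * rng.standard_normal(n)
        planted_pair("env", i, la, lb, "environmental_selection", 1)
    for i in range(spec.n_space_pairs):
        la = base + spec.space_effect * G + spec.noise_sigma * rng.standard_normal(n)
        lb = base + spec.space_effect * G + spec.noise_sigma * rng.standard_normal(n)
        planted_pair("spa", i, la, lb, "dispersal_limitation", 1)
    for i in range(spec.n_biotic_pos_pairs + spec.n_biotic_neg_pairs):
        sign = 1 if i < spec.n_biotic_pos_pairs else -1
        rho = sign * abs(spec.biotic_rho)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        la = base + spec.biotic_sigma * z[:, 0] + spec.noise_sigma * rng.standard_normal(n)
        lb = base + spec.biotic_sigma * z[:, 1] + spec.noise_sigma * rng.standard_normal(n)
        planted_pair("bio", i, la, lb, "biotic", sign)
    for i in range(spec.n_noise_taxa):
        cols[f"noise{i}"] = (
            spec.base_abundance_logmean
            + spec.base_abundance_logsd * rng.standard_normal(n)
        )

    log_abund = pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])
    abund = np.exp(log_abund.to_numpy())

    # sparsify: zero each taxon's values strictly below its own quantile
    if spec.sparsity_quantile > 0:
        cut = np.quantile(abund, spec.sparsity_quantile, axis=0)
        abund = np.where(abund < cut, 0.0, abund)
    sums = abund.sum(axis=1)
    if (sums <= 0).any():
        raise ValidationError("sparsification produced an all-zero sample; lower sparsity_quantile")
    abund = abund / sums[:, None]

    table = AbundanceTable(
        pd.DataFrame(abund, index=log_abund.index, columns=log_abund.columns),
        is_relative=True,
    )
    geo = GeoTable(
        pd.DataFrame({"longitude": x, "latitude": y}, index=log_abund.index)
    )
    env = EnvTable(pd.DataFrame({"env_gradient": E}, index=log_abund.index))
    truth = GroundTruth(
        pd.DataFrame(truth_rows, columns=["taxon_a", "taxon_b", "true_class", "sign"])
    )
    return SyntheticCommunity(table, geo, env, truth, spec)


def write_fixture(bundle: SyntheticCommunity, directory, overwrite: bool = False) -> dict:
    """Write abundance/geo/env/ground-truth TSVs into *directory*."""
    paths = {
        "abundance": os.path.join(directory, "abundance.tsv"),
        "geo": os.path.join(directory, "geo.tsv"),
        "env": os.path.join(directory, "env.tsv"),
        "ground_truth": os.path.join(directory, "ground_truth.tsv"),
    }
    os.makedirs(directory, exist_ok=True)
    if not overwrite:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise ValidationError(f"refusing to overwrite existing file(s): {existing}")
    write_abundance(bundle.table, paths["abundance"])
    geo = bundle.geo.data.copy()
    geo.index.name = "sample_id"
    geo.to_csv(paths["geo"], sep="\t")
    env = bundle.env.data.copy()
    env.index.name = "sample_id"
    env.to_csv(paths["env"], sep="\t")
    bundle.truth.table.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths


def read_fixture(directory) -> SyntheticCommunity:
    """Read back a fixture written by :func:`write_fixture`."""
    from .data_model import read_abundance, read_env, read_geo

    table = read_abundance(os.path.join(directory, "abundance.tsv"))
    table = AbundanceTable(table.data, is_relative=True)
    geo = read_geo(os.path.join(directory, "geo.tsv"))
    env = read_env(os.path.join(directory, "env.tsv"))
    truth = GroundTruth(pd.read_csv(os.path.join(directory, "ground_truth.tsv"), sep="\t"))
    return SyntheticCommunity(table, geo, env, truth, None)
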