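"""Correlative baseline: Fisher-z pooling of Spearman coefficients.

The traditional test of the evolutionary speed hypothesis asks whether key
correlations — species richness against |latitude| and temperature across
grid cells, and speciation rate (DR) against body size and temperature across
species — show a directional trend over many clades.  Per-clade coefficients
are Fisher-transformed to the z scale and pooled with a random-effects model
(between-clade variance tau^2 estimated by REML, DerSimonian-Laird as
fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EffectRecord",
    "PooledEffect",
    "fisher_transform",
    "random_effects_pool",
    "key_correlation_battery",
    "KEY_STATISTICS",
]

_Z975 = 1.959964
_CLIP = 1e-6

KEY_STATISTICS = (
    "richness_abslat",
    "richness_temperature",
    "DR_body_size",
    "DR_temperature",
)


@dataclass
class EffectRecord:
    """One clade's Spearman coefficient for one key statistic."""

    clade_id: str
    statistic: str
    rho: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4 for the Fisher variance 1/(n-3)")
        if not np.isfinite(self.rho) or abs(self.rho) > 1:
            raise ValueError("rho must be finite with |rho| <= 1")
        if abs(self.rho) == 1.0:
            warnings.warn("|rho| = 1 clipped for the Fisher transform")
            self.rho = float(np.sign(self.rho) * (1.0 - _CLIP))


@dataclass
class PooledEffect:
    """Random-effects pooled mean effect for one statistic."""

    beta_z: float
    beta_rho: float
    se: float
    z_stat: float
    p_value: float
    tau2: float
    k: int
    method: str


def fisher_transform(rho: float, n: int) -> tuple[float, float, tuple[float, float]]:
    """Fisher z-transform with variance and 95% CI.

    ``z = atanh(rho)``, ``var = 1/(n-3)``; the CI is on the z scale and can be
    back-transformed with ``tanh``.  Coefficients at exactly |rho| = 1 are
    clipped to 1 - 1e-6.
    """
    if n <= 3:
        raise ValueError("n must be > 3")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    if abs(rho) == 1.0:
        warnings.warn("|rho| = 1 clipped for the Fisher transform")
        rho = float(np.sign(rho) * (1.0 - _CLIP))
    z = float(np.arctanh(rho))
    var = 1.0 / (n - 3)
    half = _Z975 * np.sqrt(var)
    return z, var, (z - half, z + half)


def _dersimonian_laird(z: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    beta_fe = (w * z).sum() / w.sum()
    Q = (w * (z - beta_fe) ** 2).sum()
    k = z.size
    denom = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0


def _reml_tau2(z: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100):
    """Iterative REML estimate of the between-study variance."""
    tau2 = _dersimonian_laird(z, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        beta = (w * z).sum() / w.sum()
        num = (w**2 * ((z - beta) ** 2 - v)).sum()
        new = num / (w**2).sum() + 1.0 / w.sum()
        new = max(new, 0.0)
        if abs(new - tau2) < tol:
            return new, True
        tau2 = new
    return tau2, False


def random_effects_pool(records: list[EffectRecord], method: str = "reml") -> PooledEffect:
    """Pool Fisher-transformed effects across clades with random effects.

    Weights are ``1/(v_i + tau^2)``; the pooled mean, its SE, the normal test
    statistic and a two-sided p-value are reported on the z scale along with
    the back-transformed pooled correlation.  REML (iterative, tolerance
    1e-10, at most 100 iterations) is the default tau^2 estimator;
    non-convergence falls back to DerSimonian-Laird with a warning, which is
    also available directly via ``method="dl"``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 clades to pool")
    z = np.empty(len(records))
    v = np.empty(len(records))
    for i, rec in enumerate(records):
        zi, vi, _ = fisher_transform(rec.rho, rec.n)
        z[i] = zi
        v[i] = vi
    used = method
    if method == "reml":
        tau2, converged = _reml_tau2(z, v)
        if not converged:
            warnings.warn("REML did not converge; falling back to DerSimonian-Laird")
            tau2 = _dersimonian_laird(z, v)
            used = "dl"
    elif method == "dl":
        tau2 = _dersimonian_laird(z, v)
    else:
        raise ValueError("method must be 'reml' or 'dl'")
    w = 1.0 / (v + tau2)
    beta = float((w * z).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z_stat = beta / se
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return PooledEffect(
        beta_z=beta,
        beta_rho=float(np.tanh(beta)),
        se=se,
        z_stat=float(z_stat),
        p_value=p,
        tau2=float(tau2),
        k=len(records),
        method=used,
    )


def key_correlation_battery(
    bundles: dict[str, "object"],
    min_species: int = 20,
    method: str = "reml",
) -> tuple[list[EffectRecord], dict[str, PooledEffect]]:
    """Per-clade key correlations pooled across clades.

    For each clade bundle with at least ``min_species`` species, computes
    Spearman's rho for richness ~ |latitude| and richness ~ temperature across
    cells, and DR ~ body size and DR ~ temperature across species, then pools
    each statistic across clades.  Clades below the species minimum are
    excluded with a warning.
    """
    from evospeed.summaries import (
        assemblage_metrics,
        species_spatial_traits,
        tip_metrics,
    )

    records: list[EffectRecord] = []
    for clade_id, bundle in bundles.items():
        if bundle.n_species < min_species:
            warnings.warn(f"clade {clade_id!r} has fewer than {min_species} species; skipped")
            continue
        cells = assemblage_metrics(bundle)
        occupied = cells[cells["richness"] > 0]
        tips = tip_metrics(bundle.tree)
        sp = species_spatial_traits(bundle).join(tips, how="inner")
        sp = sp.join(bundle.body_size.rename("body_size").astype(float), how="inner")
        pairs = {
            "richness_abslat": (occupied["richness"], np.abs(occupied["latitude"])),
            "richness_temperature": (occupied["richness"], occupied["temperature"]),
            "DR_body_size": (sp["DR"], sp["body_size"]),
            "DR_temperature": (sp["DR"], sp["mean_range_temperature"]),
        }
        for stat, (a, b) in pairs.items():
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 4 or np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
                continue
            rho, _ = stats.spearmanr(a[ok], b[ok])
            records.append(
                EffectRecord(clade_id=str(clade_id), statistic=stat, rho=float(rho), n=int(ok.sum()))
            )
    pooled: dict[str, PooledEffect] = {}
    for stat in KEY_STATISTICS:
        recs = [r for r in records if r.statistic == stat]
        if len(recs) >= 2:
            pooled[stat] = random_effects_pool(recs, method=method)
    return records, pooled
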