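"""Sobol experiment design and ensemble execution across divergence models.

A simulation campaign samples the six varied parameters (divergence threshold
S, rate exponent lambda, filter width omega, Brownian rates sigma_B/sigma_T,
dispersal scale phi) with a quasi-random Sobol sequence so that the
six-dimensional parameter space is covered evenly, runs every parameter set
under each divergence model (M0-M3) on a shared landscape, and keeps — for the
classifier path — only parameter sets whose runs completed under all four
models, which guarantees equal class sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from evospeed.landscape import LandscapeSeries
from evospeed.simulator import MODELS, InitSpec, ParameterSet, run_simulation
from evospeed.summaries import bundle_from_result, summarize, write_bundle

__all__ = [
    "DesignSpec",
    "sobol_parameters",
    "derive_seed",
    "run_ensemble",
    "completeness_filter",
    "export_pseudo_empirical",
    "DEFAULT_RANGES",
]

#: parameter ranges of the six varied parameters
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "S": (2.0, 10.0),
    "lambda_": (2.0, 5.0),
    "omega": (0.01, 0.035),
    "sigma_B": (0.001, 0.02),
    "sigma_T": (0.001, 0.015),
    "phi": (330.0, 880.0),
}


@dataclass
class DesignSpec:
    """A simulation campaign design: sample count, ranges, fixed values."""

    n_samples: int = 48
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    psi: float = 2.5
    Kc: float = 30_000.0
    mu_t: float = 500.0
    mu_d: float = 0.01
    base_seed: int = 0
    scramble: bool = False

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if set(self.ranges) != set(DEFAULT_RANGES):
            raise ValueError(f"ranges must cover exactly {sorted(DEFAULT_RANGES)}")
        for k, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"empty range for {k}")


def sobol_parameters(spec: DesignSpec) -> list[ParameterSet]:
    """First ``n_samples`` Sobol points mapped into the parameter ranges.

    The plain (unscrambled) sequence is used by default for reproducibility;
    the all-zeros origin point is skipped so every coordinate is strictly
    inside its range.
    """
    spec.validate()
    keys = list(DEFAULT_RANGES)
    sampler = qmc.Sobol(d=len(keys), scramble=spec.scramble, seed=spec.base_seed)
    sampler.fast_forward(1)  # skip the origin
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draw
        unit = sampler.random(spec.n_samples)
    lo = np.array([spec.ranges[k][0] for k in keys])
    hi = np.array([spec.ranges[k][1] for k in keys])
    points = lo + unit * (hi - lo)
    out = []
    for i, row in enumerate(points):
        kwargs = dict(zip(keys, row))
        out.append(
            ParameterSet(
                param_id=i,
                psi=spec.psi,
                Kc=spec.Kc,
                mu_t=spec.mu_t,
                mu_d=spec.mu_d,
                **kwargs,
            )
        )
    return out


def derive_seed(base_seed: int, param_id, model: str) -> int:
    """Stable per-run seed from (base seed, parameter id, model label).

    Uses SHA-256 rather than language hashing so seeds are reproducible
    across runs and platforms; result is < 2**31.
    """
    digest = hashlib.sha256(f"{base_seed}:{param_id}:{model}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_ensemble(
    parameter_sets: list[ParameterSet],
    models: tuple[str, ...] = MODELS,
    landscape: LandscapeSeries | None = None,
    base_seed: int = 0,
    richness_min: int = 20,
    richness_max: int = 6000,
    init: InitSpec | None = None,
    out_dir: str | Path | None = None,
    keep_results: bool = False,
    progress: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Run every (parameter set, model) pair and collect summary vectors.

    Returns an ensemble table with one row per run: parameter echo, model
    label, completion flag and reason, richness, and the summary statistics of
    completed runs.  Per-run seeds derive from ``base_seed`` via
    :func:`derive_seed` and are collision-checked.  With ``out_dir`` set, rows
    are cached per run as CSV so an interrupted campaign is restartable.
    With ``keep_results`` the raw :class:`SimulationResult` objects are also
    returned, keyed by ``(param_id, model)``.
    """
    if landscape is None:
        raise ValueError("an explicit landscape is required")
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}")
    seeds = {}
    for ps in parameter_sets:
        for m in models:
            seeds[(ps.param_id, m)] = derive_seed(base_seed, ps.param_id, m)
    if len(set(seeds.values())) != len(seeds):
        raise RuntimeError("derived seed collision across the ensemble")

    cache_dir = Path(out_dir) / "runs" if out_dir is not None else None
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    results = {}
    for ps in parameter_sets:
        for m in models:
            run_key = f"param{ps.param_id}_{m}"
            cache_file = cache_dir / f"{run_key}.csv" if cache_dir is not None else None
            if cache_file is not None and cache_file.exists() and not keep_results:
                rows.append(pd.read_csv(cache_file).iloc[0].to_dict())
                continue
            from dataclasses import replace

            params = replace(ps, model=m, seed=seeds[(ps.param_id, m)])
            result = run_simulation(
                params,
                landscape,
                init=init,
                richness_min=richness_min,
                richness_max=richness_max,
            )
            row = {
                "param_id": ps.param_id,
                "model": m,
                "seed": params.seed,
                "completed": result.completed,
                "reason": result.reason,
                "n_species": result.richness,
                "S": ps.S,
                "lambda_": ps.lambda_,
                "omega": ps.omega,
                "sigma_B": ps.sigma_B,
                "sigma_T": ps.sigma_T,
                "phi": ps.phi,
            }
            if result.completed:
                vector = summarize(bundle_from_result(result))
                row.update(vector.values)
            rows.append(row)
            if keep_results:
                results[(ps.param_id, m)] = result
            if cache_file is not None:
                pd.DataFrame([row]).to_csv(cache_file, index=False)
            if progress:
                print(f"{run_key}: richness={result.richness} ({result.reason})")
    table = pd.DataFrame(rows)
    if keep_results:
        return table, results
    return table


#: columns of the ensemble table that are not summary statistics
META_COLUMNS = (
    "param_id",
    "model",
    "seed",
    "completed",
    "reason",
    "n_species",
    "S",
    "lambda_",
    "omega",
    "sigma_B",
    "sigma_T",
    "phi",
)


def completeness_filter(table: pd.DataFrame, models: tuple[str, ...] = MODELS) -> pd.DataFrame:
    """Keep only parameter ids complete under all requested models.

    The result has equal class counts across models and drops rows of
    incomplete runs; it is invariant to the input row order.
    """
    if table.empty:
        raise ValueError("ensemble table is empty")
    ok = table[table["completed"].astype(bool)]
    counts = ok.groupby("param_id")["model"].nunique()
    keep_ids = set(counts[counts == len(models)].index)
    out = table[table["param_id"].isin(keep_ids) & table["completed"].astype(bool)]
    return out.sort_values(["param_id", "model"]).reset_index(drop=True)


def export_pseudo_empirical(result, out_dir: str | Path) -> Path:
    """Write a completed run as an on-disk clade bundle.

    The bundle (extant-tree Newick + occupancy/traits/cells CSVs) stands in
    for empirical clade data so the model-selection path can be exercised
    without any external download.  Extinct tips are excluded.
    """
    if not result.completed:
        raise ValueError(f"cannot export incomplete simulation ({result.reason})")
    return write_bundle(bundle_from_result(result), out_dir)
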