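"""Clade-level biodiversity summary statistics.

Computes the multidimensional summary-statistic vector used for
simulation-based inference: species-specific phylogenetic tip metrics (ES, DR,
ED, MRD) and their trait correlations, spatial assemblage metrics (richness,
PD, MPD, MNTD, body-size moments) and their environmental correlations,
trait-distribution moments, and tree size/shape (gamma, Sackin, clade size).

A clade enters as a :class:`CladeBundle` — a phylogeny plus species-by-cell
occupancy, per-species body size, and per-cell temperature/latitude — either
built from a simulation result or read from disk (Newick + CSV tables, the
same dialect used for pseudo-empirical fixtures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CladeBundle",
    "SummaryVector",
    "bundle_from_result",
    "tip_metrics",
    "patristic_matrix",
    "assemblage_metrics",
    "tree_shape",
    "species_spatial_traits",
    "trait_distribution_stats",
    "correlation_suite",
    "summarize",
    "collinearity_filter",
    "write_bundle",
    "read_bundle",
]

CATEGORIES = ("phylo_corr", "spatial_corr", "trait_dist", "tree_shape")

#: cell-level divergence metrics (MPD, MNTD, SD) need at least two species
_MIN_SPECIES_DIVERGENCE = 2


@dataclass
class CladeBundle:
    """One clade: tree + occupancy + body size + cell environment."""

    tree: dendropy.Tree
    occupancy: pd.DataFrame  # columns: species_id, cell_row, cell_col
    body_size: pd.Series  # index: species_id
    cells: pd.DataFrame  # columns: cell_row, cell_col, temperature, latitude

    def __post_init__(self) -> None:
        self._prune_to_common()

    def _prune_to_common(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        occ_sp = set(self.occupancy["species_id"].astype(str))
        bs_sp = set(self.body_size.index.astype(str))
        common = tips & occ_sp & bs_sp
        if len(common) < 2:
            raise ValueError("fewer than 2 species shared by tree, occupancy and traits")
        dropped = (tips | occ_sp | bs_sp) - common
        if dropped:
            warnings.warn(f"pruning {len(dropped)} species without matching data")
            if tips - common:
                self.tree = self.tree.extract_tree_with_taxa_labels(
                    sorted(common), suppress_unifurcations=True
                )
            occ = self.occupancy[self.occupancy["species_id"].astype(str).isin(common)]
            self.occupancy = occ.reset_index(drop=True)
            self.body_size = self.body_size[self.body_size.index.astype(str).isin(common)]

    @property
    def species(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_species(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


@dataclass
class SummaryVector:
    """Named clade-level statistics with category tags."""

    values: dict[str, float]
    categories: dict[str, str]
    n_species: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)

    def by_category(self, category: str) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.categories[k] == category}


# ---------------------------------------------------------------------------
# phylogenetic tip metrics
# ---------------------------------------------------------------------------


def tip_metrics(tree: dendropy.Tree) -> pd.DataFrame:
    """Per-tip ES, DR, ED and MRD.

    ES (equal splits) divides each edge's contribution by the number of
    daughter lineages at every split between the edge and the tip, the pendant
    edge undivided; DR = 1/ES.  ED is the fair-proportion measure: each edge's
    length split equally among its descendant tips.  MRD is the topological
    root distance (number of nodes passed from root to tip).
    """
    n_below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_below[id(node)] = 1
        else:
            n_below[id(node)] = sum(n_below[id(c)] for c in node.child_nodes())
    rows = {}
    for leaf in tree.leaf_node_iter():
        es = 0.0
        ed = 0.0
        depth = 0
        div = 1.0
        node = leaf
        while node.parent_node is not None:
            length = node.edge.length or 0.0
            es += length / div
            ed += length / n_below[id(node)]
            depth += 1
            parent = node.parent_node
            div *= max(len(parent.child_nodes()), 2)
            node = parent
        dr = 1.0 / es if es > 0 else np.nan
        rows[leaf.taxon.label] = {"ES": es, "DR": dr, "ED": ed, "MRD": float(depth)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species_id"
    return df.sort_index()


def patristic_matrix(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Pairwise patristic distances, computed from MRCA root distances."""
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    order = np.argsort(labels)
    leaves = [leaves[i] for i in order]
    labels = [labels[i] for i in order]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    rd = np.zeros(n)
    root_dist: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else root_dist[id(parent)] + (node.edge.length or 0.0)
        root_dist[id(node)] = d
        if node.is_leaf():
            rd[index[id(node)]] = d
    tips_below: dict = {}
    D = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = np.array([index[id(node)]])
            continue
        child_sets = [tips_below[id(c)] for c in node.child_nodes()]
        d_node = root_dist[id(node)]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                a, b = child_sets[i], child_sets[j]
                block = rd[a][:, None] + rd[b][None, :] - 2.0 * d_node
                D[np.ix_(a, b)] = block
                D[np.ix_(b, a)] = block.T
        tips_below[id(node)] = np.concatenate(child_sets)
    return D, labels


# ---------------------------------------------------------------------------
# assemblage (grid-cell) metrics
# ---------------------------------------------------------------------------


def _presence_matrix(bundle: CladeBundle, labels: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
    cells = bundle.cells.reset_index(drop=True)
    cell_index = {
        (r, c): i for i, (r, c) in enumerate(zip(cells["cell_row"], cells["cell_col"]))
    }
    sp_index = {s: i for i, s in enumerate(labels)}
    P = np.zeros((len(labels), len(cells)), dtype=bool)
    for sp, r, c in zip(
        bundle.occupancy["species_id"].astype(str),
        bundle.occupancy["cell_row"],
        bundle.occupancy["cell_col"],
    ):
        ci = cell_index.get((r, c))
        si = sp_index.get(sp)
        if ci is not None and si is not None:
            P[si, ci] = True
    return P, cells


def assemblage_metrics(bundle: CladeBundle) -> pd.DataFrame:
    """Per-cell richness, PD, MPD, MNTD and body-size moments.

    PD is the total branch length of the minimal spanning subtree including
    the root; MPD/MNTD are the mean pairwise / mean nearest-taxon patristic
    distances.  Divergence-based metrics need >= 2 species; cells below that
    minimum yield NaN and are excluded pairwise downstream.
    """
    D, labels = patristic_matrix(bundle.tree)
    P, cells = _presence_matrix(bundle, labels)
    n_cells = P.shape[1]
    richness = P.sum(axis=0).astype(float)

    # edge x tip incidence for PD
    leaf_idx = {l: i for i, l in enumerate(labels)}
    tips_below: dict = {}
    edges = []
    for node in bundle.tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = [leaf_idx[node.taxon.label]]
        else:
            acc: list[int] = []
            for c in node.child_nodes():
                acc.extend(tips_below[id(c)])
            tips_below[id(node)] = acc
        if node.parent_node is not None:
            edges.append((node.edge.length or 0.0, tips_below[id(node)]))
    lengths = np.array([e[0] for e in edges])
    M = np.zeros((len(edges), len(labels)), dtype=bool)
    for i, (_, below) in enumerate(edges):
        M[i, below] = True
    pd_cell = lengths @ ((M @ P) > 0)
    pd_cell = np.where(richness >= 1, pd_cell, np.nan)

    bs_vec = bundle.body_size.astype(float).reindex(labels).to_numpy()
    mean_bs = np.full(n_cells, np.nan)
    sd_bs = np.full(n_cells, np.nan)
    mpd = np.full(n_cells, np.nan)
    mntd = np.full(n_cells, np.nan)
    for c in range(n_cells):
        present = np.flatnonzero(P[:, c])
        k = present.size
        if k == 0:
            continue
        mean_bs[c] = bs_vec[present].mean()
        if k >= _MIN_SPECIES_DIVERGENCE:
            sd_bs[c] = bs_vec[present].std(ddof=1)
            sub = D[np.ix_(present, present)]
            iu = np.triu_indices(k, 1)
            mpd[c] = sub[iu].mean()
            np.fill_diagonal(sub, np.inf)
            mntd[c] = sub.min(axis=1).mean()
    out = cells.copy()
    out["richness"] = richness
    out["PD"] = pd_cell
    out["MPD"] = mpd
    out["MNTD"] = mntd
    out["mean_body_size"] = mean_bs
    out["sd_body_size"] = sd_bs
    return out


# ---------------------------------------------------------------------------
# tree size and shape
# ---------------------------------------------------------------------------


def tree_shape(tree: dendropy.Tree) -> dict[str, float]:
    """Gamma (Pybus-Harvey), Sackin index (mean tip depth) and clade size.

    Gamma requires >= 3 tips and an ultrametric tree; on non-ultrametric input
    it is computed from the node heights as-is, with a warning.
    """
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    root_dist: dict = {}
    depths = []
    internal = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else root_dist[id(parent)] + (node.edge.length or 0.0)
        root_dist[id(node)] = d
        if node.is_leaf():
            depths.append(d)
        else:
            internal.append(d)
    tip_topo = []
    for leaf in leaves:
        depth = 0
        node = leaf
        while node.parent_node is not None:
            depth += 1
            node = node.parent_node
        tip_topo.append(depth)
    sackin = float(np.sum(tip_topo)) / n

    gamma = np.nan
    if n >= 3 and len(internal) == n - 1:
        T_max = max(depths)
        if max(depths) - min(depths) > 1e-8 * max(T_max, 1.0):
            warnings.warn("tree is not ultrametric; gamma computed on node heights as-is")
        x = np.sort(np.asarray(internal, dtype=float))
        # interval with k lineages runs between consecutive node heights
        bounds = np.concatenate([x, [T_max]])
        g = np.diff(bounds)  # g_k for k = 2..n
        ks = np.arange(2, n + 1)
        T_i = np.cumsum(ks * g)  # T_i for i = 2..n
        T_total = T_i[-1]
        if T_total > 0:
            mean_part = T_i[:-1].sum() / (n - 2)
            gamma = (mean_part - T_total / 2.0) / (T_total * np.sqrt(1.0 / (12.0 * (n - 2))))
    return {"gamma": float(gamma), "sackin": float(sackin), "clade_size": float(n)}


# ---------------------------------------------------------------------------
# species-level spatial traits and trait distributions
# ---------------------------------------------------------------------------


def species_spatial_traits(bundle: CladeBundle) -> pd.DataFrame:
    """Per-species range size, mean range temperature and mean |latitude|.

    The temperature niche is the unweighted mean of cell temperature over the
    species' occupied cells.
    """
    cells = bundle.cells.set_index(["cell_row", "cell_col"])
    occ = bundle.occupancy.copy()
    occ["species_id"] = occ["species_id"].astype(str)
    joined = occ.join(cells, on=["cell_row", "cell_col"])
    grp = joined.groupby("species_id")
    out = pd.DataFrame(
        {
            "range_size": grp.size().astype(float),
            "mean_range_temperature": grp["temperature"].mean(),
            "mean_abs_latitude": grp["latitude"].apply(lambda s: float(np.abs(s).mean())),
        }
    )
    return out.sort_index()


def trait_distribution_stats(values) -> dict[str, float]:
    """Moment summary of a trait distribution.

    Skewness is the adjusted Fisher-Pearson estimator (n >= 3), kurtosis is
    bias-corrected excess kurtosis (n >= 4); both are NaN for degenerate
    (zero-variance) input.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    out = {"mean": np.nan, "sd": np.nan, "skewness": np.nan, "kurtosis": np.nan, "range": np.nan}
    if n == 0:
        return out
    out["mean"] = float(x.mean())
    out["range"] = float(x.max() - x.min())
    if n >= 2:
        out["sd"] = float(x.std(ddof=1))
    if not out["sd"] or n < 3:
        return out
    out["skewness"] = float(stats.skew(x, bias=False))
    if n >= 4:
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=False))
    return out


def _spearman(x, y, min_n: int = 3) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_n:
        return np.nan
    if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
        return np.nan
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def correlation_suite(
    assemblage: pd.DataFrame,
    tips: pd.DataFrame,
    species_traits: pd.DataFrame,
    body_size: pd.Series,
) -> tuple[dict[str, float], dict[str, str]]:
    """Named Spearman coefficients across cells and across species.

    Cell-level: richness/PD/MPD/MNTD/mean/SD body size against absolute
    latitude and against temperature.  Species-level: each tip metric against
    body size, range temperature and range size, plus the macroecological
    trait correlations (range size vs temperature and |latitude|, body size vs
    temperature).  Ties get average ranks; coefficients with fewer than 3
    paired observations are NaN.
    """
    values: dict[str, float] = {}
    cats: dict[str, str] = {}
    abslat = np.abs(assemblage["latitude"].to_numpy())
    temp_cell = assemblage["temperature"].to_numpy()
    for metric in ("richness", "PD", "MPD", "MNTD", "mean_body_size", "sd_body_size"):
        col = assemblage[metric].to_numpy()
        values[f"cor_{metric}_abslat"] = _spearman(col, abslat)
        values[f"cor_{metric}_temperature"] = _spearman(col, temp_cell)
        cats[f"cor_{metric}_abslat"] = "spatial_corr"
        cats[f"cor_{metric}_temperature"] = "spatial_corr"

    sp = species_traits.join(tips, how="inner")
    sp = sp.join(body_size.rename("body_size").astype(float), how="inner")
    for metric in ("ES", "DR", "ED", "MRD"):
        for trait, col in (
            ("body_size", sp["body_size"]),
            ("temperature", sp["mean_range_temperature"]),
            ("range_size", sp["range_size"]),
            ("abslat", sp["mean_abs_latitude"]),
        ):
            name = f"cor_{metric}_{trait}"
            values[name] = _spearman(sp[metric], col)
            cats[name] = "phylo_corr"

    for name, (a, b) in {
        "cor_body_size_temperature": (sp["body_size"], sp["mean_range_temperature"]),
        "cor_range_size_temperature": (sp["range_size"], sp["mean_range_temperature"]),
        "cor_range_size_abslat": (sp["range_size"], sp["mean_abs_latitude"]),
    }.items():
        values[name] = _spearman(a, b)
        cats[name] = "trait_dist"
    return values, cats


# ---------------------------------------------------------------------------
# the full summary vector
# ---------------------------------------------------------------------------


def summarize(bundle: CladeBundle) -> SummaryVector:
    """Assemble the clade's full summary-statistic vector.

    Deterministic given the bundle and invariant to species/cell ordering.
    Statistics whose preconditions fail are NaN (missing), never dropped.
    """
    tips = tip_metrics(bundle.tree)
    assemblage = assemblage_metrics(bundle)
    sp_traits = species_spatial_traits(bundle)
    shape = tree_shape(bundle.tree)

    values, cats = correlation_suite(assemblage, tips, sp_traits, bundle.body_size)

    for prefix, series in (
        ("body_size", bundle.body_size.astype(float)),
        ("temp_niche", sp_traits["mean_range_temperature"]),
    ):
        m = trait_distribution_stats(series.to_numpy())
        for k in ("mean", "sd", "skewness", "kurtosis", "range"):
            values[f"{prefix}_{k}"] = m[k]
            cats[f"{prefix}_{k}"] = "trait_dist"
    m = trait_distribution_stats(sp_traits["range_size"].to_numpy())
    for k in ("mean", "sd", "skewness"):
        values[f"range_size_{k}"] = m[k]
        cats[f"range_size_{k}"] = "trait_dist"

    for k, v in shape.items():
        values[k] = v
        cats[k] = "tree_shape"

    return SummaryVector(values=values, categories=cats, n_species=bundle.n_species)


def collinearity_filter(matrix: pd.DataFrame, threshold: float = 0.90) -> list[str]:
    """Drop one member of every statistic pair with |Pearson r| above
    ``threshold`` until none remains; returns the retained column names.

    Constant columns are dropped first.  Each round resolves the highest-|r|
    pair by dropping the member with the larger mean absolute correlation to
    all remaining columns (alphabetical tie-break), so the result is
    deterministic and independent of input column order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need >= 2 columns and >= 3 rows")
    df = matrix.copy()
    constant = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"dropping constant columns: {sorted(constant)}")
        df = df.drop(columns=constant)
    df = df[sorted(df.columns)]
    while df.shape[1] >= 2:
        corr = df.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if np.nanmax(corr.values) <= threshold:
            break
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        a, b = str(corr.columns[i]), str(corr.columns[j])
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b or (mean_a == mean_b and a > b):
            drop = a
        else:
            drop = b
        df = df.drop(columns=[drop])
    return list(df.columns)


def speciation_rate_centroid(bundle: CladeBundle) -> float:
    """Latitude centroid of high speciation rates.

    Each occupied cell gets the mean DR of the species present; the centroid
    is the DR-weighted mean absolute latitude over occupied cells.  Smaller
    values mean speciation rates concentrate toward the equator.
    """
    tips = tip_metrics(bundle.tree)
    D_labels = sorted(tips.index)
    P, cells = _presence_matrix(bundle, D_labels)
    dr = tips["DR"].reindex(D_labels).to_numpy()
    weights = []
    lats = []
    for c in range(P.shape[1]):
        present = np.flatnonzero(P[:, c])
        if present.size == 0:
            continue
        vals = dr[present]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        weights.append(vals.mean())
        lats.append(abs(float(cells["latitude"].iloc[c])))
    if not weights:
        return float("nan")
    w = np.asarray(weights)
    return float((w * np.asarray(lats)).sum() / w.sum())


# ---------------------------------------------------------------------------
# bundles from simulation results and on disk
# ---------------------------------------------------------------------------


def bundle_from_result(result) -> CladeBundle:
    """Build a :class:`CladeBundle` from a finished simulation result."""
    newick = result.phylogeny.to_newick(extant_only=True)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    n_rows, n_cols = result.final_temperature01.shape
    occ_rows = []
    bs = {}
    for sp in result.final_species:
        label = f"s{sp.species_id}"
        bs[label] = float(sp.B.mean())
        rows, cols = np.divmod(sp.sites, n_cols)
        for r, c in zip(rows, cols):
            occ_rows.append((label, int(r), int(c)))
    occupancy = pd.DataFrame(occ_rows, columns=["species_id", "cell_row", "cell_col"])
    temp = result.final_temperature01
    cell_rows = [
        (r, c, float(temp[r, c]), float(result.latitude_deg[r]))
        for r in range(n_rows)
        for c in range(n_cols)
        if np.isfinite(temp[r, c])
    ]
    cells = pd.DataFrame(cell_rows, columns=["cell_row", "cell_col", "temperature", "latitude"])
    return CladeBundle(
        tree=tree,
        occupancy=occupancy,
        body_size=pd.Series(bs, name="body_size"),
        cells=cells,
    )


def write_bundle(bundle: CladeBundle, out_dir: str | Path) -> Path:
    """Write a bundle as Newick + occupancy/traits/cells CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(bundle.tree.as_string(schema="newick", suppress_rooting=True))
    bundle.occupancy.to_csv(out / "occupancy.csv", index=False)
    bundle.body_size.rename("body_size").to_csv(out / "traits.csv", index_label="species_id")
    bundle.cells.to_csv(out / "cells.csv", index=False)
    return out


def read_bundle(in_dir: str | Path) -> CladeBundle:
    """Read a bundle written by :func:`write_bundle`."""
    p = Path(in_dir)
    tree = dendropy.Tree.get(path=str(p / "tree.nwk"), schema="newick")
    occupancy = pd.read_csv(p / "occupancy.csv")
    traits = pd.read_csv(p / "traits.csv").set_index("species_id")["body_size"]
    traits.index = traits.index.astype(str)
    cells = pd.read_csv(p / "cells.csv")
    return CladeBundle(tree=tree, occupancy=occupancy, body_size=traits, cells=cells)
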