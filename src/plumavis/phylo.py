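"""Phylogenies and the tree-resampled Bayesian phylogenetic mixed model.

Phylogenetic uncertainty is handled by marginalizing over a posterior
sample of candidate ultrametric trees: at each outer iteration a tree is
drawn from the sample, the Gibbs chain for the linear mixed model

    y = X beta + Z_p u_p + Z_s u_s + e,
    u_p ~ N(0, sigma2_phylo * C(tree)),   u_s ~ N(0, sigma2_species * I),
    e   ~ N(0, sigma2_resid * I),

is advanced (warm-started from the previous outer step) for a fixed
number of sweeps, and the final state is stored.  C(tree) is the Brownian
expectation: corr(i, j) = shared root-to-MRCA path length divided by tree
height.  The phylogenetic signal per stored state is the variance share

    lambda = sigma2_phylo / (sigma2_phylo + sigma2_species + sigma2_resid).

Fixed effects get a diffuse normal prior, variance components
inverse-gamma priors; all hyperparameters are configurable.  Summaries
use shortest 95% highest-posterior-density (HPD) intervals; an effect is
"significant" when its HPD excludes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from plumavis.spectra import PATCHES

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeSamplePosterior:
    """An ordered sample of rooted ultrametric trees over one tip set."""

    trees: list
    taxon_labels: tuple

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def _leaf_depths(tree) -> dict:
    depths = {}
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.root_distance
    return depths


def tree_height(tree) -> float:
    return max(_leaf_depths(tree).values())


def is_ultrametric(tree, rel_tol: float = 1e-6) -> bool:
    depths = np.array(list(_leaf_depths(tree).values()))
    h = depths.max()
    return bool(np.all(h - depths <= rel_tol * h))


def make_ultrametric(tree, rel_tol: float = 1e-3):
    """Rescale tip branches so all root-to-tip depths equal the height.

    Trees within ``rel_tol`` (relative to height) of ultrametric are
    adjusted by extending each terminal branch; larger deviations raise.
    """
    depths = _leaf_depths(tree)
    h = max(depths.values())
    worst = max(h - d for d in depths.values())
    if worst <= 1e-12 * max(h, 1.0):
        return tree
    if worst > rel_tol * h:
        raise ValueError(
            f"tree deviates from ultrametric by {worst:.4g} (> {rel_tol} of height {h:.4g})"
        )
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += h - depths[leaf.taxon.label]
    logger.info("re-ultrametrized tree (max tip adjustment %.3g)", worst)
    return tree


def read_trees(path) -> TreeSamplePosterior:
    """Read a multi-tree file (Newick one-per-line, or NEXUS).

    All trees must share one tip-label set; near-ultrametric trees
    (within 1e-3 of height) are rescaled to exactly ultrametric.
    """
    with open(path) as fh:
        head = fh.read(64)
    schema = "nexus" if head.lstrip().lower().startswith("#nexus") else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    if len(tl) == 0:
        raise ValueError(f"{path}: no trees found")
    ref = frozenset(l.taxon.label for l in tl[0].leaf_node_iter())
    for i, t in enumerate(tl):
        tips = frozenset(l.taxon.label for l in t.leaf_node_iter())
        if tips != ref:
            extra = sorted(tips - ref)
            missing = sorted(ref - tips)
            raise ValueError(
                f"{path}: tree {i + 1} tip set differs from tree 1 "
                f"(extra: {extra}, missing: {missing})"
            )
        make_ultrametric(t)
    return TreeSamplePosterior(trees=list(tl), taxon_labels=tuple(sorted(ref)))


def write_trees(posterior: TreeSamplePosterior, path) -> None:
    with open(path, "w") as fh:
        for t in posterior.trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def graft_subspecies(tree, species_tip: str, subspecies, bl: float = 0.025):
    """Graft subspecies tips as the closest relatives of a nominal species.

    The species tip becomes a clade: a new node at depth (tip depth - bl)
    whose children are the nominal species and each subspecies, all with
    terminal branch length ``bl`` (a polytomy for two or more subspecies).
    Ultrametricity and all uninvolved pairwise distances are preserved.
    Operates in place and returns the tree.
    """
    if isinstance(subspecies, str):
        subspecies = [subspecies]
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == species_tip:
            node = leaf
            break
    if node is None:
        raise ValueError(f"species tip {species_tip!r} not in tree")
    if node.edge.length is None or bl >= node.edge.length:
        raise ValueError(
            f"branch length {bl} must be smaller than the terminal branch "
            f"of {species_tip!r} ({node.edge.length}); use a smaller bl"
        )
    ns = tree.taxon_namespace
    sp_taxon = node.taxon
    node.taxon = None
    node.edge.length -= bl
    child = dendropy.Node(edge_length=bl)
    child.taxon = sp_taxon
    node.add_child(child)
    for label in subspecies:
        c = dendropy.Node(edge_length=bl)
        c.taxon = ns.require_taxon(label=label)
        node.add_child(c)
    return tree


def graft_posterior(
    posterior: TreeSamplePosterior, grafting: pd.DataFrame, bl: float = 0.025
) -> TreeSamplePosterior:
    """Apply a species -> subspecies grafting table to every tree (on clones)."""
    out = []
    for t in posterior.trees:
        clone = t.clone(depth=1)
        for species, grp in grafting.groupby("species"):
            graft_subspecies(clone, species, grp["subspecies"].tolist(), bl=bl)
        out.append(clone)
    labels = set(posterior.taxon_labels) | set(grafting["subspecies"])
    return TreeSamplePosterior(trees=out, taxon_labels=tuple(sorted(labels)))


def phylo_covariance(tree, labels=None) -> tuple[list, np.ndarray]:
    """Brownian correlation structure of an ultrametric tree.

    Entry (i, j) is the root-to-MRCA shared path length divided by tree
    height; the diagonal is 1.  Returns (labels, matrix) with labels
    sorted unless given.
    """
    depths = _leaf_depths(tree)
    h = max(depths.values())
    if labels is None:
        labels = sorted(depths)
    else:
        missing = [l for l in labels if l not in depths]
        if missing:
            raise ValueError(f"taxa not in tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    k = len(labels)
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            C[i, j] = C[j, i] = 1.0 - d / (2.0 * h)
    return list(labels), C


# ---------------------------------------------------------------------------
# HPD intervals


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted samples.

    Ties between equal-width windows break toward the lowest lower bound.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < 20:
        raise ValueError(f"need at least 20 samples for an HPD interval, got {n}")
    k = int(np.ceil(mass * n))
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))  # first minimum = lowest lower bound
    return float(s[i]), float(s[i + k - 1])


# ---------------------------------------------------------------------------
# Model specification and design


@dataclass
class ModelSpec:
    """Fixed and random structure of the phylogenetic mixed model.

    Fixed effects: the vegetation PC, patch (categorical over the 7-patch
    vocabulary, treatment-coded), the PC x patch interaction, and
    optionally latitude.  Random effects: a phylogenetic taxon effect and
    a species-identity effect (subspecies of one species share a level).
    ``species_map`` maps taxon_id -> species; identity when None.
    """

    response: str
    pc_col: str = "vegetation_pc"
    latitude_col: str | None = "latitude"
    patch_col: str = "patch"
    taxon_col: str = "taxon_id"
    species_map: dict | None = None

    def species_of(self, taxon: str) -> str:
        if self.species_map is None:
            return taxon
        return self.species_map.get(taxon, taxon)


@dataclass
class Priors:
    tau_beta: float = 1e8       # prior variance of fixed effects
    ig_shape: float = 0.001     # inverse-gamma shape for variances
    ig_scale: float = 0.001     # inverse-gamma scale for variances


@dataclass
class PosteriorSummary:
    """Stored states, parameter summaries and phylogenetic-signal samples."""

    samples: pd.DataFrame
    summary: pd.DataFrame
    lambda_mean: float
    lambda_hpd: tuple
    patch_slopes: pd.DataFrame
    n_stored: int


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrices for the mixed model.

    Returns (y, X, colnames, taxon_idx, species_idx, taxa, species,
    patch_levels).  Patch uses treatment coding with the first observed
    patch (in canonical patch order) as reference; interaction columns
    with no data are dropped and the result must be full rank.
    """
    present = [p for p in PATCHES if p in set(data[spec.patch_col])]
    extra = sorted(set(data[spec.patch_col]) - set(PATCHES))
    if extra:
        raise ValueError(f"unknown patches {extra}")
    ref = present[0]
    y = data[spec.response].to_numpy(dtype=float)
    pc = data[spec.pc_col].to_numpy(dtype=float)
    cols = [np.ones(len(data)), pc]
    names = ["intercept", "pc"]
    for p in present[1:]:
        d = (data[spec.patch_col] == p).to_numpy(dtype=float)
        cols.append(d)
        names.append(f"patch[{p}]")
    for p in present[1:]:
        d = (data[spec.patch_col] == p).to_numpy(dtype=float) * pc
        if np.all(d == 0):
            logger.warning("dropping empty interaction cell pc:%s", p)
            continue
        cols.append(d)
        names.append(f"pc:patch[{p}]")
    if spec.latitude_col is not None:
        cols.append(data[spec.latitude_col].to_numpy(dtype=float))
        names.append("latitude")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    taxa = sorted(set(data[spec.taxon_col]))
    species = sorted({spec.species_of(t) for t in taxa})
    tmap = {t: i for i, t in enumerate(taxa)}
    smap = {s: i for i, s in enumerate(species)}
    taxon_idx = np.array([tmap[t] for t in data[spec.taxon_col]], dtype=np.int64)
    species_idx = np.array(
        [smap[spec.species_of(t)] for t in data[spec.taxon_col]], dtype=np.int64
    )
    return y, X, names, taxon_idx, species_idx, taxa, species, (ref, present)


# ---------------------------------------------------------------------------
# Gibbs sampler


def gibbs_sweep(state, y, X, taxon_idx, species_idx, Ainv, dp, ds, priors, rng):
    """One full Gibbs sweep over (beta, u_p, u_s, variances), in place.

    Pure-numpy reference implementation of the full conditionals; the
    production path runs the compiled kernel, which this one validates
    (joint-distribution tests, single-tree cross-checks).
    """
    beta, up, us, s2p, s2s, s2e = (
        state["beta"], state["up"], state["us"],
        state["s2p"], state["s2s"], state["s2e"],
    )
    n, p = X.shape
    q, m = up.size, us.size
    a0, b0 = priors.ig_shape, priors.ig_scale

    r = y - up[taxon_idx] - us[species_idx]
    P = X.T @ X / s2e + np.eye(p) / priors.tau_beta
    L = np.linalg.cholesky(P)
    mu = np.linalg.solve(P, X.T @ r / s2e)
    beta = mu + np.linalg.solve(L.T, rng.standard_normal(p))

    xb = X @ beta
    r2 = y - xb - us[species_idx]
    rhs = np.bincount(taxon_idx, weights=r2, minlength=q) / s2e
    Pp = Ainv / s2p + np.diag(dp / s2e)
    Lp = np.linalg.cholesky(Pp)
    up = np.linalg.solve(Pp, rhs) + np.linalg.solve(Lp.T, rng.standard_normal(q))

    r3 = y - xb - up[taxon_idx]
    rhs_s = np.bincount(species_idx, weights=r3, minlength=m) / s2e
    var_s = 1.0 / (ds / s2e + 1.0 / s2s)
    us = var_s * rhs_s + np.sqrt(var_s) * rng.standard_normal(m)

    e = r3 - us[species_idx]
    s2e = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * (e @ e)))
    s2p = 1.0 / rng.gamma(a0 + 0.5 * q, 1.0 / (b0 + 0.5 * (up @ Ainv @ up)))
    s2s = 1.0 / rng.gamma(a0 + 0.5 * m, 1.0 / (b0 + 0.5 * (us @ us)))

    state.update(beta=beta, up=up, us=us, s2p=s2p, s2s=s2s, s2e=s2e)
    return state


@njit(cache=True)
def _gibbs_kernel(
    y, X, taxon_idx, species_idx, Ainv_all, tree_draws, inner,
    a0, b0, tau_beta, s2p0, s2s0, s2e0, seed, warm_start,
):  # pragma: no cover - exercised via fit_tree_resampled_lmm
    np.random.seed(seed)
    n, p = X.shape
    q = Ainv_all.shape[1]
    m = 0
    for i in range(n):
        if species_idx[i] + 1 > m:
            m = species_idx[i] + 1
    XT = np.ascontiguousarray(X.T)
    XtX = XT @ X
    dp = np.zeros(q)
    ds = np.zeros(m)
    for i in range(n):
        dp[taxon_idx[i]] += 1.0
        ds[species_idx[i]] += 1.0
    outer = tree_draws.size
    store = np.empty((outer, p + 3))
    beta = np.zeros(p)
    up = np.zeros(q)
    us = np.zeros(m)
    s2p, s2s, s2e = s2p0, s2s0, s2e0
    for t in range(outer):
        if not warm_start:
            beta = np.zeros(p)
            up = np.zeros(q)
            us = np.zeros(m)
            s2p, s2s, s2e = s2p0, s2s0, s2e0
        Ainv = Ainv_all[tree_draws[t]]
        for _ in range(inner):
            # fixed effects
            r = y - up[taxon_idx] - us[species_idx]
            P = XtX / s2e + np.eye(p) / tau_beta
            L = np.linalg.cholesky(P)
            mu = np.linalg.solve(P, XT @ r / s2e)
            beta = mu + np.linalg.solve(
                np.ascontiguousarray(L.T), np.random.standard_normal(p)
            )
            xb = X @ beta
            # phylogenetic effect
            r2 = y - xb - us[species_idx]
            rhs = np.zeros(q)
            for i in range(n):
                rhs[taxon_idx[i]] += r2[i]
            Pp = Ainv / s2p
            for j in range(q):
                Pp[j, j] += dp[j] / s2e
            Lp = np.linalg.cholesky(Pp)
            up = np.linalg.solve(Pp, rhs / s2e) + np.linalg.solve(
                np.ascontiguousarray(Lp.T), np.random.standard_normal(q)
            )
            # species effect
            r3 = y - xb - up[taxon_idx]
            rhs_s = np.zeros(m)
            for i in range(n):
                rhs_s[species_idx[i]] += r3[i]
            us_new = np.empty(m)
            for j in range(m):
                v = 1.0 / (ds[j] / s2e + 1.0 / s2s)
                us_new[j] = v * rhs_s[j] / s2e + np.sqrt(v) * np.random.standard_normal()
            us = us_new
            # variances
            e = r3 - us[species_idx]
            s2e = 1.0 / np.random.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * (e @ e)))
            s2p = 1.0 / np.random.gamma(a0 + 0.5 * q, 1.0 / (b0 + 0.5 * (up @ Ainv @ up)))
            s2s = 1.0 / np.random.gamma(a0 + 0.5 * m, 1.0 / (b0 + 0.5 * (us @ us)))
            if not (np.isfinite(s2e) and np.isfinite(s2p) and np.isfinite(s2s)):
                store[0, 0] = np.nan
                return store
        store[t, :p] = beta
        store[t, p] = s2p
        store[t, p + 1] = s2s
        store[t, p + 2] = s2e
    return store


def fit_tree_resampled_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    trees: TreeSamplePosterior,
    outer: int = 1300,
    inner: int = 1000,
    burn: int = 300,
    seed: int | None = None,
    priors: Priors | None = None,
    warm_start: bool = True,
    tree_order: str = "random",
    hpd_mass: float = 0.95,
) -> PosteriorSummary:
    """Fit the phylogenetic mixed model marginalized over a tree posterior.

    At outer step t a tree is drawn from ``trees`` (uniformly with
    replacement by default, or in file order with ``tree_order="sequential"``),
    the Gibbs chain runs ``inner`` sweeps warm-started from the previous
    state, and the final state is stored; the first ``burn`` stored states
    are discarded.  Per-patch marginal slopes of the PC are derived from
    the main effect plus interaction contrasts; each parameter gets a
    mean, a 95% HPD interval and an excludes-zero flag, and lambda (the
    phylogenetic variance share) is summarized per stored state.
    """
    priors = priors or Priors()
    y, X, names, taxon_idx, species_idx, taxa, species, (ref, present) = build_design(
        data, spec
    )
    missing = [t for t in taxa if t not in set(trees.taxon_labels)]
    if missing:
        raise ValueError(f"taxa absent from trees: {missing}")

    rng = np.random.default_rng(seed)
    n_trees = len(trees)
    if tree_order == "sequential":
        draws = np.arange(outer, dtype=np.int64) % n_trees
    else:
        draws = rng.integers(0, n_trees, size=outer).astype(np.int64)

    used = np.unique(draws)
    Ainv_all = np.zeros((n_trees, len(taxa), len(taxa)))
    for ti in used:
        _, C = phylo_covariance(trees[int(ti)], labels=taxa)
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"non-PSD phylogenetic covariance for tree {ti}") from err
        Ainv_all[ti] = np.linalg.inv(C)

    var0 = max(float(np.var(y)), 1e-6)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    store = _gibbs_kernel(
        y, X, taxon_idx, species_idx, Ainv_all, draws, inner,
        priors.ig_shape, priors.ig_scale, priors.tau_beta,
        var0 / 3.0, var0 / 3.0, var0 / 3.0, kernel_seed, warm_start,
    )
    if np.isnan(store[0, 0]):
        raise FloatingPointError(
            "variance draw diverged (overflow); consider tighter priors"
        )
    p = X.shape[1]
    kept = store[burn:]
    cols = dict(zip(names, kept[:, :p].T))
    cols["sigma2_phylo"] = kept[:, p]
    cols["sigma2_species"] = kept[:, p + 1]
    cols["sigma2_resid"] = kept[:, p + 2]
    samples = pd.DataFrame(cols)
    lam = samples["sigma2_phylo"] / (
        samples["sigma2_phylo"] + samples["sigma2_species"] + samples["sigma2_resid"]
    )
    samples["lambda"] = lam

    slope_cols = {}
    for pch in present:
        s = samples["pc"].to_numpy().copy()
        key = f"pc:patch[{pch}]"
        if key in samples:
            s = s + samples[key].to_numpy()
        slope_cols[pch] = s
    patch_slopes = pd.DataFrame(slope_cols)

    rows = []
    for name in list(samples.columns) + [f"slope[{p_}]" for p_ in present]:
        vals = (
            samples[name].to_numpy()
            if name in samples
            else patch_slopes[name[6:-1]].to_numpy()
        )
        lo, hi = hpd_interval(vals, hpd_mass)
        rows.append({
            "parameter": name,
            "mean": float(vals.mean()),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "significant": bool(lo > 0 or hi < 0),
        })
    summary = pd.DataFrame(rows).set_index("parameter")
    lam_hpd = hpd_interval(lam.to_numpy(), hpd_mass)
    return PosteriorSummary(
        samples=samples,
        summary=summary,
        lambda_mean=float(lam.mean()),
        lambda_hpd=lam_hpd,
        patch_slopes=patch_slopes,
        n_stored=len(samples),
    )
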