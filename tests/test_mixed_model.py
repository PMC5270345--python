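"""Validation of the Gibbs sampler behind the phylogenetic mixed model.

The full conditionals are checked with a Geweke-style joint-distribution
test on a six-taxon toy model: moments of parameters drawn from the prior
predictive must match moments from the successive-conditional simulator
(alternate a Gibbs sweep with a redraw of the data given the state).  The
compiled tree-resampling path is cross-checked against the pure-python
reference sweeps on a single-tree posterior.
"""

import numpy as np
import pandas as pd
import pytest

from plumavis import synthetic
from plumavis.phylo import (
    ModelSpec,
    Priors,
    build_design,
    fit_tree_resampled_lmm,
    gibbs_sweep,
    phylo_covariance,
)

PRIORS = Priors(tau_beta=1.0, ig_shape=3.0, ig_scale=2.0)


def _toy_problem(seed=0):
    rng = np.random.default_rng(seed)
    post, _ = synthetic.gen_tree_posterior(n_species=6, n_trees=1, jitter=0.0,
                                           nni_prob=0.0, n_subspecies=0, seed=3)
    taxa = sorted(post.taxon_labels)
    _, C = phylo_covariance(post[0], labels=taxa)
    n_per = 2
    taxon_idx = np.repeat(np.arange(6), n_per)
    species_idx = taxon_idx.copy()
    X = np.column_stack([np.ones(12), rng.standard_normal(12)])
    return X, taxon_idx, species_idx, C, np.linalg.inv(C)


def _draw_prior_state(rng, p, q, m, C):
    s2p = 1.0 / rng.gamma(PRIORS.ig_shape, 1.0 / PRIORS.ig_scale)
    s2s = 1.0 / rng.gamma(PRIORS.ig_shape, 1.0 / PRIORS.ig_scale)
    s2e = 1.0 / rng.gamma(PRIORS.ig_shape, 1.0 / PRIORS.ig_scale)
    return {
        "beta": rng.multivariate_normal(np.zeros(p), PRIORS.tau_beta * np.eye(p)),
        "up": rng.multivariate_normal(np.zeros(q), s2p * C),
        "us": rng.normal(0.0, np.sqrt(s2s), m),
        "s2p": s2p, "s2s": s2s, "s2e": s2e,
    }


def _draw_y(rng, state, X, taxon_idx, species_idx):
    mean = X @ state["beta"] + state["up"][taxon_idx] + state["us"][species_idx]
    return mean + rng.normal(0.0, np.sqrt(state["s2e"]), X.shape[0])


def _moments(records):
    arr = np.asarray(records)
    return arr.mean(axis=0), arr.std(axis=0) / np.sqrt(_ess(arr))


def _ess(arr):
    # crude effective sample size from lag-1 autocorrelation per column
    n = arr.shape[0]
    ess = []
    for j in range(arr.shape[1]):
        x = arr[:, j] - arr[:, j].mean()
        denom = x @ x
        rho = (x[:-1] @ x[1:]) / denom if denom > 0 else 0.0
        rho = min(max(rho, -0.99), 0.99)
        ess.append(n * (1 - rho) / (1 + rho))
    return np.maximum(ess, 10.0)


class TestGewekeJointDistribution:
    def test_prior_predictive_matches_successive_conditional(self):
        X, taxon_idx, species_idx, C, Ainv = _toy_problem()
        p, q, m = X.shape[1], 6, 6
        dp = np.bincount(taxon_idx, minlength=q).astype(float)
        ds = np.bincount(species_idx, minlength=m).astype(float)

        def record(state):
            # bounded transforms keep inverse-gamma tails from dominating
            return [
                state["beta"][0], state["beta"][1],
                np.log(state["s2p"]), np.log(state["s2s"]), np.log(state["s2e"]),
            ]

        rng = np.random.default_rng(101)
        n_draws = 4000
        prior_recs = []
        for _ in range(n_draws):
            prior_recs.append(record(_draw_prior_state(rng, p, q, m, C)))

        rng2 = np.random.default_rng(202)
        state = _draw_prior_state(rng2, p, q, m, C)
        succ_recs = []
        for _ in range(n_draws):
            y = _draw_y(rng2, state, X, taxon_idx, species_idx)
            state = gibbs_sweep(state, y, X, taxon_idx, species_idx, Ainv,
                                dp, ds, PRIORS, rng2)
            succ_recs.append(record(state))

        m1, se1 = _moments(prior_recs)
        m2, se2 = _moments(succ_recs)
        z = (m1 - m2) / np.sqrt(se1**2 + se2**2)
        assert np.all(np.abs(z) < 5.0), f"joint-distribution z-scores {z}"


class TestSingleTreeEquivalence:
    def test_kernel_matches_python_reference_chain(self):
        post, _ = synthetic.gen_tree_posterior(n_species=8, n_trees=1, jitter=0.0,
                                               nni_prob=0.0, n_subspecies=0, seed=5)
        hab = synthetic.gen_habitat(sorted(post.taxon_labels), seed=6)
        data, _ = synthetic.gen_responses(post[0], hab, seed=7)
        spec = ModelSpec(response="response")
        # compiled path: single tree repeated, outer x inner continued chain
        res = fit_tree_resampled_lmm(data, spec, post, outer=150, inner=20,
                                     burn=50, seed=8)
        # reference path: plain python chain of the same total length
        y, X, names, taxon_idx, species_idx, taxa, species, _ = build_design(data, spec)
        _, C = phylo_covariance(post[0], labels=taxa)
        Ainv = np.linalg.inv(C)
        dp = np.bincount(taxon_idx, minlength=len(taxa)).astype(float)
        ds = np.bincount(species_idx, minlength=len(species)).astype(float)
        rng = np.random.default_rng(9)
        v0 = float(np.var(y)) / 3
        state = {
            "beta": np.zeros(X.shape[1]), "up": np.zeros(len(taxa)),
            "us": np.zeros(len(species)), "s2p": v0, "s2s": v0, "s2e": v0,
        }
        priors = Priors()
        keep = []
        for sweep in range(150 * 20):
            state = gibbs_sweep(state, y, X, taxon_idx, species_idx, Ainv,
                                dp, ds, priors, rng)
            if sweep >= 50 * 20 and (sweep + 1) % 20 == 0:
                keep.append([state["beta"][1], state["s2e"]])
        keep = np.asarray(keep)
        pc_ref, s2e_ref = keep[:, 0].mean(), keep[:, 1].mean()
        pc_fit = res.samples["pc"].mean()
        s2e_fit = res.samples["sigma2_resid"].mean()
        se_pc = keep[:, 0].std() / np.sqrt(30) + res.samples["pc"].std() / np.sqrt(30)
        assert abs(pc_fit - pc_ref) < max(4 * se_pc, 0.05)
        assert abs(s2e_fit - s2e_ref) < max(0.5 * s2e_ref, 0.05)


class TestFitBehaviour:
    def test_bit_for_bit_reproducible_given_seed(self, small_posterior):
        post, graft = small_posterior
        from plumavis.phylo import graft_posterior

        gp = graft_posterior(post, graft)
        hab = synthetic.gen_habitat(sorted(gp.taxon_labels), seed=21)
        data, _ = synthetic.gen_responses(gp[0], hab, seed=22)
        spec = ModelSpec(response="response",
                         species_map={t: synthetic.species_of(t) for t in hab.index})
        r1 = fit_tree_resampled_lmm(data, spec, gp, outer=30, inner=30, burn=10, seed=5)
        r2 = fit_tree_resampled_lmm(data, spec, gp, outer=30, inner=30, burn=10, seed=5)
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_missing_taxa_rejected(self, small_posterior):
        post, _ = small_posterior
        hab = synthetic.gen_habitat(list(post.taxon_labels) + ["ghost"], seed=1)
        data, _ = synthetic.gen_responses(post[0], hab.drop("ghost"), seed=2)
        data.loc[0, "taxon_id"] = "ghost"
        data["vegetation_pc"] = data["vegetation_pc"].fillna(0.0)
        spec = ModelSpec(response="response")
        with pytest.raises(ValueError, match="ghost"):
            fit_tree_resampled_lmm(data, spec, post, outer=5, inner=5, burn=1, seed=3)

    def test_summary_flags_match_hpd_sign(self, small_posterior):
        post, graft = small_posterior
        from plumavis.phylo import graft_posterior

        gp = graft_posterior(post, graft)
        hab = synthetic.gen_habitat(sorted(gp.taxon_labels), seed=31)
        data, _ = synthetic.gen_responses(gp[0], hab, seed=32)
        spec = ModelSpec(response="response",
                         species_map={t: synthetic.species_of(t) for t in hab.index})
        res = fit_tree_resampled_lmm(data, spec, gp, outer=60, inner=50, burn=20, seed=33)
        for _, row in res.summary.iterrows():
            assert row["significant"] == (row["hpd_lower"] > 0 or row["hpd_upper"] < 0)
        assert res.n_stored == 40
        lam = res.samples["lambda"]
        assert ((lam >= 0) & (lam <= 1)).all()
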