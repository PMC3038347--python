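"""DIC-based model selection and averaging for occupancy models.

Candidate models are enumerated in two stages: every covariate alone and
in pairs, then all three- and four-way combinations of a shortlist of the
covariates that performed best (lowest DIC) in stage one. Model weights
w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2) are accumulated from
largest to smallest and the smallest prefix reaching cumulative weight 0.9
forms the averaging set. Parameter estimates are averaged with renormalized
weights, absent parameters contributing 0 (the shrinkage convention), and
the unconditional standard deviation combines within-model posterior
spread with between-model disagreement.

The deviance entering DIC uses the latent-state-marginalized likelihood,
so the model focus is (alpha, beta, p); samplers that condition on the
latent states report different absolute DIC values, but rankings are
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata, spearmanr

from .occupancy import (DetectionHistory, OccupancyModelSpec,
                        PosteriorSample, run_mcmc)

__all__ = [
    "ModelComparison",
    "compute_dic",
    "stage1_covariate_sets",
    "enumerate_models",
    "model_weights",
    "select_averaging_set",
    "model_average",
    "model_averaged_prediction",
    "compare_rankings",
    "run_model_selection",
]


@dataclass
class ModelComparison:
    """Result of the selection/averaging stage.

    ``table`` has one row per candidate (covariates, Dbar, pD, DIC, delta,
    weight, in_set); ``averaged`` is the model-averaged parameter summary
    (mean, unconditional sd, importance).
    """

    table: pd.DataFrame
    averaged: pd.DataFrame
    averaging_set: list[tuple[str, ...]]
    weights: np.ndarray


# ------------------------------------------------------------------- DIC

def _log_site_likelihood(coefs, p_draws, X1, det, reps, no_det):
    """(n_draws,) total log marginal likelihood for blocks of draws."""
    eta = coefs @ X1.T                      # (D, n)
    psi = expit(eta)
    logp = np.log(p_draws)                  # (D, M)
    log1mp = np.log1p(-p_draws)
    log_occ = logp @ det + log1mp @ (reps - det)  # (D, n)
    lik = psi * np.exp(log_occ) + (1.0 - psi) * no_det
    with np.errstate(divide="ignore"):
        return np.log(lik).sum(axis=1)


def compute_dic(posterior: PosteriorSample, data: DetectionHistory,
                block: int = 5000):
    """Deviance information criterion from posterior draws.

    D(theta) = -2 sum_i ln L_i with the latent state summed out;
    Dbar is the posterior mean deviance, pD = Dbar - D(theta_bar) with
    theta_bar the posterior means (coefficients on the identity scale,
    detection probabilities on the probability scale), DIC = Dbar + pD.

    Returns ``(Dbar, pD, DIC)``.
    """
    names = posterior.covariate_names
    X1 = np.column_stack(
        [np.ones(data.n_sites)]
        + [data.X[n].to_numpy(float) for n in names]
    )
    methods = list(posterior.methods)
    det = np.array([data.detections(m) for m in methods], dtype=float)
    reps = np.array([data.n_replicates(m) for m in methods], dtype=float)
    no_det = (~data.any_detection()).astype(float)

    coefs = posterior.coef_matrix()
    devs = []
    for start in range(0, len(coefs), block):
        ll = _log_site_likelihood(coefs[start:start + block],
                                  posterior.p[start:start + block],
                                  X1, det, reps, no_det)
        devs.append(-2.0 * ll)
    dev = np.concatenate(devs)
    finite = np.isfinite(dev)
    if not finite.all():
        warnings.warn(f"excluded {int((~finite).sum())} non-finite "
                      "deviance draws")
        dev = dev[finite]
    dbar = float(dev.mean())
    theta_bar = coefs.mean(axis=0, keepdims=True)
    p_bar = posterior.p.mean(axis=0, keepdims=True)
    d_hat = float(-2.0 * _log_site_likelihood(theta_bar, p_bar, X1, det,
                                              reps, no_det)[0])
    pd_ = dbar - d_hat
    return dbar, pd_, dbar + pd_


# ------------------------------------------------------- model enumeration

def stage1_covariate_sets(covariates) -> list[tuple[str, ...]]:
    """All singleton and pair covariate sets (stage one of the search)."""
    covariates = sorted(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    singles = [(c,) for c in covariates]
    pairs = [tuple(sorted(p)) for p in combinations(covariates, 2)]
    return singles + pairs


def enumerate_models(covariates, stage1_dics=None, shortlist_size: int = 7,
                     max_size: int = 4) -> list[tuple[str, ...]]:
    """Full two-stage candidate list.

    Stage one is every covariate alone and in pairs. Covariates are then
    ranked by the best (minimum) DIC over stage-one models containing
    them; the top ``shortlist_size`` form the shortlist, and all subsets
    of sizes 3..``max_size`` of the shortlist are appended (duplicates
    removed). With 12 covariates and a shortlist of 7 this yields
    12 + 66 + 35 + 35 = 148 candidates.

    ``stage1_dics`` maps each stage-one covariate tuple (or frozenset) to
    its DIC; it is required whenever stage two applies (more covariates
    than 2 and a shortlist at least 3).
    """
    covariates = sorted(covariates)
    stage1 = stage1_covariate_sets(covariates)
    if len(covariates) < 3 or max_size < 3:
        return stage1
    if stage1_dics is None:
        raise ValueError("stage1_dics required to build the shortlist")
    dics = {frozenset(k): v for k, v in stage1_dics.items()}
    best = {}
    for c in covariates:
        vals = [v for k, v in dics.items() if c in k]
        if not vals:
            raise ValueError(f"no stage-1 DIC covers covariate {c!r}")
        best[c] = min(vals)
    shortlist = sorted(best, key=lambda c: (best[c], c))[:shortlist_size]
    seen = set(map(frozenset, stage1))
    out = list(stage1)
    for size in range(3, max_size + 1):
        for combo in combinations(sorted(shortlist), size):
            if frozenset(combo) not in seen:
                seen.add(frozenset(combo))
                out.append(tuple(combo))
    return out


# ------------------------------------------------------ weights & averaging

def model_weights(dics) -> np.ndarray:
    """DIC weights: w_i = exp(-Delta_i/2) / sum exp(-Delta_k/2)."""
    dics = np.asarray(dics, dtype=float)
    if not np.isfinite(dics).all():
        raise ValueError("DIC values must be finite")
    delta = dics - dics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def select_averaging_set(weights, cum_target: float = 0.9,
                         model_sizes=None) -> np.ndarray:
    """Indices of the smallest weight-sorted prefix with cumulative weight
    at least ``cum_target``; ties in weight are broken by fewer covariates
    (if sizes are given) then by original order."""
    weights = np.asarray(weights, dtype=float)
    sizes = (np.asarray(model_sizes) if model_sizes is not None
             else np.zeros(len(weights), dtype=int))
    order = sorted(range(len(weights)),
                   key=lambda i: (-weights[i], sizes[i], i))
    cum = 0.0
    chosen = []
    for i in order:
        chosen.append(i)
        cum += weights[i]
        if cum >= cum_target:
            break
    return np.array(chosen, dtype=int)


def model_average(summaries, weights, set_indices) -> pd.DataFrame:
    """Model-averaged parameter estimates over the averaging set.

    ``summaries`` is one mapping per model of parameter name to
    ``(mean, sd)``. Weights are renormalized within the set. A parameter
    absent from a model contributes estimate 0 (and sd 0). The reported SD
    is the unconditional estimator
    ``sum_k w_k sqrt(var_k + (theta_k - theta_avg)^2)`` and importance is
    the summed renormalized weight of models containing the parameter.
    """
    weights = np.asarray(weights, dtype=float)
    set_indices = np.asarray(set_indices, dtype=int)
    w = weights[set_indices]
    w = w / w.sum()
    subset = [summaries[i] for i in set_indices]
    params: list[str] = []
    for s in subset:
        for name in s:
            if name not in params:
                params.append(name)
    rows = []
    for name in params:
        means = np.array([s.get(name, (0.0, 0.0))[0] for s in subset])
        sds = np.array([s.get(name, (0.0, 0.0))[1] for s in subset])
        present = np.array([name in s for s in subset])
        avg = float(w @ means)
        uncond_sd = float(w @ np.sqrt(sds**2 + (means - avg) ** 2))
        rows.append({"parameter": name, "mean": avg, "sd": uncond_sd,
                     "importance": float(w[present].sum())})
    return pd.DataFrame(rows)


def model_averaged_prediction(maps, weights, set_indices) -> np.ndarray:
    """Cell-wise weighted mean of per-model posterior-mean occupancy maps,
    weights renormalized over the averaging set."""
    weights = np.asarray(weights, dtype=float)
    set_indices = np.asarray(set_indices, dtype=int)
    w = weights[set_indices]
    w = w / w.sum()
    out = np.zeros_like(np.asarray(maps[set_indices[0]], dtype=float))
    for wi, i in zip(w, set_indices):
        out = out + wi * np.asarray(maps[i], dtype=float)
    return out


# ------------------------------------------------------------- comparison

def compare_rankings(map_a, map_b, nodata_mask=None):
    """Spearman rank correlation and decile-difference grid for two
    suitability maps on the same grid.

    Each map is rescaled to deciles 1-10 by rank (average ranks for ties)
    over unmasked cells; the returned grid is decile(a) - decile(b), NaN
    at masked cells.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    valid = np.isfinite(a) & np.isfinite(b)
    if nodata_mask is not None:
        valid &= ~np.asarray(nodata_mask, dtype=bool)
    av, bv = a[valid], b[valid]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("rank correlation undefined for a constant map")
    rs = float(spearmanr(av, bv).statistic)

    def deciles(v):
        r = rankdata(v, method="average")
        return np.clip(np.ceil(10.0 * r / len(v)), 1, 10)

    diff = np.full(a.shape, np.nan)
    diff[valid] = deciles(av) - deciles(bv)
    return rs, diff


# ------------------------------------------------------------------ driver

def run_model_selection(data: DetectionHistory, covariates,
                        shortlist_size: int = 7, max_size: int = 4,
                        cum_target: float = 0.9, chains: int = 1,
                        burn_in: int = 500, iterations: int = 2000,
                        prior_beta_sd: float = 10.0, seed=None,
                        progress: bool = False):
    """Fit the full two-stage candidate set and average the best models.

    Per-candidate chain settings default to a reduced single-chain run
    (the candidate sweep only needs DIC rankings); the averaging-set
    posteriors are whatever these settings produce and can be refit at
    full settings downstream if desired.

    Returns ``(ModelComparison, posteriors)`` with ``posteriors`` the
    fitted :class:`PosteriorSample` per candidate, aligned with the table.
    """
    ss = np.random.SeedSequence(seed)

    def fit(covs, child):
        spec = OccupancyModelSpec(covs, prior_beta_sd=prior_beta_sd,
                                  chains=chains, burn_in=burn_in,
                                  iterations=iterations)
        post = run_mcmc(spec, data, seed=child)
        return post, compute_dic(post, data)

    stage1 = stage1_covariate_sets(covariates)
    seeds = iter(ss.spawn(len(stage1)))
    results: dict[tuple[str, ...], tuple] = {}
    for covs in stage1:
        results[covs] = fit(covs, next(seeds))
        if progress:
            print(f"stage1 {covs}: DIC={results[covs][1][2]:.1f}")
    stage1_dics = {k: v[1][2] for k, v in results.items()}
    candidates = enumerate_models(covariates, stage1_dics,
                                  shortlist_size, max_size)
    stage2 = [c for c in candidates if c not in results]
    seeds2 = iter(ss.spawn(len(stage2)))
    for covs in stage2:
        results[covs] = fit(covs, next(seeds2))
        if progress:
            print(f"stage2 {covs}: DIC={results[covs][1][2]:.1f}")

    dics = np.array([results[c][1][2] for c in candidates])
    weights = model_weights(dics)
    sizes = [len(c) for c in candidates]
    set_idx = select_averaging_set(weights, cum_target, sizes)
    in_set = np.zeros(len(candidates), dtype=bool)
    in_set[set_idx] = True

    summaries = []
    for covs in candidates:
        post = results[covs][0]
        s = {"alpha": (post.alpha.mean(), post.alpha.std(ddof=1))}
        for k, name in enumerate(post.covariate_names):
            s[f"beta[{name}]"] = (post.beta[:, k].mean(),
                                  post.beta[:, k].std(ddof=1))
        for k, m in enumerate(post.methods):
            s[f"p[{m}]"] = (post.p[:, k].mean(), post.p[:, k].std(ddof=1))
        summaries.append(s)
    averaged = model_average(summaries, weights, set_idx)

    table = pd.DataFrame({
        "covariates": ["+".join(c) for c in candidates],
        "n_covariates": sizes,
        "Dbar": [results[c][1][0] for c in candidates],
        "pD": [results[c][1][1] for c in candidates],
        "DIC": dics,
        "delta": dics - dics.min(),
        "weight": weights,
        "in_set": in_set,
    }).sort_values("DIC").reset_index(drop=True)
    comparison = ModelComparison(
        table=table,
        averaged=averaged,
        averaging_set=[candidates[i] for i in set_idx],
        weights=weights,
    )
    posteriors = {c: results[c][0] for c in candidates}
    return comparison, posteriors
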