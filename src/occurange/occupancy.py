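"""Bayesian state-space occupancy model with method-specific detection.

The model separates the ecological process from the observation process.
Each site i has a latent occupancy state

    z_i ~ Bernoulli(psi_i),        logit(psi_i) = alpha + x_i' beta,

and each survey replicate j of method m at site i yields

    Y_ijm ~ Bernoulli(z_i * p_m),

so an unoccupied site produces Y = 0 with probability one, and occupied
sites are detected imperfectly with a method-specific probability p_m
(faecal pellet transect, sign survey, camera trap). Priors are vague:
Normal(0, sd^2) on logit-scale coefficients (default sd 10, i.e. variance
100) and Beta(1, 1) on each p_m.

Fitting is by MCMC: Gibbs updates for the latent states z and detection
probabilities p (both conjugate given z), and per-coefficient random-walk
Metropolis for (alpha, beta), with proposal scales adapted only during
burn-in so the retained chain is Markov.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import CovariateSpec, RasterStack

__all__ = [
    "METHODS",
    "DetectionHistory",
    "OccupancyModelSpec",
    "PosteriorSample",
    "composite_detection",
    "site_marginal_likelihood",
    "update_z",
    "update_p",
    "update_beta",
    "run_mcmc",
    "predict_psi",
]

METHODS = ("pellet", "sign", "camera")


@dataclass
class DetectionHistory:
    """Replicate binary survey outcomes per site, grouped by method.

    ``outcomes[m]`` is a float array of shape (n_sites, max_replicates)
    holding 0/1 results, NaN where a replicate was not performed (e.g. no
    cameras at a site). ``X`` holds the per-site standardized covariates.
    """

    site_ids: np.ndarray
    X: pd.DataFrame
    outcomes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        n = len(self.site_ids)
        for m, arr in self.outcomes.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[0] != n:
                raise ValueError(f"outcomes[{m!r}] rows != n_sites")
            vals = arr[np.isfinite(arr)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError(f"outcomes[{m!r}] must be binary")
            self.outcomes[m] = arr
        if len(self.X) != n:
            raise ValueError("covariate rows != n_sites")
        if not np.isfinite(self.X.to_numpy(float)).all():
            raise ValueError("covariates must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def methods(self) -> list[str]:
        return list(self.outcomes)

    def detections(self, method: str) -> np.ndarray:
        """Per-site count of replicates with a detection."""
        return np.nansum(self.outcomes[method], axis=1).astype(int)

    def n_replicates(self, method: str) -> np.ndarray:
        """Per-site count of replicates performed."""
        return np.isfinite(self.outcomes[method]).sum(axis=1).astype(int)

    def any_detection(self) -> np.ndarray:
        out = np.zeros(self.n_sites, dtype=bool)
        for m in self.outcomes:
            out |= self.detections(m) > 0
        return out

    # --- CSV round trip -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"site_id": self.site_ids})
        for c in self.X.columns:
            df[c] = self.X[c].to_numpy()
        for m in self.outcomes:
            arr = self.outcomes[m]
            for j in range(arr.shape[1]):
                col = f"y_{m}" if arr.shape[1] == 1 else f"y_{m}_{j + 1}"
                df[col] = arr[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariates=None) -> "DetectionHistory":
        df = pd.read_csv(path)
        if "site_id" not in df.columns:
            raise ValueError(f"{path}: missing site_id column")
        outcomes = {}
        ycols = []
        for m in METHODS:
            cols = [c for c in df.columns
                    if c == f"y_{m}" or c.startswith(f"y_{m}_")]
            if cols:
                outcomes[m] = df[cols].to_numpy(float)
                ycols.extend(cols)
        if covariates is None:
            covariates = [c for c in df.columns
                          if c not in ycols and c not in
                          ("site_id", "x", "y", "row", "col")]
        return cls(df["site_id"].to_numpy(), df[list(covariates)].copy(),
                   outcomes)


@dataclass
class OccupancyModelSpec:
    """MCMC settings and the covariate subset entering the occupancy part."""

    covariate_subset: tuple[str, ...]
    prior_beta_sd: float = 10.0  # Normal(0, 100) variance on logit scale
    chains: int = 3
    burn_in: int = 1000
    iterations: int = 20000

    def __post_init__(self) -> None:
        self.covariate_subset = tuple(self.covariate_subset)
        if self.prior_beta_sd <= 0:
            raise ValueError("prior_beta_sd must be positive")

    @property
    def total_draws(self) -> int:
        """Combined post-burn-in draws across chains."""
        return self.chains * self.iterations


@dataclass
class PosteriorSample:
    """Combined post-burn-in MCMC draws.

    ``alpha``: (n_draws,), ``beta``: (n_draws, K) ordered as
    ``covariate_names``, ``p``: (n_draws, n_methods) ordered as ``methods``,
    ``z``: (n_draws, n_sites) latent states, ``chain``: chain label per draw.
    """

    alpha: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    z: np.ndarray
    chain: np.ndarray
    covariate_names: tuple[str, ...]
    methods: tuple[str, ...]
    rhat: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.alpha)

    def coef_matrix(self) -> np.ndarray:
        """(n_draws, 1 + K) matrix [alpha, beta...]."""
        return np.column_stack([self.alpha, self.beta])

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per parameter."""
        rows = []
        params = {"alpha": self.alpha}
        for k, name in enumerate(self.covariate_names):
            params[f"beta[{name}]"] = self.beta[:, k]
        for k, m in enumerate(self.methods):
            params[f"p[{m}]"] = self.p[:, k]
        for name, draws in params.items():
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append({"parameter": name, "mean": draws.mean(),
                         "sd": draws.std(ddof=1), "q2.5": lo, "q97.5": hi,
                         "rhat": self.rhat.get(name, np.nan)})
        return pd.DataFrame(rows)


# ----------------------------------------------------------- likelihood

def composite_detection(p_values) -> float:
    """Probability of at least one detection over independent replicates:
    p* = 1 - prod(1 - p_j). Empty input gives 0 (no surveys)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must be in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def site_marginal_likelihood(psi: float, p_per_replicate, outcomes) -> float:
    """Site likelihood with the latent state summed out:
    L = psi * prod p^Y (1-p)^(1-Y) + (1-psi) * I(all Y = 0)."""
    p = np.asarray(list(p_per_replicate), dtype=float)
    y = np.asarray(list(outcomes), dtype=float)
    if p.shape != y.shape:
        raise ValueError("p and outcomes must have equal length")
    occ = np.prod(np.where(y == 1, p, 1.0 - p))
    unocc = 0.0 if np.any(y == 1) else 1.0
    return float(psi * occ + (1.0 - psi) * unocc)


def update_z(psi_i: float, p_per_replicate, outcomes_i, rng) -> int:
    """Draw the latent state from its full conditional. A site with any
    detection is occupied with probability one; otherwise
    Pr(z=1 | Y=0) = psi (1-p*) / (psi (1-p*) + 1 - psi)."""
    y = np.asarray(list(outcomes_i), dtype=float)
    if np.any(y == 1):
        return 1
    q = 1.0 - composite_detection(p_per_replicate)  # prod(1 - p_j)
    pr = psi_i * q / (psi_i * q + 1.0 - psi_i) if psi_i < 1.0 else 1.0
    return int(rng.random() < pr)


def update_p(z, detections, replicates, rng, prior=(1.0, 1.0)) -> float:
    """Conjugate Beta draw for one method's detection probability.
    Only replicates at occupied (z=1) sites inform p."""
    z = np.asarray(z, dtype=float)
    d = float(np.sum(z * np.asarray(detections)))
    k = float(np.sum(z * np.asarray(replicates)))
    return float(rng.beta(prior[0] + d, prior[1] + (k - d)))


def _occ_loglik(eta: np.ndarray, z: np.ndarray) -> float:
    # sum_i [z eta - log(1 + e^eta)]
    return float(z @ eta - np.logaddexp(0.0, eta).sum())


def update_beta(theta, z, X1, prior_sd: float, scales, rng):
    """One random-walk Metropolis sweep over [alpha, beta...].

    ``X1`` is the design matrix with a leading column of ones. Returns the
    new coefficient vector and the per-coefficient acceptance indicator.
    """
    theta = np.asarray(theta, dtype=float).copy()
    z = np.asarray(z, dtype=float)
    eta = X1 @ theta
    ll = _occ_loglik(eta, z)
    accepted = np.zeros(len(theta), dtype=bool)
    for j in range(len(theta)):
        if scales[j] == 0:
            continue
        step = scales[j] * rng.standard_normal()
        eta_prop = eta + step * X1[:, j]
        ll_prop = _occ_loglik(eta_prop, z)
        lp = (theta[j] ** 2 - (theta[j] + step) ** 2) / (2.0 * prior_sd**2)
        if np.log(rng.random()) < ll_prop - ll + lp:
            theta[j] += step
            eta = eta_prop
            ll = ll_prop
            accepted[j] = True
    return theta, accepted


# ---------------------------------------------------------------- sampler

def run_mcmc(spec: OccupancyModelSpec, data: DetectionHistory,
             seed=None) -> PosteriorSample:
    """Fit the occupancy model by MCMC.

    Chains start from overdispersed initial values, are tuned (proposal
    scales adapted towards 20-50% acceptance) during burn-in only, and
    their post-burn-in draws are concatenated; with default settings the
    combined sample holds chains x iterations = 60 000 draws. A split-chain
    potential-scale-reduction factor is reported per parameter, with a
    warning above 1.1.
    """
    if data.n_sites < 1:
        raise ValueError("need at least one site")
    names = list(spec.covariate_subset)
    missing = [n for n in names if n not in data.X.columns]
    if missing:
        raise KeyError(f"covariates not in data: {missing}")
    X1 = np.column_stack(
        [np.ones(data.n_sites)] + [data.X[n].to_numpy(float) for n in names]
    )
    methods = data.methods
    det = np.array([data.detections(m) for m in methods])       # (M, n)
    reps = np.array([data.n_replicates(m) for m in methods])    # (M, n)
    any_det = data.any_detection()
    n, K = data.n_sites, len(names)
    M = len(methods)

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    chain_seeds = ss.spawn(spec.chains)

    a_all = np.empty((spec.chains, spec.iterations))
    b_all = np.empty((spec.chains, spec.iterations, K))
    p_all = np.empty((spec.chains, spec.iterations, M))
    z_all = np.empty((spec.chains, spec.iterations, n), dtype=np.uint8)
    acc_count = np.zeros(K + 1)

    for c in range(spec.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = np.concatenate([rng.normal(0, 1.5, 1),
                                rng.normal(0, 1.5, K)])
        p = rng.uniform(0.1, 0.9, M)
        z = any_det.astype(float)
        scales = np.full(K + 1, 0.5)
        window_acc = np.zeros(K + 1)
        window_n = 0

        total = spec.burn_in + spec.iterations
        for it in range(total):
            # latent states: hard 1 where detected, else conditional draw
            psi = expit(X1 @ theta)
            log_q = (reps * np.log1p(-p[:, None])).sum(axis=0)
            q = np.exp(log_q)  # prod_m (1 - p_m)^k_mi
            num = psi * q
            pr = num / (num + 1.0 - psi)
            z = (rng.random(n) < pr).astype(float)
            z[any_det] = 1.0

            # detection probabilities: conjugate Beta given z
            for m in range(M):
                d = float(z @ det[m])
                k = float(z @ reps[m])
                p[m] = rng.beta(1.0 + d, 1.0 + (k - d))

            # occupancy coefficients: random-walk Metropolis sweep
            theta, accepted = update_beta(theta, z, X1, spec.prior_beta_sd,
                                          scales, rng)
            if it < spec.burn_in:
                window_acc += accepted
                window_n += 1
                if window_n == 50:  # adapt during burn-in only
                    rate = window_acc / window_n
                    scales *= np.where(rate > 0.5, 1.3,
                                       np.where(rate < 0.2, 0.7, 1.0))
                    window_acc[:] = 0
                    window_n = 0
            else:
                j = it - spec.burn_in
                a_all[c, j] = theta[0]
                b_all[c, j] = theta[1:]
                p_all[c, j] = p
                z_all[c, j] = z
                acc_count += accepted

    # split-chain potential scale reduction per parameter
    rhat: dict[str, float] = {}
    named = {"alpha": a_all}
    for k, nm in enumerate(names):
        named[f"beta[{nm}]"] = b_all[:, :, k]
    for k, m in enumerate(methods):
        named[f"p[{m}]"] = p_all[:, :, k]
    for nm, draws in named.items():
        rhat[nm] = _split_rhat(draws)
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        warnings.warn(f"possible non-convergence, PSRF > 1.1: {bad}")

    denom = spec.chains * spec.iterations
    acceptance = {"alpha": acc_count[0] / denom}
    for k, nm in enumerate(names):
        acceptance[f"beta[{nm}]"] = acc_count[k + 1] / denom
    return PosteriorSample(
        alpha=a_all.reshape(-1),
        beta=b_all.reshape(-1, K),
        p=p_all.reshape(-1, M),
        z=z_all.reshape(-1, n),
        chain=np.repeat(np.arange(spec.chains), spec.iterations),
        covariate_names=tuple(names),
        methods=tuple(methods),
        rhat=rhat,
        acceptance=acceptance,
    )


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    chains, n = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    split = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n2 = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W))


# ------------------------------------------------------------- prediction

def predict_psi(posterior: PosteriorSample, grid: RasterStack,
                cov_spec: CovariateSpec | None = None,
                max_draws: int = 2000):
    """Posterior mean (and sd) of occupancy probability per grid cell.

    The grid must carry the model covariates standardized with the
    training constants; pass ``cov_spec`` to apply them here. Draws are
    thinned evenly to at most ``max_draws`` for the cell-wise average.

    Returns ``(mean_map, sd_map)`` with NaN at masked cells.
    """
    if cov_spec is not None:
        from .grids import standardize
        grid, _ = standardize(grid, spec=cov_spec)
    X = grid.design_matrix(posterior.covariate_names)
    if X.size and np.nanmax(np.abs(X)) > 50:
        raise ValueError(
            "covariate magnitudes look unstandardized; pass cov_spec"
        )
    coefs = posterior.coef_matrix()
    if len(coefs) > max_draws:
        idx = np.linspace(0, len(coefs) - 1, max_draws).astype(int)
        coefs = coefs[idx]
    X1 = np.column_stack([np.ones(len(X)), X])
    psi = expit(X1 @ coefs.T)  # (n_cells, n_draws)
    mean_map = np.full(grid.shape, np.nan)
    sd_map = np.full(grid.shape, np.nan)
    unmasked = ~grid.nodata_mask
    mean_map[unmasked] = psi.mean(axis=1)
    sd_map[unmasked] = psi.std(axis=1, ddof=1)
    return mean_map, sd_map
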