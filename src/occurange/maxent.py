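"""Maximum-entropy presence-only habitat suitability modelling.

The model is the Gibbs distribution q(x) proportional to exp(lambda . f(x))
over an evaluation set of cells (a uniform background sample plus the
presence cells), with linear and quadratic features of the standardized
covariates. The weights maximize the L1-regularized mean log-likelihood of
the presence cells,

    J(lambda) = mean_p[lambda . f(x_p)] - ln Z(lambda)
                - sum_j reg_j |lambda_j|,

a concave problem solved here by L-BFGS-B on the positive/negative split
of lambda. The habitat suitability index uses the logistic output
h = e^H q / (1 + e^H q), with H the entropy of the fitted distribution, so
the uniform model scores exactly 0.5 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import RasterStack

__all__ = [
    "MaxentModel",
    "RocSummary",
    "fit_maxent",
    "predict_hsi",
    "training_gain",
    "compute_auc",
    "compute_fpa",
    "roc_summary",
    "variable_contributions",
    "jackknife_gain",
]


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    covariate_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    lambda_: np.ndarray
    reg_beta: np.ndarray
    background_ids: np.ndarray       # flat cell ids of the background sample
    eval_ids: np.ndarray             # background union presence cells
    presence_ids: np.ndarray
    log_partition: float             # ln Z over the evaluation set
    entropy_H: float                 # entropy of q over the evaluation set
    objective_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def n_eval(self) -> int:
        return len(self.eval_ids)


@dataclass
class RocSummary:
    """Threshold sweep of omission and predicted-area statistics."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray
    fpa: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity,
             "fnr": self.fnr, "fpr": self.fpr, "fpa": self.fpa}
        )


def _feature_matrix(grid: RasterStack, cell_ids: np.ndarray,
                    covariate_names, features) -> tuple[np.ndarray, tuple]:
    cols, names = [], []
    for name in covariate_names:
        vals = grid.layers[name].ravel()[cell_ids]
        if "linear" in features:
            cols.append(vals)
            names.append(f"{name}:linear")
        if "quadratic" in features:
            cols.append(vals**2)
            names.append(f"{name}:quadratic")
    return np.column_stack(cols), tuple(names)


def fit_maxent(presence_cells, grid: RasterStack, n_background: int = 10000,
               covariate_names=None, features=("linear", "quadratic"),
               reg_multiplier: float = 1.0, tol: float = 1e-9,
               max_iter: int = 1000, seed=None) -> MaxentModel:
    """Fit the maximum-entropy model.

    Parameters
    ----------
    presence_cells
        Flat (row-major) cell ids of distinct presence cells.
    n_background
        Size of the uniform background ("pseudo-absence") sample drawn
        without replacement from unmasked cells; presence cells may also
        appear in it.
    reg_multiplier
        Scales the per-feature L1 penalty
        ``reg_j = reg_multiplier * sd_j(background) / sqrt(m_presences)``.

    Covariates are expected on a standardized scale. Degenerate
    (single-valued) features are dropped with a warning.
    """
    presence_cells = np.unique(np.asarray(presence_cells, dtype=int))
    if len(presence_cells) < 2:
        raise ValueError("need at least 2 distinct presence cells")
    if covariate_names is None:
        covariate_names = grid.names
    unmasked = np.flatnonzero(~grid.nodata_mask.ravel())
    if n_background > len(unmasked):
        raise ValueError("n_background exceeds the number of unmasked cells")
    rng = np.random.default_rng(seed)
    background = np.sort(rng.choice(unmasked, size=n_background,
                                    replace=False))
    eval_ids = np.union1d(background, presence_cells)

    F_eval, feat_names = _feature_matrix(grid, eval_ids, covariate_names,
                                         features)
    # drop features constant over the evaluation set
    keep = F_eval.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(feat_names, keep) if not k]
        warnings.warn(f"dropped degenerate features: {dropped}")
        F_eval = F_eval[:, keep]
        feat_names = tuple(n for n, k in zip(feat_names, keep) if k)
    F_bg = _feature_matrix(grid, background, covariate_names, features)[0][:, keep]
    # presence rows inside the evaluation set
    pres_rows = np.searchsorted(eval_ids, presence_cells)
    F_pres = F_eval[pres_rows]

    m = len(presence_cells)
    reg = reg_multiplier * F_bg.std(axis=0, ddof=1) / np.sqrt(m)
    mean_pres = F_pres.mean(axis=0)
    n_feat = F_eval.shape[1]

    path: list[float] = []

    def neg_obj_grad(w):
        u, v = w[:n_feat], w[n_feat:]
        lam = u - v
        scores = F_eval @ lam
        lse = logsumexp(scores)
        q = np.exp(scores - lse)
        obj = mean_pres @ lam - lse - reg @ (u + v)
        g = mean_pres - q @ F_eval
        return -obj, -np.concatenate([g - reg, -g - reg])

    w0 = np.zeros(2 * n_feat)
    res = minimize(
        neg_obj_grad, w0, jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * n_feat),
        callback=lambda w: path.append(-neg_obj_grad(w)[0]),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and res.status != 1:
        warnings.warn(
            f"maxent optimizer did not converge: {res.message} "
            f"(final gradient norm {np.max(np.abs(res.jac)):.3g})"
        )
    lam = res.x[:n_feat] - res.x[n_feat:]
    scores = F_eval @ lam
    lse = float(logsumexp(scores))
    q = np.exp(scores - lse)
    H = float(-(q * (scores - lse)).sum())
    return MaxentModel(
        covariate_names=tuple(covariate_names),
        feature_names=feat_names,
        lambda_=lam,
        reg_beta=reg,
        background_ids=background,
        eval_ids=eval_ids,
        presence_ids=presence_cells,
        log_partition=lse,
        entropy_H=H,
        objective_path=np.asarray(path),
        converged=bool(res.success),
    )


def _model_features(model: MaxentModel, grid: RasterStack,
                    cell_ids: np.ndarray) -> np.ndarray:
    cols = []
    for fname in model.feature_names:
        name, kind = fname.rsplit(":", 1)
        vals = grid.layers[name].ravel()[cell_ids]
        cols.append(vals if kind == "linear" else vals**2)
    return np.column_stack(cols)


def predict_hsi(model: MaxentModel, grid: RasterStack) -> np.ndarray:
    """Habitat suitability index per cell, strictly in (0, 1).

    Logistic output: h = e^H q_raw / (1 + e^H q_raw), with q_raw the
    Gibbs density normalized over the evaluation set; the uniform model
    (all lambda 0) gives h = 0.5 everywhere. Masked cells are NaN.
    """
    missing = [n for n in model.covariate_names if n not in grid.layers]
    if missing:
        raise KeyError(f"grid lacks covariates {missing}")
    unmasked = np.flatnonzero(~grid.nodata_mask.ravel())
    F = _model_features(model, grid, unmasked)
    log_eq = model.entropy_H + F @ model.lambda_ - model.log_partition
    h = 1.0 / (1.0 + np.exp(-log_eq))
    out = np.full(grid.shape[0] * grid.shape[1], np.nan)
    out[unmasked] = h
    return out.reshape(grid.shape)


def training_gain(model: MaxentModel, presence_cells=None,
                  grid: RasterStack | None = None) -> float:
    """Regularized training gain in nats.

    gain = mean_p[ln q_raw(x_p)] + ln(N_eval) - sum_j reg_j |lambda_j|,
    i.e. the penalized mean log-likelihood improvement of the presences
    over the uniform distribution on the evaluation set; the uniform model
    scores exactly 0, and exp(gain + penalty) is the ratio of the
    geometric-mean presence likelihood to that of a random cell.
    """
    if presence_cells is None:
        presence_cells = model.presence_ids
    presence_cells = np.asarray(presence_cells, dtype=int)
    if grid is None:
        raise ValueError("grid is required to evaluate features")
    F = _model_features(model, grid, presence_cells)
    mean_ll = float(np.mean(F @ model.lambda_)) - model.log_partition
    return mean_ll + np.log(model.n_eval) - float(
        model.reg_beta @ np.abs(model.lambda_)
    )


def compute_auc(presence_scores, background_scores) -> float:
    """Area under the ROC curve: probability that a random presence
    outranks a random background cell, ties counting one half
    (Mann-Whitney rank formulation)."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: pres.size].sum()
    return float((r_pres - pres.size * (pres.size + 1) / 2.0)
                 / (pres.size * bg.size))


def compute_fpa(hsi_map: np.ndarray, threshold: float,
                nodata_mask=None) -> float:
    """Fractional predicted area: proportion of unmasked cells at or above
    the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    vals = np.asarray(hsi_map, dtype=float).ravel()
    if nodata_mask is not None:
        vals = vals[~np.asarray(nodata_mask, dtype=bool).ravel()]
    vals = vals[np.isfinite(vals)]
    return float((vals >= threshold).mean())


def roc_summary(hsi_map: np.ndarray, presence_cells, nodata_mask=None,
                n_thresholds: int = 1001) -> RocSummary:
    """Sweep thresholds over the suitability map.

    Sensitivity/omission are computed over the presence cells; the
    false-positive rate uses unmasked non-presence cells as
    pseudo-absences; FPA is the predicted fraction of all unmasked cells.
    """
    flat = np.asarray(hsi_map, dtype=float).ravel()
    mask = np.zeros(flat.size, dtype=bool) if nodata_mask is None else \
        np.asarray(nodata_mask, dtype=bool).ravel()
    mask = mask | ~np.isfinite(flat)
    presence_cells = np.unique(np.asarray(presence_cells, dtype=int))
    pres = flat[presence_cells]
    is_pres = np.zeros(flat.size, dtype=bool)
    is_pres[presence_cells] = True
    bg = flat[~mask & ~is_pres]
    allv = flat[~mask]
    ts = np.linspace(0.0, 1.0, n_thresholds)
    pres_sorted = np.sort(pres)
    bg_sorted = np.sort(bg)
    all_sorted = np.sort(allv)
    fnr = np.searchsorted(pres_sorted, ts, side="left") / pres.size
    fpr = 1.0 - np.searchsorted(bg_sorted, ts, side="left") / bg.size
    fpa = 1.0 - np.searchsorted(all_sorted, ts, side="left") / allv.size
    return RocSummary(ts, 1.0 - fnr, fnr, fpr, fpa,
                      compute_auc(pres, bg))


def variable_contributions(model: MaxentModel, grid: RasterStack,
                           presence_cells=None, n_perm: int = 10,
                           seed=None) -> pd.Series:
    """Permutation importance of each covariate, normalized to sum to 100.

    For each covariate its values over the evaluation set are permuted
    (linear and quadratic features move together), the training gain is
    recomputed under the fitted weights, and the mean drop in gain over
    ``n_perm`` permutations is the covariate's raw importance.
    """
    if presence_cells is None:
        presence_cells = model.presence_ids
    presence_cells = np.unique(np.asarray(presence_cells, dtype=int))
    rng = np.random.default_rng(seed)
    pres_rows = np.searchsorted(model.eval_ids, presence_cells)

    values = {n: grid.layers[n].ravel()[model.eval_ids]
              for n in model.covariate_names}

    def gain_from(values_by_cov) -> float:
        cols = []
        for fname in model.feature_names:
            name, kind = fname.rsplit(":", 1)
            v = values_by_cov[name]
            cols.append(v if kind == "linear" else v**2)
        F = np.column_stack(cols)
        scores = F @ model.lambda_
        lse = logsumexp(scores)
        mean_ll = float(np.mean(scores[pres_rows])) - lse
        return mean_ll + np.log(model.n_eval) - float(
            model.reg_beta @ np.abs(model.lambda_))

    base = gain_from(values)
    drops = {}
    for name in model.covariate_names:
        d = 0.0
        for _ in range(n_perm):
            perm = dict(values)
            perm[name] = rng.permutation(values[name])
            d += base - gain_from(perm)
        drops[name] = max(d / n_perm, 0.0)
    total = sum(drops.values())
    if total == 0:
        warnings.warn("all permutation importances are zero; uniform split")
        share = 100.0 / len(drops)
        return pd.Series({n: share for n in drops})
    return pd.Series({n: 100.0 * v / total for n, v in drops.items()})


def jackknife_gain(presence_cells, grid: RasterStack, covariate_names,
                   **fit_params) -> pd.DataFrame:
    """Per-covariate jackknife of training gain.

    Refits the model with each covariate alone and with each covariate
    omitted (2K fits plus the full model); returns a frame with columns
    ``gain_alone`` and ``gain_without`` indexed by covariate, and the full
    model's gain in ``df.attrs["gain_full"]`` /  ``df.attrs["n_fits"]``.
    """
    covariate_names = list(covariate_names)
    if len(covariate_names) < 2:
        raise ValueError("jackknife needs at least 2 covariates")

    n_fits = 0

    def one_gain(names):
        nonlocal n_fits
        n_fits += 1
        m = fit_maxent(presence_cells, grid, covariate_names=names,
                       **fit_params)
        return training_gain(m, grid=grid)

    full = one_gain(covariate_names)
    rows = {}
    for name in covariate_names:
        try:
            alone = one_gain([name])
        except Exception as exc:  # a refit may legitimately fail
            warnings.warn(f"single-covariate fit failed for {name}: {exc}")
            alone = np.nan
        try:
            without = one_gain([n for n in covariate_names if n != name])
        except Exception as exc:
            warnings.warn(f"leave-one-out fit failed for {name}: {exc}")
            without = np.nan
        rows[name] = {"gain_alone": alone, "gain_without": without}
    df = pd.DataFrame(rows).T
    df.attrs["gain_full"] = full
    df.attrs["n_fits"] = n_fits
    return df
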