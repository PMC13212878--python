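"""Latent factor models of the proteome and their longitudinal extension.

Two fitters share one model class:

* :func:`fit_factor_model` — Gaussian probabilistic factor analysis,
  x = W z + eps with z ~ N(0, I_K) and heteroscedastic diagonal noise,
  fitted by expectation-maximisation.  Factor scores are posterior means.

* :func:`fit_temporal_model` — the longitudinal variant: factor scores are
  regularised toward smooth functions of time through a squared-exponential
  Gaussian-process prior per factor.  The fit alternates (i) a score update
  (posterior-mean scores given loadings, then GP-regression smoothing per
  patient with kernel hyperparameters chosen by marginal-likelihood grid
  search) and (ii) a ridge-penalised least-squares loading update.  The
  per-factor "smoothness" statistic is the share of score variance carried
  by the smooth component.

Reporting conventions that remove the usual rotational/sign ambiguity:
factors are ordered by variance explained (computed incrementally, as
100·(1 − SS_res/SS_tot) per added factor) and each loading column is signed
so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import AbundanceMatrix, timepoint_index

_GP_LENGTHSCALES = (0.5, 1.0, 2.0, 4.0, 8.0)
_GP_SMOOTH_SHARES = (0.05, 0.25, 0.5, 0.75, 0.95, 0.99)


@dataclass
class FactorModel:
    """Fitted latent-factor decomposition.

    ``Z`` is samples × K (posterior-mean factor scores), ``W`` proteins × K
    loadings, ``noise_var`` the per-protein residual variance, and
    ``var_explained`` the per-factor percentage of total variance (ordered
    descending).  ``kernel_params`` is populated by the temporal fitter.
    """

    Z: pd.DataFrame
    W: pd.DataFrame
    noise_var: pd.Series
    var_explained: np.ndarray
    mean: pd.Series
    K: int
    sample_meta: pd.DataFrame | None = None
    kernel_params: pd.DataFrame | None = None
    converged: bool = True
    n_iter: int = 0
    seed: int | None = None

    @property
    def factor_names(self) -> list[str]:
        return list(self.Z.columns)

    def reconstruction(self) -> pd.DataFrame:
        rec = self.W.to_numpy() @ self.Z.to_numpy().T
        return pd.DataFrame(
            rec + self.mean.to_numpy()[:, None], index=self.W.index, columns=self.Z.index
        )

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.Z.to_csv(out / "Z.tsv", sep="\t")
        self.W.to_csv(out / "W.tsv", sep="\t")
        extra = {
            "noise_var": self.noise_var.to_dict(),
            "var_explained": self.var_explained.tolist(),
            "mean": self.mean.to_dict(),
            "K": self.K,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "kernel_params": (
                None if self.kernel_params is None
                else self.kernel_params.to_dict(orient="index")
            ),
        }
        (out / "model.json").write_text(json.dumps(extra))
        if self.sample_meta is not None:
            self.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t")


def _as_array(matrix) -> tuple[np.ndarray, pd.Index, pd.Index, pd.DataFrame | None]:
    if isinstance(matrix, AbundanceMatrix):
        df, meta = matrix.values, matrix.meta
    else:
        df, meta = matrix, None
    arr = df.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values; interpolate before fitting")
    return arr, df.index, df.columns, meta


def _varimax(W: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix.

    The factor-analysis likelihood is invariant under orthogonal rotation of
    the latent space; varimax picks the rotation whose loading columns are
    maximally sparse, which axis-aligns estimated factors with sparse
    generating factors and makes fits reproducible across restarts.
    """
    m, K = W.shape
    if K == 1:
        return np.eye(1)
    R = np.eye(K)
    d = 0.0
    for _ in range(max_iter):
        L = W @ R
        u, s, vt = np.linalg.svd(
            W.T @ (L ** 3 - L * ((L ** 2).sum(axis=0) / m)[None, :])
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


def _order_and_sign(X: np.ndarray, W: np.ndarray, Z: np.ndarray):
    """Order factors greedily by incremental explained SS and fix signs.

    Variance explained is incremental: at each step the factor whose rank-1
    term removes the most residual sum of squares is appended, and its
    contribution is 100·(SS_res drop)/SS_tot.  Greedy ordering keeps the
    increments (near-)descending; tiny negative increments from correlated
    posterior scores are floored at 0.
    """
    ss_tot = float((X ** 2).sum())
    K = W.shape[1]
    remaining = list(range(K))
    order: list[int] = []
    ve = np.empty(K)
    R = X.copy()
    prev = ss_tot
    for step in range(K):
        drops = []
        for k in remaining:
            drops.append(prev - float(((R - np.outer(W[:, k], Z[:, k])) ** 2).sum()))
        best = remaining[int(np.argmax(drops))]
        order.append(best)
        remaining.remove(best)
        R = R - np.outer(W[:, best], Z[:, best])
        res = float((R ** 2).sum())
        ve[step] = max(0.0, 100.0 * (prev - res) / ss_tot)
        prev = res
    order = np.asarray(order)
    # greedy increments can be marginally non-monotone when scores correlate;
    # a final stable sort enforces the descending reporting convention
    final = np.argsort(-ve, kind="stable")
    ve = ve[final]
    order = order[final]
    W, Z = W[:, order], Z[:, order]
    # sign: largest-|w| entry positive
    for k in range(K):
        j = int(np.argmax(np.abs(W[:, k])))
        if W[j, k] < 0:
            W[:, k] *= -1
            Z[:, k] *= -1
    return W, Z, ve, order


def fit_factor_model(
    matrix,
    k_max: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorModel:
    """EM fit of a K-factor Gaussian factor-analysis model.

    ``matrix`` may be an :class:`AbundanceMatrix` or a protein × sample
    DataFrame.  Deterministic given ``seed`` (which only drives the loading
    initialisation).  Non-convergence within ``max_iter`` EM sweeps returns
    the model with ``converged=False`` and a warning.
    """
    arr, proteins, samples, meta = _as_array(matrix)
    m, n = arr.shape
    if not 1 <= k_max < min(m, n):
        raise ConfigError(f"k_max must lie in [1, {min(m, n) - 1}] for a {m}x{n} matrix")
    mu = arr.mean(axis=1)
    X = arr - mu[:, None]
    rng = np.random.default_rng(seed)
    scale = X.std() or 1.0
    W = rng.normal(0.0, scale / np.sqrt(k_max), size=(m, k_max))
    diag_S = (X ** 2).mean(axis=1)
    psi = np.maximum(diag_S * 0.5, 1e-8)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = W / psi[:, None]                      # Psi^-1 W,  m × K
        G = np.linalg.inv(np.eye(k_max) + W.T @ A)  # K × K posterior covariance
        Ez = G @ (A.T @ X)                        # K × n
        XEzT = X @ Ez.T                           # m × K
        Ezz = n * G + Ez @ Ez.T
        W = np.linalg.solve(Ezz, XEzT.T).T
        psi = np.maximum(diag_S - (W * XEzT).sum(axis=1) / n, 1e-10)

        # marginal log-likelihood via the Woodbury identity (K×K work only)
        A = W / psi[:, None]
        M = np.eye(k_max) + W.T @ A
        sign, logdet_M = np.linalg.slogdet(M)
        logdet_C = float(np.log(psi).sum() + logdet_M)
        AX = A.T @ X                              # K × n
        tr = float((diag_S / psi).sum() - np.trace(
            np.linalg.solve(M, AX @ AX.T) / n))
        ll = -0.5 * n * (m * np.log(2 * np.pi) + logdet_C + tr)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * abs(ll_old):
            converged = True
            break
        ll_old = ll

    if not converged:
        warnings.warn(
            f"factor model did not converge in {max_iter} EM iterations", stacklevel=2
        )
    A = W / psi[:, None]
    G = np.linalg.inv(np.eye(k_max) + W.T @ A)
    Z = (G @ (A.T @ X)).T                          # n × K posterior means
    R = _varimax(W)
    W, Z = W @ R, Z @ R
    W, Z, ve, _ = _order_and_sign(X, W, Z.copy())
    names = [f"F{k + 1}" for k in range(k_max)]
    return FactorModel(
        Z=pd.DataFrame(Z, index=samples, columns=names),
        W=pd.DataFrame(W, index=proteins, columns=names),
        noise_var=pd.Series(psi, index=proteins, name="noise_var"),
        var_explained=ve,
        mean=pd.Series(mu, index=proteins, name="mean"),
        K=k_max,
        sample_meta=None if meta is None else meta.copy(),
        converged=converged,
        n_iter=it,
        seed=seed,
    )


def retain_factors(model: FactorModel, threshold_pct: float = 2.0) -> FactorModel:
    """Truncate to factors explaining at least ``threshold_pct`` % of variance.

    At least one factor (the strongest) is always retained.
    """
    keep = np.flatnonzero(model.var_explained >= threshold_pct)
    if keep.size == 0:
        keep = np.array([0])
    names = [model.factor_names[k] for k in keep]
    return FactorModel(
        Z=model.Z[names].copy(),
        W=model.W[names].copy(),
        noise_var=model.noise_var.copy(),
        var_explained=model.var_explained[keep],
        mean=model.mean.copy(),
        K=len(names),
        sample_meta=None if model.sample_meta is None else model.sample_meta.copy(),
        kernel_params=(
            None if model.kernel_params is None else model.kernel_params.loc[names]
        ),
        converged=model.converged,
        n_iter=model.n_iter,
        seed=model.seed,
    )


# ---------------------------------------------------------------------------
# Temporal (GP-smoothed) variant
# ---------------------------------------------------------------------------


def _se_kernel(t: np.ndarray, lengthscale: float) -> np.ndarray:
    d = t[:, None] - t[None, :]
    return np.exp(-0.5 * (d / lengthscale) ** 2)


def _gp_smooth_factor(z: np.ndarray, times: np.ndarray, groups: np.ndarray,
                      lengthscale: float | None, smooth_share: float | None):
    """Smooth one factor's scores per patient; returns (z_smooth, ell, share).

    Hyperparameters are chosen by maximising the summed GP marginal
    likelihood over patients on a fixed grid unless given explicitly.
    ``smooth_share`` is the fraction of total score variance assigned to the
    smooth (signal) component; the remainder is treated as iid noise.
    """
    v = float(np.var(z))
    if v == 0:
        return z.copy(), lengthscale or 1.0, smooth_share or 0.0
    uniq = np.unique(groups)
    ells = _GP_LENGTHSCALES if lengthscale is None else (lengthscale,)
    shares = _GP_SMOOTH_SHARES if smooth_share is None else (smooth_share,)
    best = (-np.inf, ells[0], shares[0])
    if len(ells) > 1 or len(shares) > 1:
        for ell in ells:
            for r in shares:
                ll = 0.0
                for g in uniq:
                    sel = groups == g
                    y, t = z[sel], times[sel]
                    Kmat = r * v * _se_kernel(t, ell) + (1 - r) * v * np.eye(len(t))
                    sign, logdet = np.linalg.slogdet(Kmat)
                    alpha = np.linalg.solve(Kmat, y)
                    ll += -0.5 * (y @ alpha + logdet + len(t) * np.log(2 * np.pi))
                if ll > best[0]:
                    best = (ll, ell, r)
        _, ell, r = best
    else:
        ell, r = ells[0], shares[0]
    if ell < 1e-6:
        # no-smoothing limit: scores left exactly at their EM values
        return z.copy(), ell, 1.0
    z_smooth = np.empty_like(z)
    for g in uniq:
        sel = groups == g
        y, t = z[sel], times[sel]
        Ksig = r * v * _se_kernel(t, ell)
        Kmat = Ksig + (1 - r) * v * np.eye(len(t))
        z_smooth[sel] = Ksig @ np.linalg.solve(Kmat, y)
    return z_smooth, ell, r


def fit_temporal_model(
    matrix: AbundanceMatrix,
    k: int = 15,
    seed: int = 0,
    n_align_iter: int = 3,
    lengthscale: float | None = None,
    smooth_share: float | None = None,
    ridge: float = 1e-6,
    **em_kwargs,
) -> FactorModel:
    """Latent factors with squared-exponential GP smoothing of scores over time.

    Requires an :class:`AbundanceMatrix` whose metadata carries patient and
    timepoint labels (time is taken as the integer timepoint index, i.e.
    weeks).  With a single observed timepoint the temporal prior is vacuous
    and the fit falls back to :func:`fit_factor_model` with a warning.
    """
    if matrix.meta is None or "timepoint" not in matrix.meta.columns:
        raise ConfigError("temporal model requires sample metadata with timepoints")
    times = np.array([timepoint_index(t) for t in matrix.meta["timepoint"]], float)
    if len(np.unique(times)) < 2:
        warnings.warn(
            "single observed timepoint: temporal prior is vacuous; "
            "falling back to the non-temporal factor model",
            stacklevel=2,
        )
        return fit_factor_model(matrix, k, seed=seed, **em_kwargs)
    groups = matrix.meta["patient_id"].to_numpy()

    base = fit_factor_model(matrix, k, seed=seed, **em_kwargs)
    X = matrix.values.to_numpy(float) - base.mean.to_numpy()[:, None]
    W = base.W.to_numpy().copy()
    psi = base.noise_var.to_numpy().copy()
    K = base.K
    n = X.shape[1]

    Zs = base.Z.to_numpy().copy()
    kern = np.zeros((K, 3))  # lengthscale, smooth_share, smoothness
    for _ in range(n_align_iter):
        # score update: posterior means given current loadings ...
        A = W / psi[:, None]
        G = np.linalg.inv(np.eye(K) + W.T @ A)
        Z = (G @ (A.T @ X)).T
        # ... then GP smoothing per factor
        Zs = np.empty_like(Z)
        for kk in range(K):
            zsm, ell, r = _gp_smooth_factor(
                Z[:, kk], times, groups, lengthscale, smooth_share
            )
            var_raw = float(np.var(Z[:, kk]))
            smoothness = float(np.var(zsm) / var_raw) if var_raw > 0 else 0.0
            kern[kk] = (ell, r, min(smoothness, 1.0))
            Zs[:, kk] = zsm
        # loading update: ridge least squares on smoothed scores
        ZtZ = Zs.T @ Zs + ridge * n * np.eye(K)
        W = np.linalg.solve(ZtZ, Zs.T @ X.T).T
        resid = X - W @ Zs.T
        psi = np.maximum((resid ** 2).mean(axis=1), 1e-10)

    W, Zs, ve, order = _order_and_sign(X, W, Zs.copy())
    names = [f"F{kk + 1}" for kk in range(K)]
    kernel_params = pd.DataFrame(
        kern[order], columns=["lengthscale", "smooth_share", "smoothness"], index=names
    )
    return FactorModel(
        Z=pd.DataFrame(Zs, index=matrix.samples, columns=names),
        W=pd.DataFrame(W, index=matrix.proteins, columns=names),
        noise_var=pd.Series(psi, index=matrix.proteins, name="noise_var"),
        var_explained=ve,
        mean=base.mean,
        K=K,
        sample_meta=matrix.meta.copy(),
        kernel_params=kernel_params,
        converged=base.converged,
        n_iter=base.n_iter,
        seed=seed,
    )


def factor_scores_at(model: FactorModel, timepoint: str) -> pd.DataFrame:
    """Factor scores restricted to one timepoint: one row per patient."""
    if model.sample_meta is None:
        raise ConfigError("model carries no sample metadata; cannot slice by timepoint")
    meta = model.sample_meta
    available = sorted(set(map(str, meta["timepoint"])), key=timepoint_index)
    if timepoint not in available:
        raise KeyError(
            f"timepoint {timepoint!r} not in model; available: {', '.join(available)}"
        )
    sel = meta.index[meta["timepoint"] == timepoint]
    out = model.Z.loc[sel].copy()
    out.index = meta.loc[sel, "patient_id"].to_numpy()
    return out
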