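"""Linear mixed-effects prediction under nested leave-one-session-out CV.

The model is the random-intercept LME

    y = X beta + Z u + eps,   u_i ~ N(0, sigma_u^2),  eps ~ N(0, sigma_e^2)

with oculomotor-feature principal components as fixed effects X and subject
indicators as Z, estimated by maximum likelihood.  Two variants are fitted:
raw (R-LME, intercept included) and subtractive-normalized (SN-LME, no
intercept, since baseline subtraction removes offsets).

Evaluation is leave-one-session-out (LOSO): each subject-session is held out
once; everything learned from data — feature imputation means,
standardization, the feature PCA, the number of retained PCs and the model
itself — is recomputed from the outer training rows only.  The number of PCs
is chosen by an inner LOSO over the training rows, maximizing inner
predicted-vs-actual Pearson correlation (ties go to the smallest count).
Held-out predictions use the held-out subject's random intercept, estimated
from that subject's *other* sessions, which are in the training set because
folds are sessions, not subjects.

For speed, the ML fit profiles the likelihood over the variance ratio
``lambda = sigma_u^2 / sigma_e^2``: given lambda, the GLS fixed effects and
the residual variance are closed-form, leaving a one-dimensional
optimization.  Inner-loop fold predictions re-solve the GLS fixed effects
exactly for every left-out row (rank-one downdates of the sufficient
statistics) with lambda held at its training-set ML value per candidate PC
count; outer-fold models are always full ML fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar


# ---------------------------------------------------------------------------
# Random-intercept LME by profiled maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """ML estimates for the random-intercept model."""

    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float
    group_labels: np.ndarray  # unique subject labels, aligned with ``u``
    u: np.ndarray  # empirical best linear unbiased predictors per subject
    method: str = "ML"

    @property
    def lam(self) -> float:
        return self.sigma2_u / self.sigma2_e if self.sigma2_e > 0 else 0.0

    def predict(self, X: np.ndarray, subjects) -> np.ndarray:
        """x·beta plus the subject's random intercept (0 for unseen subjects)."""
        X = np.asarray(X, dtype=float)
        fixed = X @ self.beta
        lut = {g: self.u[i] for i, g in enumerate(self.group_labels)}
        offs = np.array([lut.get(s, 0.0) for s in np.asarray(subjects)])
        return fixed + offs


class _Profile:
    """Sufficient statistics for the profiled likelihood in lambda."""

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
        self.X = X
        self.y = y
        self.codes = codes
        self.G = n_groups
        self.n, self.p = X.shape
        self.m = np.bincount(codes, minlength=n_groups).astype(float)
        self.SX = np.zeros((n_groups, self.p))
        np.add.at(self.SX, codes, X)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)
        self.Sxx = X.T @ X
        self.Sxy = X.T @ y
        self.yy = float(y @ y)

    def solve(self, lam: float):
        """GLS beta, ML sigma2_e and profile log-likelihood at ``lam``."""
        c = lam / (1.0 + lam * self.m)  # (G,)
        A = self.Sxx - np.einsum("g,gp,gq->pq", c, self.SX, self.SX)
        b = self.Sxy - (c * self.Sy) @ self.SX
        beta = np.linalg.solve(A, b)
        ywy = self.yy - float(c @ self.Sy**2)
        rss = ywy - float(beta @ b)
        rss = max(rss, 1e-12)
        sigma2 = rss / self.n
        logdet = float(np.sum(np.log1p(lam * self.m)))
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return beta, sigma2, ll

    def blups(self, lam: float, beta: np.ndarray) -> np.ndarray:
        resid_sum = self.Sy - self.SX @ beta
        return lam * resid_sum / (1.0 + lam * self.m)


def _codes(subjects) -> tuple[np.ndarray, np.ndarray]:
    labels, codes = np.unique(np.asarray(subjects), return_inverse=True)
    return labels, codes


def fit_lme(X: np.ndarray, y: np.ndarray, subjects, add_intercept: bool = False) -> LMEFit:
    """Maximum-likelihood fit of the random-intercept LME.

    ``X`` is the fixed-effects matrix (``add_intercept`` prepends a column of
    ones); ``subjects`` assigns each row to its random-intercept group.
    Raises on singular designs or fewer than two subjects.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == len(y) and len(y) != 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    labels, codes = _codes(subjects)
    if labels.size < 2:
        raise ValueError("need at least 2 subjects for a random-intercept model")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than fixed-effect columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is singular")
    prof = _Profile(X, y, codes, labels.size)
    lam, beta, sigma2, ll = _ml_lambda(prof)
    u = prof.blups(lam, beta)
    return LMEFit(beta=beta, sigma2_u=lam * sigma2, sigma2_e=sigma2, loglik=ll,
                  group_labels=labels, u=u)


def _ml_lambda(prof: _Profile):
    """Maximize the profile likelihood over log lambda (with lambda=0 boundary)."""

    def neg(t: float) -> float:
        return -prof.solve(np.exp(t))[2]

    res = minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    beta, sigma2, ll = prof.solve(lam)
    beta0, sigma20, ll0 = prof.solve(0.0)
    if ll0 >= ll:
        return 0.0, beta0, sigma20, ll0
    return lam, beta, sigma2, ll


def _loo_predictions(prof: _Profile, lam: float, p_use: int) -> np.ndarray:
    """Exact GLS leave-one-row-out predictions at fixed ``lam``.

    Uses the first ``p_use`` design columns.  For every row the sufficient
    statistics are downdated (the row leaves both the design and its
    subject's aggregates), the fixed effects are re-solved, and the row is
    predicted with its subject's re-estimated random intercept.  Fully
    vectorized across rows.
    """
    X = prof.X[:, :p_use]
    y = prof.y
    n = prof.n
    m_g = prof.m[prof.codes]  # (n,)
    SXg = prof.SX[prof.codes, :p_use]  # (n, p)
    Syg = prof.Sy[prof.codes]
    c_full = lam / (1.0 + lam * prof.m)
    A_full = prof.Sxx[:p_use, :p_use] - np.einsum(
        "g,gp,gq->pq", c_full, prof.SX[:, :p_use], prof.SX[:, :p_use])
    b_full = prof.Sxy[:p_use] - (c_full * prof.Sy) @ prof.SX[:, :p_use]
    cg = lam / (1.0 + lam * m_g)
    mp = m_g - 1.0
    cgp = lam / (1.0 + lam * mp)
    SXp = SXg - X
    Syp = Syg - y
    A = (A_full[None, :, :]
         - np.einsum("ni,nj->nij", X, X)
         + cg[:, None, None] * np.einsum("ni,nj->nij", SXg, SXg)
         - cgp[:, None, None] * np.einsum("ni,nj->nij", SXp, SXp))
    b = (b_full[None, :]
         - X * y[:, None]
         + cg[:, None] * SXg * Syg[:, None]
         - cgp[:, None] * SXp * Syp[:, None])
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # (n, p)
    u = lam * (Syp - np.einsum("np,np->n", SXp, beta)) / (1.0 + lam * mp)
    return np.einsum("np,np->n", X, beta) + u


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate(predicted, actual) -> dict:
    """Pearson correlation (two-sided t p-value), RMSE, bias and R^2.

    Bias is mean(predicted) - mean(actual); R^2 is the squared correlation.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.size != act.size:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(pred) == 0 or np.std(act) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(pred, act)
    rmse = float(np.sqrt(np.mean((pred - act) ** 2)))
    bias = float(np.mean(pred) - np.mean(act))
    return {"corr": float(r), "p_value": float(p), "rmse": rmse, "bias": bias,
            "r2": float(r) ** 2, "n": int(pred.size)}


# ---------------------------------------------------------------------------
# Nested LOSO cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldInfo:
    """What one outer fold learned (for the feature-importance analysis)."""

    held_out_index: int
    n_pcs: int
    loadings: np.ndarray  # (n_features, n_pcs) of the training-fold PCA
    beta_pcs: np.ndarray  # fixed-effect coefficients of the PCs (no intercept)
    lam: float


@dataclass
class PredictionResult:
    """Held-out predictions and pooled metrics for one LOSO run."""

    variant: str  # "raw" | "sn"
    predictions: pd.DataFrame  # subject_id, actual, predicted, n_pcs [, baseline_*]
    metrics: dict
    baseline_metrics: dict | None
    folds: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)


def _prepare_fold(F: np.ndarray, train: np.ndarray):
    """Imputation means, standardization and PCA from training rows only."""
    Ftr = F[train]
    col_mean = np.nanmean(Ftr, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    Ftr = np.where(np.isnan(Ftr), col_mean, Ftr)
    sd = np.std(Ftr, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Ftr - col_mean) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0])) if s.size else 0
    scores = u[:, :rank] * s[:rank]
    return col_mean, sd, vt[:rank], scores


def _select_pcs(scores: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int,
                kmax: int, lam_mode: str, use_intercept: bool) -> tuple[int, list]:
    """Inner LOSO: choose the PC count maximizing inner Pearson correlation."""
    n = len(y)
    off = 1 if use_intercept else 0
    cols = [np.ones((n, 1))] if use_intercept else []
    cols.append(scores[:, :kmax])
    Xall = np.hstack(cols) if cols else np.empty((n, 0))
    prof = _Profile(Xall, y, codes, n_groups)
    best_k, best_corr = 1, -np.inf
    inner = []
    sy = np.std(y)
    for k in range(1, kmax + 1):
        p_use = off + k
        if lam_mode == "mixed":
            sub = _Profile(Xall[:, :p_use], y, codes, n_groups)
            lam = _ml_lambda(sub)[0]
        else:
            lam = 0.0
        preds = _loo_predictions(prof, lam, p_use)
        if sy == 0 or np.std(preds) == 0:
            corr = -np.inf  # correlation undefined: flagged, never selected
        else:
            corr = float(np.corrcoef(preds, y)[0, 1])
        inner.append(corr)
        if corr > best_corr:  # strict: ties resolve to the smallest count
            best_corr, best_k = corr, k
    return best_k, inner


def loso_predict(features: pd.DataFrame, y, subjects, variant: str = "raw",
                 pc_grid_max: int = 10, compute_baseline: bool = True,
                 ) -> PredictionResult:
    """Nested leave-one-session-out prediction of ``y`` from feature PCs.

    Parameters
    ----------
    features
        One row per subject-session (columns = oculomotor features; NaNs
        allowed, imputed per training fold).  For the ``"sn"`` variant the
        caller passes subtractive-normalized features/outcomes with baseline
        rows already removed.
    y, subjects
        Outcome vector and subject identifier per row.
    variant
        ``"raw"`` fits with an intercept; ``"sn"`` without one (normalized
        data are already offset-free).
    compute_baseline
        Also run the identical procedure with a fixed-effects-only model
        (ordinary regression, no random intercept) for comparison.
    """
    if variant not in ("raw", "sn"):
        raise ValueError("variant must be 'raw' or 'sn'")
    feature_names = list(features.columns)
    F = features.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    n = len(y)
    labels, codes = _codes(subjects)
    use_intercept = variant == "raw"
    preds = np.full(n, np.nan)
    base_preds = np.full(n, np.nan)
    n_pcs = np.zeros(n, dtype=int)
    base_n_pcs = np.zeros(n, dtype=int)
    folds: list[FoldInfo] = []
    for r in range(n):
        train = np.ones(n, dtype=bool)
        train[r] = False
        col_mean, sd, Vt, scores = _prepare_fold(F, train)
        y_tr = y[train]
        sub_tr = subjects[train]
        lab_tr, codes_tr = _codes(sub_tr)
        kmax = max(1, min(pc_grid_max, Vt.shape[0], len(y_tr) - 2 - int(use_intercept)))
        k_star, _ = _select_pcs(scores, y_tr, codes_tr, lab_tr.size, kmax,
                                "mixed", use_intercept)
        fit = fit_lme(scores[:, :k_star], y_tr, sub_tr, add_intercept=use_intercept)
        z_heldout = (np.where(np.isnan(F[r]), col_mean, F[r]) - col_mean) / sd
        score_heldout = Vt[:k_star] @ z_heldout
        xrow = np.concatenate([[1.0], score_heldout]) if use_intercept else score_heldout
        preds[r] = fit.predict(xrow[None, :], [subjects[r]])[0]
        n_pcs[r] = k_star
        beta_pcs = fit.beta[1:] if use_intercept else fit.beta
        folds.append(FoldInfo(held_out_index=r, n_pcs=k_star,
                              loadings=Vt[:k_star].T.copy(), beta_pcs=beta_pcs.copy(),
                              lam=fit.lam))
        if compute_baseline:
            kb, _ = _select_pcs(scores, y_tr, codes_tr, lab_tr.size, kmax,
                                "fixed", use_intercept)
            Xb = scores[:, :kb]
            if use_intercept:
                Xb = np.column_stack([np.ones(len(y_tr)), Xb])
            beta_b, *_ = np.linalg.lstsq(Xb, y_tr, rcond=None)
            xb = np.concatenate([[1.0], Vt[:kb] @ z_heldout]) if use_intercept \
                else Vt[:kb] @ z_heldout
            base_preds[r] = float(xb @ beta_b)
            base_n_pcs[r] = kb
    pred_df = pd.DataFrame({
        "subject_id": subjects, "actual": y, "predicted": preds, "n_pcs": n_pcs,
    })
    metrics = evaluate(preds, y)
    baseline_metrics = None
    if compute_baseline:
        pred_df["baseline_predicted"] = base_preds
        pred_df["baseline_n_pcs"] = base_n_pcs
        baseline_metrics = evaluate(base_preds, y)
    return PredictionResult(variant=variant, predictions=pred_df, metrics=metrics,
                            baseline_metrics=baseline_metrics, folds=folds,
                            feature_names=feature_names)


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

def feature_importance(result_or_folds, feature_names=None, top_k: int = 20,
                       channel_of=None) -> pd.DataFrame:
    """Aggregate per-fold PCA loadings into normalized feature weights.

    Within each fold, the ``top_k`` features of each selected PC (by
    absolute loading) receive weight |loading| x |PC coefficient|; weights
    are summed per feature, averaged across folds, and divided by the
    maximum so the top feature has weight exactly 1.
    """
    if isinstance(result_or_folds, PredictionResult):
        folds = result_or_folds.folds
        feature_names = feature_names or result_or_folds.feature_names
    else:
        folds = list(result_or_folds)
        if feature_names is None:
            raise ValueError("feature_names required when passing raw folds")
    nf = len(feature_names)
    acc = np.zeros(nf)
    n_folds = 0
    for fold in folds:
        if isinstance(fold, FoldInfo):
            L, beta = fold.loadings, fold.beta_pcs
        else:
            L, beta = fold
        L = np.asarray(L, dtype=float)
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if L.size == 0 or beta.size == 0:
            continue
        w = np.zeros(nf)
        for j in range(L.shape[1]):
            mag = np.abs(L[:, j])
            top = np.argsort(-mag, kind="stable")[:top_k]
            w[top] += mag[top] * abs(beta[j])
        acc += w
        n_folds += 1
    if n_folds == 0:
        return pd.DataFrame(columns=["feature", "weight", "channel"])
    avg = acc / n_folds
    peak = avg.max()
    if peak > 0:
        avg = avg / peak
    if channel_of is None:
        try:
            from .oculo_features import FEATURE_CHANNEL
            channel_of = FEATURE_CHANNEL
        except Exception:  # pragma: no cover
            channel_of = {}
    out = pd.DataFrame({
        "feature": feature_names,
        "weight": avg,
        "channel": [channel_of.get(f, "central") for f in feature_names],
    })
    return out.sort_values("weight", ascending=False, ignore_index=True)
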