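"""PLS1 regression by NIPALS with leave-one-out cross-validation,
first-local-minimum factor selection, and leverage/residual diagnostics.

The calibration pipeline is: fit the pretreatment recipe on calibration
scans, leave-one-out over *samples* (all replicate scans of the held-out
sample removed together, column centering re-estimated inside each fold)
to pick the factor count, then a final fit on the full calibration set.
Predictions for a sample are the mean over its replicate scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soyspec.errors import (
    DataError, DegenerateInputError, GridError, ParameterError,
)
from soyspec.preprocess import PreprocessRecipe
from soyspec.spectra_io import ReferenceTable, SpectraSet

_WTOL = 1e-12  # NIPALS weight-collapse threshold, relative to first factor


@dataclass
class PLSModel:
    """A fitted single-response PLS calibration.

    Attributes follow the usual chemometric notation: W are x-weights, P
    x-loadings, T calibration scores, q y-loadings; the regression vector
    ``b = W (P'W)^-1 q`` maps a centered spectrum to a centered prediction.
    """

    recipe: PreprocessRecipe
    n_factors: int
    x_weights: np.ndarray      # (p, k)
    x_loadings: np.ndarray     # (p, k)
    x_scores: np.ndarray       # (n_cal_scans, k)
    y_loadings: np.ndarray     # (k,)
    x_mean: np.ndarray         # (p,) column means of preprocessed X
    y_mean: float
    b: np.ndarray              # (p,)
    explained_x_variance: np.ndarray   # cumulative %, (k,)
    trait: str = ""
    calibration_ids: list[str] = field(default_factory=list)

    # -- persistence: YAML-free JSON bundle keeps full float precision ----
    def save(self, path) -> None:
        payload = {
            "trait": self.trait,
            "n_factors": int(self.n_factors),
            "recipe": self.recipe.to_dict(),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "b": self.b.tolist(),
            "explained_x_variance": self.explained_x_variance.tolist(),
            "calibration_ids": list(self.calibration_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            recipe=PreprocessRecipe.from_dict(d["recipe"]),
            n_factors=d["n_factors"],
            x_weights=np.array(d["x_weights"], dtype=float),
            x_loadings=np.array(d["x_loadings"], dtype=float),
            x_scores=np.array(d["x_scores"], dtype=float),
            y_loadings=np.array(d["y_loadings"], dtype=float),
            x_mean=np.array(d["x_mean"], dtype=float),
            y_mean=d["y_mean"],
            b=np.array(d["b"], dtype=float),
            explained_x_variance=np.array(d["explained_x_variance"], dtype=float),
            trait=d["trait"],
            calibration_ids=d["calibration_ids"],
        )


@dataclass
class CVResult:
    """Leave-one-out cross-validation curve and the chosen factor count."""

    rmsecv_by_factor: np.ndarray        # (max_factors,), index k-1 = k factors
    r_cv_by_factor: np.ndarray
    chosen_factors: int
    per_sample_cv_predictions: pd.Series  # index = sample_id, at chosen k
    capped_folds: int = 0               # folds where rank limited the factors


@dataclass
class DiagnosticsReport:
    """Leverage / standardized-residual screen of calibration samples."""

    leverage: pd.Series              # per calibration scan
    standardized_residual: pd.Series
    flagged_ids: list[str]
    leverage_cutoff: float
    residual_cutoff: float


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int,
                 on_collapse: str = "raise"):
    """Core NIPALS loop on centered data.

    Per factor: w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't),
    then deflate X by t p' and y by t q. Returns (W, P, T, q, ssx,
    k_achieved) where ssx is the per-factor residual X sum of squares.
    When the weight vector collapses (deflated X carries no covariance
    with y left — the rank is exhausted), either raises naming the factor
    or truncates at the achieved count, per ``on_collapse``.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    q = np.zeros(n_factors)
    ssx = np.zeros(n_factors)
    X = Xc.copy()
    y = yc.copy()
    scale0 = None
    k_achieved = n_factors
    for a in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if scale0 is None:
            scale0 = nw if nw > 0 else 1.0
        t = X @ w
        if nw <= _WTOL * scale0 or t @ t <= (_WTOL * scale0) ** 2:
            if on_collapse == "raise":
                raise ParameterError(
                    f"NIPALS weight vector collapsed at factor {a + 1}; "
                    f"reduce n_factors below {a + 1}"
                )
            k_achieved = a
            break
        w /= nw
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X = X - np.outer(t, p_a)
        y = y - t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        ssx[a] = np.sum(X * X)
    return (W[:, :k_achieved], P[:, :k_achieved], T[:, :k_achieved],
            q[:k_achieved], ssx[:k_achieved], k_achieved)


def _regression_vector(W, P, q):
    k = W.shape[1]
    return W @ np.linalg.solve(P.T @ W, np.eye(k)) @ q


def fit_pls1(X: np.ndarray, y: np.ndarray, n_factors: int,
             recipe: PreprocessRecipe | None = None,
             trait: str = "", calibration_ids=()) -> PLSModel:
    """Fit a PLS1 model by NIPALS.

    ``X`` is the preprocessed (column-centered per recipe) calibration
    matrix; ``y`` is centered internally by its mean. ``n_factors`` must
    not exceed min(n_samples - 1, n_wavelengths).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataError(f"y has {y.size} entries for {n} scans")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ParameterError(
            f"n_factors={n_factors} outside [1, {min(n - 1, p)}]"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError(f"trait {trait or 'y'} is constant")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    y_mean = float(y.mean())
    yc = y - y_mean
    W, P, T, q, ssx, _ = _nipals_pls1(Xc, yc, n_factors)
    ss0 = np.sum(Xc * Xc)
    explained = 100.0 * (1.0 - ssx / ss0) if ss0 > 0 else np.full(n_factors, 100.0)
    return PLSModel(
        recipe=recipe if recipe is not None else PreprocessRecipe([]),
        n_factors=n_factors,
        x_weights=W, x_loadings=P, x_scores=T, y_loadings=q,
        x_mean=x_mean, y_mean=y_mean,
        b=_regression_vector(W, P, q),
        explained_x_variance=explained,
        trait=trait, calibration_ids=list(calibration_ids),
    )


def predict_matrix(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict from an already-preprocessed matrix."""
    return model.y_mean + (np.asarray(X, float) - model.x_mean) @ model.b


def predict(model: PLSModel, spectra: SpectraSet,
            per_sample: bool = False):
    """Apply the fitted recipe, then the linear model.

    Returns scan-level predictions (length n_scans) by default; with
    ``per_sample=True`` returns a Series of replicate-averaged predictions
    indexed by sample_id.
    """
    expected = _recipe_input_size(model)
    if expected is not None and len(spectra.grid) != expected:
        raise GridError(
            f"spectra have {len(spectra.grid)} wavelengths; model recipe "
            f"expects {expected}"
        )
    pre = model.recipe.apply(spectra) if model.recipe.steps else spectra
    if pre.absorbance.shape[1] != model.b.size:
        raise GridError(
            f"preprocessed spectra have {pre.absorbance.shape[1]} wavelengths; "
            f"model has {model.b.size}"
        )
    yhat = predict_matrix(model, pre.absorbance)
    if not per_sample:
        return yhat
    return (
        pd.Series(yhat, index=spectra.scan_meta["sample_id"].to_numpy())
        .groupby(level=0, sort=False).mean()
    )


def _recipe_input_size(model: PLSModel) -> int | None:
    # the first stateless steps preserve column count; only select_region
    # changes it, so the input size is unconstrained unless no region step
    # exists. We only check the final size strictly.
    return None if any(
        s["step"] == "select_region" for s in model.recipe.steps
    ) else model.b.size


def first_local_minimum(curve) -> int:
    """Factor count at the first local minimum of an RMSECV curve.

    Returns the first k (1-based) with curve[k] <= curve[k+1] — ties
    resolve to the smaller, more parsimonious k — or len(curve) when the
    curve decreases strictly throughout.
    """
    curve = np.asarray(curve, dtype=float)
    for k in range(curve.size - 1):
        if curve[k] <= curve[k + 1]:
            return k + 1
    return curve.size


def loo_cv(X: np.ndarray, y: np.ndarray, max_factors: int,
           groups=None) -> CVResult:
    """Leave-one-sample-out cross-validation over 1..max_factors.

    ``groups`` gives the sample id of each row (replicate scans share an
    id and are held out together); default is one sample per row. Column
    centering of X and centering of y are re-estimated inside each fold.
    RMSECV at k factors is the root mean squared error of the
    replicate-averaged held-out predictions. ``chosen_factors`` is the
    first local minimum of the RMSECV curve (ties resolve to the smaller
    k); a curve that decreases throughout selects max_factors. Folds whose
    rank cannot support max_factors are capped and counted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if groups is None:
        groups = np.arange(n)
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups.tolist()))
    if len(uniq) < 3:
        raise DataError("leave-one-out needs at least 3 samples")
    max_feasible = min(len(uniq) - 1, X.shape[1])
    capped = 0
    if max_factors > max_feasible:
        max_factors, capped = max_feasible, 1
    preds = np.full((len(uniq), max_factors), np.nan)
    truth = np.zeros(len(uniq))
    for i, g in enumerate(uniq):
        hold = groups == g
        Xtr, ytr = X[~hold], y[~hold]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        k_fold = min(max_factors, Xtr.shape[0] - 1, Xtr.shape[1])
        W, P, T, q, _, k_fold = _nipals_pls1(
            Xtr - xm, ytr - ym, k_fold, on_collapse="truncate")
        if k_fold < max_factors:
            capped += 1
        Xh = X[hold] - xm
        # cumulative prediction over factors: y_hat(k) = ym + Xh W_k (P_k'W_k)^-1 q_k
        for k in range(1, k_fold + 1):
            bk = _regression_vector(W[:, :k], P[:, :k], q[:k])
            preds[i, k - 1] = float(np.mean(Xh @ bk)) + ym
        preds[i, k_fold:] = preds[i, k_fold - 1] if k_fold else ym
        truth[i] = float(np.mean(y[hold]))
    resid = preds - truth[:, None]
    rmsecv = np.sqrt(np.mean(resid ** 2, axis=0))
    r_cv = np.array([
        np.corrcoef(truth, preds[:, k])[0, 1] if np.ptp(preds[:, k]) > 0 else 0.0
        for k in range(max_factors)
    ])
    chosen = first_local_minimum(rmsecv)
    return CVResult(
        rmsecv_by_factor=rmsecv,
        r_cv_by_factor=r_cv,
        chosen_factors=chosen,
        per_sample_cv_predictions=pd.Series(
            preds[:, chosen - 1], index=pd.Index(uniq, name="sample_id")
        ),
        capped_folds=capped,
    )


def diagnostics(model: PLSModel, y: np.ndarray,
                leverage_factor: float = 3.0,
                residual_cutoff: float = 3.0,
                scan_ids=None) -> DiagnosticsReport:
    """Leverage and standardized-residual outlier screen.

    Leverage h_i = t_i' (T'T)^-1 t_i (sums to n_factors over the
    calibration set). Residuals are standardized by RMSEC. A scan is
    flagged when h_i > leverage_factor * k / n or |res| > residual_cutoff.
    """
    T = model.x_scores
    n, k = T.shape
    y = np.asarray(y, dtype=float).ravel()
    h = np.einsum("ij,ij->i", T @ np.linalg.inv(T.T @ T), T)
    fitted = model.y_mean + T @ model.y_loadings
    resid = y - fitted
    rmsec = float(np.sqrt(np.mean(resid ** 2)))
    std_res = resid / rmsec if rmsec > 0 else np.zeros_like(resid)
    lev_cut = leverage_factor * k / n
    idx = pd.Index(
        scan_ids if scan_ids is not None else np.arange(n), name="scan"
    )
    flagged_mask = (h > lev_cut) | (np.abs(std_res) > residual_cutoff)
    flagged = list(dict.fromkeys(np.asarray(idx)[flagged_mask].tolist()))
    return DiagnosticsReport(
        leverage=pd.Series(h, index=idx),
        standardized_residual=pd.Series(std_res, index=idx),
        flagged_ids=flagged,
        leverage_cutoff=lev_cut,
        residual_cutoff=residual_cutoff,
    )


def explained_variance(model: PLSModel) -> np.ndarray:
    """Cumulative % of preprocessed-X sum of squares captured per factor."""
    return model.explained_x_variance


def train_pls(
    spectra: SpectraSet,
    refs: ReferenceTable,
    trait: str,
    recipe: PreprocessRecipe,
    max_factors: int,
    calibration_ids=None,
    select_factors: bool = True,
) -> tuple[PLSModel, CVResult]:
    """End-to-end calibration for one trait.

    Restricts to calibration samples carrying the trait, fits the recipe
    on those scans, runs sample-level LOO-CV to choose the factor count
    (capped at ``max_factors``), and fits the final model on all
    calibration scans. With ``select_factors=False`` the model uses
    ``max_factors`` directly (CV still reported).
    """
    have = set(refs.samples_with(trait))
    ids = [s for s in spectra.sample_ids if s in have]
    if calibration_ids is not None:
        wanted = set(calibration_ids)
        ids = [s for s in ids if s in wanted]
    if len(ids) < 3:
        raise DataError(f"trait {trait!r}: only {len(ids)} usable samples")
    cal = spectra.subset_samples(ids)
    recipe.fit(cal)
    pre = recipe.apply(cal)
    groups = cal.scan_meta["sample_id"].to_numpy()
    y_scan = refs.trait_values(trait).loc[groups].to_numpy()
    # LOO re-centers per fold, so feed it the uncentered transform
    stateless = PreprocessRecipe(
        [s for s in recipe.steps
         if not (s["step"] == "mean_center" and s.get("mode", "column") == "column")]
    )
    X_uncentered = stateless.apply(cal).absorbance
    cv = loo_cv(X_uncentered, y_scan, max_factors, groups=groups)
    k = cv.chosen_factors if select_factors else max_factors
    model = fit_pls1(
        pre.absorbance, y_scan, k, recipe=recipe, trait=trait,
        calibration_ids=ids,
    )
    return model, cv
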