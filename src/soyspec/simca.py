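"""SIMCA class modeling: per-class principal-component envelopes with an
F-test membership rule, interclass distance, and discriminating power.

Each labeled class gets its own PCA subspace (SVD of the class-mean-
centered block of preprocessed calibration scans). A new scan is compared
to every class by the variance of its residual after projection onto the
class subspace; membership is an F-test of that variance against the
class's own pooled residual variance s0^2, and the scan is assigned to the
accepting class with the smallest residual distance (or "no_match").

Degrees of freedom follow the (n_c - k - 1)(p - k) convention for the
class and (p - k) for a single new scan; conventions vary between
implementations, so both are explicit here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from soyspec.errors import (
    DataError, DegenerateInputError, GridError, ParameterError,
)
from soyspec.preprocess import PreprocessRecipe
from soyspec.spectra_io import SpectraSet


@dataclass
class ClassModel:
    """One class's PCA envelope in preprocessed space."""

    label: str
    mean: np.ndarray          # (p,)
    loadings: np.ndarray      # (p, k), orthonormal columns
    k: int
    s0: float                 # pooled residual sd of own calibration scans
    dof: float                # residual dof: (n_c - k - 1)(p - k)
    n_scans: int
    explained: np.ndarray     # cumulative % variance per PC

    def residuals(self, X: np.ndarray) -> np.ndarray:
        """Residual matrix after projecting rows onto the class subspace."""
        Xc = np.asarray(X, float) - self.mean
        return Xc - (Xc @ self.loadings) @ self.loadings.T


@dataclass
class SIMCAModel:
    classes: dict[str, ClassModel]
    alpha: float
    recipe: PreprocessRecipe
    n_wavelengths: int

    def class_labels(self) -> list[str]:
        return list(self.classes)

    # single-file JSON bundle; full float precision so classification
    # decisions survive a save/load round trip unchanged
    def save(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "n_wavelengths": self.n_wavelengths,
            "recipe": self.recipe.to_dict(),
            "classes": {
                lab: {
                    "mean": cm.mean.tolist(),
                    "loadings": cm.loadings.tolist(),
                    "k": cm.k,
                    "s0": cm.s0,
                    "dof": cm.dof,
                    "n_scans": cm.n_scans,
                    "explained": cm.explained.tolist(),
                }
                for lab, cm in self.classes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SIMCAModel":
        with open(path) as fh:
            d = json.load(fh)
        classes = {
            lab: ClassModel(
                label=lab,
                mean=np.array(c["mean"], dtype=float),
                loadings=np.array(c["loadings"], dtype=float),
                k=c["k"],
                s0=c["s0"],
                dof=c["dof"],
                n_scans=c["n_scans"],
                explained=np.array(c["explained"], dtype=float),
            )
            for lab, c in d["classes"].items()
        }
        return cls(
            classes=classes, alpha=d["alpha"],
            recipe=PreprocessRecipe.from_dict(d["recipe"]),
            n_wavelengths=d["n_wavelengths"],
        )


@dataclass
class ClassDecision:
    """Per-scan classification outcome.

    ``distance`` maps class label -> residual sd ratio (sample residual sd
    over the class s0); ``accepted`` lists every class whose F-test passed;
    ``assigned`` is the accepting class with minimal distance, or
    "no_match".
    """

    distance: dict[str, float]
    accepted: list[str]
    assigned: str


def _fit_class(label: str, X: np.ndarray, k: int | None,
               variance_target: float, k_cap: int) -> ClassModel:
    n, p = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    # economy SVD of the centered class block; PCs = right singular vectors
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    # relative threshold: rounding noise on identical scans is not variance
    if total <= 1e-20 * max(np.sum(X * X), 1.0):
        raise DegenerateInputError(
            f"class {label!r} has zero spectral variance (s0 = 0)"
        )
    cum = 100.0 * np.cumsum(var) / total
    if k is None:
        k = int(np.searchsorted(cum, variance_target) + 1)
        k = min(k, k_cap, n - 2, p)
        k = max(k, 1)
    if n < k + 2:
        raise DataError(
            f"class {label!r} has {n} scans; needs at least {k + 2} for k={k}"
        )
    L = Vt[:k].T
    R = Xc - (Xc @ L) @ L.T
    dof = (n - k - 1) * (p - k)
    s0_sq = float(np.sum(R * R)) / dof
    if s0_sq <= 0:
        raise DegenerateInputError(f"class {label!r} residual variance is 0")
    return ClassModel(
        label=label, mean=mu, loadings=L, k=k, s0=float(np.sqrt(s0_sq)),
        dof=dof, n_scans=n, explained=cum[: max(k, 1)],
    )


def fit_simca(
    calibration: SpectraSet,
    recipe: PreprocessRecipe,
    k_per_class: int | None = None,
    alpha: float = 1e-4,
    variance_target: float = 98.0,
    k_cap: int = 10,
) -> SIMCAModel:
    """Fit per-class PCA models on labeled calibration scans.

    The recipe is fitted on the pooled calibration scans; each class is
    then mean-centered on its own class mean and decomposed by SVD. With
    ``k_per_class=None`` each class keeps the smallest number of PCs whose
    cumulative class variance reaches ``variance_target`` % (capped at
    ``k_cap``).

    ``alpha`` is the per-scan significance level of the membership F-test.
    The default is deliberately conservative (1e-4): membership is tested
    once per scan, so a conventional 0.05 level would reject roughly one
    in twenty scans from a batch of genuine class members, while spectra
    that truly fall outside a class exceed the critical variance ratio by
    orders of magnitude and are rejected at any reasonable level.
    """
    labels = calibration.scan_meta["class_label"]
    if labels.isna().any():
        raise DataError("every calibration scan needs a class label")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise DataError(f"need at least 2 classes, got {uniq}")
    recipe.fit(calibration)
    pre = recipe.apply(calibration)
    classes = {}
    for lab in uniq:
        mask = (labels == lab).to_numpy()
        if k_per_class is not None and mask.sum() < k_per_class + 2:
            raise DataError(
                f"class {lab!r}: {mask.sum()} scans < k_per_class + 2"
            )
        classes[lab] = _fit_class(
            lab, pre.absorbance[mask], k_per_class, variance_target, k_cap
        )
    return SIMCAModel(
        classes=classes, alpha=alpha, recipe=recipe,
        n_wavelengths=pre.absorbance.shape[1],
    )


def classify(model: SIMCAModel, spectra: SpectraSet) -> list[ClassDecision]:
    """Classify each scan against every class envelope.

    A scan is inside class c's envelope when its residual variance ratio
    (s/s0)^2 is below the F critical value at the model alpha with
    (p - k, class dof) degrees of freedom.
    """
    pre = model.recipe.apply(spectra)
    X = pre.absorbance
    if X.shape[1] != model.n_wavelengths:
        raise GridError(
            f"preprocessed spectra have {X.shape[1]} wavelengths; "
            f"model was fitted with {model.n_wavelengths}"
        )
    p = model.n_wavelengths
    decisions = []
    dist = {}
    crit = {}
    res_sd = {}
    for lab, cm in model.classes.items():
        R = cm.residuals(X)
        sd = np.sqrt(np.sum(R * R, axis=1) / (p - cm.k))
        res_sd[lab] = sd
        crit[lab] = stats.f.ppf(1.0 - model.alpha, p - cm.k, cm.dof)
    for i in range(X.shape[0]):
        dist = {lab: float(res_sd[lab][i] / model.classes[lab].s0)
                for lab in model.classes}
        accepted = [lab for lab in model.classes
                    if dist[lab] ** 2 <= crit[lab]]
        if accepted:
            assigned = min(accepted, key=lambda lab: dist[lab])
        else:
            assigned = "no_match"
        decisions.append(ClassDecision(dist, accepted, assigned))
    return decisions


def _cross_fit_ms(model: SIMCAModel, cal_pre: dict[str, np.ndarray],
                  x: str, y: str, per_variable: bool) -> np.ndarray | float:
    """Mean squared residual of class-x calibration scans under class-y's
    model (per variable when requested)."""
    R = model.classes[y].residuals(cal_pre[x])
    if per_variable:
        return np.mean(R * R, axis=0)
    return float(np.mean(R * R))


def _cal_blocks(model: SIMCAModel, calibration: SpectraSet) -> dict[str, np.ndarray]:
    pre = model.recipe.apply(calibration)
    labels = calibration.scan_meta["class_label"]
    return {
        lab: pre.absorbance[(labels == lab).to_numpy()]
        for lab in model.classes
    }


def interclass_distance(model: SIMCAModel, calibration: SpectraSet,
                        a: str, b: str) -> float:
    """Pooled-residual interclass distance between two fitted classes.

    ICD = sqrt((s2_ab + s2_ba) / (s2_aa + s2_bb)) where s2_xy is the mean
    squared residual of class-x calibration scans fitted to class-y's
    model. Two classes drawn from one distribution give ICD near 1; values
    above 3 are conventionally read as significant separation.
    """
    if a == b:
        raise ParameterError("interclass distance needs two distinct classes")
    for lab in (a, b):
        if lab not in model.classes:
            raise ParameterError(f"class {lab!r} not in model")
    blocks = _cal_blocks(model, calibration)
    s2_ab = _cross_fit_ms(model, blocks, a, b, False)
    s2_ba = _cross_fit_ms(model, blocks, b, a, False)
    s2_aa = _cross_fit_ms(model, blocks, a, a, False)
    s2_bb = _cross_fit_ms(model, blocks, b, b, False)
    return float(np.sqrt((s2_ab + s2_ba) / (s2_aa + s2_bb)))


def discriminating_power(model: SIMCAModel, calibration: SpectraSet,
                         a: str, b: str) -> np.ndarray:
    """Per-wavelength contribution to the separation of classes a and b.

    DP_j = sqrt((s2_ab,j + s2_ba,j) / (s2_aa,j + s2_bb,j)) with
    per-variable residual mean squares; near 1 at wavelengths that carry
    no class information, large where the classes differ.
    """
    if a == b:
        raise ParameterError("discriminating power needs two distinct classes")
    for lab in (a, b):
        if lab not in model.classes:
            raise ParameterError(f"class {lab!r} not in model")
    blocks = _cal_blocks(model, calibration)
    s2_ab = _cross_fit_ms(model, blocks, a, b, True)
    s2_ba = _cross_fit_ms(model, blocks, b, a, True)
    s2_aa = _cross_fit_ms(model, blocks, a, a, True)
    s2_bb = _cross_fit_ms(model, blocks, b, b, True)
    return np.sqrt((s2_ab + s2_ba) / (s2_aa + s2_bb))


def confusion_metrics(decisions: list[ClassDecision], truth) -> dict:
    """Sensitivity/specificity per class plus misclassified and no-match
    counts.

    Sensitivity of class c = fraction of class-c scans assigned to c;
    specificity = fraction of non-c scans not assigned to c. No-match
    decisions count in the denominators (a no-match on a class-c scan
    costs sensitivity; on a non-c scan it is a true negative for c).
    """
    truth = list(truth)
    if len(decisions) != len(truth):
        raise DataError("decisions and truth lengths differ")
    labels = list(dict.fromkeys(truth))
    out = {"per_class": {}, "misclassified": 0, "no_match": 0}
    assigned = [d.assigned for d in decisions]
    for d, t in zip(assigned, truth):
        if d == "no_match":
            out["no_match"] += 1
        elif d != t:
            out["misclassified"] += 1
    for c in labels:
        tp = sum(1 for d, t in zip(assigned, truth) if t == c and d == c)
        n_c = sum(1 for t in truth if t == c)
        tn = sum(1 for d, t in zip(assigned, truth) if t != c and d != c)
        n_not = len(truth) - n_c
        out["per_class"][c] = {
            "sensitivity": 100.0 * tp / n_c if n_c else float("nan"),
            "specificity": 100.0 * tn / n_not if n_not else float("nan"),
        }
    return out
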