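"""Spectral pretreatment: 2-norm*100 vector normalization, Savitzky-Golay
derivatives, mean-centering, and wavelength-region selection, composable
into a fit-once / apply-many recipe.

The regression pipeline default is normalize -> 2nd-derivative SG (21-point
window) -> region cut -> column mean-centering; the class-modeling default
is row-centering followed by normalization. Stateless steps are applied
per scan; column centering learns its means on the calibration set only
and reuses them on any later data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml
from scipy.signal import savgol_filter

from soyspec.errors import DegenerateInputError, ParameterError
from soyspec.spectra_io import SpectraSet, WavelengthGrid


def normalize_2norm100(spectrum: np.ndarray) -> np.ndarray:
    """Scale a spectrum (or each row of a matrix) to Euclidean norm 100.

    Idempotent and invariant to positive scaling; suppresses multiplicative
    scatter differences between scans.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim == 1:
        nrm = np.linalg.norm(x)
        if nrm == 0:
            raise DegenerateInputError("cannot normalize an all-zero spectrum")
        return 100.0 * x / nrm
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(nrm == 0):
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    return 100.0 * x / nrm


def savgol(
    spectra: SpectraSet,
    window: int = 21,
    polyorder: int = 3,
    deriv_order: int = 2,
    per_nm: bool = False,
) -> SpectraSet:
    """Savitzky-Golay smoothing/differentiation along the wavelength axis.

    Each point is the ``deriv_order``-th derivative of the least-squares
    polynomial of degree ``polyorder`` fitted to the window centered there;
    edge points evaluate the polynomial fitted to the nearest full interior
    window at the edge offset (no padding with fabricated data).

    With ``per_nm=False`` (default) derivatives are per grid step; with
    ``per_nm=True`` they are per nm**deriv_order. Either convention is fine
    for PLS modeling, which is column-scale equivariant after centering.
    """
    _check_savgol_params(window, polyorder, deriv_order, len(spectra.grid))
    delta = spectra.grid.spacing if per_nm else 1.0
    out = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv_order, delta=delta, axis=1, mode="interp",
    )
    return spectra.with_absorbance(out)


def _check_savgol_params(window, polyorder, deriv_order, n_points):
    if window % 2 == 0:
        raise ParameterError(f"savgol window must be odd, got {window}")
    if window < polyorder + 1:
        raise ParameterError(
            f"savgol window {window} must exceed polyorder {polyorder}"
        )
    if deriv_order > polyorder:
        raise ParameterError(
            f"derivative order {deriv_order} exceeds polyorder {polyorder}"
        )
    if window > n_points:
        raise ParameterError(
            f"savgol window {window} exceeds grid length {n_points}"
        )


def mean_center(
    spectra: SpectraSet,
    mode: str = "column",
    fitted_means: np.ndarray | None = None,
) -> SpectraSet:
    """Subtract means from the absorbance matrix.

    ``row`` mode subtracts each scan's own mean (the per-spectrum centering
    used before class modeling); ``column`` mode subtracts per-wavelength
    means — ``fitted_means`` when given (means learned on calibration data),
    otherwise the matrix's own column means.
    """
    A = spectra.absorbance
    if mode == "row":
        if fitted_means is not None:
            raise ParameterError("fitted_means is meaningless in row mode")
        out = A - A.mean(axis=1, keepdims=True)
    elif mode == "column":
        if fitted_means is None:
            mu = A.mean(axis=0)
        else:
            mu = np.asarray(fitted_means, dtype=float)
            if mu.shape != (A.shape[1],):
                raise ParameterError(
                    f"fitted_means length {mu.size} != {A.shape[1]} wavelengths"
                )
        out = A - mu
    else:
        raise ParameterError(f"unknown centering mode {mode!r}")
    return spectra.with_absorbance(out)


def select_region(spectra: SpectraSet, lo_nm: float, hi_nm: float) -> SpectraSet:
    """Keep grid points in the closed interval [lo_nm, hi_nm]."""
    if lo_nm >= hi_nm:
        raise ParameterError(f"empty region: lo {lo_nm} >= hi {hi_nm}")
    wl = spectra.grid.values
    mask = (wl >= lo_nm) & (wl <= hi_nm)
    if not mask.any():
        raise ParameterError(
            f"no grid point inside [{lo_nm}, {hi_nm}] nm "
            f"(grid spans {wl[0]:g}-{wl[-1]:g} nm)"
        )
    return spectra.with_absorbance(
        spectra.absorbance[:, mask], WavelengthGrid(wl[mask])
    )


@dataclass
class PreprocessRecipe:
    """Ordered pretreatment steps with fit-once state.

    Steps are dicts with a ``step`` key:

    * ``{"step": "normalize_2norm100"}``
    * ``{"step": "savgol", "window": 21, "polyorder": 3, "deriv_order": 2,
       "per_nm": False}``
    * ``{"step": "select_region", "lo_nm": ..., "hi_nm": ...}``
    * ``{"step": "mean_center", "mode": "column"|"row"}``

    ``fit`` learns the column means (the only stateful step) from the
    calibration set; ``apply`` then transforms any set with that stored
    state and never re-estimates.
    """

    steps: list[dict]
    fitted_state: dict[int, Any] = field(default_factory=dict)

    _KNOWN = ("normalize_2norm100", "savgol", "select_region", "mean_center")

    def __post_init__(self):
        for s in self.steps:
            name = s.get("step")
            if name not in self._KNOWN:
                raise ParameterError(f"unknown recipe step {name!r}")
            if name == "savgol":
                _check_savgol_params(
                    s.get("window", 21), s.get("polyorder", 3),
                    s.get("deriv_order", 2), np.inf,
                )
            if name == "select_region" and s["lo_nm"] >= s["hi_nm"]:
                raise ParameterError("select_region needs lo_nm < hi_nm")

    @property
    def is_fitted(self) -> bool:
        return all(
            i in self.fitted_state
            for i, s in enumerate(self.steps)
            if s["step"] == "mean_center" and s.get("mode", "column") == "column"
        )

    def fit(self, calibration: SpectraSet) -> "PreprocessRecipe":
        """Learn stateful parameters from the calibration set (in order,
        each step seeing the output of the previous)."""
        self.fitted_state = {}
        current = calibration
        for i, s in enumerate(self.steps):
            if s["step"] == "mean_center" and s.get("mode", "column") == "column":
                self.fitted_state[i] = current.absorbance.mean(axis=0)
            current = self._apply_step(current, i, s)
        return self

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        if not self.is_fitted:
            raise ParameterError("recipe has unfitted column-centering steps")
        current = spectra
        for i, s in enumerate(self.steps):
            current = self._apply_step(current, i, s)
        return current

    def _apply_step(self, spectra, i, s):
        name = s["step"]
        if name == "normalize_2norm100":
            return spectra.with_absorbance(normalize_2norm100(spectra.absorbance))
        if name == "savgol":
            return savgol(
                spectra, s.get("window", 21), s.get("polyorder", 3),
                s.get("deriv_order", 2), s.get("per_nm", False),
            )
        if name == "select_region":
            return select_region(spectra, s["lo_nm"], s["hi_nm"])
        mode = s.get("mode", "column")
        if mode == "column":
            return mean_center(spectra, "column", self.fitted_state[i])
        return mean_center(spectra, "row")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "steps": [dict(s) for s in self.steps],
            "fitted_state": {
                int(i): np.asarray(v).tolist()
                for i, v in self.fitted_state.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        recipe = cls([dict(s) for s in d["steps"]])
        recipe.fitted_state = {
            int(i): np.asarray(v, dtype=float)
            for i, v in d.get("fitted_state", {}).items()
        }
        return recipe

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessRecipe":
        return cls.from_dict(yaml.safe_load(text))


def regression_recipe(lo_nm: float, hi_nm: float, window: int = 21,
                      polyorder: int = 3) -> PreprocessRecipe:
    """Default quantification pretreatment: normalize -> 2nd-derivative SG
    -> region cut -> column centering."""
    return PreprocessRecipe([
        {"step": "normalize_2norm100"},
        {"step": "savgol", "window": window, "polyorder": polyorder,
         "deriv_order": 2},
        {"step": "select_region", "lo_nm": lo_nm, "hi_nm": hi_nm},
        {"step": "mean_center", "mode": "column"},
    ])


def simca_recipe() -> PreprocessRecipe:
    """Default class-modeling pretreatment: per-spectrum (row) centering
    followed by 2-norm*100 normalization, no derivative."""
    return PreprocessRecipe([
        {"step": "mean_center", "mode": "row"},
        {"step": "normalize_2norm100"},
    ])


def fit_apply_recipe(
    recipe: PreprocessRecipe,
    calibration: SpectraSet,
    others: list[SpectraSet] = (),
) -> tuple[SpectraSet, list[SpectraSet]]:
    """Fit the recipe on the calibration set, then transform the calibration
    set and every other set with the same frozen state."""
    recipe.fit(calibration)
    return recipe.apply(calibration), [recipe.apply(s) for s in others]
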