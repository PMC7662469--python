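"""Spectra and reference-table I/O, scan metadata, and the replicate-aware
calibration/validation split.

On-disk formats are plain CSV (UTF-8, "." decimal, "," separator):

* spectra: columns ``sample_id, replicate_id, class_label`` followed by one
  numeric column per wavelength (header = wavelength in nm, strictly
  increasing, uniform spacing);
* references: ``sample_id`` plus one column per trait, blank cell = missing.

Replicate scans of one sample are never split across the calibration and
validation sets: sampling happens over unique sample ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from soyspec.errors import DataError, FormatError, GridError

#: Traits modeled by the study, in reporting order.
TRAITS = (
    "threonine", "cysteine", "methionine", "lysine", "tryptophan",
    "total_protein", "palmitic", "stearic", "oleic", "linoleic",
    "linolenic", "fat", "moisture",
)

FATTY_ACIDS = ("palmitic", "stearic", "oleic", "linoleic", "linolenic")

CLASS_LABELS = ("high_oleic", "conventional", "soy_product")

_META_COLUMNS = ("sample_id", "replicate_id", "class_label")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing wavelength axis in nm.

    The instrument emulated here covers 1350-2560 nm; grids must stay
    inside those bounds and keep a constant spacing (SG differentiation
    and region selection both assume uniformity).
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 8:
            raise GridError("wavelength grid needs at least 8 points")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if np.ptp(diffs) > 1e-9:
            raise GridError(
                f"wavelength spacing must be uniform (spread {np.ptp(diffs):.3g} nm)"
            )
        if vals[0] < 1350.0 - 1e-9 or vals[-1] > 2560.0 + 1e-9:
            raise GridError(
                f"grid [{vals[0]:g}, {vals[-1]:g}] nm outside the 1350-2560 nm range"
            )

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )


@dataclass
class SpectraSet:
    """Absorbance matrix on a shared grid with per-scan metadata.

    ``scan_meta`` has exactly the columns sample_id (str), replicate_id
    (int) and class_label (str or None); (sample_id, replicate_id) pairs
    are unique.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    scan_meta: pd.DataFrame

    def __post_init__(self):
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise DataError("absorbance must be a 2-D matrix")
        if A.shape[1] != len(self.grid):
            raise GridError(
                f"absorbance has {A.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if np.isnan(A).any():
            raise DataError("absorbance matrix contains missing values")
        self.absorbance = A
        meta = self.scan_meta.reset_index(drop=True).copy()
        for col in _META_COLUMNS:
            if col not in meta.columns:
                raise DataError(f"scan_meta missing column {col!r}")
        if len(meta) != A.shape[0]:
            raise DataError("scan_meta length must equal number of scans")
        meta["sample_id"] = meta["sample_id"].astype(str)
        meta["replicate_id"] = meta["replicate_id"].astype(int)
        dup = meta.duplicated(subset=["sample_id", "replicate_id"])
        if dup.any():
            pair = meta.loc[dup.idxmax(), ["sample_id", "replicate_id"]].tolist()
            raise DataError(f"duplicate (sample_id, replicate_id) pair: {pair}")
        self.scan_meta = meta[list(_META_COLUMNS)]

    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        """Unique sample ids in first-appearance order."""
        return list(dict.fromkeys(self.scan_meta["sample_id"]))

    def subset_scans(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(self.grid, self.absorbance[mask],
                          self.scan_meta.loc[mask])

    def subset_samples(self, sample_ids) -> "SpectraSet":
        keep = set(sample_ids)
        mask = self.scan_meta["sample_id"].isin(keep).to_numpy()
        return self.subset_scans(mask)

    def with_absorbance(self, A: np.ndarray,
                        grid: WavelengthGrid | None = None) -> "SpectraSet":
        """Copy with a new matrix (and optionally grid); metadata shared."""
        return SpectraSet(grid or self.grid, A, self.scan_meta)


@dataclass
class ReferenceTable:
    """Per-sample trait values.

    Amino acids, protein, fat and moisture are % wet basis; fatty acids
    are % of GC peak area. Missing values (NaN) are allowed per trait.
    """

    values: pd.DataFrame  # index = sample_id (str), columns = trait names

    def __post_init__(self):
        df = self.values.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            df.index.name = "sample_id"
        df.index = df.index.astype(str)
        df = df.astype(float)
        if (df.min(skipna=True) < 0).any():
            bad = df.columns[(df.min(skipna=True) < 0)].tolist()
            raise DataError(f"negative trait values in {bad}")
        fa = [c for c in df.columns if c in FATTY_ACIDS]
        if fa and (df[fa].max(skipna=True) > 100).any():
            raise DataError("fatty-acid percentages exceed 100")
        self.values = df

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.values.columns:
            raise DataError(f"trait {trait!r} not in reference table")
        return self.values[trait]

    def samples_with(self, trait: str) -> list[str]:
        s = self.trait_values(trait)
        return list(s.index[s.notna()])


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint calibration/validation sample-id sets for one trait."""

    calibration_ids: frozenset
    validation_ids: frozenset
    seed: int

    def __post_init__(self):
        if self.calibration_ids & self.validation_ids:
            raise DataError("calibration and validation sets overlap")


def read_spectra(path) -> SpectraSet:
    """Read a wide spectra CSV (see module docstring for the dialect)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"spectra file missing column {col!r}")
    wl_cols = [c for c in df.columns if c not in _META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header: {exc}") from None
    try:
        grid = WavelengthGrid(wavelengths)
    except GridError as exc:
        raise FormatError(str(exc)) from None
    A = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(A).any():
        row, col = np.argwhere(np.isnan(A))[0]
        raise FormatError(
            f"missing absorbance at row {row}, wavelength {wl_cols[col]}"
        )
    meta = df[list(_META_COLUMNS)].copy()
    meta["class_label"] = meta["class_label"].where(
        meta["class_label"].notna() & (meta["class_label"].astype(str) != ""),
        None,
    )
    return SpectraSet(grid, A, meta)


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write the wide spectra CSV; absorbance at 17 significant digits so a
    round-trip reproduces the matrix bit-for-bit."""
    meta = spectra.scan_meta.copy()
    meta["class_label"] = meta["class_label"].fillna("")
    wl_cols = [format(w, "g") for w in spectra.grid.values]
    body = pd.DataFrame(spectra.absorbance, columns=wl_cols)
    out = pd.concat([meta.reset_index(drop=True), body], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def read_references(path) -> ReferenceTable:
    """Read a reference CSV: sample_id column + one column per trait."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("reference file missing 'sample_id' column")
    return ReferenceTable(df)


def write_references(refs: ReferenceTable, path) -> None:
    refs.values.to_csv(path, float_format="%.17g")


def assign_splits(
    spectra: SpectraSet,
    refs: ReferenceTable,
    trait: str,
    fraction: float = 0.8,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly split samples carrying ``trait`` into calibration and
    validation sets.

    Sampling is over unique sample ids so every replicate scan of a sample
    lands on the same side; |calibration| = round(fraction * n_samples).
    Deterministic in (sample-id set, fraction, seed).
    """
    if not 0 < fraction < 1:
        raise DataError(f"fraction must be in (0, 1), got {fraction}")
    with_trait = set(refs.samples_with(trait))
    ids = [s for s in spectra.sample_ids if s in with_trait]
    if len(ids) < 2:
        raise DataError(
            f"trait {trait!r} present for {len(ids)} sample(s); need at least 2"
        )
    ids = sorted(ids)  # order-independent determinism
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_cal = int(round(fraction * len(ids)))
    n_cal = min(max(n_cal, 1), len(ids) - 1)
    cal = frozenset(ids[i] for i in perm[:n_cal])
    val = frozenset(ids[i] for i in perm[n_cal:])
    return SplitAssignment(cal, val, seed)
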