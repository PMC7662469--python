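"""Synthetic soy compositions and NIR-like diffuse-reflectance spectra.

The generator emulates the measured populations — conventional soybeans,
high-oleic (Plenish-type) soybeans, and powdered soy products — by drawing
trait values from the published population statistics and rendering each
sample's spectrum as a linear mixture of Gaussian-band pure-component
spectra plus multiplicative scatter, a linear baseline, and white noise:

    scan = m * sum_k fraction_k * pure_k(lambda) + (offset + slope * s(lambda)) + eps

with m lognormal, s(lambda) the wavelength scaled to [-1, 1], and eps iid
normal. Replicate scans of one sample share the composition and differ in
scatter, baseline, and noise. All randomness flows from an explicit seed.

This is a phenomenological model: it makes composition linearly
identifiable from spectra, which real powders (particle-size effects,
nonlinear scatter, band shifts) are not guaranteed to be.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from soyspec.errors import ConfigError, DataError
from soyspec.spectra_io import ReferenceTable, SpectraSet, WavelengthGrid

COMPONENTS = ("protein", "fat_oleic", "fat_linoleic_linolenic",
              "fat_saturated", "water", "carbohydrate")

#: Amino-acid mass as a fraction of total protein, from the measured
#: soybean means (e.g. lysine 2.43% of a 34.12% protein sample).
AMINO_RATIOS = {
    "threonine": 1.45 / 34.12,
    "cysteine": 0.55 / 34.12,
    "methionine": 0.51 / 34.12,
    "lysine": 2.43 / 34.12,
    "tryptophan": 0.44 / 34.12,
}

AMINO_JITTER_REL = 0.075  # sd of the per-sample ratio jitter, relative

#: Oleic-linoleic anticorrelation of the deviations from the class means.
#: The desaturation pathway trades oleate against linoleate, and without it
#: independent draws would push the fatty-acid sum past 100% so often that
#: renormalization would visibly distort the printed class statistics.
OLEIC_LINOLEIC_R = -0.9


@dataclass
class BandLibrary:
    """Gaussian band parameters per pure component.

    ``components`` maps a component name to a list of
    ``{"center_nm": ..., "sigma_nm": ..., "height": ...}`` dicts; height is
    absorbance per unit mass fraction.
    """

    components: dict[str, list[dict]]

    def __post_init__(self):
        for name, bands in self.components.items():
            if name not in COMPONENTS:
                raise ConfigError(f"unknown component {name!r}")
            for b in bands:
                if not 1350.0 <= b["center_nm"] <= 2560.0:
                    raise ConfigError(
                        f"{name}: band center {b['center_nm']} nm outside 1350-2560"
                    )
                if b["sigma_nm"] <= 0 or b["height"] <= 0:
                    raise ConfigError(f"{name}: sigma and height must be positive")

    @classmethod
    def from_yaml(cls, text: str) -> "BandLibrary":
        return cls(yaml.safe_load(text)["components"])

    @classmethod
    def from_file(cls, path) -> "BandLibrary":
        with open(path) as fh:
            return cls.from_yaml(fh.read())


def default_band_library() -> BandLibrary:
    """The band library shipped with the package (editable YAML)."""
    text = (resources.files("soyspec") / "data" / "band_library.yaml").read_text()
    return BandLibrary.from_yaml(text)


@dataclass
class TraitDist:
    """Truncated normal (mean, sd, lo, hi) or uniform (lo, hi) draw."""

    kind: str  # "truncnorm" | "uniform"
    mean: float = 0.0
    sd: float = 0.0
    lo: float = 0.0
    hi: float = 0.0

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConfigError(f"infeasible truncation: lo {self.lo} > hi {self.hi}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, n)
        out = np.empty(n)
        remaining = np.arange(n)
        # rejection sampling; truncation bounds are several sd wide
        while remaining.size:
            cand = rng.normal(self.mean, self.sd, remaining.size)
            ok = (cand >= self.lo) & (cand <= self.hi)
            out[remaining[ok]] = cand[ok]
            remaining = remaining[~ok]
        return out


@dataclass
class PopulationSpec:
    """Composition distributions for one sample population."""

    name: str
    traits: dict[str, TraitDist]


def population_spec(name: str) -> PopulationSpec:
    """Built-in population statistics.

    ``conventional`` and ``high_oleic`` use the measured class means/sds
    (protein 33.66+-0.60 vs 34.17+-0.61 %, oleic 23.35+-3.65 vs
    79.25+-2.00 % of peak area, ...); ``soybean`` is the pooled
    conventional-type soybean population (protein 34.12+-0.89 % truncated
    to the printed 32.48-37.40 range); ``soy_product`` draws protein
    uniformly over the printed 42.96-81.91 % range with the low fat
    content of isolates and concentrates.
    """
    if name == "conventional":
        t = {
            "total_protein": TraitDist("truncnorm", 33.66, 0.60, 31.26, 36.06),
            "fat": TraitDist("truncnorm", 16.27, 0.10, 15.87, 16.67),
            "moisture": TraitDist("truncnorm", 5.49, 0.09, 5.30, 5.68),
            "palmitic": TraitDist("truncnorm", 11.95, 0.69, 9.19, 14.71),
            "stearic": TraitDist("truncnorm", 4.91, 0.23, 3.99, 5.83),
            "oleic": TraitDist("truncnorm", 23.35, 3.65, 8.75, 37.95),
            "linoleic": TraitDist("truncnorm", 51.61, 3.13, 39.09, 64.13),
            "linolenic": TraitDist("truncnorm", 7.09, 0.53, 4.97, 9.21),
        }
    elif name == "high_oleic":
        t = {
            "total_protein": TraitDist("truncnorm", 34.17, 0.61, 31.73, 36.61),
            "fat": TraitDist("truncnorm", 16.42, 0.19, 15.66, 17.18),
            "moisture": TraitDist("truncnorm", 5.49, 0.09, 5.30, 5.68),
            "palmitic": TraitDist("truncnorm", 7.00, 0.52, 4.92, 9.08),
            "stearic": TraitDist("truncnorm", 3.87, 0.33, 2.55, 5.19),
            "oleic": TraitDist("truncnorm", 79.25, 2.00, 71.25, 87.25),
            "linoleic": TraitDist("truncnorm", 5.99, 1.32, 0.71, 11.27),
            "linolenic": TraitDist("truncnorm", 2.21, 0.32, 0.93, 3.49),
        }
    elif name == "soybean":
        t = {
            "total_protein": TraitDist("truncnorm", 34.12, 0.89, 32.48, 37.40),
            "fat": TraitDist("truncnorm", 16.35, 0.18, 16.07, 16.97),
            "moisture": TraitDist("truncnorm", 5.49, 0.09, 5.30, 5.68),
            "palmitic": TraitDist("truncnorm", 11.95, 0.69, 9.19, 14.71),
            "stearic": TraitDist("truncnorm", 4.91, 0.23, 3.99, 5.83),
            "oleic": TraitDist("truncnorm", 23.35, 3.65, 8.75, 37.95),
            "linoleic": TraitDist("truncnorm", 51.61, 3.13, 39.09, 64.13),
            "linolenic": TraitDist("truncnorm", 7.09, 0.53, 4.97, 9.21),
        }
    elif name == "soy_product":
        t = {
            "total_protein": TraitDist("uniform", lo=42.96, hi=81.91),
            "fat": TraitDist("uniform", lo=1.0, hi=6.0),
            "moisture": TraitDist("uniform", lo=4.0, hi=7.0),
            "palmitic": TraitDist("truncnorm", 11.95, 0.69, 9.19, 14.71),
            "stearic": TraitDist("truncnorm", 4.91, 0.23, 3.99, 5.83),
            "oleic": TraitDist("truncnorm", 23.35, 3.65, 8.75, 37.95),
            "linoleic": TraitDist("truncnorm", 51.61, 3.13, 39.09, 64.13),
            "linolenic": TraitDist("truncnorm", 7.09, 0.53, 4.97, 9.21),
        }
    else:
        raise ConfigError(f"unknown population {name!r}")
    return PopulationSpec(name, t)


@dataclass
class SyntheticConfig:
    """Spectra-rendering parameters.

    Defaults: 1350-2558 nm grid at 8 nm spacing (152 points), triplicate
    scans, noise sd 0.02 absorbance, 2% multiplicative scatter sd, and
    baseline offset/slope sds of 0.004 absorbance. The noise sd is a
    catch-all error budget (detector noise plus everything the linear
    mixture model leaves out, including reference-assay error), calibrated
    once so the protein calibration's residual predictive deviation lands
    in the 5-10 regime the study reports.
    """

    grid: WavelengthGrid = field(
        default_factory=lambda: WavelengthGrid(1350.0 + 8.0 * np.arange(152))
    )
    replicates: int = 3
    noise_sd: float = 0.02
    scatter_sd: float = 0.02
    baseline_offset_sd: float = 0.004
    baseline_slope_sd: float = 0.004
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ConfigError("noise_sd and scatter_sd must be >= 0")
        if self.replicates < 1:
            raise ConfigError("need at least 1 replicate")


def sample_compositions(spec: PopulationSpec, n: int, seed: int,
                        prefix: str | None = None) -> ReferenceTable:
    """Draw ``n`` sample compositions from a population.

    Linoleic deviations are drawn anticorrelated with oleic deviations
    (``OLEIC_LINOLEIC_R``) with the marginal sd preserved; fatty-acid
    percentages are then renormalized to sum at most 100 (rare). Amino
    acids are fixed fractions of protein with small relative jitter, so
    amino-acid levels track protein across a wide-protein population.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = prefix if prefix is not None else spec.name
    ids = [f"{prefix}_{i:03d}" for i in range(n)]
    data = {}
    for trait, dist in spec.traits.items():
        data[trait] = dist.draw(n, rng)
    o_dist, l_dist = spec.traits.get("oleic"), spec.traits.get("linoleic")
    if (o_dist is not None and l_dist is not None
            and o_dist.kind == "truncnorm" and l_dist.kind == "truncnorm"
            and o_dist.sd > 0):
        r = OLEIC_LINOLEIC_R
        z = (data["oleic"] - o_dist.mean) / o_dist.sd
        resid = rng.normal(0.0, 1.0, n)
        lin = l_dist.mean + l_dist.sd * (r * z + np.sqrt(1 - r * r) * resid)
        data["linoleic"] = np.clip(lin, l_dist.lo, l_dist.hi)
    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
    fa = ["palmitic", "stearic", "oleic", "linoleic", "linolenic"]
    total = df[fa].sum(axis=1)
    over = total > 100.0
    if over.any():
        df.loc[over, fa] = df.loc[over, fa].mul(100.0 / total[over], axis=0)
    for amino, ratio in AMINO_RATIOS.items():
        jitter = rng.normal(0.0, AMINO_JITTER_REL * ratio, n)
        df[amino] = df["total_protein"] * np.maximum(ratio + jitter, 0.0)
    return ReferenceTable(df)


def pure_component_spectra(lib: BandLibrary, grid: WavelengthGrid) -> pd.DataFrame:
    """Evaluate each component's Gaussian bands on the grid.

    Returns a DataFrame (components x wavelengths) of absorbance per unit
    mass fraction; deterministic.
    """
    wl = grid.values
    rows = {}
    for name in COMPONENTS:
        spectrum = np.zeros_like(wl)
        for b in lib.components.get(name, []):
            spectrum = spectrum + b["height"] * np.exp(
                -0.5 * ((wl - b["center_nm"]) / b["sigma_nm"]) ** 2
            )
        rows[name] = spectrum
    return pd.DataFrame(rows, index=wl).T


def component_fractions(refs: ReferenceTable) -> pd.DataFrame:
    """Map trait percentages to pure-component mass fractions.

    Fat is split over the three fat components by the fatty-acid profile
    (% of peak area taken as % of total fat); carbohydrate is the
    remainder 1 - protein - fat - moisture. Raises on negative remainder.
    """
    df = refs.values
    needed = ["total_protein", "fat", "moisture", "palmitic", "stearic",
              "oleic", "linoleic", "linolenic"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"reference table missing traits {missing}")
    if df[needed].isna().any().any():
        raise DataError("composition traits must be complete to render spectra")
    protein = df["total_protein"] / 100.0
    fat = df["fat"] / 100.0
    water = df["moisture"] / 100.0
    carb = 1.0 - protein - fat - water
    if (carb < 0).any():
        bad = df.index[carb < 0].tolist()
        raise DataError(f"negative implied carbohydrate for samples {bad}")
    frac = pd.DataFrame({
        "protein": protein,
        "fat_oleic": fat * df["oleic"] / 100.0,
        "fat_linoleic_linolenic": fat * (df["linoleic"] + df["linolenic"]) / 100.0,
        "fat_saturated": fat * (df["palmitic"] + df["stearic"]) / 100.0,
        "water": water,
        "carbohydrate": carb,
    })
    return frac[list(COMPONENTS)]


def generate_spectra(
    refs: ReferenceTable,
    lib: BandLibrary,
    config: SyntheticConfig,
    labels: dict | pd.Series | None = None,
) -> SpectraSet:
    """Render replicate scans for every sample in ``refs``.

    ``labels`` optionally maps sample_id -> class label stored in the scan
    metadata. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pure = pure_component_spectra(lib, config.grid).to_numpy()  # (6, p)
    frac = component_fractions(refs)
    clean = frac.to_numpy() @ pure  # (n_samples, p)
    wl = config.grid.values
    lam = 2.0 * (wl - wl.mean()) / (wl[-1] - wl[0])  # scaled to [-1, 1]
    n, p = clean.shape
    r = config.replicates
    m = rng.lognormal(0.0, config.scatter_sd, (n, r)) if config.scatter_sd > 0 \
        else np.ones((n, r))
    offset = rng.normal(0.0, config.baseline_offset_sd, (n, r))
    slope = rng.normal(0.0, config.baseline_slope_sd, (n, r))
    eps = rng.normal(0.0, config.noise_sd, (n, r, p)) if config.noise_sd > 0 \
        else np.zeros((n, r, p))
    scans = (m[:, :, None] * clean[:, None, :]
             + offset[:, :, None] + slope[:, :, None] * lam[None, None, :]
             + eps)
    sample_ids = list(refs.values.index)
    if labels is None:
        lab_of = {}
    elif isinstance(labels, pd.Series):
        lab_of = labels.to_dict()
    else:
        lab_of = dict(labels)
    meta = pd.DataFrame({
        "sample_id": np.repeat(sample_ids, r),
        "replicate_id": np.tile(np.arange(1, r + 1), n),
        "class_label": [lab_of.get(s) for s in np.repeat(sample_ids, r)],
    })
    return SpectraSet(config.grid, scans.reshape(n * r, p), meta)


def make_study_fixture(
    seed: int,
    config: SyntheticConfig | None = None,
    lib: BandLibrary | None = None,
    mask_reference_counts: bool = True,
):
    """Build the full emulated study: 30 conventional + 30 high-oleic +
    47 additional soybeans + 15 soy products, scanned in triplicate.

    Returns ``(spectra, refs, labels)`` where labels is a Series over the
    60 class-labeled samples. With ``mask_reference_counts=True`` the
    reference table reproduces the study's per-assay coverage: amino acids
    on 32 samples (all products plus 17 soybeans), protein on 92 (all
    products plus 77 soybeans), fatty acids on 96 soybeans, fat and
    moisture on 60 soybeans each. Masked cells are missing, exactly as an
    incompletely assayed sample bank would be.
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    else:
        config = SyntheticConfig(
            grid=config.grid, replicates=config.replicates,
            noise_sd=config.noise_sd, scatter_sd=config.scatter_sd,
            baseline_offset_sd=config.baseline_offset_sd,
            baseline_slope_sd=config.baseline_slope_sd, seed=seed,
        )
    if lib is None:
        lib = default_band_library()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2 ** 31))
    parts = [
        sample_compositions(population_spec("conventional"), 30, sub(), "conv"),
        sample_compositions(population_spec("high_oleic"), 30, sub(), "oleic"),
        sample_compositions(population_spec("soybean"), 47, sub(), "osc"),
        sample_compositions(population_spec("soy_product"), 15, sub(), "prod"),
    ]
    refs = ReferenceTable(pd.concat([p.values for p in parts]))
    labels = pd.Series(
        {f"conv_{i:03d}": "conventional" for i in range(30)}
        | {f"oleic_{i:03d}": "high_oleic" for i in range(30)},
        name="class_label",
    )
    spectra = generate_spectra(refs, lib, config, labels=labels)
    if mask_reference_counts:
        refs = _mask_to_study_counts(refs, rng)
    return spectra, refs, labels


def _mask_to_study_counts(refs: ReferenceTable, rng: np.random.Generator
                          ) -> ReferenceTable:
    df = refs.values.copy()
    soybeans = [s for s in df.index if not s.startswith("prod_")]
    products = [s for s in df.index if s.startswith("prod_")]

    def keep(pool, k):
        pool = np.asarray(pool)
        return set(pool[rng.permutation(len(pool))[:k]])

    amino_keep = set(products) | keep(soybeans, 32 - len(products))
    protein_keep = set(products) | keep(soybeans, 92 - len(products))
    fa_keep = keep(soybeans, 96)
    fat_keep = keep(soybeans, 60)
    moist_keep = keep(soybeans, 60)
    groups = [
        (["threonine", "cysteine", "methionine", "lysine", "tryptophan"],
         amino_keep),
        (["total_protein"], protein_keep),
        (["palmitic", "stearic", "oleic", "linoleic", "linolenic"], fa_keep),
        (["fat"], fat_keep),
        (["moisture"], moist_keep),
    ]
    for cols, keep_set in groups:
        drop = [s for s in df.index if s not in keep_set]
        df.loc[drop, cols] = np.nan
    return ReferenceTable(df)
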