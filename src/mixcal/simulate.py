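"""Synthetic UV/Vis mixture spectra with controllable departures from linearity.

The three analytes of interest — pioglitazone (PIO), alogliptin (ALG) and
glimepiride (GLM) — absorb between 200 and 400 nm with severe band overlap:
ALG and PIO share the 230–300 nm region almost completely, while GLM is a
minor component (design ratio roughly 30:25:4 µg/mL) whose only distinctive
feature is a weak, broad band above 300 nm.  No measured spectra are
distributed with this package; instead this module builds Gaussian-band pure
spectra with exactly that overlap structure, mixes them under the
Beer–Lambert law, and then optionally injects the real-world defects that
break linear calibration: absorbance saturation, multiplicative/additive
scatter, baseline drift and instrumental noise.

All randomness is driven by one integer seed; each sample draws from its own
counter-based substream so that adding or removing samples never perturbs the
draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WL_MIN = 200.0
WL_MAX = 400.0
WL_STEP = 0.5
N_POINTS = 401  # 200.0 .. 400.0 inclusive at 0.5 nm


def default_grid() -> np.ndarray:
    """The instrument wavelength grid: 200–400 nm at 0.5 nm (401 points)."""
    return WL_MIN + WL_STEP * np.arange(N_POINTS)


@dataclass(frozen=True)
class PureComponent:
    """A pure analyte spectrum as a sum of Gaussian absorption bands.

    Each band is a ``(center_nm, width_nm, peak_absorptivity)`` triple; the
    peak absorptivity is in absorbance units per µg/mL so that mixing is a
    plain matrix product with concentrations.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError(f"component {self.name!r} needs at least one band")
        for center, width, eps in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
            if eps < 0:
                raise ValueError(f"peak absorptivity must be >= 0, got {eps}")


#: Default three-component library.  ALG and PIO carry strong, almost
#: coincident bands in 235–285 nm plus broad low-absorptivity tails that
#: persist past 300 nm (real UV bands do not die off as fast as a narrow
#: Gaussian); GLM has a weak 235 nm band and a broad, low band centred at
#: 330 nm.  The result is severe overlap along the whole informative range:
#: at the design-centre mixture (PIO 30, ALG 25, GLM 4 µg/mL) GLM carries
#: only ~3 % of the total absorbance and even its 300–380 nm region sits on
#: a comparable ALG/PIO tail background, so no analyte owns a clean channel.
DEFAULT_LIBRARY: tuple[PureComponent, ...] = (
    PureComponent("PIO", ((238.0, 11.0, 0.026), (266.0, 14.0, 0.028), (320.0, 40.0, 0.005))),
    PureComponent("ALG", ((240.0, 12.0, 0.030), (272.0, 15.0, 0.024), (310.0, 35.0, 0.006))),
    PureComponent("GLM", ((235.0, 8.0, 0.012), (330.0, 30.0, 0.008))),
)


def severe_distortion(seed: int = 0) -> DistortionConfig:
    """The severe non-linear study regime: deep saturation, realistic noise.

    saturation_k = 2 puts the strong 230–300 nm bands (A ≈ 1–2) at
    k·A ≈ 2–4, i.e. deeply into the bounded-saturation regime, while
    0.005 AU noise is ordinary photometric noise.  Used for the
    model-ordering experiments on non-linear spectra.
    """
    return DistortionConfig(saturation_k=2.0, noise_sd=0.005, seed=seed)


@dataclass(frozen=True)
class DistortionConfig:
    """Per-sample distortions applied on top of Beer–Lambert absorbances.

    saturation_k
        Strength of the bounded saturation law ``A -> A / (1 + k A)``;
        0 leaves the spectra exactly linear in concentration.
    scatter_slope_sd / scatter_offset_sd
        Standard deviations of a per-sample multiplicative slope
        (``N(1, sd^2)``) and additive offset (``N(0, sd^2)``), emulating
        multiplicative/additive scatter.
    baseline_drift_sd
        SD of a linear baseline ramp accumulated across the full grid span,
        in absorbance units.
    noise_sd
        SD of i.i.d. Gaussian noise per wavelength, in absorbance units.
    """

    saturation_k: float = 0.0
    scatter_slope_sd: float = 0.0
    scatter_offset_sd: float = 0.0
    baseline_drift_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.saturation_k < 0:
            raise ValueError("saturation_k must be >= 0")
        for name in ("scatter_slope_sd", "scatter_offset_sd",
                     "baseline_drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SpectraSet:
    """A block of absorbance spectra on a shared wavelength grid.

    ``absorbance`` is samples × wavelengths; rows are labelled by
    ``sample_ids``.  The grid must be strictly increasing with a uniform step
    and the matrix must be finite.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = list(self.sample_ids)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        # acquisition grids are uniform; band-selected subsets are not, so the
        # container only demands strict monotonicity
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.wavelengths.copy(), self.absorbance.copy(),
                          list(self.sample_ids))

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Rows for the given sample ids, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectraSet(self.wavelengths.copy(), self.absorbance[rows], list(ids))

    # -- wide-CSV round trip: first column wavelength_nm, one column/sample --

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.absorbance.T, columns=self.sample_ids)
        df.insert(0, "wavelength_nm", self.wavelengths)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        if df.columns[0] != "wavelength_nm":
            raise ValueError("first column of a spectra CSV must be wavelength_nm")
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        ids = [str(c) for c in df.columns[1:]]
        return cls(wl, df.iloc[:, 1:].to_numpy(dtype=float).T, ids)


def pure_spectrum(component: PureComponent, grid: np.ndarray) -> np.ndarray:
    """Evaluate a pure-component absorptivity vector on a wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    out = np.zeros_like(grid)
    for center, width, eps in component.bands:
        out += eps * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def mix_beer_lambert(
    components: Sequence[PureComponent],
    concentrations: pd.DataFrame | np.ndarray,
    grid: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> SpectraSet:
    """Beer–Lambert superposition: absorbance = concentrations · pure spectra.

    ``concentrations`` is samples × analytes in µg/mL; if a DataFrame, its
    columns must match the component names (order is taken from the
    components) and its index supplies sample ids.
    """
    if grid is None:
        grid = default_grid()
    names = [c.name for c in components]
    if isinstance(concentrations, pd.DataFrame):
        missing = [n for n in names if n not in concentrations.columns]
        if missing:
            raise ValueError(f"concentration table lacks columns {missing}")
        if sample_ids is None:
            sample_ids = [str(i) for i in concentrations.index]
        conc = concentrations[names].to_numpy(dtype=float)
    else:
        conc = np.atleast_2d(np.asarray(concentrations, dtype=float))
        if conc.shape[1] != len(components):
            raise ValueError(
                f"{conc.shape[1]} concentration columns for {len(components)} components"
            )
        if sample_ids is None:
            sample_ids = [f"S{i + 1}" for i in range(conc.shape[0])]
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    pure = np.stack([pure_spectrum(c, grid) for c in components])  # analytes x wl
    return SpectraSet(np.asarray(grid, float), conc @ pure, list(sample_ids))


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # counter-based substream: independent of how many samples precede this one
    return np.random.default_rng([int(seed), int(sample_index)])


def distort(spectra: SpectraSet, cfg: DistortionConfig) -> SpectraSet:
    """Apply saturation, scatter, drift and noise; deterministic given seed.

    Per sample, in order: ``A -> A/(1 + k A)``; multiplicative slope
    ``N(1, scatter_slope_sd^2)``; additive offset ``N(0, scatter_offset_sd^2)``;
    a linear baseline ramp whose full-span amplitude is
    ``N(0, baseline_drift_sd^2)``; i.i.d. Gaussian noise.
    """
    wl = spectra.wavelengths
    span = wl[-1] - wl[0]
    ramp = (wl - wl[0]) / span if span > 0 else np.zeros_like(wl)
    out = np.empty_like(spectra.absorbance)
    for i in range(spectra.n_samples):
        a = spectra.absorbance[i]
        if cfg.saturation_k > 0:
            a = a / (1.0 + cfg.saturation_k * a)
        rng = _sample_rng(cfg.seed, i)
        # fixed draw order keeps each effect reproducible even when its sd is 0
        slope = 1.0 + cfg.scatter_slope_sd * rng.standard_normal()
        offset = cfg.scatter_offset_sd * rng.standard_normal()
        drift_amp = cfg.baseline_drift_sd * rng.standard_normal()
        noise = cfg.noise_sd * rng.standard_normal(wl.size)
        out[i] = slope * a + offset + drift_amp * ramp + noise
    return SpectraSet(wl.copy(), out, list(spectra.sample_ids))


def simulate_dataset(
    design,
    components: Sequence[PureComponent] = DEFAULT_LIBRARY,
    cfg: DistortionConfig | None = None,
    grid: np.ndarray | None = None,
) -> tuple[SpectraSet, pd.DataFrame]:
    """One distorted spectrum per design row, plus the concentration table.

    ``design`` may be a :class:`mixcal.design.ConcentrationDesign` or any
    DataFrame with a ``sample_id`` index/column and one µg/mL column per
    analyte named after the components.
    """
    conc = getattr(design, "concentrations", design)
    if not isinstance(conc, pd.DataFrame):
        raise TypeError("design must expose a concentration DataFrame")
    conc = conc.copy()
    if "sample_id" in conc.columns:
        conc = conc.set_index("sample_id")
    names = [c.name for c in components]
    conc = conc[[n for n in conc.columns if n in names]]
    if grid is None:
        grid = default_grid()
    if len(conc) == 0:
        empty = SpectraSet(np.asarray(grid, float),
                           np.empty((0, np.asarray(grid).size)), [])
        return empty, conc
    spectra = mix_beer_lambert(components, conc, grid)
    if cfg is not None:
        spectra = distort(spectra, cfg)
    return spectra, conc


def write_concentrations_csv(conc: pd.DataFrame, path) -> None:
    """Concentration table CSV: sample_id + one µg/mL column per analyte."""
    out = conc.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_concentrations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
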