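"""Multilevel multifactor calibration design (5 levels, 3 factors, 25 runs).

The calibration set is a balanced five-level design built from a single
24-element cyclic generator over the coded alphabet {−2, −1, 0, +1, +2}:
run 1 puts every factor at code 0 and, for runs 2–25, factor *f* reads the
generator cyclically advanced by *f − 1* positions.  The construction makes
every pair of coded factor columns exactly orthogonal and gives each level
exactly five occurrences per factor, which is what makes a 25-run design
adequate for three analytes over five concentration levels.

Codes map affinely to concentrations, ``c = center + step · code``; with the
centres/steps used here (PIO 30 ± 3, ALG 25 ± 2.5, GLM 4.0 ± 0.4 µg/mL) the
generated design reproduces the packaged 43-row layout (25 calibration "M"
runs, 6 replicate instrumental-stability "St" runs, 12 test "T" mixtures)
cell for cell on the M block.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

CODED_ALPHABET = (-2, -1, 0, 1, 2)

#: Cyclic generator for the 25-run, 3-factor, 5-level design: the coded
#: first-factor values of calibration runs 2..25.  Shipped as a constant
#: (validated by the balance/orthogonality invariants) rather than re-derived.
CANONICAL_GENERATOR: tuple[int, ...] = (
    0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
    0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)

ANALYTES = ("PIO", "ALG", "GLM")

_TABLE1_SHA256 = "b0c3ad0bc48c36627a6e89eb66a8002e462494ec8f4558b6bc1ee4f9cb232600"


@dataclass(frozen=True)
class LevelMapping:
    """Affine code→concentration map per factor: c = center + step · code."""

    centers: dict[str, float]
    steps: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.centers) != set(self.steps):
            raise ValueError("centers and steps must cover the same factors")
        for name, step in self.steps.items():
            if step <= 0:
                raise ValueError(f"step for {name} must be > 0")

    def to_concentration(self, factor: str, code: float) -> float:
        if code not in CODED_ALPHABET:
            raise ValueError(f"code {code} outside coded alphabet {CODED_ALPHABET}")
        return self.centers[factor] + self.steps[factor] * code


#: Mapping that reproduces the packaged design: concentration ranges
#: ALG 20–30, PIO 24–36, GLM 3.2–4.8 µg/mL.
TABLE1_MAPPING = LevelMapping(
    centers={"PIO": 30.0, "ALG": 25.0, "GLM": 4.0},
    steps={"PIO": 3.0, "ALG": 2.5, "GLM": 0.4},
)


@dataclass
class CodedDesign:
    """Runs × factors matrix of coded levels in {−2, −1, 0, +1, +2}."""

    codes: np.ndarray
    factor_names: list[str]
    run_labels: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != (len(self.run_labels), len(self.factor_names)):
            raise ValueError("codes shape does not match labels")
        if not np.isin(self.codes, CODED_ALPHABET).all():
            raise ValueError("codes outside the coded alphabet")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes,
            index=pd.Index(self.run_labels, name="sample_id"),
            columns=[f"{n}_code" for n in self.factor_names],
        )


@dataclass
class ConcentrationDesign:
    """Sample table: id, set label in {M, St, T}, µg/mL per analyte.

    ``concentrations`` is indexed by sample_id with one column per analyte;
    ``sets`` is the parallel M/St/T label series.
    """

    concentrations: pd.DataFrame
    sets: pd.Series

    def __post_init__(self) -> None:
        if not self.concentrations.index.equals(self.sets.index):
            raise ValueError("concentrations and set labels must share an index")
        bad = set(self.sets.unique()) - {"M", "St", "T"}
        if bad:
            raise ValueError(f"unknown set labels: {sorted(bad)}")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    def rows(self, set_label: str) -> pd.DataFrame:
        return self.concentrations[self.sets == set_label]

    def to_frame(self) -> pd.DataFrame:
        out = self.concentrations.copy()
        out.insert(0, "set", self.sets)
        out.columns = ["set"] + [f"{a}_ugmL" for a in self.analytes]
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationDesign":
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        conc = df[[c for c in df.columns if c.endswith("_ugmL")]].astype(float)
        conc.columns = [c[: -len("_ugmL")] for c in conc.columns]
        return cls(conc, df["set"].astype(str))


def generate_multilevel_design(
    generator: tuple[int, ...] = CANONICAL_GENERATOR,
    n_factors: int = 3,
    factor_names: tuple[str, ...] | None = None,
) -> CodedDesign:
    """Build the cyclic 5-level design: 1 centre run + len(generator) runs.

    Factor *f* (1-based) takes, for runs 2..25, the generator advanced
    cyclically by *f − 1* positions.  The generator must be drawn from the
    coded alphabet with the level balance that makes the columns orthogonal.
    """
    gen = np.asarray(generator, dtype=int)
    if gen.size != 24:
        raise ValueError(f"generator must have 24 coded entries, got {gen.size}")
    if not np.isin(gen, CODED_ALPHABET).all():
        raise ValueError("generator entries must lie in the coded alphabet")
    if factor_names is None:
        factor_names = ANALYTES[:n_factors]
    if len(factor_names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    cols = [np.concatenate([[0], np.roll(gen, -f)]) for f in range(n_factors)]
    codes = np.stack(cols, axis=1)
    labels = [f"M{i + 1}" for i in range(codes.shape[0])]
    return CodedDesign(codes, list(factor_names), labels)


def map_levels(coded: CodedDesign, mapping: LevelMapping) -> ConcentrationDesign:
    """Decode a coded design to µg/mL concentrations (calibration set M)."""
    missing = [f for f in coded.factor_names if f not in mapping.centers]
    if missing:
        raise ValueError(f"mapping lacks factors {missing}")
    centers = np.array([mapping.centers[f] for f in coded.factor_names])
    steps = np.array([mapping.steps[f] for f in coded.factor_names])
    conc = pd.DataFrame(
        centers + steps * coded.codes,
        index=pd.Index(coded.run_labels, name="sample_id"),
        columns=coded.factor_names,
    )
    sets = pd.Series("M", index=conc.index, name="set")
    return ConcentrationDesign(conc, sets)


@dataclass
class DesignDiagnostics:
    """Summary of a concentration design's geometry.

    ``scores`` are the first ≤3 principal-component scores of the
    mean-centred calibration concentration matrix (via SVD), the quantity
    plotted to check that the calibration spans the mixture space with the
    orthogonality/symmetry/rotatability a balanced design provides.
    """

    means: pd.Series
    correlations: pd.DataFrame
    level_counts: dict[str, dict[float, int]]
    scores: pd.DataFrame
    test_outside_box: list[str]


def design_diagnostics(design: ConcentrationDesign) -> DesignDiagnostics:
    """Means, pairwise correlations, level occupancy and PC scores (M rows)."""
    cal = design.rows("M")
    if cal.shape[1] < 2:
        raise ValueError("diagnostics need at least 2 factors")
    if len(cal) < 3:
        raise ValueError("diagnostics need at least 3 calibration samples")
    X = cal.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [c for c, s in zip(cal.columns, sd) if s == 0]
        raise ValueError(f"zero-variance factor(s): {flat}")
    corr = pd.DataFrame(np.corrcoef(Xc, rowvar=False),
                        index=cal.columns, columns=cal.columns)
    counts = {
        col: {float(v): int(n) for v, n in cal[col].value_counts().items()}
        for col in cal.columns
    }
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(3, s.size)
    scores = pd.DataFrame(U[:, :k] * s[:k], index=cal.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    lo, hi = X.min(axis=0), X.max(axis=0)
    test = design.rows("T")
    outside = [
        str(idx) for idx, row in test.iterrows()
        if np.any(row.to_numpy(dtype=float) < lo - 1e-12)
        or np.any(row.to_numpy(dtype=float) > hi + 1e-12)
    ]
    return DesignDiagnostics(cal.mean(), corr, counts, scores, outside)


def load_table1_fixture() -> ConcentrationDesign:
    """The packaged 43-row design: 25 M + 6 St + 12 T, verbatim.

    The file's checksum is verified so silent corruption is caught.
    """
    data = resources.files("mixcal.data").joinpath("table1.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            f"design fixture checksum mismatch: {digest} != {_TABLE1_SHA256}"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(data.decode("utf-8")))
    return ConcentrationDesign.from_frame(df)


def decode_to_codes(design: ConcentrationDesign,
                    mapping: LevelMapping = TABLE1_MAPPING) -> CodedDesign:
    """Invert the level mapping on the calibration rows (must decode exactly)."""
    cal = design.rows("M")
    codes = np.empty(cal.shape)
    for j, f in enumerate(cal.columns):
        codes[:, j] = (cal[f] - mapping.centers[f]) / mapping.steps[f]
    rounded = np.round(codes)
    if not np.allclose(codes, rounded, atol=1e-9):
        raise ValueError("calibration rows do not decode to integer codes")
    return CodedDesign(rounded.astype(int), list(cal.columns), [str(i) for i in cal.index])
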