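"""Wavelength-band selection and spectral preprocessing.

Everything here follows the fit-on-calibration / apply-to-new-samples
discipline: a transform is fitted on the calibration spectra only and its
fitted parameters travel in a :class:`PreprocessorState`, so stability and
test samples are corrected with calibration statistics and nothing leaks
from the evaluation sets into the model.

Implemented transforms:

* band selection — restrict the grid to informative intervals (inclusive
  endpoints, so e.g. 230.5–245 nm at 0.5 nm is 30 points);
* mean centring (MC) and autoscaling (AS) by calibration column statistics;
* standard normal variate (SNV), a stateless row-wise standardisation;
* multiplicative scatter correction (MSC) against the calibration mean
  spectrum, ``x ≈ a·ref + b`` then ``(x − b)/a``;
* orthogonal signal correction (OSC), which strips spectral components whose
  scores carry no information about the response y before calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulate import SpectraSet


@dataclass(frozen=True)
class BandSelection:
    """Sorted, non-overlapping inclusive wavelength intervals in nm."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_stop = -np.inf
        for start, stop in self.bands:
            if start >= stop:
                raise ValueError(f"band ({start}, {stop}) has start >= stop")
            if start <= prev_stop:
                raise ValueError("bands must be sorted and non-overlapping")
            prev_stop = stop


#: Informative bands per analyte: ALG/PIO respond in 230.5–245 and 260–300 nm
#: (111 grid points at 0.5 nm); GLM in 230.5–245 and 300.5–380 nm (190 points).
ANALYTE_BANDS: dict[str, BandSelection] = {
    "ALG": BandSelection(((230.5, 245.0), (260.0, 300.0))),
    "PIO": BandSelection(((230.5, 245.0), (260.0, 300.0))),
    "GLM": BandSelection(((230.5, 245.0), (300.5, 380.0))),
}


def select_bands(spectra: SpectraSet, bands: BandSelection) -> SpectraSet:
    """Keep the union of grid points inside the bands, order preserved.

    Band endpoints must sit on the grid (within 1e−9 nm) and inside its span.
    """
    wl = spectra.wavelengths
    step = wl[1] - wl[0] if wl.size > 1 else 1.0
    mask = np.zeros(wl.size, dtype=bool)
    for start, stop in bands.bands:
        if start < wl[0] - 1e-9 or stop > wl[-1] + 1e-9:
            raise ValueError(f"band ({start}, {stop}) outside grid span")
        for edge in (start, stop):
            offset = (edge - wl[0]) / step
            if abs(offset - round(offset)) > 1e-9 / step:
                raise ValueError(f"band edge {edge} nm is off-grid")
        mask |= (wl >= start - 1e-9) & (wl <= stop + 1e-9)
    return SpectraSet(wl[mask], spectra.absorbance[:, mask], list(spectra.sample_ids))


@dataclass
class PreprocessorState:
    """Fitted parameters of one preprocessing transform.

    ``method`` is one of MC, AS, SNV, MSC, OSC; ``params`` holds the fitted
    arrays (column means/sds, MSC reference, OSC weights/loadings).  Applying
    a state is deterministic; fitting happens on calibration spectra only.
    """

    method: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        enc = {
            k: v.tolist() if isinstance(v, np.ndarray) else v
            for k, v in self.params.items()
        }
        return json.dumps({"method": self.method, "params": enc}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessorState":
        raw = json.loads(text)
        params = {
            k: np.asarray(v, dtype=float) if isinstance(v, list) else v
            for k, v in raw["params"].items()
        }
        return cls(raw["method"], params)


# ----------------------------- MC / AS ---------------------------------


def fit_centering(spectra: SpectraSet, method: str = "MC") -> tuple[PreprocessorState, SpectraSet]:
    """Fit mean centring (MC) or autoscale (AS) on calibration spectra.

    AS divides by the n−1 column standard deviation and refuses columns with
    zero variance (the error names the offending wavelength).
    """
    if method not in ("MC", "AS"):
        raise ValueError(f"unknown centering method {method!r}")
    X = spectra.absorbance
    if X.shape[0] < 2:
        raise ValueError("centering needs at least 2 samples")
    means = X.mean(axis=0)
    params = {"means": means, "wavelengths": spectra.wavelengths.copy()}
    if method == "AS":
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            wl = spectra.wavelengths[np.argmax(sds == 0)]
            raise ValueError(f"zero-variance column at {wl} nm; cannot autoscale")
        params["sds"] = sds
    state = PreprocessorState(method, params)
    return state, apply_state(state, spectra)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each row to zero mean, unit (n−1) sd."""
    X = spectra.absorbance
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 wavelengths")
    sds = X.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = spectra.sample_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"constant spectrum for sample {bad!r}; SNV undefined")
    out = (X - X.mean(axis=1, keepdims=True)) / sds[:, None]
    return SpectraSet(spectra.wavelengths.copy(), out, list(spectra.sample_ids))


# ------------------------------- MSC ------------------------------------


def msc_fit(spectra: SpectraSet) -> tuple[PreprocessorState, SpectraSet]:
    """Fit MSC: reference = calibration mean spectrum; correct calibration."""
    if spectra.n_samples < 2:
        raise ValueError("MSC needs at least 2 calibration samples")
    ref = spectra.absorbance.mean(axis=0)
    state = PreprocessorState(
        "MSC", {"reference": ref, "wavelengths": spectra.wavelengths.copy()}
    )
    return state, msc_apply(state, spectra)


def msc_apply(state: PreprocessorState, spectra: SpectraSet) -> SpectraSet:
    """Regress each spectrum on the reference, x ≈ a·ref + b; return (x−b)/a."""
    ref = np.asarray(state.params["reference"], dtype=float)
    _check_wavelengths(state, spectra)
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    out = np.empty_like(spectra.absorbance)
    for i, x in enumerate(spectra.absorbance):
        a = float(refc @ (x - x.mean())) / denom
        if abs(a) < 1e-12:
            raise ValueError(
                f"MSC slope ~0 for sample {spectra.sample_ids[i]!r}; cannot correct"
            )
        b = x.mean() - a * ref.mean()
        out[i] = (x - b) / a
    return SpectraSet(spectra.wavelengths.copy(), out, list(spectra.sample_ids))


# ------------------------------- OSC ------------------------------------


def osc_fit(
    spectra: SpectraSet,
    y: np.ndarray,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[PreprocessorState, SpectraSet]:
    """Fit orthogonal signal correction on centred calibration spectra.

    Per component: start from the first principal-component score of X,
    orthogonalise it against y, find the spectral direction w whose score
    Xw best reproduces it (least-norm solution, normalised), and iterate to
    a fixed point; then remove the rank-one component t pᵀ with loading
    p = Xᵀt/(tᵀt).  The removed scores are orthogonal to y, so the stripped
    variation is, by construction, uninformative about concentration.

    X must already be mean-centred (fit MC first). ``n_components = 0``
    returns an identity state.
    """
    X = spectra.absorbance.copy()
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("y length must equal the number of samples")
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    weights, loadings = [], []
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy == 0:
        raise ValueError("y has zero variance")
    for comp in range(n_components):
        if not np.any(np.abs(X) > 0):
            raise ValueError("zero-variance X; nothing to correct")
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        t = U[:, 0] * s[0]
        # nothing y-orthogonal to remove (e.g. X = y s^T, pure signal):
        # stop instead of deflating a degenerate component
        t_perp = t - yc * (float(yc @ t) / yy)
        if np.linalg.norm(t_perp) < 1e-8 * np.linalg.norm(t):
            break
        # least-norm inverse with a firm rank cutoff: near-null singular
        # directions otherwise dominate the normalised weight with noise
        pinv = np.linalg.pinv(X, rcond=1e-10)
        converged = False
        trace = []
        for it in range(max_iter):
            t_orth = t - yc * (float(yc @ t) / yy)
            w = pinv @ t_orth
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("degenerate OSC weight (orthogonalised score in null space)")
            w = w / nw
            t_new = X @ w
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            trace.append(delta)
            t = t_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"OSC component {comp + 1} did not converge in {max_iter} iterations; "
                f"relative score changes: {trace[-5:]}"
            )
        # exact final orthogonalisation: for full-rank centred X the projected
        # score X w equals t_orth, so corr(t, y) is zero to machine precision
        t_orth = t - yc * (float(yc @ t) / yy)
        w = pinv @ t_orth
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / float(t @ t)
        X = X - np.outer(t, p)
        weights.append(w)
        loadings.append(p)
    params = {"wavelengths": spectra.wavelengths.copy()}
    if weights:
        params["weights"] = np.stack(weights)
        params["loadings"] = np.stack(loadings)
    state = PreprocessorState("OSC", params)
    corrected = SpectraSet(spectra.wavelengths.copy(), X, list(spectra.sample_ids))
    return state, corrected


def osc_apply(state: PreprocessorState, spectra: SpectraSet) -> SpectraSet:
    """Remove the fitted orthogonal components from new spectra."""
    _check_wavelengths(state, spectra)
    X = spectra.absorbance.copy()
    if "weights" in state.params:
        W = np.atleast_2d(np.asarray(state.params["weights"], dtype=float))
        P = np.atleast_2d(np.asarray(state.params["loadings"], dtype=float))
        for w, p in zip(W, P):
            t = X @ w
            X = X - np.outer(t, p)
    return SpectraSet(spectra.wavelengths.copy(), X, list(spectra.sample_ids))


# --------------------------- generic apply ------------------------------


def _check_wavelengths(state: PreprocessorState, spectra: SpectraSet) -> None:
    wl = np.asarray(state.params["wavelengths"], dtype=float)
    if wl.size != spectra.wavelengths.size or not np.allclose(
        wl, spectra.wavelengths, atol=1e-9
    ):
        raise ValueError("wavelength grid does not match the fitted state")


def apply_state(state: PreprocessorState, spectra: SpectraSet) -> SpectraSet:
    """Apply any fitted state to new spectra (deterministic)."""
    if state.method in ("MC", "AS"):
        _check_wavelengths(state, spectra)
        X = spectra.absorbance - np.asarray(state.params["means"], dtype=float)
        if state.method == "AS":
            X = X / np.asarray(state.params["sds"], dtype=float)
        return SpectraSet(spectra.wavelengths.copy(), X, list(spectra.sample_ids))
    if state.method == "MSC":
        return msc_apply(state, spectra)
    if state.method == "OSC":
        return osc_apply(state, spectra)
    if state.method == "SNV":
        return snv(spectra)
    raise ValueError(f"unknown preprocessing method {state.method!r}")


def fit_chain(
    spectra: SpectraSet,
    methods: Sequence[str],
    y: np.ndarray | None = None,
    osc_components: int = 1,
) -> tuple[list[PreprocessorState], SpectraSet]:
    """Fit a sequence of transforms on calibration spectra, left to right.

    OSC requires the response ``y`` and must come after MC (enforced by
    inserting MC automatically if the chain requests OSC without a prior
    centring step).
    """
    states: list[PreprocessorState] = []
    current = spectra
    methods = list(methods)
    if "OSC" in methods:
        i = methods.index("OSC")
        if "MC" not in methods[:i] and "AS" not in methods[:i]:
            methods.insert(i, "MC")
    for m in methods:
        if m in ("MC", "AS"):
            state, current = fit_centering(current, m)
        elif m == "SNV":
            state, current = PreprocessorState(
                "SNV", {"wavelengths": current.wavelengths.copy()}
            ), snv(current)
        elif m == "MSC":
            state, current = msc_fit(current)
        elif m == "OSC":
            if y is None:
                raise ValueError("OSC requires the response y")
            state, current = osc_fit(current, y, n_components=osc_components)
        else:
            raise ValueError(f"unknown preprocessing method {m!r}")
        states.append(state)
    return states, current


def apply_chain(states: Sequence[PreprocessorState], spectra: SpectraSet) -> SpectraSet:
    """Apply fitted states in order to new spectra."""
    current = spectra
    for state in states:
        current = apply_state(state, current)
    return current
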