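"""Spectral pretreatment operators and named chains.

Model-level pretreatment compares six conditions: none, first derivative
(Savitzky-Golay, 17-point window), MSC, SNV, and the derivative followed
by MSC or SNV.  Block-level fusion pretreatment additionally uses min-max
normalisation (see :mod:`nirbran.fusion`).

All operators are per-spectrum (row-wise) except MSC, whose reference
spectrum is a fitted state: it is estimated on calibration data only and
reused to transform validation/prediction spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectraSet

__all__ = [
    "snv",
    "msc",
    "first_derivative",
    "minmax",
    "PretreatmentSpec",
    "apply_chain",
    "MODEL_CONDITIONS",
]


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        return a[None, :], True
    return a, False


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to SD 1.

    Uses the sample (n-1) standard deviation across variables.  Raises on
    a constant spectrum (zero SD).
    """
    a, was_1d = _as_matrix(x)
    if a.shape[1] < 2:
        raise ValueError("SNV needs at least 2 variables")
    sd = a.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"SNV undefined for constant spectrum (row {bad})")
    out = (a - a.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if was_1d else out


def msc(
    x: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``s`` is regressed on the reference by ordinary least
    squares, ``s ~ a * ref + b``, and replaced by ``(s - b) / a``.  The
    reference defaults to the set mean and is returned so that new samples
    can be corrected identically.
    """
    a, was_1d = _as_matrix(x)
    if reference is None:
        if a.shape[0] < 2:
            raise ValueError("MSC needs >= 2 spectra to form a mean reference")
        reference = a.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    slope = (a - a.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slope == 0):
        raise ValueError("MSC slope is zero for some spectrum")
    intercept = a.mean(axis=1) - slope * reference.mean()
    out = (a - intercept[:, None]) / slope[:, None]
    return (out[0] if was_1d else out), reference


def first_derivative(
    x: np.ndarray,
    window: int = 17,
    polyorder: int = 2,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay first derivative along the variable axis.

    The derivative is taken per grid index (``delta=1``); pass the grid
    step as ``delta`` for per-cm^-1 units — after mean-centring the choice
    only rescales PLS scores.  Edges use the polynomial-extension policy,
    so output length equals input length.
    """
    a, was_1d = _as_matrix(x)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > a.shape[1]:
        raise ValueError(f"window {window} exceeds variable count {a.shape[1]}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    out = savgol_filter(a, window, polyorder, deriv=1, delta=delta,
                        axis=1, mode="interp")
    return out[0] if was_1d else out


def minmax(x: np.ndarray) -> np.ndarray:
    """Min-max normalise each spectrum to [0, 1]."""
    a, was_1d = _as_matrix(x)
    lo = a.min(axis=1, keepdims=True)
    hi = a.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        bad = int(np.flatnonzero((hi == lo).ravel())[0])
        raise ValueError(f"min-max undefined for constant spectrum (row {bad})")
    out = (a - lo) / (hi - lo)
    return out[0] if was_1d else out


_OPS = ("none", "1st der", "msc", "snv", "minmax")

#: The six model-level pretreatment conditions, by their conventional names.
MODEL_CONDITIONS: dict[str, tuple[str, ...]] = {
    "none": (),
    "1st der": ("1st der",),
    "MSC": ("msc",),
    "SNV": ("snv",),
    "1st der + MSC": ("1st der", "msc"),
    "1st der + SNV": ("1st der", "snv"),
}


@dataclass(frozen=True)
class PretreatmentSpec:
    """An ordered pretreatment chain of at most two operators.

    Operators: ``none``, ``1st der``, ``msc``, ``snv``, ``minmax``.
    ``minmax`` is reserved for block-level use and cannot be combined.
    Chains named like ``"1st der + MSC"`` apply the derivative first.
    """

    chain: tuple[str, ...] = ()
    sg_window: int = 17
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        chain = tuple(op for op in self.chain if op != "none")
        object.__setattr__(self, "chain", chain)
        for op in chain:
            if op not in _OPS:
                raise ValueError(f"unknown pretreatment operator {op!r}")
        if len(chain) > 2:
            raise ValueError("pretreatment chains have at most 2 operators")
        if "minmax" in chain and len(chain) > 1:
            raise ValueError("minmax is a block-level operator; not combinable")

    @classmethod
    def from_name(cls, name: str, **kw) -> "PretreatmentSpec":
        if name not in MODEL_CONDITIONS:
            raise ValueError(
                f"unknown condition {name!r}; expected one of {list(MODEL_CONDITIONS)}"
            )
        return cls(chain=MODEL_CONDITIONS[name], **kw)

    @property
    def name(self) -> str:
        for nm, chain in MODEL_CONDITIONS.items():
            if chain == self.chain:
                return nm
        return " + ".join(self.chain) or "none"

    @property
    def has_msc(self) -> bool:
        return "msc" in self.chain


def apply_chain(
    x: np.ndarray | SpectraSet,
    spec: PretreatmentSpec,
    state: list | None = None,
) -> tuple[np.ndarray | SpectraSet, list]:
    """Apply a pretreatment chain left to right.

    ``state`` carries fitted parameters (currently only the MSC reference),
    one slot per chain position.  Fit on calibration data by passing
    ``state=None``; reuse the returned state to transform new samples
    identically.
    """
    is_set = isinstance(x, SpectraSet)
    mat = x.absorbance if is_set else np.asarray(x, dtype=float)
    fitting = state is None
    out_state: list = [] if fitting else list(state)
    if not fitting and len(out_state) != len(spec.chain):
        raise ValueError("state length does not match chain length")
    for i, op in enumerate(spec.chain):
        try:
            if op == "1st der":
                mat = first_derivative(mat, spec.sg_window, spec.sg_polyorder)
                if fitting:
                    out_state.append(None)
            elif op == "snv":
                mat = snv(mat)
                if fitting:
                    out_state.append(None)
            elif op == "minmax":
                mat = minmax(mat)
                if fitting:
                    out_state.append(None)
            elif op == "msc":
                ref = None if fitting else out_state[i]
                mat, ref = msc(mat, reference=ref)
                if fitting:
                    out_state.append(ref)
                else:
                    out_state[i] = ref
        except ValueError as exc:
            raise ValueError(f"chain step {i + 1} ({op}): {exc}") from exc
    if is_set:
        return x.with_absorbance(mat if mat.ndim == 2 else mat[None, :]), out_state
    return mat, out_state
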