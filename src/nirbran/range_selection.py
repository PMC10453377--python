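"""Synergy-interval optimisation of pretreatment and spectral range.

The calibration spectrum (single-block or fused) is cut into 10 equal
segments on the variable axis; every combination of 1-6 segments, crossed
with the six model-level pretreatment conditions, is scored by
cross-validated PLS and the candidate with the lowest RMSECV wins.  The
1-6-of-10 space holds ``sum(C(10,k), k=1..6) = 847`` combinations, small
enough to enumerate exhaustively, which dominates any random subset of
the same space; a seeded random subsample is available for parity with
sampling-based implementations.

Pretreatment is applied to the whole spectrum before segmentation
(derivatives and row-wise scalings see the full variable axis); the MSC
reference, being a fitted state, is estimated on the selected variables
inside each cross-validation fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import FusedSpectraSet
from .io import Role, SpectraSet
from .pls import CVResult, PLSModel, cross_validate, evaluate as _evaluate, fit as _fit, lv_cap
from .preprocess import MODEL_CONDITIONS, PretreatmentSpec, apply_chain, msc as _msc

logger = logging.getLogger("nirbran")

__all__ = [
    "SegmentScheme",
    "SearchResult",
    "SpectralModel",
    "segment",
    "enumerate_combinations",
    "optimize",
    "fit_spectral_model",
    "format_ranges",
]


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of ``n_variables`` into contiguous equal segments.

    A remainder of r variables puts one extra variable into each of the
    first r segments.
    """

    n_variables: int
    n_segments: int = 10
    boundaries: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        n, k = self.n_variables, self.n_segments
        if n < k:
            raise ValueError(f"cannot cut {n} variables into {k} segments")
        base, rem = divmod(n, k)
        bounds = []
        start = 0
        for i in range(k):
            size = base + (1 if i < rem else 0)
            bounds.append((start, start + size))
            start += size
        object.__setattr__(self, "boundaries", tuple(bounds))

    def columns(self, segments: tuple[int, ...]) -> np.ndarray:
        """Variable indices covered by a segment combination."""
        idx = [np.arange(*self.boundaries[s]) for s in sorted(segments)]
        return np.concatenate(idx)


def segment(n_variables: int, n_segments: int = 10) -> SegmentScheme:
    """Equal-interval segmentation of the variable axis."""
    return SegmentScheme(n_variables, n_segments)


def enumerate_combinations(
    n_segments: int = 10,
    k_min: int = 1,
    k_max: int = 6,
    sample: int | None = None,
    seed: int | None = None,
) -> list[tuple[int, ...]]:
    """All k_min..k_max-segment index sets in lexicographic order.

    With ``sample`` given, a seeded random subset of that size is drawn
    instead (order preserved), mirroring random-combination searches.
    """
    if k_max > n_segments:
        raise ValueError("k_max cannot exceed n_segments")
    combos: list[tuple[int, ...]] = []
    for k in range(k_min, k_max + 1):
        combos.extend(itertools.combinations(range(n_segments), k))
    if sample is not None and sample < len(combos):
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(combos), size=sample, replace=False))
        combos = [combos[i] for i in keep]
    return combos


# ---------------------------------------------------------------------------
# a calibrated model with its full spectral provenance

@dataclass
class SpectralModel:
    """PLS model plus the pretreatment and variable selection that feed it.

    ``prefix`` holds the per-spectrum operators (applied to the full
    spectrum), ``columns`` the selected variable indices, and
    ``msc_reference`` the calibration-fitted MSC reference on those
    variables (None when the condition has no MSC step).
    """

    condition: str
    prefix: PretreatmentSpec
    columns: np.ndarray
    msc_reference: np.ndarray | None
    pls: PLSModel
    cv: CVResult | None = None

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if self.prefix.chain:
            X, _ = apply_chain(X, self.prefix)
        X = X[:, self.columns]
        if self.msc_reference is not None:
            X, _ = _msc(X, reference=self.msc_reference)
        return X

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        return self.pls.predict(self.transform(X_raw))

    def evaluate(self, X_raw: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(R^2, RMSE) on held-out raw spectra."""
        return _evaluate(self.pls, self.transform(X_raw), y)

    # -- structured-text serialization (bit-exact reload) ------------------
    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "condition": self.condition,
                "prefix": {
                    "chain": list(self.prefix.chain),
                    "sg_window": self.prefix.sg_window,
                    "sg_polyorder": self.prefix.sg_polyorder,
                },
                "columns": self.columns.tolist(),
                "msc_reference": (
                    None if self.msc_reference is None
                    else self.msc_reference.tolist()
                ),
                "pls": self.pls.to_json(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SpectralModel":
        import json

        doc = json.loads(text)
        return cls(
            condition=doc["condition"],
            prefix=PretreatmentSpec(
                chain=tuple(doc["prefix"]["chain"]),
                sg_window=doc["prefix"]["sg_window"],
                sg_polyorder=doc["prefix"]["sg_polyorder"],
            ),
            columns=np.array(doc["columns"], dtype=int),
            msc_reference=(
                None if doc["msc_reference"] is None
                else np.array(doc["msc_reference"])
            ),
            pls=PLSModel.from_json(doc["pls"]),
        )

    def save(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SpectralModel":
        from pathlib import Path

        return cls.from_json(Path(path).read_text())


def _split_condition(condition: str, sg_window: int, sg_polyorder: int):
    chain = MODEL_CONDITIONS[condition]
    has_msc = bool(chain) and chain[-1] == "msc"
    prefix = chain[:-1] if has_msc else chain
    return (
        PretreatmentSpec(prefix, sg_window, sg_polyorder),
        has_msc,
    )


def fit_spectral_model(
    X_raw: np.ndarray,
    y: np.ndarray,
    condition: str = "none",
    columns: np.ndarray | None = None,
    n_lvs: int | None = None,
    max_lvs: int | None = None,
    cv: int | str = "loo",
    sg_window: int = 17,
    sg_polyorder: int = 2,
) -> SpectralModel:
    """Fit one pretreatment condition on (optionally windowed) spectra.

    When ``n_lvs`` is None the LV count is selected by cross-validation
    under the one-tenth cap, and the CV table is attached to the result.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    prefix, has_msc = _split_condition(condition, sg_window, sg_polyorder)
    X = X_raw
    if prefix.chain:
        X, _ = apply_chain(X, prefix)
    if columns is None:
        columns = np.arange(X.shape[1])
    columns = np.asarray(columns, dtype=int)
    Xw = X[:, columns]

    cv_result = None
    if n_lvs is None:
        chain = PretreatmentSpec(("msc",)) if has_msc else None
        cv_result = cross_validate(Xw, y, max_lvs=max_lvs, chain=chain, cv=cv)
        n_lvs = cv_result.best_lvs

    msc_reference = None
    if has_msc:
        Xw, msc_reference = _msc(Xw)
    pls = _fit(
        Xw, y, n_lvs,
        provenance={"condition": condition, "n_columns": int(columns.size)},
    )
    return SpectralModel(
        condition=condition,
        prefix=prefix,
        columns=columns,
        msc_reference=msc_reference,
        pls=pls,
        cv=cv_result,
    )


# ---------------------------------------------------------------------------
# the search

@dataclass
class SearchResult:
    """Ranked outcome of the pretreatment x segment-combination search."""

    table: pd.DataFrame          # sorted ascending by rmsecv
    scheme: SegmentScheme
    conditions: tuple[str, ...]

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]


def optimize(
    data: SpectraSet | np.ndarray,
    y: np.ndarray | None = None,
    conditions: tuple[str, ...] = tuple(MODEL_CONDITIONS),
    n_segments: int = 10,
    k_min: int = 1,
    k_max: int = 6,
    cv: int | str = "loo",
    max_lvs: int | None = None,
    sg_window: int = 17,
    sg_polyorder: int = 2,
    sample: int | None = None,
    seed: int | None = None,
) -> SearchResult:
    """Exhaustive siPLS-style search over pretreatments and segment sets.

    ``data`` is a calibration :class:`SpectraSet` (samples tagged with
    roles are filtered to the calibration role) or a raw matrix with ``y``
    supplied.  Every (condition, combination) candidate is scored by
    cross-validated PLS with LV selection under the one-tenth cap;
    candidates with fewer variables than admissible LVs are skipped with a
    logged warning.  Ties rank by fewer LVs, then fewer segments, then
    lexicographic combination order.
    """
    if isinstance(data, SpectraSet):
        sset = data
        if sset.roles is not None:
            sset = sset.by_role(Role.CALIBRATION)
        if sset.reference is None:
            raise ValueError("calibration set carries no reference values")
        X_raw, yv = sset.absorbance, sset.reference
    else:
        if y is None:
            raise ValueError("y is required when data is a matrix")
        X_raw, yv = np.atleast_2d(np.asarray(data, dtype=float)), np.asarray(y, float)

    n = X_raw.shape[0]
    cap = lv_cap(n) if max_lvs is None else max_lvs
    scheme = segment(X_raw.shape[1], n_segments)
    combos = enumerate_combinations(n_segments, k_min, k_max, sample=sample, seed=seed)
    logger.info(
        "optimize: %d conditions x %d combinations = %d candidates",
        len(conditions), len(combos), len(conditions) * len(combos),
    )

    records = []
    for condition in conditions:
        prefix, has_msc = _split_condition(condition, sg_window, sg_polyorder)
        X = X_raw
        if prefix.chain:
            X, _ = apply_chain(X, prefix)
        chain = PretreatmentSpec(("msc",)) if has_msc else None
        for combo in combos:
            cols = scheme.columns(combo)
            if cols.size < cap:
                logger.warning(
                    "skipping %s %s: %d variables < %d admissible LVs",
                    condition, combo, cols.size, cap,
                )
                continue
            res = cross_validate(X[:, cols], yv, max_lvs=cap, chain=chain, cv=cv)
            records.append(
                {
                    "condition": condition,
                    "segments": combo,
                    "n_lvs": res.best_lvs,
                    "rmsecv": res.best_rmsecv,
                    "r2_cv": res.best_r2_cv,
                }
            )
    if not records:
        raise ValueError("no admissible candidates")
    table = pd.DataFrame.from_records(records)
    table["n_segments_used"] = table["segments"].map(len)
    table = table.sort_values(
        ["rmsecv", "n_lvs", "n_segments_used", "segments"],
        kind="mergesort",
    ).reset_index(drop=True)
    return SearchResult(table=table, scheme=scheme, conditions=tuple(conditions))


def format_ranges(
    columns: np.ndarray,
    spectra: SpectraSet,
) -> str:
    """Report selected variables as high-low cm^-1 ranges per block.

    Contiguous index runs become ``hi-lo`` ranges; for fused sets each run
    is tagged with its origin block and split at the junction, e.g.
    ``"DR 7583.1-6109.7; DT 8732-7259"``.
    """
    cols = np.sort(np.asarray(columns, dtype=int))
    if isinstance(spectra, FusedSpectraSet):
        wn, origin = spectra.origin_wavenumbers, spectra.block_origin
    else:
        wn = spectra.wavenumbers
        origin = np.array([spectra.block.value] * spectra.n_variables)
    runs: list[tuple[int, int]] = []
    start = prev = int(cols[0])
    for c in map(int, cols[1:]):
        if c == prev + 1 and origin[c] == origin[prev]:
            prev = c
            continue
        runs.append((start, prev))
        start = prev = c
    runs.append((start, prev))
    parts = []
    for a, b in runs:
        lo, hi = sorted((wn[a], wn[b]))
        parts.append(f"{origin[a]} {hi:g}-{lo:g}")
    return "; ".join(parts)
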