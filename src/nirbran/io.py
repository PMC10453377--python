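"""Spectral data containers and delimited-text I/O.

The package works on near-infrared absorbance spectra of rice bran layer
samples recorded in two instrument geometries: diffuse reflectance (DR,
4000-12000 cm^-1) and diffuse transmittance (DT, 5793-12489 cm^-1), plus
the concatenated FUSED block produced by :mod:`nirbran.fusion`.

Spectra travel between modules as a :class:`SpectraSet`: an aligned
``(n_samples, n_variables)`` absorbance matrix on one wavenumber grid,
with per-sample reference cellulose contents (%, w/w) attached when known.
On disk a set is a wide CSV: one row per sample, wavenumbers as column
headers, an optional trailing ``reference`` column.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Block",
    "Role",
    "Spectrum",
    "SpectraSet",
    "ReferenceStats",
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "summarize_reference",
    "restrict_range",
]


class Block(str, enum.Enum):
    """Measurement geometry of a spectral block."""

    DR = "DR"
    DT = "DT"
    FUSED = "FUSED"


class Role(str, enum.Enum):
    """Modeling role of a sample within a set."""

    CALIBRATION = "calibration"
    VALIDATION = "validation"
    PREDICTION = "prediction"


#: Wavenumber span (cm^-1) each instrument geometry can produce.
BLOCK_SPANS: dict[Block, tuple[float, float]] = {
    Block.DR: (4000.0, 12000.0),
    Block.DT: (5793.0, 12489.0),
}


class SpectraParseError(ValueError):
    """Raised when a spectra CSV cannot be parsed."""


def _validate_grid(wavenumbers: np.ndarray, block: Block) -> None:
    if wavenumbers.ndim != 1 or wavenumbers.size == 0:
        raise ValueError("wavenumber grid must be a nonempty 1-D vector")
    diffs = np.diff(wavenumbers)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("wavenumber grid must be strictly monotonic")
    if block in BLOCK_SPANS:
        lo, hi = BLOCK_SPANS[block]
        wlo, whi = float(wavenumbers.min()), float(wavenumbers.max())
        if wlo < lo - 1e-9 or whi > hi + 1e-9:
            raise ValueError(
                f"{block.value} grid [{wlo:g}, {whi:g}] outside the "
                f"instrument span [{lo:g}, {hi:g}] cm^-1"
            )


@dataclass(frozen=True)
class Spectrum:
    """One sample's absorbance values on a wavenumber grid.

    Parameters
    ----------
    sample_id : str
        Sample identifier.
    block : Block
        Measurement geometry (DR, DT or FUSED).
    wavenumbers : ndarray
        Strictly monotonic grid in cm^-1.
    absorbance : ndarray
        Unitless absorbance, same length as the grid.
    """

    sample_id: str
    block: Block
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        _validate_grid(wn, self.block)
        if ab.shape != wn.shape:
            raise ValueError(
                f"absorbance length {ab.size} != grid length {wn.size}"
            )
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass
class SpectraSet:
    """Aligned spectra matrix plus per-sample reference cellulose contents.

    All spectra share one grid and one block.  ``reference`` holds the
    wet-chemistry cellulose content in % (w/w), one value per sample, or
    ``None`` when contents are unknown (prediction-only sets).
    """

    sample_ids: list[str]
    block: Block
    wavenumbers: np.ndarray
    absorbance: np.ndarray  # (n_samples, n_variables)
    reference: np.ndarray | None = None
    roles: list[Role] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        _validate_grid(self.wavenumbers, self.block)
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} ids for {n} spectra")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if p != self.wavenumbers.size:
            raise ValueError(
                f"matrix has {p} variables but grid has {self.wavenumbers.size}"
            )
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (n,):
                raise ValueError("one reference value per spectrum required")
            if np.any(self.reference <= 0):
                raise ValueError("reference cellulose contents must be positive")
        if self.roles is not None and len(self.roles) != n:
            raise ValueError("one role per spectrum required")
        # canonical ascending grid orientation
        if self.wavenumbers.size > 1 and self.wavenumbers[0] > self.wavenumbers[-1]:
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def __len__(self) -> int:
        return self.n_samples

    def __iter__(self) -> Iterator[Spectrum]:
        for i, sid in enumerate(self.sample_ids):
            yield Spectrum(sid, self.block, self.wavenumbers, self.absorbance[i])

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        """Copy of the set with the absorbance matrix replaced."""
        return replace(self, absorbance=np.asarray(matrix, dtype=float))

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset preserving order of ``indices``."""
        idx = list(indices)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            block=self.block,
            wavenumbers=self.wavenumbers,
            absorbance=self.absorbance[idx],
            reference=None if self.reference is None else self.reference[idx],
            roles=None if self.roles is None else [self.roles[i] for i in idx],
        )

    def by_role(self, role: Role) -> "SpectraSet":
        """Samples tagged with ``role``."""
        if self.roles is None:
            raise ValueError("set has no role tags; run the splitter first")
        return self.subset([i for i, r in enumerate(self.roles) if r == role])


@dataclass(frozen=True)
class ReferenceStats:
    """Descriptive statistics of a set's reference cellulose contents."""

    n: int
    range_lo: float
    range_hi: float
    mean: float
    sd: float
    se: float

    @property
    def interval(self) -> tuple[float, float]:
        """Confidence interval for the mean, reported as mean +/- SE."""
        return (self.mean - self.se, self.mean + self.se)


# ---------------------------------------------------------------------------
# CSV I/O

def read_spectra(path: str | Path, block: Block | str) -> SpectraSet:
    """Read a wide spectra CSV into a :class:`SpectraSet`.

    Layout: header row ``sample_id, <wavenumber...>[, reference]``; one row
    per sample.  The grid is stored ascending regardless of file order
    (instruments commonly write descending cm^-1).

    Raises
    ------
    SpectraParseError
        On an empty file, a ragged row (the offending sample id is named)
        or a non-numeric cell (row and column are named).
    """
    block = Block(block)
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise SpectraParseError(f"{path}: file is empty")
    header = rows[0]
    if len(header) < 2:
        raise SpectraParseError(f"{path}: header must list at least one wavenumber")
    has_reference = header[-1].strip().lower() == "reference"
    wn_cols = header[1:-1] if has_reference else header[1:]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric wavenumber header: {exc}") from None
    expected = len(header)
    ids: list[str] = []
    data: list[list[float]] = []
    refs: list[float] = []
    for irow, row in enumerate(rows[1:], start=2):
        sid = row[0].strip()
        if len(row) != expected:
            raise SpectraParseError(
                f"{path}: row {irow} (sample {sid!r}) has {len(row)} fields, "
                f"expected {expected}"
            )
        values = row[1:-1] if has_reference else row[1:]
        parsed = []
        for j, cell in enumerate(values):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise SpectraParseError(
                    f"{path}: non-numeric cell at row {irow} (sample {sid!r}), "
                    f"column {header[1 + j]!r}: {cell!r}"
                ) from None
        if has_reference:
            try:
                refs.append(float(row[-1]))
            except ValueError:
                raise SpectraParseError(
                    f"{path}: non-numeric reference at row {irow} (sample {sid!r}): "
                    f"{row[-1]!r}"
                ) from None
        ids.append(sid)
        data.append(parsed)
    return SpectraSet(
        sample_ids=ids,
        block=block,
        wavenumbers=wavenumbers,
        absorbance=np.array(data),
        reference=np.array(refs) if has_reference else None,
    )


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write a set as a wide CSV (lossless float round-trip via repr)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["sample_id"] + [repr(w) for w in spectra.wavenumbers.tolist()]
        if spectra.reference is not None:
            header.append("reference")
        writer.writerow(header)
        for i, sid in enumerate(spectra.sample_ids):
            row = [sid] + [repr(v) for v in spectra.absorbance[i].tolist()]
            if spectra.reference is not None:
                row.append(repr(float(spectra.reference[i])))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Reference summaries and range restriction

def summarize_reference(spectra: SpectraSet) -> ReferenceStats:
    """Descriptive statistics (n, range, mean, SD, SE) of the references.

    SD uses the n-1 (sample) denominator; SE = SD / sqrt(n); the interval
    around the mean is reported as mean +/- SE.
    """
    if spectra.reference is None:
        raise ValueError("set carries no reference values")
    y = spectra.reference
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples (SD undefined for n < 2)")
    sd = float(np.std(y, ddof=1))
    return ReferenceStats(
        n=n,
        range_lo=float(y.min()),
        range_hi=float(y.max()),
        mean=float(y.mean()),
        sd=sd,
        se=sd / math.sqrt(n),
    )


def restrict_range(
    spectra: SpectraSet, windows: Iterable[tuple[float, float]]
) -> SpectraSet:
    """Keep only variables whose wavenumber falls in any closed window.

    Window endpoints are inclusive and order-insensitive (ranges are
    conventionally printed high-to-low cm^-1).  Variable order is preserved.
    """
    windows = [tuple(sorted(map(float, w))) for w in windows]
    wn = spectra.wavenumbers
    keep = np.zeros(wn.size, dtype=bool)
    for lo, hi in windows:
        keep |= (wn >= lo) & (wn <= hi)
    if not keep.any():
        raise ValueError("no variables in range")
    return replace(
        spectra,
        wavenumbers=wn[keep],
        absorbance=spectra.absorbance[:, keep],
    )
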