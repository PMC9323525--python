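"""Domain types, CSV I/O, grid handling and sample-mode (un)folding.

An EEM (excitation-emission matrix) stores fluorescence intensity on an
emission x excitation wavelength grid; a dataset stacks many EEMs that
share grids into a three-way array (samples x emission x excitation).
Unfolding flattens each EEM into a row vector with the emission index
varying fastest -- column ``c`` holds ``(em[c % n_em], ex[c // n_em])`` --
a fixed, documented ordering so variable-wise results (e.g. VIP vectors)
can be refolded back onto the wavelength plane.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DimensionError,
    FormatError,
    GridError,
    RangeError,
)

__all__ = [
    "WavelengthGrid",
    "AbsorbanceSpectrum",
    "EEM",
    "EEMDataset",
    "SpectralMatrix",
    "read_eem_csv",
    "write_eem_csv",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_manifest",
    "stack_dataset",
    "crop",
    "unfold",
    "refold",
]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing grid of positive wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise GridError("wavelength grid needs at least 2 points")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise GridError("wavelengths must be finite and positive")
        if np.any(np.diff(vals) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0.0, atol=1e-9
        )

    def __hash__(self):
        return hash((len(self.values), float(self.values[0]), float(self.values[-1])))

    @property
    def step(self) -> float:
        """Median grid spacing in nm."""
        return float(np.median(np.diff(self.values)))

    def nearest_index(self, wavelength: float, max_dist: float | None = None) -> int:
        """Index of the grid point nearest ``wavelength``.

        Raises :class:`GridError` if the nearest point is farther than
        ``max_dist`` (default: half the grid step).
        """
        idx = int(np.argmin(np.abs(self.values - wavelength)))
        limit = 0.5 * self.step if max_dist is None else max_dist
        if abs(self.values[idx] - wavelength) > limit + 1e-9:
            raise GridError(
                f"{wavelength} nm is farther than {limit:.3g} nm from any grid point"
            )
        return idx

    def index_range(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid points with lo <= wavelength <= hi (inclusive)."""
        sel = np.nonzero((self.values >= lo - 1e-9) & (self.values <= hi + 1e-9))[0]
        if sel.size == 0:
            raise RangeError(f"range [{lo}, {hi}] nm selects no grid points")
        return sel


@dataclass
class AbsorbanceSpectrum:
    """A UV-vis absorbance spectrum A(lambda) in absorbance units (AU)."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise DimensionError(
                f"absorbance length {a.shape} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise FormatError("absorbance values must be finite")
        self.absorbance = a

    def interpolate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation of A(lambda) onto ``wavelengths`` (no extrapolation)."""
        w = np.asarray(wavelengths, dtype=float)
        g = self.grid.values
        if w.min() < g[0] - 1e-9 or w.max() > g[-1] + 1e-9:
            from .errors import CoverageError

            raise CoverageError(
                f"absorbance grid [{g[0]}, {g[-1]}] does not cover "
                f"requested [{w.min()}, {w.max()}] nm"
            )
        return np.interp(w, g, self.absorbance)

    @property
    def has_negative(self) -> bool:
        """True when baseline artifacts push absorbance below zero."""
        return bool(np.any(self.absorbance < 0))


@dataclass
class EEM:
    """One sample's fluorescence landscape on an emission x excitation grid.

    ``intensity`` has shape ``(len(em_grid), len(ex_grid))``; ``mask`` marks
    excised cells (True = missing) that all downstream fitters must skip.
    """

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensity: np.ndarray
    sample_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        inten = np.asarray(self.intensity, dtype=float)
        expected = (len(self.em_grid), len(self.ex_grid))
        if inten.shape != expected:
            raise DimensionError(
                f"intensity shape {inten.shape} != (|em|, |ex|) = {expected}"
            )
        self.intensity = inten
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != expected:
                raise DimensionError(f"mask shape {m.shape} != {expected}")
            self.mask = m
        if not np.all(np.isfinite(inten[~self.effective_mask])):
            raise FormatError("unmasked intensities must be finite")

    @property
    def effective_mask(self) -> np.ndarray:
        """Boolean mask (True = excised), all-False when no mask is set."""
        if self.mask is None:
            return np.zeros(self.intensity.shape, dtype=bool)
        return self.mask

    def copy(self) -> "EEM":
        return EEM(
            self.ex_grid,
            self.em_grid,
            self.intensity.copy(),
            self.sample_id,
            None if self.mask is None else self.mask.copy(),
        )


@dataclass
class EEMDataset:
    """Aligned three-way array of EEMs with two-class labels.

    ``array`` has shape (n_samples, |em|, |ex|); ``mask`` (same shape,
    True = excised) marks cells removed during preprocessing.
    """

    samples: list[str]
    labels: list[str]
    array: np.ndarray
    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    mask: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.array, dtype=float)
        n = len(self.samples)
        expected = (n, len(self.em_grid), len(self.ex_grid))
        if arr.shape != expected:
            raise DimensionError(f"array shape {arr.shape} != {expected}")
        if len(self.labels) != n:
            raise DimensionError("one label per sample required")
        self.array = arr
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != expected:
                raise DimensionError(f"mask shape {m.shape} != {expected}")
            self.mask = m

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.zeros(self.array.shape, dtype=bool)
        return self.mask

    def masked_array(self) -> np.ndarray:
        """Array with excised cells as NaN (the fitters' input convention)."""
        out = self.array.copy()
        out[self.effective_mask] = np.nan
        return out

    def eem(self, i: int) -> EEM:
        m = None if self.mask is None else self.mask[i]
        return EEM(self.ex_grid, self.em_grid, self.array[i], self.samples[i], m)


@dataclass
class SpectralMatrix:
    """A samples x variables matrix whose columns are wavelength-tagged.

    ``column_em`` / ``column_ex`` give each column's (lambda_em, lambda_ex);
    for pure absorbance blocks ``column_ex`` is NaN.
    """

    values: np.ndarray
    column_em: np.ndarray
    column_ex: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DimensionError("SpectralMatrix.values must be 2-D")
        if len(self.column_em) != v.shape[1] or len(self.column_ex) != v.shape[1]:
            raise DimensionError("one (em, ex) tag per column required")
        self.values = v
        self.column_em = np.asarray(self.column_em, dtype=float)
        self.column_ex = np.asarray(self.column_ex, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_arrays(
            [self.column_em, self.column_ex], names=["em_nm", "ex_nm"]
        )
        idx = self.sample_ids if self.sample_ids else range(self.values.shape[0])
        return pd.DataFrame(self.values, index=idx, columns=cols)


# ---------------------------------------------------------------------------
# CSV I/O
#
# EEM CSV layout: header row "em_nm,<ex1>,<ex2>,..."; each following row is
# an emission wavelength followed by the intensities at that emission for
# every excitation. Masked cells are written as the token "NA".
# ---------------------------------------------------------------------------


def read_eem_csv(path: str | Path) -> EEM:
    """Read an EEM from plain CSV (see module docstring for the layout)."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if len(rows) < 3:
        raise FormatError(f"{path}: need a header and at least 2 emission rows")
    header = rows[0]
    try:
        ex_vals = [float(c) for c in header[1:]]
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric excitation header: {e}") from None
    width = len(header)
    em_vals: list[float] = []
    body: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, expected {width}"
            )
        try:
            em_vals.append(float(row[0]))
        except ValueError:
            raise FormatError(f"{path}: non-numeric emission at row {r}") from None
        vals, miss = [], []
        for c, cell in enumerate(row[1:], start=2):
            tok = cell.strip()
            if tok.upper() in {"NA", "NAN", ""}:
                vals.append(np.nan)
                miss.append(True)
            else:
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {r}, column {c}"
                    ) from None
                miss.append(False)
        body.append(vals)
        mask_rows.append(miss)
    try:
        ex_grid = WavelengthGrid(np.array(ex_vals))
        em_grid = WavelengthGrid(np.array(em_vals))
    except GridError as e:
        raise GridError(f"{path}: {e}") from None
    mask = np.array(mask_rows, dtype=bool)
    inten = np.array(body, dtype=float)
    inten[mask] = 0.0
    return EEM(ex_grid, em_grid, inten, sample_id=path.stem,
               mask=mask if mask.any() else None)


def write_eem_csv(eem: EEM, path: str | Path) -> None:
    """Write an EEM to CSV, masked cells as "NA"; round-trips with reader."""
    path = Path(path)
    m = eem.effective_mask
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["em_nm"] + [_FLOAT_FMT % v for v in eem.ex_grid.values])
        for j, em in enumerate(eem.em_grid.values):
            row = [_FLOAT_FMT % em]
            for k in range(len(eem.ex_grid)):
                row.append("NA" if m[j, k] else _FLOAT_FMT % eem.intensity[j, k])
            w.writerow(row)


def read_absorbance_csv(path: str | Path) -> AbsorbanceSpectrum:
    """Read a two-column (wavelength_nm, absorbance_au) CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"wavelength_nm", "absorbance_au"} <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns wavelength_nm, absorbance_au"
        )
    return AbsorbanceSpectrum(
        WavelengthGrid(df["wavelength_nm"].to_numpy(float)),
        df["absorbance_au"].to_numpy(float),
        sample_id=path.stem,
    )


def write_absorbance_csv(spec: AbsorbanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.grid.values, "absorbance_au": spec.absorbance}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV (sample_id, class, eem_path, absorbance_path)."""
    df = pd.read_csv(path)
    required = {"sample_id", "class", "eem_path", "absorbance_path"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# Dataset construction and reshaping
# ---------------------------------------------------------------------------


def stack_dataset(eems: Sequence[EEM], labels: Sequence[str]) -> EEMDataset:
    """Stack grid-aligned EEMs into (n_samples, |em|, |ex|), order preserved."""
    if len(eems) < 2:
        raise DimensionError("need at least 2 samples to stack")
    if len(labels) != len(eems):
        raise DimensionError("one label per sample required")
    ref = eems[0]
    for e in eems[1:]:
        if e.ex_grid != ref.ex_grid or e.em_grid != ref.em_grid:
            raise AlignmentError(
                f"sample '{e.sample_id}' has a different wavelength grid"
            )
    arr = np.stack([e.intensity for e in eems])
    masks = np.stack([e.effective_mask for e in eems])
    return EEMDataset(
        samples=[e.sample_id for e in eems],
        labels=list(labels),
        array=arr,
        ex_grid=ref.ex_grid,
        em_grid=ref.em_grid,
        mask=masks if masks.any() else None,
    )


def crop(
    ds: EEMDataset,
    ex_range: tuple[float, float] | None = None,
    em_range: tuple[float, float] | None = None,
) -> EEMDataset:
    """Restrict a dataset to closed wavelength intervals on both grids."""
    ex_idx = (
        np.arange(len(ds.ex_grid))
        if ex_range is None
        else ds.ex_grid.index_range(*ex_range)
    )
    em_idx = (
        np.arange(len(ds.em_grid))
        if em_range is None
        else ds.em_grid.index_range(*em_range)
    )
    arr = ds.array[:, em_idx][:, :, ex_idx]
    mask = None if ds.mask is None else ds.mask[:, em_idx][:, :, ex_idx]
    return EEMDataset(
        samples=list(ds.samples),
        labels=list(ds.labels),
        array=arr,
        ex_grid=WavelengthGrid(ds.ex_grid.values[ex_idx]),
        em_grid=WavelengthGrid(ds.em_grid.values[em_idx]),
        mask=mask,
    )


def unfold(ds: EEMDataset) -> SpectralMatrix:
    """Unfold along the sample mode into (n_samples, |em|*|ex|) (uEEMs).

    Column ordering: emission index fastest, excitation slowest, i.e.
    column ``c`` carries ``(em[c % n_em], ex[c // n_em])``. Masked cells
    become NaN and must be filled (or skipped) downstream.
    """
    n, j, k = ds.shape
    vals = ds.masked_array().transpose(0, 2, 1).reshape(n, j * k)
    em_tags = np.tile(ds.em_grid.values, k)
    ex_tags = np.repeat(ds.ex_grid.values, j)
    return SpectralMatrix(vals, em_tags, ex_tags, sample_ids=list(ds.samples))


def refold(
    v: np.ndarray, em_grid: WavelengthGrid, ex_grid: WavelengthGrid
) -> np.ndarray:
    """Inverse of :func:`unfold`'s column ordering for a single row vector."""
    v = np.asarray(v, dtype=float).ravel()
    j, k = len(em_grid), len(ex_grid)
    if v.size != j * k:
        raise DimensionError(f"vector length {v.size} != |em|*|ex| = {j * k}")
    return v.reshape(k, j).T
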