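"""EEM preprocessing: inner-filter correction, scatter excision, averaging.

The inner filter effect (IFE) attenuates both the excitation beam and the
emitted light in optically dense samples. With a 1 cm path and absorbance
measured on the same solution, the standard absorbance-based correction is

    F_corr(ex, em) = F_obs(ex, em) * 10 ** ((A(ex) + A(em)) / 2),

reliable up to roughly A = 2 AU. First- and second-order Rayleigh scatter
ridges (em = ex and em = 2*ex) carry no fluorophore information and are
excised in a band around each ridge, either masked (for missing-data
PARAFAC) or interpolated along the emission axis (for PCA / PLS-DA, which
need complete matrices).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EEM, AbsorbanceSpectrum, EEMDataset, SpectralMatrix
from .errors import AlignmentError, ConfigError, DimensionError, GridError

__all__ = [
    "ScatterSpec",
    "ife_correct",
    "remove_rayleigh",
    "average_replicates",
    "extract_emission_slices",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)

#: absorbance above which the multiplicative IFE correction degrades
IFE_ABSORBANCE_LIMIT = 2.0


@dataclass
class ScatterSpec:
    """Rayleigh excision bands and the policy for the excised cells.

    ``order1_halfwidth`` masks |em - ex| <= h1; ``order2_halfwidth`` masks
    |em - 2*ex| <= h2 (both in nm). ``fill_policy`` is one of ``mask``,
    ``interpolate_emission`` or ``zero``.
    """

    order1_halfwidth: float = 10.0
    order2_halfwidth: float = 15.0
    fill_policy: str = "mask"

    def __post_init__(self):
        if self.order1_halfwidth <= 0 or self.order2_halfwidth <= 0:
            raise ConfigError("scatter halfwidths must be positive")
        if self.fill_policy not in {"mask", "interpolate_emission", "zero"}:
            raise ConfigError(f"unknown fill_policy '{self.fill_policy}'")

    def band_mask(self, em: np.ndarray, ex: np.ndarray) -> np.ndarray:
        """Boolean (|em|, |ex|) matrix of cells inside either scatter band."""
        em = em[:, None]
        ex = ex[None, :]
        return (np.abs(em - ex) <= self.order1_halfwidth) | (
            np.abs(em - 2.0 * ex) <= self.order2_halfwidth
        )


def ife_correct(
    eem: EEM,
    abs_spec: AbsorbanceSpectrum,
    return_factors: bool = False,
) -> EEM | tuple[EEM, np.ndarray]:
    """Undo inner-filter attenuation using the sample's absorbance spectrum.

    Absorbance is linearly interpolated onto the EEM's excitation and
    emission grids; each cell is multiplied by 10**((A_ex + A_em)/2).
    Masked cells keep their (undefined) value. Raises ``CoverageError``
    when the absorbance grid does not span the EEM grids, and warns when
    any absorbance exceeds 2 AU.
    """
    a_ex = abs_spec.interpolate(eem.ex_grid.values)
    a_em = abs_spec.interpolate(eem.em_grid.values)
    amax = max(a_ex.max(), a_em.max())
    if amax > IFE_ABSORBANCE_LIMIT:
        warnings.warn(
            f"absorbance reaches {amax:.2f} AU; IFE correction is unreliable "
            "above 2 AU",
            stacklevel=2,
        )
    factors = 10.0 ** ((a_em[:, None] + a_ex[None, :]) / 2.0)
    out = eem.copy()
    keep = ~eem.effective_mask
    out.intensity[keep] = eem.intensity[keep] * factors[keep]
    if return_factors:
        return out, factors
    return out


def remove_rayleigh(
    eem: EEM, spec: ScatterSpec | None = None, return_count: bool = False
) -> EEM | tuple[EEM, int]:
    """Excise first- and second-order Rayleigh scatter ridges.

    Cells within the bands are removed per ``spec.fill_policy``: added to
    the mask, replaced by linear interpolation along each emission column,
    or zeroed. Columns fully inside a band cannot be interpolated and fall
    back to masking with a warning.
    """
    spec = spec or ScatterSpec()
    band = spec.band_mask(eem.em_grid.values, eem.ex_grid.values)
    prior = eem.effective_mask
    new_cells = band & ~prior
    count = int(new_cells.sum())
    out = eem.copy()
    if spec.fill_policy == "mask":
        out.mask = prior | band
    elif spec.fill_policy == "zero":
        out.intensity[new_cells] = 0.0
        out.mask = prior if prior.any() else None
    else:  # interpolate_emission
        em = eem.em_grid.values
        mask_out = prior.copy()
        for k in range(len(eem.ex_grid)):
            bad = band[:, k] | prior[:, k]
            good = ~bad
            if not bad.any():
                continue
            if good.sum() < 2:
                warnings.warn(
                    f"excitation column {eem.ex_grid.values[k]:g} nm is fully "
                    "excised; falling back to mask",
                    stacklevel=2,
                )
                mask_out[:, k] = True
                continue
            out.intensity[bad, k] = np.interp(em[bad], em[good],
                                              eem.intensity[good, k])
            mask_out[bad, k] = False
        out.mask = mask_out if mask_out.any() else None
    logger.debug("remove_rayleigh: excised %d cells (%s)", count, spec.fill_policy)
    if return_count:
        return out, count
    return out


def average_replicates(eems: Sequence[EEM]) -> EEM:
    """Cell-wise mean of replicate EEMs sharing grids and sample_id.

    A cell masked in any replicate is masked in the mean.
    """
    if len(eems) == 0:
        raise DimensionError("need at least one replicate")
    ref = eems[0]
    for e in eems[1:]:
        if e.ex_grid != ref.ex_grid or e.em_grid != ref.em_grid:
            raise AlignmentError(
                f"replicate '{e.sample_id}' has a different wavelength grid"
            )
        if e.sample_id != ref.sample_id:
            raise AlignmentError(
                f"replicate sample_id '{e.sample_id}' != '{ref.sample_id}'"
            )
    stack = np.stack([e.intensity for e in eems])
    masks = np.stack([e.effective_mask for e in eems])
    mask = masks.any(axis=0)
    mean = stack.mean(axis=0)
    mean[mask] = 0.0
    return EEM(ref.ex_grid, ref.em_grid, mean, ref.sample_id,
               mask if mask.any() else None)


def extract_emission_slices(
    ds: EEMDataset, ex_wavelengths: Sequence[float]
) -> SpectralMatrix:
    """Concatenate the emission spectra at selected excitation wavelengths.

    Each requested excitation snaps to the nearest grid point within half
    a grid step (a note is logged when snapping moves the wavelength);
    farther requests raise :class:`GridError`. Columns are tagged with
    their (lambda_em, lambda_ex) pairs in request order.
    """
    if len(ex_wavelengths) == 0:
        raise GridError("no excitation wavelengths requested")
    cols = []
    em_tags, ex_tags = [], []
    for w in ex_wavelengths:
        k = ds.ex_grid.nearest_index(w)
        actual = ds.ex_grid.values[k]
        if abs(actual - w) > 1e-9:
            logger.info("excitation %g nm snapped to grid point %g nm", w, actual)
        block = ds.masked_array()[:, :, k]
        cols.append(block)
        em_tags.append(ds.em_grid.values)
        ex_tags.append(np.full(len(ds.em_grid), actual))
    return SpectralMatrix(
        np.concatenate(cols, axis=1),
        np.concatenate(em_tags),
        np.concatenate(ex_tags),
        sample_ids=list(ds.samples),
    )


def preprocess_dataset(
    replicates: dict[str, Sequence[EEM]],
    absorbance: dict[str, AbsorbanceSpectrum],
    labels: dict[str, str],
    scatter: ScatterSpec | None = None,
    apply_ife: bool = True,
) -> EEMDataset:
    """Full per-sample pipeline: IFE -> scatter removal -> replicate averaging.

    The stage order is fixed; returns the stacked dataset in manifest
    (insertion) order of ``replicates``.
    """
    from .core import stack_dataset

    scatter = scatter or ScatterSpec()
    processed, labs = [], []
    for sid, reps in replicates.items():
        eems = list(reps)
        if apply_ife:
            eems = [ife_correct(e, absorbance[sid]) for e in eems]
        eems = [remove_rayleigh(e, scatter) for e in eems]
        processed.append(average_replicates(eems))
        labs.append(labels[sid])
    logger.info("preprocessed %d samples (IFE=%s, fill=%s)", len(processed),
                apply_ife, scatter.fill_policy)
    return stack_dataset(processed, labs)
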