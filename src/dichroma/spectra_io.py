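"""Reading, validation, smoothing and normalisation of reflectance spectra.

Spectra are stored wide: a strictly increasing wavelength grid (nm) and one
reflectance column per measured patch, expressed as a proportion in [0, 1]
(percent input is detected and rescaled on read). Every spectrum carries a
metadata record: spectrum id, individual, sex (M/F) and body region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import (
    DegenerateInputError,
    MetadataMismatchError,
    ParameterError,
    RegionNotFoundError,
    SpectraFormatError,
)

logger = logging.getLogger(__name__)

SEXES = ("M", "F")

#: The ten body regions of the sampling design.
REGIONS = (
    "Abdomen",
    "Chest",
    "Throat",
    "Cloaca",
    "Dorsum",
    "Flanks",
    "Head",
    "Legs",
    "Mouth",
    "Head profile",
)

META_COLUMNS = ("spectrum_id", "individual_id", "sex", "region", "patch_index")

#: Default common wavelength grid, 300-700 nm at 1 nm.
DEFAULT_WL = np.arange(300.0, 701.0)


@dataclass(frozen=True)
class SpectrumSet:
    """A collection of reflectance spectra on a shared wavelength grid.

    Attributes
    ----------
    wavelengths : (n_wl,) array, strictly increasing, nm
    reflectance : (n_wl, n_spectra) array, proportion reflectance, >= 0
    meta : DataFrame with one row per spectrum (columns ``META_COLUMNS``)
    from_percent : True if the input was detected as percent and rescaled
    processing_log : free-form record of processing steps applied
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame
    from_percent: bool = False
    processing_log: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if refl.ndim == 1:
            refl = refl[:, None]
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraFormatError("need a 1-D wavelength grid with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if refl.shape[0] != wl.size:
            raise SpectraFormatError(
                f"reflectance has {refl.shape[0]} rows for {wl.size} wavelengths"
            )
        if np.any(~np.isfinite(refl)):
            raise SpectraFormatError("reflectance contains NaN or infinite values")
        meta = self.meta.reset_index(drop=True)
        object.__setattr__(self, "meta", meta)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise MetadataMismatchError(f"metadata lacks columns {missing}")
        if len(meta) != refl.shape[1]:
            raise MetadataMismatchError(
                f"{refl.shape[1]} spectra but {len(meta)} metadata rows"
            )
        if meta["spectrum_id"].duplicated().any():
            raise MetadataMismatchError("duplicate spectrum_id in metadata")
        bad_sex = set(meta["sex"]) - set(SEXES)
        if bad_sex:
            raise MetadataMismatchError(f"sex labels outside {SEXES}: {bad_sex}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.reflectance.shape[1]

    @property
    def spectrum_ids(self) -> list[str]:
        return list(self.meta["spectrum_id"])

    def select(self, mask) -> "SpectrumSet":
        """Subset spectra by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            reflectance=self.reflectance[:, idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def region(self, name: str) -> "SpectrumSet":
        """All spectra of one body region."""
        mask = (self.meta["region"] == name).to_numpy()
        if not mask.any():
            raise RegionNotFoundError(f"no spectra for region {name!r}")
        return self.select(mask)

    def regions(self) -> list[str]:
        seen = self.meta["region"].unique()
        return [r for r in REGIONS if r in seen] + [
            r for r in seen if r not in REGIONS
        ]


# ---------------------------------------------------------------------------
# Reading / writing


def read_spectra(
    path,
    meta_path,
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Read a wide spectra CSV (first column ``wl``) plus its metadata CSV.

    Wavelengths must be strictly monotone (a descending export is flipped);
    spectra are linearly interpolated onto a common 1-nm grid clipped to
    300-700 nm. Values with a maximum above 1.5 are treated as percent and
    divided by 100. Every spectrum column must have a metadata row and vice
    versa.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wl":
        raise SpectraFormatError(
            f"first column must be 'wl', found {df.columns[0]!r}"
        )
    wl = df["wl"].to_numpy(dtype=float)
    d = np.diff(wl)
    if np.all(d < 0):  # descending export
        df = df.iloc[::-1].reset_index(drop=True)
        wl = wl[::-1]
    elif np.any(d <= 0):
        raise SpectraFormatError("wavelength column is not strictly monotone")
    refl = df.drop(columns="wl").to_numpy(dtype=float)
    ids = [str(c) for c in df.columns[1:]]
    if np.any(~np.isfinite(refl)):
        raise SpectraFormatError("spectra contain missing values")

    meta = pd.read_csv(meta_path, dtype={"spectrum_id": str})
    meta_ids = list(meta["spectrum_id"])
    if set(ids) - set(meta_ids):
        raise MetadataMismatchError(
            f"spectra without metadata: {sorted(set(ids) - set(meta_ids))}"
        )
    if set(meta_ids) - set(ids):
        raise MetadataMismatchError(
            f"metadata without spectra: {sorted(set(meta_ids) - set(ids))}"
        )
    meta = meta.set_index("spectrum_id").loc[ids].reset_index()

    from_percent = bool(np.nanmax(refl) > 1.5)
    if from_percent:
        refl = refl / 100.0

    if grid is None:
        lo = max(300.0, np.ceil(wl[0]))
        hi = min(700.0, np.floor(wl[-1]))
        grid = np.arange(lo, hi + 0.5)
    if not np.array_equal(wl, grid):
        refl = np.column_stack(
            [np.interp(grid, wl, refl[:, j]) for j in range(refl.shape[1])]
        )
        wl = grid
    return SpectrumSet(wl, refl, meta, from_percent=from_percent)


def write_spectra(s: SpectrumSet, path, meta_path) -> None:
    """Write a SpectrumSet back to the wide CSV + metadata CSV pair."""
    df = pd.DataFrame(s.reflectance, columns=s.spectrum_ids)
    df.insert(0, "wl", s.wavelengths)
    df.to_csv(path, index=False)
    s.meta.to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Processing


def smooth_spectra(s: SpectrumSet, span: float = 0.2) -> SpectrumSet:
    """LOESS-smooth every spectrum over the wavelength grid.

    Local-linear regression with tricube weights; ``span`` is the fraction
    of grid points in each local window. Constants and straight lines pass
    through unchanged; measurement noise is suppressed.
    """
    if not 0 < span <= 1:
        raise ParameterError(f"span must be in (0, 1], got {span}")
    wl = s.wavelengths
    sm = np.empty_like(s.reflectance)
    for j in range(s.n_spectra):
        sm[:, j] = lowess(
            s.reflectance[:, j], wl, frac=span, it=0, return_sorted=False
        )
    log = dict(s.processing_log)
    log["smoothed_span"] = span
    return replace(s, reflectance=sm, processing_log=log)


def clamp_negative(s: SpectrumSet) -> SpectrumSet:
    """Clamp negative reflectance (instrument noise) to zero.

    The number of clamped values is logged and recorded under
    ``processing_log['clamped']``; nonnegative values are untouched.
    """
    n_neg = int(np.sum(s.reflectance < 0))
    if n_neg:
        logger.info("clamped %d negative reflectance values to 0", n_neg)
    refl = np.clip(s.reflectance, 0.0, None) if n_neg else s.reflectance
    log = dict(s.processing_log)
    log["clamped"] = n_neg
    return replace(s, reflectance=refl, processing_log=log)


def concat(sets: list[SpectrumSet]) -> SpectrumSet:
    """Concatenate spectrum sets sharing a wavelength grid."""
    if not sets:
        raise DegenerateInputError("nothing to concatenate")
    wl = sets[0].wavelengths
    for t in sets[1:]:
        if not np.array_equal(t.wavelengths, wl):
            raise SpectraFormatError("wavelength grids differ")
    return SpectrumSet(
        wl,
        np.concatenate([t.reflectance for t in sets], axis=1),
        pd.concat([t.meta for t in sets], ignore_index=True),
        from_percent=any(t.from_percent for t in sets),
    )
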