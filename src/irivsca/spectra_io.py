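"""Reading, writing and validation of wide-format spectral tables.

A spectral table is a delimited text file whose numeric header (or index)
holds wavelengths in nm and whose body holds reflectance in [0, 1], one
sample per row (or per column with ``layout="samples-as-columns"``).
Targets (e.g. soil As concentration, µg/g) live in a two-column CSV of
``sample_id, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SpectraError(ValueError):
    """Raised for malformed spectral tables or invalid operations on them."""


@dataclass(frozen=True)
class SpectrumSet:
    """A set of reflectance spectra on a common wavelength grid.

    Attributes
    ----------
    wavelengths : (n_bands,) float array, strictly increasing, nm.
    reflectance : (n_samples, n_bands) float array, unitless, in [0, 1].
    sample_ids : tuple of unique sample labels.
    target : optional (n_samples,) float array (concentration, µg/g).
    metadata : free-form dict (e.g. planted ground truth of a simulation).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: tuple
    target: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)
        if refl.ndim != 2:
            raise SpectraError("reflectance must be a 2-D matrix")
        if wl.ndim != 1 or wl.size != refl.shape[1]:
            raise SpectraError(
                f"wavelength count ({wl.size}) != reflectance columns ({refl.shape[1]})"
            )
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise SpectraError("reflectance contains non-finite values")
        if refl.size and refl.min() < 0:
            raise SpectraError("negative reflectance values are not allowed")
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        if len(ids) != refl.shape[0]:
            raise SpectraError("sample_ids length != number of rows")
        if len(set(ids)) != len(ids):
            raise SpectraError("sample_ids must be unique")
        if self.target is not None:
            t = np.asarray(self.target, dtype=float)
            if t.shape != (refl.shape[0],):
                raise SpectraError("target length != number of samples")
            if not np.all(np.isfinite(t)):
                raise SpectraError("target contains non-finite values")
            object.__setattr__(self, "target", t)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def with_target(self, target) -> "SpectrumSet":
        return replace(self, target=np.asarray(target, dtype=float))

    def select_bands(self, indices) -> "SpectrumSet":
        """Restrict to the given band indices (kept in ascending-λ order)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return replace(
            self,
            wavelengths=self.wavelengths[idx],
            reflectance=self.reflectance[:, idx],
        )


def _parse_wavelengths(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        try:
            out[i] = float(str(lab).strip())
        except ValueError:
            raise SpectraError(f"non-numeric wavelength label: {lab!r}") from None
    uniq, counts = np.unique(out, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1]
        raise SpectraError(f"duplicate wavelength(s): {', '.join(format_wavelength(d) for d in dup)}")
    return out


def read_spectra(path, layout: str = "samples-as-rows") -> SpectrumSet:
    """Read a delimited spectral table into a validated :class:`SpectrumSet`.

    Columns are reordered so wavelengths come out strictly ascending.
    The first column (samples-as-rows) or the header (samples-as-columns)
    holds sample ids.
    """
    if layout not in ("samples-as-rows", "samples-as-columns"):
        raise SpectraError(f"unknown layout: {layout!r}")
    df = pd.read_csv(path, index_col=0)
    if layout == "samples-as-columns":
        df = df.T
        labels = list(df.columns)
    else:
        # pandas mangles duplicate header labels (740, 740.1); read the raw
        # header line so duplicated wavelengths are actually caught
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        labels = [c.strip() for c in header.split(",")[1:]]
    wl = _parse_wavelengths(labels)
    values = df.to_numpy(dtype=float)
    if np.any(np.isnan(values)):
        rows = df.index[np.isnan(values).any(axis=1)].tolist()
        raise SpectraError(f"missing/non-numeric reflectance in row(s): {rows}")
    order = np.argsort(wl)
    return SpectrumSet(
        wavelengths=wl[order],
        reflectance=values[:, order],
        sample_ids=tuple(df.index.astype(str)),
    )


def write_spectra(ss: SpectrumSet, path) -> None:
    """Write a :class:`SpectrumSet` as a samples-as-rows CSV table."""
    df = pd.DataFrame(
        ss.reflectance,
        index=pd.Index(ss.sample_ids, name="sample_id"),
        columns=[format_wavelength(w) for w in ss.wavelengths],
    )
    df.to_csv(path, float_format="%.10g")


def read_targets(path) -> pd.Series:
    """Read a ``sample_id,value`` CSV into a Series indexed by sample id."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise SpectraError("target file must have exactly one value column")
    s = df.iloc[:, 0].astype(float)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise SpectraError(f"missing target value(s) for sample(s): {missing}")
    return s


def write_targets(target, sample_ids: Sequence, path) -> None:
    pd.Series(
        np.asarray(target, dtype=float),
        index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
        name="value",
    ).to_csv(path, float_format="%.10g")


def attach_targets(ss: SpectrumSet, targets: pd.Series) -> SpectrumSet:
    """Align a target Series to the sample ids of ``ss`` and attach it."""
    missing = [s for s in ss.sample_ids if s not in targets.index]
    if missing:
        raise SpectraError(f"targets missing for sample(s): {missing}")
    return ss.with_target(targets.loc[list(ss.sample_ids)].to_numpy())


def trim_edges(ss: SpectrumSet, low: float = 400.0, high: float = 2399.0) -> SpectrumSet:
    """Remove noisy edge bands, keeping the closed interval [low, high] nm.

    With the defaults this drops the 350–399 nm and 2400–2500 nm fringes of a
    full-range Vis-NIR grid (a 1 nm / 2151-band grid retains 2000 variables).
    """
    if not low < high:
        raise SpectraError("trim window requires low < high")
    keep = np.flatnonzero((ss.wavelengths >= low) & (ss.wavelengths <= high))
    if keep.size == 0:
        raise SpectraError(f"no bands inside trim window [{low}, {high}] nm")
    return ss.select_bands(keep)


def format_wavelength(w: float) -> str:
    """Render a wavelength the way band labels are written: 486, not 486.0."""
    w = float(w)
    if w == int(w):
        return str(int(w))
    return format(w, ".10g")
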