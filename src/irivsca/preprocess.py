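"""Spectral preprocessing: Gaussian smoothing, first-derivative features,
the GF→FD→GFA cascade, and train-statistics standardization.

The cascade operates on the IRIV-retained band set: derivative pairs are
consecutive retained bands, which is what produces pair-labelled features
such as ``GFA_849–769`` from a retained set containing 769 and 849 nm. The
initial Gaussian smoothing can run either over the retained-band sequence
(default; σ in retained-index units) or, given the full spectrum, over each
retained band's grid neighbours — see :func:`gfa_cascade`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectrumSet, format_wavelength

# en dash, the conventional band-pair label separator
PAIR_SEP = "–"


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureBlock:
    """A named block of derived features of one kind (GF, FD or GFA).

    ``source_wavelengths`` holds one wavelength per GF feature and an
    ordered (lower, upper) pair per FD/GFA feature.
    """

    kind: str  # "GF" | "FD" | "GFA"
    names: tuple
    values: np.ndarray  # (n_samples, n_features)
    source_wavelengths: tuple

    def __post_init__(self):
        if self.kind not in ("GF", "FD", "GFA"):
            raise PreprocessError(f"unknown block kind: {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(self.names) != vals.shape[1]:
            raise PreprocessError("names length != feature count")
        if len(set(self.names)) != len(self.names):
            raise PreprocessError("feature names must be unique within a block")
        if len(self.source_wavelengths) != vals.shape[1]:
            raise PreprocessError("source_wavelengths length != feature count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def gaussian_kernel_matrix(n: int, sigma: float) -> np.ndarray:
    """Row-stochastic smoothing matrix for a length-``n`` band sequence.

    Discrete Gaussian weights exp(-d²/2σ²), truncated at radius ceil(3σ) and
    renormalized over the in-range taps, so edges average only real
    observations instead of inventing padding values.
    """
    if sigma <= 0:
        raise PreprocessError("sigma must be > 0")
    if n < 1:
        raise PreprocessError("need at least one band")
    radius = int(np.ceil(3.0 * sigma))
    idx = np.arange(n)
    d = idx[:, None] - idx[None, :]
    w = np.where(np.abs(d) <= radius, np.exp(-0.5 * (d / sigma) ** 2), 0.0)
    return w / w.sum(axis=1, keepdims=True)


def gaussian_filter(values: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian-smooth each row of ``values`` along its band axis.

    Accepts a 1-D sequence or a (n_samples, n_bands) matrix; distances are in
    band-index units. Constant sequences are preserved exactly (the kernel is
    normalized), and the operator is linear.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    out = arr @ gaussian_kernel_matrix(arr.shape[1], sigma).T
    return out[0] if np.asarray(values).ndim == 1 else out


def _pair_names(kind: str, wavelengths: np.ndarray):
    names, pairs = [], []
    for lo, hi in zip(wavelengths[:-1], wavelengths[1:]):
        names.append(f"{kind}_{format_wavelength(hi)}{PAIR_SEP}{format_wavelength(lo)}")
        pairs.append((float(lo), float(hi)))
    return tuple(names), tuple(pairs)


def first_derivative(values: np.ndarray, wavelengths) -> FeatureBlock:
    """Forward difference quotient between consecutive bands.

    Feature j = (v(λ_{j+1}) − v(λ_j)) / (λ_{j+1} − λ_j), named
    ``FD_{λ_{j+1}}–{λ_j}``. Removes per-sample additive baseline offsets.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size < 2:
        raise PreprocessError("first derivative needs at least two bands")
    if np.any(np.diff(wl) <= 0):
        raise PreprocessError("wavelengths must be strictly increasing")
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[1] != wl.size:
        raise PreprocessError("values width != wavelength count")
    deriv = np.diff(arr, axis=1) / np.diff(wl)[None, :]
    names, pairs = _pair_names("FD", wl)
    return FeatureBlock(kind="FD", names=names, values=deriv, source_wavelengths=pairs)


def _gf_at_bands(full: SpectrumSet, bands: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth the *full-grid* spectra, evaluated at the given bands.

    Each retained band is averaged with its grid neighbours (truncation
    ceil(3σ) grid steps, kernel renormalized in-range), so the smoothed
    feature carries information from bands outside the retained set — this
    is what makes a GF feature genuinely less noisy than the raw band.
    """
    if sigma <= 0:
        raise PreprocessError("sigma must be > 0")
    idx = []
    for b in bands:
        hits = np.flatnonzero(full.wavelengths == b)
        if hits.size != 1:
            raise PreprocessError(f"retained band {b} nm not on the full grid")
        idx.append(int(hits[0]))
    radius = int(np.ceil(3.0 * sigma))
    n_full = full.n_bands
    out = np.empty((full.n_samples, len(idx)))
    for j, gj in enumerate(idx):
        lo, hi = max(0, gj - radius), min(n_full, gj + radius + 1)
        w = np.exp(-0.5 * ((np.arange(lo, hi) - gj) / sigma) ** 2)
        out[:, j] = full.reflectance[:, lo:hi] @ (w / w.sum())
    return out


def gfa_cascade(ss: SpectrumSet, sigma: float = 1.0,
                full: SpectrumSet | None = None) -> dict:
    """Gaussian filter → first derivative → Gaussian filter again.

    ``ss`` must already be restricted to the retained (characteristic)
    bands. Returns ``{"GF": ..., "FD": ..., "GFA": ...}`` FeatureBlocks with
    k, k−1 and k−1 features respectively for k retained bands.

    When ``full`` (the untrimmed-spectrum superset of ``ss``) is given, the
    initial GF stage smooths each retained band over its *grid* neighbours
    instead of over the retained-band sequence, averaging away band noise
    with information the raw retained bands do not contain; the FD and GFA
    stages always run over the retained sequence (consecutive retained bands
    form the derivative pairs, hence pair labels like ``GFA_849–769``).
    """
    if ss.n_bands < 2:
        raise PreprocessError("cascade needs at least two retained bands")
    if full is not None:
        gf_vals = _gf_at_bands(full, ss.wavelengths, sigma)
    else:
        gf_vals = gaussian_filter(ss.reflectance, sigma)
    gf = FeatureBlock(
        kind="GF",
        names=tuple(f"GF_{format_wavelength(w)}" for w in ss.wavelengths),
        values=gf_vals,
        source_wavelengths=tuple(float(w) for w in ss.wavelengths),
    )
    fd = first_derivative(gf_vals, ss.wavelengths)
    gfa_names, gfa_pairs = _pair_names("GFA", ss.wavelengths)
    gfa = FeatureBlock(
        kind="GFA",
        names=gfa_names,
        values=gaussian_filter(fd.values, sigma),
        source_wavelengths=gfa_pairs,
    )
    return {"GF": gf, "FD": fd, "GFA": gfa}


@dataclass(frozen=True)
class ScalerStats:
    mean: np.ndarray
    sd: np.ndarray


def standardize(train: np.ndarray, test: np.ndarray | None = None,
                feature_names=None):
    """Column-wise (x − mean)/sd using *training* statistics only.

    Population standard deviation (divide by n). The identical transform is
    applied to ``test`` so held-out data never leaks into the statistics.
    Returns ``(train_scaled, test_scaled, stats)``; ``test_scaled`` is None
    when no test matrix is given.
    """
    tr = np.asarray(train, dtype=float)
    if tr.ndim != 2 or tr.shape[0] < 2:
        raise PreprocessError("train must be 2-D with at least two samples")
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0)  # population sd
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = feature_names[bad[0]] if feature_names is not None else f"column {bad[0]}"
        raise PreprocessError(f"zero-variance training feature: {name}")
    stats = ScalerStats(mean=mean, sd=sd)
    tr_s = (tr - mean) / sd
    te_s = None
    if test is not None:
        te = np.asarray(test, dtype=float)
        if te.ndim != 2 or te.shape[1] != tr.shape[1]:
            raise PreprocessError("test width != train width")
        te_s = (te - mean) / sd
    return tr_s, te_s, stats
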