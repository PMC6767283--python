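"""Spearman rank correlation screening of derived features (SCA).

Every feature of the GF / FD / GFA blocks is rank-correlated with the
target; features whose |r| strictly exceeds the threshold (default 0.6)
are combined — in block order GF, FD, GFA, then by
wavelength — into the final characteristic feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureBlock
from .spectra_io import SpectraError


class ScaError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSet:
    """Named derived features with their Spearman coefficients."""

    names: tuple
    values: np.ndarray  # (n_samples, n_features)
    spearman_r: np.ndarray
    kinds: tuple  # block provenance per feature
    source_wavelengths: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spearman_r", np.asarray(self.spearman_r, dtype=float))
        if len(set(self.names)) != len(self.names):
            raise ScaError("feature names must be unique across blocks")
        if not (len(self.names) == vals.shape[1] == len(self.spearman_r)
                == len(self.kinds) == len(self.source_wavelengths)):
            raise ScaError("inconsistent FeatureSet field lengths")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_features == 0

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: name, kind, wavelength(s), spearman_r."""
        return pd.DataFrame({
            "name": self.names,
            "kind": self.kinds,
            "wavelengths": [
                w if np.isscalar(w) else f"{w[0]}:{w[1]}" for w in self.source_wavelengths
            ],
            "spearman_r": self.spearman_r,
        })


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on average-ranked data.

    Ties receive mean ranks. Constant inputs have undefined rank correlation
    and raise rather than returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScaError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ScaError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ScaError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ScaError("rank correlation undefined for a constant input")
    return float(stats.spearmanr(x, y).statistic)


def _block_feature_order(block: FeatureBlock) -> np.ndarray:
    keys = [w if np.isscalar(w) else w[0] for w in block.source_wavelengths]
    return np.argsort(np.asarray(keys, dtype=float), kind="stable")


def select_features(blocks: dict, y, threshold: float = 0.6) -> FeatureSet:
    """Retain every derived feature with |spearman(feature, y)| > threshold.

    ``blocks`` maps kind → FeatureBlock (any subset of GF/FD/GFA). The
    result is ordered by block (GF, FD, GFA) then wavelength and carries the
    correlation and provenance of each retained feature. An empty result is
    returned as an empty FeatureSet (``.is_empty``) so the caller decides the
    fallback — it is never silently dropped.
    """
    y = np.asarray(y, dtype=float)
    names, cols, rs, kinds, wls = [], [], [], [], []
    for kind in ("GF", "FD", "GFA"):
        if kind not in blocks:
            continue
        block = blocks[kind]
        if block.values.shape[0] != y.size:
            raise ScaError(f"{kind} block sample count != target length")
        for j in _block_feature_order(block):
            r = spearman(block.values[:, j], y)
            if abs(r) > threshold:
                names.append(block.names[j])
                cols.append(block.values[:, j])
                rs.append(r)
                kinds.append(kind)
                wls.append(block.source_wavelengths[j])
    values = np.column_stack(cols) if cols else np.empty((y.size, 0))
    return FeatureSet(
        names=tuple(names),
        values=values,
        spearman_r=np.array(rs, dtype=float),
        kinds=tuple(kinds),
        source_wavelengths=tuple(wls),
    )


def write_features(fs: FeatureSet, path) -> None:
    """Serialize a FeatureSet (with per-sample values) to CSV."""
    meta = fs.to_frame().set_index("name").T
    data = pd.DataFrame(fs.values, columns=list(fs.names))
    pd.concat([meta, data.set_axis([f"s{i}" for i in range(len(data))])]).to_csv(
        path, index_label="row", float_format="%.12g"
    )


def read_features(path) -> FeatureSet:
    """Read back a FeatureSet written by :func:`write_features`."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        return FeatureSet((), np.empty((max(df.shape[0] - 3, 0), 0)), np.array([]), (), ())
    kinds = tuple(df.loc["kind"])
    wl_raw = df.loc["wavelengths"]
    wls = tuple(
        tuple(float(v) for v in str(w).split(":")) if ":" in str(w) else float(w)
        for w in wl_raw
    )
    rs = df.loc["spearman_r"].astype(float).to_numpy()
    values = df.iloc[3:].astype(float).to_numpy()
    return FeatureSet(tuple(df.columns), values, rs, kinds, wls)
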