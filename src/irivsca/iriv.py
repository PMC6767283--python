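"""Iteratively Retaining Informative Variables (IRIV).

A wrapper wavelength selector in the BMSF lineage: each round draws a
balanced random binary design matrix A (rows = sub-models, columns =
variables), scores every sub-model by 5-fold PLS RMSECV, and contrasts for
each variable the error distribution of sub-models that include it (φ0)
against those that exclude it (φi), pooling rows of A with rows of its
complement matrix B = 1 − A. The mean difference DMEAN_i = mean(φ0) −
mean(φi) and a two-sided Mann–Whitney U p-value classify each variable as
strongly informative, weakly informative, uninformative or interfering;
strong + weak survive to the next round. When no uninformative or
interfering variables remain, a greedy backward elimination prunes the
survivors to the final characteristic-band set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._pls import cv_rmse, make_folds
from .spectra_io import SpectrumSet

STRONG = "strong"
WEAK = "weak"
UNINFORMATIVE = "uninformative"
INTERFERING = "interfering"


class IrivError(RuntimeError):
    def __init__(self, message, rounds=None):
        super().__init__(message)
        self.rounds = rounds or []


@dataclass(frozen=True)
class IrivConfig:
    """Knobs of the IRIV screen.

    n_rows : sub-models per round (rows of A); even, ≥ 2.
    cv_folds : folds of the RMSECV criterion (default 5).
    max_pls_factors : cap on PLS latent factors per sub-model (10).
    alpha : Mann–Whitney significance threshold (0.05).
    seed : drives the fold partition and every design-matrix draw.
    max_rounds : safety cap on screening rounds.
    """

    n_rows: int = 500
    cv_folds: int = 5
    max_pls_factors: int = 10
    alpha: float = 0.05
    seed: int = 0
    max_rounds: int = 20

    def __post_init__(self):
        if self.n_rows < 2 or self.n_rows % 2:
            raise ValueError("n_rows must be even and >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_pls_factors < 1:
            raise ValueError("max_pls_factors must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass(frozen=True)
class RoundResult:
    """Per-variable scores and classes of one screening round."""

    wavelengths: np.ndarray  # variables entering this round
    dmean: np.ndarray
    pvalues: np.ndarray
    classes: tuple
    retained_wavelengths: np.ndarray  # strong + weak

    @property
    def n_retained(self) -> int:
        return len(self.retained_wavelengths)


@dataclass(frozen=True)
class IrivResult:
    rounds: tuple
    final_wavelengths: np.ndarray
    final_indices: np.ndarray  # band indices into the input SpectrumSet
    final_rmsecv: float
    eliminated_trace: tuple = field(default=())

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def generate_design_matrix(p: int, n_rows: int, seed) -> np.ndarray:
    """Balanced binary design: every column holds exactly n_rows/2 ones,
    independently permuted per column. Deterministic for a fixed seed."""
    if n_rows % 2:
        raise ValueError("n_rows must be even")
    if p < 1:
        raise ValueError("need at least one variable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    col = np.concatenate([np.ones(n_rows // 2, dtype=np.int8),
                          np.zeros(n_rows - n_rows // 2, dtype=np.int8)])
    return rng.permuted(np.tile(col[:, None], (1, p)), axis=0)


def rmsecv(X: np.ndarray, y: np.ndarray, cfg: IrivConfig | None = None,
           folds=None) -> float:
    """k-fold cross-validated PLS RMSE of the given variable subset.

    The fold partition is derived from ``cfg.seed`` unless explicit folds are
    passed (IRIV fixes one partition per run so sub-model scores are
    comparable). An empty subset scores +inf.
    """
    cfg = cfg or IrivConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        if len(y) < cfg.cv_folds:
            raise ValueError("fewer samples than cv folds")
        folds = make_folds(len(y), cfg.cv_folds, np.random.default_rng(cfg.seed))
    return cv_rmse(X, y, folds, cfg.max_pls_factors)


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value; exact for small untied samples,
    normal approximation with tie correction otherwise."""
    if a.size == 0 or b.size == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # identical distributions, no evidence of difference
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(a.size, b.size) < 8 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def score_variables(X: np.ndarray, y: np.ndarray, A: np.ndarray,
                    cfg: IrivConfig, folds=None):
    """DMEAN_i and Mann–Whitney p_i for every variable under design A.

    RMSECV is computed for every row of A and of its complement B = 1 − A;
    for variable i, φ0 pools the scores of sub-models that include i (rows of
    A with A_ki = 1 plus rows of B with B_ki = 1) and φi those that exclude
    it. Rows whose sub-model is empty score +inf and are dropped from the
    pools. Returns ``(dmean, pvalues)`` arrays of length p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    A = np.asarray(A)
    n_rows, p = A.shape
    if p != X.shape[1]:
        raise ValueError("design width != variable count")
    if folds is None:
        folds = make_folds(len(y), cfg.cv_folds, np.random.default_rng(cfg.seed))
    B = 1 - A

    def row_scores(M):
        out = np.empty(n_rows)
        for k in range(n_rows):
            cols = np.flatnonzero(M[k])
            out[k] = cv_rmse(X[:, cols], y, folds, cfg.max_pls_factors)
        return out

    r_a = row_scores(A)
    r_b = row_scores(B)
    ok_a, ok_b = np.isfinite(r_a), np.isfinite(r_b)

    dmean = np.empty(p)
    pvals = np.empty(p)
    for i in range(p):
        in_a = A[:, i] == 1
        phi0 = np.concatenate([r_a[in_a & ok_a], r_b[~in_a & ok_b]])
        phii = np.concatenate([r_a[~in_a & ok_a], r_b[in_a & ok_b]])
        if phi0.size == 0 or phii.size == 0:
            # every sub-model on one side was empty (p = 1 degenerate case):
            # no evidence either way
            dmean[i], pvals[i] = 0.0, 1.0
            continue
        dmean[i] = phi0.mean() - phii.mean()
        pvals[i] = _mannwhitney_p(phi0, phii)
    return dmean, pvals


def classify_variable(dmean: float, p: float, alpha: float = 0.05) -> str:
    """Four-quadrant variable typing on (DMEAN, p).

    DMEAN < 0 marks informative variables (strong if p < alpha, else weak);
    DMEAN > 0 marks harmful ones (interfering if p < alpha, else
    uninformative). DMEAN exactly 0 offers no evidence of benefit and is
    typed uninformative.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if dmean < 0:
        return STRONG if p < alpha else WEAK
    if dmean == 0:
        return UNINFORMATIVE
    return INTERFERING if p < alpha else UNINFORMATIVE


def backward_eliminate(X: np.ndarray, y: np.ndarray, variables: Sequence[int],
                       cfg: IrivConfig, folds=None):
    """Greedy backward elimination of the retained variables.

    Repeatedly drops the variable whose exclusion gives the smallest RMSECV,
    as long as that minimum does not exceed the current RMSECV; stops when
    every single-variable removal hurts. Ties break toward the lowest
    variable index, and the ≤ comparison carries a 1e-9 relative tolerance so
    exact redundancies (e.g. duplicated columns, where removal leaves the
    fit unchanged up to rounding) are eliminated rather than kept. Returns
    ``(surviving variables, final RMSECV, trace)``.
    """
    current = list(variables)
    if not current:
        raise ValueError("variables must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        folds = make_folds(len(y), cfg.cv_folds, np.random.default_rng(cfg.seed))
    theta = cv_rmse(X[:, current], y, folds, cfg.max_pls_factors)
    trace = []
    while len(current) > 1:
        theta_minus = np.array([
            cv_rmse(X[:, current[:j] + current[j + 1:]], y, folds, cfg.max_pls_factors)
            for j in range(len(current))
        ])
        j_best = int(np.argmin(theta_minus))  # first minimum = lowest index
        if theta_minus[j_best] > theta * (1 + 1e-9):
            break
        trace.append((current[j_best], float(theta_minus[j_best])))
        theta = float(theta_minus[j_best])
        del current[j_best]
    return current, float(theta), tuple(trace)


def run_iriv(ss: SpectrumSet, cfg: IrivConfig | None = None) -> IrivResult:
    """Run the full IRIV screen on a SpectrumSet with a target attached.

    Rounds of score → classify → retain {strong, weak} continue until a
    round produces no uninformative or interfering variables (or max_rounds
    is hit); the survivors then pass through backward elimination. The
    design matrix is redrawn each round from the run's seeded RNG stream; the
    fold partition is drawn once so all RMSECV values are comparable.
    """
    cfg = cfg or IrivConfig()
    if ss.target is None:
        raise IrivError("SpectrumSet must carry a target")
    if ss.n_samples < cfg.cv_folds:
        raise IrivError("fewer samples than cv folds")
    X, y, wl = ss.reflectance, ss.target, ss.wavelengths
    rng = np.random.default_rng(cfg.seed)
    folds = make_folds(ss.n_samples, cfg.cv_folds, rng)

    current = np.arange(ss.n_bands)
    rounds = []
    for _ in range(cfg.max_rounds):
        if len(current) < 2:
            break  # a single survivor cannot be contrasted against exclusion
        A = generate_design_matrix(len(current), cfg.n_rows, rng)
        dmean, pvals = score_variables(X[:, current], y, A, cfg, folds)
        classes = tuple(classify_variable(d, p, cfg.alpha) for d, p in zip(dmean, pvals))
        keep = np.array([c in (STRONG, WEAK) for c in classes])
        rounds.append(RoundResult(
            wavelengths=wl[current].copy(),
            dmean=dmean,
            pvalues=pvals,
            classes=classes,
            retained_wavelengths=wl[current[keep]].copy(),
        ))
        if not keep.any():
            raise IrivError("all variables eliminated", rounds=rounds)
        if keep.all():
            break
        current = current[keep]
    survivors, final_rmsecv, trace = backward_eliminate(X, y, list(current), cfg, folds)
    final = np.array(sorted(survivors), dtype=int)
    return IrivResult(
        rounds=tuple(rounds),
        final_wavelengths=wl[final].copy(),
        final_indices=final,
        final_rmsecv=final_rmsecv,
        eliminated_trace=trace,
    )
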