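"""Per-subject processing: thresholding of correlations and FD edge weights.

The FD ("functional-distance") model weights the edge between nodes i and j
by their degrees, their anatomical distance and their thresholded
correlation:

    w_ij = deg(i) * deg(j) * exp(-(eta * D_ij - Fs_ij)),      W = w / max(w)

where Fs is the subject's correlation matrix after zeroing negatives and
applying a histogram-based cut (the "neighbourhood of interest"), and D is
the normalized distance matrix.  Degrees are counted on the support of Fs,
so well-connected hubs are up-weighted even where individual correlations
are modest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Upper edge of the second bin of a 10-bin histogram on [0, 1]: the
#: operational first-threshold cut (entries strictly above it are kept).
DEFAULT_FIRST_CUT = 0.2


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram convention behind the first thresholding step.

    With ``support="unit_interval"`` (default) bin h covers
    [(h-1)/n_bins, h/n_bins]; the cut sits at the upper edge of bin 2.
    """

    n_bins: int = 10
    support: str = "unit_interval"

    @property
    def first_cut(self) -> float:
        if self.support != "unit_interval":
            raise ValueError("only unit_interval support defines a fixed cut")
        return 2.0 / self.n_bins


@dataclass
class ThresholdedCorrelation:
    """Non-negative correlation matrix retained above the first threshold."""

    values: np.ndarray
    noi_threshold: float
    retained_fraction: float


@dataclass
class FDWeightMatrix:
    """Normalized FD weights for one subject (max entry 1, or all-zero)."""

    W: np.ndarray
    wmax: float
    degrees: np.ndarray = field(default=None)


def _check_symmetric(F: np.ndarray, tol: float = 1e-8) -> None:
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {F.shape}")
    if not np.allclose(F, F.T, atol=tol):
        raise ValueError("correlation matrix is not symmetric within tolerance")


def clip_negatives(F: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Zero all negative correlations, leaving positives untouched."""
    _check_symmetric(F, tol)
    return np.where(F < 0, 0.0, F.astype(float))


def first_threshold(
    F: np.ndarray,
    hist: HistogramSpec | None = None,
    cut: float | None = None,
) -> ThresholdedCorrelation:
    """Keep off-diagonal entries strictly above the first-threshold cut.

    ``F`` must be non-negative with entries in [0, 1] (diagonal excluded
    from the check and zeroed in the output).  Records the cut used and the
    fraction of off-diagonal entries retained.
    """
    if cut is None:
        cut = (hist or HistogramSpec()).first_cut
    F = np.asarray(F, dtype=float)
    _check_symmetric(F)
    off = ~np.eye(F.shape[0], dtype=bool)
    vals = F[off]
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("entries outside [0, 1]; clip negatives first")
    Fs = np.where(F > cut, F, 0.0)
    np.fill_diagonal(Fs, 0.0)
    n_data = np.count_nonzero(F[off])  # the observed (nonzero) correlations
    retained = float(np.count_nonzero(Fs[off]) / n_data) if n_data else 0.0
    return ThresholdedCorrelation(Fs, float(cut), retained)


def node_degrees(Fs: ThresholdedCorrelation | np.ndarray) -> np.ndarray:
    """Degree of each node: nonzero off-diagonal entries in its row."""
    M = Fs.values if isinstance(Fs, ThresholdedCorrelation) else np.asarray(Fs)
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    return (M != 0).sum(axis=1).astype(int)


def fd_weights(
    Fs: ThresholdedCorrelation | np.ndarray,
    D: np.ndarray,
    eta: float = 1.0,
    mask_zero_correlation: bool = False,
) -> FDWeightMatrix:
    """FD weights from a thresholded correlation matrix and distances.

    All off-diagonal pairs are weighted (the formula imposes no mask);
    ``mask_zero_correlation=True`` restricts the output to the support of
    ``Fs``.  If every unnormalized weight is zero (all nodes isolated) the
    result is all-zero with ``wmax == 0``.
    """
    M = Fs.values if isinstance(Fs, ThresholdedCorrelation) else np.asarray(Fs)
    D = np.asarray(D, dtype=float)
    if M.shape != D.shape:
        raise ValueError(f"shape mismatch: correlations {M.shape}, distances {D.shape}")
    if eta <= 0:
        raise ValueError("eta must be positive")
    deg = node_degrees(M)
    w = np.outer(deg, deg) * np.exp(-(eta * D - M))
    np.fill_diagonal(w, 0.0)
    if mask_zero_correlation:
        w = np.where(M != 0, w, 0.0)
        np.fill_diagonal(w, 0.0)
    wmax = float(w.max())
    W = w / wmax if wmax > 0 else np.zeros_like(w)
    return FDWeightMatrix(W=W, wmax=wmax, degrees=deg)


def subject_weights(
    F: np.ndarray,
    D: np.ndarray,
    eta: float = 1.0,
    cut: float | None = None,
    mask_zero_correlation: bool = False,
) -> FDWeightMatrix:
    """Full per-subject chain: clip negatives, first threshold, FD weights."""
    Fs = first_threshold(clip_negatives(F), cut=cut)
    return fd_weights(Fs, D, eta=eta, mask_zero_correlation=mask_zero_correlation)
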