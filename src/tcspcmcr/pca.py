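"""Principal component analysis of autoscaled decay matrices.

The bilinear model is D = T P' + E with orthonormal loadings P and
scores T ordered by descending explained variance.  Score plots expose
clustering of sequences and pH values; a *local* model refits a row
subset (e.g. only the acidic pH range) after re-autoscaling it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import linalg

from .matrix import DecayMatrix, Preprocessing, RowMeta, autoscale, inverse_autoscale

__all__ = ["PCAModel", "fit_pca", "local_pca", "suggest_components"]


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA decomposition of a preprocessed decay matrix."""

    scores: np.ndarray              # (m, s)
    loadings: np.ndarray            # (s, n)
    explained_variance: np.ndarray  # per-component %, of total variance
    singular_values: np.ndarray     # all min(m, n) singular values
    residuals: np.ndarray           # E = D - T P'
    row_meta: tuple[RowMeta, ...]
    preprocessing_ref: Preprocessing

    @property
    def s(self) -> int:
        return self.loadings.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rank-s reconstruction T P' of the preprocessed matrix."""
        return self.scores @ self.loadings

    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.s + 1),
                "explained_variance_%": self.explained_variance,
                "cumulative_%": self.cumulative_variance(),
            }
        )

    def summary(self) -> str:
        return (
            f"PCA model: {self.scores.shape[0]} rows, {self.s} components, "
            f"{self.cumulative_variance()[-1]:.2f}% cumulative variance\n"
            + self.variance_table().to_string(index=False, float_format="%.3f")
        )

    def plot_scores(self, pc_x: int = 1, pc_y: int = 2, ax=None, color_by="ph"):
        """Score plot of two components, coloured by pH or sequence."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.scores[:, pc_x - 1]
        y = self.scores[:, pc_y - 1]
        if color_by == "ph":
            c = [m.ph for m in self.row_meta]
            sc = ax.scatter(x, y, c=c, cmap="viridis")
            plt.colorbar(sc, ax=ax, label="pH")
        else:
            for seq in sorted({m.sequence_id for m in self.row_meta}):
                idx = [i for i, m in enumerate(self.row_meta) if m.sequence_id == seq]
                ax.scatter(x[idx], y[idx], label=seq)
            ax.legend()
        ax.set_xlabel(f"PC{pc_x} ({self.explained_variance[pc_x - 1]:.1f}%)")
        ax.set_ylabel(f"PC{pc_y} ({self.explained_variance[pc_y - 1]:.1f}%)")
        return ax


def fit_pca(D: DecayMatrix, s: int) -> PCAModel:
    """Fit an s-component PCA model to an autoscaled matrix.

    Component signs follow a deterministic convention: the
    largest-magnitude loading element of each component is positive.
    """
    if not D.is_autoscaled:
        raise ValueError("fit_pca expects an autoscaled matrix; call autoscale(D) first")
    m, n = D.shape
    if not (1 <= s <= min(m, n)):
        raise ValueError(f"s must be in [1, {min(m, n)}], got {s}")
    U, sv, Vt = linalg.svd(D.values, full_matrices=False)
    # sign convention
    for k in range(sv.size):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    total = np.sum(sv**2)
    explained = 100.0 * sv[:s] ** 2 / total
    scores = U[:, :s] * sv[:s]
    return PCAModel(
        scores=scores,
        loadings=Vt[:s],
        explained_variance=explained,
        singular_values=sv,
        residuals=D.values - scores @ Vt[:s],
        row_meta=D.row_meta,
        preprocessing_ref=D.preprocessing,
    )


def local_pca(
    D: DecayMatrix, row_filter: Callable[[RowMeta], bool], s: int, ddof: int | None = None
) -> PCAModel:
    """PCA of a metadata-selected row subset, re-autoscaled before fitting.

    ``D`` may be raw or autoscaled; an autoscaled input is inverted first
    so the subset is scaled on its own statistics.
    """
    if D.is_autoscaled:
        if ddof is None:
            ddof = D.preprocessing.ddof
        D = inverse_autoscale(D)
    elif ddof is None:
        ddof = 1
    sub = D.select_rows(row_filter)
    if sub.shape[0] < 2:
        raise ValueError("row filter must retain at least 2 rows")
    return fit_pca(autoscale(sub, ddof=ddof), s)


def suggest_components(D: DecayMatrix, target_percent: float = 95.0) -> int:
    """Smallest component count reaching the cumulative-variance target."""
    full = fit_pca(D if D.is_autoscaled else autoscale(D), min(D.shape))
    cum = full.cumulative_variance()
    return int(np.searchsorted(cum, target_percent - 1e-9) + 1)
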