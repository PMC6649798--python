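"""EFA-initialized multivariate curve resolution by alternating least squares.

A single-sequence decay matrix D (rows = traces ordered by pH, columns =
time bins) is resolved into the bilinear model

    D = C S' + E,

where the p columns of C describe how much each conformer contributes to
each trace and the p rows of S' are the pure decay traces of the
conformers.  Both factors are constrained non-negative; the scale
ambiguity is fixed by normalising each pure trace to unit maximum.

The component count is estimated from the singular-value spectrum
(:func:`svd_rank`); initial concentration profiles come from evolving
factor analysis (:func:`efa`), which exploits the sequential character of
the conformational transitions along pH: one conformation decays as the
next emerges, with no reversals.  Because the wavelength replicates
within one pH share the same composition, EFA windows are computed over
pH blocks and replicated across the rows of a block.

Fit quality is reported as the percentage lack of fit,

    LOF = 100 * sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2),

and the explained variance R^2 = sum dhat_ij^2 / sum d_ij^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import nnls

from .matrix import DecayMatrix, RowMeta

__all__ = [
    "svd_rank",
    "EFAResult",
    "efa",
    "MCRALS",
    "MCRResults",
    "mcr_als",
    "lack_of_fit",
    "explained_r2",
]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _as_array_pair(D, d_hat):
    d = D.values if isinstance(D, DecayMatrix) else np.asarray(D, dtype=float)
    dh = np.asarray(d_hat, dtype=float)
    if d.shape != dh.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {dh.shape}")
    if not np.any(d != 0):
        raise ValueError("all-zero data matrix")
    return d, dh


def lack_of_fit(D, d_hat) -> float:
    """Percentage lack of fit of a reconstruction."""
    d, dh = _as_array_pair(D, d_hat)
    return float(100.0 * np.sqrt(np.sum((d - dh) ** 2) / np.sum(d**2)))


def explained_r2(D, d_hat) -> float:
    """Explained variance: ratio of summed squared reconstruction to data."""
    d, dh = _as_array_pair(D, d_hat)
    return float(np.sum(dh**2) / np.sum(d**2))


# ---------------------------------------------------------------------------
# rank estimation
# ---------------------------------------------------------------------------

def svd_rank(
    D,
    ratio_threshold: float = 1e-3,
) -> tuple[int, np.ndarray, dict]:
    """Estimate the chemical rank of D from its singular values.

    Two strategies are computed and reported: the ratio rule (count of
    singular values above ``ratio_threshold`` of the largest; suited to
    noiseless data) and a knee heuristic for noisy data (largest drop in
    log singular value).  The returned count is the ratio rule for
    effectively noiseless spectra and the knee rule otherwise.

    Returns
    -------
    (rank, singular_values, details)
    """
    d = D.values if isinstance(D, DecayMatrix) else np.asarray(D, dtype=float)
    if min(d.shape) < 2:
        raise ValueError("need at least a 2x2 matrix")
    sv = linalg.svdvals(d)
    ratio_rank = int(np.sum(sv > ratio_threshold * sv[0]))
    # knee: largest log-spectrum gap among the leading values
    k = min(sv.size, 10)
    logsv = np.log10(np.maximum(sv[:k], np.finfo(float).tiny))
    gaps = logsv[:-1] - logsv[1:]
    knee_rank = int(np.argmax(gaps) + 1)
    noiseless = ratio_rank < sv.size and sv[min(ratio_rank, sv.size - 1)] < 1e-8 * sv[0]
    rank = ratio_rank if noiseless else knee_rank
    return rank, sv, {
        "ratio_rank": ratio_rank,
        "knee_rank": knee_rank,
        "noiseless": bool(noiseless),
    }


# ---------------------------------------------------------------------------
# evolving factor analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EFAResult:
    """Forward/backward EFA singular-value profiles and the derived C init.

    Profiles are per pH block (the process axis); ``c_init`` replicates
    the block values across the wavelength rows of each block.
    """

    forward_sv: np.ndarray      # (n_blocks, p)
    backward_sv: np.ndarray     # (n_blocks, p)
    rank_estimate: int
    c_init: np.ndarray          # (m, p), >= 0
    block_ph: np.ndarray


def _ph_blocks(row_meta: tuple[RowMeta, ...]) -> tuple[np.ndarray, list[np.ndarray]]:
    ph = np.array([m.ph for m in row_meta])
    uniq = np.unique(ph)
    return uniq, [np.nonzero(ph == u)[0] for u in uniq]


def efa(D: DecayMatrix, p: int, noise_floor_factor: float = 3.0) -> EFAResult:
    """Evolving factor analysis along the pH axis.

    Forward profiles are the leading ``p`` singular values of the
    submatrices formed by the first k pH blocks (k = 1..B); backward
    profiles analogously from the last blocks.  The initial concentration
    estimate for component j is the classical sequential-window
    construction ``min(forward_j, backward_{p-j+1})`` floored at zero,
    with singular values below ``noise_floor_factor`` times the median
    trailing (noise) singular value of the full matrix treated as absent
    (the factor sits a little above the Poisson noise plateau so that
    weak, nearly collinear components are still detected).  If flooring
    empties a component's window entirely, the unfloored profile is kept
    instead.  Components are ordered by emergence, most acidic first.
    """
    block_ph, blocks = _ph_blocks(D.row_meta)
    B = len(blocks)
    if p > D.shape[0]:
        raise ValueError(f"p={p} exceeds the number of rows {D.shape[0]}")
    if p < 1:
        raise ValueError("p must be >= 1")

    full_sv = linalg.svdvals(D.values)
    trailing = full_sv[p:]
    noise_floor = noise_floor_factor * np.median(trailing) if trailing.size else 0.0

    def profiles(order: range) -> np.ndarray:
        out = np.zeros((B, p))
        rows: list[int] = []
        for pos, b in enumerate(order):
            rows.extend(blocks[b])
            sv = linalg.svdvals(D.values[np.array(rows)])
            out[b, : min(p, sv.size)] = sv[:p]
        return out

    fwd = profiles(range(B))
    bwd = profiles(range(B - 1, -1, -1))
    fwd_clean = np.where(fwd > noise_floor, fwd, 0.0)
    bwd_clean = np.where(bwd > noise_floor, bwd, 0.0)

    c_blocks = np.minimum(fwd_clean, bwd_clean[:, ::-1])
    c_blocks = np.maximum(c_blocks, 0.0)
    raw_blocks = np.maximum(np.minimum(fwd, bwd[:, ::-1]), 0.0)
    # guard: if the floor removed a component entirely, keep its raw profile
    for j in range(p):
        if not np.any(c_blocks[:, j] > 0):
            c_blocks[:, j] = raw_blocks[:, j]

    c_init = np.zeros((D.shape[0], p))
    for b, idx in enumerate(blocks):
        c_init[idx] = c_blocks[b]
    return EFAResult(
        forward_sv=fwd,
        backward_sv=bwd,
        rank_estimate=int(np.sum(full_sv[:p] > noise_floor)),
        c_init=c_init,
        block_ph=block_ph,
    )


# ---------------------------------------------------------------------------
# alternating least squares
# ---------------------------------------------------------------------------

@dataclass
class MCRResults:
    """Resolved concentration profiles, pure traces and diagnostics."""

    C: np.ndarray               # (m, p)
    S: np.ndarray               # (p, n) pure traces, unit maximum each
    lof: float                  # %
    r2: float
    iterations: int
    converged: bool
    lof_history: list[float]
    row_meta: tuple[RowMeta, ...]
    axis: object = None

    @property
    def d_hat(self) -> np.ndarray:
        return self.C @ self.S

    @property
    def n_components(self) -> int:
        return self.S.shape[0]

    def dominant_ph(self) -> np.ndarray:
        """pH at which each component's mean concentration peaks."""
        ph = np.array([m.ph for m in self.row_meta])
        uniq = np.unique(ph)
        means = np.array(
            [[self.C[ph == u, j].mean() for u in uniq] for j in range(self.n_components)]
        )
        return uniq[np.argmax(means, axis=1)]

    def concentration_table(self) -> pd.DataFrame:
        rows = []
        for meta, c in zip(self.row_meta, self.C):
            row = {"sequence_id": meta.sequence_id, "ph": meta.ph,
                   "wavelength": meta.wavelength}
            row.update({f"C{j + 1}": c[j] for j in range(self.n_components)})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        dom = self.dominant_ph()
        lines = [
            f"MCR-ALS: {self.n_components} components, "
            f"LOF = {self.lof:.3f}%, R2 = {self.r2:.6f}",
            f"iterations: {self.iterations}   converged: {self.converged}",
            "component dominance (pH at max mean concentration): "
            + ", ".join(f"C{j + 1}@pH{ph:g}" for j, ph in enumerate(dom)),
        ]
        return "\n".join(lines)

    def plot(self, axs=None):
        """Concentration profiles vs pH and pure traces vs time."""
        import matplotlib.pyplot as plt

        if axs is None:
            _, axs = plt.subplots(1, 2, figsize=(9, 3.5))
        ph = np.array([m.ph for m in self.row_meta])
        for j in range(self.n_components):
            axs[0].plot(ph, self.C[:, j], "o", ms=3, label=f"C{j + 1}")
            if self.axis is not None:
                axs[1].semilogy(self.axis.centers,
                                np.maximum(self.S[j], 1e-6), label=f"S{j + 1}")
        axs[0].set_xlabel("pH")
        axs[0].set_ylabel("relative contribution")
        axs[0].legend()
        axs[1].set_xlabel("time (ns)")
        axs[1].set_ylabel("normalised intensity")
        return axs


class MCRALS:
    """Alternating-least-squares curve resolution under non-negativity.

    Parameters
    ----------
    D : DecayMatrix
        Raw (non-negative) single-sequence decay matrix, rows ordered by pH.
    n_components : int, optional
        Number of conformers p; estimated by :func:`svd_rank` if omitted.
    c_init : ndarray, optional
        Initial (m, p) concentration estimate; EFA by default.
    tol : float
        Convergence threshold on |delta LOF| in percentage points.  The
        default (1e-4) is deliberately tight: with nearly collinear pure
        traces the ALS drift per iteration is tiny long before the
        factors settle, and a loose threshold stops the rotation early.
    max_iter : int
        Iteration cap.
    """

    def __init__(
        self,
        D: DecayMatrix,
        n_components: int | None = None,
        c_init: np.ndarray | None = None,
        tol: float = 1e-4,
        max_iter: int = 500,
    ) -> None:
        if D.is_autoscaled:
            raise ValueError("MCR-ALS operates on raw counts, not autoscaled data")
        if np.any(D.values < 0):
            raise ValueError("D must be non-negative")
        self.D = D
        if n_components is None:
            n_components, _, _ = svd_rank(D)
        self.p = int(n_components)
        if c_init is None:
            c_init = efa(D, self.p).c_init
        c_init = np.asarray(c_init, dtype=float)
        if c_init.shape != (D.shape[0], self.p):
            raise ValueError(
                f"c_init must have shape {(D.shape[0], self.p)}, got {c_init.shape}"
            )
        if np.any(c_init < 0):
            raise ValueError("c_init must be non-negative")
        self.c_init = c_init
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Solve min ||A X - B||_F with X >= 0, column-block by column."""
        X = np.empty((A.shape[1], B.shape[1]))
        for j in range(B.shape[1]):
            X[:, j], _ = nnls(A, B[:, j])
        return X

    def fit(self) -> MCRResults:
        d = self.D.values
        C = self.c_init.copy()
        history: list[float] = []
        converged = False
        it = 0
        S = np.zeros((self.p, d.shape[1]))
        for it in range(1, self.max_iter + 1):
            # (1) pure traces given concentrations
            S = self._nnls_rows(C, d)
            # drop empty components
            alive = S.max(axis=1) > 0
            if not np.all(alive):
                warnings.warn(
                    f"dropping {np.sum(~alive)} empty MCR component(s)",
                    RuntimeWarning, stacklevel=2,
                )
                S = S[alive]
                C = C[:, alive]
                self.p = S.shape[0]
            # scale ambiguity: unit-maximum pure traces (scale goes into C)
            S = S / S.max(axis=1, keepdims=True)
            # (2) concentrations given pure traces
            C = self._nnls_rows(S.T, d.T).T
            lof = lack_of_fit(d, C @ S)
            if history and abs(history[-1] - lof) < self.tol:
                history.append(lof)
                converged = True
                break
            history.append(lof)

        # order components: most acidic dominance first
        ph = np.array([m.ph for m in self.D.row_meta])
        uniq = np.unique(ph)
        mean_c = np.array(
            [[C[ph == u, j].mean() for u in uniq] for j in range(self.p)]
        )
        dom = uniq[np.argmax(mean_c, axis=1)]
        order = np.argsort(dom, kind="stable")
        C, S = C[:, order], S[order]

        d_hat = C @ S
        return MCRResults(
            C=C,
            S=S,
            lof=lack_of_fit(d, d_hat),
            r2=explained_r2(d, d_hat),
            iterations=it,
            converged=converged,
            lof_history=history,
            row_meta=self.D.row_meta,
            axis=self.D.axis,
        )


def mcr_als(
    D: DecayMatrix,
    c_init: np.ndarray | None = None,
    n_components: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> MCRResults:
    """Functional wrapper around :class:`MCRALS`."""
    if c_init is not None and n_components is None:
        n_components = c_init.shape[1]
    return MCRALS(D, n_components=n_components, c_init=c_init, tol=tol,
                  max_iter=max_iter).fit()
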