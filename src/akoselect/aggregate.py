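"""Knockoff-adjusted scores, intermediate p-values, aggregation and BH selection.

Given importance scores for each original metabolite and its knockoff, the
knockoff-adjusted score is

    W_j = |Z_orig_j| - |Z_knockoff_j|,

large positive values indicating genuine association.  Each knockoff draw's
W vector is converted to empirical intermediate p-values

    pi_j = (1 + #{k : W_k <= -W_j}) / p   if W_j > 0,   else 1,

which reference every feature's negative scores as the empirical null.  The
B draws are combined per feature by gamma-quantile aggregation,

    pibar_j = min(1, q_gamma({pi_j^(1..B)}) / gamma),

(at gamma = 0.5: twice the median, capped at one), and the aggregated
p-values enter the Benjamini-Hochberg step-up procedure at level alpha.

Note an intrinsic granularity: pi_j is at least 1/p, so pibar_j is at least
1/(p * gamma), and BH at level alpha can therefore only ever reject
ceil(1 / (gamma * alpha)) or more features at once — or none at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "knockoff_statistic",
    "intermediate_pvalues",
    "quantile_aggregate",
    "bh_select",
    "SelectionResult",
]


def knockoff_statistic(z_original: np.ndarray, z_knockoff: np.ndarray) -> np.ndarray:
    """W_j = |Z_orig_j| - |Z_knockoff_j| for each original/knockoff pair."""
    z_original = np.asarray(z_original, dtype=float)
    z_knockoff = np.asarray(z_knockoff, dtype=float)
    if z_original.shape != z_knockoff.shape:
        raise ValueError("original and knockoff score vectors differ in length")
    W = np.abs(z_original) - np.abs(z_knockoff)
    if not np.all(np.isfinite(W)):
        raise ValueError("knockoff-adjusted scores must be finite")
    return W


def intermediate_pvalues(W: np.ndarray) -> np.ndarray:
    """Empirical p-values from one draw's knockoff-adjusted scores.

    ``pi_j = (1 + #{k : W_k <= -W_j}) / p`` when ``W_j > 0``; features with
    ``W_j <= 0`` carry no evidence and receive ``pi_j = 1``.  The count is
    over all features including ``j`` itself and uses a closed inequality, so
    ties ``W_k = -W_j`` are counted.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 1 or W.size == 0:
        raise ValueError("W must be a non-empty 1-D vector")
    p = W.size
    sorted_W = np.sort(W)
    counts = np.searchsorted(sorted_W, -W, side="right")
    pi = (1.0 + counts) / p
    return np.where(W > 0, np.minimum(pi, 1.0), 1.0)


def quantile_aggregate(pi_b: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """gamma-quantile aggregation of a B x p matrix of intermediate p-values.

    Uses the lower empirical quantile (order statistic at rank
    ``ceil(gamma * B)``), the deterministic, conservative convention; with
    ``gamma = 0.5`` the result is ``min(1, 2 * median)`` for odd B.
    """
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    pi_b = np.atleast_2d(np.asarray(pi_b, dtype=float))
    B = pi_b.shape[0]
    rank = max(int(np.ceil(gamma * B)), 1)  # 1-based order statistic
    q = np.sort(pi_b, axis=0)[rank - 1]
    return np.minimum(1.0, q / gamma)


def bh_select(
    pi_bar: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up selection.

    Returns the boolean rejection mask and the data-driven threshold
    ``pibar_(k*)`` (0.0 when nothing is rejected), where ``k*`` is the
    largest ``k`` with ``pibar_(k) <= k * alpha / m``.  Ties at the threshold
    are all selected.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pi_bar = np.asarray(pi_bar, dtype=float)
    m = pi_bar.size
    if m == 0:
        raise ValueError("pi_bar must be non-empty")
    order = np.sort(pi_bar)
    ks = np.nonzero(order <= alpha * np.arange(1, m + 1) / m)[0]
    if ks.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(order[ks[-1]])
    return pi_bar <= threshold, threshold


@dataclass
class SelectionResult:
    """Outcome of one aggregated-knockoff selection run."""

    selected: list[str]
    alpha: float
    bh_threshold: float
    pi_bar: pd.Series = field(repr=False)
    W_mean: pd.Series = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        """Ranked table: metabolite, mean W over draws, pi_bar, selected flag."""
        df = pd.DataFrame(
            {
                "metabolite": self.pi_bar.index,
                "W_mean": self.W_mean.to_numpy(),
                "pi_bar": self.pi_bar.to_numpy(),
                "selected": self.pi_bar.index.isin(self.selected),
            }
        )
        return df.sort_values(
            ["pi_bar", "W_mean"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected": list(self.selected),
            "alpha": self.alpha,
            "bh_threshold": self.bh_threshold,
            "pi_bar": {str(k): float(v) for k, v in self.pi_bar.items()},
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)
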