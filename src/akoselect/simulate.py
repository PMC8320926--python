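"""Synthetic LC-MS-style feature tables with known ground truth.

Generates samples-by-metabolites intensity tables that mimic the structure of
untargeted metabolomics data: correlated features, positive (log-normal)
intensities, per-metabolite missingness that can depend on the underlying
intensity (left censoring), and a known subset of metabolites whose mean
differs between sample classes.  Ground truth is recorded so that downstream
selection procedures can be scored for false discovery proportion and power.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri  # inverse standard normal CDF

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "write_dataset",
    "read_ground_truth",
]

# logistic(u) ~ Phi(u / 1.702); used to calibrate intensity-dependent missingness
_LOGIT_PROBIT_SCALE = 1.702


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic metabolomics generator.

    Defaults emulate a cohort of the size and shape typical of a multi-mode
    untargeted metabolomics study of a chronic disease: ~546 stool samples,
    100-200 annotated metabolites per chromatography mode, three diagnostic
    groups, moderately correlated features, and a sizeable minority of
    metabolites genuinely associated with the group label.

    Parameters
    ----------
    n_samples : int
        Number of samples (rows).
    n_metabolites : int
        Number of metabolite features (columns).
    n_classes : int
        Number of diagnostic groups (>= 2); class sizes are equal, with any
        remainder assigned to class 0.
    n_signal : int
        Number of metabolites truly associated with the class label.
    effect_size : float
        Mean shift between consecutive classes for signal metabolites, in
        within-class SD units of the latent Gaussian scale.  Class ``c`` has
        latent mean ``c * effect_size`` at signal metabolites.
    correlation : str
        One of ``"independent"``, ``"ar1"`` or ``"block"``.
    rho : float
        Correlation parameter for ``ar1`` / ``block`` structures, ``|rho| < 1``.
    block_size : int
        Block width for the ``block`` structure (equicorrelated within block).
    missing_rate : float
        Expected fraction of missing entries per metabolite, in ``[0, 1)``.
    missing_mechanism : str
        ``"mcar"`` (uniform Bernoulli) or ``"intensity"`` (probability of
        missingness decreases with the latent intensity through a logistic
        link, mimicking left censoring at the detection limit).
    censor_steepness : float
        Slope of the logistic link for intensity-dependent missingness.
    intensity_scale : str
        ``"gaussian"`` keeps the latent values; ``"lognormal"`` reports
        ``exp(latent)`` to mimic positive MS peak intensities.
    seed : int or None
        RNG seed; the same seed reproduces the dataset bit for bit.
    """

    n_samples: int = 546
    n_metabolites: int = 150
    n_classes: int = 3
    n_signal: int = 45
    effect_size: float = 1.0
    correlation: str = "ar1"
    rho: float = 0.5
    block_size: int = 10
    missing_rate: float = 0.2
    missing_mechanism: str = "intensity"
    censor_steepness: float = 2.0
    intensity_scale: str = "lognormal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if not 0 <= self.n_signal <= self.n_metabolites:
            raise ValueError("n_signal must lie in [0, n_metabolites]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.correlation not in ("independent", "ar1", "block"):
            raise ValueError(f"unknown correlation structure {self.correlation!r}")
        if self.correlation != "independent" and not abs(self.rho) < 1:
            raise ValueError("rho must satisfy |rho| < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("mcar", "intensity"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        if self.intensity_scale not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown intensity_scale {self.intensity_scale!r}")
        if self.correlation == "block" and self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Which metabolites are truly class-associated, and the class means."""

    signal_indices: tuple[int, ...]
    signal_names: tuple[str, ...]
    class_means: np.ndarray = field(repr=False)  # n_classes x n_metabolites

    def to_dict(self) -> dict:
        return {
            "signal_indices": list(self.signal_indices),
            "signal_names": list(self.signal_names),
            "class_means": np.asarray(self.class_means).tolist(),
        }


def correlation_matrix(config: SimulationConfig) -> np.ndarray:
    """Latent correlation matrix implied by the config.

    Raises ``ValueError`` naming the offending parameter when the requested
    structure is not positive definite.
    """
    p = config.n_metabolites
    if config.correlation == "independent":
        return np.eye(p)
    if config.correlation == "ar1":
        idx = np.arange(p)
        return config.rho ** np.abs(np.subtract.outer(idx, idx))
    # block-equicorrelated; PD requires rho > -1/(block_size-1)
    size = min(config.block_size, p)
    if size > 1 and config.rho <= -1.0 / (size - 1):
        raise ValueError(
            f"block correlation with rho={config.rho} and block_size={size} "
            "is not positive definite (rho must exceed -1/(block_size-1))"
        )
    sigma = np.eye(p)
    for start in range(0, p, size):
        stop = min(start + size, p)
        sigma[start:stop, start:stop] = config.rho
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _class_assignment(n_samples: int, n_classes: int) -> np.ndarray:
    """Equal class sizes; the remainder goes to class 0."""
    base = n_samples // n_classes
    sizes = np.full(n_classes, base)
    sizes[0] += n_samples - base * n_classes
    return np.repeat(np.arange(n_classes), sizes)


def _censor_offset(mean: np.ndarray, rate: float, steepness: float) -> np.ndarray:
    """Offset z0 so that E[logistic(-s*(Z - z0))] ~ rate for Z ~ N(mean, 1).

    Uses the probit approximation of the logistic CDF; the realised missing
    fraction therefore matches ``rate`` approximately, not exactly.
    """
    b = steepness / _LOGIT_PROBIT_SCALE
    return mean + ndtri(rate) * np.sqrt(1.0 + b * b) / b


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw one synthetic feature table.

    Returns
    -------
    table : pandas.DataFrame
        ``n_samples x n_metabolites`` intensities with ``NaN`` for missing
        entries; index are sample ids, columns metabolite names.
    labels : pandas.Series
        Integer class labels in ``{0, ..., n_classes-1}`` aligned to the table.
    truth : GroundTruth
        Indices/names of the truly associated metabolites and the per-class
        latent mean vectors.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_samples, config.n_metabolites, config.n_classes

    sigma = correlation_matrix(config)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError(
            f"correlation structure {config.correlation!r} with rho={config.rho} "
            "is not positive definite"
        ) from exc

    # seeded shuffle decouples signal placement from the correlation blocks
    signal_idx = np.sort(rng.permutation(p)[: config.n_signal])
    y = _class_assignment(n, k)

    class_means = np.zeros((k, p))
    for c in range(k):
        class_means[c, signal_idx] = c * config.effect_size

    latent = rng.standard_normal((n, p)) @ chol.T + class_means[y]

    if config.intensity_scale == "lognormal":
        values = np.exp(latent)
    else:
        values = latent.copy()

    if config.missing_rate > 0:
        if config.missing_mechanism == "mcar":
            mask_missing = rng.random((n, p)) < config.missing_rate
        else:
            z0 = _censor_offset(
                class_means[y], config.missing_rate, config.censor_steepness
            )
            prob = 1.0 / (1.0 + np.exp(config.censor_steepness * (latent - z0)))
            mask_missing = rng.random((n, p)) < prob
        values = np.where(mask_missing, np.nan, values)

    names = [f"M{j + 1:04d}" for j in range(p)]
    ids = [f"S{i + 1:04d}" for i in range(n)]
    table = pd.DataFrame(values, index=ids, columns=names)
    labels = pd.Series(y, index=ids, name="class")
    truth = GroundTruth(
        signal_indices=tuple(int(j) for j in signal_idx),
        signal_names=tuple(names[j] for j in signal_idx),
        class_means=class_means,
    )
    return table, labels, truth


def write_dataset(
    table: pd.DataFrame,
    labels: pd.Series,
    truth: GroundTruth,
    config: SimulationConfig,
    csv_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write the table (+ class column) as CSV and ground truth as JSON.

    The CSV is in the orientation and missing-value convention that
    :func:`akoselect.io.read_feature_table` reads back (samples as rows,
    blank cells for missing entries).
    """
    csv_path = Path(csv_path)
    out = table.copy()
    out.insert(0, "class", labels.to_numpy())
    out.to_csv(csv_path, index_label="sample_id", float_format="%.17g")
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".truth.json")
    payload = {
        "config": dataclasses.asdict(config),
        "ground_truth": truth.to_dict(),
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(sidecar_path: str | Path) -> tuple[SimulationConfig, GroundTruth]:
    """Read back the JSON sidecar written by :func:`write_dataset`."""
    payload = json.loads(Path(sidecar_path).read_text())
    config = SimulationConfig(**payload["config"])
    gt = payload["ground_truth"]
    truth = GroundTruth(
        signal_indices=tuple(gt["signal_indices"]),
        signal_names=tuple(gt["signal_names"]),
        class_means=np.asarray(gt["class_means"]),
    )
    return config, truth


def false_discovery_proportion(
    selected: Sequence[str], truth: GroundTruth
) -> float:
    """|selected \\ signal| / max(1, |selected|)."""
    sel = set(selected)
    return len(sel - set(truth.signal_names)) / max(1, len(sel))


def power(selected: Sequence[str], truth: GroundTruth) -> float:
    """|selected ∩ signal| / n_signal; 0 by convention when n_signal = 0."""
    sig = set(truth.signal_names)
    if not sig:
        return 0.0
    return len(set(selected) & sig) / len(sig)
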