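"""End-to-end aggregated-knockoff selection pipeline.

The full workflow for one missingness threshold ``t`` is::

    t% filter -> KNN imputation (skipped at t = 100) -> standardization
    -> Gaussian knockoff model -> B knockoff draws
    -> per-draw RF OOB importance on [X, X~] -> W -> intermediate p-values
    -> gamma-quantile aggregation -> Benjamini-Hochberg selection

:class:`AggregatedKnockoffFilter` packages the inference part (everything
after standardization) as a scikit-learn feature selector, so it composes
with :class:`sklearn.pipeline.Pipeline`; :func:`run_pipeline`,
:func:`sweep_thresholds` and :func:`evaluate_fdr_power` orchestrate whole
analyses on feature tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .aggregate import (
    SelectionResult,
    bh_select,
    intermediate_pvalues,
    knockoff_statistic,
    quantile_aggregate,
)
from .importance import OOBImportanceForest, augment
from .knockoffs import GaussianKnockoffs
from .preprocess import PreprocessReport, knn_impute, standardize, t_percent_filter
from .simulate import (
    SimulationConfig,
    false_discovery_proportion,
    generate_dataset,
    power,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AggregatedKnockoffFilter",
    "PipelineConfig",
    "SweepResult",
    "run_pipeline",
    "sweep_thresholds",
    "evaluate_fdr_power",
]


class AggregatedKnockoffFilter(SelectorMixin, BaseEstimator):
    """Aggregated model-X knockoff feature selector with FDR control.

    Fits a Gaussian knockoff model to a complete (ideally standardized)
    feature matrix, draws ``n_draws`` independent knockoff copies, scores
    every original/knockoff pair with random-forest OOB permutation
    importance on the augmented matrix, converts each draw's adjusted scores
    to intermediate p-values, aggregates them at the ``gamma`` quantile, and
    selects features by Benjamini-Hochberg at level ``alpha``.

    Parameters
    ----------
    n_draws : int
        Number of independent knockoff copies B (default 15).
    gamma : float
        Quantile level of the p-value aggregation (default 0.5).
    alpha : float
        Target false discovery rate of the BH step (default 0.05).
    n_trees : int
        Trees per random forest (default 1000).
    mtry : int or None
        Features tried per split; None uses ``round(sqrt(2p))``.
    shrinkage : "lw", float or None
        Covariance shrinkage passed to :class:`GaussianKnockoffs`.
    pair_swap : bool
        Randomly swap each original/knockoff column pair before fitting the
        forest (recorded and undone when pairing scores); True by default.
    class_weight : None or "balanced"
        Forest class weighting.
    random_state : int or None
        Master seed for knockoff draws, pair swaps and forests.

    Attributes
    ----------
    knockoff_model_ : GaussianKnockoffs
        The fitted Gaussian working model (mu, Sigma, s).
    W_ : ndarray of shape (n_draws, p)
        Knockoff-adjusted scores per draw.
    pi_ : ndarray of shape (n_draws, p)
        Intermediate p-values per draw.
    pi_bar_ : ndarray of shape (p,)
        Aggregated p-values.
    bh_threshold_ : float
        Data-driven BH cutoff (0.0 if nothing selected).
    support_ : ndarray of bool, shape (p,)
        Selected-feature mask (also via ``get_support()``).
    """

    def __init__(
        self,
        n_draws: int = 15,
        gamma: float = 0.5,
        alpha: float = 0.05,
        n_trees: int = 1000,
        mtry: int | None = None,
        shrinkage: str | float | None = "lw",
        pair_swap: bool = True,
        class_weight: str | None = None,
        random_state: int | None = None,
    ):
        self.n_draws = n_draws
        self.gamma = gamma
        self.alpha = alpha
        self.n_trees = n_trees
        self.mtry = mtry
        self.shrinkage = shrinkage
        self.pair_swap = pair_swap
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        X_arr = np.asarray(X, dtype=float)
        if np.isnan(X_arr).any():
            raise ValueError("X contains missing values; impute and standardize first")
        y = np.asarray(y)
        n, p = X_arr.shape

        self.feature_names_in_ = (
            np.asarray(X.columns, dtype=object)
            if isinstance(X, pd.DataFrame)
            else np.asarray([f"x{j}" for j in range(p)], dtype=object)
        )

        model = GaussianKnockoffs(shrinkage=self.shrinkage).fit(X_arr)
        draws = model.sample(X_arr, B=self.n_draws, random_state=self.random_state)

        root = np.random.SeedSequence(
            self.random_state if self.random_state is not None else None,
            spawn_key=(1,),
        )
        run_seeds = root.spawn(self.n_draws)

        W = np.empty((self.n_draws, p))
        pi = np.empty((self.n_draws, p))
        for b, (Xk, child) in enumerate(zip(draws.copies, run_seeds)):
            swap_seq, forest_seq = child.spawn(2)
            design = augment(
                X_arr, Xk, swap=self.pair_swap, random_state=swap_seq
            )
            forest = OOBImportanceForest(
                n_trees=self.n_trees,
                mtry=self.mtry,
                class_weight=self.class_weight,
                random_state=forest_seq,
            ).fit(design.matrix, y)
            z_orig, z_ko = design.split_scores(forest.importances_)
            W[b] = knockoff_statistic(z_orig, z_ko)
            pi[b] = intermediate_pvalues(W[b])
            logger.debug("draw %d/%d: max W = %.4g", b + 1, self.n_draws, W[b].max())

        pi_bar = quantile_aggregate(pi, gamma=self.gamma)
        support, threshold = bh_select(pi_bar, alpha=self.alpha)

        self.knockoff_model_ = model
        self.knockoff_seeds_ = draws.seeds
        self.W_ = W
        self.pi_ = pi
        self.pi_bar_ = pi_bar
        self.bh_threshold_ = threshold
        self.support_ = support
        self.n_features_in_ = p
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def selection_result(self, provenance: dict | None = None) -> SelectionResult:
        """Package the fitted state as a :class:`SelectionResult`."""
        check_is_fitted(self, "support_")
        names = pd.Index(self.feature_names_in_)
        return SelectionResult(
            selected=list(names[self.support_]),
            alpha=self.alpha,
            bh_threshold=self.bh_threshold_,
            pi_bar=pd.Series(self.pi_bar_, index=names),
            W_mean=pd.Series(self.W_.mean(axis=0), index=names),
            provenance=dict(provenance or {}),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the full workflow; defaults are the study settings
    (B = 15 draws, gamma = 0.5, alpha = 0.05, 1000 trees, mtry = sqrt(2p),
    thresholds T = {0, 60, 70, 80, 100})."""

    t_values: tuple[float, ...] = (0, 60, 70, 80, 100)
    n_draws: int = 15
    gamma: float = 0.5
    alpha: float = 0.05
    knn_k: int = 10
    n_trees: int = 1000
    mtry: int | None = None
    shrinkage: str | float | None = "lw"
    pair_swap: bool = True
    class_weight: str | None = None
    seed: int | None = None
    share_randomness: bool = False


@dataclass
class SweepResult:
    """Selections across the threshold sweep, plus their set algebra."""

    per_t: dict[float, SelectionResult]
    union: set[str]
    intersection: set[str]
    pairwise_overlap: pd.DataFrame = field(repr=False)

    def counts(self) -> pd.Series:
        """Number of selected metabolites per threshold."""
        return pd.Series(
            {t: r.n_selected for t, r in self.per_t.items()}, name="n_selected"
        )


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            self.start = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - self.start)
            return False

    return _StageContext()


def run_pipeline(
    table: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig = PipelineConfig(),
    t: float = 0.0,
) -> SelectionResult:
    """Run the full workflow at one missingness threshold ``t``.

    ``table`` holds intensities with NaN for missing entries; ``labels`` the
    integer class per sample.  The per-``t`` random stream is derived from
    ``config.seed`` with ``t`` mixed in (unless ``share_randomness``), so
    selections at different thresholds do not share knockoff noise.
    """
    if len(labels) != len(table):
        raise ValueError("labels length does not match the table")

    with _stage(f"t%-filter(t={t})"):
        filtered, report = t_percent_filter(table, t)
        logger.info(
            "t=%s kept %d / %d metabolites",
            t,
            len(report.kept_metabolites),
            table.shape[1],
        )

    with _stage("impute"):
        if t >= 100:
            imputed = filtered  # complete by construction; no imputation needed
        else:
            all_missing = filtered.columns[filtered.isna().all(axis=0)]
            if len(all_missing) > 0:
                logger.warning(
                    "dropping %d metabolite(s) with no observed values: %s",
                    len(all_missing),
                    list(all_missing[:5]),
                )
                filtered = filtered.drop(columns=all_missing)
                report.dropped_metabolites.extend(all_missing)
                report.kept_metabolites = list(filtered.columns)
            imputed = knn_impute(filtered, k=config.knn_k)
            report.imputation_k = config.knn_k if filtered.isna().to_numpy().any() else None

    with _stage("standardize"):
        X, (means, sds) = standardize(imputed)
        report.standardization = {
            "mean": means.to_dict(),
            "sd": sds.to_dict(),
        }

    if config.seed is None:
        run_seed = None
    elif config.share_randomness:
        run_seed = config.seed
    else:
        # mix t into the stream so thresholds use independent knockoff noise
        run_seed = int(
            np.random.SeedSequence(config.seed, spawn_key=(int(round(t)),))
            .generate_state(1, dtype=np.uint32)[0]
            % (2**31)
        )

    with _stage("aggregated-knockoff-filter"):
        selector = AggregatedKnockoffFilter(
            n_draws=config.n_draws,
            gamma=config.gamma,
            alpha=config.alpha,
            n_trees=config.n_trees,
            mtry=config.mtry,
            shrinkage=config.shrinkage,
            pair_swap=config.pair_swap,
            class_weight=config.class_weight,
            random_state=run_seed,
        ).fit(X, labels.to_numpy())

    provenance = {
        "t": t,
        "B": config.n_draws,
        "gamma": config.gamma,
        "alpha": config.alpha,
        "n_trees": config.n_trees,
        "knn_k": report.imputation_k,
        "seed": config.seed,
        "n_samples": int(X.shape[0]),
        "n_metabolites": int(X.shape[1]),
        "dropped_metabolites": report.dropped_metabolites,
    }
    return selector.selection_result(provenance)


def sweep_thresholds(
    table: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig = PipelineConfig(),
) -> SweepResult:
    """Run the pipeline at every threshold in ``config.t_values``.

    Each threshold re-filters, re-imputes and re-standardizes the raw table,
    then reports per-threshold selections together with their union,
    intersection and pairwise overlap counts.
    """
    if not config.t_values:
        raise ValueError("t_values must be non-empty")
    per_t: dict[float, SelectionResult] = {}
    for t in config.t_values:
        per_t[t] = run_pipeline(table, labels, config, t=t)

    sets = {t: set(r.selected) for t, r in per_t.items()}
    union: set[str] = set().union(*sets.values())
    intersection = set.intersection(*sets.values()) if sets else set()
    ts = list(sets)
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in ts] for a in ts], index=ts, columns=ts
    )
    return SweepResult(
        per_t=per_t, union=union, intersection=intersection, pairwise_overlap=overlap
    )


def evaluate_fdr_power(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig = PipelineConfig(),
    n_replicates: int = 30,
    t: float = 0.0,
    seed: int | None = 0,
) -> dict:
    """Empirical FDR and power of the pipeline over simulated replicates.

    For each replicate a dataset is generated with known ground truth, the
    pipeline is run at threshold ``t``, and the false discovery proportion
    and power of the selection are recorded.  Returns means with Monte-Carlo
    standard errors.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    root = np.random.SeedSequence(seed)
    fdp, pwr, n_sel = [], [], []
    for r, child in enumerate(root.spawn(n_replicates)):
        states = child.generate_state(2, dtype=np.uint32) % (2**31)
        rep_sim = replace(sim_config, seed=int(states[0]))
        rep_pipe = replace(pipeline_config, seed=int(states[1]))
        table, labels, truth = generate_dataset(rep_sim)
        result = run_pipeline(table, labels, rep_pipe, t=t)
        fdp.append(false_discovery_proportion(result.selected, truth))
        pwr.append(power(result.selected, truth))
        n_sel.append(result.n_selected)
        logger.info(
            "replicate %d/%d: selected=%d FDP=%.3f power=%.3f",
            r + 1,
            n_replicates,
            n_sel[-1],
            fdp[-1],
            pwr[-1],
        )
    fdp_arr, pwr_arr = np.asarray(fdp), np.asarray(pwr)
    k = len(fdp_arr)
    return {
        "n_replicates": k,
        "fdp": fdp,
        "power": pwr,
        "n_selected": n_sel,
        "mean_fdp": float(fdp_arr.mean()),
        "se_fdp": float(fdp_arr.std(ddof=1) / np.sqrt(k)),
        "mean_power": float(pwr_arr.mean()),
        "se_power": float(pwr_arr.std(ddof=1) / np.sqrt(k)),
    }
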