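"""Greedy forward wavelength selection for shallow-network calibration.

One wavelength channel is added per step: every remaining candidate is
scored by training a quick network on the calibration set (validation-based
early stopping) and evaluating the variant's criterion, and the candidate
with the lowest criterion joins the subset. Selection stops at the variable
budget or after a patience-run of additions without a new best criterion;
the best-so-far subset is retrained fully and returned.

Three model variants mirror the study design:

* ``Model1`` — NIR region 0.75--1.90 um; criterion is the mean of the test
  and arthroscopic NRMSEs (the variant tuned for arthroscopic use).
* ``Model2`` — NIR region 0.75--1.90 um; test NRMSE only.
* ``Model3`` — wide region 0.40--1.90 um; test NRMSE only.

Scoring candidate subsets against the test group reproduces the original
analysis design faithfully; it is an optimistic protocol, and the docs flag
it as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import aggregate_location_prediction, nrmse
from .network import LMRegressor
from .preprocess import REGION_FULL, REGION_NIR

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelVariant:
    name: str
    region: tuple[float, float]
    criterion: str  # "test_only" | "test_plus_arthro"

    def __post_init__(self) -> None:
        if self.criterion not in ("test_only", "test_plus_arthro"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


MODEL1 = ModelVariant("Model1", REGION_NIR, "test_plus_arthro")
MODEL2 = ModelVariant("Model2", REGION_NIR, "test_only")
MODEL3 = ModelVariant("Model3", REGION_FULL, "test_only")
VARIANTS = {v.name: v for v in (MODEL1, MODEL2, MODEL3)}


def candidate_grid(
    wavelengths: np.ndarray, region: tuple[float, float], stride: int = 1
) -> np.ndarray:
    """Indices of every ``stride``-th channel inside the region."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    wavelengths = np.asarray(wavelengths)
    lo, hi = region
    idx = np.flatnonzero((wavelengths >= lo) & (wavelengths < hi))
    if idx.size == 0:
        raise ValueError(f"no channels in region {region}")
    return idx[::stride]


def combined_criterion(nrmse_test: float, nrmse_arthro: float) -> float:
    """Model 1 criterion: arithmetic mean of the test-group and arthroscopic
    NRMSEs (scale-free, equal weight)."""
    return 0.5 * (nrmse_test + nrmse_arthro)


@dataclass
class SelectionResult:
    """Outcome of one forward-selection run."""

    ordered_selected_wavelengths: list[float]
    selected_indices: list[int]
    criterion_trajectory: list[float]
    n_variables: int
    variant: str
    final_n_hidden: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @staticmethod
    def from_json(text: str) -> "SelectionResult":
        return SelectionResult(**json.loads(text))


def selection_histogram(
    selected_wavelengths, all_wavelengths, bin_channels: int = 10
) -> pd.DataFrame:
    """Histogram of selected wavelengths in bins of ``bin_channels``
    consecutive channels (bin start in um, count)."""
    all_wavelengths = np.asarray(all_wavelengths)
    selected = np.asarray(selected_wavelengths)
    starts = all_wavelengths[::bin_channels]
    edges = np.append(starts, all_wavelengths[-1] + 1e-9)
    counts, _ = np.histogram(selected, bins=edges)
    return pd.DataFrame({"bin_start_um": starts, "count": counts})


class ForwardWavelengthSelector(BaseEstimator):
    """Greedy forward selection wrapped around :class:`LMRegressor`.

    Candidate evaluation uses a reduced training budget (few epochs, one
    restart, fixed small hidden layer); the returned subset is retrained
    fully with a hidden-layer grid search on validation RMSE.

    Parameters
    ----------
    variant : ModelVariant or str
        Model variant; decides region and criterion.
    budget : int
        Maximum number of selected wavelengths.
    patience : int
        Stop after this many consecutive additions without improving the
        best criterion.
    stride : int
        Candidate-grid stride over the processed channels.
    n_hidden : int
        Hidden units for candidate scoring.
    candidate_epochs, candidate_restarts : int
        Reduced budget for candidate scoring.
    final_hidden_grid : tuple of int
        Hidden-unit counts searched for the final retrain.
    final_epochs, final_restarts : int
        Full budget for the final retrain.
    """

    def __init__(
        self,
        variant: ModelVariant | str = MODEL2,
        budget: int = 220,
        patience: int = 10,
        stride: int = 4,
        n_hidden: int = 3,
        candidate_epochs: int = 20,
        candidate_restarts: int = 1,
        final_hidden_grid: tuple = (1, 2, 3, 4, 5, 6, 7, 8),
        final_epochs: int = 200,
        final_restarts: int = 2,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.budget = budget
        self.patience = patience
        self.stride = stride
        self.n_hidden = n_hidden
        self.candidate_epochs = candidate_epochs
        self.candidate_restarts = candidate_restarts
        self.final_hidden_grid = final_hidden_grid
        self.final_epochs = final_epochs
        self.final_restarts = final_restarts
        self.random_state = random_state

    def _variant(self) -> ModelVariant:
        if isinstance(self.variant, ModelVariant):
            return self.variant
        return VARIANTS[self.variant]

    def fit(
        self,
        X_cal,
        y_cal,
        X_val,
        y_val,
        X_test,
        y_test,
        wavelengths=None,
        reference_range: float | None = None,
        X_arthro=None,
        arthro_groups=None,
        y_arthro=None,
    ):
        """Run forward selection.

        ``X_arthro`` holds one row per retained arthroscopic spectrum with
        ``arthro_groups`` labelling its location and ``y_arthro`` mapping
        location label -> measured value; required for the
        ``test_plus_arthro`` criterion. ``reference_range`` is the pooled
        measured range used by every NRMSE (defaults to the pooled
        cal/val/test range).
        """
        variant = self._variant()
        X_cal = np.asarray(X_cal, dtype=float)
        y_cal = np.asarray(y_cal, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        X_test = np.asarray(X_test, dtype=float)
        y_test = np.asarray(y_test, dtype=float)
        if wavelengths is None:
            wavelengths = np.arange(X_cal.shape[1], dtype=float)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if reference_range is None:
            pooled = np.concatenate([y_cal, y_val, y_test])
            reference_range = float(np.ptp(pooled))
        if variant.criterion == "test_plus_arthro":
            if X_arthro is None or arthro_groups is None or y_arthro is None:
                raise ValueError(
                    f"{variant.name} requires arthroscopic spectra, location "
                    "labels and measured values"
                )
            X_arthro = np.asarray(X_arthro, dtype=float)
            arthro_groups = np.asarray(arthro_groups)

        candidates = candidate_grid(wavelengths, variant.region, self.stride)
        ss = np.random.SeedSequence(self.random_state)
        cand_seed, final_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

        def criterion_for(subset: list[int], seed: int) -> float:
            est = LMRegressor(
                n_hidden=min(self.n_hidden, 8),
                max_epochs=self.candidate_epochs,
                n_restarts=self.candidate_restarts,
                random_state=seed,
            )
            cols = np.asarray(subset)
            est.fit(X_cal[:, cols], y_cal, X_val=X_val[:, cols], y_val=y_val)
            n_test = nrmse(y_test, est.predict(X_test[:, cols]), reference_range)
            if variant.criterion == "test_only":
                return n_test
            preds = est.predict(X_arthro[:, cols])
            y_loc_true, y_loc_pred = [], []
            for g in pd.unique(arthro_groups):
                agg = aggregate_location_prediction(preds[arthro_groups == g])
                if np.isfinite(agg):
                    y_loc_true.append(y_arthro[g])
                    y_loc_pred.append(agg)
            if not y_loc_true:
                return float("nan")
            n_arthro = nrmse(y_loc_true, y_loc_pred, reference_range)
            return combined_criterion(n_test, n_arthro)

        selected: list[int] = []
        best_len = 0
        best_criterion = float("inf")
        trajectory: list[float] = []
        stall = 0
        remaining = list(candidates)
        step = 0
        while remaining and len(selected) < self.budget and stall < self.patience:
            scores = []
            for c in remaining:
                val = criterion_for(selected + [int(c)], cand_seed + step)
                if not np.isfinite(val):
                    logger.warning("non-finite criterion for channel %d; skipped", c)
                    continue
                scores.append((val, int(c)))
            if not scores:
                break
            val, chosen = min(scores)
            selected.append(chosen)
            remaining.remove(chosen)
            trajectory.append(val)
            if val < best_criterion:
                best_criterion = val
                best_len = len(selected)
                stall = 0
            else:
                stall += 1
            step += 1

        if not selected:
            raise RuntimeError("no candidate produced a finite criterion")
        selected = selected[:best_len] if best_len else selected[:1]
        # Trajectory reported as the best criterion reached at each subset
        # size, so it is non-increasing at every retained addition.
        trajectory = list(np.minimum.accumulate(trajectory[: len(selected)]))

        # Final retrain on the best-so-far subset: hidden-unit grid search
        # on validation RMSE, full training budget.
        cols = np.asarray(selected)
        best_est, best_val_rmse = None, float("inf")
        for i, h in enumerate(self.final_hidden_grid):
            est = LMRegressor(
                n_hidden=h,
                max_epochs=self.final_epochs,
                n_restarts=self.final_restarts,
                random_state=final_seed + i,
            )
            est.fit(X_cal[:, cols], y_cal, X_val=X_val[:, cols], y_val=y_val)
            v = float(np.sqrt(np.mean((y_val - est.predict(X_val[:, cols])) ** 2)))
            if v < best_val_rmse:
                best_est, best_val_rmse = est, v

        self.estimator_ = best_est
        self.selected_indices_ = [int(i) for i in selected]
        self.selected_wavelengths_ = [float(wavelengths[i]) for i in selected]
        self.criterion_trajectory_ = [float(v) for v in trajectory]
        self.n_variables_ = len(selected)
        self.reference_range_ = reference_range
        self.wavelengths_ = wavelengths
        self.result_ = SelectionResult(
            ordered_selected_wavelengths=self.selected_wavelengths_,
            selected_indices=self.selected_indices_,
            criterion_trajectory=self.criterion_trajectory_,
            n_variables=self.n_variables_,
            variant=variant.name,
            final_n_hidden=best_est.n_hidden,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.estimator_.predict(X[:, np.asarray(self.selected_indices_)])

    def histogram(self, bin_channels: int = 10) -> pd.DataFrame:
        return selection_histogram(
            self.selected_wavelengths_, self.wavelengths_, bin_channels
        )
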