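"""Final model fitting, median-ensemble projection, and range geometry.

The selected (combination, learner family) pairs are refitted on the full
record set, their probability surfaces are combined cell-wise by the median,
and the ensemble is binarized into a range map from which southern/northern
range-limit latitudes and scenario-to-scenario shift tables are read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nichegen.enm import (
    LearnerSpec,
    RecordsProvider,
    Standardizer,
    repeat_seed,
    tss,
    tune_learner,
)
from nichegen.grids import RasterStack
from nichegen.learners import predict_proba

__all__ = [
    "EnsembleMember",
    "EnsemblePrediction",
    "RangeMap",
    "fit_final",
    "ensemble_project",
    "binarize",
    "range_shift_report",
]

MARGINAL_BAND = (0.3, 0.4)


@dataclass
class EnsembleMember:
    combo: tuple[str, ...]
    family: str
    model: object
    params: dict
    threshold: float  # training-data TSS-maximizing threshold


@dataclass
class EnsemblePrediction:
    """Per-cell median probability over ensemble members."""

    grid: object
    P: np.ndarray
    member_count: int
    scenario: str = "present"

    @property
    def median_threshold(self) -> float | None:
        return self._median_threshold

    _median_threshold: float | None = None


@dataclass
class RangeMap:
    """Binary presence grid with range-limit latitudes and marginal band."""

    grid: object
    occupied: np.ndarray
    threshold: float
    marginal: np.ndarray  # 0.3 < P < 0.4, disjoint from P >= 0.4 by design
    southern_limit: float | None
    northern_limit: float | None
    scenario: str = "present"


def fit_final(
    selection: list[tuple[tuple[str, ...], LearnerSpec]],
    provider: RecordsProvider,
    seed: int = 0,
    k: int = 10,
) -> list[EnsembleMember]:
    """Refit each selected (combo, family) on the full record set.

    Hyperparameters are re-tuned exactly as during evaluation (k-fold
    deviance); each member stores the threshold maximizing sensitivity +
    specificity on its own training records, later pooled (median) to
    binarize the ensemble.
    """
    if not selection:
        raise ValueError("empty model selection")
    members = []
    for i, (combo, spec) in enumerate(selection):
        try:
            rng = repeat_seed(seed, 10_000 + i)
            records = provider(tuple(combo), rng)
            model, params = tune_learner(
                records.X, records.y, spec, k=k,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scores = predict_proba(model, records.X)
            _, thr, _, _ = tss(scores, records.y)
        except Exception as err:
            raise RuntimeError(
                f"final fit failed for member (combo={combo}, family={spec.family})"
            ) from err
        members.append(
            EnsembleMember(tuple(combo), spec.family, model, params, thr)
        )
    return members


def ensemble_project(
    members: list[EnsembleMember],
    stack: RasterStack,
    standardizer: Standardizer,
    scenario: str = "present",
) -> EnsemblePrediction:
    """Project every member onto the (raw) stack and take the cell-wise
    median; an even member count averages the two central values."""
    std = standardizer.transform_stack(stack)
    surfaces = []
    for m in members:
        missing = [p for p in m.combo if p not in std]
        if missing:
            raise KeyError(f"member {m.combo}/{m.family}: missing predictors {missing}")
        X = np.column_stack([std[p].ravel() for p in m.combo])
        surfaces.append(predict_proba(m.model, X))
    P = np.median(np.stack(surfaces), axis=0).reshape(stack.grid.shape)
    pred = EnsemblePrediction(
        grid=stack.grid, P=P, member_count=len(members), scenario=scenario
    )
    pred._median_threshold = float(np.median([m.threshold for m in members]))
    return pred


def binarize(
    pred: EnsemblePrediction,
    threshold: float | None = None,
    validity_mask: np.ndarray | None = None,
) -> RangeMap:
    """Reclassify the ensemble probability surface into a range map.

    ``threshold`` defaults to the median of the member evaluation
    thresholds. Cells are occupied when P >= threshold; the marginal-habitat
    mask flags 0.3 < P < 0.4 (strict on both sides). Range limits are the
    min/max occupied cell-center latitudes (None when the map is empty).
    """
    if threshold is None:
        threshold = pred.median_threshold
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    P = pred.P
    occupied = P >= threshold
    marginal = (P > MARGINAL_BAND[0]) & (P < MARGINAL_BAND[1])
    if validity_mask is not None:
        occupied = occupied & validity_mask
        marginal = marginal & validity_mask
    lats = pred.grid.lats
    rows = np.flatnonzero(occupied.any(axis=1))
    south = float(lats[rows.min()]) if rows.size else None
    north = float(lats[rows.max()]) if rows.size else None
    return RangeMap(
        grid=pred.grid,
        occupied=occupied,
        threshold=float(threshold),
        marginal=marginal,
        southern_limit=south,
        northern_limit=north,
        scenario=pred.scenario,
    )


def range_shift_report(baseline: RangeMap, scenarios: list[RangeMap]) -> pd.DataFrame:
    """Cells lost/gained/stable and range-limit changes per scenario.

    Limit changes are in degrees latitude, positive = poleward (northward).
    """
    rows = []
    for sc in scenarios:
        if sc.grid != baseline.grid:
            raise ValueError(f"scenario {sc.scenario}: grid mismatch with baseline")
        lost = int(np.sum(baseline.occupied & ~sc.occupied))
        gained = int(np.sum(~baseline.occupied & sc.occupied))
        stable = int(np.sum(baseline.occupied & sc.occupied))

        def delta(new, old):
            if new is None or old is None:
                return np.nan
            return new - old

        rows.append(
            {
                "scenario": sc.scenario,
                "cells_lost": lost,
                "cells_gained": gained,
                "cells_stable": stable,
                "southern_limit_shift": delta(sc.southern_limit, baseline.southern_limit),
                "northern_limit_shift": delta(sc.northern_limit, baseline.northern_limit),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
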