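"""Model-selection engine for transferable niche models.

The pipeline standardizes predictors, derives a Mahalanobis habitat-
suitability surface from the presences, samples equal numbers of
pseudo-absences from low-suitability regions (suitability <= 0.2), and for
every admissible predictor combination runs a repeated 70/30 split-sample
evaluation (fresh pseudo-absences and splits per repeat, hyperparameters
tuned by 10-fold cross-validated binomial deviance), scoring each repeat by
the True Skill Statistic on the held-out 30%. The transferable model set is
then chosen by sorting combinations by mean TSS and pooling replicate TSS
samples into successive Kruskal–Wallis tests until significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from nichegen.grids import RasterStack
from nichegen.learners import LearnerSpec, fit_learner, predict_proba

__all__ = [
    "Standardizer",
    "LabelledRecords",
    "ModelEvaluation",
    "standardize",
    "mahalanobis_suitability",
    "sample_pseudoabsences",
    "split_records",
    "binomial_deviance",
    "tune_learner",
    "tss",
    "RecordsProvider",
    "evaluate_combination",
    "predictor_importance",
    "select_top_combos",
    "repeat_seed",
]

PSEUDOABSENCE_EXCLUSION = 0.2
TRAIN_FRACTION = 0.7


def repeat_seed(seed: int, *counters: int) -> np.random.Generator:
    """Expand a single pipeline seed into an independent per-stage stream."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=counters))


@dataclass(frozen=True)
class Standardizer:
    """Stored per-predictor (mean, sd) so projection grids share the
    training frame. Population (divide-by-n) moments."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def transform_stack(self, stack: RasterStack) -> RasterStack:
        missing = [n for n in self.names if n not in stack]
        if missing:
            raise KeyError(f"predictors missing from stack: {missing}")
        layers = {
            n: (stack[n] - m) / s
            for n, m, s in zip(self.names, self.means, self.sds)
        }
        return RasterStack(stack.grid, layers)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


def standardize(
    stack: RasterStack, reference_mask: np.ndarray | None = None
) -> tuple[RasterStack, Standardizer]:
    """Normalize each predictor to mean 0 / sd 1 over the reference cells."""
    names = tuple(stack.names)
    means, sds = [], []
    for n in names:
        v = stack[n].ravel()
        if reference_mask is not None:
            v = v[np.asarray(reference_mask).ravel()]
        v = v[np.isfinite(v)]
        sd = v.std()  # population convention
        if sd == 0:
            raise ValueError(f"predictor {n!r} has zero variance over reference cells")
        means.append(v.mean())
        sds.append(sd)
    sz = Standardizer(names, np.array(means), np.array(sds))
    return sz.transform_stack(stack), sz


def mahalanobis_suitability(
    presence_vectors: np.ndarray, stack_standardized: RasterStack
) -> np.ndarray:
    """Habitat suitability surface from the Mahalanobis distance to the
    presence centroid.

    D^2(cell) = (x - mu)' S^-1 (x - mu) with mu, S estimated from the
    presence predictor vectors; suitability = upper chi-square tail of D^2
    with dof = number of predictors, giving values in [0, 1] with 1 at the
    centroid. A singular covariance is ridge-regularized (1e-6 on the
    diagonal) with a warning.
    """
    X = np.asarray(presence_vectors, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} presences for {p} predictors")
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False).reshape(p, p)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular presence covariance; ridge-regularizing")
        S_inv = np.linalg.inv(S + 1e-6 * np.eye(p))
    cells = np.column_stack([stack_standardized[n_].ravel() for n_ in stack_standardized.names])
    d = cells - mu
    d2 = np.einsum("ij,jk,ik->i", d, S_inv, d)
    suit = sps.chi2.sf(d2, df=p)
    return suit.reshape(stack_standardized.grid.shape)


def sample_pseudoabsences(
    surface: np.ndarray,
    n_presences: int,
    presence_cells: np.ndarray,
    rng: np.random.Generator,
    exclusion: float = PSEUDOABSENCE_EXCLUSION,
) -> np.ndarray:
    """Uniformly sample ``n_presences`` cells with suitability <= ``exclusion``,
    excluding presence cells, without replacement. Returns flat cell ids."""
    flat = np.asarray(surface, dtype=float).ravel()
    eligible = np.flatnonzero(np.isfinite(flat) & (flat <= exclusion))
    eligible = np.setdiff1d(eligible, np.asarray(presence_cells), assume_unique=False)
    if eligible.size < n_presences:
        raise ValueError(
            f"only {eligible.size} cells with suitability <= {exclusion}; "
            f"need {n_presences} pseudo-absences"
        )
    return rng.choice(eligible, size=n_presences, replace=False)


@dataclass
class LabelledRecords:
    """Presence / pseudo-absence records with extracted predictor vectors."""

    X: np.ndarray  # (n, p), standardized predictor values
    y: np.ndarray  # 1 = presence, 0 = pseudo-absence
    cells: np.ndarray  # flat cell ids
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        pres = self.cells[self.y == 1]
        absn = self.cells[self.y == 0]
        if len(pres) != len(absn):
            raise ValueError("presence and pseudo-absence counts must be equal")
        if len(np.unique(pres)) != len(pres) or len(np.unique(absn)) != len(absn):
            raise ValueError("duplicated cell ids within a label class")

    @property
    def n(self) -> int:
        return len(self.y)


def split_records(
    records: LabelledRecords, rng: np.random.Generator,
    train_fraction: float = TRAIN_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train_idx, test_idx)."""
    if records.n < 10:
        raise ValueError("need at least 10 records to split")
    train_idx, test_idx = [], []
    for label in (0, 1):
        idx = np.flatnonzero(records.y == label)
        if len(idx) < 2:
            raise ValueError(f"label class {label} has fewer than 2 records")
        k = int(round(train_fraction * len(idx)))
        perm = rng.permutation(idx)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def binomial_deviance(y, p) -> float:
    """-2 sum [y log p + (1-y) log(1-p)], probabilities clipped at 1e-15."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-15, 1 - 1e-15)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def tune_learner(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: LearnerSpec,
    k: int = 10,
    seed: int | None = None,
):
    """Grid search minimizing mean held-out binomial deviance over ``k``
    stratified folds; ties resolve to the earliest (simplest) grid entry.

    Returns ``(fitted model on all of X_train, chosen params)``.
    """
    y_train = np.asarray(y_train, dtype=int)
    counts = np.bincount(y_train, minlength=2)
    if counts.min() == 0:
        raise ValueError("training data must contain both classes")
    k_eff = min(k, int(counts.min()))
    if k_eff < 2:
        raise ValueError("not enough records per class for cross-validation")
    cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=_as_int_seed(seed))
    folds = list(cv.split(X_train, y_train))
    best = None
    for params in spec.grid:
        dev = 0.0
        for fold_i, (tr, te) in enumerate(folds):
            model = fit_learner(spec.family, X_train[tr], y_train[tr], params,
                                seed=_as_int_seed(seed, fold_i))
            dev += binomial_deviance(y_train[te], predict_proba(model, X_train[te]))
        dev /= len(folds)
        if best is None or dev < best[0] - 1e-12:
            best = (dev, params)
    _, params = best
    model = fit_learner(spec.family, X_train, y_train, params, seed=_as_int_seed(seed))
    return model, params


def _as_int_seed(seed, *extra) -> int | None:
    if seed is None:
        return None
    rng = repeat_seed(seed, *extra) if extra else np.random.default_rng(seed)
    return int(rng.integers(0, 2**31 - 1))


def tss(scores, labels) -> tuple[float, float, float, float]:
    """True Skill Statistic at the threshold maximizing sensitivity +
    specificity.

    Candidate thresholds are the observed scores plus {0, 1}; a record is
    predicted present when its score >= threshold. Ties resolve to the
    lowest threshold (the more inclusive range map). Returns
    ``(TSS, threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes required to compute TSS")
    pos = labels == 1
    n_pos = pos.sum()
    n_neg = len(labels) - n_pos
    best = None
    for t in np.unique(np.concatenate([scores, [0.0, 1.0]])):
        pred = scores >= t
        sens = np.sum(pred & pos) / n_pos
        spec = np.sum(~pred & ~pos) / n_neg
        score = sens + spec
        if best is None or score > best[0] + 1e-12:
            best = (score, t, sens, spec)
    score, t, sens, spec = best
    return float(score - 1.0), float(t), float(sens), float(spec)


@dataclass
class RecordsProvider:
    """Builds fresh labelled records for a predictor combination.

    Holds the standardized stack, its transform, the presence cells, and the
    Mahalanobis surface used for pseudo-absence exclusion; each call with a
    fresh RNG draws a new pseudo-absence set.
    """

    stack_standardized: RasterStack
    presence_cells: np.ndarray
    surface: np.ndarray
    exclusion: float = PSEUDOABSENCE_EXCLUSION

    def __call__(self, combo: tuple[str, ...], rng: np.random.Generator) -> LabelledRecords:
        absences = sample_pseudoabsences(
            self.surface, len(self.presence_cells), self.presence_cells, rng,
            self.exclusion,
        )
        cells = np.concatenate([self.presence_cells, absences])
        y = np.concatenate(
            [np.ones(len(self.presence_cells), int), np.zeros(len(absences), int)]
        )
        cols = [self.stack_standardized[p].ravel()[cells] for p in combo]
        return LabelledRecords(
            X=np.column_stack(cols), y=y, cells=cells, predictors=tuple(combo)
        )


def build_provider(
    stack: RasterStack,
    occurrences: pd.DataFrame,
    exclusion: float = PSEUDOABSENCE_EXCLUSION,
    surface_predictors: list[str] | None = None,
) -> tuple[RecordsProvider, Standardizer]:
    """Standardize the stack, derive the Mahalanobis surface from the
    occurrences, and wrap both into a :class:`RecordsProvider`.

    ``surface_predictors`` restricts the suitability surface used for
    pseudo-absence exclusion to a subset of predictors (default: all);
    useful for null experiments and sensitivity analyses.
    """
    std_stack, sz = standardize(stack)
    iy, ix = stack.grid.cell_index(
        occurrences["lon"].to_numpy(), occurrences["lat"].to_numpy()
    )
    presence_cells = np.unique(stack.grid.flat_index(iy, ix))
    surf_stack = (
        std_stack if surface_predictors is None else std_stack.subset(surface_predictors)
    )
    pres_X = np.column_stack(
        [surf_stack[n].ravel()[presence_cells] for n in surf_stack.names]
    )
    surface = mahalanobis_suitability(pres_X, surf_stack)
    return RecordsProvider(std_stack, presence_cells, surface, exclusion), sz


@dataclass
class ModelEvaluation:
    """Replicate TSS values and tuned settings for one (combo, family)."""

    combo: tuple[str, ...]
    family: str
    tss_values: np.ndarray
    thresholds: np.ndarray
    params: list[dict] = field(default_factory=list)

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tss_values))

    @property
    def sd_tss(self) -> float:
        return float(np.std(self.tss_values, ddof=1)) if len(self.tss_values) > 1 else 0.0


def evaluate_combination(
    combo: tuple[str, ...],
    spec: LearnerSpec,
    provider: RecordsProvider,
    repeats: int = 50,
    seed: int = 0,
    k: int = 10,
) -> ModelEvaluation:
    """Repeated split-sample evaluation of one predictor combination.

    Each repeat draws a fresh pseudo-absence set and a fresh stratified
    70/30 split, tunes the learner on the training side by k-fold deviance,
    and scores the held-out 30% with the TSS. Per-repeat seeds derive from
    the single pipeline seed by a fixed counter scheme.
    """
    tss_vals, thresholds, params_list = [], [], []
    for rep in range(repeats):
        try:
            rng = repeat_seed(seed, rep)
            records = provider(combo, rng)
            train, test = split_records(records, rng)
            model, params = tune_learner(
                records.X[train], records.y[train], spec, k=k,
                seed=_as_int_seed(seed, rep, 1),
            )
            scores = predict_proba(model, records.X[test])
            t, thr, _, _ = tss(scores, records.y[test])
        except Exception as err:
            raise RuntimeError(f"repeat {rep} of combo {combo} failed") from err
        tss_vals.append(t)
        thresholds.append(thr)
        params_list.append(params)
    return ModelEvaluation(
        combo=tuple(combo),
        family=spec.family,
        tss_values=np.array(tss_vals),
        thresholds=np.array(thresholds),
        params=params_list,
    )


def predictor_importance(evaluations: list[ModelEvaluation]) -> pd.DataFrame:
    """Per-predictor mean TSS alone and mean TSS gain when added to a model.

    "Alone" is the singleton-combination mean TSS; "gain" averages
    TSS(combo) - TSS(combo without the predictor) over all evaluated combos
    where both are available (NaN when no such pair exists).
    """
    by_combo = {tuple(sorted(e.combo)): e.mean_tss for e in evaluations}
    predictors = sorted({p for e in evaluations for p in e.combo})
    missing = [p for p in predictors if (p,) not in by_combo]
    if missing:
        raise ValueError(f"missing singleton evaluations for: {missing}")
    rows = []
    for p in predictors:
        gains = [
            mean_tss - by_combo[tuple(sorted(set(combo) - {p}))]
            for combo, mean_tss in by_combo.items()
            if p in combo
            and len(combo) > 1
            and tuple(sorted(set(combo) - {p})) in by_combo
        ]
        rows.append(
            {
                "predictor": p,
                "tss_alone": by_combo[(p,)],
                "mean_gain": float(np.mean(gains)) if gains else np.nan,
                "n_gain_pairs": len(gains),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def select_top_combos(
    evaluations: list[ModelEvaluation], alpha: float = 0.05
) -> list[ModelEvaluation]:
    """Transferable model set by successive Kruskal–Wallis rank tests.

    Combinations are sorted by decreasing mean TSS; starting from the best,
    the next combination's replicate TSS sample is pooled into a
    Kruskal–Wallis test with the already-selected samples. While p >= alpha
    the candidate joins the selection; the first p < alpha stops the scan.
    """
    if len(evaluations) < 2:
        raise ValueError("need at least two evaluations")
    counts = {len(e.tss_values) for e in evaluations}
    if len(counts) != 1:
        raise ValueError("replicate counts differ between evaluations")
    if counts.pop() < 2:
        raise ValueError("need at least two replicates per evaluation")
    ranked = sorted(evaluations, key=lambda e: (-e.mean_tss, e.family, e.combo))
    selected = [ranked[0]]
    for candidate in ranked[1:]:
        samples = [e.tss_values for e in selected] + [candidate.tss_values]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            p = 1.0  # indistinguishable replicate vectors
        else:
            p = sps.kruskal(*samples).pvalue
        if p < alpha:
            break
        selected.append(candidate)
    return selected
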