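"""Random-forest imputation of missing climate covariates.

Candidate feature sets are compared by k-fold cross-validated RMSE and
out-of-bag explained variance; the winning set is refit on all complete
records and used to fill the gaps.  Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .corpus import SimulationRecord

__all__ = [
    "KNOWN_FEATURES",
    "CATEGORICAL_FEATURES",
    "IMPUTATION_TARGETS",
    "CandidateResult",
    "ImputationReport",
    "FittedImputer",
    "default_candidates",
    "fit_imputer",
    "impute_missing",
    "impute_all",
]

#: Record attributes usable as model inputs.
CATEGORICAL_FEATURES = ("scenario", "climate_family", "crop")
NUMERIC_FEATURES = (
    "dTg_2005",
    "dTg_pi",
    "dTl_2005",
    "dPr_2005",
    "lat",
    "lon",
    "Tave",
    "Tave_w",
    "Pr_base",
    "future_mid",
    "base_mid",
    "YI_2005",
)
KNOWN_FEATURES = NUMERIC_FEATURES + CATEGORICAL_FEATURES

IMPUTATION_TARGETS = ("dTg_2005", "dTl_2005", "dPr_2005")


def default_candidates(target: str) -> list[tuple[str, ...]]:
    """Candidate feature sets per target, broadest first plus nested reductions."""
    if target == "dTl_2005":
        return [
            ("dTg_2005", "Tave_w", "lat", "lon", "future_mid", "scenario"),
            ("dTg_2005", "lat", "lon"),
            ("dTg_2005", "lat"),
            ("dTg_2005",),
        ]
    if target == "dTg_2005":
        return [
            ("dTl_2005", "Tave_w", "lat", "lon", "scenario", "future_mid"),
            ("dTl_2005", "lat", "lon"),
            ("dTl_2005",),
        ]
    if target in ("dPr_2005", "dPr"):
        return [
            ("dTg_2005", "dTl_2005", "lat", "lon", "scenario", "future_mid", "Pr_base"),
            ("dTg_2005", "lat", "lon", "Pr_base"),
            ("Pr_base", "lat", "lon"),
        ]
    raise ValueError(f"unknown imputation target {target!r}")


@dataclass(frozen=True)
class CandidateResult:
    feature_set: tuple[str, ...]
    cv_rmse: float
    oob_explained_variance: float  # percent


@dataclass
class ImputationReport:
    target: str
    candidates: list[CandidateResult]
    selected: tuple[str, ...]
    n_train: int
    n_imputed: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "candidates": [
                {
                    "features": list(c.feature_set),
                    "cv_rmse": c.cv_rmse,
                    "oob_explained_variance": c.oob_explained_variance,
                }
                for c in self.candidates
            ],
            "selected": list(self.selected),
            "n_train": self.n_train,
            "n_imputed": self.n_imputed,
            "seed": self.seed,
        }


@dataclass
class FittedImputer:
    target: str
    features: tuple[str, ...]
    estimator: RandomForestRegressor
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def design_row(self, rec: SimulationRecord) -> list[float] | None:
        """Encode one record; None if any feature is missing."""
        row: list[float] = []
        for f in self.features:
            v = getattr(rec, f)
            if v is None:
                return None
            if f in self.categories:
                cats = self.categories[f]
                row.extend(1.0 if str(v) == c else 0.0 for c in cats)
            else:
                row.append(float(v))
        return row


def _complete_for(records: Sequence[SimulationRecord], target: str, features: Sequence[str]):
    rows = []
    for rec in records:
        if getattr(rec, target) is None:
            continue
        if all(getattr(rec, f) is not None for f in features):
            rows.append(rec)
    return rows


def _encode(records: Sequence[SimulationRecord], features: Sequence[str], categories):
    X = []
    for rec in records:
        row: list[float] = []
        for f in features:
            v = getattr(rec, f)
            if f in categories:
                row.extend(1.0 if str(v) == c else 0.0 for c in categories[f])
            else:
                row.append(float(v))
        X.append(row)
    return np.asarray(X, dtype=float)


def _categories_for(records: Sequence[SimulationRecord], features: Sequence[str]):
    # Alphabetical category order keeps the one-hot encoding deterministic.
    cats = {}
    for f in features:
        if f in CATEGORICAL_FEATURES:
            cats[f] = tuple(sorted({str(getattr(r, f)) for r in records}))
    return cats


def _make_rf(n_estimators: int, seed: int, oob: bool) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_estimators, oob_score=oob, random_state=seed, n_jobs=1
    )


def fit_imputer(
    records: Sequence[SimulationRecord],
    target: str,
    candidates: Sequence[Sequence[str]] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    min_train: int = 50,
) -> tuple[FittedImputer, ImputationReport]:
    """Select a feature set by CV and refit the imputer on all complete records.

    For each candidate, the pooled k-fold RMSE and the out-of-bag explained
    variance (R^2 x 100) are computed on records where the target is present;
    the candidate with the highest explained variance wins (first wins ties).
    """
    if target not in IMPUTATION_TARGETS and target not in ("dPr",):
        raise ValueError(f"unknown imputation target {target!r}")
    if candidates is None:
        candidates = default_candidates(target)
    for cand in candidates:
        unknown = [f for f in cand if f not in KNOWN_FEATURES]
        if unknown:
            raise ValueError(f"unknown feature names {unknown} in candidate {tuple(cand)}")

    results: list[CandidateResult] = []
    for cand in candidates:
        cand = tuple(cand)
        train = _complete_for(records, target, cand)
        if len(train) < min_train:
            raise ValueError(
                f"only {len(train)} complete records for candidate {cand}; need >= {min_train}"
            )
        cats = _categories_for(train, cand)
        X = _encode(train, cand, cats)
        y = np.array([getattr(r, target) for r in train], dtype=float)
        if np.all(X == X[0]):
            raise ValueError(f"candidate {cand} has no observed variation")

        sq_errors: list[np.ndarray] = []
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in kf.split(X):
            rf = _make_rf(n_estimators, seed, oob=False)
            rf.fit(X[train_idx], y[train_idx])
            pred = rf.predict(X[test_idx])
            sq_errors.append((pred - y[test_idx]) ** 2)
        cv_rmse = float(np.sqrt(np.mean(np.concatenate(sq_errors))))

        if np.var(y) == 0.0:
            oob_pct = 100.0  # constant target: trivially explained
        else:
            rf_full = _make_rf(n_estimators, seed, oob=True)
            rf_full.fit(X, y)
            oob_pct = float(rf_full.oob_score_) * 100.0
        results.append(CandidateResult(cand, cv_rmse, oob_pct))

    best = max(results, key=lambda c: c.oob_explained_variance)
    train = _complete_for(records, target, best.feature_set)
    cats = _categories_for(train, best.feature_set)
    X = _encode(train, best.feature_set, cats)
    y = np.array([getattr(r, target) for r in train], dtype=float)
    final = _make_rf(n_estimators, seed, oob=False)
    final.fit(X, y)

    model = FittedImputer(target, best.feature_set, final, cats)
    n_missing = sum(1 for r in records if getattr(r, target) is None)
    report = ImputationReport(
        target=target,
        candidates=results,
        selected=best.feature_set,
        n_train=len(train),
        n_imputed=n_missing,
        seed=seed,
    )
    return model, report


def impute_missing(
    records: Sequence[SimulationRecord],
    model: FittedImputer,
    target: str,
) -> tuple[list[SimulationRecord], list[SimulationRecord]]:
    """Fill the target on records where it is missing; everything else is untouched.

    Returns ``(records_out, skipped)``.  Records that lack one of the model's
    features cannot be predicted; they are passed through unchanged and listed
    in ``skipped``.  Records with the target already present are returned as
    the same objects, guaranteeing observed values are never altered.
    """
    if model.target != target:
        raise ValueError(f"model fitted for {model.target!r}, not {target!r}")
    out: list[SimulationRecord] = []
    skipped: list[SimulationRecord] = []
    pending: list[tuple[int, list[float]]] = []
    for rec in records:
        if getattr(rec, target) is not None:
            out.append(rec)
            continue
        row = model.design_row(rec)
        if row is None:
            out.append(rec)
            skipped.append(rec)
            continue
        filled = rec.copy()
        filled.imputed_fields.add(target)
        out.append(filled)
        pending.append((len(out) - 1, row))
    if pending:
        X = np.asarray([row for _, row in pending], dtype=float)
        preds = model.estimator.predict(X)
        for (idx, _), pred in zip(pending, preds):
            setattr(out[idx], target, float(pred))
    return out, skipped


def impute_all(
    records: Sequence[SimulationRecord],
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
) -> tuple[list[SimulationRecord], list[ImputationReport]]:
    """Impute dTg, then dTl, then dPr (feature sets imply this dependency order)."""
    reports = []
    for target in ("dTg_2005", "dTl_2005", "dPr_2005"):
        if not any(getattr(r, target) is None for r in records):
            continue
        model, report = fit_imputer(
            records, target, folds=folds, seed=seed, n_estimators=n_estimators
        )
        records, _ = impute_missing(records, model, target)
        report.n_imputed = sum(1 for r in records if target in r.imputed_fields)
        reports.append(report)
    return list(records), reports
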