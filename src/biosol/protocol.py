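"""The model-construction protocol: response-sorted train/test split,
PCA-based outlier relocation, VIP truncation, greedy backward descriptor
elimination monitored by cross-validated Q^2, and augmentation with
experimentally determined properties.

The whole protocol is deterministic: a pure function of the dataset, the
descriptor matrix and the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset import Medium, SolubilityDataset
from .latent import (NipalsPLS, PCAModel, choose_components, dmodx,
                     hotelling_t2, vip)

__all__ = [
    "SplitResult",
    "SelectionTrace",
    "ModelSummary",
    "sorted_thirds_split",
    "relocate_outliers",
    "truncate_top_vip",
    "greedy_backward_selection",
    "augment_experimental",
    "build_summary",
    "VipGreedyPLS",
]


class ProtocolError(ValueError):
    pass


@dataclass
class SplitResult:
    """Train/test membership with a log of outlier relocations."""

    train: list[str]
    test: list[str]
    relocations: list[tuple[str, str]] = field(default_factory=list)  # (name, criterion)

    def __post_init__(self):
        overlap = set(n.casefold() for n in self.train) & set(n.casefold() for n in self.test)
        if overlap:
            raise ProtocolError(f"train/test overlap: {sorted(overlap)}")


@dataclass
class SelectionStep:
    pass_index: int
    descriptor: str
    q2_before: float
    q2_after: float
    accepted: bool


@dataclass
class SelectionTrace:
    """Every elimination trial, plus the final descriptor set and Q^2."""

    steps: list[SelectionStep]
    final_descriptors: list[str]
    final_q2: float

    @property
    def accepted_steps(self) -> list[SelectionStep]:
        return [s for s in self.steps if s.accepted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


@dataclass
class ModelSummary:
    """Model-card statistics in the shape of a model-summary table row."""

    model_id: str
    descriptors: list[str]
    n_components: int
    r2: float
    q2: float
    rmse_tr: float
    rmse_te: float | None
    n_train: int
    n_test: int
    augmentation: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.rmse_tr < 0 or (self.rmse_te is not None and self.rmse_te < 0):
            raise ProtocolError("RMSE must be non-negative")
        if self.r2 > 1 + 1e-12 or self.q2 > 1 + 1e-12:
            raise ProtocolError("R2 and Q2 cannot exceed 1")

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, list) else v) for k, v in vars(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def sorted_thirds_split(ds: SolubilityDataset, medium: Medium | str) -> SplitResult:
    """Sort compounds by response (most soluble first) and send every third
    one to the test set.

    Positions divisible by 3 (1-based) go to test, so n compounds yield
    floor(n/3) test compounds. Ties in the response are broken by compound
    name for determinism.
    """
    med = Medium.coerce(medium)
    missing = [r.name for r in ds if r.solubility(med) is None]
    if missing:
        raise ProtocolError(
            f"response {med.value} missing for: {', '.join(missing)}")
    ordered = sorted(ds.records, key=lambda r: (-r.solubility(med), r.name.casefold()))
    train, test = [], []
    for pos, rec in enumerate(ordered, start=1):
        (test if pos % 3 == 0 else train).append(rec.name)
    order = {n: i for i, n in enumerate(ds.names)}
    return SplitResult(train=sorted(train, key=order.get), test=sorted(test, key=order.get))


def relocate_outliers(split: SplitResult, X: pd.DataFrame,
                      criterion: str = "both", n_components: int = 2,
                      alpha: float = 0.05, max_passes: int = 5) -> SplitResult:
    """Move training compounds flagged by PCA diagnostics to the test set.

    A PCA is fitted on the training rows of the (preprocessed) descriptor
    matrix; training compounds above the 95% Hotelling T^2 or DModX limit
    are relocated, and the procedure iterates (at most ``max_passes``)
    because the model changes after each relocation. Test compounds are
    never touched.
    """
    if criterion not in ("t2", "dmodx", "both"):
        raise ProtocolError(f"unknown criterion {criterion!r}")
    train = list(split.train)
    test = list(split.test)
    moves: list[tuple[str, str]] = list(split.relocations)
    for _ in range(max_passes):
        if len(train) <= n_components + 2:
            raise ProtocolError("relocation would empty the training set")
        Xtr = X.loc[train]
        k = min(n_components, len(train) - 1, X.shape[1])
        pca = PCAModel(n_components=k).fit(Xtr)
        flagged: dict[str, str] = {}
        if criterion in ("t2", "both"):
            t2, lim = hotelling_t2(pca, alpha=alpha)
            for name, v in zip(train, t2):
                if v > lim:
                    flagged[name] = "t2"
        if criterion in ("dmodx", "both"):
            d, lim = dmodx(pca, alpha=alpha)
            for name, v in zip(train, d):
                if v > lim:
                    flagged.setdefault(name, "dmodx")
        if not flagged:
            break
        for name, why in flagged.items():
            train.remove(name)
            test.append(name)
            moves.append((name, why))
    if not train:
        raise ProtocolError("relocation emptied the training set")
    return SplitResult(train=train, test=test, relocations=moves)


def _fit_with_chosen(X, y, max_components, groups, threshold):
    a, cv = choose_components(X, y, max_a=max_components, groups=groups,
                              threshold=threshold)
    return NipalsPLS(n_components=a).fit(X, y), cv


def truncate_top_vip(X: pd.DataFrame, y, keep: int = 100,
                     max_components: int = 10, groups: int = 7,
                     threshold: float = 0.01) -> list[str]:
    """Descriptors ranked by VIP of a preliminary PLS; top ``keep`` kept.

    Boundary ties are broken by descriptor name. If there are no more than
    ``keep`` descriptors the full list is returned unchanged.
    """
    if X.shape[1] <= keep:
        return list(X.columns)
    model, _ = _fit_with_chosen(X, y, max_components, groups, threshold)
    scores = vip(model)
    ranked = sorted(X.columns, key=lambda c: (-scores[c], str(c).casefold()))
    return [c for c in X.columns if c in set(ranked[:keep])]


def greedy_backward_selection(X: pd.DataFrame, y, groups: int = 7,
                              q2_tol: float = 1e-6, max_components: int = 10,
                              threshold: float = 0.01) -> SelectionTrace:
    """Eliminate descriptors one at a time while Q^2 does not degrade.

    Within a pass, candidates are visited in ascending VIP order (computed
    once per pass). A candidate is permanently removed iff the model
    re-fitted without it — with the component count re-chosen — has a Q^2
    at least as high as the current one (equality within ``q2_tol``).
    Passes repeat until a full pass removes nothing.
    """
    if X.shape[1] < 2:
        raise ProtocolError("need at least two descriptors to select from")
    current = list(X.columns)
    _, cv = _fit_with_chosen(X[current], y, max_components, groups, threshold)
    q2_cur = cv.q2_at_chosen
    steps: list[SelectionStep] = []
    pass_index = 0
    while True:
        pass_index += 1
        model, _ = _fit_with_chosen(X[current], y, max_components, groups, threshold)
        order = vip(model).sort_values(kind="stable").index.tolist()
        removed_any = False
        for cand in order:
            if cand not in current or len(current) == 1:
                continue
            trial = [c for c in current if c != cand]
            _, cv_t = _fit_with_chosen(X[trial], y, max_components, groups, threshold)
            q2_new = cv_t.q2_at_chosen
            accepted = q2_new >= q2_cur - q2_tol
            steps.append(SelectionStep(pass_index, str(cand), q2_cur, q2_new, accepted))
            if accepted:
                current = trial
                q2_cur = q2_new
                removed_any = True
        if not removed_any or len(current) == 1:
            break
    return SelectionTrace(steps=steps, final_descriptors=current, final_q2=q2_cur)


class VipGreedyPLS(RegressorMixin, BaseEstimator):
    """Full descriptor-selection protocol as a scikit-learn regressor.

    ``fit(X, y)`` runs: preliminary PLS on all descriptors, truncation to
    the ``keep`` highest-VIP descriptors, then greedy backward elimination
    monitored by grouped cross-validated Q^2 with the component count
    re-chosen at every trial. The final model is a :class:`NipalsPLS` on
    the surviving descriptors.

    Fitted attributes: ``selected_`` (descriptor names), ``trace_``
    (:class:`SelectionTrace`), ``model_`` (final PLS), ``q2_``, ``cv_``.
    """

    def __init__(self, keep: int = 100, groups: int = 7, q2_tol: float = 1e-6,
                 max_components: int = 10, component_threshold: float = 0.01):
        self.keep = keep
        self.groups = groups
        self.q2_tol = q2_tol
        self.max_components = max_components
        self.component_threshold = component_threshold

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{j}" for j in range(np.shape(X)[1])])
        y = np.asarray(y, dtype=float).ravel()
        kept = truncate_top_vip(X, y, keep=self.keep,
                                max_components=self.max_components,
                                groups=self.groups,
                                threshold=self.component_threshold)
        self.trace_ = greedy_backward_selection(
            X[kept], y, groups=self.groups, q2_tol=self.q2_tol,
            max_components=self.max_components,
            threshold=self.component_threshold)
        self.selected_ = list(self.trace_.final_descriptors)
        a, cv = choose_components(X[self.selected_], y,
                                  max_a=self.max_components,
                                  groups=self.groups,
                                  threshold=self.component_threshold)
        self.cv_ = cv
        self.q2_ = cv.q2_at_chosen
        self.model_ = NipalsPLS(n_components=a).fit(X[self.selected_], y)
        return self

    def predict(self, X):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{j}" for j in range(np.shape(X)[1])])
        return self.model_.predict(X[self.selected_])


_AUG_FIELD = {"phb_solubility": "logs_phb", "tm": "tm_c", "logd": "logd65"}


@dataclass
class AugmentationResult:
    matrix: pd.DataFrame            # selected descriptors + augmentation columns
    rows: list[str]                 # training compounds with complete data
    q2_base: float
    q2_augmented: float
    retained: bool
    leak_flag: bool
    model: NipalsPLS | None


def augment_experimental(X: pd.DataFrame, ds: SolubilityDataset, y: pd.Series,
                         which: list[str], groups: int = 7,
                         max_components: int = 10, threshold: float = 0.01,
                         q2_tol: float = 1e-6, impute: bool = False) -> AugmentationResult:
    """Append measured properties as extra descriptors and re-fit.

    ``which`` is a subset of {"phb_solubility", "tm", "logd"}. Compounds
    missing a requested value are excluded from the variant's training
    (default) or mean-imputed. Augmentation columns are autoscaled with the
    training statistics. The augmentation is retained only if the grouped
    cross-validated Q^2 improves (same rule as descriptor elimination). A
    column nearly collinear with the response raises the leak flag.
    """
    bad = [w for w in which if w not in _AUG_FIELD]
    if bad:
        raise ProtocolError(f"unknown augmentation(s): {bad}")
    if not which:
        raise ProtocolError("no augmentation requested")
    cols = {}
    for w in which:
        values = {r.name: getattr(r, _AUG_FIELD[w]) for r in ds}
        if all(v is None for v in values.values()):
            raise ProtocolError(f"augmentation column {w!r} entirely missing")
        cols[w] = values
    rows = list(X.index)
    complete = [n for n in rows
                if all(cols[w].get(n) is not None for w in which)]
    if impute:
        used_rows = rows
    else:
        used_rows = complete
        if not used_rows:
            raise ProtocolError("no training compound has all requested augmentations")

    aug = pd.DataFrame(index=used_rows)
    for w in which:
        series = pd.Series({n: cols[w].get(n) for n in used_rows}, dtype=float)
        if impute and series.isna().any():
            series = series.fillna(series.mean())
        mu, sd = series.mean(), series.std(ddof=1)
        if sd < 1e-12:
            raise ProtocolError(f"augmentation column {w!r} is constant")
        aug[w] = (series - mu) / sd

    y_used = y.loc[used_rows]
    X_used = X.loc[used_rows]
    _, cv_base = choose_components(X_used, y_used, max_a=max_components,
                                   groups=groups, threshold=threshold)
    X_aug = pd.concat([X_used, aug], axis=1)
    a_aug, cv_aug = choose_components(X_aug, y_used, max_a=max_components,
                                      groups=groups, threshold=threshold)
    leak = any(
        abs(np.corrcoef(aug[w], y_used)[0, 1]) > 0.999 for w in which)
    retained = cv_aug.q2_at_chosen >= cv_base.q2_at_chosen + q2_tol
    model = NipalsPLS(n_components=a_aug).fit(X_aug, y_used) if retained else None
    return AugmentationResult(matrix=X_aug, rows=used_rows,
                              q2_base=cv_base.q2_at_chosen,
                              q2_augmented=cv_aug.q2_at_chosen,
                              retained=retained, leak_flag=leak, model=model)


def build_summary(model: NipalsPLS, split: SplitResult, y_test=None,
                  y_pred_test=None, model_id: str = "model", q2: float = float("nan"),
                  augmentation: list[str] | None = None) -> ModelSummary:
    """Assemble a model-summary row from a fitted model and test predictions.

    Test-set R^2 follows the external-validation convention (residual sum
    of squares over the spread about the *training* response mean), so a
    constant predictor at the training mean scores exactly zero.
    """
    rmse_te = None
    if y_test is not None:
        y_test = np.asarray(y_test, dtype=float)
        y_pred_test = np.asarray(y_pred_test, dtype=float)
        if y_test.shape != y_pred_test.shape:
            raise ProtocolError("test observations and predictions differ in length")
        rmse_te = float(np.sqrt(np.mean((y_test - y_pred_test) ** 2)))
    return ModelSummary(
        model_id=model_id,
        descriptors=list(model.feature_names_in_),
        n_components=model.n_components_,
        r2=model.r2_,
        q2=float(q2),
        rmse_tr=model.rmse_tr_,
        rmse_te=rmse_te,
        n_train=len(split.train),
        n_test=len(split.test),
        augmentation=list(augmentation or []),
    )
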