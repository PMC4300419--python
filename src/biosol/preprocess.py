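"""Descriptor-matrix preprocessing for latent-variable modelling.

A descriptor matrix is a pandas ``DataFrame`` (compounds x descriptors) with
unique row and column names. The standard preparation before PLS/PCA is:
signed cube-root transform, exclusion of non-normally distributed columns,
then mean-centering and unit-variance scaling (autoscaling) with the sample
(n-1) variance convention. :class:`DescriptorPreprocessor` chains the three
steps with a single fitted state that can be re-applied to new compounds
and round-tripped through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "blind_descriptors",
    "unblind_descriptors",
    "signed_cube_root",
    "SignedCubeRoot",
    "NormalityFilter",
    "Autoscaler",
    "DescriptorPreprocessor",
]

#: variance below this is treated as a constant column
CONSTANT_TOL = 1e-12


class PreprocessingError(ValueError):
    pass


def _check_matrix(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    if X.isna().any().any():
        raise PreprocessingError("descriptor matrix contains missing cells")
    if len(set(X.columns)) != X.shape[1]:
        raise PreprocessingError("descriptor names must be unique")
    if len(set(X.index)) != X.shape[0]:
        raise PreprocessingError("compound names must be unique")
    return X.astype(float)


def blind_descriptors(X: pd.DataFrame, prefix: str = "D") -> tuple[pd.DataFrame, dict[str, str]]:
    """Replace descriptor names with opaque aliases to avoid selection bias.

    Returns the aliased matrix (values untouched) and the alias->name map.
    """
    X = _check_matrix(X)
    width = max(3, len(str(X.shape[1])))
    aliases = [f"{prefix}{j:0{width}d}" for j in range(1, X.shape[1] + 1)]
    out = X.copy()
    out.columns = aliases
    return out, dict(zip(aliases, X.columns))


def unblind_descriptors(X: pd.DataFrame, alias_map: dict[str, str]) -> pd.DataFrame:
    out = X.copy()
    out.columns = [alias_map.get(c, c) for c in X.columns]
    return out


def signed_cube_root(X: pd.DataFrame) -> pd.DataFrame:
    """Elementwise sign(x)*|x|^(1/3); monotone, defined for negatives."""
    X = _check_matrix(X)
    return np.sign(X) * np.abs(X) ** (1.0 / 3.0)


class SignedCubeRoot(TransformerMixin, BaseEstimator):
    """Stateless signed cube-root transformer (sklearn-compatible)."""

    def fit(self, X, y=None):
        _check_matrix(X)
        self.n_features_in_ = np.shape(X)[1]
        return self

    def transform(self, X):
        return signed_cube_root(X)


class NormalityFilter(TransformerMixin, BaseEstimator):
    """Drop descriptors whose training distribution is far from normal.

    Two modes:

    - ``mode="moments"`` (default): keep a column iff
      ``|skewness| <= skew_limit`` and ``|excess kurtosis| <= kurt_limit``.
      Moment screens are deterministic and scale-free.
    - ``mode="test"``: keep iff the D'Agostino-Pearson normality test does
      not reject at level ``alpha``.

    Constant columns (variance < ``CONSTANT_TOL``) are always dropped.
    Fitted attributes: ``retained_`` and ``excluded_`` (column name lists).
    """

    def __init__(self, skew_limit: float = 2.0, kurt_limit: float = 7.0,
                 mode: str = "moments", alpha: float = 0.05):
        self.skew_limit = skew_limit
        self.kurt_limit = kurt_limit
        self.mode = mode
        self.alpha = alpha

    def fit(self, X, y=None):
        X = _check_matrix(X)
        values = X.to_numpy()
        keep = np.ones(X.shape[1], dtype=bool)
        variances = values.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        keep &= variances >= CONSTANT_TOL
        if self.mode == "moments":
            with np.errstate(invalid="ignore", divide="ignore"):
                skew = stats.skew(values, axis=0, bias=False)
                kurt = stats.kurtosis(values, axis=0, bias=False)  # excess
                keep &= (np.abs(skew) <= self.skew_limit) & (np.abs(kurt) <= self.kurt_limit)
        elif self.mode == "test":
            for j in np.flatnonzero(keep):
                _, p = stats.normaltest(values[:, j])
                if p < self.alpha:
                    keep[j] = False
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.retained_ = [c for c, k in zip(X.columns, keep) if k]
        self.excluded_ = [c for c, k in zip(X.columns, keep) if not k]
        return self

    def transform(self, X):
        X = _check_matrix(X)
        return X.loc[:, self.retained_]


class Autoscaler(TransformerMixin, BaseEstimator):
    """Mean-center and scale each descriptor to unit (n-1) variance.

    Constant columns are dropped and recorded in ``dropped_``. Fitted
    attributes ``centers_`` and ``scales_`` are pandas Series indexed by the
    retained descriptor names.
    """

    def fit(self, X, y=None):
        X = _check_matrix(X)
        var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else pd.Series(0.0, index=X.columns)
        keep = var >= CONSTANT_TOL
        if not keep.any():
            raise PreprocessingError("all descriptor columns are constant")
        self.dropped_ = list(X.columns[~keep])
        kept = X.loc[:, keep]
        self.centers_ = kept.mean(axis=0)
        self.scales_ = kept.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        X = _check_matrix(X)
        missing = [c for c in self.centers_.index if c not in X.columns]
        if missing:
            raise PreprocessingError(f"matrix lacks fitted descriptors: {missing[:5]}")
        return (X.loc[:, self.centers_.index] - self.centers_) / self.scales_

    def inverse_transform(self, X):
        X = _check_matrix(X)
        return X * self.scales_ + self.centers_


class DescriptorPreprocessor(TransformerMixin, BaseEstimator):
    """Cube-root -> normality filter -> autoscale, with one fitted state.

    The fitted state (retained descriptors, centers, scales) is derived from
    the training matrix only; ``transform`` applies it unchanged to new
    compounds. ``cube_root`` and the filter limits are constructor
    parameters so variants can be configured per run.
    """

    def __init__(self, cube_root: bool = True, normality: bool = True,
                 skew_limit: float = 2.0, kurt_limit: float = 7.0,
                 mode: str = "moments", alpha: float = 0.05):
        self.cube_root = cube_root
        self.normality = normality
        self.skew_limit = skew_limit
        self.kurt_limit = kurt_limit
        self.mode = mode
        self.alpha = alpha

    def fit(self, X, y=None):
        X = _check_matrix(X)
        if self.cube_root:
            X = signed_cube_root(X)
        if self.normality:
            self.filter_ = NormalityFilter(
                self.skew_limit, self.kurt_limit, self.mode, self.alpha).fit(X)
            X = self.filter_.transform(X)
            if X.shape[1] == 0:
                raise PreprocessingError("normality filter excluded every descriptor")
        else:
            self.filter_ = None
        self.scaler_ = Autoscaler().fit(X)
        self.retained_ = list(self.scaler_.centers_.index)
        return self

    def transform(self, X):
        X = _check_matrix(X)
        if self.cube_root:
            X = signed_cube_root(X)
        if self.filter_ is not None:
            X = self.filter_.transform(X)
        return self.scaler_.transform(X)

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        state = {
            "cube_root": bool(self.cube_root),
            "normality": bool(self.normality),
            "skew_limit": float(self.skew_limit),
            "kurt_limit": float(self.kurt_limit),
            "mode": self.mode,
            "alpha": float(self.alpha),
            "excluded": self.filter_.excluded_ if self.filter_ is not None else [],
            "retained": self.retained_,
            "centers": {k: float(v) for k, v in self.scaler_.centers_.items()},
            "scales": {k: float(v) for k, v in self.scaler_.scales_.items()},
        }
        Path(path).write_text(yaml.safe_dump(state, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DescriptorPreprocessor":
        state = yaml.safe_load(Path(path).read_text())
        obj = cls(cube_root=state["cube_root"], normality=state["normality"],
                  skew_limit=state["skew_limit"], kurt_limit=state["kurt_limit"],
                  mode=state["mode"], alpha=state["alpha"])
        if obj.normality:
            obj.filter_ = NormalityFilter(obj.skew_limit, obj.kurt_limit, obj.mode, obj.alpha)
            obj.filter_.retained_ = state["retained"]
            obj.filter_.excluded_ = state["excluded"]
        else:
            obj.filter_ = None
        obj.scaler_ = Autoscaler()
        obj.scaler_.centers_ = pd.Series(state["centers"]).loc[state["retained"]]
        obj.scaler_.scales_ = pd.Series(state["scales"]).loc[state["retained"]]
        obj.scaler_.dropped_ = []
        obj.retained_ = list(state["retained"])
        return obj
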