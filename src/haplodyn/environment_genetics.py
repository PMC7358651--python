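"""Environmental PCA and diversity ~ environmental-variance regressions.

Environmental conditions (19 bioclim-style climate variables plus
elevation) are extracted at jittered replicate localities, decorrelated by
a standardized (correlation-matrix) principal component analysis — the
variables mix degrees Celsius, millimetres and metres, so unit-variance
scaling is required — and the within-group variances of the two leading
component scores serve as predictors in ordinary least-squares regressions
of genetic diversity (haplotype or nucleotide) on environmental variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .rasters import Raster

__all__ = [
    "EnvMatrix",
    "PcaResult",
    "RegressionResult",
    "extract_environment",
    "env_pca",
    "group_variance",
    "diversity_regression",
]


@dataclass
class EnvMatrix:
    """Replicate x variable environmental matrix with population labels."""

    data: pd.DataFrame  # columns = layer names
    populations: pd.Series  # row -> population
    n_dropped_nodata: int = 0


def extract_environment(
    layers: dict[str, Raster],
    replicates: dict[str, np.ndarray],
) -> EnvMatrix:
    """One row per replicate per population; nodata rows are dropped."""
    names = list(layers)
    ref = layers[names[0]]
    for n in names[1:]:
        if not ref.same_geometry(layers[n]):
            raise ValueError(f"layer geometry mismatch: {names[0]} vs {n}")
    rows, pops = [], []
    dropped = 0
    for pop, reps in replicates.items():
        kept = 0
        for lat, lon in reps:
            values = [layers[n].sample_nearest(lat, lon) for n in names]
            if any(np.isnan(v) for v in values):
                dropped += 1
                continue
            rows.append(values)
            pops.append(pop)
            kept += 1
        if kept == 0:
            raise ValueError(f"all replicates on nodata for population {pop}")
    data = pd.DataFrame(rows, columns=names)
    return EnvMatrix(data, pd.Series(pops, name="population"), dropped)


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # rows x components
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)


def env_pca(matrix: EnvMatrix, n_components: int | None = None) -> PcaResult:
    """Correlation-matrix PCA of the environmental matrix.

    Columns are standardized to zero mean and unit variance; zero-variance
    columns are dropped with a warning.  Components are ordered by
    decreasing variance and signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    data = matrix.data
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    sd = data.std(ddof=0)
    dropped = list(data.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
        data = data.drop(columns=dropped)
        sd = sd.drop(dropped)
    standardized = (data - data.mean()) / sd
    k = n_components or min(standardized.shape)
    k = min(k, min(standardized.shape))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(standardized.to_numpy())
    loadings = pca.components_.T.copy()
    for c in range(k):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comp_names),
        scores=pd.DataFrame(scores, columns=comp_names, index=data.index),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
    )


def group_variance(
    scores: pd.DataFrame,
    groups: pd.Series | dict,
    components: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """Sample variance (ddof=1) of member scores per group and component."""
    groups = pd.Series(groups)
    if len(groups) != len(scores):
        raise ValueError("group labels must match score rows")
    out = {}
    for g, idx in scores.groupby(groups.to_numpy()).groups.items():
        sub = scores.loc[idx, list(components)]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 score rows")
        out[g] = sub.var(ddof=1)
    frame = pd.DataFrame(out).T
    frame.index.name = "group"
    return frame


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int
    controls: dict[str, "RegressionResult"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "n": self.n,
        }
        if self.controls:
            d["controls"] = {k: v.to_dict() for k, v in self.controls.items()}
        return d


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue ** 2),
        n=len(x),
    )


def diversity_regression(
    variances: pd.Series | dict,
    diversity: pd.Series | dict,
    sample_sizes: pd.Series | dict | None = None,
) -> RegressionResult:
    """OLS of genetic diversity on within-group environmental variance.

    Two-sided t-test p-value on the slope.  When group sample sizes are
    supplied, the sample-size control regressions (diversity ~ n and
    variance ~ n) are attached under ``controls``.
    """
    variances = pd.Series(variances).astype(float)
    diversity = pd.Series(diversity).astype(float)
    groups = [g for g in variances.index if g in diversity.index]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    x = variances[groups].to_numpy()
    y = diversity[groups].to_numpy()
    result = _ols(x, y)
    if np.allclose(y, y[0]):
        # constant response: slope 0 by convention, R^2 undefined -> 0
        result = RegressionResult(0.0, float(y[0]), 1.0, 0.0, len(x))
    if sample_sizes is not None:
        n_vec = pd.Series(sample_sizes).astype(float)[groups].to_numpy()
        result.controls["diversity_vs_n"] = _ols(n_vec, y)
        result.controls["variance_vs_n"] = _ols(n_vec, x)
    return result
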