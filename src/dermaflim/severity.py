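"""PCA-based severity scoring of standardized feature tables.

The central statistical object of the package: features extracted from
optical biopsies are individually scaled to zero mean and unit variance
(population divisor), a principal component analysis is fitted, and the
first principal component — oriented so that larger values mean more
severe skin condition — serves as a numerical severity score.  Because the
inputs are standardized, this equals correlation-matrix PCA.

The API follows the Model/Results idiom: construct a
:class:`SeverityModel` from a feature table (``from_dataframe`` for a
labelled table), call :meth:`~SeverityModel.fit`, and use the returned
:class:`SeverityResults` for scores, projections of new subjects, group
separation and clinical-score correlation.

PCA is computed by singular value decomposition of the centred, scaled
table, which is numerically equivalent to an eigendecomposition of the
correlation matrix but stabler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score as _silhouette_score

from .exceptions import (
    ConfigurationError,
    DegenerateFeatureError,
    InsufficientDataError,
    SchemaMismatchError,
    UndefinedValueError,
    ValidationError,
)
from .simulate import GROUP_ORDER

__all__ = [
    "standardize",
    "pearson_r",
    "group_separation",
    "SeverityModel",
    "SeverityResults",
]


def standardize(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Scale each column to zero mean and unit variance (divisor N).

    Returns ``(scaled, means, stds)``.  A zero-variance column cannot be
    standardized and raises ``DegenerateFeatureError`` naming it.
    """
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("feature table contains non-finite values")
    means = table.mean(axis=0)
    stds = table.std(axis=0, ddof=0)
    dead = stds.index[stds.to_numpy() == 0].tolist()
    if dead:
        raise DegenerateFeatureError(
            f"zero-variance feature column(s): {dead}"
        )
    scaled = (table - means) / stds
    return scaled, means, stds


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined for constant input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def group_separation(
    scores: pd.DataFrame, labels: pd.Series
) -> dict[str, object]:
    """Silhouette-style summary of group separation in PC1-PC2 space.

    Groups with fewer than two members are excluded (with a warning).
    Returns the mean silhouette over the retained rows plus pairwise
    differences of group means along PC1.
    """
    labels = pd.Series(labels, index=scores.index)
    counts = labels.value_counts()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        warnings.warn(
            f"excluding singleton group(s) from separation: {singletons}",
            stacklevel=2,
        )
    keep = ~labels.isin(singletons)
    labels = labels[keep]
    if labels.nunique() < 2:
        raise InsufficientDataError(
            "need >= 2 groups with >= 2 members each"
        )
    cols = [c for c in ("PC1", "PC2") if c in scores.columns]
    pts = scores.loc[keep, cols].to_numpy()
    sil = float(_silhouette_score(pts, labels.to_numpy()))
    pc1_means = scores.loc[keep, "PC1"].groupby(labels).mean()
    gaps = {
        f"{a}_vs_{b}": float(pc1_means[b] - pc1_means[a])
        for i, a in enumerate(pc1_means.index)
        for b in pc1_means.index[i + 1 :]
    }
    return {
        "silhouette": sil,
        "pc1_group_means": pc1_means.to_dict(),
        "pc1_gaps": gaps,
    }


class SeverityModel:
    """PCA severity-scoring model over a named feature table.

    Parameters
    ----------
    features
        DataFrame of finite feature values, one row per subject or site.
    groups
        Optional group label per row (control / pseudo_control / eczema /
        psoriasis) used to orient PC1 and to report separation.
    pasi, lis
        Optional clinical scores per row, enabling correlation reports.
    n_components
        Number of principal components to keep (default 2, enough for the
        PC1-PC2 score plane).
    orient
        ``"groups"`` (default): flip PC1 so the most severe group scores
        highest; ``("feature", name)``: flip so the named feature loads
        positively on PC1; ``None``: leave the SVD sign.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        groups: pd.Series | None = None,
        pasi: pd.Series | None = None,
        lis: pd.Series | None = None,
        n_components: int = 2,
        orient: object = "groups",
    ) -> None:
        features = pd.DataFrame(features).astype(float)
        n_rows, n_cols = features.shape
        if n_rows < 3 or n_cols < 2:
            raise ValidationError(
                "need at least 3 rows and 2 feature columns for PCA"
            )
        if n_components > min(n_rows - 1, n_cols):
            raise ConfigurationError(
                f"n_components={n_components} exceeds "
                f"min(rows-1, columns)={min(n_rows - 1, n_cols)}"
            )
        self.features = features
        self.groups = None if groups is None else pd.Series(
            groups, index=features.index
        )
        self.pasi = None if pasi is None else pd.Series(
            pasi, index=features.index
        )
        self.lis = None if lis is None else pd.Series(
            lis, index=features.index
        )
        self.n_components = n_components
        self.orient = orient

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_columns: list[str] | None = None,
        group_column: str | None = "group",
        pasi_column: str | None = "pasi",
        lis_column: str | None = "lis",
        **kwargs,
    ) -> "SeverityModel":
        """Build a model from one table holding features and labels."""
        meta = {c for c in (group_column, pasi_column, lis_column) if c}
        if feature_columns is None:
            feature_columns = [c for c in df.columns if c not in meta]
        groups = df[group_column] if group_column in df.columns else None
        pasi = df[pasi_column] if pasi_column in df.columns else None
        lis = df[lis_column] if lis_column in df.columns else None
        return cls(
            df[feature_columns], groups=groups, pasi=pasi, lis=lis, **kwargs
        )

    def fit(self) -> "SeverityResults":
        scaled, means, stds = standardize(self.features)
        pca = _SkPCA(n_components=self.n_components, svd_solver="full")
        raw_scores = pca.fit_transform(scaled.to_numpy())
        loadings = pd.DataFrame(
            pca.components_.T,
            index=self.features.columns,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        sign = self._orient_sign(raw_scores[:, 0], loadings)
        loadings_oriented = loadings.copy()
        loadings_oriented["PC1"] *= sign
        scores = pd.DataFrame(
            raw_scores,
            index=self.features.index,
            columns=loadings.columns,
        )
        scores["PC1"] *= sign
        return SeverityResults(
            model=self,
            feature_means=means,
            feature_stds=stds,
            loadings=loadings_oriented,
            explained_variance_ratio=np.asarray(
                pca.explained_variance_ratio_
            ),
            full_variance_ratio=self._full_spectrum(scaled),
            pc1_sign=sign,
            scores=scores,
        )

    def _orient_sign(self, pc1: np.ndarray, loadings: pd.DataFrame) -> int:
        if self.orient is None:
            return 1
        if self.orient == "groups":
            if self.groups is None or self.groups.nunique() < 2:
                warnings.warn(
                    "no usable group labels; PC1 orientation left at +1",
                    stacklevel=3,
                )
                return 1
            order = self.groups.map(GROUP_ORDER)
            if order.isna().any():
                raise ValidationError(
                    f"unknown group labels: "
                    f"{sorted(self.groups[order.isna()].unique())}"
                )
            lo = pc1[order.to_numpy() == order.min()].mean()
            hi = pc1[order.to_numpy() == order.max()].mean()
            return -1 if hi < lo else 1
        if (
            isinstance(self.orient, tuple)
            and len(self.orient) == 2
            and self.orient[0] == "feature"
        ):
            name = self.orient[1]
            if name not in loadings.index:
                raise SchemaMismatchError(
                    f"orientation feature {name!r} not in the table"
                )
            return -1 if loadings.loc[name, "PC1"] < 0 else 1
        raise ConfigurationError(f"unknown orientation {self.orient!r}")

    @staticmethod
    def _full_spectrum(scaled: pd.DataFrame) -> np.ndarray:
        x = scaled.to_numpy()
        x = x - x.mean(axis=0)
        sv = np.linalg.svd(x, compute_uv=False)
        var = sv**2
        return var / var.sum()


@dataclass
class SeverityResults:
    """Fitted standardization, rotation, orientation and scores."""

    model: SeverityModel
    feature_means: pd.Series
    feature_stds: pd.Series
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    full_variance_ratio: np.ndarray
    pc1_sign: int
    scores: pd.DataFrame
    schema_version: int = field(default=1)

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_means.index)

    def project(self, features: pd.DataFrame | pd.Series) -> pd.DataFrame:
        """Score new subjects with the fitted standardization and rotation.

        The input must carry exactly the training feature columns (order
        free); the severity score is the oriented PC1 column.
        """
        if isinstance(features, pd.Series):
            features = features.to_frame().T
        missing = [c for c in self.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in self.feature_names]
        if missing or extra:
            raise SchemaMismatchError(
                f"feature schema mismatch: missing={missing}, extra={extra}"
            )
        x = features[self.feature_names].astype(float)
        z = (x - self.feature_means) / self.feature_stds
        raw = z.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(
            raw, index=features.index, columns=list(self.loadings.columns)
        )

    def severity_scores(self) -> pd.Series:
        """Oriented PC1 score per training row."""
        return self.scores["PC1"]

    def group_separation(self) -> dict[str, object]:
        if self.model.groups is None:
            raise ValidationError("model was built without group labels")
        return group_separation(self.scores, self.model.groups)

    def pasi_correlation(self) -> float:
        """Pearson correlation of the PC1 severity score with PASI."""
        if self.model.pasi is None:
            raise ValidationError("model was built without PASI scores")
        keep = self.model.pasi.notna()
        return pearson_r(
            self.scores.loc[keep, "PC1"].to_numpy(),
            self.model.pasi[keep].to_numpy(dtype=float),
        )

    def summary(self) -> str:
        """Plain-text summary table of the fitted model."""
        lines = [
            "Severity scoring model (standardized PCA)",
            "=" * 57,
            f"rows: {len(self.scores)}   features: {len(self.feature_names)}"
            f"   components kept: {self.loadings.shape[1]}",
            f"PC1 orientation sign: {self.pc1_sign:+d}",
            "",
            "Explained variance ratio:",
        ]
        for i, r in enumerate(self.explained_variance_ratio):
            lines.append(f"  PC{i + 1}: {r:7.4f}")
        lines.append(
            f"  PC1+PC2 of total: "
            f"{self.full_variance_ratio[: min(2, len(self.full_variance_ratio))].sum():7.4f}"
        )
        lines.append("")
        lines.append("PC1 loadings (oriented):")
        for name in self.feature_names:
            lines.append(f"  {name:<40s} {self.loadings.loc[name, 'PC1']:+.4f}")
        if self.model.groups is not None and self.model.groups.nunique() >= 2:
            sep = self.group_separation()
            lines.append("")
            lines.append(
                f"group separation: silhouette = {sep['silhouette']:.3f}"
            )
            for g, m in sep["pc1_group_means"].items():
                lines.append(f"  mean PC1[{g}] = {m:+.3f}")
        if self.model.pasi is not None and self.model.pasi.notna().sum() >= 3:
            lines.append("")
            lines.append(
                f"Pearson r(PC1, PASI) = {self.pasi_correlation():+.3f}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------ io
    def to_json(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "feature_names": self.feature_names,
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "loadings": self.loadings.to_numpy().tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "full_variance_ratio": self.full_variance_ratio.tolist(),
            "pc1_sign": int(self.pc1_sign),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SeverityResults":
        with open(path) as fh:
            payload = json.load(fh)
        names = payload["feature_names"]
        loadings = pd.DataFrame(
            payload["loadings"],
            index=names,
            columns=[f"PC{i + 1}" for i in range(len(payload["loadings"][0]))],
        )
        dummy_features = pd.DataFrame(
            np.zeros((3, len(names))), columns=names
        )
        model = SeverityModel.__new__(SeverityModel)
        model.features = dummy_features
        model.groups = model.pasi = model.lis = None
        model.n_components = loadings.shape[1]
        model.orient = None
        return cls(
            model=model,
            feature_means=pd.Series(payload["feature_means"], index=names),
            feature_stds=pd.Series(payload["feature_stds"], index=names),
            loadings=loadings,
            explained_variance_ratio=np.asarray(
                payload["explained_variance_ratio"]
            ),
            full_variance_ratio=np.asarray(payload["full_variance_ratio"]),
            pc1_sign=int(payload["pc1_sign"]),
            scores=pd.DataFrame(columns=list(loadings.columns)),
            schema_version=payload["schema_version"],
        )

    def plot_scores(self, path=None, ax=None):
        """Scatter of PC1 vs PC2, coloured by group when available."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        pc2 = (
            self.scores["PC2"]
            if "PC2" in self.scores.columns
            else pd.Series(0.0, index=self.scores.index)
        )
        if self.model.groups is not None:
            for g, idx in self.scores.groupby(self.model.groups).groups.items():
                ax.scatter(
                    self.scores.loc[idx, "PC1"], pc2.loc[idx], label=str(g), s=18
                )
            ax.legend(frameon=False)
        else:
            ax.scatter(self.scores["PC1"], pc2, s=18)
        ax.set_xlabel("PC1 (severity)")
        ax.set_ylabel("PC2")
        ax.set_title("Severity score plane")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
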