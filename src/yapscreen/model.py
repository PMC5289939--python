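"""Multivariate linear shape model of the YAP nuclear/cytoplasmic ratio.

Wild-type (mock-transfected) cells are used to fit an ordinary least squares
model

    yap_ratio = x1*cellA + x2*nucA + x3*NF + x4*LCD + x5*proA + x6*proX + b0

where ``yap_ratio`` is log10(mean nuclear YAP / mean perinuclear-ring YAP).
Applying the fitted model to any cell yields a predicted ratio (``yap_pred``)
and a residual (``yap_diff = yap_ratio - yap_pred``); the residual is the
shape-normalized activation score used to separate direct YAP regulation from
changes that merely follow from morphology and crowding.

The API follows the model/results split of statsmodels:
``ShapeNormalizationModel(data).fit()`` returns a :class:`ShapeModelResults`
carrying coefficients, standard errors, standardized betas, fit diagnostics
and a ``summary()`` table. Features are deliberately *not* rescaled before
fitting; standardized betas are computed post hoc as
``beta_j = x_j * sd(feature_j) / sd(yap_ratio)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import MLR4_FEATURES, MLR6_FEATURES

__all__ = [
    "ShapeNormalizationModel",
    "ShapeModelResults",
    "reference_mlr6",
    "subsample_stability",
    "pc1_score",
    "RankDeficientDesignError",
]


class RankDeficientDesignError(ValueError):
    """Raised when the design matrix is not full rank; names the offenders."""


@dataclass
class ShapeModelResults:
    """Fitted (or packaged) shape model: coefficients plus diagnostics.

    Parameters are keyed by feature name; ``feature_order`` fixes the order
    used everywhere (serialization, summary, design matrices).
    """

    coefficients: dict[str, float]
    intercept: float
    standardized_betas: dict[str, float]
    r_squared: float
    rmse: float
    n_train: int
    feature_order: tuple[str, ...]
    plate_id: str | None = None
    std_errors: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None
    notes: dict = field(default_factory=dict)

    # ------------------------------------------------------------- predict
    def linear_predictor(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Evaluate intercept + sum_j x_j * feature_j row-wise."""
        if isinstance(features, pd.DataFrame):
            X = features.loc[:, list(self.feature_order)].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.feature_order):
                raise ValueError(
                    f"expected {len(self.feature_order)} feature columns, got {X.shape[1]}"
                )
        coef = np.array([self.coefficients[f] for f in self.feature_order])
        return self.intercept + X @ coef

    def predict(self, records: pd.DataFrame) -> pd.DataFrame:
        """Predict YAP ratios for ``records`` and compute residuals.

        Returns a table with ``yap_pred`` and, when ``yap_ratio`` is present
        in the input, ``yap_diff = yap_ratio - yap_pred``. Records with any
        missing model feature are skipped; their count is reported through a
        warning and the ``n_skipped`` attribute of the result.
        """
        missing_cols = [f for f in self.feature_order if f not in records.columns]
        if missing_cols:
            raise KeyError(f"records lack model feature columns: {missing_cols}")
        feats = records.loc[:, list(self.feature_order)]
        ok = feats.notna().all(axis=1)
        n_skipped = int((~ok).sum())
        if n_skipped:
            warnings.warn(f"skipped {n_skipped} records with missing features")
        out = pd.DataFrame(index=records.index)
        if "cell_id" in records.columns:
            out["cell_id"] = records["cell_id"]
        out["yap_pred"] = np.nan
        out.loc[ok, "yap_pred"] = self.linear_predictor(feats.loc[ok])
        if "yap_ratio" in records.columns:
            out["yap_diff"] = records["yap_ratio"] - out["yap_pred"]
        out.attrs["n_skipped"] = n_skipped
        return out

    # ------------------------------------------------------------- reporting
    def summary(self) -> str:
        lines = [
            f"Shape model ({len(self.feature_order)} features)"
            + (f", plate {self.plate_id}" if self.plate_id else ""),
            f"n_train = {self.n_train}   R^2 = {self.r_squared:.4f}   RMSE = {self.rmse:.4f}",
            f"{'term':<12}{'coef':>14}{'std err':>12}{'beta':>10}",
        ]
        se = self.std_errors or {}
        ise = f"{self.intercept_se:12.4g}" if self.intercept_se is not None else " " * 12
        lines.append(f"{'intercept':<12}{self.intercept:14.6g}{ise}{'':>10}")
        for f_ in self.feature_order:
            s = f"{se[f_]:12.4g}" if f_ in se else " " * 12
            lines.append(
                f"{f_:<12}{self.coefficients[f_]:14.6g}{s}"
                f"{self.standardized_betas.get(f_, float('nan')):10.4f}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------- serialization
    def to_json(self) -> str:
        payload = {
            "feature_order": list(self.feature_order),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "standardized_betas": self.standardized_betas,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_train": self.n_train,
            "plate_id": self.plate_id,
            "std_errors": self.std_errors,
            "intercept_se": self.intercept_se,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ShapeModelResults":
        d = json.loads(text)
        d["feature_order"] = tuple(d["feature_order"])
        return cls(**d)


class ShapeNormalizationModel:
    """OLS model of yap_ratio on shape/context features, statsmodels-backed.

    Parameters
    ----------
    records : DataFrame
        One row per cell with the feature columns and ``yap_ratio``. Pass
        QC-passing wild-type cells only; rows with missing values in the
        model columns are dropped.
    feature_set : {"MLR6", "MLR4"} or sequence of column names
        The six-feature model, the four-feature variant without the
        protrusion terms, or an explicit column list.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        feature_set: str | Sequence[str] = "MLR6",
        plate_id: str | None = None,
    ):
        if isinstance(feature_set, str):
            try:
                features = {"MLR6": MLR6_FEATURES, "MLR4": MLR4_FEATURES}[feature_set.upper()]
            except KeyError:
                raise ValueError(f"unknown feature_set {feature_set!r}") from None
        else:
            features = tuple(feature_set)
        missing = [f for f in (*features, "yap_ratio") if f not in records.columns]
        if missing:
            raise KeyError(f"records lack columns: {missing}")
        data = records.loc[:, [*features, "yap_ratio"]].dropna()
        if len(data) < len(features) + 2:
            raise ValueError(
                f"need at least {len(features) + 2} complete records, got {len(data)}"
            )
        self.feature_order = features
        self.plate_id = plate_id
        self.endog = data["yap_ratio"].to_numpy(dtype=float)
        self.exog = data.loc[:, list(features)].to_numpy(dtype=float)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        feature_set: str | Sequence[str] = "MLR6",
        plate_id: str | None = None,
        qc_pass_only: bool = True,
    ) -> "ShapeNormalizationModel":
        """Build from a feature table, honouring QC and border flags."""
        if qc_pass_only and "qc_flags" in records.columns:
            flags = records["qc_flags"].fillna("")
            records = records.loc[flags.str.len() == 0]
        return cls(records, feature_set=feature_set, plate_id=plate_id)

    def fit(self) -> ShapeModelResults:
        X = sm.add_constant(self.exog, has_constant="add")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            culprits = [
                f for j, f in enumerate(self.feature_order)
                if np.std(self.exog[:, j]) == 0
            ] or list(self.feature_order)
            raise RankDeficientDesignError(
                f"design matrix rank {rank} < {X.shape[1]}; "
                f"collinear or constant features: {culprits}"
            )
        res = sm.OLS(self.endog, X).fit()
        coefs = dict(zip(self.feature_order, res.params[1:]))
        ses = dict(zip(self.feature_order, res.bse[1:]))
        sd_y = float(np.std(self.endog, ddof=0))
        betas = {
            f: float(coefs[f] * np.std(self.exog[:, j], ddof=0) / sd_y)
            for j, f in enumerate(self.feature_order)
        }
        rmse = float(np.sqrt(np.mean(res.resid**2)))
        return ShapeModelResults(
            coefficients={k: float(v) for k, v in coefs.items()},
            intercept=float(res.params[0]),
            standardized_betas=betas,
            r_squared=float(res.rsquared),
            rmse=rmse,
            n_train=len(self.endog),
            feature_order=self.feature_order,
            plate_id=self.plate_id,
            std_errors={k: float(v) for k, v in ses.items()},
            intercept_se=float(res.bse[0]),
        )


def subsample_stability(
    records: pd.DataFrame,
    iterations: int = 10,
    per_plate_n: int = 500,
    seed: int = 0,
    feature_set: str | Sequence[str] = "MLR6",
    plate_col: str = "plate_id",
) -> pd.DataFrame:
    """Coefficient stability under repeated random subsampling.

    Refits the model ``iterations`` times on ``per_plate_n`` cells drawn
    without replacement from each plate (all rows treated as one plate when
    ``plate_col`` is absent) and reports the mean and SD of every coefficient
    including the intercept.
    """
    rng = np.random.default_rng(seed)
    groups = (
        [g for _, g in records.groupby(plate_col)]
        if plate_col in records.columns
        else [records]
    )
    for g in groups:
        if per_plate_n > len(g):
            raise ValueError(
                f"per_plate_n={per_plate_n} exceeds available records ({len(g)})"
            )
    rows = []
    for _ in range(iterations):
        parts = [
            g.iloc[rng.choice(len(g), size=per_plate_n, replace=False)] for g in groups
        ]
        sub = pd.concat(parts, ignore_index=True)
        res = ShapeNormalizationModel(sub, feature_set=feature_set).fit()
        rows.append({"intercept": res.intercept, **res.coefficients})
    draws = pd.DataFrame(rows)
    return pd.DataFrame({"mean": draws.mean(), "sd": draws.std(ddof=1 if iterations > 1 else 0)})


def pc1_score(feature_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """First principal component score of standardized morphology features.

    Features are z-scored before the decomposition; scores are centered and
    the sign is fixed so that PC1 correlates positively with the first
    column (cell area in the canonical ordering).
    """
    if isinstance(feature_matrix, pd.DataFrame):
        X = feature_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 features")
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("constant feature matrix: PC1 undefined")
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the centered standardized matrix; scores = U*s of first component
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, 0] * s[0]
    anchor = X[:, 0] if sd[0] > 0 else Z[:, 0]
    if np.corrcoef(scores, anchor)[0, 1] < 0:
        scores = -scores
    return scores


#: Printed reference coefficients of the published six-feature model.
#: Note: the published table pairs a negative nucA coefficient with a
#: positive standardized beta, which a single OLS fit cannot produce; the
#: betas are stored verbatim under ``standardized_betas`` with a note, and a
#: warning is attached at construction.
_REFERENCE_MLR6 = {
    "coefficients": {
        "cellA": 3.242e-5,
        "nucA": -4.743e-3,
        "NF": -0.1413,
        "LCD": -3.201e-2,
        "proA": 3.86e-5,
        "proX": -0.1357,
    },
    "intercept": 0.6145,
    "standardized_betas": {
        "cellA": 0.2252,
        "nucA": 0.3449,
        "NF": -0.2282,
        "LCD": -0.4345,
        "proA": 0.0342,
        "proX": -0.1988,
    },
    "r_squared": 0.4776,
    "rmse": 0.1054,
}


def reference_mlr6() -> ShapeModelResults:
    """The packaged published six-feature model, for worked examples.

    This object reproduces the printed coefficient table verbatim. It is a
    documentation/teaching artifact: synthetic screens are always scored
    with a model fitted to their own control cells, never with this one.
    """
    return ShapeModelResults(
        coefficients=dict(_REFERENCE_MLR6["coefficients"]),
        intercept=_REFERENCE_MLR6["intercept"],
        standardized_betas=dict(_REFERENCE_MLR6["standardized_betas"]),
        r_squared=_REFERENCE_MLR6["r_squared"],
        rmse=_REFERENCE_MLR6["rmse"],
        n_train=0,
        feature_order=MLR6_FEATURES,
        plate_id="reference",
        notes={
            "warning": (
                "published table: nucA coefficient is negative while its "
                "standardized beta is positive; a single OLS fit cannot "
                "produce this, so the beta is presumed a typo and both "
                "printed values are stored verbatim"
            )
        },
    )
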