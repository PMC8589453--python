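"""Biological-age estimators: the Klemera-Doubal method (variant 1) and
multiple linear regression.

KDM1 inverts the per-biomarker calibration regressions.  For each gender,
each biomarker j is regressed on CA in training controls, giving an
intercept q_j, slope k_j and residual sd s_j.  A new subject's biological
age is then the precision-weighted combination of the per-biomarker
stand-alone age estimates (x_j - q_j) / k_j:

    BA = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j k_j^2 / s_j^2

which is exactly the weighted-least-squares minimiser of
sum_j ((x_j - q_j - k_j BA) / s_j)^2 over BA.  Chronological age itself is
not an input to the estimate (that CA-augmented refinement is the "KDM2"
variant, not implemented here).

MLR instead regresses CA directly on the biomarker panel and reads the
fitted value as BA.  Because the biomarkers measure CA with noise, these
predictions shrink toward the mean training age ("regression to the
mean"), which flattens the BA-vs-CA slope relative to KDM1 — the classic
argument for preferring KDM.

Both models are fitted per gender and applied out-of-sample; subjects whose
gender has no trained sub-model are rejected rather than pooled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, PredictionError

__all__ = ["KDMModel", "MLRModel", "fit_kdm", "predict_kdm", "fit_mlr", "predict_mlr"]

# Floor on s_j when forming KDM weights, so that an (essentially) noise-free
# calibration degrades gracefully to an equal-weight average of the
# per-biomarker age estimates instead of dividing by zero.
_S_FLOOR = 1e-12


@dataclass
class KDMModel:
    """Per-gender, per-biomarker calibration triples (q_j, k_j, s_j).

    ``s_j`` is the residual root-mean-square with denominator n - 2.
    """

    panel: tuple[str, ...]
    params: dict[str, dict[str, tuple[float, float, float]]]
    n_train: dict[str, int] = field(default_factory=dict)
    panel_id: str = "custom"

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimator": "kdm1",
                "panel": list(self.panel),
                "panel_id": self.panel_id,
                "params": {
                    g: {m: list(t) for m, t in per.items()}
                    for g, per in self.params.items()
                },
                "n_train": self.n_train,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KDMModel":
        obj = json.loads(text)
        return cls(
            panel=tuple(obj["panel"]),
            params={
                g: {m: tuple(t) for m, t in per.items()}
                for g, per in obj["params"].items()
            },
            n_train={g: int(n) for g, n in obj.get("n_train", {}).items()},
            panel_id=obj.get("panel_id", "custom"),
        )


@dataclass
class MLRModel:
    """Per-gender linear model BA = b0 + sum_j b_j x_j."""

    panel: tuple[str, ...]
    coef: dict[str, tuple[float, np.ndarray]]  # gender -> (b0, b vector)
    n_train: dict[str, int] = field(default_factory=dict)
    panel_id: str = "custom"

    def to_json(self) -> str:
        return json.dumps(
            {
                "estimator": "mlr",
                "panel": list(self.panel),
                "panel_id": self.panel_id,
                "coef": {g: [b0, list(b)] for g, (b0, b) in self.coef.items()},
                "n_train": self.n_train,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLRModel":
        obj = json.loads(text)
        return cls(
            panel=tuple(obj["panel"]),
            coef={
                g: (float(b0), np.asarray(b, dtype=float))
                for g, (b0, b) in obj["coef"].items()
            },
            n_train={g: int(n) for g, n in obj.get("n_train", {}).items()},
            panel_id=obj.get("panel_id", "custom"),
        )


def _per_gender(train: pd.DataFrame, gender_column: str):
    for gender, stratum in train.groupby(gender_column, sort=True):
        yield str(gender), stratum


def fit_kdm(
    train: pd.DataFrame,
    panel: list[str] | tuple[str, ...],
    ca_column: str = "ca",
    gender_column: str = "gender",
    panel_id: str = "custom",
) -> KDMModel:
    """Calibrate KDM1 on control training data, per gender.

    For each gender and biomarker, OLS of the biomarker on CA yields
    (q_j, k_j); s_j is the residual RMS with denominator n - 2.
    """
    panel = tuple(panel)
    params: dict[str, dict[str, tuple[float, float, float]]] = {}
    n_train: dict[str, int] = {}
    for gender, stratum in _per_gender(train, gender_column):
        ca = stratum[ca_column].to_numpy(dtype=float)
        per: dict[str, tuple[float, float, float]] = {}
        for name in panel:
            if name not in stratum.columns:
                raise FitError(f"panel biomarker {name!r} absent from training table")
            x = stratum[name].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(ca))
            n = int(ok.sum())
            if n < 3:
                raise FitError(f"{gender}/{name}: need >= 3 complete rows, have {n}")
            if np.std(x[ok]) == 0.0:
                raise FitError(
                    f"biomarker {name!r} is constant in {gender} training data"
                )
            A = np.column_stack([np.ones(n), ca[ok]])
            coefs, _, _, _ = np.linalg.lstsq(A, x[ok], rcond=None)
            q, k = float(coefs[0]), float(coefs[1])
            resid = x[ok] - (q + k * ca[ok])
            s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
            per[name] = (q, k, s)
        if all(t[1] == 0.0 for t in per.values()):
            raise FitError(f"no biomarker has a nonzero CA slope in {gender} stratum")
        params[gender] = per
        n_train[gender] = len(stratum)
    if not params:
        raise FitError("training table is empty")
    return KDMModel(panel=panel, params=params, n_train=n_train, panel_id=panel_id)


def predict_kdm(
    model: KDMModel,
    subjects: pd.DataFrame,
    gender_column: str = "gender",
) -> pd.DataFrame:
    """KDM1 biological age for each subject, using the gender-matched model.

    Returns a frame with columns ``subject_id, ba, estimator, panel_id,
    gender``.  CA is deliberately not used.
    """
    for name in model.panel:
        if name not in subjects.columns:
            raise PredictionError(f"panel biomarker {name!r} absent from subjects")
    out_ba = np.full(len(subjects), np.nan)
    genders = subjects[gender_column].astype(str).to_numpy()
    unknown = set(genders) - set(model.params)
    if unknown:
        raise PredictionError(
            f"no trained sub-model for gender(s) {sorted(unknown)}; "
            "models are fitted per gender and subjects are not pooled"
        )
    X = subjects[list(model.panel)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PredictionError("missing biomarker values; impute or exclude first")
    for gender, per in model.params.items():
        mask = genders == gender
        if not mask.any():
            continue
        q = np.array([per[m][0] for m in model.panel])
        k = np.array([per[m][1] for m in model.panel])
        s = np.maximum(np.array([per[m][2] for m in model.panel]), _S_FLOOR)
        w = k**2 / s**2
        num = (X[mask] - q) @ (k / s**2)
        out_ba[mask] = num / w.sum()
    result = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "ba": out_ba,
            "estimator": "kdm1",
            "panel_id": model.panel_id,
            "gender": genders,
        }
    )
    return result


def fit_mlr(
    train: pd.DataFrame,
    panel: list[str] | tuple[str, ...],
    ca_column: str = "ca",
    gender_column: str = "gender",
    panel_id: str = "custom",
) -> MLRModel:
    """OLS of CA on the biomarker panel, per gender."""
    panel = tuple(panel)
    coef: dict[str, tuple[float, np.ndarray]] = {}
    n_train: dict[str, int] = {}
    for gender, stratum in _per_gender(train, gender_column):
        for name in panel:
            if name not in stratum.columns:
                raise FitError(f"panel biomarker {name!r} absent from training table")
        X = stratum[list(panel)].to_numpy(dtype=float)
        y = stratum[ca_column].to_numpy(dtype=float)
        ok = ~(np.isnan(X).any(axis=1) | np.isnan(y))
        Xo, yo = X[ok], y[ok]
        design = np.column_stack([np.ones(len(Xo)), Xo])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            corr = np.corrcoef(Xo, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise FitError(
                f"rank-deficient design in {gender} stratum; most collinear "
                f"pair: {panel[worst[0]]!r} / {panel[worst[1]]!r}"
            )
        beta, _, _, _ = np.linalg.lstsq(design, yo, rcond=None)
        coef[gender] = (float(beta[0]), beta[1:].copy())
        n_train[gender] = int(ok.sum())
    if not coef:
        raise FitError("training table is empty")
    return MLRModel(panel=panel, coef=coef, n_train=n_train, panel_id=panel_id)


def predict_mlr(
    model: MLRModel,
    subjects: pd.DataFrame,
    gender_column: str = "gender",
) -> pd.DataFrame:
    """Apply the stored linear form BA = b0 + sum_j b_j x_j, gender-matched."""
    for name in model.panel:
        if name not in subjects.columns:
            raise PredictionError(f"panel biomarker {name!r} absent from subjects")
    genders = subjects[gender_column].astype(str).to_numpy()
    unknown = set(genders) - set(model.coef)
    if unknown:
        raise PredictionError(
            f"no trained sub-model for gender(s) {sorted(unknown)}"
        )
    X = subjects[list(model.panel)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise PredictionError("missing biomarker values; impute or exclude first")
    out_ba = np.full(len(subjects), np.nan)
    for gender, (b0, b) in model.coef.items():
        mask = genders == gender
        if mask.any():
            out_ba[mask] = b0 + X[mask] @ b
    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "ba": out_ba,
            "estimator": "mlr",
            "panel_id": model.panel_id,
            "gender": genders,
        }
    )
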