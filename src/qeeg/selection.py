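"""Training-set construction and the logistic-regression feature screen.

Three designs are built from the feature table:

* SET 1 -- every feature at every channel and state (13 x channels x 2),
* SET 2 -- the channel-averaged features (13 x 2 = 26 columns),
* SET 3 -- the SET 2 columns whose univariate logistic regression against the
  outcome (SF = 1) is significant at p < alpha, without multiplicity
  correction.

Features are standardised before the screen, so odds ratios are per one
standard deviation of the feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import FEATURE_NAMES
from .recording import STATES

#: |beta| beyond which a fit is flagged as (quasi-)separated.
_SEPARATION_BETA = 15.0


@dataclass
class LRResult:
    """Univariate logistic-regression summary for one feature."""

    feature_name: str
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    separated: bool = False


@dataclass
class DesignMatrix:
    set_id: int
    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    subject_ids: list[str]

    @property
    def shape(self):
        return self.X.shape


def _as_label_series(labels, subject_ids) -> pd.Series:
    if isinstance(labels, pd.Series):
        return labels.reindex(subject_ids)
    labels = np.asarray(labels)
    return pd.Series(labels, index=subject_ids)


def _pivot(table: pd.DataFrame, channels: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Wide frame: one row per subject, columns ordered feature-within-state
    -within-channel (channel outermost)."""
    cols, names = [], []
    sub = table.set_index(["channel", "state", "subject_id"]).sort_index()
    for ch in channels:
        for state in STATES:
            try:
                block = sub.loc[(ch, state)]
            except KeyError:
                raise ValueError(f"missing rows for channel={ch!r}, state={state!r}")
            for feat in FEATURE_NAMES:
                name = f"{feat}|{state}" if ch == "avg" else f"{feat}|{state}|{ch}"
                cols.append(block[feat])
                names.append(name)
    wide = pd.concat(cols, axis=1)
    wide.columns = names
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing subject-state rows for subjects {missing}")
    return wide, names


def build_design_matrix(
    table: pd.DataFrame,
    labels,
    set_id: int,
    selected_features: list[str] | None = None,
    alpha: float = 0.05,
) -> DesignMatrix:
    """Assemble the design matrix for one of the three training sets.

    For SET 3, ``selected_features`` (SET 2 column names) may be passed in;
    otherwise the logistic screen is run internally at level ``alpha``.
    """
    if set_id not in (1, 2, 3):
        raise ValueError("set_id must be 1, 2 or 3")
    if set_id == 1:
        channels = [c for c in table["channel"].unique() if c != "avg"]
        channels = sorted(channels, key=list(table["channel"].unique()).index)
        wide, names = _pivot(table, list(channels))
    else:
        wide, names = _pivot(table, ["avg"])
        if set_id == 3:
            if selected_features is None:
                selected_features, _ = select_features(table, labels, alpha=alpha)
            unknown = [f for f in selected_features if f not in names]
            if unknown:
                raise ValueError(f"selected features not in SET 2: {unknown}")
            wide = wide[selected_features]
            names = list(selected_features)

    y = _as_label_series(labels, list(wide.index))
    if y.isna().any():
        raise ValueError("labels missing for some subjects in the feature table")
    return DesignMatrix(
        set_id=set_id,
        X=wide.to_numpy(dtype=float),
        feature_names=names,
        y=y.to_numpy(dtype=int),
        subject_ids=list(wide.index),
    )


def fit_univariate_lr(x: np.ndarray, y: np.ndarray,
                      feature_name: str = "x") -> LRResult:
    """Maximum-likelihood logistic fit of y on (1, x) with Wald inference.

    OR = exp(beta); the 95 % CI is exp(beta +/- 1.96 SE).  Complete or
    quasi-complete separation is flagged (infinite |beta| indicator) rather
    than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")

    design = sm.add_constant(x)
    separated = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA:
            separated = True
    except Exception:
        separated = True
        beta = np.nan

    if separated:
        sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
        binf = np.inf * sign
        return LRResult(feature_name, binf, np.inf, np.exp(binf) if sign > 0 else 0.0,
                        np.nan, np.nan, 0.0, separated=True)

    or_value = float(np.exp(beta))
    ci_low = float(np.exp(beta - 1.96 * se))
    ci_high = float(np.exp(beta + 1.96 * se))
    p = float(fit.pvalues[1])
    return LRResult(feature_name, beta, se, or_value, ci_low, ci_high, p)


def select_features(table: pd.DataFrame, labels, alpha: float = 0.05):
    """Univariate logistic screen over the 26 channel-averaged features.

    Each feature is standardised (mean 0, SD 1) and regressed against the
    outcome; features with Wald p < alpha are selected, with no
    multiple-testing correction.  Returns (selected names ordered by
    ascending p, full results frame).
    """
    design = build_design_matrix(table, labels, set_id=2)
    results = []
    for j, name in enumerate(design.feature_names):
        col = design.X[:, j]
        sd = col.std()
        if sd < 1e-12:
            results.append(
                LRResult(name, 0.0, np.inf, 1.0, np.nan, np.nan, 1.0)
            )
            continue
        z = (col - col.mean()) / sd
        results.append(fit_univariate_lr(z, design.y, feature_name=name))

    frame = pd.DataFrame(
        {
            "feature_name": [r.feature_name for r in results],
            "beta": [r.beta for r in results],
            "or_value": [r.or_value for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "separated": [r.separated for r in results],
        }
    )
    frame["selected"] = frame["p_value"] < alpha
    selected = (
        frame[frame["selected"]]
        .sort_values("p_value")["feature_name"]
        .tolist()
    )
    return selected, frame
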