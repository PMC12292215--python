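"""One-factor-at-a-time sensitivity and Shapley-value feature attribution.

Both analyses operate on *any* fitted predictor through a plain callable
``predict_fn(X) -> (n,)`` over the natural-unit feature table (the seven
numeric design variables plus the three one-hot type indicators), so they
apply uniformly to the neural surrogate, a random forest, or any test
model.

Shapley values use the interventional (marginal) expectation: a feature
absent from a coalition is replaced by its value in rows drawn from a
background sample, and the coalition's worth is the mean prediction over
those hybrid rows.  The exact estimator enumerates all 2^n coalitions
(capped at n = 13); the sampled estimator averages marginal contributions
over random feature permutations and reports Monte-Carlo standard errors.
Efficiency (base value + sum of attributions = prediction) holds by
construction for the exact estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

EXACT_FEATURE_CAP = 13


@dataclass
class SensitivityCurve:
    feature: str
    grid: np.ndarray          # feature values, natural units
    response: np.ndarray      # (n_grid,) or (n_grid, n_targets)
    target: str | None = None


@dataclass
class AttributionResult:
    """Shapley attribution of one prediction against a background sample."""

    phi: np.ndarray           # per-feature Shapley values, target units
    base_value: float         # expected prediction over the background
    prediction: float         # model output at the explained design
    feature_names: list
    standard_error: np.ndarray | None = None  # sampled estimator only

    def to_series(self) -> pd.Series:
        return pd.Series(self.phi, index=self.feature_names)


def ofat_sensitivity(predict_fn, X: pd.DataFrame, feature: str,
                     n_grid: int = 25, target: str | None = None,
                     categorical: bool = False) -> SensitivityCurve:
    """Vary one feature over its observed range, others at training means.

    ``X`` is the natural-unit feature frame the model was trained against;
    the response is evaluated on an evenly spaced grid between the
    feature's min and max (or its distinct levels when ``categorical``).
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in the dataset")
    col = X[feature].to_numpy(dtype=float)
    if categorical:
        grid = np.unique(col)
    else:
        grid = np.linspace(col.min(), col.max(), n_grid)
    base = X.mean(axis=0)
    probe = pd.DataFrame([base] * len(grid)).reset_index(drop=True)
    probe[feature] = grid
    response = np.asarray(predict_fn(probe.to_numpy(dtype=float)))
    return SensitivityCurve(feature=feature, grid=grid, response=response,
                            target=target)


def _as_matrix(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def exact_shapley(predict_fn, x, background, feature_names=None,
                  batch_rows: int = 200_000) -> AttributionResult:
    """Exact Shapley values by full coalition enumeration.

    ``x`` is the explained row (n_features,), ``background`` an
    (n_background, n_features) sample defining the interventional
    expectation.  Cost is 2^n coalition values, each averaged over the
    background, evaluated in bounded batches.
    """
    x = _as_matrix(x).ravel()
    bg = np.atleast_2d(_as_matrix(background))
    n = x.size
    if n > EXACT_FEATURE_CAP:
        raise ValueError(
            f"{n} features exceed the exact-enumeration cap "
            f"{EXACT_FEATURE_CAP}; use sampled_shapley instead")
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(n)]
    masks = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)

    # v(S) = mean over background rows of f(x_S, b_{~S})
    nb = len(bg)
    v = np.empty(2 ** n)
    rows_per_chunk = max(1, batch_rows // nb)
    for start in range(0, 2 ** n, rows_per_chunk):
        chunk = masks[start:start + rows_per_chunk]
        hybrid = np.where(chunk[:, None, :], x[None, None, :], bg[None, :, :])
        preds = np.asarray(predict_fn(hybrid.reshape(-1, n)), dtype=float)
        v[start:start + len(chunk)] = preds.reshape(len(chunk), nb).mean(axis=1)

    sizes = masks.sum(axis=1)
    # Shapley kernel weight |S|! (n-|S|-1)! / n! indexed by coalition size
    w = np.array([1.0 / (comb(n - 1, s) * n) for s in range(n)])
    phi = np.zeros(n)
    for i in range(n):
        without = ~masks[:, i]
        idx = np.flatnonzero(without)
        gain = v[idx | (1 << i)] - v[idx]
        phi[i] = float((w[sizes[idx]] * gain).sum())
    return AttributionResult(
        phi=phi, base_value=float(v[0]),
        prediction=float(v[-1]), feature_names=names)


def sampled_shapley(predict_fn, x, background, n_permutations: int = 50,
                    seed: int = 0, feature_names=None) -> AttributionResult:
    """Permutation-sampling Shapley estimator (unbiased), with MC errors.

    Each permutation walks features in a random order, measuring the
    marginal change in the background-averaged prediction as each feature
    switches from its background value to the explained row's value.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = _as_matrix(x).ravel()
    bg = np.atleast_2d(_as_matrix(background))
    n = x.size
    nb = len(bg)
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        # hybrid rows after adding each feature in order, background-stacked
        hybrids = np.empty((n + 1, nb, n))
        hybrids[0] = bg
        current = bg.copy()
        for step, feat in enumerate(order, start=1):
            current = current.copy()
            current[:, feat] = x[feat]
            hybrids[step] = current
        preds = np.asarray(
            predict_fn(hybrids.reshape(-1, n)), dtype=float
        ).reshape(n + 1, nb).mean(axis=1)
        contrib[p, order] = np.diff(preds)
    phi = contrib.mean(axis=0)
    se = (contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
          if n_permutations > 1 else np.full(n, np.nan))
    base = float(np.asarray(predict_fn(bg), dtype=float).mean())
    pred = float(np.asarray(predict_fn(x[None, :]), dtype=float)[0])
    return AttributionResult(phi=phi, base_value=base, prediction=pred,
                             feature_names=names, standard_error=se)


def summary_attributions(predict_fn, X: pd.DataFrame,
                         background: pd.DataFrame | None = None,
                         method: str = "sampled", n_samples: int | None = None,
                         n_permutations: int = 30, n_background: int = 100,
                         seed: int = 0) -> pd.DataFrame:
    """Per-sample, per-feature attributions for a group (beeswarm data).

    Returns a long-form frame (sample, feature, value, phi) with a
    ``rank`` column ordering features by mean |phi| (1 = most influential).
    ``background`` defaults to ``n_background`` rows of ``X`` drawn with
    the given seed.
    """
    rng = np.random.default_rng(seed)
    if background is None:
        idx = rng.choice(len(X), size=min(n_background, len(X)),
                         replace=False)
        background = X.iloc[idx]
    rows = X
    if n_samples is not None and n_samples < len(X):
        idx = rng.choice(len(X), size=n_samples, replace=False)
        rows = X.iloc[idx]
    bg = background.to_numpy(dtype=float)
    names = list(X.columns)
    records = []
    for pos, (label, row) in enumerate(rows.iterrows()):
        xrow = row.to_numpy(dtype=float)
        if method == "exact":
            res = exact_shapley(predict_fn, xrow, bg, feature_names=names)
        elif method == "sampled":
            res = sampled_shapley(predict_fn, xrow, bg,
                                  n_permutations=n_permutations,
                                  seed=seed + pos, feature_names=names)
        else:
            raise ValueError("method must be 'exact' or 'sampled'")
        for j, name in enumerate(names):
            rec = {"sample": label, "feature": name,
                   "value": xrow[j], "phi": res.phi[j]}
            if res.standard_error is not None:
                rec["se"] = res.standard_error[j]
            records.append(rec)
    out = pd.DataFrame(records)
    ranking = (out.groupby("feature")["phi"].apply(lambda s: s.abs().mean())
               .rank(ascending=False, method="min").astype(int))
    out["rank"] = out["feature"].map(ranking)
    return out


def feature_ranking(attributions: pd.DataFrame) -> pd.Series:
    """Mean |phi| per feature, most influential first."""
    return (attributions.groupby("feature")["phi"]
            .apply(lambda s: s.abs().mean())
            .sort_values(ascending=False))


__all__ = [
    "EXACT_FEATURE_CAP", "SensitivityCurve", "AttributionResult",
    "ofat_sensitivity", "exact_shapley", "sampled_shapley",
    "summary_attributions", "feature_ranking",
]
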