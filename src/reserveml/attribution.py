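"""Variable importance and Shapley attributions for trained proxies.

Importance is total split gain per feature, normalised to sum to one.
Per-prediction attributions are path-dependent tree Shapley values computed
by the boosted ensemble itself (``pred_contribs``), which satisfy local
accuracy exactly: base value plus the per-feature attributions reproduce the
model prediction for every row.  Missing feature values are flagged so
beeswarm exports can colour them as a distinct category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .proxy import TrainedProxy

__all__ = [
    "ImportanceTable",
    "AttributionMatrix",
    "gain_importance",
    "shap_attributions",
    "beeswarm_export",
    "plot_importance",
    "plot_beeswarm",
]


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # columns: feature, importance, rank


@dataclass
class AttributionMatrix:
    values: pd.DataFrame        # rows x features
    base_value: float
    missing_mask: pd.DataFrame  # same shape, bool
    row_ids: np.ndarray


def gain_importance(proxy: TrainedProxy) -> ImportanceTable:
    """Split-gain importance per feature, normalised to sum to 1.

    Features never used by any tree get importance 0.  Ranks are descending,
    ties broken by position in the proxy's feature order.  A model with no
    splits at all yields all-zero importances.
    """
    booster = proxy.model.get_booster()
    raw = booster.get_score(importance_type="gain")
    gains = np.array([raw.get(name, 0.0) for name in proxy.feature_order], dtype=float)
    total = gains.sum()
    importance = gains / total if total > 0 else gains
    order = np.lexsort((np.arange(len(gains)), -importance))
    ranks = np.empty(len(gains), dtype=int)
    ranks[order] = np.arange(1, len(gains) + 1)
    table = pd.DataFrame(
        {
            "feature": list(proxy.feature_order),
            "importance": importance,
            "rank": ranks,
        }
    )
    return ImportanceTable(table=table)


def shap_attributions(proxy: TrainedProxy, rows: pd.DataFrame) -> AttributionMatrix:
    """Path-dependent tree Shapley attributions for each row.

    Satisfies local accuracy: ``base_value + sum(attributions) == prediction``
    for every row (up to float tolerance).
    """
    missing_cols = set(proxy.feature_order) - set(rows.columns)
    if missing_cols:
        raise KeyError(f"rows lack feature columns: {sorted(missing_cols)}")
    X = rows[list(proxy.feature_order)]
    dmat = xgb.DMatrix(X, missing=np.nan, feature_names=list(proxy.feature_order))
    contribs = proxy.model.get_booster().predict(dmat, pred_contribs=True)
    values = pd.DataFrame(
        contribs[:, :-1], columns=list(proxy.feature_order), index=X.index
    )
    base = float(np.mean(contribs[:, -1]))
    mask = X.isna()
    ids = rows["id"].to_numpy() if "id" in rows.columns else X.index.to_numpy()
    return AttributionMatrix(values=values, base_value=base, missing_mask=mask, row_ids=ids)


def beeswarm_export(attr: AttributionMatrix, rows: pd.DataFrame) -> pd.DataFrame:
    """Long-format (feature, attribution, feature value, row id) table.

    Missing feature values are carried as the string category ``"MISSING"``
    rather than dropped, so plots can colour them separately.
    """
    features = list(attr.values.columns)
    X = rows[features]
    records = []
    for i, rid in enumerate(attr.row_ids):
        for f in features:
            missing = bool(attr.missing_mask.iloc[i][f])
            records.append(
                {
                    "row_id": rid,
                    "feature": f,
                    "attribution": float(attr.values.iloc[i][f]),
                    "feature_value": "MISSING" if missing else float(X.iloc[i][f]),
                }
            )
    return pd.DataFrame.from_records(records)


def plot_importance(importance: ImportanceTable, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = importance.table.sort_values("rank", ascending=False)
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(table) + 1))
    ax.barh(table["feature"], table["importance"], color="#4878d0")
    ax.set_xlabel("relative importance (gain)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_beeswarm(attr: AttributionMatrix, rows: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = list(attr.values.columns)
    order = attr.values.abs().mean().sort_values().index
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(features) + 1))
    rng = np.random.default_rng(0)
    for j, f in enumerate(order):
        vals = attr.values[f].to_numpy()
        raw = rows[f].to_numpy(dtype=float)
        missing = attr.missing_mask[f].to_numpy()
        jitter = rng.normal(0, 0.08, len(vals))
        finite = raw[~missing]
        if finite.size and np.ptp(finite) > 0:
            colour_vals = (raw - np.nanmin(raw)) / (np.nanmax(raw) - np.nanmin(raw))
        else:
            colour_vals = np.zeros(len(raw))
        ax.scatter(vals[~missing], j + jitter[~missing], c=colour_vals[~missing],
                   cmap="viridis", s=8)
        ax.scatter(vals[missing], j + jitter[missing], color="grey", s=8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order)
    ax.set_xlabel("Shapley attribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
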