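"""Control analyses: metadata->label predictability and PIP-space colorings.

The predictability control asks whether the class label can be predicted
from acquisition metadata alone — if it can, the metadata leaks label
information and the proxy task is confounded.  With labels assigned
independently of the metadata the control accuracy should be statistically
indistinguishable from chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = ["ControlResult", "JoinError", "pip_label_control", "stat_coloring"]


class JoinError(KeyError):
    """Embedding ids missing from the statistics table."""


@dataclass(frozen=True)
class ControlResult:
    """Mean accuracy over repeated splits with a 95% normal-approximation CI."""

    mean_accuracy: float
    ci_halfwidth: float
    n_repeats: int
    accuracies: tuple = ()

    def covers(self, value: float) -> bool:
        return abs(self.mean_accuracy - value) <= self.ci_halfwidth


def pip_label_control(pip_table: pd.DataFrame, labels, n_repeats: int = 20,
                      seed: int = 0, *, test_size: float = 0.3,
                      n_estimators: int = 100) -> ControlResult:
    """Tree-ensemble label-from-metadata predictability check.

    Runs ``n_repeats`` stratified 70/30 train/test splits, fitting a
    random forest on the numeric PIP columns only.  The 95% CI uses the
    Nadeau-Bengio variance correction for repeated random splits,
    ``1.96 * sd * sqrt(1/n + test/train)``: the repeats share rows, so the
    naive ``sd/sqrt(n)`` scaling would shrink below the estimator's true
    variance and undercover.
    """
    x = pip_table.to_numpy(float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(y) != len(x):
        raise ValueError("labels length must match the table")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2 ** 31 - 1, size=n_repeats)
    accs = []
    for rs in split_seeds:
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=test_size, stratify=y, random_state=int(rs) % (2 ** 32 - 1))
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=int(rs) % (2 ** 32 - 1))
        clf.fit(xtr, ytr)
        accs.append(float((clf.predict(xte) == yte).mean()))
    accs = np.array(accs)
    sd = accs.std(ddof=1) if n_repeats > 1 else 0.0
    nb_factor = np.sqrt(1.0 / n_repeats + test_size / (1.0 - test_size))
    return ControlResult(
        mean_accuracy=float(accs.mean()),
        ci_halfwidth=float(1.96 * sd * nb_factor),
        n_repeats=n_repeats,
        accuracies=tuple(accs),
    )


def stat_coloring(embedding, stats_table: pd.DataFrame,
                  *, labels=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-image statistics onto PC coordinates for coloring the space.

    ``stats_table`` must be indexed by (or carry an ``image_id`` column of)
    the embedding's ids.  Returns the joined table plus a Spearman
    rank-correlation matrix (statistic x PC axis).
    """
    stats_df = stats_table.set_index("image_id") if "image_id" in stats_table.columns \
        else stats_table
    missing = [i for i in embedding.image_ids if i not in stats_df.index]
    if missing:
        raise JoinError(f"ids missing from stats table: {missing[:10]}"
                        + ("..." if len(missing) > 10 else ""))
    k = embedding.points.shape[1]
    out = pd.DataFrame(embedding.points, columns=[f"pc{i+1}" for i in range(k)])
    out.insert(0, "image_id", list(embedding.image_ids))
    out["domain"] = list(embedding.domains)
    aligned = stats_df.loc[list(embedding.image_ids)]
    for col in aligned.columns:
        out[col] = aligned[col].to_numpy()
    if labels is not None:
        out["label"] = np.asarray(labels)

    stat_cols = [c for c in aligned.columns if pd.api.types.is_numeric_dtype(aligned[c])]
    corr = pd.DataFrame(index=stat_cols, columns=[f"pc{i+1}" for i in range(k)],
                        dtype=float)
    for sc in stat_cols:
        vals = out[sc].to_numpy(float)
        for i in range(k):
            if np.ptp(vals) == 0:
                corr.loc[sc, f"pc{i+1}"] = 0.0
            else:
                rho = stats.spearmanr(out[f"pc{i+1}"], vals).statistic
                corr.loc[sc, f"pc{i+1}"] = 0.0 if np.isnan(rho) else float(rho)
    return out, corr
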