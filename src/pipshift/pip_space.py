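"""Standardized PCA space over per-image acquisition metadata.

The 12 physical imaging parameters are z-scored (population sd, fitted on the
combined all-domain table) and projected onto principal components; Euclidean
distance from the training centroid in this space is the proxy for domain
divergence.  Ring-shaped regions at increasing centroid distance define the
out-of-distribution test-set sampling scheme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .sim_xray import PIP_FIELDS

__all__ = [
    "Standardizer",
    "PCAModel",
    "Embedding",
    "RingRegion",
    "EmptyTableError",
    "DegenerateColumnError",
    "ShortfallError",
    "clean_pips",
    "fit_standardizer",
    "standardize",
    "fit_pca",
    "embed",
    "centroid",
    "centroid_distance",
    "ring_partition",
    "quantile_radii",
    "sample_test_set",
    "biplot_loadings",
    "scree",
    "save_space",
    "load_space",
]

log = logging.getLogger(__name__)


class EmptyTableError(ValueError):
    """Cleaning removed every row of the PIP table."""


class DegenerateColumnError(ValueError):
    """A column has zero variance and cannot be z-scored."""


class ShortfallError(ValueError):
    """A sampling region lacks the requested number of members for a class."""


# ---------------------------------------------------------------------------
# cleaning and standardization
# ---------------------------------------------------------------------------


def clean_pips(table: pd.DataFrame) -> pd.DataFrame:
    """Retain the 12 numeric PIP columns and drop incomplete rows.

    Non-PIP columns (including any text metadata) are removed; cells that do
    not parse as numbers become missing and their rows are dropped.
    """
    present = [c for c in PIP_FIELDS if c in table.columns]
    numeric = table[present].apply(pd.to_numeric, errors="coerce")
    kept = numeric.dropna(axis=0)
    n_cols_dropped = table.shape[1] - len(present)
    n_rows_dropped = len(numeric) - len(kept)
    if n_cols_dropped or n_rows_dropped:
        log.info("clean_pips: dropped %d non-PIP columns, %d incomplete rows",
                 n_cols_dropped, n_rows_dropped)
    if kept.empty:
        raise EmptyTableError("no complete rows remain after cleaning")
    return kept


@dataclass(frozen=True)
class Standardizer:
    """Per-column z-score parameters (population standard deviation)."""

    columns: tuple
    means: np.ndarray
    sds: np.ndarray


def fit_standardizer(table: pd.DataFrame) -> Standardizer:
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    means = table.mean(axis=0).to_numpy(float)
    sds = table.std(axis=0, ddof=0).to_numpy(float)
    for col, mean, sd in zip(table.columns, means, sds):
        # tolerance absorbs float accumulation on constant columns
        if sd <= 1e-12 * max(1.0, abs(mean)):
            raise DegenerateColumnError(f"column {col!r} has zero variance")
    return Standardizer(tuple(table.columns), means, sds)


def standardize(table: pd.DataFrame, s: Standardizer) -> pd.DataFrame:
    missing = set(s.columns) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks fitted columns: {sorted(missing)}")
    ordered = table[list(s.columns)]
    return (ordered - s.means) / s.sds


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal loadings with a fixed sign convention.

    Components are eigenvectors of the sample covariance ordered by
    decreasing eigenvalue; each component is flipped so its
    largest-magnitude loading is positive, making the embedding
    reproducible across linear-algebra backends.
    """

    columns: tuple
    loadings: np.ndarray                 # (n_components, n_features)
    explained_variance: np.ndarray       # eigenvalues
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass(frozen=True)
class Embedding:
    """Points in PC coordinates with image ids and domain labels."""

    points: np.ndarray
    image_ids: tuple
    domains: tuple

    def __len__(self) -> int:
        return len(self.points)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(table: pd.DataFrame, n_components: int = 2) -> PCAModel:
    if n_components > table.shape[1]:
        raise ValueError("n_components exceeds the number of columns")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(table.to_numpy(float))
    return PCAModel(
        columns=tuple(table.columns),
        loadings=_fix_signs(sk.components_),
        explained_variance=sk.explained_variance_.copy(),
        explained_variance_ratio=sk.explained_variance_ratio_.copy(),
        mean=sk.mean_.copy(),
    )


def embed(table: pd.DataFrame, model: PCAModel, *, image_ids=None,
          domains=None) -> Embedding:
    x = table[list(model.columns)].to_numpy(float)
    points = (x - model.mean) @ model.loadings.T
    n = len(points)
    ids = tuple(image_ids) if image_ids is not None else tuple(f"row{i}" for i in range(n))
    doms = tuple(domains) if domains is not None else ("",) * n
    if len(ids) != n or len(doms) != n:
        raise ValueError("image_ids/domains length must match table rows")
    return Embedding(points, ids, doms)


def reconstruct(embedding: Embedding, model: PCAModel) -> np.ndarray:
    """Map PC coordinates back to (standardized) feature space."""
    return embedding.points @ model.loadings + model.mean


# ---------------------------------------------------------------------------
# centroids, rings, sampling
# ---------------------------------------------------------------------------


def centroid(embedding: Embedding, subset=None) -> np.ndarray:
    """Coordinate-wise mean of the selected points (all points by default)."""
    if subset is None:
        pts = embedding.points
    else:
        idx = np.asarray(list(subset), dtype=int)
        pts = embedding.points[idx] if idx.size else np.empty((0,))
    if len(pts) == 0:
        raise ValueError("cannot take the centroid of an empty subset")
    return pts.mean(axis=0)


def centroid_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


@dataclass(frozen=True)
class RingRegion:
    """Annulus in PC space: r_inner <= distance from center < r_outer."""

    name: str
    center: np.ndarray
    r_inner: float
    r_outer: float
    member_indices: tuple = ()
    member_ids: tuple = ()


def ring_partition(embedding: Embedding, center: np.ndarray,
                   radii) -> list[RingRegion]:
    """Partition points into half-open annuli between consecutive radii.

    ``radii`` must be strictly increasing and start at 0; ring k covers
    ``[radii[k], radii[k+1])`` so every point within the outermost radius
    belongs to exactly one ring.  Ring 0 (the innermost disk) is the
    conventional training region.
    """
    radii = list(map(float, radii))
    if len(radii) < 2 or radii[0] != 0.0 or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing and start at 0")
    center = np.asarray(center, float)
    d = np.linalg.norm(embedding.points - center, axis=1)
    rings = []
    for k in range(len(radii) - 1):
        sel = np.flatnonzero((d >= radii[k]) & (d < radii[k + 1]))
        rings.append(RingRegion(
            name=f"ring{k}", center=center, r_inner=radii[k], r_outer=radii[k + 1],
            member_indices=tuple(int(i) for i in sel),
            member_ids=tuple(embedding.image_ids[i] for i in sel),
        ))
    return rings


def quantile_radii(embedding: Embedding, center: np.ndarray,
                   fractions) -> list[float]:
    """Radii at given quantiles of the distance-from-center distribution,
    prefixed with 0 — a data-driven way to keep every ring populated."""
    d = np.linalg.norm(embedding.points - np.asarray(center, float), axis=1)
    qs = np.quantile(d, list(fractions))
    return [0.0] + [float(q) for q in qs]


def sample_test_set(member_ids, labels, n_per_class: int, seed: int) -> list:
    """Draw a class-balanced sample of ids, uniform without replacement.

    ``labels`` maps id -> class.  Raises :class:`ShortfallError` naming the
    class when a class has fewer than ``n_per_class`` members.
    """
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for mid in member_ids:
        by_class.setdefault(labels[mid], []).append(mid)
    chosen = []
    for cls in sorted(by_class):
        pool = by_class[cls]
        if len(pool) < n_per_class:
            raise ShortfallError(
                f"class {cls!r} has {len(pool)} members, need {n_per_class}")
        take = rng.choice(len(pool), size=n_per_class, replace=False)
        chosen.extend(pool[i] for i in take)
    return chosen


# ---------------------------------------------------------------------------
# loadings diagnostics
# ---------------------------------------------------------------------------


def biplot_loadings(model: PCAModel) -> pd.DataFrame:
    """Correlation-scaled 2-D feature vectors for a biplot.

    Each input feature gets the vector ``loading * sqrt(eigenvalue)`` in the
    first two components; on standardized data these are the feature-PC
    correlations, so vector lengths are at most 1 and longer vectors mark
    features contributing more to the plane.
    """
    if model.n_components < 2:
        raise ValueError("biplot requires at least 2 components")
    vecs = model.loadings[:2].T * np.sqrt(model.explained_variance[:2])
    return pd.DataFrame(vecs, index=list(model.columns), columns=["pc1", "pc2"])


def scree(model: PCAModel) -> np.ndarray:
    """Explained-variance ratio per component, in order."""
    return model.explained_variance_ratio.copy()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_space(path, standardizer: Standardizer, model: PCAModel) -> None:
    """Serialize the fitted standardizer + PCA model to JSON for exact reload."""
    payload = {
        "standardizer": {
            "columns": list(standardizer.columns),
            "means": standardizer.means.tolist(),
            "sds": standardizer.sds.tolist(),
        },
        "pca": {
            "columns": list(model.columns),
            "loadings": model.loadings.tolist(),
            "explained_variance": model.explained_variance.tolist(),
            "explained_variance_ratio": model.explained_variance_ratio.tolist(),
            "mean": model.mean.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_space(path) -> tuple[Standardizer, PCAModel]:
    with open(path) as fh:
        payload = json.load(fh)
    s = payload["standardizer"]
    p = payload["pca"]
    return (
        Standardizer(tuple(s["columns"]), np.array(s["means"]), np.array(s["sds"])),
        PCAModel(tuple(p["columns"]), np.array(p["loadings"]),
                 np.array(p["explained_variance"]),
                 np.array(p["explained_variance_ratio"]), np.array(p["mean"])),
    )
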