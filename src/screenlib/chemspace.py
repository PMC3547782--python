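"""2-D chemical-space projection: autoscaled PCA and dense-region contours.

A model is fit on any descriptor matrix drawn from the store: columns are
autoscaled (centred, unit variance) and the two leading principal
components retained, so projecting the training mean gives (0, 0).

The contour marks the densely populated region of a projected reference
library: the most isolated points (ranked by mean k-nearest-neighbour
distance) are excluded as outliers, the remainder is bootstrap-resampled,
each resample's convex hull is taken, and the hulls are averaged radially
about the centroid on a fixed angular grid into a single star-shaped
polygon.  This "average convex hull" is deliberately softer than the plain
hull: it traces where the mass of the library lives rather than its
extreme points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon
from sklearn.decomposition import PCA

from .store import MoleculeStore, Scope


@dataclass
class PCAModel:
    descriptor_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (2, n_descriptors), rows orthonormal
    explained_var: np.ndarray  # fraction per component, descending

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps({
            "descriptor_names": self.descriptor_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_var": self.explained_var.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=d["descriptor_names"],
            means=np.asarray(d["means"]),
            scales=np.asarray(d["scales"]),
            loadings=np.asarray(d["loadings"]),
            explained_var=np.asarray(d["explained_var"]),
        )


def descriptor_matrix(
    store: MoleculeStore, mol_ids: Sequence[int], descriptor_names: Sequence[str]
) -> tuple[np.ndarray, list[int]]:
    """Descriptor rows for ``mol_ids``; rows with missing values dropped."""
    rows, kept = [], []
    for mol_id in mol_ids:
        d = store.get_record(mol_id).descriptors.as_dict()
        try:
            rows.append([float(d[name]) for name in descriptor_names])
        except KeyError:
            continue
        kept.append(mol_id)
    return np.asarray(rows, dtype=float), kept


def fit_pca_matrix(X: np.ndarray, descriptor_names: Sequence[str]) -> PCAModel:
    """Autoscaled 2-component PCA on a data matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >=3 rows and >=2 descriptors")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales[scales == 0] = 1.0  # constant column carries no variance
    Z = (X - means) / scales
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    return PCAModel(
        descriptor_names=list(descriptor_names),
        means=means,
        scales=scales,
        loadings=pca.components_.copy(),
        explained_var=pca.explained_variance_ratio_.copy(),
    )


def fit_pca(
    store: MoleculeStore, descriptor_names: Sequence[str], scope: Scope = None
) -> PCAModel:
    X, _ = descriptor_matrix(store, store.resolve_scope(scope), descriptor_names)
    return fit_pca_matrix(X, descriptor_names)


@dataclass
class Projection:
    mol_ids: list[int]
    coords: np.ndarray  # (n, 2)


def project_matrix(model: PCAModel, X: np.ndarray) -> np.ndarray:
    Z = (np.asarray(X, dtype=float) - model.means) / model.scales
    return Z @ model.loadings.T


def project(model: PCAModel, store: MoleculeStore, scope: Scope = None) -> Projection:
    X, kept = descriptor_matrix(store, store.resolve_scope(scope), model.descriptor_names)
    return Projection(mol_ids=kept, coords=project_matrix(model, X))


@dataclass
class Contour:
    vertices: np.ndarray  # (m, 2), closed implicitly
    fraction_enclosed: float  # measured on the non-outlier reference points

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains_points(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        poly = self.polygon.buffer(tol)
        return np.array([poly.contains(Point(*p)) for p in np.atleast_2d(pts)])


def _knn_outliers(pts: np.ndarray, outlier_fraction: float, k: int = 5) -> np.ndarray:
    """Boolean mask of the retained (non-outlier) points."""
    n = len(pts)
    n_out = int(round(outlier_fraction * n))
    if n_out == 0:
        return np.ones(n, dtype=bool)
    from sklearn.neighbors import NearestNeighbors

    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)
    isolation = dist[:, 1:].mean(axis=1)
    keep = np.ones(n, dtype=bool)
    keep[np.argsort(isolation)[-n_out:]] = False
    return keep


def _hull_radii(hull_pts: np.ndarray, centre: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from ``centre`` to the hull boundary along each angle."""
    poly = Polygon(hull_pts)
    reach = 4.0 * max(np.linalg.norm(hull_pts - centre, axis=1).max(), 1e-12)
    radii = np.empty(len(angles))
    boundary = poly.exterior
    for i, a in enumerate(angles):
        ray = LineString(
            [centre, centre + reach * np.array([np.cos(a), np.sin(a)])]
        )
        hit = boundary.intersection(ray)
        if hit.is_empty:  # centre on the boundary of a degenerate hull
            radii[i] = 0.0
            continue
        pts = (
            [hit] if isinstance(hit, Point)
            else list(getattr(hit, "geoms", []))
        )
        dists = []
        for g in pts:
            for c in getattr(g, "coords", [g.coords[0]] if hasattr(g, "coords") else []):
                dists.append(np.linalg.norm(np.asarray(c) - centre))
        radii[i] = max(dists) if dists else 0.0
    return radii


def fit_contour(
    projection: Union[Projection, np.ndarray],
    outlier_fraction: float = 0.02,
    n_resamples: int = 100,
    seed: int = 0,
    n_angles: int = 360,
    target_fraction: Optional[float] = None,
) -> Contour:
    """Average-convex-hull contour of a 2-D point cloud.

    The bootstrap-averaged hull is calibrated radially so that at least
    ``target_fraction`` (default ``1 - outlier_fraction``) of the
    non-outlier points fall inside it.  With ``n_resamples=1`` and
    ``outlier_fraction=0`` this reduces to the plain convex hull.
    """
    pts = projection.coords if isinstance(projection, Projection) else np.asarray(projection)
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    if target_fraction is None:
        target_fraction = 1.0 - outlier_fraction
    keep = _knn_outliers(pts, outlier_fraction)
    core = pts[keep]
    centre = core.mean(axis=0)
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    rng = np.random.default_rng(seed)
    radii = np.zeros(n_angles)
    for r in range(n_resamples):
        if n_resamples == 1:
            sample = core
        else:
            sample = core[rng.integers(0, len(core), size=len(core))]
        try:
            hull = ConvexHull(sample)
        except Exception:  # degenerate resample (collinear) — skip
            radii += _hull_radii(core[ConvexHull(core).vertices], centre, angles) / n_resamples
            continue
        radii += _hull_radii(sample[hull.vertices], centre, angles) / n_resamples
    radii *= _calibration_scale(core, centre, angles, radii, target_fraction)
    unit = np.column_stack([np.cos(angles), np.sin(angles)])
    contour = Contour(vertices=centre + radii[:, None] * unit, fraction_enclosed=0.0)
    contour.fraction_enclosed = float(contour.contains_points(core).mean())
    # the angular grid discretises the boundary; nudge outward if a boundary
    # point fell between grid angles
    for _ in range(20):
        if contour.fraction_enclosed >= target_fraction:
            break
        radii *= 1.005
        contour = Contour(vertices=centre + radii[:, None] * unit, fraction_enclosed=0.0)
        contour.fraction_enclosed = float(contour.contains_points(core).mean())
    return contour


def _calibration_scale(
    core: np.ndarray,
    centre: np.ndarray,
    angles: np.ndarray,
    radii: np.ndarray,
    target_fraction: float,
) -> float:
    """Scale factor putting ``target_fraction`` of the core points inside the
    radial polygon (quantile of point-radius / contour-radius ratios)."""
    rel = core - centre
    point_r = np.linalg.norm(rel, axis=1)
    point_a = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    idx = np.minimum(
        np.round(point_a / (2 * np.pi) * len(angles)).astype(int), len(angles) - 1
    )
    contour_r = np.maximum(radii[idx], 1e-12)
    ratios = np.sort(point_r / contour_r)
    k = min(int(np.ceil(target_fraction * len(ratios))), len(ratios)) - 1
    return float(max(ratios[max(k, 0)], 1e-12)) * (1 + 1e-9)


def xy_plot_data(
    store: MoleculeStore,
    prop_x: str,
    prop_y: str,
    scope: Scope = None,
    highlight: Scope = None,
) -> pd.DataFrame:
    """(id, x, y, highlighted) rows for every molecule in scope that has both
    properties; molecules missing either are dropped (count via the index)."""
    mol_ids = store.resolve_scope(scope)
    marked = set(store.resolve_scope(highlight)) if highlight is not None else set()
    rows = []
    for mol_id in mol_ids:
        d = store.get_record(mol_id).descriptors.as_dict()
        x = d.get(prop_x, store.get_property("default", mol_id, prop_x))
        y = d.get(prop_y, store.get_property("default", mol_id, prop_y))
        if x is None or y is None:
            continue
        rows.append((mol_id, float(x), float(y), mol_id in marked))
    return pd.DataFrame(rows, columns=["id", "x", "y", "highlighted"])
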