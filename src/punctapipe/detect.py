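"""Trainable spot detection: multi-scale blob features, random-forest voxel
classification, 26-connected component grouping and ellipsoidal ROIs.

The feature set is deliberately rotation-invariant — per scale, the
scale-normalized Laplacian of Gaussian plus the three eigenvalues of the
scale-normalized Hessian — so arbitrarily oriented dendrites and puncta
produce the same responses.  Scales are physical (µm); anisotropic voxels
are handled by smoothing with per-axis sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .volume import ImageVolume

#: 26-connected neighborhood: all voxels sharing a face, edge or corner.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


# ------------------------------------------------------------------ features

@dataclass
class FeatureStack:
    """Per-voxel feature vectors on the detection grid.

    ``data`` has shape (n_features, z, y, x); ``names`` are stable across
    runs (scale value embedded in the name).
    """

    data: np.ndarray
    names: list[str]
    scales_um: tuple[float, ...]
    voxel_size: tuple[float, float, float]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def matrix(self) -> np.ndarray:
        """Flattened (n_voxels, n_features) design matrix."""
        return self.data.reshape(self.n_features, -1).T

    def at(self, voxels_zyx: np.ndarray) -> np.ndarray:
        """(n, n_features) feature rows at the given voxel indices."""
        v = np.atleast_2d(voxels_zyx)
        return self.data[:, v[:, 0], v[:, 1], v[:, 2]].T


def _symmetric_eigvals_3x3(h: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of symmetric 3x3 matrices, closed form.

    ``h`` is (..., 6) packed as (zz, yy, xx, zy, zx, yx).  Uses the
    trigonometric solution of the characteristic cubic, which is exact for
    symmetric matrices and fully vectorized.
    """
    a, b, c, d, e, f = (h[..., i] for i in range(6))
    # matrix [[a, d, e], [d, b, f], [e, f, c]]
    q = (a + b + c) / 3.0
    da, db, dc = a - q, b - q, c - q
    p2 = (da ** 2 + db ** 2 + dc ** 2 + 2.0 * (d ** 2 + e ** 2 + f ** 2)) / 6.0
    p = np.sqrt(np.maximum(p2, 0.0))
    # det of (H - qI) / p
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(
            p > 0,
            (da * (db * dc - f ** 2) - d * (d * dc - f * e) + e * (d * f - db * e))
            / np.where(p > 0, 2.0 * p ** 3, 1.0),
            0.0,
        )
    r = np.clip(r, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return np.stack([e3, e2, e1], axis=-1)  # ascending


def compute_features(vol: ImageVolume, scales_um: tuple[float, ...] = (1.0, 2.0, 4.0)
                     ) -> FeatureStack:
    """Scale-normalized Laplacian and Hessian-eigenvalue features at 3 scales.

    For each scale s the volume is Gaussian-smoothed with per-axis sigma
    s/voxel_size, second derivatives are taken by central differences in
    physical units, and responses are γ-normalized (multiplied by s²) so
    that blobs of matching size give comparable magnitudes at every scale.
    """
    scales = tuple(float(s) for s in scales_um)
    if len(scales) < 3:
        raise ValueError("need at least 3 scales")
    if any(b <= a for a, b in zip(scales, scales[1:])) or scales[0] <= 0:
        raise ValueError("scales must be strictly increasing and positive")
    vs = np.asarray(vol.voxel_size)
    img = np.asarray(vol.voxels, dtype=np.float64)
    feats, names = [], []
    for s in scales:
        smoothed = ndimage.gaussian_filter(img, s / vs, mode="nearest")
        # edge-replicated pad, then textbook central differences everywhere
        S = np.pad(smoothed, 1, mode="edge")

        def sl(dz, dy, dx):
            return S[1 + dz:S.shape[0] - 1 + dz or None,
                     1 + dy:S.shape[1] - 1 + dy or None,
                     1 + dx:S.shape[2] - 1 + dx or None]

        hzz = (sl(1, 0, 0) - 2 * smoothed + sl(-1, 0, 0)) / vs[0] ** 2
        hyy = (sl(0, 1, 0) - 2 * smoothed + sl(0, -1, 0)) / vs[1] ** 2
        hxx = (sl(0, 0, 1) - 2 * smoothed + sl(0, 0, -1)) / vs[2] ** 2
        hzy = (sl(1, 1, 0) - sl(1, -1, 0) - sl(-1, 1, 0) + sl(-1, -1, 0)) \
            / (4 * vs[0] * vs[1])
        hzx = (sl(1, 0, 1) - sl(1, 0, -1) - sl(-1, 0, 1) + sl(-1, 0, -1)) \
            / (4 * vs[0] * vs[2])
        hyx = (sl(0, 1, 1) - sl(0, 1, -1) - sl(0, -1, 1) + sl(0, -1, -1)) \
            / (4 * vs[1] * vs[2])
        packed = np.stack([hzz, hyy, hxx, hzy, hzx, hyx], axis=-1)
        eig = _symmetric_eigvals_3x3(packed)  # (..., 3) ascending
        norm = s ** 2
        feats.append(norm * (hzz + hyy + hxx))
        names.append(f"log_s{s:g}")
        for k in range(3):
            feats.append(norm * eig[..., k])
            names.append(f"hess_eig{k + 1}_s{s:g}")
    data = np.stack(feats)
    return FeatureStack(data=data, names=names, scales_um=scales,
                        voxel_size=vol.voxel_size)


# ---------------------------------------------------------------- classifier

@dataclass
class VoxelClassifier:
    """Random-forest spot / no-spot voxel classifier."""

    model: RandomForestClassifier
    feature_names: list[str]
    seed: int
    n_samples_per_class: dict[str, int]
    holdout_accuracy: float

    CLASSES = ("no spot", "spot")

    def predict_spot_probability(self, features: FeatureStack) -> np.ndarray:
        if features.names != self.feature_names:
            raise ValueError("feature names at predict time differ from training")
        shape = features.data.shape[1:]
        proba = self.model.predict_proba(features.matrix())[:, 1]
        return proba.reshape(shape)

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump({"version": 1, "classifier": self}, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelClassifier":
        import joblib

        payload = joblib.load(str(path))
        if payload.get("version") != 1:
            raise ValueError("unsupported classifier file version")
        return payload["classifier"]


def train_classifier(
    features: FeatureStack,
    labels: np.ndarray,
    n_trees: int = 30,
    max_depth: int | None = 12,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> VoxelClassifier:
    """Fit the spot / no-spot random forest on sparsely labeled voxels.

    ``labels`` is an int array on the feature grid: 1 = spot, 0 = no spot,
    -1 = unlabeled.  A held-out fraction of the labeled voxels is scored to
    report generalization accuracy.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    if labels.shape != features.data.shape[1:]:
        raise ValueError("labels must be on the feature grid (-1 = unlabeled)")
    idx = np.argwhere(labels >= 0)
    y = labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need labeled voxels of both classes ('spot', 'no spot')")
    X = features.at(idx)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    model.fit(X_tr, y_tr)
    acc = float(model.score(X_te, y_te))
    counts = {"no spot": int((y == 0).sum()), "spot": int((y == 1).sum())}
    return VoxelClassifier(model=model, feature_names=list(features.names),
                           seed=seed, n_samples_per_class=counts,
                           holdout_accuracy=acc)


# -------------------------------------------------------------- segmentation

@dataclass
class SpotROI:
    """One detected synapse: a 26-connected voxel cluster and its ellipsoid.

    The ellipsoid is axis-aligned, centered on the cluster centroid, with
    semi-axes sqrt(3) * max |deviation| per axis plus half a voxel — a
    closed-form enclosing ellipsoid (every member voxel center lies inside
    or on it).
    """

    id: int
    voxels: np.ndarray  # (n, 3) int, (z, y, x)
    centroid_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    volume_voxels: int
    timepoint: int = 0

    def contains_um(self, points_um: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_um) - np.asarray(self.centroid_um)
        a = np.asarray(self.semi_axes_um)
        return np.sum((p / a) ** 2, axis=1) <= 1.0 + 1e-9


def segment_spots(
    spot_map: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_size_voxels: int = 4,
    max_size_voxels: int = 2000,
    probability_threshold: float = 0.5,
    timepoint: int = 0,
) -> list[SpotROI]:
    """Group classifier-positive voxels into ROIs.

    ``spot_map`` is a boolean mask or a spot-probability map (thresholded at
    ``probability_threshold``).  Components are found under 26-connectivity
    (voxels touching only at a corner still merge); components outside
    [min, max] voxel count are discarded.  IDs follow raster order of first
    occurrence, so output is deterministic.
    """
    mask = spot_map >= probability_threshold if spot_map.dtype != bool else spot_map
    labeled, n = ndimage.label(mask, structure=STRUCTURE_26)
    if n == 0:
        return []
    vs = np.asarray(voxel_size)
    rois: list[SpotROI] = []
    objects = ndimage.find_objects(labeled)
    next_id = 0
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        sub = labeled[slc] == lab
        count = int(sub.sum())
        if count < min_size_voxels or count > max_size_voxels:
            continue
        vox = np.argwhere(sub) + np.array([s.start for s in slc])
        pos_um = vox * vs
        centroid = pos_um.mean(axis=0)
        dev = np.abs(pos_um - centroid).max(axis=0)
        semi = np.sqrt(3.0) * dev + vs / 2.0
        rois.append(SpotROI(
            id=next_id, voxels=vox, centroid_um=tuple(centroid),
            semi_axes_um=tuple(semi), volume_voxels=count, timepoint=timepoint,
        ))
        next_id += 1
    return rois


def rois_to_table(rois: list[SpotROI]) -> pd.DataFrame:
    rows = [{
        "roi_id": r.id,
        "z_um": r.centroid_um[0], "y_um": r.centroid_um[1], "x_um": r.centroid_um[2],
        "semi_z_um": r.semi_axes_um[0], "semi_y_um": r.semi_axes_um[1],
        "semi_x_um": r.semi_axes_um[2], "volume_voxels": r.volume_voxels,
    } for r in rois]
    return pd.DataFrame(rows)


def rois_to_labelmap(rois: list[SpotROI], shape) -> np.ndarray:
    """Label volume with roi_id + 1 at member voxels (0 = background)."""
    lab = np.zeros(shape, dtype=np.int32)
    for r in rois:
        lab[r.voxels[:, 0], r.voxels[:, 1], r.voxels[:, 2]] = r.id + 1
    return lab


def rois_from_truth(truth, dilate_um: float = 0.0,
                    include_clutter: bool = False) -> list[SpotROI]:
    """Oracle ROIs built directly from phantom ground truth.

    One ROI per truth synapse (plus, optionally, per clutter granule, with
    ids continuing after the synapses): all voxels within its radius
    (+ dilate_um) of the center.  Used to test quantification and rejection
    independently of the detector.
    """
    vs = np.asarray(truth.voxel_size)
    shape = truth.volume_shape
    table = truth.synapses
    if include_clutter and len(truth.clutter):
        cl = truth.clutter.copy()
        cl["id"] = cl["id"] + len(table)
        table = pd.concat([table, cl], ignore_index=True)
    rois = []
    for _, row in table.iterrows():
        c = np.array([row.z_um, row.y_um, row.x_um])
        r_um = row.radius_um + dilate_um
        lo = np.maximum(np.floor((c - r_um) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((c + r_um) / vs).astype(int) + 1, shape)
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        d2 = np.sum(((pts * vs - c) / r_um) ** 2, axis=1)
        vox = pts[d2 <= 1.0]
        if len(vox) == 0:
            vox = np.atleast_2d(np.round(c / vs).astype(int))
        pos_um = vox * vs
        centroid = pos_um.mean(axis=0)
        dev = np.abs(pos_um - centroid).max(axis=0)
        rois.append(SpotROI(
            id=int(row.id), voxels=vox, centroid_um=tuple(centroid),
            semi_axes_um=tuple(np.sqrt(3.0) * dev + vs / 2.0),
            volume_voxels=len(vox),
        ))
    return rois


def match_centers(
    detected_um: np.ndarray,
    truth_um: np.ndarray,
    max_distance_um: float,
) -> dict:
    """Hungarian matching of detected spot centers to ground-truth centers.

    Returns precision / recall / F1 and the matched index pairs.  A match
    counts only when the pair distance is within ``max_distance_um``.
    """
    det = np.atleast_2d(detected_um)
    tru = np.atleast_2d(truth_um)
    if det.size == 0 or tru.size == 0:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0, "pairs": []}
    dmat = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    cost = np.where(dmat <= max_distance_um, dmat, 1e6)
    ri, ci = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if dmat[i, j] <= max_distance_um]
    tp = len(pairs)
    precision = tp / len(det)
    recall = tp / len(tru)
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "pairs": pairs}
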