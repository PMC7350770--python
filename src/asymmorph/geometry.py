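"""Symmetry-plane mirroring, TPS missing-landmark estimation, and GPA.

Pipeline order: :func:`estimate_missing` (complete every configuration) ->
:func:`mirror_fill` (build the symmetric reference) -> :func:`gpa` (superimpose
the focal configurations only) -> :func:`align_mirrored` (carry each mirrored
configuration into its focal specimen's Procrustes frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, LandmarkScheme


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# symmetry plane


@dataclass(frozen=True)
class SymmetryPlane:
    point: np.ndarray  # (3,)
    normal: np.ndarray  # (3,) unit

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Reflect point(s) through the plane. Involution: reflect(reflect(p)) = p."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        out = pts - 2.0 * d[:, None] * self.normal
        return out if np.asarray(points).ndim == 2 else out[0]


def fit_symmetry_plane(
    config: LandmarkConfiguration,
    scheme: LandmarkScheme,
    use_pair_midpoints: bool = False,
) -> SymmetryPlane:
    """Total-least-squares midsagittal plane.

    Anchors are the non-missing midline landmarks plus (optionally) the
    midpoints of fully observed bilateral pairs. The normal is the
    smallest-eigenvalue direction of the centered anchor scatter.
    """
    anchors = [config.coords[m] for m in scheme.midline if not config.missing[m]]
    if use_pair_midpoints:
        for l, r in scheme.pairs:
            if not config.missing[l] and not config.missing[r]:
                anchors.append(0.5 * (config.coords[l] + config.coords[r]))
    if len(anchors) < 3:
        raise GeometryError(
            f"{config.specimen_id}: cannot fit plane ({len(anchors)} anchors, need >= 3)"
        )
    A = np.asarray(anchors, dtype=float)
    centroid = A.mean(axis=0)
    _, s, vt = np.linalg.svd(A - centroid, full_matrices=False)
    # collinear anchors: second singular value vanishes relative to the first
    if s[0] <= 0 or s[1] / s[0] < 1e-12:
        raise GeometryError(f"{config.specimen_id}: cannot fit plane (collinear anchors)")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return SymmetryPlane(point=centroid, normal=normal)


# ---------------------------------------------------------------------------
# mirroring


@dataclass
class MirroredConfiguration:
    """Computer-mirrored counterpart of a focal configuration.

    Right-side landmarks are reflections of their left partners through the
    specimen's symmetry plane; left and midline landmarks are copied verbatim.
    """

    specimen_id: str
    coords: np.ndarray
    missing: np.ndarray
    source: str
    plane: SymmetryPlane | None = None


def mirror_fill(
    config: LandmarkConfiguration,
    scheme: LandmarkScheme,
    use_pair_midpoints: bool = False,
) -> MirroredConfiguration:
    """Mirror left-side landmarks onto the right to build the symmetric reference."""
    plane = fit_symmetry_plane(config, scheme, use_pair_midpoints=use_pair_midpoints)
    coords = config.coords.copy()
    missing = config.missing.copy()
    for l, r in scheme.pairs:
        if config.missing[l]:
            missing[r] = True
            coords[r] = np.nan
        else:
            coords[r] = plane.reflect(config.coords[l])
            missing[r] = False
    return MirroredConfiguration(
        specimen_id=f"{config.specimen_id}__mirror",
        coords=coords,
        missing=missing,
        source=config.specimen_id,
        plane=plane,
    )


# ---------------------------------------------------------------------------
# thin-plate spline (3D, kernel U(r) = r)


@dataclass
class TpsModel:
    """3D thin-plate spline interpolant mapping control points exactly.

    Kernel U(r) = r (volumetric spline). ``affine`` is a 4x3 matrix acting on
    [1, x, y, z]; ``weights`` is (n_control, 3). Bending energy is
    trace(W^T K W), zero iff the map is affine.
    """

    control_points: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float

    @classmethod
    def fit(cls, source: np.ndarray, target: np.ndarray) -> "TpsModel":
        src = np.asarray(source, dtype=float)
        tgt = np.asarray(target, dtype=float)
        n = src.shape[0]
        if n < 4:
            raise GeometryError(f"TPS needs >= 4 control points, got {n}")
        # non-coplanarity check: affine part must be solvable
        P = np.hstack([np.ones((n, 1)), src])
        if np.linalg.matrix_rank(P) < 4:
            raise GeometryError("TPS control points are coplanar/degenerate")
        K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
        L = np.zeros((n + 4, n + 4))
        L[:n, :n] = K
        L[:n, n:] = P
        L[n:, :n] = P.T
        rhs = np.zeros((n + 4, 3))
        rhs[:n] = tgt
        sol = np.linalg.solve(L, rhs)
        W, A = sol[:n], sol[n:]
        bending = float(np.trace(W.T @ K @ W))
        return cls(control_points=src, affine=A, weights=W, bending_energy=bending)

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        U = np.linalg.norm(pts[:, None, :] - self.control_points[None, :, :], axis=-1)
        out = np.hstack([np.ones((len(pts), 1)), pts]) @ self.affine + U @ self.weights
        return out if np.asarray(points).ndim == 2 else out[0]


def estimate_missing(
    config: LandmarkConfiguration, reference: LandmarkConfiguration
) -> LandmarkConfiguration:
    """Fill missing landmarks by TPS warp of the reference (reference -> config).

    The warp is built on the shared observed landmarks; each missing landmark
    is placed at the warp image of the reference position. Observed landmarks
    are returned unchanged; provenance is recorded in ``estimated``.
    """
    if not reference.is_complete:
        raise GeometryError("reference configuration must be complete")
    if config.is_complete:
        return config.copy()
    obs = ~config.missing
    if obs.sum() < 4:
        raise GeometryError(
            f"{config.specimen_id}: only {int(obs.sum())} observed landmarks, need >= 4"
        )
    tps = TpsModel.fit(reference.coords[obs], config.coords[obs])
    coords = config.coords.copy()
    miss_idx = np.where(config.missing)[0]
    coords[miss_idx] = tps.transform(reference.coords[miss_idx])
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        coords=coords,
        missing=np.zeros(config.n_landmarks, dtype=bool),
        estimated=tuple(int(i) for i in miss_idx),
    )


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def centroid_size(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


@dataclass
class ProcrustesTransform:
    """aligned = ((X - translation) / scale) @ rotation, det(rotation) = +1."""

    translation: np.ndarray
    scale: float
    rotation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return ((coords - self.translation) / self.scale) @ self.rotation


@dataclass
class AlignedDataset:
    specimen_ids: list[str]
    coords: np.ndarray  # (n_config, n_landmarks, 3), Procrustes units
    transforms: list[ProcrustesTransform]
    consensus: np.ndarray  # (n_landmarks, 3)
    iterations: int
    final_change: float
    objective_history: list[float] = field(default_factory=list)

    def aligned(self, specimen_id: str) -> np.ndarray:
        return self.coords[self.specimen_ids.index(specimen_id)]

    def transform_for(self, specimen_id: str) -> ProcrustesTransform:
        return self.transforms[self.specimen_ids.index(specimen_id)]


def _optimal_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimising ||moving @ R - target||_F."""
    u, _, vt = np.linalg.svd(moving.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Full generalized Procrustes superimposition with proper rotations only.

    Every configuration is centered, scaled to unit centroid size, and rotated
    to the running consensus; the consensus is re-estimated (and re-normalised
    to unit size) until its change drops below ``tol``.
    """
    if not configs:
        raise GeometryError("gpa requires at least one configuration")
    n_lm = configs[0].n_landmarks
    for c in configs:
        if not c.is_complete:
            raise GeometryError(f"{c.specimen_id}: incomplete (run estimate_missing first)")
        if c.n_landmarks != n_lm:
            raise GeometryError(f"{c.specimen_id}: landmark count mismatch")

    ids = [c.specimen_id for c in configs]
    translations, scales, shapes = [], [], []
    for c in configs:
        t = c.coords.mean(axis=0)
        s = centroid_size(c.coords)
        if s <= 0:
            raise GeometryError(f"{c.specimen_id}: zero centroid size")
        translations.append(t)
        scales.append(s)
        shapes.append((c.coords - t) / s)
    shapes = np.array(shapes)
    rotations = [np.eye(3) for _ in configs]

    if len(configs) == 1:
        return AlignedDataset(
            specimen_ids=ids,
            coords=shapes.copy(),
            transforms=[ProcrustesTransform(translations[0], scales[0], np.eye(3))],
            consensus=shapes[0].copy(),
            iterations=0,
            final_change=0.0,
        )

    consensus = shapes[0].copy()
    aligned = shapes.copy()
    change = np.inf
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(configs)):
            R = _optimal_rotation(shapes[i], consensus)
            rotations[i] = R
            aligned[i] = shapes[i] @ R
        new_consensus = aligned.mean(axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus)
        history.append(float(((aligned - new_consensus) ** 2).sum()))
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            break

    transforms = [
        ProcrustesTransform(translations[i], scales[i], rotations[i])
        for i in range(len(configs))
    ]
    return AlignedDataset(
        specimen_ids=ids,
        coords=aligned,
        transforms=transforms,
        consensus=consensus,
        iterations=it,
        final_change=change,
        objective_history=history,
    )


def align_mirrored(aligned: AlignedDataset, mirrored: MirroredConfiguration) -> np.ndarray:
    """Apply the focal specimen's Procrustes transform to its mirrored twin.

    Puts Fn and Rn in one shared frame so per-landmark radii are comparable.
    """
    if mirrored.source not in aligned.specimen_ids:
        raise GeometryError(f"unknown source specimen {mirrored.source!r}")
    if mirrored.missing.any():
        raise GeometryError(
            f"{mirrored.specimen_id}: mirrored configuration has missing landmarks"
        )
    return aligned.transform_for(mirrored.source).apply(mirrored.coords)


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Pairwise (partial) Procrustes distance between two centered unit-size shapes.

    With ``allow_reflection`` the rotation may be improper — used only as a
    test oracle; the pipeline itself never absorbs reflections.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / centroid_size(a)
    b = b / centroid_size(b)
    if allow_reflection:
        u, _, vt = np.linalg.svd(a.T @ b)
        R = u @ vt
    else:
        R = _optimal_rotation(a, b)
    return float(np.sqrt(((a @ R - b) ** 2).sum()))
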