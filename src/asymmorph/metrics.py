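"""Per-landmark asymmetry radii, specimen/group summaries, and PCA.

Radii are spherical-coordinate decompositions of the displacement between a
focal configuration (Fn) and its mirrored reference (Rn) in one Procrustes
frame: rho = ||Fn_i - Rn_i||, phi the azimuth in the consensus equatorial
plane, theta the polar angle. Only rho feeds the downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, LandmarkDataset, LandmarkScheme, SchemeError
from .geometry import AlignedDataset, centroid_size


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class RadiiRecord:
    specimen_id: str
    landmark_index: int  # 0-based
    rho: float
    phi: float  # nan when rho == 0
    theta: float  # nan when rho == 0
    estimated: bool = False


def consensus_frame(aligned: AlignedDataset) -> np.ndarray:
    """Rotation whose first two axes span the principal plane of the mean shape.

    Defines the equatorial plane for the phi/theta angles.
    """
    c = aligned.consensus - aligned.consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    frame = vt.T
    if np.linalg.det(frame) < 0:
        frame[:, -1] *= -1
    return frame


def radii(
    aligned_fn: np.ndarray,
    aligned_rn: np.ndarray,
    specimen_id: str,
    frame: np.ndarray | None = None,
    estimated: tuple[int, ...] = (),
) -> list[RadiiRecord]:
    """One RadiiRecord per landmark for a focal/mirrored pair in one frame."""
    fn = np.asarray(aligned_fn, dtype=float)
    rn = np.asarray(aligned_rn, dtype=float)
    if fn.shape != rn.shape:
        raise MetricsError(
            f"{specimen_id}: frame mismatch ({fn.shape} vs {rn.shape})"
        )
    disp = fn - rn
    if frame is not None:
        disp = disp @ frame
    rho = np.linalg.norm(disp, axis=1)
    est = set(estimated)
    records = []
    for i in range(fn.shape[0]):
        if rho[i] > 0:
            phi = float(np.arctan2(disp[i, 1], disp[i, 0]))
            theta = float(np.arccos(np.clip(disp[i, 2] / rho[i], -1.0, 1.0)))
        else:
            phi = theta = float("nan")
        records.append(
            RadiiRecord(
                specimen_id=specimen_id,
                landmark_index=i,
                rho=float(rho[i]),
                phi=phi,
                theta=theta,
                estimated=i in est,
            )
        )
    return records


def radii_frame(records: list[RadiiRecord]) -> pd.DataFrame:
    """Records as a DataFrame with 1-based landmark numbers for reporting."""
    return pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "landmark": [r.landmark_index + 1 for r in records],
            "rho": [r.rho for r in records],
            "phi": [r.phi for r in records],
            "theta": [r.theta for r in records],
            "estimated": [r.estimated for r in records],
        }
    )


def specimen_sum(
    records: list[RadiiRecord], include_estimated: bool = True
) -> dict[str, float]:
    """Sum of rho over all landmarks per specimen (the per-specimen score)."""
    sums: dict[str, float] = {}
    for r in records:
        if not include_estimated and r.estimated:
            continue
        sums[r.specimen_id] = sums.get(r.specimen_id, 0.0) + r.rho
    return sums


def group_summary(
    records: list[RadiiRecord],
    groups: dict[str, str],
    include_estimated: bool = True,
    top_k: int = 10,
) -> dict:
    """Group mean scores, per-landmark group means, and the top-k ranking.

    Returns ``{"mean_total": {group: mean of specimen sums},
    "mean_per_landmark": DataFrame (group x landmark),
    "ranking": DataFrame sorted descending by specimen sum}``.
    """
    sums = specimen_sum(records, include_estimated=include_estimated)
    missing = sorted(s for s in sums if s not in groups)
    if missing:
        raise MetricsError(f"specimens without a group label: {missing}")

    by_group: dict[str, list[float]] = {}
    for sid, total in sums.items():
        by_group.setdefault(groups[sid], []).append(total)
    mean_total = {}
    for g in sorted(by_group):
        if not by_group[g]:
            warnings.warn(f"group {g!r} empty; omitted", stacklevel=2)
            continue
        mean_total[g] = float(np.mean(by_group[g]))

    df = radii_frame(records)
    if not include_estimated:
        df = df[~df["estimated"]]
    df["group"] = df["specimen_id"].map(groups)
    mean_per_landmark = (
        df.groupby(["group", "landmark"])["rho"].mean().unstack("landmark")
    )

    ranking = pd.DataFrame(
        sorted(sums.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["specimen_id", "sum_rho"],
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking["group"] = ranking["specimen_id"].map(groups)
    return {
        "mean_total": mean_total,
        "mean_per_landmark": mean_per_landmark,
        "ranking": ranking.head(top_k) if top_k else ranking,
        "full_ranking": ranking,
    }


def region_fraction(
    records: list[RadiiRecord], scheme: LandmarkScheme, region: str
) -> dict[str, float]:
    """Percent of each specimen's summed rho carried by one region's landmarks.

    Specimens with zero total are reported as NaN.
    """
    idx = set(scheme.region_indices(region))  # raises on unknown region
    totals = specimen_sum(records)
    in_region: dict[str, float] = {}
    for r in records:
        if r.landmark_index in idx:
            in_region[r.specimen_id] = in_region.get(r.specimen_id, 0.0) + r.rho
    out = {}
    for sid, total in totals.items():
        if total == 0:
            out[sid] = float("nan")
        else:
            out[sid] = 100.0 * in_region.get(sid, 0.0) / total
    return out


def drop_region(
    dataset: LandmarkDataset, region: str
) -> LandmarkDataset:
    """Remove one region's landmarks from the scheme and every configuration.

    Regions must respect bilaterality: a pair with only one side in the
    region cannot be dropped.
    """
    scheme = dataset.scheme
    drop = set(scheme.region_indices(region))
    for l, r in scheme.pairs:
        if (l in drop) != (r in drop):
            raise SchemeError(
                f"region {region!r} contains landmark {min(l, r) + 1} but not its "
                f"partner {max(l, r) + 1}; cannot drop"
            )
    keep = [i for i in range(scheme.n_total) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    new_scheme = LandmarkScheme(
        n_total=len(keep),
        pairs=tuple(
            (remap[l], remap[r]) for l, r in scheme.pairs if l not in drop
        ),
        midline=tuple(remap[m] for m in scheme.midline if m not in drop),
        regions={remap[i]: reg for i, reg in scheme.regions.items() if i not in drop},
    )
    keep_arr = np.array(keep, dtype=int)
    new_configs = []
    for c in dataset.configurations:
        new_configs.append(
            LandmarkConfiguration(
                specimen_id=c.specimen_id,
                coords=c.coords[keep_arr],
                missing=c.missing[keep_arr],
                estimated=tuple(remap[i] for i in c.estimated if i not in drop),
            )
        )
    return LandmarkDataset(
        scheme=new_scheme, configurations=new_configs, metadata=list(dataset.metadata)
    )


@dataclass
class PcaResult:
    specimen_ids: list[str]
    scores: np.ndarray  # (n_specimens, n_components)
    proportion_variance: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns


def pca(aligned: AlignedDataset) -> PcaResult:
    """PCA of the flattened Procrustes-aligned coordinates."""
    if len(aligned.specimen_ids) < 2:
        raise MetricsError("pca requires >= 2 specimens")
    X = aligned.coords.reshape(len(aligned.specimen_ids), -1)
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        # constant data: a single zero-variance component, no division by zero
        return PcaResult(
            specimen_ids=list(aligned.specimen_ids),
            scores=np.zeros((len(aligned.specimen_ids), 1)),
            proportion_variance=np.array([1.0]),
            loadings=vt[:1].T,
        )
    return PcaResult(
        specimen_ids=list(aligned.specimen_ids),
        scores=u * s,
        proportion_variance=var / total,
        loadings=vt.T,
    )


def quantify(
    dataset: LandmarkDataset,
    include_estimated: bool = True,
    use_pair_midpoints: bool = False,
) -> dict:
    """Full quantification pipeline on a landmark dataset.

    estimate_missing -> mirror_fill -> gpa (focal configurations only) ->
    align_mirrored -> radii. Specimens whose symmetry plane cannot be fitted
    are excluded with a logged reason.

    Returns a dict with keys ``records``, ``sums``, ``aligned``, ``pca``,
    ``excluded`` (specimen_id -> reason) and ``reference_id``.
    """
    from .geometry import (
        GeometryError,
        align_mirrored,
        estimate_missing,
        gpa,
        mirror_fill,
    )

    scheme = dataset.scheme
    complete = [c for c in dataset.configurations if c.is_complete]
    excluded: dict[str, str] = {}

    # TPS reference = Procrustes mean shape of all complete specimens
    reference_id = "__consensus__"
    if complete and any(not c.is_complete for c in dataset.configurations):
        ref_aligned = gpa(complete)
        ref_scale = float(np.mean([centroid_size(c.coords) for c in complete]))
        reference = LandmarkConfiguration(
            reference_id,
            ref_aligned.consensus * ref_scale,
            np.zeros(scheme.n_total, dtype=bool),
        )
    elif not complete:
        raise MetricsError("no complete configurations to build a TPS reference")
    else:
        reference = None

    completed = []
    for c in dataset.configurations:
        if c.is_complete:
            completed.append(c)
            continue
        try:
            completed.append(estimate_missing(c, reference))
        except GeometryError as e:
            excluded[c.specimen_id] = str(e)

    mirrored = {}
    focal = []
    for c in completed:
        try:
            mirrored[c.specimen_id] = mirror_fill(
                c, scheme, use_pair_midpoints=use_pair_midpoints
            )
            focal.append(c)
        except GeometryError as e:
            excluded[c.specimen_id] = str(e)

    aligned = gpa(focal)
    frame = consensus_frame(aligned)
    records: list[RadiiRecord] = []
    for c in focal:
        rn = align_mirrored(aligned, mirrored[c.specimen_id])
        records.extend(
            radii(
                aligned.aligned(c.specimen_id),
                rn,
                c.specimen_id,
                frame=frame,
                estimated=c.estimated,
            )
        )
    return {
        "records": records,
        "sums": specimen_sum(records, include_estimated=include_estimated),
        "aligned": aligned,
        "pca": pca(aligned) if len(focal) >= 2 else None,
        "excluded": excluded,
        "reference_id": reference_id if reference is not None else None,
    }
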