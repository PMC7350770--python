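"""Reading, validation, and writing of landmark datasets, schemes, and metadata.

Tabular conventions
-------------------
Long CSV:   header ``specimen_id,landmark,x,y,z``, one row per specimen x landmark.
Wide CSV:   header ``specimen_id,x1,y1,z1,...``, one row per specimen.
Scheme CSV: header ``landmark,side,partner,region`` with side in {left, right, midline}.
Metadata:   header ``specimen_id,species,family,group,...`` (see :class:`SpecimenMetadata`).

Landmark indices are 1-based in all files and reports, 0-based internally.
A missing landmark is marked by the sentinel value -9999 in any coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_SENTINEL = -9999.0

#: groups used throughout the analysis
GROUPS = ("archaeocete", "odontocete", "mysticete", "terrestrial")

#: core region vocabulary; schemes may add labels but these must be recognisable
CORE_REGIONS = (
    "rostrum",
    "nasal",
    "premaxilla",
    "maxilla",
    "orbit",
    "jugal",
    "squamosal",
    "posterior",
    "other",
)


class SchemeError(ValueError):
    """Raised when a landmark scheme violates its structural invariants."""


class DatasetError(ValueError):
    """Raised when a landmark table cannot be parsed into a valid dataset."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Bilateral landmark scheme: paired left/right indices plus midline points.

    Indices are 0-based internally. ``pairs`` holds ``(left, right)`` tuples,
    ``midline`` the unpaired sagittal landmarks. The ``reference_set`` (the
    mirroring source) is derived as left indices + midline indices.
    """

    n_total: int
    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        left = [l for l, _ in self.pairs]
        right = [r for _, r in self.pairs]
        mid = list(self.midline)
        all_idx = left + right + mid
        if len(set(left) & set(right)) or len(set(left) & set(mid)) or len(set(right) & set(mid)):
            overlap = (set(left) & set(right)) | (set(left) & set(mid)) | (set(right) & set(mid))
            raise SchemeError(
                f"left/right/midline sets overlap at 1-based indices "
                f"{sorted(i + 1 for i in overlap)}"
            )
        if sorted(all_idx) != list(range(self.n_total)):
            raise SchemeError(
                f"pairs+midline do not partition 1..{self.n_total}: "
                f"got {len(all_idx)} indices, {len(set(all_idx))} unique"
            )

    @property
    def left_indices(self) -> tuple[int, ...]:
        return tuple(l for l, _ in self.pairs)

    @property
    def right_indices(self) -> tuple[int, ...]:
        return tuple(r for _, r in self.pairs)

    @property
    def reference_set(self) -> tuple[int, ...]:
        """Mirroring source landmarks: left side plus midline, sorted."""
        return tuple(sorted(self.left_indices + tuple(self.midline)))

    def partner(self, index: int) -> int | None:
        """Bilateral partner of a landmark, or None for midline points."""
        for l, r in self.pairs:
            if l == index:
                return r
            if r == index:
                return l
        return None

    def region_indices(self, region: str) -> tuple[int, ...]:
        if region not in set(self.regions.values()):
            raise SchemeError(f"unknown region {region!r}")
        return tuple(sorted(i for i, reg in self.regions.items() if reg == region))


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D landmarks (mm) with a missing mask.

    ``estimated`` records indices filled in by TPS estimation (provenance);
    such landmarks are observed (mask False) but flagged for sensitivity runs.
    """

    specimen_id: str
    coords: np.ndarray  # (n_total, 3) float
    missing: np.ndarray  # (n_total,) bool
    estimated: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise DatasetError(f"{self.specimen_id}: coords must be (n, 3)")
        if self.missing.shape != (self.coords.shape[0],):
            raise DatasetError(f"{self.specimen_id}: mask/coords length mismatch")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.specimen_id, self.coords.copy(), self.missing.copy(), self.estimated
        )


@dataclass(frozen=True)
class SpecimenMetadata:
    specimen_id: str
    species: str
    family: str = ""
    group: str = ""
    geologic_age: str = ""
    echo_presence: str = ""
    echo_frequency: str = ""
    regime: str = ""
    regime_split: str = ""
    is_fossil: bool = False


@dataclass
class LandmarkDataset:
    scheme: LandmarkScheme
    configurations: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen ids: {dupes}")
        if self.metadata:
            meta_ids = {m.specimen_id for m in self.metadata}
            if meta_ids != set(ids):
                raise DatasetError(
                    f"metadata/configuration id mismatch: "
                    f"only-in-meta={sorted(meta_ids - set(ids))}, "
                    f"only-in-configs={sorted(set(ids) - meta_ids)}"
                )

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def configuration(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(specimen_id)

    def metadata_for(self, specimen_id: str) -> SpecimenMetadata:
        for m in self.metadata:
            if m.specimen_id == specimen_id:
                return m
        raise KeyError(specimen_id)


@dataclass
class ValidationReport:
    n_specimens: int
    n_landmarks: int
    missing_per_specimen: dict[str, int]
    fraction_with_missing: float
    flagged: list[str]
    threshold: float


# ---------------------------------------------------------------------------
# scheme I/O


def read_scheme(path) -> LandmarkScheme:
    """Read a scheme CSV (columns landmark, side, partner, region; 1-based)."""
    df = pd.read_csv(path, dtype={"landmark": int, "side": str})
    required = {"landmark", "side"}
    if not required.issubset(df.columns):
        raise SchemeError(f"scheme file missing columns {sorted(required - set(df.columns))}")
    sides = {}
    partners = {}
    regions = {}
    for _, row in df.iterrows():
        idx = int(row["landmark"]) - 1
        side = str(row["side"]).strip().lower()
        if side not in ("left", "right", "midline"):
            raise SchemeError(f"landmark {idx + 1}: bad side {side!r}")
        if idx in sides:
            raise SchemeError(f"landmark {idx + 1} listed twice")
        sides[idx] = side
        if side != "midline":
            if "partner" not in df.columns or pd.isna(row.get("partner")):
                raise SchemeError(f"{side} landmark {idx + 1} has no partner")
            partners[idx] = int(row["partner"]) - 1
        regions[idx] = str(row["region"]).strip() if "region" in df.columns and not pd.isna(row.get("region")) else "other"

    pairs = []
    for idx, side in sides.items():
        if side == "left":
            r = partners.get(idx)
            if r is None or sides.get(r) != "right" or partners.get(r) != idx:
                raise SchemeError(
                    f"left landmark {idx + 1} lacks a reciprocal right partner"
                )
            pairs.append((idx, r))
    # every right landmark must have been claimed by a left one
    rights = {r for _, r in pairs}
    for idx, side in sides.items():
        if side == "right" and idx not in rights:
            raise SchemeError(f"right landmark {idx + 1} has no left partner")

    midline = tuple(sorted(i for i, s in sides.items() if s == "midline"))
    return LandmarkScheme(
        n_total=len(sides),
        pairs=tuple(sorted(pairs)),
        midline=midline,
        regions=regions,
    )


def write_scheme(scheme: LandmarkScheme, path) -> None:
    rows = []
    for l, r in scheme.pairs:
        rows.append((l + 1, "left", r + 1, scheme.regions.get(l, "other")))
        rows.append((r + 1, "right", l + 1, scheme.regions.get(r, "other")))
    for m in scheme.midline:
        rows.append((m + 1, "midline", "", scheme.regions.get(m, "other")))
    rows.sort(key=lambda t: t[0])
    pd.DataFrame(rows, columns=["landmark", "side", "partner", "region"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# landmark table I/O


def _parse_long(df: pd.DataFrame, scheme: LandmarkScheme, path) -> list[LandmarkConfiguration]:
    for col in ("x", "y", "z"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2  # header + 1-based
            raise DatasetError(f"{path}: unreadable numeric in column {col!r} at line {line}")
    dup = df.duplicated(subset=["specimen_id", "landmark"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise DatasetError(
            f"duplicate row for (specimen={row['specimen_id']}, landmark={int(row['landmark'])})"
        )
    configs = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        if len(sub) != scheme.n_total:
            raise DatasetError(
                f"specimen {sid!r} has {len(sub)} landmarks, expected {scheme.n_total}"
            )
        sub = sub.sort_values("landmark")
        idx = sub["landmark"].to_numpy(dtype=int) - 1
        if not np.array_equal(idx, np.arange(scheme.n_total)):
            raise DatasetError(f"specimen {sid!r}: landmark indices not 1..{scheme.n_total}")
        coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
        missing = (coords == MISSING_SENTINEL).any(axis=1)
        partial = missing & ~(coords == MISSING_SENTINEL).all(axis=1)
        if partial.any():
            warnings.warn(
                f"specimen {sid!r}: landmarks {[int(i) + 1 for i in np.where(partial)[0]]} "
                "have partial -9999 sentinels; treated as whole-landmark missing",
                stacklevel=3,
            )
        coords = coords.copy()
        coords[missing] = np.nan
        configs.append(LandmarkConfiguration(str(sid), coords, missing))
    return configs


def _parse_wide(df: pd.DataFrame, scheme: LandmarkScheme, path) -> list[LandmarkConfiguration]:
    cols = [f"{ax}{i}" for i in range(1, scheme.n_total + 1) for ax in ("x", "y", "z")]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"{path}: wide table missing columns {missing_cols[:5]}...")
    configs = []
    for _, row in df.iterrows():
        coords = row[cols].to_numpy(dtype=float).reshape(scheme.n_total, 3)
        missing = (coords == MISSING_SENTINEL).any(axis=1)
        coords = coords.copy()
        coords[missing] = np.nan
        configs.append(LandmarkConfiguration(str(row["specimen_id"]), coords, missing))
    return configs


def read_landmark_table(path, scheme: LandmarkScheme) -> LandmarkDataset:
    """Read a long- or wide-form landmark CSV (auto-detected by header)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise DatasetError("no specimens in landmark table")
    if "specimen_id" not in df.columns:
        raise DatasetError(f"{path}: missing specimen_id column")
    if "landmark" in df.columns:
        configs = _parse_long(df, scheme, path)
    else:
        configs = _parse_wide(df, scheme, path)
    return LandmarkDataset(scheme=scheme, configurations=configs)


def write_landmark_table(dataset: LandmarkDataset, path) -> None:
    """Write the long-form CSV; missing landmarks become -9999 sentinel rows."""
    rows = []
    for cfg in dataset.configurations:
        for i in range(cfg.n_landmarks):
            if cfg.missing[i]:
                x = y = z = MISSING_SENTINEL
            else:
                x, y, z = cfg.coords[i]
            rows.append((cfg.specimen_id, i + 1, x, y, z))
    pd.DataFrame(rows, columns=["specimen_id", "landmark", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# metadata I/O


_META_FIELDS = (
    "species",
    "family",
    "group",
    "geologic_age",
    "echo_presence",
    "echo_frequency",
    "regime",
    "regime_split",
)


def read_metadata(path) -> list[SpecimenMetadata]:
    df = pd.read_csv(path, dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise DatasetError("metadata missing specimen_id column")
    out = []
    for _, row in df.iterrows():
        kwargs = {f: str(row[f]) for f in _META_FIELDS if f in df.columns}
        fossil = str(row.get("is_fossil", "")).strip().lower() in ("1", "true", "yes")
        out.append(SpecimenMetadata(specimen_id=str(row["specimen_id"]), is_fossil=fossil, **kwargs))
    return out


def write_metadata(metadata: list[SpecimenMetadata], path) -> None:
    rows = [
        {
            "specimen_id": m.specimen_id,
            **{f: getattr(m, f) for f in _META_FIELDS},
            "is_fossil": m.is_fossil,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


def validate_dataset(dataset: LandmarkDataset, missing_threshold: float = 0.5) -> ValidationReport:
    """Report per-specimen missingness; flag (never drop) heavy missingness."""
    per_spec = {c.specimen_id: int(c.missing.sum()) for c in dataset.configurations}
    n = len(dataset.configurations)
    with_missing = sum(1 for v in per_spec.values() if v > 0)
    n_lm = dataset.scheme.n_total
    flagged = sorted(
        sid for sid, v in per_spec.items() if v / n_lm > missing_threshold
    )
    return ValidationReport(
        n_specimens=n,
        n_landmarks=n_lm,
        missing_per_specimen=per_spec,
        fraction_with_missing=with_missing / n if n else 0.0,
        flagged=flagged,
        threshold=missing_threshold,
    )
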