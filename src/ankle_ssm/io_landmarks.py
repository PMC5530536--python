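"""Landmark and metadata I/O for 2-D ankle shape analysis.

Landmark configurations travel in TPS format (``LM=`` / coordinate pairs /
``ID=`` / optional ``SCALE=``), the interchange format of geometric
morphometrics.  Per-ankle metadata (participant id, side, injury history,
race, sex, BMI, Kellgren-Lawrence grade, symptoms, age) lives in a separate
delimited table joined on ``ankle_id``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkScheme",
    "Configuration",
    "AnkleMetadata",
    "ShapeDataset",
    "FormatError",
    "ValidationError",
    "default_scheme",
    "read_tps",
    "write_tps",
    "read_metadata_table",
    "mirror_left_to_right",
    "build_dataset",
    "summarize_cohort",
]


class FormatError(ValueError):
    """A landmark or metadata file violates its format contract."""


class ValidationError(ValueError):
    """A record violates a domain rule (e.g. the KLG 0/1 case definition)."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Fixed landmark numbering shared by every configuration in a study.

    ``bone_groups`` maps each bone of the lateral ankle view to the
    half-open index range ``(start, stop)`` of its points.  The anatomical
    assignment of the 68 points per bone is configurable; the default split
    below is a stylized placeholder, not a published anatomy.
    """

    n_points: int = 68
    labels: tuple[str, ...] = ()
    bone_groups: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"p{i + 1}" for i in range(self.n_points))
            )
        if len(self.labels) != self.n_points:
            raise ValidationError(
                f"scheme has {len(self.labels)} labels for {self.n_points} points"
            )
        if len(set(self.labels)) != self.n_points:
            raise ValidationError("landmark labels must be unique")
        if self.bone_groups:
            covered: list[int] = []
            for name, (start, stop) in self.bone_groups.items():
                if not (0 <= start < stop <= self.n_points):
                    raise ValidationError(f"bone group {name!r} range out of bounds")
                covered.extend(range(start, stop))
            if sorted(covered) != list(range(self.n_points)):
                raise ValidationError(
                    "bone group ranges must be disjoint and cover all points"
                )

    def group_indices(self, bone: str) -> np.ndarray:
        start, stop = self.bone_groups[bone]
        return np.arange(start, stop)


def default_scheme() -> LandmarkScheme:
    """68-point scheme: distal tibia, talus, calcaneus, navicular.

    Point 18 (1-based) opens the talus block, echoing the convention that
    it sits at the center of the top of the talar dome.
    """
    return LandmarkScheme(
        n_points=68,
        bone_groups={
            "tibia": (0, 17),
            "talus": (17, 38),
            "calcaneus": (38, 60),
            "navicular": (60, 68),
        },
    )


@dataclass(frozen=True)
class Configuration:
    """One ankle's ordered 2-D landmarks, coordinates in mm."""

    ankle_id: str
    coords: np.ndarray  # (n_points, 2)
    side: str = "right"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(f"{self.ankle_id}: coords must be (n, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"{self.ankle_id}: non-finite coordinates")
        # exact coincidence of two landmarks means a digitization failure
        d = coords[:, None, :] - coords[None, :, :]
        same = (np.abs(d).sum(axis=2) == 0.0) & ~np.eye(len(coords), dtype=bool)
        if same.any():
            raise ValidationError(f"{self.ankle_id}: coincident landmarks")
        if self.side not in ("left", "right"):
            raise ValidationError(f"{self.ankle_id}: side must be left|right")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class AnkleMetadata:
    """Clinical covariates for one ankle.

    Codings follow the referents of the association models: race 1 = white
    (0 = African American, referent), sex 1 = male (0 = female, referent),
    symptoms 1 = any symptom score > 0.  Only KLG 0/1 ankles (no
    radiographic tibiotalar OA) are admissible.
    """

    ankle_id: str
    participant_id: str
    side: str
    injury: int
    race: int
    sex: int
    bmi: float
    klg: int
    symptoms: int
    age: float
    physical_activity: int | None = None

    def __post_init__(self) -> None:
        if self.klg not in (0, 1):
            raise ValidationError(
                f"{self.ankle_id}: KLG={self.klg}; only grades 0 and 1 "
                "(no radiographic OA) are admitted by the case definition"
            )
        for name in ("injury", "race", "sex", "symptoms"):
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{self.ankle_id}: {name} must be 0/1")
        if self.side not in ("left", "right"):
            raise ValidationError(f"{self.ankle_id}: side must be left|right")


@dataclass
class ShapeDataset:
    """Configurations plus their metadata, joined on ankle_id."""

    scheme: LandmarkScheme
    configurations: list[Configuration]
    metadata: dict[str, AnkleMetadata]

    def __post_init__(self) -> None:
        for cfg in self.configurations:
            if cfg.n_points != self.scheme.n_points:
                raise ValidationError(
                    f"{cfg.ankle_id}: {cfg.n_points} points under a "
                    f"{self.scheme.n_points}-point scheme"
                )
            if cfg.ankle_id not in self.metadata:
                raise ValidationError(f"{cfg.ankle_id}: no metadata record")
        sides: dict[str, set[str]] = {}
        for md in self.metadata.values():
            sides.setdefault(md.participant_id, set()).add(md.side)
        for pid, s in sides.items():
            n = sum(1 for m in self.metadata.values() if m.participant_id == pid)
            if n > 2:
                raise ValidationError(f"participant {pid} has {n} ankles (max 2)")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def ankle_ids(self) -> list[str]:
        return [c.ankle_id for c in self.configurations]

    def metadata_frame(self) -> pd.DataFrame:
        """Metadata as a DataFrame in configuration order."""
        rows = [vars(self.metadata[c.ankle_id]) for c in self.configurations]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TPS interchange
# ---------------------------------------------------------------------------

def read_tps(path, scheme: LandmarkScheme) -> list[Configuration]:
    """Read a TPS landmark file.

    Each record holds ``LM=<n>``, ``n`` whitespace-separated coordinate
    pairs, an ``ID=`` line, and optionally ``SCALE=<mm per unit>`` by which
    the coordinates are multiplied.  File order and record ids are
    preserved.
    """
    configs: list[Configuration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i, n_rec = 0, 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise FormatError(f"record {n_rec + 1}: expected LM=, got {lines[i]!r}")
        try:
            n_lm = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"record {n_rec + 1}: bad LM line {lines[i]!r}") from exc
        if n_lm != scheme.n_points:
            raise FormatError(
                f"record {n_rec + 1}: LM={n_lm} does not match the "
                f"{scheme.n_points}-point scheme"
            )
        i += 1
        coords = np.empty((n_lm, 2))
        for j in range(n_lm):
            if i >= len(lines):
                raise FormatError(f"record {n_rec + 1}: truncated coordinates")
            parts = lines[i].split()
            if len(parts) != 2:
                raise FormatError(
                    f"record {n_rec + 1}, point {j + 1}: bad coordinate line "
                    f"{lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise FormatError(
                    f"record {n_rec + 1}, point {j + 1}: non-numeric coordinates"
                ) from exc
            i += 1
        ankle_id: str | None = None
        scale: float | None = None
        while i < len(lines) and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                ankle_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if ankle_id is None:
            raise FormatError(f"record {n_rec + 1}: missing ID= line")
        if scale is not None:
            coords = coords * scale
        configs.append(Configuration(ankle_id=ankle_id, coords=coords))
        n_rec += 1
    return configs


def write_tps(configs: list[Configuration], path) -> None:
    """Write configurations to a TPS file (inverse of :func:`read_tps`)."""
    if not configs:
        raise ValueError("cannot write an empty configuration list")
    n_points = configs[0].n_points
    if any(c.n_points != n_points for c in configs):
        raise ValueError("heterogeneous landmark counts")
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.n_points}\n")
            for x, y in cfg.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={cfg.ankle_id}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "ankle_id",
    "participant_id",
    "side",
    "injury",
    "race",
    "sex",
    "bmi",
    "klg",
    "age",
)


def read_metadata_table(path, delimiter: str = ",") -> list[AnkleMetadata]:
    """Read the per-ankle metadata table.

    The symptom column may be either a pre-dichotomized ``symptoms`` 0/1
    indicator or a raw 0-10 ``symptom_score``, which is dichotomized by the
    rule score > 0 -> 1 (no symptoms = 0, any symptoms > 0).
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing required columns: {missing}")
    if "symptoms" not in df.columns and "symptom_score" not in df.columns:
        raise FormatError("metadata table needs a symptoms or symptom_score column")
    out: list[AnkleMetadata] = []
    for _, row in df.iterrows():
        if "symptom_score" in df.columns and not pd.isna(row.get("symptom_score")):
            symptoms = int(float(row["symptom_score"]) > 0)
        else:
            symptoms = int(row["symptoms"])
        pa = row.get("physical_activity")
        out.append(
            AnkleMetadata(
                ankle_id=str(row["ankle_id"]),
                participant_id=str(row["participant_id"]),
                side=str(row["side"]),
                injury=int(row["injury"]),
                race=int(row["race"]),
                sex=int(row["sex"]),
                bmi=float(row["bmi"]),
                klg=int(row["klg"]),
                symptoms=symptoms,
                age=float(row["age"]),
                physical_activity=None if pd.isna(pa) else int(pa),
            )
        )
    return out


def write_metadata_table(metadata: list[AnkleMetadata], path, delimiter=",") -> None:
    pd.DataFrame([vars(m) for m in metadata]).to_csv(path, sep=delimiter, index=False)


def mirror_left_to_right(config: Configuration) -> Configuration:
    """Reflect a left ankle about its centroid's vertical axis.

    Pooling both sides in one Procrustes/PCA is only geometrically coherent
    in a common chirality, so left configurations are mirrored to right
    orientation before alignment.  The reflection is about the centroid, so
    centroid size and all inter-landmark distances are preserved exactly.
    """
    if config.side == "right":
        warnings.warn(f"{config.ankle_id}: already right-sided; no-op")
        return config
    coords = config.coords.copy()
    coords[:, 0] = 2.0 * coords[:, 0].mean() - coords[:, 0]
    return replace(config, coords=coords, side="right")


def build_dataset(
    configs: list[Configuration],
    metadata: list[AnkleMetadata],
    scheme: LandmarkScheme | None = None,
    mirror: bool = True,
) -> ShapeDataset:
    """Join configurations with metadata; optionally mirror left ankles.

    Configurations without a usable metadata record are excluded with a
    logged reason rather than aborting the build.
    """
    scheme = scheme or default_scheme()
    md = {m.ankle_id: m for m in metadata}
    kept: list[Configuration] = []
    for cfg in configs:
        if cfg.ankle_id not in md:
            logger.warning("excluding %s: unusable record (no metadata)", cfg.ankle_id)
            continue
        cfg = replace(cfg, side=md[cfg.ankle_id].side)
        if mirror and cfg.side == "left":
            cfg = mirror_left_to_right(cfg)
        kept.append(cfg)
    md = {k: v for k, v in md.items() if k in {c.ankle_id for c in kept}}
    return ShapeDataset(scheme=scheme, configurations=kept, metadata=md)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def summarize_cohort(data: ShapeDataset | pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: overall (by participant) and by injury status (by ankle).

    Returns a tidy frame with one row per (variable, stratum): mean/SD for
    age and BMI, count and percentage for race (white), sex (female),
    KLG = 0 and symptoms present.  Percentages use the stratum totals as
    denominators; ``pct`` carries the value rounded to one decimal and
    ``pct_raw`` the unrounded value.
    """
    df = data.metadata_frame() if isinstance(data, ShapeDataset) else data.copy()
    strata: dict[str, pd.DataFrame] = {
        "overall": df.drop_duplicates("participant_id"),
        "injured": df[df["injury"] == 1],
        "uninjured": df[df["injury"] == 0],
    }
    rows = []
    for stratum, sub in strata.items():
        if sub.empty:
            warnings.warn(f"stratum {stratum!r} is empty; omitted")
            continue
        n = len(sub)
        for var in ("age", "bmi"):
            rows.append(
                dict(variable=var, stratum=stratum, n=n,
                     mean=float(sub[var].mean()), sd=float(sub[var].std(ddof=1)) if n > 1 else 0.0,
                     count=np.nan, pct=np.nan, pct_raw=np.nan)
            )
        for var, indicator in (
            ("white", sub["race"] == 1),
            ("female", sub["sex"] == 0),
            ("klg0", sub["klg"] == 0),
            ("symptoms", sub["symptoms"] == 1),
        ):
            count = int(indicator.sum())
            pct_raw = 100.0 * count / n
            rows.append(
                dict(variable=var, stratum=stratum, n=n, mean=np.nan, sd=np.nan,
                     count=count, pct=round(pct_raw, 1), pct_raw=pct_raw)
            )
    return pd.DataFrame(rows)
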