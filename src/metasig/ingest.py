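"""Ingestion and standardization of study-level miRNA signature lists.

A *study signature* is one study's ordered list of up- or down-regulated
miRNAs together with the size of the profiling platform.  The module
standardizes reported names against a bundled (user-extensible) alias
map, assembles direction-stratified normalized rank matrices, and
computes the descriptive bookkeeping of the pooled study collection.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UP = "up"
DOWN = "down"
DIRECTIONS = (UP, DOWN)

_MIRNA_PATTERN = re.compile(r"^hsa-(miR|mir|let)-", re.IGNORECASE)

__all__ = [
    "StudySignature",
    "AliasMap",
    "RankMatrix",
    "CohortSummary",
    "DirectionBreadth",
    "standardize_names",
    "build_rank_matrix",
    "discordance_report",
    "cohort_summary",
    "percent_reported",
    "read_signatures",
    "read_rank_matrix",
    "write_rank_matrix",
    "load_study_table",
    "load_meta_signature_table",
    "load_signature_breadth",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySignature:
    """One study's directional, ordered miRNA list.

    Parameters
    ----------
    study_id : str
        Identifier of the originating study.
    platform_size : int
        Number of miRNA probes assayed by the study's platform; the
        denominator of the normalized rank.
    direction : {"up", "down"}
        Direction of differential expression of the listed members.
    members : tuple of str
        Canonical miRNA names, best-ranked first.
    effect : tuple of float, optional
        Per-member effect magnitudes (fold change or p value) used only
        for ordering; not stored per normalized rank.
    """

    study_id: str
    platform_size: int
    direction: str
    members: tuple[str, ...]
    effect: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.platform_size < 1:
            raise ValueError("platform_size must be >= 1")
        if not (1 <= len(self.members) <= self.platform_size):
            raise ValueError(
                f"study {self.study_id!r}: need 1 <= |members| <= platform_size "
                f"({len(self.members)} vs {self.platform_size})"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"study {self.study_id!r}: duplicate members")
        if self.effect is not None and len(self.effect) != len(self.members):
            raise ValueError("effect length must match members")

    def normalized_ranks(self) -> dict[str, float]:
        """Map each member to its normalized rank j / platform_size."""
        n = self.platform_size
        return {m: (j + 1) / n for j, m in enumerate(self.members)}


@dataclass(frozen=True)
class AliasMap:
    """Deterministic mapping from reported miRNA names to canonical names.

    ``mapping`` sends reported names/probe IDs to canonical mature names;
    ``excluded`` holds names dropped outright (viral miRNAs, control
    probes).  Canonical names never appear in the exclusion set.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) & set(self.excluded)
        if bad:
            raise ValueError(f"canonical names map into the exclusion set: {sorted(bad)}")

    @classmethod
    def load(cls, alias_path: str | Path, exclusion_path: str | Path | None = None) -> "AliasMap":
        """Load from a two-column TSV (reported_name, canonical_name) and an
        optional one-column exclusion list."""
        aliases = pd.read_csv(alias_path, sep="\t", dtype=str)
        mapping = dict(zip(aliases.iloc[:, 0].str.strip(), aliases.iloc[:, 1].str.strip()))
        excluded: frozenset[str] = frozenset()
        if exclusion_path is not None:
            excl = pd.read_csv(exclusion_path, sep="\t", dtype=str)
            excluded = frozenset(excl.iloc[:, 0].str.strip())
        return cls(mapping=mapping, excluded=excluded)

    @classmethod
    def bundled(cls) -> "AliasMap":
        """The alias map shipped with the package (covers the meta-signature
        miRNAs plus common viral/control probes)."""
        data = resources.files("metasig.data")
        return cls.load(data / "aliases.tsv", data / "excluded.tsv")


@dataclass
class RankMatrix:
    """miRNAs x studies matrix of normalized ranks in (0, 1].

    Unreported cells hold exactly 1.0 with ``reported_mask`` false.
    """

    item_names: list[str]
    study_ids: list[str]
    values: np.ndarray
    reported_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.reported_mask = np.asarray(self.reported_mask, dtype=bool)
        shape = (len(self.item_names), len(self.study_ids))
        if self.values.shape != shape or self.reported_mask.shape != shape:
            raise ValueError("values/reported_mask shape mismatch")
        if self.values.size:
            if np.any(self.values <= 0) or np.any(self.values > 1):
                raise ValueError("normalized ranks must lie in (0, 1]")
            if np.any(self.values[~self.reported_mask] != 1.0):
                raise ValueError("unreported cells must equal exactly 1.0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_names, columns=self.study_ids)


def write_rank_matrix(matrix: RankMatrix, path: str | Path) -> None:
    """Write a rank matrix as TSV, plus a sibling ``.mask.tsv`` carrying the
    reported mask (needed to round-trip reported cells that equal 1.0)."""
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "mirna"
    df.to_csv(path, sep="\t", float_format="%.17g")
    mask = pd.DataFrame(
        matrix.reported_mask.astype(int), index=matrix.item_names, columns=matrix.study_ids
    )
    mask.index.name = "mirna"
    mask.to_csv(path.with_suffix(path.suffix + ".mask.tsv"), sep="\t")


def read_rank_matrix(path: str | Path) -> RankMatrix:
    """Read a rank matrix TSV written by :func:`write_rank_matrix`.

    If the sibling mask file is absent, cells < 1.0 are taken as reported.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    mask_path = path.with_suffix(path.suffix + ".mask.tsv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).to_numpy(dtype=bool)
    else:
        mask = df.to_numpy() < 1.0
    return RankMatrix(
        item_names=list(df.index),
        study_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        reported_mask=mask,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def standardize_names(
    names: Sequence[str], aliases: AliasMap
) -> tuple[list[str], list[tuple[str, str]]]:
    """Standardize reported miRNA names.

    Applies, in order: exclusion-set lookup on the raw name, alias
    mapping, and a species/probe-pattern check on the mapped name
    (non-``hsa-miR/let`` entries are treated as viral miRNAs or
    non-miRNA probes).  Duplicates arising after mapping are collapsed
    keeping the earliest (best-ranked) occurrence.

    Returns
    -------
    canonical : list of str
        Standardized names, original order preserved.
    dropped : list of (name, reason)
        Inputs removed, with reason codes ``"excluded"``, ``"non_mirna"``
        or ``"duplicate"``.
    """
    if len(names) == 0:
        raise ValueError("names must be non-empty")
    canonical: list[str] = []
    seen: set[str] = set()
    dropped: list[tuple[str, str]] = []
    for raw in names:
        name = raw.strip()
        if name in aliases.excluded:
            dropped.append((raw, "excluded"))
            continue
        mapped = aliases.mapping.get(name, name)
        if not _MIRNA_PATTERN.match(mapped):
            dropped.append((raw, "excluded" if not mapped.startswith("hsa-") else "non_mirna"))
            continue
        if mapped in seen:
            dropped.append((raw, "duplicate"))
            continue
        seen.add(mapped)
        canonical.append(mapped)
    return canonical, dropped


def build_rank_matrix(signatures: Sequence[StudySignature], direction: str) -> RankMatrix:
    """Assemble one direction's normalized rank matrix.

    The member at 1-based position ``j`` in a study with platform size
    ``N`` receives rank ``j / N``; non-members receive exactly 1.0 with a
    false reported mask.  Rows are ordered lexicographically, columns in
    input study order.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    for sig in signatures:
        if sig.direction != direction:
            raise ValueError(
                f"study {sig.study_id!r} has direction {sig.direction!r}, expected {direction!r}"
            )
    items = sorted({m for sig in signatures for m in sig.members})
    study_ids = [sig.study_id for sig in signatures]
    values = np.ones((len(items), len(signatures)))
    mask = np.zeros_like(values, dtype=bool)
    row = {name: i for i, name in enumerate(items)}
    for j, sig in enumerate(signatures):
        for name, r in sig.normalized_ranks().items():
            values[row[name], j] = r
            mask[row[name], j] = True
    return RankMatrix(item_names=items, study_ids=study_ids, values=values, reported_mask=mask)


def discordance_report(
    up_signatures: Sequence[StudySignature], down_signatures: Sequence[StudySignature]
) -> pd.DataFrame:
    """Table of miRNAs reported in both directions across the collection.

    One row per miRNA present in at least one up-list and one down-list;
    counts are numbers of studies reporting it per direction.  Sorted by
    total count descending, then name.
    """
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for sig in up_signatures:
        for m in sig.members:
            up_counts[m] = up_counts.get(m, 0) + 1
    for sig in down_signatures:
        for m in sig.members:
            down_counts[m] = down_counts.get(m, 0) + 1
    shared = sorted(set(up_counts) & set(down_counts))
    rows = [(m, up_counts[m], down_counts[m]) for m in shared]
    df = pd.DataFrame(rows, columns=["mirna", "up_count", "down_count"])
    if len(df):
        df["total"] = df["up_count"] + df["down_count"]
        df = (
            df.sort_values(["total", "mirna"], ascending=[False, True])
            .drop(columns="total")
            .reset_index(drop=True)
        )
    return df


@dataclass(frozen=True)
class DirectionBreadth:
    """Unique-miRNA bookkeeping for one direction."""

    n_unique: int
    n_reported_gt_k: int
    percent_gt_k: float


@dataclass(frozen=True)
class CohortSummary:
    n_studies: int
    total_cases: int
    total_controls: int
    up: DirectionBreadth | None = None
    down: DirectionBreadth | None = None


def percent_reported(part: int, whole: int) -> float:
    """Percentage ``100 * part / whole`` rounded to one decimal place."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, 1)


def _breadth(signatures: Sequence[StudySignature], k: int) -> DirectionBreadth:
    counts: dict[str, int] = {}
    for sig in signatures:
        for m in sig.members:
            counts[m] = counts.get(m, 0) + 1
    n_unique = len(counts)
    n_gt = sum(1 for c in counts.values() if c > k)
    pct = percent_reported(n_gt, n_unique) if n_unique else 0.0
    return DirectionBreadth(n_unique=n_unique, n_reported_gt_k=n_gt, percent_gt_k=pct)


def cohort_summary(
    study_table: pd.DataFrame,
    up_signatures: Sequence[StudySignature] | None = None,
    down_signatures: Sequence[StudySignature] | None = None,
    k: int = 3,
) -> CohortSummary:
    """Descriptive summary of the pooled study collection.

    ``study_table`` needs columns ``n_cases`` and ``n_controls``.  When
    signature lists are supplied, per-direction unique miRNA counts and
    the share reported in more than ``k`` studies are included.
    """
    if (study_table["n_cases"] < 0).any() or (study_table["n_controls"] < 0).any():
        raise ValueError("negative case/control counts")
    return CohortSummary(
        n_studies=len(study_table),
        total_cases=int(study_table["n_cases"].sum()),
        total_controls=int(study_table["n_controls"].sum()),
        up=_breadth(up_signatures, k) if up_signatures is not None else None,
        down=_breadth(down_signatures, k) if down_signatures is not None else None,
    )


# ---------------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------------


def read_signatures(
    signatures_path: str | Path,
    metadata_path: str | Path,
    aliases: AliasMap | None = None,
    order_by: str = "effect",
) -> list[StudySignature]:
    """Read study signatures from the long-format TSV.

    ``signatures_path`` columns: study_id, direction, mirna and optional
    rank_or_effect.  ``metadata_path`` columns: study_id, platform_size,
    n_cases, n_controls.  Ordering: ``order_by="effect"`` sorts members
    by descending |rank_or_effect| (ties broken lexicographically),
    ``"rank"`` sorts ascending, ``"file"`` keeps file order.  When the
    column is absent, file order is kept and a warning is emitted.
    """
    if order_by not in ("effect", "rank", "file"):
        raise ValueError("order_by must be 'effect', 'rank' or 'file'")
    sig_df = pd.read_csv(signatures_path, sep="\t", dtype={"study_id": str, "mirna": str})
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"study_id": str}).set_index("study_id")
    has_effect = "rank_or_effect" in sig_df.columns
    if not has_effect and order_by != "file":
        warnings.warn("no rank_or_effect column; keeping file order", stacklevel=2)
    signatures: list[StudySignature] = []
    for (study_id, direction), grp in sig_df.groupby(["study_id", "direction"], sort=True):
        names = list(grp["mirna"])
        effects = list(grp["rank_or_effect"]) if has_effect else None
        if aliases is not None:
            keep, _ = standardize_names(names, aliases)
            kept_idx = []
            seen: set[str] = set()
            mapped = [aliases.mapping.get(n.strip(), n.strip()) for n in names]
            for i, m in enumerate(mapped):
                if m in keep and m not in seen:
                    seen.add(m)
                    kept_idx.append(i)
            names = [mapped[i] for i in kept_idx]
            effects = [effects[i] for i in kept_idx] if effects is not None else None
        if effects is not None and order_by == "effect":
            order = sorted(range(len(names)), key=lambda i: (-abs(effects[i]), names[i]))
        elif effects is not None and order_by == "rank":
            order = sorted(range(len(names)), key=lambda i: (effects[i], names[i]))
        else:
            order = list(range(len(names)))
        members = tuple(names[i] for i in order)
        eff = tuple(float(effects[i]) for i in order) if effects is not None else None
        signatures.append(
            StudySignature(
                study_id=str(study_id),
                platform_size=int(meta.loc[str(study_id), "platform_size"]),
                direction=str(direction),
                members=members,
                effect=eff,
            )
        )
    return signatures


# ---------------------------------------------------------------------------
# bundled worked-number fixtures
# ---------------------------------------------------------------------------


def _bundled(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("metasig.data") / name) as p:
        return pd.read_csv(p, sep="\t")


def load_study_table() -> pd.DataFrame:
    """Bundled 14-study characteristics table (platform sizes, sample counts)."""
    return _bundled("study_table.tsv")


def load_meta_signature_table() -> pd.DataFrame:
    """Bundled 7-row meta-signature table (p-values and corrected p-values)."""
    return _bundled("meta_signature.tsv")


def load_signature_breadth() -> pd.DataFrame:
    """Bundled per-direction unique/recurrent miRNA counts."""
    return _bundled("signature_breadth.tsv")
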