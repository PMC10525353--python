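"""Reading, writing and validation of connectomes, atlases and cohort tables.

A structural connectome is a symmetric, non-negative, zero-diagonal weighted
adjacency matrix over the nodes of a parcellation atlas (by default the
90-region AAL cortical/subcortical parcellation).  Matrices are stored as
plain delimited text with no header; node order is fixed by the atlas.

The cohort table is a CSV with one row per subject carrying the diagnostic
group (CU / prodromalAD / ADdementia), sex, age, education, cognitive scores
(K-MMSE, CDR sum of boxes) and a path to the subject's connectivity matrix.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("richclubnet")

GROUPS = ("CU", "prodromalAD", "ADdementia")
SEXES = ("F", "M")

#: Regions whose bilateral nodes form the default rich-club set: superior
#: frontal cortex, superior parietal cortex, precuneus, hippocampus, putamen
#: and thalamus (12 nodes).
DEFAULT_RICH_CLUB_REGIONS = (
    "Frontal_Sup",
    "Parietal_Sup",
    "Precuneus",
    "Hippocampus",
    "Putamen",
    "Thalamus",
)

# AAL-90 base region names in atlas order; each expands to a left/right pair.
_AAL90_REGIONS = (
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
)


class ConnectomeValidationError(ValueError):
    """Base class for connectome input validation failures."""


class NonSquareMatrixError(ConnectomeValidationError):
    pass


class NegativeWeightError(ConnectomeValidationError):
    pass


class NonFiniteWeightError(ConnectomeValidationError):
    pass


class AsymmetricMatrixError(ConnectomeValidationError):
    pass


class AtlasError(ValueError):
    """Invalid atlas specification (duplicate node, bad hemisphere code...)."""


class CohortError(ValueError):
    """Invalid cohort metadata (bad vocabulary, missing file or column)."""


@dataclasses.dataclass(frozen=True)
class WeightedConnectome:
    """One subject's symmetric non-negative weighted adjacency matrix."""

    subject_id: str
    weights: np.ndarray
    node_ids: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degrees(self) -> np.ndarray:
        """Binary degree per node (an edge exists iff w > 0)."""
        return (self.weights > 0).sum(axis=1).astype(np.int64)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle edges as (i, j, w) arrays with i < j."""
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return iu, ju, self.weights[iu, ju]

    def total_weight(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(np.triu(self.weights, 1).sum())


@dataclasses.dataclass(frozen=True)
class NodeAtlas:
    """Node labels, hemispheres, region groupings and rich-club flags."""

    node_ids: tuple[str, ...]
    region_names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    rich_club_flags: np.ndarray  # boolean per node

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def rich_node_indices(self) -> np.ndarray:
        return np.flatnonzero(self.rich_club_flags)

    @property
    def rich_club_regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for i in self.rich_node_indices:
            seen.setdefault(self.region_names[i], None)
        return tuple(seen)

    def region_pair(self, region: str) -> tuple[int, int]:
        """(left, right) node indices of a bilateral region."""
        left = right = None
        for i, (r, h) in enumerate(zip(self.region_names, self.hemispheres)):
            if r == region:
                if h == "left":
                    left = i
                else:
                    right = i
        if left is None or right is None:
            raise AtlasError(f"region {region!r} has no (left, right) node pair")
        return left, right

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "region_name": self.region_names,
                "hemisphere": self.hemispheres,
                "rich_club_flag": self.rich_club_flags.astype(int),
            }
        )


def _validate_weights(w: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise NonSquareMatrixError(f"matrix has shape {w.shape}, expected square")
    if not np.isfinite(w).all():
        raise NonFiniteWeightError("matrix contains NaN or infinite entries")
    if (w < 0).any():
        raise NegativeWeightError("matrix contains negative weights")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > atol:
        raise AsymmetricMatrixError(
            f"matrix asymmetry {asym:.3g} exceeds tolerance {atol:.3g}"
        )
    w = (w + w.T) / 2.0  # symmetrize round-trip noise below tolerance
    np.fill_diagonal(w, 0.0)
    return w


def make_connectome(
    weights: np.ndarray,
    node_ids: Sequence[str] | None = None,
    subject_id: str = "subject",
) -> WeightedConnectome:
    """Validate a weight matrix and wrap it as a :class:`WeightedConnectome`."""
    w = _validate_weights(np.asarray(weights, dtype=float).copy())
    if node_ids is None:
        node_ids = tuple(f"n{i}" for i in range(w.shape[0]))
    if len(node_ids) != w.shape[0]:
        raise ConnectomeValidationError(
            f"{len(node_ids)} node ids for a {w.shape[0]}-node matrix"
        )
    return WeightedConnectome(subject_id=str(subject_id), weights=w,
                              node_ids=tuple(node_ids))


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if "," in first else None  # None -> any whitespace


def read_connectome(
    path: str | os.PathLike,
    delimiter: str | None = None,
    node_ids: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> WeightedConnectome:
    """Read a delimited-text connectivity matrix.

    The file must be a square numeric matrix with no header; comma- or
    whitespace-delimited dialects are auto-detected when ``delimiter`` is
    omitted.  Symmetry is enforced to 1e-8 absolute tolerance.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ConnectomeValidationError(f"cannot parse {path}: {exc}") from exc
    if subject_id is None:
        subject_id = path.stem
    return make_connectome(w, node_ids=node_ids, subject_id=subject_id)


def write_connectome(c: WeightedConnectome, path: str | os.PathLike,
                     delimiter: str = ",") -> None:
    """Write the weight matrix as delimited text (17 significant digits)."""
    np.savetxt(path, c.weights, delimiter=delimiter, fmt="%.17g")


def make_atlas(
    node_ids: Sequence[str],
    region_names: Sequence[str],
    hemispheres: Sequence[str],
    rich_club_flags: Sequence[bool],
) -> NodeAtlas:
    if len(set(node_ids)) != len(node_ids):
        dupes = sorted({n for n in node_ids if list(node_ids).count(n) > 1})
        raise AtlasError(f"duplicate node_id(s): {dupes}")
    for h in hemispheres:
        if h not in ("left", "right"):
            raise AtlasError(f"unknown hemisphere code {h!r}")
    return NodeAtlas(
        node_ids=tuple(node_ids),
        region_names=tuple(region_names),
        hemispheres=tuple(hemispheres),
        rich_club_flags=np.asarray(rich_club_flags, dtype=bool).copy(),
    )


def _builtin_aal90(rich_regions: Sequence[str]) -> NodeAtlas:
    node_ids, regions, hemis, flags = [], [], [], []
    for base in _AAL90_REGIONS:
        for hemi, suffix in (("left", "L"), ("right", "R")):
            node_ids.append(f"{base}_{suffix}")
            regions.append(base)
            hemis.append(hemi)
            flags.append(base in rich_regions)
    return make_atlas(node_ids, regions, hemis, flags)


def load_atlas(
    spec: str | os.PathLike = "aal90",
    rich_regions: Sequence[str] | None = None,
) -> NodeAtlas:
    """Load the builtin ``"aal90"`` atlas or a user atlas CSV.

    A user atlas CSV needs columns node_id, region_name, hemisphere,
    rich_club_flag.  ``rich_regions`` overrides the rich-club membership by
    region name (the builtin default is the 12-node bilateral set).
    """
    if str(spec) == "aal90":
        return _builtin_aal90(rich_regions or DEFAULT_RICH_CLUB_REGIONS)
    df = pd.read_csv(spec)
    required = {"node_id", "region_name", "hemisphere", "rich_club_flag"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"atlas file missing column(s): {sorted(missing)}")
    flags = df["rich_club_flag"].astype(bool).to_numpy()
    if rich_regions is not None:
        flags = df["region_name"].isin(rich_regions).to_numpy()
    return make_atlas(
        df["node_id"].astype(str), df["region_name"].astype(str),
        df["hemisphere"].astype(str), flags,
    )


COHORT_COLUMNS = (
    "subject_id", "group", "sex", "age", "education",
    "kmmse", "cdr_sob", "connectome_path",
)


@dataclasses.dataclass
class CohortTable:
    """Validated cohort metadata plus loaded per-subject connectomes."""

    table: pd.DataFrame
    connectomes: dict[str, WeightedConnectome]

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def read_cohort(
    metadata_path: str | os.PathLike,
    matrix_dir: str | os.PathLike | None = None,
    atlas: NodeAtlas | None = None,
) -> CohortTable:
    """Read and validate the cohort CSV and every referenced matrix.

    ``connectome_path`` entries are resolved relative to ``matrix_dir``
    (default: the CSV's directory).  Counts per group×sex cell are logged.
    """
    metadata_path = Path(metadata_path)
    base = Path(matrix_dir) if matrix_dir is not None else metadata_path.parent
    df = pd.read_csv(metadata_path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"cohort CSV missing column(s): {sorted(missing)}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicate subject_id(s): {dupes}")
    bad_group = sorted(set(df["group"]) - set(GROUPS))
    if bad_group:
        raise CohortError(
            f"unknown group label(s) {bad_group}; expected one of {GROUPS}"
        )
    bad_sex = sorted(set(df["sex"]) - set(SEXES))
    if bad_sex:
        raise CohortError(f"unknown sex label(s) {bad_sex}; expected F or M")

    node_ids = atlas.node_ids if atlas is not None else None
    connectomes: dict[str, WeightedConnectome] = {}
    for row in df.itertuples(index=False):
        p = Path(row.connectome_path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise CohortError(
                f"connectome file for subject {row.subject_id!r} not found: {p}"
            )
        connectomes[row.subject_id] = read_connectome(
            p, node_ids=node_ids, subject_id=row.subject_id
        )
    counts = df.groupby(["group", "sex"], observed=True).size()
    logger.info("cohort loaded: %d subjects; cells:\n%s", len(df), counts)
    return CohortTable(table=df, connectomes=connectomes)
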