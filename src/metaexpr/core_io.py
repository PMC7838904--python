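"""Data model and TSV readers/writers shared by every pipeline stage.

All tabular files use a fixed dialect: tab delimiter, "." decimal, UTF-8.
Expression matrices are features x samples with the first column named
``feature_id``. Array intensities are expected on log2 scale; sequencing
data enter as log-CPM (see :mod:`metaexpr.preprocess`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of biological group labels. ``control`` is the merged
#: label produced by :func:`merge_control_groups`.
GROUP_VOCABULARY = frozenset(
    {
        "normal",
        "BPH",
        "NAD",
        "HGPIN",
        "primary_tumor",
        "metastatic_primary_tumor",
        "metastasis",
        "control",
    }
)

#: Labels merged into the single ``control`` group.
CONTROL_SOURCE_GROUPS = frozenset({"normal", "BPH", "NAD"})

#: Groups whose samples carry tumor tissue (subject to content filtering).
TUMOR_GROUPS = frozenset({"primary_tumor", "metastatic_primary_tumor", "metastasis"})


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class ExpressionDataset:
    """One study's feature x sample expression matrix with annotations.

    Parameters
    ----------
    dataset_id, platform_id
        Study and measurement-platform identifiers.
    values
        ``(n_features, n_samples)`` float array of expression intensities
        (log scale).
    feature_ids, sample_ids
        Ordered identifiers matching the matrix axes.
    sample_groups
        Per-sample biological group label from :data:`GROUP_VOCABULARY`.
    tumor_content
        Optional per-sample tumor-tissue fraction in [0, 1]; NaN encodes
        "unknown" and is treated as passing by downstream filters.
    feature_level
        ``"probe"`` or ``"gene"``.
    """

    dataset_id: str
    platform_id: str
    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    sample_groups: list[str]
    tumor_content: np.ndarray | None = None
    feature_level: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.sample_groups = [str(g) for g in self.sample_groups]
        if self.tumor_content is not None:
            self.tumor_content = np.asarray(self.tumor_content, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        nf, ns = self.values.shape
        if len(self.feature_ids) != nf:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.sample_ids) != ns:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {ns} matrix columns"
            )
        if len(self.sample_groups) != ns:
            raise ValidationError("one group label per sample required")
        if len(set(self.sample_ids)) != ns:
            raise ValidationError("duplicate sample ids")
        if self.feature_level not in ("probe", "gene"):
            raise ValidationError(f"unknown feature_level {self.feature_level!r}")
        if self.feature_level == "gene" and len(set(self.feature_ids)) != nf:
            raise ValidationError("duplicate feature ids at gene level")
        bad = sorted(set(self.sample_groups) - GROUP_VOCABULARY)
        if bad:
            raise ValidationError(
                f"unknown group label(s) {bad}; allowed: {sorted(GROUP_VOCABULARY)}"
            )
        if self.tumor_content is not None:
            if self.tumor_content.shape != (ns,):
                raise ValidationError("tumor_content length must match samples")
            known = self.tumor_content[~np.isnan(self.tumor_content)]
            if known.size and (known.min() < 0 or known.max() > 1):
                raise ValidationError("tumor_content must lie in [0, 1]")

    # -- convenience ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def groups_array(self) -> np.ndarray:
        return np.asarray(self.sample_groups, dtype=object)

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        tc = self.tumor_content[keep] if self.tumor_content is not None else None
        return replace(
            self,
            values=self.values[:, keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            sample_groups=[self.sample_groups[i] for i in keep],
            tumor_content=tc,
        )

    def subset_features(self, keep: Sequence[int] | np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            values=self.values[keep, :],
            feature_ids=[self.feature_ids[i] for i in keep],
        )


@dataclass
class ProbeGeneMap:
    """Unambiguous probe -> gene relation (each probe maps to one gene)."""

    mapping: dict[str, str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeGeneMap":
        if not {"probe_id", "gene_id"}.issubset(df.columns):
            raise ValidationError("probe map needs probe_id and gene_id columns")
        probes = df["probe_id"].astype(str)
        if probes.duplicated().any():
            dupes = sorted(probes[probes.duplicated()].unique())
            raise ValidationError(f"ambiguous probes map to multiple genes: {dupes}")
        return cls(dict(zip(probes, df["gene_id"].astype(str))))

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]


@dataclass
class SurvivalTable:
    """Right-censored survival records (time in months, event 1 = observed)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in survival table")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValidationError("survival columns must have one row per sample")
        if np.any(self.time < 0):
            raise ValidationError("survival times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class Comparison:
    """A named two-sided contrast between (possibly merged) group sets."""

    name: str
    case_group: frozenset[str]
    control_group: frozenset[str]

    @classmethod
    def create(
        cls,
        name: str,
        case: str | Iterable[str],
        control: str | Iterable[str],
    ) -> "Comparison":
        case_set = frozenset([case]) if isinstance(case, str) else frozenset(case)
        ctrl_set = frozenset([control]) if isinstance(control, str) else frozenset(control)
        if not case_set or not ctrl_set:
            raise ValidationError(f"comparison {name!r}: empty case or control set")
        if case_set & ctrl_set:
            raise ValidationError(
                f"comparison {name!r}: case and control overlap: {sorted(case_set & ctrl_set)}"
            )
        return cls(name, case_set, ctrl_set)


#: The five disease-stage contrasts run by the default pipeline.
DEFAULT_COMPARISONS = (
    Comparison.create("tumor_vs_control", "primary_tumor", "control"),
    Comparison.create("hgpin_vs_control", "HGPIN", "control"),
    Comparison.create("tumor_vs_hgpin", "primary_tumor", "HGPIN"),
    Comparison.create("aggressive_vs_tumor", "metastatic_primary_tumor", "primary_tumor"),
    Comparison.create("mets_vs_tumor", "metastasis", "primary_tumor"),
)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    feature_level: str = "gene",
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from a matrix TSV and metadata TSV.

    The matrix carries feature ids in the first column (``feature_id``) and
    sample ids in the header. Metadata needs one row per sample with columns
    ``sample_id``, ``dataset``, ``platform``, ``group`` and optionally
    ``tumor_content``. Samples present in the matrix but absent from the
    metadata are an error; metadata rows without a matching matrix column are
    dropped with a warning. Sample order is canonicalized to metadata order.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    matrix.index = matrix.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "dataset", "platform", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing required columns: {sorted(missing)}")

    meta_samples = meta["sample_id"].tolist()
    matrix_samples = [str(c) for c in matrix.columns]
    orphan = sorted(set(matrix_samples) - set(meta_samples))
    if orphan:
        raise ValidationError(
            f"matrix samples absent from metadata: {orphan}"
        )
    extra = [s for s in meta_samples if s not in set(matrix_samples)]
    if extra:
        logger.warning(
            "dropping %d metadata rows without matrix columns: %s", len(extra), extra
        )
        meta = meta[meta["sample_id"].isin(matrix_samples)].reset_index(drop=True)

    matrix = matrix[meta["sample_id"].tolist()]
    datasets = meta["dataset"].unique()
    platforms = meta["platform"].unique()
    if len(datasets) != 1 or len(platforms) != 1:
        raise ValidationError(
            "metadata must describe a single dataset/platform per file; "
            f"got datasets={list(datasets)}, platforms={list(platforms)}"
        )
    tumor_content = None
    if "tumor_content" in meta.columns:
        tumor_content = pd.to_numeric(meta["tumor_content"], errors="coerce").to_numpy()
    return ExpressionDataset(
        dataset_id=str(datasets[0]),
        platform_id=str(platforms[0]),
        values=matrix.to_numpy(dtype=float),
        feature_ids=list(matrix.index),
        sample_ids=list(matrix.columns),
        sample_groups=meta["group"].astype(str).tolist(),
        tumor_content=tumor_content,
        feature_level=feature_level,
    )


def write_dataset(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a dataset as matrix + metadata TSVs (inverse of :func:`load_dataset`)."""
    frame = ds.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(matrix_path, sep="\t", float_format="%.12g")
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "dataset": ds.dataset_id,
            "platform": ds.platform_id,
            "group": ds.sample_groups,
        }
    )
    if ds.tumor_content is not None:
        meta["tumor_content"] = ds.tumor_content
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.12g")


def load_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    genes: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            genes.append(entry)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n", encoding="utf-8")


def load_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a probe map TSV with columns ``probe_id`` and ``gene_id``."""
    return ProbeGeneMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def load_survival_table(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValidationError(f"survival table missing columns: {sorted(missing)}")
    return SurvivalTable(
        sample_ids=df["sample_id"].tolist(),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# group handling
# ---------------------------------------------------------------------------

def merge_control_groups(ds: ExpressionDataset) -> ExpressionDataset:
    """Relabel ``normal``/``BPH``/``NAD`` samples to the merged ``control`` group.

    Matrix values and sample count are never changed; the operation is
    idempotent.
    """
    merged = [
        "control" if g in CONTROL_SOURCE_GROUPS else g for g in ds.sample_groups
    ]
    return replace(ds, sample_groups=merged)
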