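"""Reading, validation and writing of phosphosite quantification tables.

Input tables are tab-separated text: the first column holds phosphosite
identifiers (``PROT_S123``, with ``PROT;S123`` also accepted on input), the
remaining columns hold log2 fold-changes relative to the dataset's control,
one column per condition/treatment. A blank cell means the site was not
quantified in that condition; an explicit ``0.0`` means it was quantified and
unchanged. The two are semantically different and are never conflated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PHOSPHO_RESIDUES = frozenset("STY")

#: greedy protein group so the *last* separator splits protein from residue,
#: letting accessions like ``NP_001_S5`` parse as protein ``NP_001``.
_SITE_RE = re.compile(r"^(?P<protein>.+)(?P<sep>[_;])(?P<residue>[A-Za-z])(?P<position>\d+)$")


class SiteParseError(ValueError):
    """Raised when a phosphosite identifier cannot be parsed."""


@dataclass(frozen=True, order=True)
class SiteId:
    """Canonical phosphosite identifier: protein + residue + 1-based position.

    The protein field is an opaque string (gene symbol or accession); the
    residue must be one of the phosphorylatable amino acids S, T or Y.
    """

    protein: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if not self.protein:
            raise SiteParseError("empty protein identifier")
        if self.residue not in PHOSPHO_RESIDUES:
            raise SiteParseError(
                f"residue {self.residue!r} is not phosphorylatable (expected S, T or Y)"
            )
        if self.position < 1:
            raise SiteParseError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"


def parse_site_id(raw: str, dialect: str | None = None) -> SiteId:
    """Parse a phosphosite identifier string into a canonical :class:`SiteId`.

    Parameters
    ----------
    raw
        Identifier such as ``"SRSF1_S199"`` or ``"SRSF1;S199"``. The residue
        letter is case-normalized to upper case.
    dialect
        ``"underscore"``, ``"semicolon"`` or ``None`` to accept either
        separator (the last separator in the string wins).
    """
    if not raw or not raw.strip():
        raise SiteParseError("empty site identifier")
    token = raw.strip()
    m = _SITE_RE.match(token)
    if m is None:
        raise SiteParseError(f"malformed site identifier: {token!r}")
    sep = m.group("sep")
    if dialect == "underscore" and sep != "_":
        raise SiteParseError(f"expected '_' separator in {token!r}")
    if dialect == "semicolon" and sep != ";":
        raise SiteParseError(f"expected ';' separator in {token!r}")
    residue = m.group("residue").upper()
    position = int(m.group("position"))
    if residue not in PHOSPHO_RESIDUES:
        raise SiteParseError(
            f"residue {residue!r} in {token!r} is not phosphorylatable (expected S, T or Y)"
        )
    if position < 1:
        raise SiteParseError(f"non-positive position in {token!r}")
    return SiteId(m.group("protein"), residue, position)


@dataclass
class DatasetTable:
    """One dataset's site-by-condition log2 fold-change matrix.

    ``data`` is a float DataFrame indexed by :class:`SiteId` with one column
    per condition; NaN marks a missing (not quantified) value. Rows that are
    entirely missing are invalid — a never-detected site must simply be absent.
    """

    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.data.shape[1] < 1:
            raise ValueError(f"dataset {self.dataset_id!r} has no condition columns")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise ValueError(f"dataset {self.dataset_id!r} has duplicate condition labels")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(
                f"dataset {self.dataset_id!r} has duplicate sites after "
                f"canonicalization: {', '.join(str(s) for s in dups[:5])}"
            )
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            bad = [str(s) for s in self.data.index[all_missing][:5]]
            raise ValueError(
                f"dataset {self.dataset_id!r} has fully-missing rows "
                f"(sites {', '.join(bad)}); a non-identified site must be absent"
            )
        self.data = self.data.astype(float)

    @property
    def sites(self) -> list[SiteId]:
        return list(self.data.index)

    @property
    def site_set(self) -> frozenset[SiteId]:
        return frozenset(self.data.index)

    @property
    def conditions(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]


@dataclass
class Collection:
    """A collection of datasets sharing a phosphosite identifier space."""

    datasets: list[DatasetTable]

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset_ids in collection")

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def universe(self) -> frozenset[SiteId]:
        out: set[SiteId] = set()
        for d in self.datasets:
            out |= d.site_set
        return frozenset(out)


def _collapse_duplicates(df: pd.DataFrame, dataset_id: str) -> pd.DataFrame:
    """Collapse duplicate site rows keeping, per condition, the value with the
    maximum absolute magnitude (conservative for a maximum-change feature)."""
    if not df.index.has_duplicates:
        return df
    n_dup = int(df.index.duplicated().sum())
    logger.warning(
        "dataset %s: collapsing %d duplicate site row(s) by max-|value| per condition",
        dataset_id,
        n_dup,
    )

    def _pick(col: pd.Series) -> float:
        vals = col.dropna()
        if vals.empty:
            return np.nan
        return float(vals.iloc[int(np.argmax(np.abs(vals.to_numpy())))])

    collapsed = df.groupby(level=0, sort=False).agg(_pick)
    # groupby preserves first-appearance order with sort=False
    return collapsed


def read_dataset_table(
    path: Union[str, Path],
    dataset_id: str | None = None,
    dialect: str | None = None,
) -> DatasetTable:
    """Read a tab-separated site-by-condition log2FC table.

    First column: site identifiers; remaining columns: numeric-or-blank
    fold-changes. Duplicate site rows (same canonical identifier) are
    collapsed by keeping the value of maximum absolute magnitude per
    condition, with a warning.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: no condition columns")
    conditions = header[1:]
    if len(set(conditions)) != len(conditions):
        raise ValueError(f"{path}: duplicate condition labels in header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = conditions

    def _to_float(x: str) -> float:
        if x == "":
            return np.nan
        try:
            return float(x)  # exact strtod, round-trips %.17g output
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell {x!r}") from exc

    values = df.apply(lambda col: col.map(_to_float)).astype(float)
    values.index = pd.Index([parse_site_id(str(s), dialect=dialect) for s in df.index])
    values = _collapse_duplicates(values, dataset_id)
    return DatasetTable(dataset_id=dataset_id, data=values)


def write_dataset_table(table: DatasetTable, path: Union[str, Path]) -> None:
    """Write a :class:`DatasetTable` as tab-separated text (blank = missing)."""
    out = table.data.copy()
    out.index = pd.Index([str(s) for s in out.index], name="site")
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


STABILITY_COLUMNS = [
    "site",
    "recurrence",
    "phospho_change",
    "p_recurrence",
    "p_change",
    "p_combined",
    "is_sps",
]


def write_stability_table(results: Sequence, path: Union[str, Path]) -> None:
    """Write per-site stability statistics as tab-separated text.

    ``results`` is a sequence of :class:`stablephos.stability.StabilityResult`.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rows = [
        {
            "site": str(r.site),
            "recurrence": r.features.recurrence,
            "phospho_change": r.features.phospho_change,
            "p_recurrence": r.p_recurrence,
            "p_change": r.p_change,
            "p_combined": r.p_combined,
            "is_sps": r.is_sps,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=STABILITY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stability_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a stability table written by :func:`write_stability_table`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(STABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing stability columns {sorted(missing)}")
    df["is_sps"] = df["is_sps"].astype(bool)
    return df


def write_feature_table(features: Sequence, path: Union[str, Path]) -> None:
    """Write the intermediate per-site feature table (TSV)."""
    rows = [
        {
            "site": str(f.site),
            "recurrence": f.recurrence,
            "phospho_change": f.phospho_change,
            "n_contributing": f.n_contributing,
        }
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_manifest(path: Union[str, Path]) -> list[tuple[str, Path]]:
    """Read a collection manifest mapping dataset_id -> file path.

    Accepts a YAML mapping ``{id: path}`` (optionally nested under a
    ``datasets`` key) or a YAML list of ``{id: ..., path: ...}`` entries.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict) and "datasets" in doc:
        doc = doc["datasets"]
    entries: list[tuple[str, Path]] = []
    if isinstance(doc, dict):
        for k, v in doc.items():
            entries.append((str(k), Path(v)))
    elif isinstance(doc, list):
        for item in doc:
            entries.append((str(item["id"]), Path(item["path"])))
    else:
        raise ValueError(f"{path}: manifest must be a mapping or a list of entries")
    base = path.parent
    return [(k, p if p.is_absolute() else base / p) for k, p in entries]


def read_collection(manifest_path: Union[str, Path], dialect: str | None = None) -> Collection:
    """Load every dataset named in a manifest into a :class:`Collection`."""
    entries = read_manifest(manifest_path)
    datasets = []
    for dataset_id, p in entries:
        if not p.exists():
            raise FileNotFoundError(
                f"manifest entry {dataset_id!r} points to missing file {p}"
            )
        datasets.append(read_dataset_table(p, dataset_id=dataset_id, dialect=dialect))
    return Collection(datasets=datasets)
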