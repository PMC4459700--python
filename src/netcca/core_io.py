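"""Reading, writing and identifier harmonization for paired omics matrices.

All matrices are held samples-in-rows. Feature identifiers are free-form
strings; metabolites are normalized to the ``CHEBI:<integer>`` form and gene
identifiers are matched case-sensitively after harmonization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "AnnotationMap",
    "GeneSetCollection",
    "read_omics_matrix",
    "write_omics_matrix",
    "harmonize_identifiers",
    "read_annotation_map",
    "read_gene_sets",
    "normalize_chebi_id",
]


_CHEBI_RE = re.compile(r"^(?:chebi[:_\s]*)?(\d+)$", re.IGNORECASE)


def normalize_chebi_id(raw: str) -> str:
    """Normalize a ChEBI identifier to ``CHEBI:<integer>``.

    Accepts bare integers (``16196``), prefixed forms (``ChEBI: 16196``,
    ``chebi_16196``) and returns the canonical upper-case form. Strings that
    do not look like ChEBI identifiers are returned unchanged.
    """
    m = _CHEBI_RE.match(str(raw).strip())
    if m:
        return f"CHEBI:{int(m.group(1))}"
    return str(raw).strip()


@dataclass
class OmicsBlock:
    """A samples x features real matrix for one omics layer.

    Parameters
    ----------
    sample_ids
        Unique, ordered sample identifiers (rows).
    feature_ids
        Unique, ordered feature identifiers (columns) — gene symbols for a
        transcriptomics block, ``CHEBI:<n>`` identifiers for a metabolite
        block.
    values
        ``(n_samples, n_features)`` float array with no missing values.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"column count {p} != number of feature ids {len(self.feature_ids)}"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dups = _duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {name} ids: {sorted(dups)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r} (and {len(bad) - 1} more)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, feature_ids: Iterable[str]) -> "OmicsBlock":
        """Column-subset the block, preserving the requested order."""
        wanted = list(feature_ids)
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise KeyError(f"features not in block: {missing}")
        cols = [index[f] for f in wanted]
        return OmicsBlock(list(self.sample_ids), wanted, self.values[:, cols].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class AnnotationMap:
    """Platform-to-standard identifier mapping.

    ``entries`` maps a platform identifier to a gene symbol or a
    ``CHEBI:<integer>`` identifier; ``unmapped`` lists platform identifiers
    known to have no standard counterpart. An identifier appears in exactly
    one of the two.
    """

    entries: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.entries) & set(self.unmapped)
        if overlap:
            raise ValueError(f"ids both mapped and unmapped: {sorted(overlap)}")
        for pid, sid in self.entries.items():
            if not sid:
                raise ValueError(f"empty standard id for platform id {pid!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with an optional enrichment universe."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    return dups


def read_omics_matrix(
    path: str | Path,
    orientation: Literal["samples_in_rows", "features_in_rows"] = "samples_in_rows",
) -> OmicsBlock:
    """Read a TSV omics matrix into an :class:`OmicsBlock`.

    The file has one header row and one identifier column; the body is
    numeric with ``.`` as decimal separator. ``orientation`` names what the
    file's rows are; the returned block is always samples-in-rows.

    Raises
    ------
    ValueError
        On duplicate identifiers, non-numeric cells or missing values.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    # pandas silently mangles duplicate header names; check the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = _duplicates(header)
    if dups:
        raise ValueError(f"{path}: duplicate column ids: {sorted(dups)}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    for name, ids in (("row", row_ids), ("column", col_ids)):
        dups = _duplicates(ids)
        if dups:
            raise ValueError(f"{path}: duplicate {name} ids: {sorted(dups)}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(
                    f"{path}: missing value at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r} (imputation is out of scope)"
                )
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
    if orientation == "features_in_rows":
        return OmicsBlock(col_ids, row_ids, values.T)
    return OmicsBlock(row_ids, col_ids, values)


def write_omics_matrix(block: OmicsBlock, path: str | Path) -> None:
    """Write an :class:`OmicsBlock` as TSV, samples-in-rows, 17 significant
    digits (round-trips float64 exactly through text)."""
    block.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def harmonize_identifiers(
    block: OmicsBlock,
    annotation: AnnotationMap,
    drop_unmapped: bool = True,
) -> tuple[OmicsBlock, list[str]]:
    """Rename features to standard identifiers, dropping unmapped ones.

    Retained columns keep their original order. Two platform identifiers
    mapping to one standard identifier is an error: collapsing them would
    require an aggregation rule the caller must choose.

    Returns
    -------
    (harmonized block, list of dropped platform identifiers)
    """
    new_ids: list[str] = []
    keep_cols: list[int] = []
    dropped: list[str] = []
    for j, fid in enumerate(block.feature_ids):
        std = annotation.entries.get(fid)
        if std is None:
            if drop_unmapped:
                dropped.append(fid)
                continue
            std = fid
        new_ids.append(std)
        keep_cols.append(j)
    dups = _duplicates(new_ids)
    if dups:
        raise ValueError(
            f"ambiguous collapse: multiple platform ids map to {sorted(dups)}; "
            "aggregate upstream before harmonizing"
        )
    out = OmicsBlock(
        list(block.sample_ids), new_ids, block.values[:, keep_cols].copy()
    )
    return out, dropped


def read_annotation_map(path: str | Path, chebi: bool = False) -> AnnotationMap:
    """Read a two-column TSV ``platform_id <tab> standard_id``.

    Rows with an empty standard id are recorded as unmapped. With
    ``chebi=True`` standard ids are normalized to ``CHEBI:<integer>``.
    """
    entries: dict[str, str] = {}
    unmapped: list[str] = []
    df = pd.read_csv(
        path, sep="\t", header=None, names=["platform_id", "standard_id"], dtype=str
    )
    for _, row in df.iterrows():
        pid = str(row["platform_id"]).strip()
        sid = row["standard_id"]
        if pid in entries or pid in unmapped:
            raise ValueError(f"{path}: duplicate platform id {pid!r}")
        if sid is None or (isinstance(sid, float) and np.isnan(sid)) or not str(sid).strip():
            unmapped.append(pid)
        else:
            sid = str(sid).strip()
            entries[pid] = normalize_chebi_id(sid) if chebi else sid
    return AnnotationMap(entries=entries, unmapped=unmapped)


def read_gene_sets(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read standard GMT (name, description, members; tab-separated).

    Duplicate members within a set are de-duplicated; a duplicated set name
    or a line with fewer than three fields is an error naming the line.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    uni = frozenset(universe) if universe is not None else None
    return GeneSetCollection(sets=sets, universe=uni)
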