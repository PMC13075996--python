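"""Tabular I/O for the co-association pipeline.

All on-disk artifacts are tab-delimited UTF-8 text with a header row:
count tables (features as rows, samples as columns), taxonomy tables
(feature id, lineage string), phenotype tables and edge lists.  Reading
followed by writing is the identity on every table kind (exact for
integers and identifiers; correlations to six decimal places).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = ""
PHENOTYPE_NAMES = ("EFF", "CH4Y", "ACET_PROP")

_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")
_RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the expected format."""


@dataclasses.dataclass
class CountMatrix:
    """Integer ASV x sample abundance table.

    ``counts`` has shape ``(len(feature_ids), len(sample_ids))``;
    features are rows, matching the canonical on-disk orientation.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        if len(self.feature_ids) == 0 or len(self.sample_ids) == 0:
            raise TableFormatError("feature and sample id lists must be non-empty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise TableFormatError(f"duplicate feature ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise TableFormatError(f"duplicate sample ids: {dupes}")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, self.counts):
                i, j = np.argwhere(as_int != self.counts)[0]
                raise TableFormatError(
                    f"non-integer count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def select_features(self, ids: Sequence[str]) -> "CountMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in ids]
        return CountMatrix(list(ids), list(self.sample_ids), self.counts[rows])


@dataclasses.dataclass
class TaxonomyTable:
    """Per-ASV ranked lineage parsed from Greengenes-style strings.

    ``lineages`` maps feature id to a dict of rank name -> label, where
    an absent or empty rank is recorded as :data:`MISSING`.
    """

    feature_ids: list[str]
    lineages: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise TableFormatError(f"duplicate feature ids: {_duplicates(self.feature_ids)}")

    def family(self, feature_id: str) -> str:
        return self.lineages[feature_id].get("family", MISSING)

    def genus(self, feature_id: str) -> str:
        return self.lineages[feature_id].get("genus", MISSING)

    def rank_labels(self, rank: str) -> dict[str, str]:
        """Map feature id -> label at ``rank`` (MISSING when unassigned)."""
        return {f: self.lineages[f].get(rank, MISSING) for f in self.feature_ids}

    def lineage_string(self, feature_id: str) -> str:
        ranks = self.lineages[feature_id]
        return "; ".join(
            f"{pre}{ranks.get(name, MISSING)}" for pre, name in zip(_RANK_PREFIXES, _RANK_NAMES)
        )


@dataclasses.dataclass
class PhenotypeTable:
    """Per-sample continuous phenotypes: feed efficiency (EFF, output per
    kg dry-matter intake), methane yield (CH4Y, g CH4 per kg dry-matter
    intake) and the molar acetate:propionate ratio (ACET_PROP)."""

    sample_ids: list[str]
    values: pd.DataFrame  # index = sample_ids, columns = PHENOTYPE_NAMES

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError(f"duplicate sample ids: {_duplicates(self.sample_ids)}")
        missing = [c for c in PHENOTYPE_NAMES if c not in self.values.columns]
        if missing:
            raise TableFormatError(f"phenotype table lacks columns: {missing}")
        self.values = self.values.loc[self.sample_ids, list(PHENOTYPE_NAMES)].astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise TableFormatError("phenotype values must all be finite")
        if (self.values["CH4Y"] <= 0).any():
            raise TableFormatError("CH4Y must be positive")
        if (self.values["ACET_PROP"] <= 0).any():
            raise TableFormatError("ACET_PROP must be positive")

    def vector(self, phenotype: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        return self.values.loc[ids, phenotype].to_numpy(dtype=float)


@dataclasses.dataclass
class EdgeList:
    """Retained network edges as (node_a, node_b, correlation, edge_type)
    rows with edge_type in {asv-asv, asv-phenotype}."""

    rows: list[tuple[str, str, float, str]]

    def __post_init__(self) -> None:
        seen = set()
        for a, b, r, kind in self.rows:
            if a == b:
                raise TableFormatError(f"self edge on node {a!r}")
            if r == 0 or not -1.0 <= r <= 1.0:
                raise TableFormatError(f"edge {a}-{b} correlation {r} outside (0,1] magnitude")
            if kind not in ("asv-asv", "asv-phenotype"):
                raise TableFormatError(f"unknown edge type {kind!r}")
            key = frozenset((a, b))
            if key in seen:
                raise TableFormatError(f"duplicate edge {a}-{b}")
            seen.add(key)

    def sorted_rows(self) -> list[tuple[str, str, float, str]]:
        return sorted(self.rows, key=lambda row: (row[3], row[0], row[1]))


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for item in ids:
        if item in seen and item not in dupes:
            dupes.append(item)
        seen.add(item)
    return dupes


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # A leading "# Constructed from biom file" comment (BIOM TSV export) is skipped.
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    while start < len(lines) and lines[start].startswith("# Constructed from biom"):
        start += 1
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines[start:])), sep="\t", header=0, dtype=str)


def read_count_table(path: str | Path, samples_as_rows: bool = False) -> CountMatrix:
    """Read a tab-delimited count table (first column = feature id,
    header = sample ids; transposed when ``samples_as_rows``)."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise TableFormatError(f"{path}: count table needs an id column plus data columns")
    frame = frame.set_index(frame.columns[0])
    if samples_as_rows:
        frame = frame.T
    feature_ids = [str(f) for f in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    values = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                as_float = float(raw)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: non-numeric count {raw!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if as_float < 0 or as_float != int(as_float):
                raise TableFormatError(
                    f"{path}: count {raw!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} is not a non-negative integer"
                )
            values[i, j] = int(as_float)
    return CountMatrix(feature_ids, sample_ids, values)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``d__...; p__...; ...`` into rank -> label, MISSING for
    empty or absent ranks."""
    ranks = {name: MISSING for name in _RANK_NAMES}
    for field in str(lineage).split(";"):
        field = field.strip()
        for prefix, name in zip(_RANK_PREFIXES, _RANK_NAMES):
            if field.startswith(prefix):
                ranks[name] = field[len(prefix):].strip() or MISSING
                break
    return ranks


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column (feature id, lineage) tab-delimited taxonomy table."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise TableFormatError(f"{path}: taxonomy table needs feature id and lineage columns")
    feature_ids = [str(f) for f in frame.iloc[:, 0]]
    lineages = {
        fid: parse_lineage(lin if pd.notna(lin) else "")
        for fid, lin in zip(feature_ids, frame.iloc[:, 1])
    }
    return TaxonomyTable(feature_ids, lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tlineage\n")
        for fid in taxonomy.feature_ids:
            fh.write(f"{fid}\t{taxonomy.lineage_string(fid)}\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype table (TSV or CSV) with header
    ``sample_id, EFF, CH4Y, ACET_PROP``."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, header=0)
    if "sample_id" not in frame.columns:
        raise TableFormatError(f"{path}: phenotype table needs a sample_id column")
    sample_ids = [str(s) for s in frame["sample_id"]]
    values = frame.drop(columns=["sample_id"])
    values.index = sample_ids
    return PhenotypeTable(sample_ids, values)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    frame = table.values.copy()
    frame.insert(0, "sample_id", table.sample_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    """Write edges sorted by (edge_type, node_a, node_b); correlations
    to six decimal places."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcorrelation\tedge_type\n")
        for a, b, r, kind in edges.sorted_rows():
            fh.write(f"{a}\t{b}\t{r:.6f}\t{kind}\n")


def read_edge_list(path: str | Path) -> EdgeList:
    frame = _read_tsv(path)
    expected = ["node_a", "node_b", "correlation", "edge_type"]
    if list(frame.columns) != expected:
        raise TableFormatError(f"{path}: edge list columns must be {expected}")
    rows = [
        (str(a), str(b), float(r), str(kind))
        for a, b, r, kind in frame.itertuples(index=False)
    ]
    return EdgeList(rows)
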