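"""Readers and writers for every on-disk artifact the pipeline touches.

All tables are UTF-8, tab-separated, LF-terminated. Readers validate
eagerly and raise :class:`FormatError` with row/column context instead of
silently coercing; writers emit a canonical form (sorted identifiers) so
that read -> write round-trips are byte-stable.

Coordinates in the gene annotation are 1-based inclusive. Fusion
breakpoints keep the caller's ``chrom:pos:strand`` string convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CountMatrix",
    "PathwayModel",
    "GeneSet",
    "GeneSetCollection",
    "FusionRecord",
    "DrugModel",
    "MITOCHONDRIAL_CHROMOSOMES",
    "read_count_matrix",
    "write_count_matrix",
    "write_sample_sheet",
    "read_pathways",
    "write_pathways",
    "read_fusion_table",
    "write_fusion_table",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_annotation",
    "write_annotation",
    "read_drug_models",
    "write_drug_models",
]

#: Chromosome labels treated as the mitochondrial contig.
MITOCHONDRIAL_CHROMOSOMES = frozenset({"MT", "chrM", "chrMT"})

VALID_CONDITIONS = frozenset({"case", "control"})


class FormatError(ValueError):
    """A malformed on-disk artifact; the message carries row/column context."""


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample read counts plus per-sample metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = gene ids, columns = sample ids.
    sample_meta : pandas.DataFrame
        Indexed by sample id with columns ``tissue``, ``condition``
        (``case`` or ``control``) and ``group`` (free label).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dupes = c.index[c.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.duplicated().any():
            dupes = c.columns[c.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise FormatError("counts must be integers")
        if (c.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        missing = c.columns.difference(self.sample_meta.index)
        if len(missing):
            raise FormatError(f"unannotated sample(s): {sorted(missing)}")
        for col in ("tissue", "condition", "group"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample sheet lacks column {col!r}")
        bad = set(self.sample_meta.loc[c.columns, "condition"]) - VALID_CONDITIONS
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        meta = self.sample_meta.loc[self.sample_ids]
        return list(meta.index[meta["group"] == group])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order kept)."""
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return CountMatrix(
            counts=self.counts.loc[:, list(sample_ids)].copy(),
            sample_meta=self.sample_meta.loc[list(sample_ids)].copy(),
        )


def read_count_matrix(path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample sheet.

    The matrix file has a header row of sample ids and gene ids in the
    first column. The sample sheet has columns ``sample_id``, ``tissue``,
    ``condition``, ``group``. Samples present in the matrix but absent
    from the sheet are an error.
    """
    path = Path(path)
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"{path}: cannot parse count matrix: {exc}") from exc
    for col in counts.columns:
        series = counts[col]
        if not np.issubdtype(series.dtype, np.integer):
            bad = series[pd.to_numeric(series, errors="coerce").isna()]
            if len(bad):
                raise FormatError(
                    f"{path}: non-numeric count at gene {bad.index[0]!r}, "
                    f"sample {col!r}: {bad.iloc[0]!r}"
                )
            as_float = series.astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                off = as_float[as_float != np.round(as_float)]
                raise FormatError(
                    f"{path}: non-integer count at gene {off.index[0]!r}, sample {col!r}"
                )
            counts[col] = as_float.astype(np.int64)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "condition", "group"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"{sample_sheet_path}: sample sheet needs columns {sorted(required)}"
        )
    if sheet["sample_id"].duplicated().any():
        raise FormatError(f"{sample_sheet_path}: duplicate sample_id rows")
    meta = sheet.set_index("sample_id")[["tissue", "condition", "group"]]
    return CountMatrix(counts=counts.astype(np.int64), sample_meta=meta)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write counts in canonical form: genes and samples sorted, LF endings."""
    ordered = cm.counts.sort_index(axis=0).sort_index(axis=1)
    ordered.to_csv(Path(path), sep="\t", index_label="gene_id", lineterminator="\n")


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    meta = cm.sample_meta.loc[sorted(cm.sample_ids)]
    meta.to_csv(Path(path), sep="\t", index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Pathways (gene -> activator/repressor role maps)
# ---------------------------------------------------------------------------


@dataclass
class PathwayModel:
    """A named pathway: member genes each with an activator/repressor role.

    ``arr`` is +1 for an activator, -1 for a repressor, and 0 when the
    gene's role in the pathway is ambiguous. A pathway is scoreable only
    if at least one member has a non-zero role.
    """

    pathway_id: str
    members: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: a for g, a in self.members.items() if a not in (-1, 0, 1)}
        if bad:
            raise FormatError(f"pathway {self.pathway_id}: invalid ARR value(s) {bad}")

    @property
    def scoreable(self) -> bool:
        return any(a != 0 for a in self.members.values())


def read_pathways(path: str | Path) -> dict[str, PathwayModel]:
    """Read a pathway TSV with columns ``pathway_id``, ``gene_id``, ``arr``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"pathway_id": str, "gene_id": str})
    if df.empty:
        raise FormatError(f"{path}: empty pathway file")
    required = {"pathway_id", "gene_id", "arr"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pathway TSV needs columns {sorted(required)}")
    dup = df.duplicated(subset=["pathway_id", "gene_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (pathway, gene) row ({row['pathway_id']}, {row['gene_id']})"
        )
    pathways: dict[str, PathwayModel] = {}
    for (pid,), sub in df.groupby(["pathway_id"], sort=True):
        members: dict[str, int] = {}
        for _, row in sub.iterrows():
            arr = row["arr"]
            if arr not in (-1, 0, 1):
                raise FormatError(
                    f"{path}: invalid ARR {arr!r} for ({pid}, {row['gene_id']})"
                )
            members[str(row["gene_id"])] = int(arr)
        pathways[str(pid)] = PathwayModel(pathway_id=str(pid), members=members)
    return pathways


def write_pathways(pathways: Mapping[str, PathwayModel], path: str | Path) -> None:
    rows = [
        (pid, gene, arr)
        for pid in sorted(pathways)
        for gene, arr in sorted(pathways[pid].members.items())
    ]
    pd.DataFrame(rows, columns=["pathway_id", "gene_id", "arr"]).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]


GeneSetCollection = dict[str, GeneSet]


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``term<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    collection: GeneSetCollection = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {term!r}")
            if term in collection:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            collection[term] = GeneSet(name=desc, genes=frozenset(genes))
    if not collection:
        raise FormatError(f"{path}: empty GMT file")
    return collection


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for term in sorted(collection):
            gs = collection[term]
            fh.write("\t".join([term, gs.name, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (BED-like, 1-based inclusive)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chromosome", "start", "end", "strand"]


def _is_mitochondrial(chromosome: str, symbol: str) -> bool:
    return chromosome in MITOCHONDRIAL_CHROMOSOMES or symbol.startswith("MT-")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV.

    Columns ``gene_id, symbol, chromosome, start, end, strand`` with
    1-based inclusive coordinates. Returns a DataFrame indexed by gene_id
    with an added ``is_mitochondrial`` flag derived from the chromosome
    label (MT/chrM/chrMT) or an ``MT-`` symbol prefix.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not set(ANNOTATION_COLUMNS).issubset(df.columns):
        raise FormatError(f"{path}: annotation needs columns {ANNOTATION_COLUMNS}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id(s): {dupes[:5]}")
    for col in ("start", "end"):
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer {col}: {exc}") from exc
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise FormatError(
            f"{path}: start > end for gene {bad.iloc[0]['gene_id']!r}"
        )
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise FormatError(f"{path}: invalid strand value(s) {sorted(bad_strand)}")
    df = df.set_index("gene_id")
    df["is_mitochondrial"] = [
        _is_mitochondrial(c, s) for c, s in zip(df["chromosome"], df["symbol"])
    ]
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.sort_index()[["symbol", "chromosome", "start", "end", "strand"]]
    out.to_csv(Path(path), sep="\t", index_label="gene_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Fusion caller output (STAR-Fusion tab-delimited dialect)
# ---------------------------------------------------------------------------

FUSION_COLUMNS = [
    "FusionName",
    "JunctionReadCount",
    "SpanningFragCount",
    "LeftGene",
    "LeftBreakpoint",
    "RightGene",
    "RightBreakpoint",
]


@dataclass
class FusionRecord:
    """One raw fusion call from the caller's output table."""

    fusion_name: str
    left_gene: str
    right_gene: str
    left_breakpoint: tuple[str, int, str]  # (chromosome, position, strand)
    right_breakpoint: tuple[str, int, str]
    junction_read_count: int
    spanning_frag_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.junction_read_count < 0 or self.spanning_frag_count < 0:
            raise FormatError(
                f"{self.fusion_name}: negative support counts"
            )

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.left_gene, self.right_gene)


def _parse_breakpoint(text: str, context: str) -> tuple[str, int, str]:
    parts = text.split(":")
    if len(parts) != 3 or parts[2] not in {"+", "-"}:
        raise FormatError(f"{context}: unparseable breakpoint {text!r}")
    try:
        pos = int(parts[1])
    except ValueError as exc:
        raise FormatError(f"{context}: unparseable breakpoint {text!r}") from exc
    return (parts[0], pos, parts[2])


def _parse_gene_field(text: str) -> str:
    # the caller uses "SYMBOL^ENSGxxxx"; keep the symbol when present
    return text.split("^", 1)[0]


def read_fusion_table(path: str | Path, sample_id: str) -> list[FusionRecord]:
    """Read one fusion-caller output table for one sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        ctx = f"{path}: row {i + 1}"
        try:
            junction = int(row["JunctionReadCount"])
            spanning = int(row["SpanningFragCount"])
        except ValueError as exc:
            raise FormatError(f"{ctx}: non-integer support count") from exc
        records.append(
            FusionRecord(
                fusion_name=row["FusionName"],
                left_gene=_parse_gene_field(row["LeftGene"]),
                right_gene=_parse_gene_field(row["RightGene"]),
                left_breakpoint=_parse_breakpoint(row["LeftBreakpoint"], ctx),
                right_breakpoint=_parse_breakpoint(row["RightBreakpoint"], ctx),
                junction_read_count=junction,
                spanning_frag_count=spanning,
                sample_id=sample_id,
            )
        )
    return records


def write_fusion_table(records: Iterable[FusionRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "FusionName": r.fusion_name,
                "JunctionReadCount": r.junction_read_count,
                "SpanningFragCount": r.spanning_frag_count,
                "LeftGene": r.left_gene,
                "LeftBreakpoint": ":".join(map(str, r.left_breakpoint)),
                "RightGene": r.right_gene,
                "RightBreakpoint": ":".join(map(str, r.right_breakpoint)),
            }
        )
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Drug models
# ---------------------------------------------------------------------------


@dataclass
class DrugModel:
    """A therapy scored through its target genes and (optionally) pathways."""

    drug_id: str
    target_gene_ids: frozenset[str]
    pathway_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.target_gene_ids:
            raise FormatError(f"drug {self.drug_id!r} without targets")


def read_drug_models(
    path: str | Path, pathways: Mapping[str, PathwayModel] | None = None
) -> list[DrugModel]:
    """Read a drug-model TSV: ``drug_id, targets, pathways`` (comma-joined).

    When a pathway collection is supplied, referenced pathway ids must
    exist in it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "targets"}.issubset(df.columns):
        raise FormatError(f"{path}: drug TSV needs columns drug_id, targets")
    if df["drug_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate drug_id rows")
    drugs = []
    for _, row in df.iterrows():
        targets = frozenset(
            t for t in str(row["targets"]).split(",") if t and t != "nan"
        )
        if not targets or pd.isna(row["targets"]):
            raise FormatError(f"{path}: drug {row['drug_id']!r} without targets")
        raw_pw = row.get("pathways")
        pw = frozenset(
            p for p in str(raw_pw).split(",") if p and not pd.isna(raw_pw) and p != "nan"
        )
        if pathways is not None:
            unknown = pw - set(pathways)
            if unknown:
                raise FormatError(
                    f"{path}: drug {row['drug_id']!r} references unknown "
                    f"pathway(s) {sorted(unknown)}"
                )
        drugs.append(
            DrugModel(drug_id=str(row["drug_id"]), target_gene_ids=targets, pathway_ids=pw)
        )
    return drugs


def write_drug_models(drugs: Iterable[DrugModel], path: str | Path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "targets": ",".join(sorted(d.target_gene_ids)),
            "pathways": ",".join(sorted(d.pathway_ids)),
        }
        for d in sorted(drugs, key=lambda d: d.drug_id)
    ]
    pd.DataFrame(rows, columns=["drug_id", "targets", "pathways"]).to_csv(
        Path(path), sep="\t", index=False, lineterminator="\n"
    )
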