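"""Readers and writers for every external artifact of the pipeline.

Canonical interchange is TSV: counts are gene_id + one column per sample,
sample sheets carry ``sample_id, timepoint, fraction, replicate``, annotation
tables carry ``gene_id, length_bp, biotype`` and gene sets use the standard
GMT layout.  MatrixMarket triplets (with ``.rows``/``.cols`` sidecars) are
accepted as count input only.  Gene identifiers are opaque strings; no
Ensembl/symbol mapping is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

FRACTIONS = ("free", "polysome")

SAMPLE_COLUMNS = ["sample_id", "timepoint", "fraction", "replicate"]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout or invariants."""


@dataclasses.dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample sheet describing columns.

    ``counts`` is a genes x samples DataFrame (index = gene ids, columns =
    sample ids); ``samples`` is indexed by sample_id with columns
    ``timepoint`` (ordered categorical), ``fraction`` and ``replicate``.
    Column order of ``counts`` always follows the sample sheet.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups[:5])}")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.samples.index) - set(self.counts.columns)
            orphan = set(self.counts.columns) - set(self.samples.index)
            if missing or orphan:
                raise FormatError(
                    f"sample sheet / matrix mismatch: missing from matrix "
                    f"{sorted(missing)}, not in sheet {sorted(orphan)}"
                )
            # same set, wrong order: realign to the sheet
            self.counts = self.counts[list(self.samples.index)]
        arr = self.counts.to_numpy()
        if np.issubdtype(arr.dtype, np.floating):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.round(arr)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        bad = set(self.samples["fraction"]) - set(FRACTIONS)
        if bad:
            raise FormatError(f"unknown fraction labels: {sorted(bad)}")
        if self.samples.index.duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def timepoints(self) -> list[str]:
        """Time-point labels in sheet order (categorical order if set)."""
        tp = self.samples["timepoint"]
        if isinstance(tp.dtype, pd.CategoricalDtype):
            return [t for t in tp.cat.categories if t in set(tp)]
        seen: list[str] = []
        for t in tp:
            if t not in seen:
                seen.append(t)
        return seen

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, mask: pd.Series | Sequence[bool] | list[str]) -> "CountMatrix":
        """Subset to samples by boolean mask or explicit id list."""
        if isinstance(mask, (list, tuple, pd.Index)) and len(mask) and isinstance(mask[0], str):
            ids = [s for s in self.samples.index if s in set(mask)]
        else:
            ids = list(self.samples.index[np.asarray(mask, dtype=bool)])
        return CountMatrix(self.counts[ids].copy(), self.samples.loc[ids].copy())

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return CountMatrix(self.counts.loc[genes].copy(), self.samples.copy())

    def contrast_samples(self, contrast: tuple[str, str], fraction: str | None = None) -> "CountMatrix":
        """Samples belonging to the two time points of a contrast (one fraction if given)."""
        tp_a, tp_b = contrast
        keep = self.samples["timepoint"].isin([tp_a, tp_b])
        if fraction is not None:
            keep &= self.samples["fraction"] == fraction
        if keep.sum() == 0:
            raise FormatError(f"no samples for contrast {tp_a}:{tp_b} fraction={fraction}")
        return self.subset_samples(keep)


@dataclasses.dataclass
class GeneSetCollection:
    """Named collection of gene sets (term -> member gene ids)."""

    name: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set: {term}")

    def __len__(self) -> int:
        return len(self.sets)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "timepoint": str})
    missing = set(SAMPLE_COLUMNS) - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    if sheet.index.duplicated().any():
        raise FormatError("duplicate sample ids in sample sheet")
    order = list(dict.fromkeys(sheet["timepoint"]))
    sheet["timepoint"] = pd.Categorical(sheet["timepoint"], categories=order, ordered=True)
    sheet["replicate"] = sheet["replicate"].astype(int)
    if (sheet["replicate"] < 1).any():
        raise FormatError("replicate numbers must be positive")
    return sheet


def read_counts(path: str | Path, samplesheet_path: str | Path) -> CountMatrix:
    """Read a count matrix (TSV, or MTX triplet with sidecars) plus its sample sheet.

    Columns are reordered to sample-sheet order; samples present in only one
    of the two files are an error naming the offender.
    """
    samples = read_sample_sheet(samplesheet_path)
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.sparse.coo_matrix(scipy.io.mmread(path))
        rows = path.parent / (path.name + ".rows")
        cols = path.parent / (path.name + ".cols")
        if not rows.exists() or not cols.exists():
            raise FormatError(f"MTX sidecars {rows.name}/{cols.name} not found")
        gene_ids = rows.read_text().split()
        sample_ids = cols.read_text().split()
        dense = np.asarray(mat.todense())
        counts = pd.DataFrame(dense, index=gene_ids, columns=sample_ids)
    else:
        counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        counts.index = counts.index.astype(str)
    orphan = set(counts.columns) - set(samples.index)
    if orphan:
        raise FormatError(f"matrix columns absent from sample sheet: {sorted(orphan)}")
    missing = set(samples.index) - set(counts.columns)
    if missing:
        raise FormatError(f"sheet samples absent from matrix: {sorted(missing)}")
    counts = counts[list(samples.index)]
    return CountMatrix(counts, samples)


def _header_comment(seed: int | None = None) -> str:
    from . import __version__

    line = f"# translatome v{__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index=index)


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path | None = None,
                 seed: int | None = None) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    write_table(df, counts_path, seed=seed, index=True)
    if samples_path is not None:
        sheet = cm.samples.reset_index()
        sheet.columns = SAMPLE_COLUMNS
        write_table(sheet, samples_path, seed=seed)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, length_bp, biotype (one row per gene)."""
    annot = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = {"gene_id", "length_bp", "biotype"} - set(annot.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    annot = annot.set_index("gene_id")
    if annot.index.duplicated().any():
        raise FormatError("duplicate gene ids in annotation")
    annot["length_bp"] = annot["length_bp"].astype(int)
    if (annot["length_bp"] < 1).any():
        raise FormatError("gene lengths must be >= 1 bp")
    return annot


def write_annotation(annot: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    df = annot.reset_index()
    write_table(df, path, seed=seed)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``term TAB description TAB gene TAB gene ...`` per line.

    Duplicate genes within a line are dropped (first occurrence kept).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: GMT line has <3 fields")
            term = fields[0]
            if term in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate term {term!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path.name}:{lineno}: gene set {term!r} is empty")
            sets[term] = genes
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in collection.sets.items():
            fh.write("\t".join([term, collection.name] + list(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
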