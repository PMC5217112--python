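"""Readers, writers and the core in-memory containers.

The analysis operates on four kinds of external artifact:

* integer gene x sample count tables (TSV, genes as rows) with a sample
  metadata sheet mapping each library to a genotype, batch and replicate;
* gene annotation giving each gene a chromosome and a feature class
  (GFF3 or a 3-column TSV);
* a karyotype: chromosome copy numbers per genotype, relative to a haploid
  reference genotype;
* gene sets (e.g. the environmental stress response induced/repressed lists),
  optionally signed with an expected direction.

All numeric output uses a fixed 6-significant-digit format so that rerunning
a pipeline with the same inputs produces byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AnnotationError, FormatError, MetadataError

#: feature classes recognised in gene annotation
GENE_CLASSES = ("nuclear_ORF", "noncoding", "nonreference", "other")

#: numeric format used by every table writer (6 significant digits)
FLOAT_FORMAT = "%.5e"


def default_nuclear_orf_predicate(gene_id: str) -> bool:
    """Systematic yeast ORF names begin with 'Y' (e.g. YPL049C)."""
    return gene_id.startswith("Y")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    Attributes
    ----------
    counts
        DataFrame of nonnegative integers, genes as rows, samples as columns.
    sample_meta
        DataFrame indexed by sample id with columns ``genotype``, ``batch``
        and ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count table")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # locate the first offending cell for the error message
            bad = ~np.isclose(arr.astype(float) % 1, 0) | (arr.astype(float) < 0)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer or negative count {arr[g, s]!r} for gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count for gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise MetadataError(f"samples missing metadata: {missing}")
        for col in ("genotype", "batch"):
            if col not in self.sample_meta.columns:
                raise MetadataError(f"sample metadata lacks required column {col!r}")
            if self.sample_meta.loc[self.counts.columns, col].isna().any():
                bad = self.sample_meta.loc[self.counts.columns, col].isna()
                raise MetadataError(
                    f"sample {bad.index[bad][0]!r} has no {col}"
                )
        # keep metadata aligned to the count columns
        self.sample_meta = self.sample_meta.loc[self.counts.columns].copy()

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def genotypes(self) -> pd.Series:
        """Genotype label per sample, in column order."""
        return self.sample_meta["genotype"]

    def samples_for(self, genotype: str) -> list[str]:
        sel = self.sample_meta.index[self.sample_meta["genotype"] == genotype]
        return list(sel)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, list(sample_ids)],
            self.sample_meta.loc[list(sample_ids)],
        )

    def subset_batch(self, batch: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["batch"] == batch]
        return self.subset_samples(list(keep))


@dataclass
class GeneAnnotation:
    """Chromosome and feature class per gene.

    ``table`` is indexed by gene id with columns ``chromosome`` and
    ``gene_class`` (one of :data:`GENE_CLASSES`).  Genes that a count table
    contains but the annotation does not are classified ``nonreference`` on
    chromosome ``"unplaced"`` — these are strain-specific genes absent from
    the reference genome, so their encoding chromosome is unknown and they
    are never copy-number adjusted.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise AnnotationError(f"duplicate gene id {dup!r} in annotation")
        bad = set(self.table["gene_class"]) - set(GENE_CLASSES)
        if bad:
            raise AnnotationError(f"unknown gene classes: {sorted(bad)}")

    def resolve(self, gene_ids: Iterable[str]) -> pd.DataFrame:
        """Annotation rows for ``gene_ids``; unknown genes become
        (``unplaced``, ``nonreference``)."""
        idx = pd.Index(gene_ids)
        out = self.table.reindex(idx)
        unknown = out["chromosome"].isna()
        out.loc[unknown, "chromosome"] = "unplaced"
        out.loc[unknown, "gene_class"] = "nonreference"
        return out

    def chromosome_of(self, gene_ids: Iterable[str]) -> pd.Series:
        return self.resolve(gene_ids)["chromosome"]

    def nuclear_orf_mask(self, gene_ids: Iterable[str]) -> pd.Series:
        return self.resolve(gene_ids)["gene_class"] == "nuclear_ORF"


@dataclass
class Karyotype:
    """Chromosome copy numbers per genotype, against a haploid reference.

    ``copies`` is a DataFrame indexed by genotype with one column per
    chromosome; the reference genotype row must be all ones.
    """

    reference_genotype: str
    copies: pd.DataFrame

    def __post_init__(self) -> None:
        if self.reference_genotype not in self.copies.index:
            raise FormatError(
                f"reference genotype {self.reference_genotype!r} absent from karyotype"
            )
        ref = self.copies.loc[self.reference_genotype]
        if not (ref == 1).all():
            raise FormatError("reference genotype must have copy number 1 everywhere")
        if (self.copies.to_numpy() <= 0).any():
            raise FormatError("chromosome copy numbers must be positive")

    @property
    def chromosomes(self) -> pd.Index:
        return self.copies.columns

    @property
    def genotypes(self) -> pd.Index:
        return self.copies.index

    def copy_ratio(self, genotype: str, chromosome: str) -> float:
        """Copy number of ``chromosome`` in ``genotype`` over the reference."""
        num = self.copies.at[genotype, chromosome]
        den = self.copies.at[self.reference_genotype, chromosome]
        return float(num) / float(den)

    def ratio_between(self, genotype_a: str, genotype_b: str, chromosome: str) -> float:
        """Copy ratio of ``chromosome`` between two genotypes (a over b)."""
        return self.copy_ratio(genotype_a, chromosome) / self.copy_ratio(
            genotype_b, chromosome
        )

    def disomic_chromosomes(self, genotype: str) -> list[str]:
        """Chromosomes with copy number above the reference in ``genotype``."""
        row = self.copies.loc[genotype]
        ref = self.copies.loc[self.reference_genotype]
        return list(row.index[row > ref])


@dataclass(frozen=True)
class GeneSet:
    """A named gene list, optionally signed.

    ``direction`` is +1 for a set expected to be induced, -1 for repressed,
    0 for unsigned.
    """

    name: str
    members: tuple[str, ...]
    direction: int = 0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 0, 1):
            raise FormatError(f"gene set direction must be -1, 0 or +1")
        if len(set(self.members)) != len(self.members):
            dups = sorted({m for m in self.members if self.members.count(m) > 1})
            warnings.warn(
                f"gene set {self.name!r}: duplicate members collapsed: {dups}",
                stacklevel=2,
            )
            seen: dict[str, None] = {}
            for m in self.members:
                seen.setdefault(m)
            object.__setattr__(self, "members", tuple(seen))

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Load a TSV count table (genes as rows, header row of sample ids)
    together with its sample metadata sheet.

    The metadata TSV must have columns ``sample``, ``genotype``, ``batch``
    and optionally ``replicate``; every sample column of the count table
    must appear in it.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.size == 0:
        raise FormatError(f"{path}: no sample columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna()
        g = bad.index[bad.any(axis=1)][0]
        s = bad.columns[bad.loc[g]][0]
        raise FormatError(
            f"{path}: non-numeric count {raw.at[g, s]!r} for gene {g!r}, sample {s!r}"
        )
    frac = (numeric % 1 != 0) | (numeric < 0)
    if frac.any().any():
        g = frac.index[frac.any(axis=1)][0]
        s = frac.columns[frac.loc[g]][0]
        raise FormatError(
            f"{path}: non-integer or negative count {raw.at[g, s]!r} "
            f"for gene {g!r}, sample {s!r}"
        )
    counts = numeric.astype(np.int64)

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise MetadataError(f"{meta_path}: missing 'sample' column")
    meta = meta.set_index("sample")
    if "replicate" not in meta.columns:
        meta["replicate"] = [str(i + 1) for i in range(len(meta))]
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise MetadataError(f"{meta_path}: samples missing metadata: {missing}")
    return CountMatrix(counts, meta)


def write_count_table(
    matrix: CountMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")
    if meta_path is not None:
        matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def read_annotation(
    path: str | Path,
    noncoding_ids: Iterable[str] | None = None,
    nuclear_orf_predicate: Callable[[str], bool] = default_nuclear_orf_predicate,
) -> GeneAnnotation:
    """Read gene annotation from GFF3 or from a 3-column TSV.

    GFF3 files are parsed for gene-like features only; the seqid becomes the
    chromosome and the ``ID`` attribute the gene id (coordinates are never
    used — the analysis is gene-level).  The TSV dialect has columns
    ``gene``, ``chromosome``, ``class``.

    ``noncoding_ids`` optionally lists genes (CUTs/SUTs/MUTs/XUTs) to force
    into the ``noncoding`` class regardless of naming.
    """
    path = Path(path)
    text_head = path.open().readline()
    if path.suffix.lower() in (".gff", ".gff3") or text_head.startswith("##gff"):
        table = _annotation_from_gff3(path, nuclear_orf_predicate)
    else:
        table = _annotation_from_tsv(path)
    if noncoding_ids is not None:
        nc = [g for g in noncoding_ids if g in table.index]
        table.loc[nc, "gene_class"] = "noncoding"
    return GeneAnnotation(table)


def _annotation_from_gff3(
    path: Path, nuclear_orf_predicate: Callable[[str], bool]
) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    rows: dict[str, tuple[str, str]] = {}
    noncoding_types = {
        "ncRNA",
        "ncRNA_gene",
        "CUT",
        "SUT",
        "MUT",
        "XUT",
    }
    for feat in db.all_features():
        if feat.featuretype not in {"gene"} | noncoding_types:
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in rows:
            raise AnnotationError(f"duplicate gene id {gid!r} in {path}")
        if feat.featuretype in noncoding_types:
            cls = "noncoding"
        elif nuclear_orf_predicate(gid):
            cls = "nuclear_ORF"
        else:
            cls = "other"
        rows[gid] = (feat.seqid, cls)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chromosome", "gene_class"]
    )
    table.index.name = "gene"
    return table


def _annotation_from_tsv(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"gene", "chromosome", "class"}
    if not expected <= set(table.columns):
        raise FormatError(
            f"{path}: annotation TSV needs columns {sorted(expected)}"
        )
    if table["gene"].duplicated().any():
        dup = table["gene"][table["gene"].duplicated()].iloc[0]
        raise AnnotationError(f"duplicate gene id {dup!r} in {path}")
    table = table.set_index("gene").rename(columns={"class": "gene_class"})
    return table[["chromosome", "gene_class"]]


def write_annotation_tsv(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.rename(columns={"gene_class": "class"})
    out.to_csv(path, sep="\t", index_label="gene")


def write_annotation_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write a minimal GFF3 (gene features only, placeholder coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        pos = {}
        for gid, row in annotation.table.iterrows():
            start = pos.get(row["chromosome"], 1)
            pos[row["chromosome"]] = start + 1000
            ftype = "ncRNA_gene" if row["gene_class"] == "noncoding" else "gene"
            fh.write(
                f"{row['chromosome']}\tkaryodiff\t{ftype}\t{start}\t{start + 999}"
                f"\t.\t+\t.\tID={gid}\n"
            )


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------


def read_karyotype(path: str | Path) -> Karyotype:
    """Read a karyotype from YAML/JSON.

    Layout::

        reference: F45
        chromosomes: [chrI, chrII, ...]
        copies:
          disomeXV: {chrXV: 2}

    Genotype/chromosome pairs not listed default to copy number 1.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        reference = doc["reference"]
        chroms = list(doc["chromosomes"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: karyotype needs 'reference' and 'chromosomes'") from exc
    genotypes = sorted(set(doc.get("copies", {})) | {reference})
    copies = pd.DataFrame(1.0, index=genotypes, columns=chroms)
    for genotype, mapping in (doc.get("copies") or {}).items():
        for chrom, n in (mapping or {}).items():
            if chrom not in copies.columns:
                raise FormatError(f"{path}: unknown chromosome {chrom!r}")
            copies.at[genotype, chrom] = float(n)
    return Karyotype(reference, copies)


def write_karyotype(karyotype: Karyotype, path: str | Path) -> None:
    doc = {
        "reference": karyotype.reference_genotype,
        "chromosomes": list(karyotype.chromosomes),
        "copies": {},
    }
    for genotype, row in karyotype.copies.iterrows():
        nondefault = {c: float(row[c]) for c in row.index if row[c] != 1}
        if nondefault:
            doc["copies"][genotype] = nondefault
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gene_set(
    path: str | Path, name: str | None = None, direction: int = 0
) -> GeneSet | None:
    """Read a one-gene-per-line set file.  Empty sets are skipped (None)."""
    genes = [ln.strip() for ln in open(path) if ln.strip() and not ln.startswith("#")]
    name = name or Path(path).stem
    if not genes:
        warnings.warn(f"gene set {name!r} is empty; skipped", stacklevel=2)
        return None
    return GeneSet(name, tuple(genes), direction)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a 2-column (set, gene) TSV into one GeneSet per set name.

    A third optional column ``direction`` (+1/-1/0) signs the set.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"set", "gene"} <= set(table.columns):
        raise FormatError(f"{path}: gene set TSV needs columns ['set', 'gene']")
    sets: list[GeneSet] = []
    for name, grp in table.groupby("set", sort=True):
        genes = tuple(grp["gene"])
        if not genes:
            warnings.warn(f"gene set {name!r} is empty; skipped", stacklevel=2)
            continue
        direction = 0
        if "direction" in grp.columns and grp["direction"].notna().any():
            direction = int(float(grp["direction"].dropna().iloc[0]))
        sets.append(GeneSet(str(name), genes, direction))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    rows = [
        {"set": s.name, "gene": g, "direction": s.direction}
        for s in sets
        for g in s.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# differential profiles
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["log2FC", "adjusted_log2FC", "p", "FDR", "mean_logCPM"]
_PROFILE_RENAME = {
    "log2FC": "log2fc",
    "adjusted_log2FC": "adjusted_log2fc",
    "p": "pvalue",
    "FDR": "fdr",
    "mean_logCPM": "mean_logcpm",
}


def write_profile(
    profile: "pd.DataFrame | object", path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a differential profile as TSV (gene, log2FC, adjusted_log2FC,
    p, FDR, mean_logCPM), 6 significant digits, optional ``#`` provenance
    header lines."""
    table = getattr(profile, "table", profile)
    out = table.rename(columns={v: k for k, v in _PROFILE_RENAME.items()})
    out = out[[c for c in PROFILE_COLUMNS if c in out.columns]]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_profile(path: str | Path):
    """Read a profile TSV written by :func:`write_profile`."""
    from .de import DifferentialProfile

    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table = table.rename(columns=_PROFILE_RENAME)
    return DifferentialProfile(table)
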