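"""Readers/writers for the external formats and the coordinate boundary.

All genomic coordinates inside the package are 0-based half-open.  The
conversion from 1-based inclusive dialects (SEG, GFF-like tables) happens
here and only here.  Every reader/writer pair is a lossless round-trip on
valid input (exact for integers and identifiers, to float precision for
segment means and intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file; message names the offending line or cell."""


@dataclass
class GeneAnnotation:
    """One gene locus with its category tags.

    Coordinates are 0-based half-open.  ``categories`` holds functional tags
    (RBP, miRNA, TF, kinase, ...); ``family`` an optional stoichiometric
    family label such as a histone family.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    categories: set = field(default_factory=set)
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got ({self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


ANNOTATION_COLUMNS = ["chrom", "start", "end", "symbol", "strand", "family"]


def annotation_to_frame(genes: list[GeneAnnotation]) -> pd.DataFrame:
    """Catalog as a DataFrame indexed by gene_id (categories as frozensets)."""
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "symbol": [g.symbol for g in genes],
            "strand": [g.strand for g in genes],
            "family": [g.family for g in genes],
            "categories": [frozenset(g.categories) for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return df


def read_annotation(path: str | Path, dialect: str = "bed") -> pd.DataFrame:
    """Read a gene catalog.

    dialect "bed": whitespace/tab columns chrom, start, end, name, score,
    strand — native 0-based half-open, passed through.
    dialect "gff-like": tab columns chrom, start, end, gene_id, strand with a
    header, 1-based inclusive — converted to 0-based half-open.

    Duplicate gene ids are an error naming the id; malformed rows are an
    error naming the line number.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "bed":
                    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) > 5 else "."
                elif dialect == "gff-like":
                    if lineno == 1 and not parts[1].isdigit():
                        continue  # header
                    chrom, name = parts[0], parts[3]
                    start, end = int(parts[1]) - 1, int(parts[2])
                    strand = parts[4] if len(parts) > 4 else "."
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate gene_id {name!r}")
                seen.add(name)
                genes.append(
                    GeneAnnotation(gene_id=name, symbol=name, chrom=chrom,
                                   start=start, end=end, strand=strand)
                )
            except FormatError:
                raise
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return annotation_to_frame(genes)


def write_annotation(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write a catalog as BED6 (0-based half-open; score column unused)."""
    with Path(path).open("w") as fh:
        for gene_id, row in catalog.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                f"\t{gene_id}\t0\t{row['strand']}\n"
            )


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2 intensities.

    First column gene ids, header row sample ids, "NA" for missing.
    Non-numeric cells raise with their (gene, sample) coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, na_values=[])
    raw.index = raw.index.astype(str)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].replace({"NA": None, "": None}),
                                  errors="coerce")
        bad = converted.isna() & ~raw[col].isin(["NA", ""])
        if bad.any():
            gene = bad.idxmax()
            raise FormatError(
                f"{path}: non-numeric value {raw.at[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        out[col] = converted
    out.index.name = "gene_id"
    return out


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id",
                  float_format="%.10g")


SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file into internal coordinates.

    SEG is 1-based inclusive; internally start = Start - 1, end = End.
    Segments must be non-overlapping within each (sample, chromosome);
    an overlap is an error naming the sample and region.  Returns a frame
    with columns sample, chrom, start, end, n_probes, mean[, call].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing SEG columns {missing}")
    out = pd.DataFrame(
        {
            "sample": df["Sample"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) - 1,
            "end": df["End"].astype(int),
            "n_probes": df["Num_Probes"].astype(int) if "Num_Probes" in df else 0,
            "mean": df["Segment_Mean"].astype(float),
        }
    )
    if "Call" in df.columns:
        out["call"] = df["Call"].astype(str)
    for (sample, chrom), grp in out.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start")
        prev_end = -1
        for _, row in grp.iterrows():
            if row["start"] < prev_end:
                raise FormatError(
                    f"{path}: overlapping segments for sample {sample!r} at "
                    f"{chrom}:{row['start']}-{row['end']}"
                )
            prev_end = row["end"]
    return out


def write_seg(segments: pd.DataFrame, path: str | Path) -> None:
    """Write internal segments back to 1-based inclusive SEG."""
    df = pd.DataFrame(
        {
            "Sample": segments["sample"],
            "Chromosome": segments["chrom"],
            "Start": segments["start"].astype(int) + 1,
            "End": segments["end"].astype(int),
            "Num_Probes": segments.get("n_probes", 0),
            "Segment_Mean": segments["mean"],
        }
    )
    if "call" in segments.columns:
        df["Call"] = segments["call"]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV table (category tables, complex catalog, frequencies...)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_category_table(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (category, gene_id) -> mapping category -> gene set."""
    df = pd.read_csv(path, sep="\t")
    cat_col, gene_col = df.columns[:2]
    return {c: set(g[gene_col].astype(str)) for c, g in df.groupby(cat_col)}


def read_complex_catalog(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (complex_id, gene_id); complexes of < 2 members error."""
    catalog = read_category_table(path)
    for cid, members in catalog.items():
        if len(members) < 2:
            raise FormatError(f"complex {cid!r} has fewer than 2 members")
    return catalog


def read_probe_tracks(path: str | Path) -> pd.DataFrame:
    """Probe-level log-ratio TSV: columns chrom, position, sample, log_ratio."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "position", "sample", "log_ratio"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: probe track needs columns {sorted(need)}")
    df["position"] = df["position"].astype(int)
    df["sample"] = df["sample"].astype(str)
    return df


def write_probe_tracks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def nearly_equal_frames(a: pd.DataFrame, b: pd.DataFrame, tol: float = 1e-12) -> bool:
    """Round-trip check helper: identical shape/index, floats within tol."""
    if a.shape != b.shape or list(a.index) != list(b.index):
        return False
    av, bv = a.to_numpy(float), b.to_numpy(float)
    both_nan = np.isnan(av) & np.isnan(bv)
    return bool(np.all(both_nan | (np.abs(av - bv) <= tol)))
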