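"""Genomic data model, standard-format I/O, interval arithmetic and signal scaling.

Coordinates are 0-based half-open (BED dialect) everywhere. Two regions
overlap when their intersection covers at least one base, so abutting
intervals like [100,200) and [200,300) do not overlap. Interval joins and
merges are delegated to :mod:`pyranges`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "GenomeAssembly",
    "GenomicRegion",
    "RegionSet",
    "GeneModel",
    "SignalTable",
    "read_regions",
    "write_regions",
    "overlap",
    "merge_regions",
    "normalize_per_million",
    "read_genes_tsv",
    "read_genes_gtf",
]

_STRANDS = ("+", "-", ".")


class RegionFormatError(ValueError):
    """Raised for malformed region files or invalid coordinates."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Named chromosomes with lengths in bases.

    Stands in for a reference genome build: every region referencing the
    assembly must lie within ``[0, length)`` of its chromosome.
    """

    chrom_lengths: Mapping[str, int]
    name: str = "custom"

    def __post_init__(self) -> None:
        lengths = dict(self.chrom_lengths)
        if not lengths:
            raise ValueError("assembly needs at least one chromosome")
        for chrom, length in lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval ``[start, end)`` on a named chromosome.

    ``summit`` is an offset from ``start`` (narrowPeak column 10); ``None``
    encodes the narrowPeak ``-1`` sentinel.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionFormatError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in _STRANDS:
            raise RegionFormatError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (0 <= self.summit < self.end - self.start):
            raise RegionFormatError(
                f"summit offset {self.summit} outside [0,{self.end - self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def summit_pos(self) -> int:
        """Absolute summit base; midpoint when no summit is recorded."""
        return self.start + self.summit if self.summit is not None else self.midpoint


_RS_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "summit"]


class RegionSet:
    """Ordered collection of regions backed by a DataFrame.

    The frame has columns chrom/start/end/name/score/strand/summit with
    ``summit`` as an offset from ``start`` (NaN when absent). Regions keep
    input order; ``sort()`` returns a coordinate-sorted copy.
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion] | pd.DataFrame,
        assembly: GenomeAssembly | None = None,
        name: str = "",
        allow_duplicates: bool = True,
    ):
        if isinstance(regions, pd.DataFrame):
            df = regions.copy()
            for col in _RS_COLUMNS:
                if col not in df.columns:
                    df[col] = np.nan if col in ("score", "summit") else (
                        "." if col == "strand" else None
                    )
            df = df[_RS_COLUMNS].reset_index(drop=True)
        else:
            rows = [
                (r.chrom, r.start, r.end, r.name, r.score, r.strand, r.summit)
                for r in regions
            ]
            df = pd.DataFrame(rows, columns=_RS_COLUMNS)
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
                bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
                raise RegionFormatError(
                    f"invalid interval at row {bad}: "
                    f"[{df.at[bad, 'start']},{df.at[bad, 'end']})"
                )
        else:
            df = df.astype({"start": np.int64, "end": np.int64})
        self.df = df
        self.assembly = assembly
        self.name = name
        if assembly is not None and len(df):
            unknown = set(df["chrom"]) - set(assembly.chroms)
            if unknown:
                raise RegionFormatError(f"chromosomes not in assembly: {sorted(unknown)}")
            lengths = df["chrom"].map(assembly.chrom_lengths)
            if (df["end"] > lengths).any():
                raise RegionFormatError("region extends past chromosome end")
        if not allow_duplicates:
            dup = df.duplicated(subset=["chrom", "start", "end"])
            if dup.any():
                raise RegionFormatError("duplicate regions not allowed")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicRegion]:
        for row in self.df.itertuples(index=False):
            yield GenomicRegion(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand if isinstance(row.strand, str) else ".",
                score=None if pd.isna(row.score) else float(row.score),
                summit=None if pd.isna(row.summit) else int(row.summit),
                name=row.name if isinstance(row.name, str) else None,
            )

    def __getitem__(self, i: int) -> GenomicRegion:
        row = self.df.iloc[i]
        return GenomicRegion(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"] if isinstance(row["strand"], str) else ".",
            score=None if pd.isna(row["score"]) else float(row["score"]),
            summit=None if pd.isna(row["summit"]) else int(row["summit"]),
            name=row["name"] if isinstance(row["name"], str) else None,
        )

    def sort(self) -> "RegionSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return RegionSet(df.reset_index(drop=True), self.assembly, self.name)

    def to_pyranges(self, with_index: bool = True) -> pr.PyRanges:
        df = pd.DataFrame(
            {
                "Chromosome": self.df["chrom"],
                "Start": self.df["start"],
                "End": self.df["end"],
            }
        )
        if with_index:
            df["row"] = np.arange(len(df))
        return pr.PyRanges(df)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        assembly: GenomeAssembly | None = None,
        name: str = "",
        **extra,
    ) -> "RegionSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        for k, v in extra.items():
            df[k] = v
        return cls(df, assembly=assembly, name=name)

    def region_ids(self) -> pd.Index:
        """Stable ``chrom:start-end`` identifiers, useful as table index."""
        return pd.Index(
            self.df["chrom"].astype(str)
            + ":"
            + self.df["start"].astype(str)
            + "-"
            + self.df["end"].astype(str)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, plus a transcription-factor flag."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int
    strand: str
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("negative TSS")


@dataclass
class SignalTable:
    """Non-negative signal values (rows: regions or genes, columns: samples).

    ``library_sizes`` (reads per sample) enables per-million scaling.
    """

    values: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("signal values must be finite and >= 0")
        if self.library_sizes is not None:
            self.library_sizes = pd.Series(self.library_sizes)
            missing = [c for c in self.values.columns if c not in self.library_sizes.index]
            if missing:
                raise ValueError(f"library sizes missing for samples: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, library_sizes: pd.Series | None = None) -> "SignalTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), library_sizes)


# ---------------------------------------------------------------------------
# region I/O


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    return "narrowpeak" if suffix == ".narrowpeak" else "bed"


def read_regions(
    path: str | Path,
    format: str | None = None,
    assembly: GenomeAssembly | None = None,
    name: str | None = None,
) -> RegionSet:
    """Read a BED3+/BED6 or ENCODE narrowPeak file into a RegionSet.

    narrowPeak column 10 (summit offset from start) is kept; ``-1`` becomes
    absent. Malformed lines raise :class:`RegionFormatError` naming the line.
    """
    fmt = _infer_format(path, format)
    if fmt not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown region format {fmt!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise RegionFormatError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if start >= end or start < 0:
                raise RegionFormatError(
                    f"{path}: line {lineno}: invalid interval [{start},{end})"
                )
            rname = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            summit = None
            if fmt == "narrowpeak":
                if len(fields) < 10:
                    raise RegionFormatError(
                        f"{path}: line {lineno}: narrowPeak needs 10 columns"
                    )
                raw = int(fields[9])
                if raw != -1:
                    if not (0 <= raw < end - start):
                        raise RegionFormatError(
                            f"{path}: line {lineno}: summit {raw} outside peak"
                        )
                    summit = raw
            rows.append((chrom, start, end, rname, score, strand, summit))
    df = pd.DataFrame(rows, columns=_RS_COLUMNS)
    return RegionSet(df, assembly=assembly, name=name or Path(path).stem)


def write_regions(rs: RegionSet, path: str | Path, format: str | None = None) -> None:
    """Write BED6 or narrowPeak; read(write(rs)) reproduces coordinates exactly."""
    fmt = _infer_format(path, format)
    with open(path, "w") as fh:
        for i, row in enumerate(rs.df.itertuples(index=False)):
            name = row.name if isinstance(row.name, str) else f"region_{i}"
            score = 0 if pd.isna(row.score) else row.score
            score = int(score) if float(score).is_integer() else score
            strand = row.strand if isinstance(row.strand, str) else "."
            base = f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{strand}"
            if fmt == "narrowpeak":
                summit = -1 if pd.isna(row.summit) else int(row.summit)
                fh.write(base + f"\t0\t-1\t-1\t{summit}\n")
            else:
                fh.write(base + "\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def _check_same_assembly(a: RegionSet, b: RegionSet) -> None:
    if a.assembly is not None and b.assembly is not None and a.assembly is not b.assembly:
        if a.assembly.chrom_lengths != b.assembly.chrom_lengths:
            raise ValueError("region sets reference different assemblies")


def overlap(a: RegionSet, b: RegionSet, min_overlap: int = 1) -> pd.DataFrame:
    """Pair regions of ``a`` with regions of ``b`` intersecting >= min_overlap bases.

    Returns a frame with columns ``a_index``, ``b_index``, ``bases``
    (intersection length), ordered by a-index. Strand is ignored.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    _check_same_assembly(a, b)
    if not len(a) or not len(b):
        return pd.DataFrame(columns=["a_index", "b_index", "bases"]).astype(np.int64)
    ga = a.to_pyranges()
    gb = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": b.df["chrom"],
                "Start": b.df["start"],
                "End": b.df["end"],
                "row_b": np.arange(len(b)),
            }
        )
    )
    joined = ga.join(gb).df
    if joined.empty:
        return pd.DataFrame(columns=["a_index", "b_index", "bases"]).astype(np.int64)
    inter = np.minimum(joined["End"], joined["End_b"]) - np.maximum(
        joined["Start"], joined["Start_b"]
    )
    out = pd.DataFrame(
        {
            "a_index": joined["row"].to_numpy(np.int64),
            "b_index": joined["row_b"].to_numpy(np.int64),
            "bases": inter.to_numpy(np.int64),
        }
    )
    out = out[out["bases"] >= min_overlap]
    return out.sort_values(["a_index", "b_index"]).reset_index(drop=True)


def overlaps_any(a: RegionSet, b: RegionSet, min_overlap: int = 1) -> np.ndarray:
    """Boolean per a-region: overlaps at least one b-region."""
    mask = np.zeros(len(a), dtype=bool)
    pairs = overlap(a, b, min_overlap=min_overlap)
    mask[pairs["a_index"].to_numpy()] = True
    return mask


def merge_regions(sets: Sequence[RegionSet] | RegionSet, name: str = "merged") -> RegionSet:
    """Merge overlapping (>=1 bp) regions across one or more sets.

    Abutting half-open intervals are kept separate, matching the overlap
    convention.
    """
    if isinstance(sets, RegionSet):
        sets = [sets]
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("nothing to merge")
    assembly = next((s.assembly for s in sets if s.assembly is not None), None)
    df = pd.concat(
        [
            pd.DataFrame(
                {"Chromosome": s.df["chrom"], "Start": s.df["start"], "End": s.df["end"]}
            )
            for s in sets
        ],
        ignore_index=True,
    )
    merged = pr.PyRanges(df).merge(slack=-1).df
    merged = merged.sort_values(["Chromosome", "Start", "End"]).reset_index(drop=True)
    return RegionSet.from_arrays(
        merged["Chromosome"].astype(str),
        merged["Start"],
        merged["End"],
        assembly=assembly,
        name=name,
    )


# ---------------------------------------------------------------------------
# signal scaling


def normalize_per_million(raw: SignalTable) -> SignalTable:
    """Scale each sample column to one million reads: v' = v * 1e6 / library."""
    if raw.library_sizes is None:
        raise ValueError("library sizes required for per-million normalization")
    libs = raw.library_sizes.loc[raw.values.columns].astype(float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"non-positive library sizes for: {bad}")
    values = raw.values * (1e6 / libs)
    return SignalTable(values, raw.library_sizes)


# ---------------------------------------------------------------------------
# gene models


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read a TSS table: gene_id, gene_name, chrom, tss, strand[, is_tf]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "gene_name", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    has_tf = "is_tf" in df.columns
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_name),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            is_tf=bool(r.is_tf) if has_tf else False,
        )
        for r in df.itertuples(index=False)
    ]


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.gene_name, g.chrom, g.tss, g.strand, g.is_tf)
            for g in genes
        ],
        columns=["gene_id", "gene_name", "chrom", "tss", "strand", "is_tf"],
    ).to_csv(path, sep="\t", index=False)


def read_genes_gtf(path: str | Path, tf_ids: set[str] | None = None) -> list[GeneModel]:
    """Read gene features from a GTF-lite file (1-based -> 0-based TSS).

    Only ``gene`` feature lines are used; attributes must carry gene_id and
    gene_name. TSS is the 5' end: start for + strand, end for - strand.
    """
    genes: list[GeneModel] = []
    tf_ids = tf_ids or set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise RegionFormatError(f"{path}: line {lineno}: needs 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = (
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
                fields[8],
            )
            kv = {}
            for part in attrs.strip().strip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                kv[key] = val.strip().strip('"')
            gid = kv.get("gene_id")
            if gid is None:
                raise RegionFormatError(f"{path}: line {lineno}: missing gene_id")
            tss = start1 - 1 if strand == "+" else end1 - 1
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=kv.get("gene_name", gid),
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    is_tf=gid in tf_ids or kv.get("gene_name") in tf_ids,
                )
            )
    return genes
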