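"""Readers and writers for the tables and FASTA files the pipeline touches.

All tabular formats are UTF-8, tab-separated text. Lines starting with ``#``
are comments; a lone ``.`` denotes a missing numeric value. Readers validate
on construction and reject structurally invalid input instead of coercing;
every writer/reader pair is an exact round-trip.

File layouts
------------
``otu_counts.tsv``
    first column ``otu_id``, one column of non-negative integer counts per
    sample (rows are OTUs, columns are samples; in memory the matrix is
    samples x OTUs).
``samples.tsv``
    columns ``sample_id  core_id  depth_cm  qpcr_arch  qpcr_bac``; depth is
    the sample midpoint in cm below seafloor, qPCR values are 16S copies per
    gram of sediment.
``taxonomy.tsv``
    columns ``otu_id  lineage`` and optionally ``database``; the lineage is a
    semicolon-separated path ``domain;phylum;class;order;family;genus``.
``geochem.tsv``
    columns ``core_id  depth_cm`` plus any of ``o2_uM no3_uM no2_uM nh4_uM``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_SAMPLE_COLUMNS = ("sample_id", "core_id", "depth_cm", "qpcr_arch", "qpcr_bac")
_GEOCHEM_SERIES = ("o2_uM", "no3_uM", "no2_uM", "nh4_uM")

_READ_KWARGS = dict(sep="\t", comment="#", na_values=["."], keep_default_na=False)


@dataclasses.dataclass
class OtuTable:
    """Amplicon count matrix, samples x OTUs, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in OTU table")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate OTU id {dup!r} in OTU table")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise FormatError("OTU counts must be integers")
        if (self.counts.values < 0).any():
            r, c = np.argwhere(self.counts.values < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"OTU {self.counts.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclasses.dataclass
class Taxonomy:
    """OTU id -> six-rank lineage (domain..genus), plus the source database label."""

    lineages: dict[str, tuple[str, ...]]
    database: str | None = None

    def __post_init__(self) -> None:
        for otu, lineage in self.lineages.items():
            if len(lineage) != len(RANKS):
                raise FormatError(
                    f"lineage of {otu!r} has {len(lineage)} ranks, expected {len(RANKS)}"
                )

    def rank(self, otu_id: str, rank_name: str) -> str:
        return self.lineages[otu_id][RANKS.index(rank_name)]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


@dataclasses.dataclass
class SampleTable:
    """Per-sample metadata: core, depth midpoint, and qPCR totals."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _SAMPLE_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"sample table is missing mandatory column {col!r}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample table")
        if (self.data["depth_cm"].to_numpy(dtype=float) < 0).any():
            raise FormatError("sample table contains a negative depth_cm")
        for col in ("qpcr_arch", "qpcr_bac"):
            vals = self.data[col].to_numpy(dtype=float)
            if (vals[np.isfinite(vals)] < 0).any():
                raise FormatError(f"sample table contains a negative {col}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def total_cells(self) -> pd.Series:
        """qPCR proxy for total cells: archaeal + bacterial 16S copies per gram."""
        tot = self.data["qpcr_arch"].astype(float) + self.data["qpcr_bac"].astype(float)
        tot.index = pd.Index(self.data["sample_id"])
        return tot

    def depths(self) -> pd.Series:
        d = self.data["depth_cm"].astype(float)
        d.index = pd.Index(self.data["sample_id"])
        return d

    def cores(self) -> pd.Series:
        c = self.data["core_id"].astype(str)
        c.index = pd.Index(self.data["sample_id"])
        return c


@dataclasses.dataclass
class GeochemProfile:
    """Porewater chemistry of one core vs depth; any series may be absent."""

    core_id: str
    depth_cm: np.ndarray
    o2_uM: np.ndarray | None = None
    no3_uM: np.ndarray | None = None
    no2_uM: np.ndarray | None = None
    nh4_uM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth_cm = np.asarray(self.depth_cm, dtype=float)
        if self.depth_cm.ndim != 1 or len(self.depth_cm) == 0:
            raise FormatError(f"core {self.core_id!r}: empty depth series")
        if not np.all(np.diff(self.depth_cm) > 0):
            raise FormatError(f"core {self.core_id!r}: depths must be strictly increasing")
        for name in _GEOCHEM_SERIES:
            series = getattr(self, name)
            if series is None:
                continue
            series = np.asarray(series, dtype=float)
            if series.shape != self.depth_cm.shape:
                raise FormatError(
                    f"core {self.core_id!r}: {name} length does not match depths"
                )
            if (series[np.isfinite(series)] < 0).any():
                raise FormatError(f"core {self.core_id!r}: negative {name} value")
            setattr(self, name, series)


@dataclasses.dataclass
class AssemblyStats:
    n_sequences: int
    total_length_bp: int
    gc_percent: float
    n50_bp: int


# ---------------------------------------------------------------------------
# OTU table


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU count table (rows = OTUs, columns = samples)."""
    df = pd.read_csv(path, dtype=str, **_READ_KWARGS)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: OTU table needs an id column and >=1 sample column")
    otu_ids = df.iloc[:, 0].tolist()
    sample_ids = list(df.columns[1:])
    mat = np.empty((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(sample_ids):
        for i, raw in enumerate(df[col]):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at OTU {otu_ids[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at OTU {otu_ids[i]!r}, "
                    f"sample {col!r}"
                )
            mat[j, i] = value
    counts = pd.DataFrame(mat, index=pd.Index(sample_ids), columns=pd.Index(otu_ids))
    return OtuTable(counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.T.rename_axis("otu_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample table


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, **_READ_KWARGS)
    for col in _SAMPLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["core_id"] = df["core_id"].astype(str)
    for col in ("depth_cm", "qpcr_arch", "qpcr_bac"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, dtype=str, **_READ_KWARGS)
    for col in ("otu_id", "lineage"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    database = None
    if "database" in df.columns:
        labels = df["database"].dropna().unique()
        database = str(labels[0]) if len(labels) else None
    lineages: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        otu = str(row["otu_id"])
        if otu in lineages:
            raise FormatError(f"{path}: duplicate OTU id {otu!r} in taxonomy")
        raw = "" if pd.isna(row["lineage"]) else str(row["lineage"])
        ranks = [r.strip() for r in raw.split(";")] if raw else []
        ranks = [r if r else "unclassified" for r in ranks][: len(RANKS)]
        ranks += ["unclassified"] * (len(RANKS) - len(ranks))
        lineages[otu] = tuple(ranks)
    return Taxonomy(lineages, database)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [
        {"otu_id": otu, "lineage": ";".join(lineage), "database": taxonomy.database or ""}
        for otu, lineage in taxonomy.lineages.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# geochemistry


def read_geochem(path: str | Path) -> dict[str, GeochemProfile]:
    """Read porewater profiles, one :class:`GeochemProfile` per core in the file."""
    df = pd.read_csv(path, **_READ_KWARGS)
    for col in ("core_id", "depth_cm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    profiles: dict[str, GeochemProfile] = {}
    for core_id, sub in df.groupby("core_id", sort=False):
        kwargs = {}
        for name in _GEOCHEM_SERIES:
            if name in sub.columns and not sub[name].isna().all():
                kwargs[name] = sub[name].to_numpy(dtype=float)
        profiles[str(core_id)] = GeochemProfile(
            core_id=str(core_id),
            depth_cm=sub["depth_cm"].to_numpy(dtype=float),
            **kwargs,
        )
    return profiles


def write_geochem(profiles: Mapping[str, GeochemProfile], path: str | Path) -> None:
    frames = []
    for core_id, prof in profiles.items():
        cols = {"core_id": core_id, "depth_cm": prof.depth_cm}
        for name in _GEOCHEM_SERIES:
            series = getattr(prof, name)
            if series is not None:
                cols[name] = series
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="."
    )


# ---------------------------------------------------------------------------
# FASTA assembly statistics


def assembly_stats(fasta_path: str | Path) -> AssemblyStats:
    """Basic statistics of a nucleotide assembly.

    GC is computed over unambiguous A/C/G/T only; residues outside that
    alphabet are logged and excluded from the GC denominator (but still count
    toward sequence length). N50 is the largest length L such that sequences
    of length >= L cover at least half the total assembly length.
    """
    lengths: list[int] = []
    gc = at = other = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        lengths.append(len(seq))
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        other += len(seq) - (seq.count("G") + seq.count("C") + seq.count("A") + seq.count("T"))
    if not lengths:
        raise FormatError(f"{fasta_path}: no FASTA records")
    if other:
        logger.warning(
            "%s: %d non-A/C/G/T residues excluded from the GC denominator",
            fasta_path, other,
        )
    if gc + at == 0:
        raise FormatError(f"{fasta_path}: no unambiguous nucleotides for GC content")
    total = int(sum(lengths))
    ordered = sorted(lengths, reverse=True)
    cumulative = 0
    n50 = ordered[-1]
    for length in ordered:
        cumulative += length
        if 2 * cumulative >= total:
            n50 = length
            break
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length_bp=total,
        gc_percent=100.0 * gc / (gc + at),
        n50_bp=int(n50),
    )
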