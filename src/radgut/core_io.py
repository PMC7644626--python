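"""Shared domain types and plain-text I/O for the pipeline.

Conventions used throughout the package:

* Genomic coordinates are 1-based; intervals are closed on both ends
  (matching the ``chrom_pos_class`` marker naming of DGRP-style genotype
  files and the GFF3 convention). BED export, where offered, converts to
  0-based half-open.
* Genotype calls are those of a panel of homozygous inbred lines: a single
  biallelic call per line, 0 = major allele, 1 = minor allele, NaN =
  missing. Missing calls are retained in the panel and dropped per marker
  at fit time.
* All files are plain text (UTF-8, tab or comma delimited). Readers reject
  out-of-contract values instead of silently coercing them.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerId",
    "GenotypePanel",
    "PhenotypeTable",
    "SurvivalTable",
    "UtrSet",
    "Feature",
    "FeatureIndex",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "read_survival",
    "read_fasta",
    "read_gff",
    "write_scan_results",
    "read_scan_results",
    "SCAN_RESULT_COLUMNS",
]

VAR_CLASSES = ("SNP", "DEL", "INS", "MNP")

SEQ_ALPHABET = frozenset("ACGTUN")


@dataclass(frozen=True, order=True)
class MarkerId:
    """A biallelic marker named ``chrom_pos_class``, e.g. ``3R_21373234_SNP``.

    ``chrom`` is a chromosome-arm label (2L, 2R, 3L, 3R, X, 4), ``pos`` a
    1-based position and ``var_class`` one of SNP/DEL/INS/MNP. Parse and
    format round-trip exactly.
    """

    chrom: str
    pos: int
    var_class: str = "SNP"

    def __post_init__(self) -> None:
        if not self.chrom or "_" in self.chrom:
            raise ValueError(f"invalid chromosome label {self.chrom!r}")
        if not isinstance(self.pos, (int, np.integer)) or self.pos < 1:
            raise ValueError(f"marker position must be a positive integer, got {self.pos!r}")
        if self.var_class not in VAR_CLASSES:
            raise ValueError(
                f"unknown variant class {self.var_class!r}; expected one of {VAR_CLASSES}"
            )

    @classmethod
    def parse(cls, text: str) -> "MarkerId":
        parts = text.split("_")
        if len(parts) != 3:
            raise ValueError(f"malformed marker id {text!r}; expected 'chrom_pos_class'")
        chrom, pos_s, var_class = parts
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"malformed marker id {text!r}: non-integer position") from exc
        return cls(chrom=chrom, pos=pos, var_class=var_class)

    def __str__(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.var_class}"


@dataclass(frozen=True)
class GenotypePanel:
    """Marker-by-line matrix of homozygous biallelic calls.

    ``calls`` has shape (n_markers, n_lines) with entries in {0.0, 1.0, NaN}.
    """

    line_ids: tuple[str, ...]
    markers: tuple[MarkerId, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "markers", tuple(self.markers))
        calls = np.asarray(self.calls, dtype=float)
        object.__setattr__(self, "calls", calls)
        if calls.ndim != 2 or calls.shape != (len(self.markers), len(self.line_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.line_ids)} lines"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids in panel")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids in panel")
        finite = calls[~np.isnan(calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise ValueError(f"genotype calls must be 0, 1 or missing; found {bad!r}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset_markers(self, mask_or_indices) -> "GenotypePanel":
        idx = np.arange(self.n_markers)[mask_or_indices]
        return GenotypePanel(
            line_ids=self.line_ids,
            markers=tuple(self.markers[i] for i in idx),
            calls=self.calls[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=[str(m) for m in self.markers], columns=list(self.line_ids)
        )


PHENOTYPE_COLUMNS = ("line_id", "dose_gy", "n_total", "n_smurf")


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format Smurf observations: one row per line x dose (x vial).

    Counts, not proportions, are stored; the Smurf proportion is derived as
    ``n_smurf / n_total``. ``vial_id`` is optional and empty-string when the
    layout is pooled.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required columns: {missing}")
        if "vial_id" not in df.columns:
            df["vial_id"] = ""
        df["vial_id"] = df["vial_id"].fillna("").astype(str)
        df["line_id"] = df["line_id"].astype(str)
        df["dose_gy"] = pd.to_numeric(df["dose_gy"], errors="raise").astype(float)
        for col in ("n_total", "n_smurf"):
            vals = pd.to_numeric(df[col], errors="raise")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"{col} must be integer counts")
            df[col] = vals.astype(int)
        if (df["dose_gy"] < 0).any():
            raise ValueError("negative irradiation dose")
        if (df["n_total"] <= 0).any():
            raise ValueError("n_total must be > 0 for every record")
        if (df["n_smurf"] < 0).any() or (df["n_smurf"] > df["n_total"]).any():
            raise ValueError("n_smurf must satisfy 0 <= n_smurf <= n_total")
        key = df[["line_id", "dose_gy", "vial_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (line_id, dose_gy, vial_id) record: {dup}")
        df = df[["line_id", "dose_gy", "vial_id", "n_total", "n_smurf"]].reset_index(drop=True)
        object.__setattr__(self, "df", df)

    @property
    def line_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lid in self.df["line_id"]:
            seen.setdefault(lid, None)
        return tuple(seen)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted(self.df["dose_gy"].unique()))

    def proportions(self) -> pd.Series:
        return self.df["n_smurf"] / self.df["n_total"]

    def with_line_ids(self, mapping: Mapping[str, str]) -> "PhenotypeTable":
        df = self.df.copy()
        df["line_id"] = df["line_id"].map(lambda x: mapping.get(x, x))
        return PhenotypeTable(df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class SurvivalTable:
    """Right-censorable lifespan records: (group, time in days, event flag)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("group", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        df["group"] = df["group"].astype(str)
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
        df["event"] = df["event"].astype(int)
        if not np.isfinite(df["time"]).all() or (df["time"] <= 0).any():
            raise ValueError("survival times must be finite and positive")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event flag must be 0 (censored) or 1 (death)")
        object.__setattr__(self, "df", df[["group", "time", "event"]].reset_index(drop=True))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["group"]))


@dataclass(frozen=True)
class UtrSet:
    """Named 3'UTR sequences over {A,C,G,T,U,N} (sense strand by contract)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq.upper()) - SEQ_ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} contains invalid characters {sorted(bad)}")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences.items())

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]


FEATURE_PRIORITY = {"EXON": 0, "INTRON": 1, "NON_CODING": 2}

_GFF_CLASS_MAP = {
    "exon": "EXON",
    "intron": "INTRON",
    "ncrna": "NON_CODING",
    "non_coding": "NON_CODING",
    "noncoding_region": "NON_CODING",
    "pseudogene": "NON_CODING",
}


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 1-based, closed
    end: int
    feature_class: str
    gene: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"feature on {self.chrom} has end < start ({self.end} < {self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class FeatureIndex:
    """Per-chromosome interval set used to label markers (INTRON/EXON/...)."""

    features: tuple[Feature, ...]
    _by_chrom: dict[str, list[Feature]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Feature]] = {}
        for feat in self.features:
            by_chrom.setdefault(feat.chrom, []).append(feat)
        object.__setattr__(self, "_by_chrom", by_chrom)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def query(self, chrom: str, pos: int) -> list[Feature]:
        return [f for f in self._by_chrom.get(chrom, []) if f.contains(pos)]


# ---------------------------------------------------------------------------
# readers


_GENOTYPE_DIALECTS = {
    "simple": {"0": 0.0, "1": 1.0, "NA": math.nan},
    "dgrp": {"0": 0.0, "2": 1.0, "-": math.nan},
}


def read_genotypes(path: str | Path, dialect: str = "simple") -> GenotypePanel:
    """Read a DGRP-style genotype TSV into a :class:`GenotypePanel`.

    The header row is ``marker<TAB>line1<TAB>line2...``; each subsequent row
    is a ``chrom_pos_class`` marker id followed by one call per line. Two
    call codings are supported: ``simple`` uses {0, 1, NA} and ``dgrp`` uses
    {0, 2, -}, remapped to {0 = major, 1 = minor, missing}.
    """
    if dialect not in _GENOTYPE_DIALECTS:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    symbols = _GENOTYPE_DIALECTS[dialect]
    markers: list[MarkerId] = []
    rows: list[list[float]] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty genotype file") from None
        line_ids = tuple(header[1:])
        if not line_ids:
            raise ValueError(f"{path}: header lists no line ids")
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {rownum} has {len(row)} fields, expected {len(header)}"
                )
            try:
                marker = MarkerId.parse(row[0])
            except ValueError as exc:
                raise ValueError(f"{path}: row {rownum}: {exc}") from None
            calls = []
            for col, symbol in enumerate(row[1:], start=2):
                try:
                    calls.append(symbols[symbol.strip()])
                except KeyError:
                    raise ValueError(
                        f"{path}: row {rownum}, column {col}: unknown call symbol "
                        f"{symbol!r} for dialect {dialect!r}"
                    ) from None
            markers.append(marker)
            rows.append(calls)
    return GenotypePanel(
        line_ids=line_ids,
        markers=tuple(markers),
        calls=np.array(rows, dtype=float).reshape(len(markers), len(line_ids)),
    )


def write_genotypes(panel: GenotypePanel, path: str | Path, dialect: str = "simple") -> None:
    """Write a panel back to the genotype TSV format (inverse of
    :func:`read_genotypes` for the chosen dialect)."""
    if dialect not in _GENOTYPE_DIALECTS:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    inverse = {}
    for symbol, value in _GENOTYPE_DIALECTS[dialect].items():
        inverse["NA" if math.isnan(value) else value] = symbol
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["marker", *panel.line_ids])
        for marker, row in zip(panel.markers, panel.calls):
            writer.writerow(
                [str(marker)]
                + [inverse["NA"] if math.isnan(v) else inverse[v] for v in row]
            )


def read_phenotypes(path: str | Path, sep: str | None = None) -> PhenotypeTable:
    """Read a delimited Smurf-count table (columns line_id, dose_gy, n_total,
    n_smurf, optional vial_id). Delimiter is sniffed when ``sep`` is None."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return PhenotypeTable(df)


def read_survival(path: str | Path, sep: str | None = None) -> SurvivalTable:
    """Read a lifespan table with columns group, time, event."""
    return SurvivalTable(pd.read_csv(path, sep=sep, engine="python"))


def read_fasta(path: str | Path) -> UtrSet:
    """Read 3'UTR sequences (DNA or RNA alphabet) from FASTA.

    Duplicate record names are an error; an all-N record is accepted (it
    carries zero information for motif scanning) with a warning.
    """
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA record name {record.id!r}")
        seq = str(record.seq).upper()
        if seq and set(seq) <= {"N"}:
            warnings.warn(f"FASTA record {record.id!r} is all-N (zero information)")
        sequences[record.id] = seq
    return UtrSet(sequences)


def _gff_gene_name(attributes: Mapping[str, Sequence[str]]) -> str:
    for key in ("gene", "gene_id", "Name", "ID", "Parent"):
        if key in attributes and attributes[key]:
            return str(attributes[key][0])
    return ""


def read_gff(path: str | Path, feature_types: Iterable[str] | None = None) -> FeatureIndex:
    """Build a :class:`FeatureIndex` from GFF3.

    Feature types are mapped onto the controlled vocabulary (exon -> EXON,
    intron -> INTRON, ncRNA and friends -> NON_CODING); unmapped types are
    skipped. Records with end < start are rejected.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    wanted = {t.lower() for t in feature_types} if feature_types else None
    features: list[Feature] = []
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if wanted is not None and ftype not in wanted:
            continue
        mapped = _GFF_CLASS_MAP.get(ftype)
        if mapped is None:
            continue
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: feature {feat.id!r} has end < start ({feat.end} < {feat.start})"
            )
        features.append(
            Feature(
                chrom=str(feat.seqid),
                start=int(feat.start),
                end=int(feat.end),
                feature_class=mapped,
                gene=_gff_gene_name(feat.attributes),
            )
        )
    return FeatureIndex(features=tuple(features))


# ---------------------------------------------------------------------------
# scan-result TSV

SCAN_RESULT_COLUMNS = (
    "marker",
    "chrom",
    "pos",
    "class",
    "n_lines_used",
    "beta_interaction",
    "se",
    "t",
    "p",
    "fdr_percent",
    "location",
    "gene",
)

_FLOAT_COLUMNS = ("beta_interaction", "se", "t", "p", "fdr_percent")


def _fmt_float(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(float(x), ".17g")


def write_scan_results(frame: pd.DataFrame, path: str | Path) -> None:
    """Write per-marker scan results as TSV with the Table-1-compatible
    column set; floats are printed with enough digits to round-trip exactly."""
    missing = [c for c in SCAN_RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"scan results missing columns: {missing}")
    out = frame[list(SCAN_RESULT_COLUMNS)].copy()
    for col in _FLOAT_COLUMNS:
        out[col] = out[col].map(_fmt_float)
    out["location"] = out["location"].fillna("")
    out["gene"] = out["gene"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_scan_results(path: str | Path) -> pd.DataFrame:
    """Read back a scan-results TSV written by :func:`write_scan_results`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"marker": str, "chrom": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    for col in _FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    df["pos"] = df["pos"].astype(int)
    df["n_lines_used"] = df["n_lines_used"].astype(int)
    return df
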