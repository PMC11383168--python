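"""Readers and writers for the formats the pipeline touches.

All genomic intervals are 0-based half-open, matching BED/narrowPeak native
coordinates. The TSS of a minus-strand gene is ``end - 1``. Validation is
strict: malformed or inconsistent input raises :class:`ParseError` or
:class:`ValidationError` with the offending line or field named.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__


class JointnetError(Exception):
    """Base class for package errors."""


class ParseError(JointnetError):
    """A file could not be parsed; the message names the line."""


class ValidationError(JointnetError):
    """Parsed content violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_intervals(df: pd.DataFrame, what: str) -> None:
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(f"{what}: start >= end for records {list(bad[:5])}")


@dataclass
class GenomeAnnotation:
    """Gene universe: coordinates, strand, TSS and TF flags.

    ``table`` is indexed by gene_id with columns
    chrom, start, end, strand, is_tf, tss.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        _check_intervals(t, "annotation")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        if "tss" not in t.columns:
            t = t.copy()
            t["tss"] = np.where(t["strand"] == "+", t["start"], t["end"] - 1)
            self.table = t
        inside = (t["tss"] >= t["start"]) & (t["tss"] < t["end"])
        if not inside.all():
            raise ValidationError("tss outside [start, end)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tf_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"].astype(bool)])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakSet:
    """One sample's open-chromatin peaks (narrowPeak content).

    ``records``: DataFrame with chrom, start, end, name, intensity
    (narrowPeak signalValue) and summit_offset (bp from start, or -1),
    sorted by (chrom, start).
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        if len(r):
            _check_intervals(r, f"peaks[{self.sample_id}]")
            if (r["intensity"] < 0).any():
                raise ValidationError("peak intensity must be >= 0")
            self.records = r.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, all values finite and >= 0."""

    values: pd.DataFrame
    unit: str = "normalized"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError(
                f"duplicate gene ids: {list(v.index[v.index.duplicated()].unique()[:5])}"
            )
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite expression values")
        if (arr < 0).any():
            raise ValidationError("negative expression values")
        v.index.name = "gene_id"
        v.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MotifLibrary:
    """Position frequency matrices keyed by TF gene id.

    Each PWM is an (L, 4) array over columns A, C, G, T with rows summing
    to 1; ``background`` is a length-4 probability vector.
    """

    pwms: dict[str, np.ndarray]
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError("background frequencies must sum to 1")
        for name, pwm in self.pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValidationError(f"PWM {name}: expected (L, 4) matrix")
            if np.abs(pwm.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValidationError(f"PWM {name}: rows must sum to 1")
            self.pwms[name] = pwm

    def __contains__(self, tf_id: str) -> bool:
        return tf_id in self.pwms

    def consensus(self, tf_id: str) -> str:
        return "".join("ACGT"[i] for i in self.pwms[tf_id].argmax(axis=1))


@dataclass
class EPInteractions:
    """Enhancer-promoter links: enhancer interval -> target gene id.

    ``table`` columns: chrom, start, end, gene_id, confidence.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            _check_intervals(t, "EP interactions")
            if not np.isfinite(t["confidence"].to_numpy(dtype=float)).all():
                raise ValidationError("non-finite interaction confidence")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SampleMetadata:
    """Per-sample group/condition/subject labels, indexed by sample_id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        for col in ("group", "condition"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing column '{col}'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in(self, group: str | None = None, condition: str | None = None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if group is not None:
            mask &= t["group"] == group
        if condition is not None:
            mask &= t["condition"] == condition
        return list(t.index[mask])

    def require_covers(self, sample_ids: Sequence[str], what: str) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"metadata missing {what} samples: {missing[:5]}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into {chrom: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_narrowpeak(path: str | Path, sample_id: str | None = None) -> PeakSet:
    """Read an ENCODE narrowPeak file (>= 10 tab-separated columns)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"{path.name}:{lineno}: expected >=10 columns, got {len(parts)}")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3],
                     float(parts[6]), int(parts[9]))
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "intensity", "summit_offset"])
    return PeakSet(sample_id or path.stem.split(".")[0], df)


def read_expression_matrix(path: str | Path, unit: str = "normalized") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(df, unit=unit)


def read_gene_annotation(path: str | Path) -> GenomeAnnotation:
    """Read the BED6-like annotation TSV: chrom, start, end, gene_id, strand, is_tf."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "gene_id", "strand", "is_tf"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    df["is_tf"] = df["is_tf"].astype(int).astype(bool)
    return GenomeAnnotation(df.set_index("gene_id"))


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata must have a 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"))


def read_bedpe(path: str | Path) -> EPInteractions:
    """Read enhancer->gene links from BEDPE.

    The first interval is the enhancer; the target gene id is taken from the
    name column (column 7). The second interval (promoter) is retained only
    implicitly through the gene id.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path.name}:{lineno}: expected >=7 columns")
            try:
                conf = float(parts[7]) if len(parts) > 7 and parts[7] != "." else 1.0
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[6], conf))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    return EPInteractions(pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "confidence"]))


def read_marker_panel(path: str | Path) -> dict[str, list[str]]:
    """Read a marker-panel TSV with columns gene, panel -> {panel: [genes]}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", "panel"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns 'gene' and 'panel'")
    return {p: list(sub["gene"]) for p, sub in df.groupby("panel", sort=True)}


PSEUDOFREQUENCY = 1e-3


def _floor_and_renormalize(freqs: np.ndarray, pseudofrequency: float = PSEUDOFREQUENCY) -> np.ndarray:
    """Floor zero cells at ``pseudofrequency`` then renormalize each row."""
    f = np.maximum(freqs, pseudofrequency)
    return f / f.sum(axis=1, keepdims=True)


def read_pwm_library(
    path: str | Path,
    annotation: GenomeAnnotation | None = None,
    pseudofrequency: float = PSEUDOFREQUENCY,
) -> MotifLibrary:
    """Read a MEME-minimal motif file; motif names must be TF gene ids.

    The letter-probability matrix is parsed directly (keeping the printed
    precision), each row validated to sum to 1 within 1e-3, then floored at
    ``pseudofrequency`` and renormalized so log-odds scores stay finite.
    When ``annotation`` is given, every motif name must resolve to an
    annotated gene.
    """
    pwms: dict[str, np.ndarray] = {}
    background = np.full(4, 0.25)
    name: str | None = None
    rows: list[list[float]] = []
    expect_bg = False

    def _finish(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}:{lineno}: motif {name} has no matrix rows")
        freqs = np.asarray(rows, dtype=float)
        if np.abs(freqs.sum(axis=1) - 1.0).max() > 1e-3:
            raise ValidationError(f"motif {name}: probability rows deviate from sum 1 by >1e-3")
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
        pwms[name] = _floor_and_renormalize(freqs, pseudofrequency)
        name, rows = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if expect_bg and line:
                parts = line.split()
                try:
                    bg = {parts[i]: float(parts[i + 1]) for i in range(0, len(parts), 2)}
                    background = np.array([bg[b] for b in "ACGT"], dtype=float)
                except (KeyError, ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad background line ({exc})") from exc
                expect_bg = False
                continue
            if line.startswith("Background letter frequencies"):
                expect_bg = True
            elif line.startswith("MOTIF"):
                _finish(lineno)
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: MOTIF line without a name")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                continue
            elif name is not None and line:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad matrix row ({exc})") from exc
                if len(vals) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(vals)}")
                rows.append(vals)
        _finish(lineno)
    if annotation is not None:
        unknown = sorted(set(pwms) - set(annotation.gene_ids))
        if unknown:
            raise ValidationError(f"motif names absent from annotation: {unknown[:10]}")
    return MotifLibrary(pwms, background)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in peaks.records.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t.\t"
                f"{r.intensity:g}\t-1\t-1\t{r.summit_offset}\n"
            )


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def write_gene_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    t = annotation.table
    with open(path, "w") as fh:
        for gid, r in t.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{gid}\t{r.strand}\t{int(r.is_tf)}\n")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def write_bedpe(interactions: EPInteractions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in interactions.table.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t.\t-1\t-1\t{r.gene_id}\t{r.confidence:g}\n"
            )


def write_pwm_library(library: MotifLibrary, path: str | Path) -> None:
    """Write a MEME-minimal motif file (readable by :func:`read_pwm_library`)."""
    bg = library.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for name in library.pwms:
            pwm = library.pwms[name]
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20\n")
            for row in pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def write_marker_panel(panels: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpanel\n")
        for panel in sorted(panels):
            for gene in panels[panel]:
                fh.write(f"{gene}\t{panel}\n")


def config_hash(obj: object) -> str:
    """Stable short hash of a configuration-like object."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def write_table(result: pd.DataFrame, path: str | Path, config: object | None = None) -> None:
    """Write a result table as TSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# jointnet {__version__} config_hash={config_hash(config)}\n")
        result.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def warn_logged(message: str) -> None:
    warnings.warn(message, stacklevel=2)
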