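"""Genome I/O and the coordinate contract shared by the whole pipeline.

Sequences are DNA strings over ``{A, C, G, T, N}``, upper-cased on read.
Feature coordinates follow GFF3: 1-based, inclusive on both ends.  Window
arithmetic inside the package converts to 0-based half-open slices and
converts back only at the I/O boundary.

Translation-initiation-region (TIR) positions are reported in the field's
usual notation: position +1 is the first nucleotide of the start codon and
there is no position 0.  Internally the first start-codon base is offset 0,
so public position p maps to internal offset p for p < 0 and p - 1 for
p > 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Contig",
    "Feature",
    "Organism",
    "GffError",
    "read_genome",
    "write_genome",
    "feature_sequence",
    "reverse_complement",
    "transcribe",
    "write_gene_table",
    "write_summary_table",
    "GENE_TABLE_COLUMNS",
    "SUMMARY_TABLE_COLUMNS",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


class GffError(ValueError):
    """Malformed annotation or FASTA/GFF inconsistency."""


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Feature:
    """An annotated region. ``start``/``end`` are 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str  # "CDS" or "rRNA16S"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in ("CDS", "rRNA16S"):
            raise ValueError(f"bad feature kind {self.kind!r}")

    @property
    def gene(self) -> str:
        return self.attrs.get("gene", "")

    @property
    def product(self) -> str:
        return self.attrs.get("product", "")

    @property
    def feature_id(self) -> str:
        return self.attrs.get("ID", "")


@dataclass
class Organism:
    id: str
    contigs: list
    features: list

    def __post_init__(self) -> None:
        self._by_id = {c.id: c for c in self.contigs}
        for f in self.features:
            c = self._by_id.get(f.contig_id)
            if c is None:
                raise GffError(
                    f"{self.id}: feature on unknown contig {f.contig_id!r}"
                )
            if f.end > len(c.seq):
                raise GffError(
                    f"{self.id}: feature ({f.start},{f.end}) exceeds contig "
                    f"{f.contig_id!r} of length {len(c.seq)}"
                )

    def contig(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def cds_features(self) -> list:
        return [f for f in self.features if f.kind == "CDS"]

    def rrna16s_features(self) -> list:
        return [f for f in self.features if f.kind == "rRNA16S"]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Organism):
            return NotImplemented
        return (
            self.id == other.id
            and self.contigs == other.contigs
            and self.features == other.features
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcribe(seq: str) -> str:
    """DNA -> RNA (T becomes U); the identity on RNA input."""
    return seq.replace("T", "U")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_gff_attrs(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GffError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def _format_gff_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _classify(gff_type: str, attrs: dict) -> str | None:
    if gff_type == "CDS":
        return "CDS"
    if gff_type == "rRNA" and "16S" in attrs.get("product", ""):
        return "rRNA16S"
    return None


def read_genome(fasta_path, gff_path, organism_id: str | None = None) -> Organism:
    """Read a FASTA + GFF3 pair into an :class:`Organism`.

    Only CDS features and 16S rRNA features (GFF type ``rRNA`` with a
    product naming 16S) are retained; coordinates are kept 1-based
    inclusive as in the file.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = [
        Contig(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not contigs:
        raise GffError(f"{fasta_path}: no FASTA records")

    features = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffError(
                    f"{gff_path}:{lineno}: expected 9 columns, got {len(cols)}"
                )
            seqid, _source, gff_type, start, end, _score, strand, _phase, attr_col = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GffError(f"{gff_path}:{lineno}: bad coordinates") from exc
            attrs = _parse_gff_attrs(attr_col)
            kind = _classify(gff_type, attrs)
            if kind is None:
                continue
            if strand not in ("+", "-"):
                raise GffError(f"{gff_path}:{lineno}: bad strand {strand!r}")
            features.append(Feature(seqid, start_i, end_i, strand, kind, attrs))

    return Organism(organism_id or fasta_path.stem, contigs, features)


def write_genome(org: Organism, fasta_path, gff_path) -> None:
    """Write an organism back to FASTA + GFF3 (deterministic byte output)."""
    with open(fasta_path, "w") as fh:
        for c in org.contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), 70):
                fh.write(c.seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in org.features:
            gff_type = "rRNA" if f.kind == "rRNA16S" else "CDS"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "sdscan",
                        gff_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if gff_type == "CDS" else ".",
                        _format_gff_attrs(f.attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def _padded_slice(seq: str, lo: int, hi: int) -> str:
    """0-based half-open slice of ``seq`` with N-fill beyond either end."""
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(seq))
    return left + seq[max(0, lo) : min(len(seq), hi)] + right


def feature_sequence(
    org: Organism, f: Feature, upstream: int = 0, downstream: int = 0
) -> str:
    """Sense-strand RNA sequence of a feature with flanking extensions.

    ``upstream`` nucleotides before the feature's 5' end and ``downstream``
    nucleotides past its 3' end are included; on the minus strand the window
    is taken from the opposite side of the genomic interval and the result
    is reverse-complemented.  Positions beyond the contig are filled with N.
    """
    seq = org.contig(f.contig_id).seq
    if f.strand == "+":
        raw = _padded_slice(seq, f.start - 1 - upstream, f.end + downstream)
    else:
        raw = _padded_slice(seq, f.start - 1 - downstream, f.end + upstream)
        raw = reverse_complement(raw)
    return transcribe(raw)


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "organism",
    "gene",
    "product",
    "sd_dG",
    "sd_offset",
    "sd_helix_len",
    "msd_dG",
]

SUMMARY_TABLE_COLUMNS = (
    ["organism", "n_genes", "n_rproteins", "E_star"]
    + [f"excess_counts_{k}" for k in range(9)]
    + ["class"]
)


def _write_table(df: pd.DataFrame, columns: Sequence[str], sort_by, path) -> None:
    df = df.reindex(columns=columns)
    if len(df):
        df = df.sort_values(list(sort_by), kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.2f")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_gene_table(rows: Iterable, path) -> None:
    """Write per-gene affinities as TSV, sorted by (organism, gene)."""
    records = [
        {
            "organism": r.organism,
            "gene": r.gene,
            "product": r.product,
            "sd_dG": r.sd_dG,
            "sd_offset": r.sd_offset,
            "sd_helix_len": r.sd_helix_len,
            "msd_dG": r.msd_dG,
        }
        for r in rows
    ]
    _write_table(
        pd.DataFrame(records), GENE_TABLE_COLUMNS, ("organism", "gene"), path
    )


def write_summary_table(rows: Iterable, path) -> None:
    """Write per-organism summaries as TSV, sorted by organism id."""
    records = []
    for r in rows:
        rec = {
            "organism": r.organism,
            "n_genes": r.n_genes,
            "n_rproteins": r.n_rproteins,
            "E_star": r.E_star,
            "class": r.classification,
        }
        for k in range(9):
            rec[f"excess_counts_{k}"] = (
                r.excess_counts[k] if r.excess_counts is not None else ""
            )
        records.append(rec)
    _write_table(
        pd.DataFrame(records), SUMMARY_TABLE_COLUMNS, ("organism",), path
    )
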