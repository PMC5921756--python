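"""Readers and writers for the plain-text formats the pipeline consumes.

Gene tables and all tabular outputs are TSV with a header row; sequences
are FASTA (written wrapped at 60 columns by default). The gene-table
writer's output is re-read byte-identically for placed records.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from famkit.errors import FamkitError, ParseError, SchemaError
from famkit.model import UNPLACED, DomainAnnotation, DuplicatePair, GeneRecord, Motif, SequenceRecord

log = logging.getLogger("famkit.io")

GENE_TABLE_COLUMNS = (
    "name",
    "locus_id",
    "protein_id",
    "chromosome",
    "start",
    "end",
    "strand",
    "protein_length",
    "pi",
    "mol_wt_kda",
    "exon_count",
    "isoform_count",
)


def _fmt_float(x: float) -> str:
    # trim trailing zeros but keep at least one decimal digit
    s = f"{x:.6f}".rstrip("0")
    if s.endswith("."):
        s += "0"
    return s


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene-family annotation table into GeneRecords.

    Raises SchemaError when a required column is absent and ParseError
    (with the 1-based line number) when a numeric field fails to parse.
    Row order is preserved; UNPLACED rows carry no coordinates.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in GENE_TABLE_COLUMNS:
            if col not in header:
                raise SchemaError(f"gene table {path}: missing required column {col!r}")
        records: list[GeneRecord] = []
        for lineno, row in enumerate(reader, start=2):
            records.append(_parse_gene_row(row, lineno))
    return records


def _parse_gene_row(row: dict, lineno: int) -> GeneRecord:
    chrom = row["chromosome"].strip()
    unplaced = chrom == UNPLACED

    def _int(col: str) -> int:
        raw = row[col].strip()
        try:
            return int(raw.replace(",", ""))
        except ValueError:
            raise ParseError(f"column {col!r}: non-numeric value {raw!r}", line=lineno)

    def _float(col: str) -> float:
        raw = row[col].strip()
        try:
            return float(raw)
        except ValueError:
            raise ParseError(f"column {col!r}: non-numeric value {raw!r}", line=lineno)

    start = end = None
    if not unplaced:
        start, end = _int("start"), _int("end")
    elif row["start"].strip() or row["end"].strip():
        raise ParseError("UNPLACED row must have empty coordinates", line=lineno)
    try:
        return GeneRecord(
            name=row["name"].strip(),
            locus_id=row["locus_id"].strip(),
            protein_id=row["protein_id"].strip(),
            chromosome=chrom,
            start=start,
            end=end,
            strand=row["strand"].strip() or ".",
            protein_length=_int("protein_length"),
            pi=_float("pi"),
            mol_wt=_float("mol_wt_kda"),
            exon_count=_int("exon_count"),
            isoform_count=_int("isoform_count"),
        )
    except FamkitError as exc:
        raise ParseError(str(exc), line=lineno) from exc


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.name,
                    r.locus_id,
                    r.protein_id,
                    r.chromosome,
                    "" if r.start is None else r.start,
                    "" if r.end is None else r.end,
                    r.strand,
                    r.protein_length,
                    _fmt_float(r.pi),
                    _fmt_float(r.mol_wt),
                    r.exon_count,
                    r.isoform_count,
                ]
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file; duplicate ids and empty sequences are errors."""
    records = []
    ids: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        ids[rec.id] += 1
        if len(rec.seq) == 0:
            raise FamkitError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), kind=kind))
    dups = sorted(i for i, n in ids.items() if n > 1)
    if dups:
        raise FamkitError(f"{path}: duplicate FASTA ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Motifs, domain spans, duplicate pairs
# ---------------------------------------------------------------------------

def read_motif_table(path: str | Path) -> list[Motif]:
    """Two-column TSV (name, IUPAC pattern); extra columns are ignored."""
    motifs = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or "name" not in reader.fieldnames or "pattern" not in reader.fieldnames:
            raise SchemaError(f"motif table {path}: requires columns 'name' and 'pattern'")
        for row in reader:
            motifs.append(Motif(name=row["name"].strip(), pattern=row["pattern"].strip()))
    return motifs


def read_domain_table(path: str | Path) -> dict[str, DomainAnnotation]:
    """TSV (protein_id, domain, start, end) -> one annotation per protein."""
    spans: dict[str, dict[str, tuple[int, int]]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "domain", "start", "end"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"domain table {path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                s, e = int(row["start"]), int(row["end"])
            except ValueError:
                raise ParseError("non-numeric domain span", line=lineno)
            spans.setdefault(row["protein_id"].strip(), {})[row["domain"].strip()] = (s, e)
    return {pid: DomainAnnotation(protein_id=pid, spans=sp) for pid, sp in spans.items()}


def read_pair_table(path: str | Path) -> list[DuplicatePair]:
    """TSV (gene_a, gene_b, ka, ks) of duplicate gene pairs."""
    pairs = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_a", "gene_b", "ka", "ks"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"pair table {path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ka, ks = float(row["ka"]), float(row["ks"])
            except ValueError:
                raise ParseError("non-numeric Ka/Ks value", line=lineno)
            pairs.append(DuplicatePair(gene_a=row["gene_a"].strip(), gene_b=row["gene_b"].strip(), ka=ka, ks=ks))
    return pairs


def read_aligned_fasta(path: str | Path):
    """Read an aligned protein FASTA into a phylogeny Alignment."""
    from famkit.phylo import Alignment

    records = read_fasta(path, kind="protein")
    return Alignment(taxa=[r.id for r in records], rows=[r.seq.upper() for r in records])
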