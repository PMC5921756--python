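"""Packaged in-repo fixtures.

Three hand-curated plain-text tables ship inside the package so every
analysis and acceptance test runs without network access:

``table1``
    The 24-row gene-family annotation table (coordinates, strand,
    protein stats, exon and isoform counts). One gene is UNPLACED.
``table2_motifs``
    The 10 promoter cis-regulatory elements with their IUPAC patterns
    plus the published per-motif occurrence statistics (observed counts,
    expected-by-chance counts where recoverable, enrichment factors).
    Two ``expected_printed`` entries are recorded as NA: one is a known
    transcription artifact of the printed source, the other is garbled.
``mor_primers``
    Primer pairs for the 5' and 3' RNA-integrity amplicons.
"""

from __future__ import annotations

import csv
from importlib import resources

from famkit.errors import FamkitError
from famkit.io import _parse_gene_row
from famkit.model import Fixture, GeneRecord, Motif

FIXTURE_NAMES = ("table1", "table2_motifs", "mor_primers")


def _data_rows(filename: str) -> list[dict]:
    ref = resources.files("famkit.data").joinpath(filename)
    with ref.open(newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _maybe_float(raw: str) -> float | None:
    raw = raw.strip()
    return None if raw in {"", "NA"} else float(raw)


def load_fixture(name: str) -> Fixture:
    """Load a packaged fixture by name.

    table1 payload: list[GeneRecord] (24 rows);
    table2_motifs payload: list[dict] with keys ``motif`` (Motif),
    ``promoters_in_query``, ``promoters_observed``, ``total_observed``,
    ``avg_per_promoter``, ``expected_printed`` (float | None),
    ``enrichment_printed``, ``pvalue_printed`` (float | None);
    mor_primers payload: list[dict].
    """
    if name not in FIXTURE_NAMES:
        raise FamkitError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "table1":
        rows = _data_rows("table1.tsv")
        payload: list = [_parse_gene_row(row, lineno) for lineno, row in enumerate(rows, start=2)]
        if len(payload) != 24:
            raise FamkitError("table1 fixture must contain exactly 24 rows")
    elif name == "table2_motifs":
        payload = []
        for row in _data_rows("table2_motifs.tsv"):
            payload.append(
                {
                    "motif": Motif(name=row["name"], pattern=row["pattern"]),
                    "promoters_in_query": int(row["promoters_in_query"]),
                    "promoters_observed": int(row["promoters_observed"]),
                    "total_observed": int(row["total_observed"]),
                    "avg_per_promoter": float(row["avg_per_promoter"]),
                    "expected_printed": _maybe_float(row["expected_printed"]),
                    "enrichment_printed": float(row["enrichment_printed"]),
                    "pvalue_printed": _maybe_float(row["pvalue_printed"]),
                }
            )
        if len(payload) != 10:
            raise FamkitError("table2_motifs fixture must contain exactly 10 motifs")
    else:
        payload = _data_rows("mor_primers.tsv")
    return Fixture(name=name, payload=payload)


def table1_records() -> list[GeneRecord]:
    """Convenience accessor for the 24 packaged gene records."""
    return list(load_fixture("table1").payload)


def table2_motif_list() -> list[Motif]:
    """The 10 packaged cis-element motifs, in published order."""
    return [row["motif"] for row in load_fixture("table2_motifs").payload]
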