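"""Protein physicochemistry and domain-architecture classification.

Molecular weight uses standard average residue masses plus one water.
The isoelectric point solves the Henderson-Hasselbalch net-charge
equation over the termini and the D, E, C, Y, H, K, R side chains with
the Bjellqvist pKa set (the set used by the common web pI calculators),
by bisection. The middle region (MR) of a transcription-factor family
member is the stretch strictly between the AUX_RESP subdomain and
subdomain III (or the C terminus when III is absent), and its residue
composition drives the activator/repressor call.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from famkit.errors import FamkitError
from famkit.model import DomainAnnotation, GeneRecord

log = logging.getLogger("famkit.proteins")

# Average (isotope-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.015

# Bjellqvist pKa values: side chains, default termini, and
# residue-specific terminal corrections.
PKA_SIDECHAIN_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_SIDECHAIN_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_CTERM_DEFAULT = 3.55
PKA_NTERM_BY_RESIDUE = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}

# Architecture classes.
FULL = "FULL"
TRUNCATED_III_ONLY = "TRUNCATED_III_ONLY"
DBD_ONLY = "DBD_ONLY"

# Regulatory roles.
ACTIVATOR_QSL = "ACTIVATOR_QSL"
REPRESSOR_SPGL = "REPRESSOR_SPGL"
REPRESSOR_NO_CTD = "REPRESSOR_NO_CTD"

SIGNATURE_SETS = {"QSL": ("Q", "S", "L"), "SPGL": ("S", "P", "G", "L"), "G": ("G",)}


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise FamkitError(f"unknown residue {aa!r} at position {i}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight of a protein in kilodaltons."""
    if not seq:
        raise FamkitError("empty sequence has no molecular weight")
    seq = _check_protein(seq)
    mass_da = sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    return mass_da / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch).

    Strictly decreasing in pH, so the isoelectric point is the unique
    zero crossing.
    """
    seq = _check_protein(seq)
    counts = Counter(seq)
    pka_nt = PKA_NTERM_BY_RESIDUE.get(seq[0], PKA_NTERM_DEFAULT)
    pka_ct = PKA_CTERM_BY_RESIDUE.get(seq[-1], PKA_CTERM_DEFAULT)
    charge = 1.0 / (1.0 + 10 ** (ph - pka_nt))
    charge -= 1.0 / (1.0 + 10 ** (pka_ct - ph))
    for aa, pka in PKA_SIDECHAIN_POSITIVE.items():
        charge += counts[aa] / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_SIDECHAIN_NEGATIVE.items():
        charge -= counts[aa] / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 0.001) -> float:
    """pH at which the net charge crosses zero, found by bisection."""
    if not seq:
        raise FamkitError("empty sequence has no isoelectric point")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_architecture(annotation: DomainAnnotation) -> str:
    """FULL / TRUNCATED_III_ONLY / DBD_ONLY from the subdomain spans."""
    if not (annotation.has("B3") and annotation.has("AUX_RESP")):
        raise FamkitError(f"{annotation.protein_id}: B3 and AUX_RESP are required")
    has_iii, has_iv = annotation.has("III"), annotation.has("IV")
    if has_iv and not has_iii:
        raise FamkitError(
            f"{annotation.protein_id}: subdomain IV without III violates domain order"
        )
    if has_iii and has_iv:
        return FULL
    if has_iii:
        return TRUNCATED_III_ONLY
    return DBD_ONLY


def extract_mr(seq: str, annotation: DomainAnnotation) -> str:
    """Middle region: residues strictly between AUX_RESP end and III
    start (1-based closed spans); to the C terminus when III is absent."""
    if not annotation.has("AUX_RESP"):
        raise FamkitError(f"{annotation.protein_id}: AUX_RESP span required")
    seq = _check_protein(seq)
    _, aux_end = annotation.spans["AUX_RESP"]
    stop = annotation.spans["III"][0] - 1 if annotation.has("III") else len(seq)
    if aux_end >= stop:
        raise FamkitError(
            f"{annotation.protein_id}: degenerate annotation leaves an empty middle region"
        )
    return seq[aux_end:stop]


@dataclass
class MRComposition:
    protein_id: str
    frequencies: dict[str, float]
    signature_scores: dict[str, float]
    role: str


def residue_frequencies(seq: str) -> dict[str, float]:
    seq = _check_protein(seq)
    counts = Counter(seq)
    n = len(seq)
    return {aa: counts[aa] / n for aa in AVERAGE_RESIDUE_MASS}


def mean_background(seqs: Iterable[str]) -> dict[str, float]:
    """Mean residue frequencies of a protein set (pooled residues)."""
    counts: Counter[str] = Counter()
    total = 0
    for s in seqs:
        s = _check_protein(s)
        counts.update(s)
        total += len(s)
    if total == 0:
        raise FamkitError("background requires at least one residue")
    return {aa: counts[aa] / total for aa in AVERAGE_RESIDUE_MASS}


def classify_regulatory_role(
    mr: str,
    architecture: str,
    background: Mapping[str, float],
    protein_id: str = "",
) -> MRComposition:
    """Call the regulatory role of a family member from its MR makeup.

    A signature score for a residue set is the summed observed frequency
    over the set divided by the summed background frequency. The
    activator call requires the QSL score to be the strict maximum AND
    observed Q to exceed background Q; otherwise the protein is a
    repressor (with or without a CTD, per its architecture). Score ties
    resolve conservatively to repressor.
    """
    if not mr:
        raise FamkitError("empty middle region")
    freqs = residue_frequencies(mr)
    present = {aa for aa in set(mr.upper())}
    missing = [aa for aa in present if aa not in background]
    if missing:
        raise FamkitError(f"background frequencies missing residues {sorted(missing)}")
    scores = {}
    for label, residues in SIGNATURE_SETS.items():
        bg = sum(background.get(aa, 0.0) for aa in residues)
        if bg <= 0:
            raise FamkitError(f"background gives zero mass to signature set {label}")
        scores[label] = sum(freqs[aa] for aa in residues) / bg
    qsl_is_max = all(scores["QSL"] > scores[k] for k in scores if k != "QSL")
    q_enriched = freqs["Q"] > background.get("Q", 0.0)
    if qsl_is_max and q_enriched:
        role = ACTIVATOR_QSL
    elif architecture == DBD_ONLY:
        role = REPRESSOR_NO_CTD
    else:
        role = REPRESSOR_SPGL
    if not qsl_is_max and max(scores.values()) == scores["QSL"]:
        log.info("%s: QSL score ties another signature; calling repressor", protein_id)
    return MRComposition(
        protein_id=protein_id, frequencies=freqs, signature_scores=scores, role=role
    )


def activator_repressor_ratio(roles: Iterable[str]) -> float:
    """#activators / #repressors over a collection of role calls."""
    roles = list(roles)
    n_act = sum(1 for r in roles if r == ACTIVATOR_QSL)
    n_rep = len(roles) - n_act
    if n_rep == 0:
        raise FamkitError("no repressors: ratio undefined")
    return n_act / n_rep


_NUMERIC_COLUMNS = {
    "protein_length": lambda r: r.protein_length,
    "pi": lambda r: r.pi,
    "mol_wt": lambda r: r.mol_wt,
    "exon_count": lambda r: r.exon_count,
    "isoform_count": lambda r: r.isoform_count,
    "start": lambda r: r.start,
    "end": lambda r: r.end,
}


def table_extrema(records: Sequence[GeneRecord], column: str):
    """(min value, genes) and (max value, genes) for a numeric column.

    Ties are reported in gene-name order.
    """
    if column not in _NUMERIC_COLUMNS:
        raise FamkitError(
            f"unknown column {column!r}; numeric columns: {sorted(_NUMERIC_COLUMNS)}"
        )
    getter = _NUMERIC_COLUMNS[column]
    values = [(getter(r), r.name) for r in records if getter(r) is not None]
    if not values:
        raise FamkitError(f"no values in column {column!r}")
    vmin = min(v for v, _ in values)
    vmax = max(v for v, _ in values)
    min_genes = sorted(name for v, name in values if v == vmin)
    max_genes = sorted(name for v, name in values if v == vmax)
    return (vmin, min_genes), (vmax, max_genes)
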