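"""Seeded synthetic-data generators.

Every generator draws from a named substream of one central seeded
stream, so adding a generator does not shift the outputs of existing
ones, and every output is bit-reproducible under a fixed seed. Outputs
satisfy the preconditions of the consuming analysis modules without
modification.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famkit.cre import BackgroundModel, PromoterSet, expand_iupac
from famkit.errors import FamkitError
from famkit.model import DomainAnnotation, DuplicatePair, Motif, SequenceRecord
from famkit.genome import annotate_pair
from famkit.phylo import Alignment, SupportedTree, TreeNode
from famkit.proteins import AVERAGE_RESIDUE_MASS, DBD_ONLY, FULL, TRUNCATED_III_ONLY
from famkit.qpcr import CYCLE_LIMIT, CqTable

AMINO_ACIDS = "".join(sorted(AVERAGE_RESIDUE_MASS))
BASES = "ACGT"


@dataclass
class SimulationSpec:
    """Scenario parameters for a seeded simulation run."""

    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise FamkitError("a seed is mandatory for every simulation")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the central seeded stream."""
    return np.random.default_rng([zlib.crc32(name.encode("utf-8")), int(seed)])


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def gen_promoters(
    n: int = 23,
    length: int = 1500,
    gc: float = 0.28,
    plant: Mapping[Motif, tuple[int, tuple[int, int]]] | None = None,
    seed: int = 0,
) -> PromoterSet:
    """i.i.d. background promoters with optionally planted motifs.

    ``plant`` maps a motif to (copies per promoter, TSS-relative
    position window). Planted copies overwrite background bases at
    uniformly drawn positions inside the window and never overlap each
    other; infeasible schedules raise.
    """
    rng = substream(seed, "promoters")
    background = BackgroundModel(gc=gc)
    p = background.probability_vector()
    records = []
    plant = dict(plant or {})
    for motif, (copies, (lo, hi)) in plant.items():
        if lo < -length or hi > -1 or lo > hi:
            raise FamkitError(f"{motif.name}: window {(lo, hi)} outside promoter span")
        if hi - lo + 1 < copies * len(motif):
            raise FamkitError(f"{motif.name}: {copies} copies cannot fit in window {(lo, hi)}")
    for i in range(n):
        codes = rng.choice(4, size=length, p=p)
        seq = list("".join(BASES[c] for c in codes))
        occupied: list[tuple[int, int]] = []
        for motif, (copies, (lo, hi)) in plant.items():
            m = len(motif)
            sets = expand_iupac(motif.pattern)
            placed = 0
            attempts = 0
            while placed < copies:
                attempts += 1
                if attempts > 10_000:
                    raise FamkitError(
                        f"{motif.name}: could not place {copies} non-overlapping copies"
                    )
                start_rel = int(rng.integers(lo, hi - m + 2))  # TSS-relative start
                start = start_rel + length  # 0-based index
                if any(start < e and start + m > s for s, e in occupied):
                    continue
                for k, allowed in enumerate(sets):
                    choices = sorted(allowed)
                    seq[start + k] = choices[int(rng.integers(len(choices)))]
                occupied.append((start, start + m))
                placed += 1
        records.append(SequenceRecord(id=f"promoter_{i+1:02d}", seq="".join(seq), kind="dna"))
    return PromoterSet(sequences=records, length=length)


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------

#: Middle-region residue profiles by intended regulatory character.
MR_PROFILES: dict[str, dict[str, float]] = {
    "activator_qsl": {"Q": 0.35, "S": 0.20, "L": 0.15, "A": 0.10, "E": 0.08, "P": 0.05, "G": 0.04, "T": 0.03},
    "repressor_spgl": {"S": 0.28, "P": 0.22, "G": 0.18, "L": 0.18, "A": 0.06, "V": 0.04, "T": 0.02, "Q": 0.02},
    "repressor_g": {"G": 0.45, "S": 0.15, "P": 0.10, "L": 0.08, "A": 0.10, "N": 0.06, "T": 0.06},
}

_LENGTH_RANGES = {FULL: (750, 1100), TRUNCATED_III_ONLY: (680, 720), DBD_ONLY: (450, 640)}


def _draw_seq(rng: np.random.Generator, n: int, profile: Mapping[str, float] | None = None) -> str:
    if profile is None:
        return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))
    residues = sorted(profile)
    probs = np.array([profile[r] for r in residues])
    probs = probs / probs.sum()
    idx = rng.choice(len(residues), size=n, p=probs)
    return "".join(residues[i] for i in idx)


def gen_protein_family(
    schedule: Mapping[str, int],
    n_activators: int = 0,
    seed: int = 0,
    mr_profiles: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[SequenceRecord], dict[str, DomainAnnotation]]:
    """Proteins with prescribed domain architectures and MR mixtures.

    ``schedule`` gives counts per architecture class; ``n_activators``
    of the CTD-bearing proteins receive the activator MR profile, the
    rest the SPGL profile, and DBD-only proteins the glycine-rich
    profile. Downstream architecture and role classification recovers
    the schedule exactly.
    """
    profiles = {**MR_PROFILES, **(mr_profiles or {})}
    for name, prof in profiles.items():
        if not prof or abs(sum(prof.values()) - 1.0) > 1e-6:
            raise FamkitError(f"profile {name!r} frequencies must sum to 1")
    rng = substream(seed, "proteins")
    with_ctd = schedule.get(FULL, 0) + schedule.get(TRUNCATED_III_ONLY, 0)
    if n_activators > with_ctd:
        raise FamkitError("more activators requested than CTD-bearing proteins")
    records: list[SequenceRecord] = []
    annotations: dict[str, DomainAnnotation] = {}
    idx = 0
    activators_left = n_activators
    for arch in (FULL, TRUNCATED_III_ONLY, DBD_ONLY):
        for _ in range(schedule.get(arch, 0)):
            idx += 1
            pid = f"protein_{idx:02d}"
            lo, hi = _LENGTH_RANGES[arch]
            total = int(rng.integers(lo, hi + 1))
            if arch == DBD_ONLY:
                profile = profiles["repressor_g"]
            elif activators_left > 0:
                profile = profiles["activator_qsl"]
                activators_left -= 1
            else:
                profile = profiles["repressor_spgl"]
            spans = {"B3": (15, 120), "AUX_RESP": (130, 220)}
            if arch == FULL:
                spans["III"] = (total - 90, total - 50)
                spans["IV"] = (total - 45, total - 10)
            elif arch == TRUNCATED_III_ONLY:
                spans["III"] = (total - 60, total - 20)
            mr_start, mr_stop = 221, (spans["III"][0] - 1 if "III" in spans else total)
            seq = (
                _draw_seq(rng, 220)
                + _draw_seq(rng, mr_stop - mr_start + 1, profile)
                + _draw_seq(rng, total - mr_stop)
            )
            records.append(SequenceRecord(id=pid, seq=seq, kind="protein"))
            annotations[pid] = DomainAnnotation(protein_id=pid, spans=spans, source="simulated")
    return records, annotations


# ---------------------------------------------------------------------------
# Alignments on trees
# ---------------------------------------------------------------------------

def _check_binary(node: TreeNode, is_root: bool) -> None:
    k = len(node.children)
    if node.is_leaf:
        return
    if (is_root and k not in (2, 3)) or (not is_root and k != 2):
        raise FamkitError("gen_alignment_on_tree requires a binary tree")
    for child, length in node.children:
        if length < 0:
            raise FamkitError("branch lengths must be >= 0")
        _check_binary(child, is_root=False)


def gen_alignment_on_tree(tree: SupportedTree | TreeNode, length: int, seed: int = 0) -> Alignment:
    """Evolve amino-acid columns along a tree under the uniform-exchange
    (Poisson) model.

    The root sequence is uniform over the 20 residues; along a branch of
    length b each site substitutes, with probability 1 - exp(-b*20/19),
    to a residue drawn uniformly from the other 19. Expected pairwise
    Poisson-corrected distances approach path lengths as columns grow.
    """
    root = tree.root if isinstance(tree, SupportedTree) else tree
    _check_binary(root, is_root=True)
    rng = substream(seed, "alignment")
    taxa: list[str] = []
    rows: list[str] = []

    def evolve(codes: np.ndarray, node: TreeNode) -> None:
        if node.is_leaf:
            taxa.append(node.name or f"taxon_{len(taxa)+1}")
            rows.append("".join(AMINO_ACIDS[c] for c in codes))
            return
        for child, b in node.children:
            child_codes = codes.copy()
            p_sub = 1.0 - np.exp(-b * 20.0 / 19.0)
            hit = rng.random(len(codes)) < p_sub
            if hit.any():
                # uniform among the 19 other residues
                shift = rng.integers(1, 20, size=int(hit.sum()))
                child_codes[hit] = (child_codes[hit] + shift) % 20
            evolve(child_codes, child)

    evolve(rng.integers(0, 20, size=length), root)
    return Alignment(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

def gen_cq_table(
    true_nrqs: pd.DataFrame,
    references: Sequence[str],
    efficiencies: Mapping[str, float],
    calibrator: str,
    replicate_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
    base_cq: float = 24.0,
    sample_load_sd: float = 0.0,
) -> CqTable:
    """Invert the quantification model to Cq space and add replicate noise.

    ``true_nrqs`` is a sample x target frame of positive quantities
    relative to the calibrator sample. Reference assays are generated
    flat (relative quantity 1 everywhere) apart from a per-sample
    loading factor that normalization must cancel. Cq values drifting
    above the cycle limit are marked not-detected (NaN).
    """
    if (true_nrqs.values <= 0).any():
        raise FamkitError("true NRQs must be positive")
    if replicate_sd < 0:
        raise FamkitError("replicate noise sd must be >= 0")
    if calibrator not in true_nrqs.index:
        raise FamkitError(f"calibrator {calibrator!r} missing from true NRQ frame")
    rng = substream(seed, "cq")
    samples = list(true_nrqs.index)
    targets = list(true_nrqs.columns)
    assays = list(references) + targets
    for a in assays:
        if a not in efficiencies:
            raise FamkitError(f"no efficiency for assay {a!r}")
    loads = {
        s: float(rng.normal(0.0, sample_load_sd)) if sample_load_sd > 0 else 0.0
        for s in samples
    }  # log2 loading offsets, shared by every assay of the sample
    rows = []
    for s in samples:
        for a in assays:
            e = efficiencies[a]
            log_q = 0.0 if a in references else float(np.log2(true_nrqs.loc[s, a]))
            # Cq decreases as quantity grows; loading shifts all assays alike
            cq_mean = base_cq - (log_q + loads[s]) * np.log(2.0) / np.log(1.0 + e)
            for rep in range(1, replicates + 1):
                cq = cq_mean + (rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0)
                rows.append(
                    {
                        "sample": s,
                        "assay": a,
                        "replicate": rep,
                        "cq": np.nan if cq > CYCLE_LIMIT else cq,
                    }
                )
    return CqTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Ka/Ks pairs
# ---------------------------------------------------------------------------

def gen_kaks_pairs(
    n: int,
    components: Sequence[tuple[float, float]] = ((1.0, 0.19),),
    ks_range: tuple[float, float] = (0.59, 1.64),
    seed: int = 0,
    gamma: float = 6.1e-9,
) -> list[DuplicatePair]:
    """Duplicate pairs from a Ka/Ks mixture over a Ks range.

    ``components`` is a sequence of (weight, ratio); each pair draws a
    component by weight, Ks uniformly over ``ks_range``, and sets
    Ka = ratio * Ks. Pairs come back fully annotated (ratio, divergence
    time, selection mode).
    """
    lo, hi = ks_range
    if lo <= 0 or hi < lo:
        raise FamkitError("ks_range must be positive and ordered")
    weights = np.array([w for w, _ in components], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise FamkitError("mixture weights must be nonnegative and sum > 0")
    weights = weights / weights.sum()
    ratios = np.array([r for _, r in components], dtype=float)
    rng = substream(seed, "kaks")
    pairs = []
    for i in range(n):
        ratio = float(ratios[rng.choice(len(ratios), p=weights)])
        ks = float(rng.uniform(lo, hi))
        pair = DuplicatePair(gene_a=f"gene_{2*i+1:03d}", gene_b=f"gene_{2*i+2:03d}", ka=ratio * ks, ks=ks)
        pairs.append(annotate_pair(pair, gamma=gamma))
    return pairs
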