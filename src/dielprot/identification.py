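"""PSM filtering, decoy FDR, protein inference, emPAI and multi-fraction coverage.

This module implements the identification half of a shotgun-proteomics
workflow: tryptic in-silico digestion, acceptance rules for peptide-spectrum
matches (PSMs), target-decoy false-discovery-rate estimation, grouping of
accepted PSMs into protein inventories, the exponentially modified protein
abundance index (emPAI), and the set algebra used to compare protein
inventories across fractionation methods (Venn regions, proteome coverage).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _mass

__all__ = [
    "PSM",
    "Peptide",
    "ProteinGroup",
    "CoverageReport",
    "digest",
    "filter_psms",
    "decoy_fdr",
    "infer_proteins",
    "empai",
    "aggregate_methods",
    "top_n_by_empai",
    "top_n_shared",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTON_MASS = 1.00727646688  # Da


class UnknownResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""


class UndefinedFDRError(ValueError):
    """FDR requested with zero accepted target PSMs."""


class UndefinedEmpaiError(ValueError):
    """emPAI requested for a protein with no observable peptides."""


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match.

    ``score`` is the search-engine match score used for acceptance,
    ``ion_score`` the per-peptide score used downstream for quantification
    eligibility, and ``consecutive_ions`` the longest run of consecutive
    y- or b-type fragment ions (the machine-checkable stand-in for manual
    spectrum inspection).
    """

    peptide: str
    protein_ids: frozenset
    score: float
    ion_score: float = 0.0
    consecutive_ions: int = 0
    decoy: bool = False
    method: str = ""
    replicate: int = 0

    def __post_init__(self):
        if self.score < 0:
            raise ValueError(f"PSM score must be >= 0, got {self.score}")
        if self.consecutive_ions < 0:
            raise ValueError("consecutive_ions must be >= 0")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    missed_cleavages: int
    mono_mass: float

    def mz(self, charge: int = 2) -> float:
        """m/z of the ``charge``-protonated ion."""
        return (self.mono_mass + charge * PROTON_MASS) / charge


@dataclass
class ProteinGroup:
    """An inferred protein (or indistinguishable set of proteins).

    Proteins whose accepted peptide sets are identical are merged into one
    group; ``protein_ids`` then lists every member and ``representative``
    is the lexicographically first id.
    """

    protein_ids: tuple
    peptides: frozenset
    n_observed: int
    n_observable: int = 0
    empai: float = 0.0
    methods: frozenset = frozenset()
    single_peptide: bool = False

    @property
    def representative(self) -> str:
        return self.protein_ids[0]


@dataclass
class CoverageReport:
    inventories: dict
    venn_regions: dict          # frozenset(methods present) -> count
    union_size: int
    exclusives: dict            # method -> count seen only there
    pairwise_overlaps: dict     # frozenset({a, b}) -> |A ∩ B|
    theoretical_size: int
    coverage: float             # union / theoretical


def _validate_sequence(sequence: str) -> None:
    for ch in sequence:
        if ch not in STANDARD_RESIDUES:
            raise UnknownResidueError(
                f"unknown residue {ch!r} in sequence {sequence[:30]!r}"
            )


def cleavage_sites(sequence: str) -> list:
    """0-based positions after which trypsin cleaves (C-term of K/R, not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, max_missed: int = 1) -> list:
    """In-silico tryptic digestion with up to ``max_missed`` missed cleavages.

    Cleaves C-terminal to lysine and arginine except when the next residue
    is proline. Returns every product with 0..max_missed internal missed
    cleavage sites, each carrying its monoisotopic mass.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _validate_sequence(sequence)
    sites = cleavage_sites(sequence)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    peptides = []
    for start in range(len(fragments)):
        for missed in range(min(max_missed, len(fragments) - start - 1) + 1):
            seq = "".join(fragments[start : start + missed + 1])
            peptides.append(
                Peptide(seq, missed, _mass.fast_mass(seq))
            )
    return peptides


def filter_psms(psms: Iterable[PSM], score_high: float = 50.0,
                score_low: float = 25.0, min_consecutive_ions: int = 4) -> list:
    """Acceptance rule for PSMs.

    Accept outright above ``score_high``; in the grey zone
    (score_low, score_high] require a progression of at least
    ``min_consecutive_ions`` consecutive y- or b-type ions; reject the rest.
    Both boundaries are strict ("greater than"), so a PSM at exactly
    ``score_low`` is rejected. Decoy PSMs pass through the same rule so the
    decoy FDR reflects the accepted population.
    """
    accepted = []
    for p in psms:
        if p.score > score_high:
            accepted.append(p)
        elif p.score > score_low and p.consecutive_ions >= min_consecutive_ions:
            accepted.append(p)
    return accepted


def decoy_fdr(accepted: Iterable[PSM], formula: str = "decoy_over_target") -> float:
    """Target-decoy FDR (%) among accepted PSMs.

    ``decoy_over_target`` is 100·D/T (the search-engine decoy-report
    convention); ``doubled`` is the alternative 100·2D/(T+D).
    """
    accepted = list(accepted)
    n_decoy = sum(1 for p in accepted if p.decoy)
    n_target = len(accepted) - n_decoy
    if n_target == 0:
        raise UndefinedFDRError("no accepted target PSMs; FDR is undefined")
    if formula == "decoy_over_target":
        return 100.0 * n_decoy / n_target
    if formula == "doubled":
        return 100.0 * 2 * n_decoy / (n_target + n_decoy)
    raise ValueError(f"unknown FDR formula {formula!r}")


def _observable_count(sequence: str, scan_range, max_missed: int) -> int:
    low, high = scan_range
    seen = set()
    for pep in digest(sequence, max_missed):
        if pep.sequence in seen:
            continue
        if low <= pep.mz(2) <= high:
            seen.add(pep.sequence)
    return len(seen)


def infer_proteins(accepted: Iterable[PSM], proteome: Mapping[str, str],
                   scan_range=(300.0, 1500.0), max_missed: int = 1) -> list:
    """Group accepted target PSMs into protein groups.

    Shared peptides count toward every matching protein, but proteins whose
    accepted peptide sets are identical are indistinguishable and reported
    as a single merged group. ``n_observable`` (for emPAI) is the number of
    distinct tryptic peptides of the representative sequence whose
    doubly-protonated m/z falls inside ``scan_range``.
    """
    per_protein: dict = {}
    methods: dict = {}
    for p in accepted:
        if p.decoy:
            continue
        for pid in p.protein_ids:
            if pid not in proteome:
                raise KeyError(f"protein id {pid!r} not found in proteome")
            per_protein.setdefault(pid, set()).add(p.peptide)
            methods.setdefault(pid, set()).add(p.method)
    # merge proteins with identical peptide sets
    by_pepset: dict = {}
    for pid, peps in per_protein.items():
        by_pepset.setdefault(frozenset(peps), []).append(pid)
    groups = []
    for pepset, pids in by_pepset.items():
        pids = tuple(sorted(pids))
        rep = pids[0]
        group = ProteinGroup(
            protein_ids=pids,
            peptides=pepset,
            n_observed=len(pepset),
            n_observable=_observable_count(proteome[rep], scan_range, max_missed),
            methods=frozenset().union(*(methods[p] for p in pids)),
            single_peptide=len(pepset) == 1,
        )
        group.empai = empai(group)
        groups.append(group)
    groups.sort(key=lambda g: g.protein_ids)
    return groups


def empai(group: ProteinGroup) -> float:
    """Exponentially modified protein abundance index: 10^(N_obs/N_obsv) − 1."""
    if group.n_observable < 1:
        raise UndefinedEmpaiError(
            f"protein {group.representative} has no observable peptides"
        )
    if not 0 <= group.n_observed:
        raise ValueError("n_observed must be >= 0")
    return 10.0 ** (group.n_observed / group.n_observable) - 1.0


def aggregate_methods(inventories: Mapping[str, set],
                      theoretical_size: int = 0) -> CoverageReport:
    """Disjoint Venn regions, union, exclusives and coverage across methods.

    Every one of the 2^k − 1 non-empty membership patterns is enumerated
    directly from per-protein membership, so region counts are non-negative
    and sum to the union size by construction.
    """
    if not inventories:
        raise ValueError("at least one inventory is required")
    methods = sorted(inventories)
    union = set().union(*inventories.values())
    regions = {
        frozenset(combo): 0
        for r in range(1, len(methods) + 1)
        for combo in itertools.combinations(methods, r)
    }
    for protein in union:
        membership = frozenset(m for m in methods if protein in inventories[m])
        regions[membership] += 1
    exclusives = {m: regions[frozenset([m])] for m in methods}
    pairwise = {
        frozenset([a, b]): len(inventories[a] & inventories[b])
        for a, b in itertools.combinations(methods, 2)
    }
    coverage = len(union) / theoretical_size if theoretical_size else float("nan")
    return CoverageReport(
        inventories={m: set(v) for m, v in inventories.items()},
        venn_regions=regions,
        union_size=len(union),
        exclusives=exclusives,
        pairwise_overlaps=pairwise,
        theoretical_size=theoretical_size,
        coverage=coverage,
    )


def top_n_by_empai(groups: Sequence[ProteinGroup], n: int) -> list:
    """Top-``n`` protein groups by descending emPAI; ties broken by protein id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sorted(groups, key=lambda g: (-g.empai, g.representative))[:n]


def top_n_shared(groups_a: Sequence[ProteinGroup],
                 groups_b: Sequence[ProteinGroup], n: int) -> int:
    """How many proteins appear in the top-``n`` emPAI ranking of both fractions."""
    ids_a = {g.representative for g in top_n_by_empai(groups_a, n)}
    ids_b = {g.representative for g in top_n_by_empai(groups_b, n)}
    return len(ids_a & ids_b)
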