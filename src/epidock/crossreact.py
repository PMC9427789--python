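"""Cross-species epitope conservation and back-to-reference mutation design.

Ortholog pairs are aligned globally (Needleman-Wunsch with affine gaps,
BLOSUM62 by default, via Bio.Align.PairwiseAligner). Differences between a
reference species (e.g. the binder) and a query ortholog (e.g. a non-binder)
are mapped onto reference numbering, intersected with epitope regions, and
turned into "back mutation" proposals: replacing the query residue with the
corresponding reference residue, singly and in cumulative combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "OrthologPair",
    "DifferenceMap",
    "BackMutationProposal",
    "align_pair",
    "difference_positions",
    "epitope_overlap",
    "propose_back_mutations",
]

VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: one aligned column: (ref position, ref residue, query position, query
#: residue); gap partners are None. Positions are 1-based.
AlignedColumn = Tuple[Optional[int], Optional[str], Optional[int], Optional[str]]


@dataclass
class OrthologPair:
    reference_id: str
    query_id: str
    aligned_positions: List[AlignedColumn]
    identity_percent: float
    score: float


@dataclass
class DifferenceMap:
    #: substitutions as (ref position, ref residue, query residue)
    differing: List[Tuple[int, str, str]]
    #: columns where one side is gapped, as ref positions (query-side gaps)
    gap_positions: List[int]
    epitope_positions: Set[int] = field(default_factory=set)
    #: ref position -> query position for matched columns
    position_map: Dict[int, int] = field(default_factory=dict)

    @property
    def on_epitope(self) -> List[Tuple[int, str, str]]:
        return [d for d in self.differing if d[0] in self.epitope_positions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_pos": pos,
                    "ref_aa": ref,
                    "query_aa": query,
                    "on_epitope": pos in self.epitope_positions,
                }
                for pos, ref, query in self.differing
            ]
        )


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper().strip()
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = sorted(set(seq) - VALID_LETTERS)
    if bad:
        raise ValueError(f"{label}: invalid amino-acid letters {bad}")
    return seq


def align_pair(
    ref_seq: str,
    query_seq: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
    reference_id: str = "reference",
    query_id: str = "query",
) -> OrthologPair:
    """Optimal global alignment of two sequences (affine gap penalties).

    ``gap_open``/``gap_extend`` are positive penalties: the first residue of
    a gap run costs ``gap_open``, each further residue ``gap_extend``.
    Identity is computed over aligned (non-gap) columns.
    """
    ref_seq = _check_sequence(ref_seq, reference_id)
    query_seq = _check_sequence(query_seq, query_id)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    alignment = aligner.align(ref_seq, query_seq)[0]

    columns: List[AlignedColumn] = []
    ref_aln, query_aln = str(alignment[0]), str(alignment[1])
    ri = qi = 0
    matches = aligned_cols = 0
    for a, b in zip(ref_aln, query_aln):
        rpos = rres = qpos = qres = None
        if a != "-":
            ri += 1
            rpos, rres = ri, a
        if b != "-":
            qi += 1
            qpos, qres = qi, b
        if a != "-" and b != "-":
            aligned_cols += 1
            if a == b:
                matches += 1
        columns.append((rpos, rres, qpos, qres))
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    return OrthologPair(
        reference_id=reference_id,
        query_id=query_id,
        aligned_positions=columns,
        identity_percent=identity,
        score=float(alignment.score),
    )


def difference_positions(
    pair: OrthologPair,
    region: Optional[Tuple[int, int]] = None,
    epitope_positions: Optional[Iterable[int]] = None,
) -> DifferenceMap:
    """Aligned columns within ``region`` (ref numbering) where ref != query.

    Gapped columns are reported separately, not as substitutions.
    """
    if region is not None and region[0] > region[1]:
        raise ValueError(f"empty region {region}")

    def in_region(pos: int) -> bool:
        return region is None or region[0] <= pos <= region[1]

    differing: List[Tuple[int, str, str]] = []
    gaps: List[int] = []
    pos_map: Dict[int, int] = {}
    for rpos, rres, qpos, qres in pair.aligned_positions:
        if rpos is None or not in_region(rpos):
            continue
        if qpos is None:
            gaps.append(rpos)
            continue
        pos_map[rpos] = qpos
        if rres != qres:
            differing.append((rpos, rres, qres))
    return DifferenceMap(
        differing=differing,
        gap_positions=gaps,
        epitope_positions=set(epitope_positions or ()),
        position_map=pos_map,
    )


def epitope_overlap(
    diff: DifferenceMap, epitope_positions: Iterable[int]
) -> Tuple[int, float]:
    """(count, percent) of species differences lying on epitope positions."""
    epi = set(epitope_positions)
    on = [d for d in diff.differing if d[0] in epi]
    if not diff.differing:
        return 0, 0.0
    return len(on), 100.0 * len(on) / len(diff.differing)


@dataclass
class BackMutationProposal:
    #: (ref position, query residue, ref residue) — label e.g. "T49N"
    mutations: List[Tuple[int, str, str]]
    combination_sets: List[List[Tuple[int, str, str]]]

    @property
    def labels(self) -> List[str]:
        return [f"{q}{p}{r}" for p, q, r in self.mutations]

    @property
    def combination_labels(self) -> List[List[str]]:
        return [[f"{q}{p}{r}" for p, q, r in s] for s in self.combination_sets]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_pos": p,
                    "query_aa": q,
                    "ref_aa": r,
                    "mutation_label": f"{q}{p}{r}",
                }
                for p, q, r in self.mutations
            ]
        )


def propose_back_mutations(
    diff: DifferenceMap,
    restrict_to: Iterable[int],
    combination_policy: str = "singles_plus_cumulative",
    priority_order: Optional[Sequence[int]] = None,
) -> BackMutationProposal:
    """Back mutations restoring reference residues at epitope differences.

    Singles: every difference at a position in ``restrict_to``, as
    query-residue -> reference-residue (labelled in reference numbering,
    e.g. "T49N"). With the cumulative policy, combination sets are the
    prefixes (length >= 2) of ``priority_order`` — mutations are added one
    at a time in stated priority.
    """
    if not diff.differing:
        raise ValueError("difference map is empty")
    restrict = set(restrict_to)
    selected = [d for d in diff.differing if d[0] in restrict]
    if not selected:
        raise ValueError("no species differences at the requested positions")
    mutations = [(p, q, r) for p, r, q in selected]  # (pos, query, ref)
    mutations.sort(key=lambda m: m[0])
    combos: List[List[Tuple[int, str, str]]] = []
    if combination_policy == "singles_plus_cumulative":
        order = list(priority_order) if priority_order else [m[0] for m in mutations]
        unknown = [p for p in order if p not in {m[0] for m in mutations}]
        if unknown:
            raise ValueError(f"priority positions without a proposed mutation: {unknown}")
        by_pos = {m[0]: m for m in mutations}
        for k in range(2, len(order) + 1):
            combos.append(sorted((by_pos[p] for p in order[:k]), key=lambda m: m[0]))
    elif combination_policy != "singles":
        raise ValueError(f"unknown combination policy {combination_policy!r}")
    return BackMutationProposal(mutations=mutations, combination_sets=combos)
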