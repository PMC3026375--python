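"""Replicate-consensus genotypes and F1-based donor inference.

Parental lines are often genotyped several times; the relationships file
links the replicates to a root sample.  A single consensus genotype per
marker is derived by strict majority vote over the non-missing replicate
calls: ties (including one-vs-one) yield a missing consensus, flagged as a
conflict.  This is deliberately conservative — discordant replicates never
fabricate a parental allele.

When a donor parent was never genotyped but an F1 of the cross was, the
donor genotype is recovered by allele subtraction: a homozygous recurrent
parent x/x together with an F1 x/y implies a donor y/y.  Anything less
clean (an F1 lacking the recurrent allele, a heterozygous recurrent
consensus, missing inputs) degrades to a missing donor call with a reason
flag rather than a guess.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

from .genotype import MISSING, Genotype, hom
from .io import GenotypeMatrix, SampleRecord


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of a majority vote over replicate calls at one marker."""

    genotype: Genotype
    n_support: int
    n_total: int
    conflict: bool

    @property
    def low_confidence(self) -> bool:
        """Heterozygous consensus for an inbred parent: plausibly an error."""
        return self.genotype.is_het


def replicate_groups(records: Sequence[SampleRecord]) -> Dict[str, Set[str]]:
    """Group sample ids by the root of their replicate chain.

    Roots (samples with a blank replicate-of field) map to themselves;
    every replicate resolves transitively to its root.
    """
    parent = {r.sample_id: r.replicate_of for r in records}

    def root_of(sid: str) -> str:
        while parent[sid] is not None:
            sid = parent[sid]
        return sid

    groups: Dict[str, Set[str]] = {}
    for sid in parent:
        groups.setdefault(root_of(sid), set()).add(sid)
    return groups


def consensus_genotype(calls: Sequence[Genotype]) -> ConsensusResult:
    """Strict-majority consensus over one replicate group's calls.

    Missing calls abstain.  The winner must exceed half of the non-missing
    votes; otherwise the consensus is missing.  ``conflict`` is true when
    two or more distinct non-missing genotypes were observed.
    """
    votes = Counter(g for g in calls if not g.is_missing)
    n_total = sum(votes.values())
    conflict = len(votes) >= 2
    if n_total == 0:
        return ConsensusResult(MISSING, 0, 0, False)
    top, top_count = votes.most_common(1)[0]
    if top_count * 2 > n_total:
        return ConsensusResult(top, top_count, n_total, conflict)
    return ConsensusResult(MISSING, 0, n_total, True)


def group_consensus(matrix: GenotypeMatrix, group: Sequence[str],
                    marker: str) -> ConsensusResult:
    """Consensus for one replicate group at one marker of the raw matrix."""
    if marker not in matrix:
        return ConsensusResult(MISSING, 0, 0, False)
    return consensus_genotype(matrix.calls_for(marker, sorted(group)))


@dataclass(frozen=True)
class DonorInference:
    """Donor genotype inferred from F1 and recurrent-parent genotypes."""

    genotype: Genotype
    flag: Optional[str] = None  # None on success / uninformative


def infer_donor_from_f1(f1: Genotype, recurrent: Genotype) -> DonorInference:
    if f1.is_missing or recurrent.is_missing:
        return DonorInference(MISSING, "missing input")
    if recurrent.is_het:
        return DonorInference(MISSING, "ambiguous: recurrent consensus het")
    r = recurrent.hom_allele()
    if f1 == recurrent:
        # uninformative marker: parents indistinguishable here
        return DonorInference(recurrent)
    if f1.is_het and r in f1.alleles:
        other = f1.alleles[0] if f1.alleles[1] == r else f1.alleles[1]
        return DonorInference(hom(other))
    return DonorInference(MISSING, "inconsistent: F1 lacks recurrent allele")


def consensus_audit_rows(matrix: GenotypeMatrix,
                         groups: Dict[str, Set[str]]) -> List[dict]:
    """Audit table: one row per (marker, replicate group) with the vote."""
    rows = []
    for marker in matrix.markers:
        for root in sorted(groups, key=str):
            members = sorted(groups[root])
            calls = matrix.calls_for(marker, members)
            res = consensus_genotype(calls)
            rows.append({
                "marker": marker,
                "group": root,
                "calls": ",".join(g.token for g in calls),
                "consensus": res.genotype.token,
                "n_support": res.n_support,
                "n_total": res.n_total,
                "conflict": int(res.conflict),
            })
    return rows
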