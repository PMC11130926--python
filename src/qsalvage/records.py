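"""Core domain types shared by every pipeline stage.

All positional reasoning downstream is done in *gene ranks* (``gene_index``),
not base pairs: an adjacent gene is at distance 1.  Strand is stored for
provenance but never conditions a distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class DomainHit(NamedTuple):
    """One domain/family assignment on a protein (1-based inclusive aa coords)."""

    accession: str
    start_aa: int
    end_aa: int


@dataclass
class ProteinRecord:
    """One annotated gene/protein in a genome.

    ``gene_index`` is the 0-based rank of the gene along its contig in
    coordinate order; it must be unique within (genome_id, contig_id).
    ``families`` always contains every accession appearing in ``domains``.
    """

    protein_id: str
    genome_id: str
    contig_id: str
    gene_index: int
    strand: str
    length_aa: int
    families: frozenset = field(default_factory=frozenset)
    domains: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"protein {self.protein_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.length_aa < 1:
            raise ValueError(f"protein {self.protein_id}: length_aa must be >= 1")
        if self.gene_index < 0:
            raise ValueError(f"protein {self.protein_id}: gene_index must be >= 0")
        doms = tuple(DomainHit(*d) for d in self.domains)
        for d in doms:
            if not (1 <= d.start_aa <= d.end_aa <= self.length_aa):
                raise ValueError(
                    f"protein {self.protein_id}: domain {d.accession} coordinates "
                    f"[{d.start_aa}, {d.end_aa}] outside 1..{self.length_aa}"
                )
        self.domains = doms
        # families must cover every domain accession
        self.families = frozenset(self.families) | {d.accession for d in doms}


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a marker query against a genome's proteins."""

    marker_id: str
    subject_protein_id: str
    genome_id: str
    percent_identity: float
    e_value: float
    bitscore: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"hit {self.marker_id}->{self.subject_protein_id}: percent_identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValueError(
                f"hit {self.marker_id}->{self.subject_protein_id}: negative E-value"
            )


@dataclass(frozen=True)
class PairScore:
    """Symmetric pairwise similarity between two proteins.

    ``alignment_score`` (AS) is -log10 of the pair's E-value, the edge unit of
    EFI-style sequence similarity networks.  At most one orientation per
    unordered pair is stored; duplicate orientations keep the maximum AS.
    """

    protein_a: str
    protein_b: str
    percent_identity: float
    alignment_score: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-pair not allowed: {self.protein_a}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"pair {self.protein_a}-{self.protein_b}: percent_identity outside [0, 100]"
            )
        if self.alignment_score < 0:
            raise ValueError(
                f"pair {self.protein_a}-{self.protein_b}: negative alignment score"
            )

    @property
    def key(self):
        """Canonical unordered key for deduplication."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)


def dedupe_pairs(pairs):
    """Collapse duplicate unordered pairs, keeping the maximum AS per pair."""
    best = {}
    for p in pairs:
        k = p.key
        old = best.get(k)
        if old is None or p.alignment_score > old.alignment_score:
            best[k] = p
    return [best[k] for k in sorted(best)]


def attach_domains(records, domains):
    """Return new ProteinRecords with domain assignments merged in.

    ``domains``: iterable of (protein_id, accession, start_aa, end_aa).
    Unknown protein ids raise; proteins without domains pass through unchanged.
    """
    by_protein = {}
    known = {r.protein_id for r in records}
    for pid, acc, start, end in domains:
        if pid not in known:
            raise ValueError(f"domain row references unknown protein {pid}")
        by_protein.setdefault(pid, []).append(DomainHit(acc, int(start), int(end)))
    out = []
    for r in records:
        if r.protein_id in by_protein:
            doms = tuple(sorted(r.domains) + sorted(by_protein[r.protein_id]))
            out.append(
                ProteinRecord(
                    r.protein_id, r.genome_id, r.contig_id, r.gene_index,
                    r.strand, r.length_aa, r.families, doms,
                )
            )
        else:
            out.append(r)
    return out
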