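"""Physical-clustering and fusion evidence for candidate transporter families.

Two classic guilt-by-association signals:

* gene-neighborhood mining — protein families repeatedly found within a small
  gene-rank window of a Q-salvage signature gene (bTGT, Qng1, or QueK) across
  genomes.  Candidates must have a median gene distance of at most 2 and a
  clustering ratio (distinct clustered members / family size) strictly above
  0.2%.
* Rosetta-stone fusions — single proteins of 500–2000 aa carrying both a bTGT
  domain and a transporter-family domain.

Distances are gene ranks (adjacent gene = 1), never base pairs, and strand is
ignored.  Contigs are linear unless flagged circular, in which case the
distance wraps: min(|i-j|, L-|i-j|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW = 10
MAX_MEDIAN_DISTANCE = 2.0
MIN_CLUSTERING_RATIO = 0.002


@dataclass(frozen=True)
class NeighborhoodRecord:
    """One (signature gene, neighbor gene) co-localization on a contig."""

    signature_protein_id: str
    signature_marker: str
    neighbor_protein_id: str
    neighbor_families: frozenset
    gene_distance: int
    genome_id: str
    neighbor_is_signature: bool = False

    def __post_init__(self):
        if self.gene_distance < 1:
            raise ValueError("gene_distance must be >= 1")
        if self.neighbor_protein_id == self.signature_protein_id:
            raise ValueError("a signature gene is not its own neighbor")


@dataclass(frozen=True)
class FamilyAssociationStats:
    """Clustering evidence for one candidate family."""

    family_accession: str
    n_neighbor_occurrences: int
    n_genomes: int
    median_distance: float
    family_total_members: int
    clustering_ratio: float
    passes_filters: bool


@dataclass(frozen=True)
class FusionCall:
    """A protein fusing a signature (bTGT-like) domain with a transporter domain."""

    protein_id: str
    genome_id: str
    length_aa: int
    signature_domain: str
    partner_domains: frozenset
    domain_order: tuple


def extract_neighborhoods(records, signature_accessions, window=DEFAULT_WINDOW,
                          circular_contigs=frozenset()):
    """Enumerate neighbors of every signature gene within a gene-rank window.

    ``signature_accessions`` maps a marker name (bTGT/Qng1/QueK) to the family
    accessions identifying it.  Every protein carrying a signature accession
    yields one record per neighbor at distance 1..window on the same contig.
    Contig ends truncate the window; contigs listed in ``circular_contigs``
    wrap, using the modular distance min(|i-j|, L-|i-j|).  Neighbors that are
    themselves signature proteins are emitted too, flagged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    for marker in signature_accessions:
        if not signature_accessions[marker]:
            raise ValueError(f"marker {marker!r} has no accessions")
    acc_to_marker = {}
    for marker, accs in signature_accessions.items():
        for acc in accs:
            acc_to_marker.setdefault(acc, set()).add(marker)
    all_sig_accs = set(acc_to_marker)

    contigs = {}
    for r in records:
        contigs.setdefault((r.genome_id, r.contig_id), []).append(r)

    out = []
    for (genome_id, contig_id), genes in sorted(contigs.items()):
        genes.sort(key=lambda r: r.gene_index)
        n = len(genes)
        circular = contig_id in circular_contigs
        span = genes[-1].gene_index + 1
        pos_of = {i: g for i, g in enumerate(genes)}
        for i, g in enumerate(genes):
            sig_accs = g.families & all_sig_accs
            if not sig_accs:
                continue
            markers = sorted({m for a in sig_accs for m in acc_to_marker[a]})
            for j in range(n):
                if j == i:
                    continue
                d = abs(genes[j].gene_index - g.gene_index)
                if circular:
                    d = min(d, span - d)
                if not 1 <= d <= window:
                    continue
                neighbor = pos_of[j]
                for marker in markers:
                    out.append(
                        NeighborhoodRecord(
                            signature_protein_id=g.protein_id,
                            signature_marker=marker,
                            neighbor_protein_id=neighbor.protein_id,
                            neighbor_families=frozenset(neighbor.families),
                            gene_distance=int(d),
                            genome_id=genome_id,
                            neighbor_is_signature=bool(neighbor.families & all_sig_accs),
                        )
                    )
    return out


def family_stats(neigh, family_sizes, max_median_distance=MAX_MEDIAN_DISTANCE,
                 min_clustering_ratio=MIN_CLUSTERING_RATIO):
    """Aggregate neighborhood records into per-family clustering statistics.

    The median is taken over all neighbor occurrences (records); the
    clustering-ratio numerator counts *distinct* neighbor proteins so a
    protein seen from two signature genes is not double-counted.  A family
    passes iff median_distance <= 2 (inclusive) and ratio > 0.002 (strict).
    """
    per_family = {}
    for rec in neigh:
        for acc in rec.neighbor_families:
            per_family.setdefault(acc, []).append(rec)

    missing = [a for a in per_family if a not in family_sizes]
    if missing:
        raise ValueError(f"family_sizes missing accession(s): {sorted(missing)}")

    out = []
    for acc in sorted(per_family):
        recs = per_family[acc]
        total = int(family_sizes[acc])
        if total <= 0:
            raise ValueError(
                f"family {acc} has {len(recs)} occurrences but size {total}"
            )
        distances = [r.gene_distance for r in recs]
        distinct = {r.neighbor_protein_id for r in recs}
        ratio = len(distinct) / total
        if ratio > 1:
            raise ValueError(
                f"family {acc}: clustering ratio {ratio} > 1 — family_sizes "
                "does not cover the dataset"
            )
        median = float(np.median(distances))
        out.append(
            FamilyAssociationStats(
                family_accession=acc,
                n_neighbor_occurrences=len(recs),
                n_genomes=len({r.genome_id for r in recs}),
                median_distance=median,
                family_total_members=total,
                clustering_ratio=ratio,
                passes_filters=(median <= max_median_distance)
                and (ratio > min_clustering_ratio),
            )
        )
    return out


def _overlap_len(a, b):
    return max(0, min(a.end_aa, b.end_aa) - max(a.start_aa, b.start_aa) + 1)


def detect_fusions(records, signature_accessions, transporter_accessions,
                   min_len=500, max_len=2000):
    """Find transporter–bTGT fusion proteins by domain co-occurrence.

    A call requires at least one signature domain and one transporter domain
    on a protein of min_len..max_len aa.  A partner domain overlapping a
    signature domain by more than 50% of the shorter domain is discarded as a
    double-annotation artifact, not a fusion.
    """
    sig_accs = set(signature_accessions)
    trans_accs = set(transporter_accessions)
    calls = []
    for r in sorted(records, key=lambda r: r.protein_id):
        if not (min_len <= r.length_aa <= max_len):
            continue
        sig_doms = [d for d in r.domains if d.accession in sig_accs]
        part_doms = [d for d in r.domains if d.accession in trans_accs]
        if not sig_doms or not part_doms:
            continue
        valid_partners = []
        for pd_ in part_doms:
            plen = pd_.end_aa - pd_.start_aa + 1
            artifact = False
            for sd in sig_doms:
                shorter = min(plen, sd.end_aa - sd.start_aa + 1)
                if _overlap_len(pd_, sd) > 0.5 * shorter:
                    artifact = True
                    break
            if not artifact:
                valid_partners.append(pd_)
        if not valid_partners:
            continue
        order = tuple(
            d.accession for d in sorted(r.domains, key=lambda d: (d.start_aa, d.end_aa))
        )
        calls.append(
            FusionCall(
                protein_id=r.protein_id,
                genome_id=r.genome_id,
                length_aa=r.length_aa,
                signature_domain=min(d.accession for d in sig_doms),
                partner_domains=frozenset(d.accession for d in valid_partners),
                domain_order=order,
            )
        )
    return calls


def stats_to_frame(stats):
    import pandas as pd

    return pd.DataFrame([{
        "family_accession": s.family_accession,
        "n_neighbor_occurrences": s.n_neighbor_occurrences,
        "n_genomes": s.n_genomes,
        "median_distance": s.median_distance,
        "family_total_members": s.family_total_members,
        "clustering_ratio": s.clustering_ratio,
        "passes_filters": int(s.passes_filters),
    } for s in stats])


def neighborhoods_to_frame(neigh):
    import pandas as pd

    return pd.DataFrame([{
        "signature_protein_id": r.signature_protein_id,
        "signature_marker": r.signature_marker,
        "neighbor_protein_id": r.neighbor_protein_id,
        "neighbor_families": ";".join(sorted(r.neighbor_families)),
        "gene_distance": r.gene_distance,
        "genome_id": r.genome_id,
        "neighbor_is_signature": int(r.neighbor_is_signature),
    } for r in neigh])


def fusions_to_frame(calls):
    import pandas as pd

    return pd.DataFrame([{
        "protein_id": c.protein_id,
        "genome_id": c.genome_id,
        "length_aa": c.length_aa,
        "signature_domain": c.signature_domain,
        "partner_domains": ";".join(sorted(c.partner_domains)),
        "domain_order": ";".join(c.domain_order),
    } for c in calls])
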