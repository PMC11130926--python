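"""Candidate prioritization: profile-weighted scores, z-selection, enrichment.

The reasoning: a transporter family that repeatedly sits next to Q-salvage
signature genes is interesting, but far more so when the genomes carrying it
*need* to import a Q precursor.  Each neighbor occurrence is therefore
weighted by the Q-pathway profile of its genome — salvage-requiring genomes
with no known transporter (the "transporter gap") count most, de novo
synthesizers little, non-users nothing.  Family scores are standardized to
z-scores and candidates selected at z >= 1, keeping known transporter
families as positive controls.  Per-SSN-cluster enrichment percentages then
show which candidate dominates each isofunctional subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiler import NON_USER, SALVAGE_REQUIRING

#: default weights; salvage-requiring transporter-gap genomes dominate by design
DEFAULT_WEIGHTS = {
    "salvager_gap": 2.0,     # salvage-requiring, no known transporter
    "salvager": 1.0,         # salvage-requiring, known transporter present
    "de_novo": 0.25,         # synthesizes de novo (may still salvage)
    "non_user": 0.0,
}

DEFAULT_Z_MIN = 1.0

#: accessions of the experimentally known Q-precursor transporter families
KNOWN_TRANSPORTER_ACCESSIONS = frozenset(
    {"QPTR", "QueT", "QrtT", "PF02592", "IPR003744", "PF12822"}
)


def profile_weight(profile, weights=None):
    """Scoring weight of one genome's Q-pathway profile."""
    w = DEFAULT_WEIGHTS if weights is None else weights
    if profile.category == NON_USER:
        return w["non_user"]
    if profile.category in SALVAGE_REQUIRING:
        return w["salvager_gap"] if profile.transporter_gap else w["salvager"]
    return w["de_novo"]


@dataclass(frozen=True)
class CandidateScore:
    """Profile-weighted association score for one candidate family."""

    family_accession: str
    raw_score: float
    z_score: float
    selected: bool
    evidence: tuple            # ((category, count), ...) distinct neighbor proteins
    fused: bool
    passes_filters: bool
    median_distance: float
    clustering_ratio: float
    n_occurrences: int
    positive_control: bool = False
    exemplars: tuple = ()      # neighbor protein ids from salvage-requiring genomes
    exclusion_reason: str = ""


def score_candidates(stats, neigh, profiles, weights=None, fusions=(),
                     z_min=DEFAULT_Z_MIN):
    """Score every family with >= 1 neighborhood occurrence.

    raw_score sums, over the family's *distinct* neighbor proteins, the
    profile weight of the encoding genome (a protein seen from two signature
    genes counts once).  z-scores standardize raw scores across all scored
    families with the sample (n-1) standard deviation; with fewer than two
    families or zero variance every z is 0 and nothing is selected.
    ``selected`` requires z >= z_min AND the family's association filters.
    Output is sorted by z desc, raw desc, accession asc.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    profile_of = {p.genome_id: p for p in profiles}
    stats_of = {s.family_accession: s for s in stats}

    # distinct neighbor proteins per family, with their genome
    seen = {}
    for rec in neigh:
        if rec.genome_id not in profile_of:
            raise ValueError(
                f"neighborhood occurrence in genome {rec.genome_id!r} lacks a profile"
            )
        for acc in rec.neighbor_families:
            if acc in stats_of:
                seen.setdefault(acc, {})[rec.neighbor_protein_id] = rec.genome_id

    fused_accs = set()
    for f in fusions:
        fused_accs |= set(f.partner_domains)

    families = sorted(seen)
    raws = {}
    evidence = {}
    exemplars = {}
    for acc in families:
        total = 0.0
        counts = {}
        ex = []
        for pid, gid in sorted(seen[acc].items()):
            pr = profile_of[gid]
            total += profile_weight(pr, weights)
            counts[pr.category] = counts.get(pr.category, 0) + 1
            if pr.category in SALVAGE_REQUIRING:
                ex.append(pid)
        raws[acc] = total
        evidence[acc] = tuple(sorted(counts.items()))
        exemplars[acc] = tuple(ex[:5])

    values = np.array([raws[a] for a in families], dtype=float)
    if len(families) >= 2 and np.std(values, ddof=1) > 0:
        mean = values.mean()
        sd = values.std(ddof=1)
        zs = {a: float((raws[a] - mean) / sd) for a in families}
        degenerate = False
    else:
        zs = {a: 0.0 for a in families}
        degenerate = True

    out = []
    for acc in families:
        s = stats_of[acc]
        z = zs[acc]
        selected = (not degenerate) and z >= z_min and s.passes_filters
        out.append(
            CandidateScore(
                family_accession=acc,
                raw_score=raws[acc],
                z_score=z,
                selected=selected,
                evidence=evidence[acc],
                fused=acc in fused_accs,
                passes_filters=s.passes_filters,
                median_distance=s.median_distance,
                clustering_ratio=s.clustering_ratio,
                n_occurrences=len(seen[acc]),
                positive_control=acc in KNOWN_TRANSPORTER_ACCESSIONS,
                exemplars=exemplars[acc],
            )
        )
    out.sort(key=lambda c: (-c.z_score, -c.raw_score, c.family_accession))
    return out


def annotate_selection(scores, z_min=DEFAULT_Z_MIN,
                       known_accessions=KNOWN_TRANSPORTER_ACCESSIONS):
    """Re-evaluate selection for every score, recording exclusion reasons.

    Known transporter families are retained and flagged positive_control
    rather than removed — recovering them is the sanity check of the method.
    """
    from dataclasses import replace

    out = []
    for c in scores:
        reasons = []
        if c.z_score < z_min:
            reasons.append(f"z_score {c.z_score:.3g} < {z_min:g}")
        if not c.passes_filters:
            reasons.append(
                f"association filters failed (median_distance={c.median_distance:g}, "
                f"clustering_ratio={c.clustering_ratio:.4g})"
            )
        if reasons:
            c = replace(c, exclusion_reason="; ".join(reasons), selected=False)
        else:
            c = replace(c, selected=True, exclusion_reason="",
                        positive_control=c.family_accession in known_accessions)
        out.append(c)
    return out


def select_candidates(scores, z_min=DEFAULT_Z_MIN,
                      known_accessions=KNOWN_TRANSPORTER_ACCESSIONS):
    """Families with z >= z_min that also pass the association filters."""
    return [c for c in annotate_selection(scores, z_min, known_accessions) if c.selected]


@dataclass(frozen=True)
class ClusterEnrichment:
    """Candidate-family occurrence percentages within one SSN cluster."""

    cluster_id: int
    total_candidate_occurrences: int
    per_family_percentage: tuple   # ((accession, percentage), ...)


def cluster_enrichment(ssn, neigh, candidate_families):
    """Percentage of occurrence of each candidate family per SSN cluster.

    Occurrences are counted per (member neighbor protein, family) among the
    neighborhoods of the cluster's member proteins, so a neighbor seen from
    two signature genes counts once.  Percentages per cluster sum to 100
    when the total is positive; clusters without candidates report total 0.
    """
    candidate_families = frozenset(candidate_families)
    if not candidate_families:
        raise ValueError("candidate family set must be non-empty")
    by_signature = {}
    for rec in neigh:
        by_signature.setdefault(rec.signature_protein_id, []).append(rec)

    out = []
    for cid, node_ids in ssn.clusters:
        members = set()
        for nid in node_ids:
            members.update(ssn.nodes[nid].members)
        counted = set()
        counts = {}
        for m in sorted(members):
            for rec in by_signature.get(m, ()):
                for acc in rec.neighbor_families & candidate_families:
                    key = (rec.neighbor_protein_id, acc)
                    if key in counted:
                        continue
                    counted.add(key)
                    counts[acc] = counts.get(acc, 0) + 1
        total = sum(counts.values())
        percentages = tuple(
            (acc, 100.0 * counts[acc] / total) for acc in sorted(counts)
        ) if total else ()
        out.append(ClusterEnrichment(cid, total, percentages))
    return out


def build_report(scores, enrichments, fusions, profiles):
    """One-row-per-selected-family report frame, deterministically ordered.

    'dominates' counts clusters where the family's percentage is the cluster
    maximum, over clusters with any candidate occurrence.
    """
    clusters_with_candidates = [e for e in enrichments if e.total_candidate_occurrences]
    dominated = {}
    for e in clusters_with_candidates:
        if not e.per_family_percentage:
            continue
        best = max(p for _, p in e.per_family_percentage)
        for acc, p in e.per_family_percentage:
            if p == best:
                dominated[acc] = dominated.get(acc, 0) + 1
    n_clusters = len(clusters_with_candidates)

    rows = []
    rank = 0
    for c in scores:
        if not c.selected:
            continue
        rank += 1
        rows.append({
            "rank": rank,
            "family_accession": c.family_accession,
            "z_score": round(c.z_score, 6),
            "raw_score": round(c.raw_score, 6),
            "median_distance": c.median_distance,
            "clustering_ratio": round(c.clustering_ratio, 6),
            "n_occurrences": c.n_occurrences,
            "dominates": f"{dominated.get(c.family_accession, 0)}/{n_clusters}",
            "fused": int(c.fused),
            "positive_control": int(c.positive_control),
            "exemplars": ";".join(c.exemplars),
            "evidence": ";".join(f"{cat}={n}" for cat, n in c.evidence),
        })
    columns = [
        "rank", "family_accession", "z_score", "raw_score", "median_distance",
        "clustering_ratio", "n_occurrences", "dominates", "fused",
        "positive_control", "exemplars", "evidence",
    ]
    return pd.DataFrame(rows, columns=columns)


def scores_to_frame(scores):
    return pd.DataFrame([{
        "family_accession": c.family_accession,
        "raw_score": round(c.raw_score, 6),
        "z_score": round(c.z_score, 6),
        "selected": int(c.selected),
        "passes_filters": int(c.passes_filters),
        "median_distance": c.median_distance,
        "clustering_ratio": round(c.clustering_ratio, 6),
        "n_occurrences": c.n_occurrences,
        "fused": int(c.fused),
        "positive_control": int(c.positive_control),
        "exclusion_reason": c.exclusion_reason,
    } for c in scores])


def enrichment_to_frame(enrichments):
    """Cluster x family percentage matrix (long form)."""
    rows = []
    for e in enrichments:
        if not e.per_family_percentage:
            rows.append({"cluster_id": e.cluster_id, "family_accession": "",
                         "percentage": 0.0,
                         "total_candidate_occurrences": e.total_candidate_occurrences})
        for acc, p in e.per_family_percentage:
            rows.append({"cluster_id": e.cluster_id, "family_accession": acc,
                         "percentage": round(p, 4),
                         "total_candidate_occurrences": e.total_candidate_occurrences})
    return pd.DataFrame(
        rows, columns=["cluster_id", "family_accession", "percentage",
                       "total_candidate_occurrences"],
    )
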