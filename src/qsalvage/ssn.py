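"""Sequence similarity networks (SSNs) over alignment-score thresholds.

An SSN is a graph whose nodes are proteins (or representative nodes collapsing
near-identical proteins) and whose edges connect pairs with an alignment score
(AS = -log10 of the pairwise E-value) at or above a cutoff.  Connected
components at a cutoff approximate isofunctional subgroups.  The workflow
mirrors EFI-EST practice: start at a cutoff where edges correspond to > 40%
sequence identity, then raise the cutoff in small steps (default 5 AS units)
until every sizeable cluster is homogeneous in its node attribute of interest
(here: the Q-pathway profile category of the encoding genome).

All tie-breaking is deterministic (lexicographic ids, size-descending cluster
numbering) so repeated runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

DEFAULT_REP_IDENTITY = 90.0
DEFAULT_TARGET_IDENTITY = 40.0
DEFAULT_AS_STEP = 5.0
DEFAULT_MAJORITY = 0.9
MIN_CLUSTER_SIZE = 3


@dataclass
class SSNNode:
    """A representative node: one or more proteins sharing high identity."""

    node_id: str
    members: tuple
    attributes: dict = field(default_factory=dict)


@dataclass
class SSN:
    """A similarity network at a specific AS threshold, with its clusters."""

    nodes: dict            # node_id -> SSNNode
    edges: list            # (node_a, node_b, AS) with node_a < node_b, AS >= threshold
    threshold: float
    clusters: list         # [(cluster_id, (node_id, ...)), ...] — size desc

    @classmethod
    def from_parts(cls, nodes, edges, threshold):
        edges = _canonical_edges(edges, threshold)
        return cls(
            nodes=nodes, edges=edges, threshold=float(threshold),
            clusters=_components(nodes, edges),
        )

    def recompute_clusters(self):
        """Connected-component partition at the stated threshold (invariant check)."""
        return _components(self.nodes, self.edges)

    def cluster_of(self):
        """node_id -> cluster_id map."""
        return {nid: cid for cid, members in self.clusters for nid in members}


def _canonical_edges(edges, threshold):
    best = {}
    for a, b, as_ in edges:
        if a == b:
            raise ValueError(f"self-edge on node {a}")
        k = (a, b) if a < b else (b, a)
        if as_ >= threshold and (k not in best or as_ > best[k]):
            best[k] = float(as_)
    return sorted((a, b, s) for (a, b), s in best.items())


def _components(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((a, b) for a, b, _ in edges)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [(i + 1, c) for i, c in enumerate(comps)]


@dataclass(frozen=True)
class ClusterHomogeneity:
    cluster_id: int
    size: int
    modal_label: str
    majority_fraction: float


@dataclass(frozen=True)
class HomogeneityReport:
    clusters: tuple
    min_majority_fraction: float   # over clusters of size >= min_cluster_size
    min_cluster_size: int
    homogeneous: bool


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def collapse_representatives(pairs, proteins, identity_cutoff=DEFAULT_REP_IDENTITY,
                             attributes=None):
    """Group proteins sharing > identity_cutoff % identity into rep nodes.

    Single-linkage: any chain of pairs above the cutoff merges (A-B at 95%,
    B-C at 92% -> one node {A,B,C}).  The boundary is strict, matching the
    "share > 90% identity" convention of representative-node SSNs.  The
    representative is the longest member, ties broken by lexicographically
    smallest id.  ``attributes`` optionally maps protein_id -> dict; node
    attributes take the union, with the modal profile category recorded.
    """
    if not 0 < identity_cutoff <= 100:
        raise ValueError("identity_cutoff must be in (0, 100]")
    length_of = {p.protein_id: p.length_aa for p in proteins}
    for p in pairs:
        for pid in (p.protein_a, p.protein_b):
            if pid not in length_of:
                raise ValueError(f"pair references unknown protein {pid}")

    g = nx.Graph()
    g.add_nodes_from(length_of)
    for p in pairs:
        if p.percent_identity > identity_cutoff:
            g.add_edge(p.protein_a, p.protein_b)

    nodes = {}
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda pid: (-length_of[pid], pid))
        attrs = {}
        if attributes:
            cats = []
            for m in members:
                a = attributes.get(m, {})
                for k, v in a.items():
                    if k == "profile_category":
                        cats.append(v)
                    elif isinstance(v, (set, frozenset)):
                        attrs[k] = frozenset(attrs.get(k, frozenset())) | v
                    else:
                        attrs.setdefault(k, v)
            if cats:
                attrs["profile_category"] = _mode(cats)
        nodes[rep] = SSNNode(node_id=rep, members=members, attributes=attrs)
    return nodes


def _mode(labels):
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return min(counts, key=lambda lab: (-counts[lab], lab))


def initial_threshold(pairs, target_identity=DEFAULT_TARGET_IDENTITY):
    """AS cutoff whose edges correspond to sequence identity above the target.

    Returns the median AS over pairs with identity within +-1 point of the
    target; if that band is empty, the band widens to +-2; if no pair lies
    within +-2 points, falls back to the minimum AS observed (every edge then
    already exceeds the target identity, or the data has no useful band).
    """
    if not pairs:
        raise ValueError("cannot derive a threshold from an empty pair list")
    import numpy as np

    for half_band in (1.0, 2.0):
        band = [p.alignment_score for p in pairs
                if abs(p.percent_identity - target_identity) <= half_band]
        if band:
            return float(np.median(band))
    return float(min(p.alignment_score for p in pairs))


def build_network(nodes, pairs, threshold):
    """Assemble the SSN at an AS threshold (edge kept iff AS >= threshold).

    Node-level AS between two representative nodes is the max over member-pair
    AS — the most permissive lift, keeping clusters as connected as the
    underlying proteins are.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    node_of = {}
    for nid, node in nodes.items():
        for m in node.members:
            node_of[m] = nid
    edges = []
    for p in pairs:
        na, nb = node_of.get(p.protein_a), node_of.get(p.protein_b)
        if na is None or nb is None:
            raise ValueError(
                f"pair {p.protein_a}-{p.protein_b} references a protein outside the node map"
            )
        if na == nb:
            continue
        edges.append((na, nb, p.alignment_score))
    return SSN.from_parts(nodes, edges, threshold)


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def homogeneity_report(ssn, attribute, majority=DEFAULT_MAJORITY,
                       min_cluster_size=MIN_CLUSTER_SIZE):
    """Per-cluster modal-label fractions; singletons are homogeneous by definition."""
    entries = []
    fractions = []
    for cid, members in ssn.clusters:
        labels = [str(ssn.nodes[m].attributes.get(attribute, "")) for m in members]
        modal = _mode(labels)
        frac = labels.count(modal) / len(labels)
        entries.append(ClusterHomogeneity(cid, len(members), modal, frac))
        if len(members) >= min_cluster_size:
            fractions.append(frac)
    min_frac = min(fractions) if fractions else 1.0
    return HomogeneityReport(
        clusters=tuple(entries),
        min_majority_fraction=min_frac,
        min_cluster_size=min_cluster_size,
        homogeneous=min_frac >= majority,
    )


def refine_until_homogeneous(ssn, attribute, step=DEFAULT_AS_STEP,
                             majority=DEFAULT_MAJORITY, max_threshold=None,
                             min_cluster_size=MIN_CLUSTER_SIZE):
    """Raise the AS threshold stepwise until clusters are attribute-homogeneous.

    Stops when every cluster of size >= min_cluster_size has a modal-label
    fraction >= ``majority``, or once the threshold reaches ``max_threshold``
    (default: one step past the maximum edge AS, at which every edge drops and
    all nodes are singletons — guaranteed homogeneous, hence guaranteed
    termination).  Returns the refined network, its homogeneity report, and
    the list of thresholds visited.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if max_threshold is None:
        max_as = max((as_ for _, _, as_ in ssn.edges), default=ssn.threshold)
        max_threshold = max_as + step
    visited = [ssn.threshold]
    current = ssn
    report = homogeneity_report(current, attribute, majority, min_cluster_size)
    while not report.homogeneous and current.threshold < max_threshold:
        new_t = current.threshold + step
        current = SSN.from_parts(current.nodes, current.edges, new_t)
        visited.append(new_t)
        report = homogeneity_report(current, attribute, majority, min_cluster_size)
    return current, report, visited


# ---------------------------------------------------------------------------
# overlay
# ---------------------------------------------------------------------------

def cluster_profile_overlay(ssn, profiles, assoc, fusions, candidate_families,
                            color_distance=3):
    """Annotate nodes with profile category and candidate-neighbor fill.

    A node is *filled* iff a member protein has a candidate-family neighbor at
    gene distance <= color_distance, or a member protein is itself a fusion
    call.  The border label is the genome's profile category; genomes without
    bTGT are labeled gray.  Every member's genome must have a profile.
    """
    profile_of = {p.genome_id: p for p in profiles}
    fusion_proteins = {f.protein_id for f in fusions}
    candidate_families = frozenset(candidate_families)

    near = {}
    for rec in assoc:
        if rec.gene_distance <= color_distance and rec.neighbor_families & candidate_families:
            near.setdefault(rec.signature_protein_id, set()).update(
                rec.neighbor_families & candidate_families
            )

    # member -> genome lookup comes from the neighborhood/fusion records plus
    # node attributes; nodes carry genome_id per member in attributes when built
    member_genome = {}
    for rec in assoc:
        member_genome[rec.signature_protein_id] = rec.genome_id
    for f in fusions:
        member_genome[f.protein_id] = f.genome_id

    annotated = {}
    for nid, node in ssn.nodes.items():
        filled_fams = set()
        fused = False
        categories = []
        for m in node.members:
            filled_fams |= near.get(m, set())
            if m in fusion_proteins:
                fused = True
            g = node.attributes.get("genome_id") or member_genome.get(m)
            if g is None:
                g = node.attributes.get("member_genomes", {}).get(m)
            if g is not None:
                if g not in profile_of:
                    raise ValueError(f"no profile for genome {g!r} (node {nid})")
                categories.append(profile_of[g])
        if not categories:
            raise ValueError(f"node {nid}: cannot resolve any member genome to a profile")
        cat_labels = [p.category for p in categories]
        modal_cat = _mode(cat_labels)
        has_tgt = any(p.has_tgt for p in categories)
        attrs = dict(node.attributes)
        attrs.update({
            "profile_category": modal_cat,
            "border": "gray" if not has_tgt else modal_cat,
            "has_tgt": has_tgt,
            "candidate_families": frozenset(filled_fams),
            "filled": bool(filled_fams) or fused,
            "fused": fused,
        })
        annotated[nid] = SSNNode(node_id=nid, members=node.members, attributes=attrs)
    return replace(ssn, nodes=annotated)
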