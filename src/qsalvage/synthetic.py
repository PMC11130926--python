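"""Synthetic pangenome generator with machine-readable ground truth.

Emulates the statistical structure of a host-associated pangenome screened
for Q-precursor transporters: genomes drawn from a mixture of Q-pathway
profile categories, marker genes placed on contigs with homology hits that
pass (present) or fail (absent) the calling thresholds, a "true" transporter
family planted within a small gene distance of the salvage signature gene
preferentially in salvage-requiring genomes, uniformly placed decoy families,
optional transporter–bTGT fusion proteins, and two-component pairwise
similarity scores that let SSN refinement separate profile groups.

It deliberately does NOT simulate sequences, phylogenetic correlation between
genomes, or uneven family sizes — see docs/methods.md for what that implies
about the tests built on it.

Everything is drawn from a single numpy Generator keyed by the config seed,
in a fixed order, so identical configs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as qio
from .association import extract_neighborhoods, family_stats
from .profiler import (
    DE_NOVO_PREQ1_TERMINAL, DE_NOVO_Q, NON_USER, PREQ_SALVAGER,
    Q_SALVAGER_DIRECT, Q_SALVAGER_INDIRECT, SALVAGE_REQUIRING,
    MarkerSet, call_presence, profile_table,
)
from .records import HitRecord, PairScore, ProteinRecord

#: default profile mixture — 40% salvage-requiring, the condition the
#: discovery method targets; remainder split between synthesizers and
#: non-users as seen in host-associated communities
DEFAULT_PROFILE_MIX = (
    (DE_NOVO_Q, 0.35),
    (NON_USER, 0.15),
    (DE_NOVO_PREQ1_TERMINAL, 0.10),
    (PREQ_SALVAGER, 0.15),
    (Q_SALVAGER_DIRECT, 0.15),
    (Q_SALVAGER_INDIRECT, 0.10),
)

PLANTED_FAMILY = "PF_planted_synthetic"
FUSION_PARTNER = PLANTED_FAMILY


@dataclass(frozen=True)
class ScoreModel:
    """Two-component (within/between profile group) identity and AS model."""

    within_identity_mean: float = 75.0
    within_identity_sd: float = 12.0
    between_identity_mean: float = 32.0
    between_identity_sd: float = 6.0
    within_as_mean: float = 120.0
    within_as_sd: float = 15.0
    between_as_mean: float = 25.0
    between_as_sd: float = 10.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_genomes: int = 200
    genes_per_genome: int = 60
    profile_mix: tuple = DEFAULT_PROFILE_MIX
    planted_family: str = PLANTED_FAMILY
    p_plant: float = 0.8
    max_plant_distance: int = 2
    n_decoy_families: int = 20
    decoy_rate: float = 0.3          # per-genome uniform placement probability
    fusion_rate: float = 0.05
    fusion_partner: str = FUSION_PARTNER
    known_transporter_rate: float = 0.3
    hydrolase_rate: float = 0.7
    absent_hit_rate: float = 0.3     # failing hit emitted for an absent marker
    circular: bool = False
    window: int = 10
    seed: int = 0
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self):
        total = sum(p for _, p in self.profile_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile_mix proportions sum to {total}, not 1")
        if not 0.0 <= self.p_plant <= 1.0:
            raise ValueError("p_plant must be in [0, 1]")
        if self.genes_per_genome < 2 * self.max_plant_distance + 1:
            raise ValueError(
                "infeasible config: genes_per_genome must be >= "
                "2 * max_plant_distance + 1"
            )
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


@dataclass
class TruthFile:
    """Ground truth of one generated pangenome, cross-checkable with outputs."""

    planted_family: str
    decoy_families: tuple
    genomes: dict    # genome_id -> {category, presence, signature_protein,
                     #               planted (pid, distance) | None,
                     #               decoys {family: pid}, fusion pid | None}

    def to_json(self, path):
        payload = {
            "planted_family": self.planted_family,
            "decoy_families": list(self.decoy_families),
            "genomes": self.genomes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_family=payload["planted_family"],
            decoy_families=tuple(payload["decoy_families"]),
            genomes=payload["genomes"],
        )


@dataclass
class Pangenome:
    """In-memory bundle of everything one generation run produced."""

    records: list
    domains: list     # (protein_id, accession, start_aa, end_aa)
    hits: list
    pairs: list
    truth: TruthFile
    config: SyntheticConfig

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qio.write_gene_table(self.records, outdir / "gene_table.tsv")
        qio.write_domain_table(self.domains, outdir / "domains.tsv")
        qio.write_hit_table(self.hits, outdir / "hits.tsv")
        qio.write_pair_table(self.pairs, outdir / "pairs.tsv")
        self.truth.to_json(outdir / "truth.json")


def _presence_for_category(category, rng, cfg, markers):
    """Marker presence vector satisfying the category's rule definition exactly."""
    p = {m: False for m in markers.all_markers()}

    def maybe(m, prob):
        if rng.random() < prob:
            p[m] = True

    if category == NON_USER:
        # a fifth of non-users carry stray synthesis genes but no bTGT
        if rng.random() < 0.2:
            p["QueD"] = p["QueE"] = True
        return p

    p["bTGT"] = True
    if category in (DE_NOVO_Q, DE_NOVO_PREQ1_TERMINAL):
        p["QueD"] = p["QueE"] = p["QueC"] = p["QueF"] = True
        if category == DE_NOVO_Q:
            p["QueA"] = True
            p["QueG" if rng.random() < 0.5 else "QueH"] = True
            maybe("QueL", 0.1)
        else:
            # preQ1-terminal: finishing incomplete (no QueA)
            maybe("QueG", 0.3)
    elif category == PREQ_SALVAGER:
        p["QueA"] = True
        p["QueG" if rng.random() < 0.5 else "QueH"] = True
        maybe("QueF", 0.5)
    elif category == Q_SALVAGER_INDIRECT:
        p["QueA"] = True
        p["QueG" if rng.random() < 0.5 else "QueH"] = True
        p["QueL"] = True
        maybe("QueF", 0.5)
        maybe("Qng1" if rng.random() < 0.5 else "QueK", 0.5)
    elif category == Q_SALVAGER_DIRECT:
        maybe("Qng1" if rng.random() < 0.5 else "QueK", cfg.hydrolase_rate)
    else:
        raise ValueError(f"unknown category {category!r}")

    if category != NON_USER and rng.random() < cfg.known_transporter_rate:
        t = ("QPTR", "QueT", "QrtT")[int(rng.integers(0, 3))]
        p[t] = True
    return p


def generate_pangenome(config=None, markers=None, with_pairs=True):
    """Generate one synthetic pangenome with its truth file.

    ``with_pairs=False`` skips the all-vs-all pair-score table (drawn last
    from the random stream, so everything else is identical either way) for
    callers that only exercise the profiling/association path.
    """
    cfg = config or SyntheticConfig()
    markers = markers or MarkerSet()
    rng = np.random.default_rng(cfg.seed)

    categories = [c for c, _ in cfg.profile_mix]
    probs = np.array([p for _, p in cfg.profile_mix])
    cum = np.cumsum(probs)

    decoys = tuple(f"PF_decoy_{k:02d}" for k in range(cfg.n_decoy_families))
    L = cfg.genes_per_genome

    records, domain_rows, hits = [], [], []
    truth_genomes = {}
    tgt_proteins = []   # (protein_id, category) for pair-score generation

    for i in range(cfg.n_genomes):
        gid = f"G{i:04d}"
        contig = f"{gid}_c1"
        u = rng.random()
        category = categories[int(np.searchsorted(cum, u, side="right"))]
        presence = _presence_for_category(category, rng, cfg, markers)

        lengths = rng.integers(100, 600, size=L)
        strands = rng.integers(0, 2, size=L)
        fams = [set() for _ in range(L)]

        present = [m for m in markers.all_markers() if presence[m]]
        sig_slot = None
        marker_slot = {}
        if presence["bTGT"]:
            sig_slot = int(rng.integers(0, L))
            marker_slot["bTGT"] = sig_slot
        others = [m for m in present if m != "bTGT"]
        if others:
            free = [s for s in range(L) if s != sig_slot]
            chosen = rng.choice(len(free), size=len(others), replace=False)
            for m, ci in zip(others, chosen):
                marker_slot[m] = free[int(ci)]
        for m, s in marker_slot.items():
            acc = markers.accessions_for(m)[0]
            fams[s].add(acc)
            domain_rows.append((f"{gid}_p{s:03d}", acc, 1, int(min(150, lengths[s]))))

        # --- planted transporter family -----------------------------------
        planted = None
        plant_here = (
            category in SALVAGE_REQUIRING
            and sig_slot is not None
            and rng.random() < cfg.p_plant
        )
        if plant_here:
            d = int(rng.integers(1, cfg.max_plant_distance + 1))
            side = 1 if rng.random() < 0.5 else -1
            pos = sig_slot + side * d
            if not 0 <= pos < L:
                pos = sig_slot - side * d
            fams[pos].add(cfg.planted_family)
            planted = (f"{gid}_p{pos:03d}", d)
        elif rng.random() < cfg.decoy_rate:
            pos = int(rng.integers(0, L))
            if pos != sig_slot:
                fams[pos].add(cfg.planted_family)
                planted = (f"{gid}_p{pos:03d}", None)

        # --- decoy families ------------------------------------------------
        decoy_placement = {}
        for fam in decoys:
            if rng.random() < cfg.decoy_rate:
                pos = int(rng.integers(0, L))
                fams[pos].add(fam)
                decoy_placement[fam] = f"{gid}_p{pos:03d}"

        # --- fusion protein -------------------------------------------------
        fusion_pid = None
        if presence["bTGT"] and rng.random() < cfg.fusion_rate:
            pos = int(rng.integers(0, L))
            if pos == sig_slot:
                pos = (pos + 1) % L
            flen = int(rng.integers(500, 2001))
            lengths[pos] = flen
            tgt_acc = markers.accessions_for("bTGT")[0]
            fams[pos] |= {tgt_acc, cfg.fusion_partner}
            fusion_pid = f"{gid}_p{pos:03d}"
            domain_rows.append((fusion_pid, tgt_acc, 1, 340))
            domain_rows.append((fusion_pid, cfg.fusion_partner, 370, flen - 10))

        # --- protein records ------------------------------------------------
        for s in range(L):
            pid = f"{gid}_p{s:03d}"
            records.append(
                ProteinRecord(
                    protein_id=pid, genome_id=gid, contig_id=contig,
                    gene_index=s, strand="+" if strands[s] else "-",
                    length_aa=int(lengths[s]), families=frozenset(fams[s]),
                )
            )
            if s == sig_slot or pid == fusion_pid:
                tgt_proteins.append((pid, category))

        # --- homology hits --------------------------------------------------
        for m in markers.all_markers():
            if presence[m]:
                slot = marker_slot[m]
                hits.append(HitRecord(
                    marker_id=m,
                    subject_protein_id=f"{gid}|{gid}_p{slot:03d}",
                    genome_id=gid,
                    percent_identity=float(np.round(rng.uniform(30, 90), 2)),
                    e_value=float(10.0 ** -rng.uniform(15, 180)),
                    bitscore=float(np.round(rng.uniform(50, 500), 1)),
                ))
            elif rng.random() < cfg.absent_hit_rate:
                slot = int(rng.integers(0, L))
                if rng.random() < 0.5:
                    pident, lexp = rng.uniform(5, 19.5), rng.uniform(15, 120)
                else:
                    pident, lexp = rng.uniform(30, 90), rng.uniform(0.0, 9.0)
                hits.append(HitRecord(
                    marker_id=m,
                    subject_protein_id=f"{gid}|{gid}_p{slot:03d}",
                    genome_id=gid,
                    percent_identity=float(np.round(pident, 2)),
                    e_value=float(10.0 ** -lexp),
                    bitscore=float(np.round(rng.uniform(10, 60), 1)),
                ))

        truth_genomes[gid] = {
            "category": category,
            "presence": {m: bool(v) for m, v in presence.items()},
            "signature_protein": (
                f"{gid}_p{sig_slot:03d}" if sig_slot is not None else None
            ),
            "planted": list(planted) if planted else None,
            "planted_near_signature": bool(plant_here),
            "decoys": decoy_placement,
            "fusion": fusion_pid,
        }

    pairs = _draw_pair_scores(tgt_proteins, cfg.score_model, rng) if with_pairs else []

    # re-attach domains so records carry them (families already include them)
    by_protein = {}
    for pid, acc, s, e in domain_rows:
        by_protein.setdefault(pid, []).append((acc, s, e))
    for idx, r in enumerate(records):
        doms = by_protein.get(r.protein_id)
        if doms:
            records[idx] = ProteinRecord(
                r.protein_id, r.genome_id, r.contig_id, r.gene_index,
                r.strand, r.length_aa, r.families, tuple(sorted(doms)),
            )

    truth = TruthFile(
        planted_family=cfg.planted_family, decoy_families=decoys,
        genomes=truth_genomes,
    )
    return Pangenome(records=records, domains=domain_rows, hits=hits,
                     pairs=pairs, truth=truth, config=cfg)


def _draw_pair_scores(tgt_proteins, model, rng):
    """All-vs-all scores among signature proteins, two-component by category."""
    n = len(tgt_proteins)
    if n < 2:
        return []
    ids = [pid for pid, _ in tgt_proteins]
    cats = np.array([c for _, c in tgt_proteins])
    ia, ib = np.triu_indices(n, k=1)
    same = cats[ia] == cats[ib]
    m = len(ia)
    ident = np.where(
        same,
        rng.normal(model.within_identity_mean, model.within_identity_sd, m),
        rng.normal(model.between_identity_mean, model.between_identity_sd, m),
    )
    as_ = np.where(
        same,
        rng.normal(model.within_as_mean, model.within_as_sd, m),
        rng.normal(model.between_as_mean, model.between_as_sd, m),
    )
    ident = np.clip(np.round(ident, 2), 1.0, 99.9)
    as_ = np.round(np.maximum(as_, 0.0), 2)
    return [
        PairScore(ids[int(a)], ids[int(b)], float(pi), float(s))
        for a, b, pi, s in zip(ia, ib, ident, as_)
    ]


# ---------------------------------------------------------------------------
# truth verification
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    n_genomes: int
    n_mismatches: int
    mismatched_genomes: tuple
    n_planted_near_signature: int
    planted_median_distance: float
    planted_clustering_ratio: float

    @property
    def ok(self):
        return self.n_mismatches == 0


def verify_truth(pangenome, truth=None, markers=None):
    """Re-derive profiles from the emitted hit table and check them against truth.

    Closes the loop between the generator and the classifier: the presence
    matrix called from the hits must reproduce each genome's assigned category
    exactly.  Also reports the planted family's empirical neighborhood
    statistics (median gene distance and clustering ratio).
    """
    truth = truth or pangenome.truth
    markers = markers or MarkerSet()
    genomes = sorted({r.genome_id for r in pangenome.records})
    matrix = call_presence(pangenome.hits, genomes, markers)
    profiles = profile_table(matrix, markers)
    mismatched = tuple(
        p.genome_id for p in profiles
        if p.category != truth.genomes[p.genome_id]["category"]
    )

    sig_accs = {m: markers.accessions_for(m) for m in markers.signature_markers}
    neigh = extract_neighborhoods(pangenome.records, sig_accs,
                                  window=pangenome.config.window)
    sizes = family_sizes_from_records(pangenome.records)
    planted = pangenome.config.planted_family
    stats = family_stats(neigh, sizes) if neigh else []
    planted_stats = next(
        (s for s in stats if s.family_accession == planted), None
    )
    return ConsistencyReport(
        n_genomes=len(genomes),
        n_mismatches=len(mismatched),
        mismatched_genomes=mismatched,
        n_planted_near_signature=sum(
            1 for g in truth.genomes.values() if g["planted_near_signature"]
        ),
        planted_median_distance=(
            planted_stats.median_distance if planted_stats else float("nan")
        ),
        planted_clustering_ratio=(
            planted_stats.clustering_ratio if planted_stats else 0.0
        ),
    )


def planted_recovery_trial(config=None, markers=None, weights=None, z_min=1.0):
    """Run the profiling->association->scoring path once, in memory.

    Returns the planted family's rank (1-based among scored families, 0 if it
    never occurs in a neighborhood), its z-score, and whether it was selected
    (z >= z_min and association filters passed).  This is the unit of the
    planted-signal recovery and null-control experiments.
    """
    from .scoring import score_candidates

    cfg = config or SyntheticConfig()
    markers = markers or MarkerSet()
    pg = generate_pangenome(cfg, markers, with_pairs=False)
    genomes = sorted({r.genome_id for r in pg.records})
    matrix = call_presence(pg.hits, genomes, markers)
    profiles = profile_table(matrix, markers)
    sig_accs = {m: markers.accessions_for(m) for m in markers.signature_markers}
    neigh = extract_neighborhoods(pg.records, sig_accs, window=cfg.window)
    stats = family_stats(neigh, family_sizes_from_records(pg.records))
    scores = score_candidates(stats, neigh, profiles, weights, z_min=z_min)
    for rank, c in enumerate(scores, start=1):
        if c.family_accession == cfg.planted_family:
            return {"rank": rank, "z_score": c.z_score, "selected": c.selected,
                    "n_families_scored": len(scores)}
    return {"rank": 0, "z_score": float("nan"), "selected": False,
            "n_families_scored": len(scores)}


def family_sizes_from_records(records):
    """Family size = number of proteins in the dataset carrying the accession."""
    sizes = {}
    for r in records:
        for acc in r.families:
            sizes[acc] = sizes.get(acc, 0) + 1
    return sizes
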