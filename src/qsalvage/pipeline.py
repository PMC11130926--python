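"""Stage orchestration: one config, plain-TSV artifacts, deterministic runs.

Every stage reads its inputs from, and writes its outputs to, the run's
output directory as headered TSV/JSON — no binary intermediates — so any
stage can be inspected, rerun, or substituted.  The exact config that
produced a directory is serialized into it (``config_used.yaml``).  With a
fixed seed and config, rerunning any stage is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as qio
from .association import (
    FamilyAssociationStats, NeighborhoodRecord, detect_fusions,
    extract_neighborhoods, family_stats, fusions_to_frame,
    neighborhoods_to_frame, stats_to_frame, FusionCall,
)
from .profiler import (
    MarkerSet, QPathwayProfile, call_presence, profile_table,
    profiles_to_frame, PREDICTION_CAVEAT,
)
from .scoring import (
    DEFAULT_WEIGHTS, KNOWN_TRANSPORTER_ACCESSIONS, annotate_selection,
    build_report, cluster_enrichment, enrichment_to_frame, score_candidates,
    scores_to_frame,
)
from .ssn import (
    build_network, cluster_profile_overlay, collapse_representatives,
    initial_threshold, refine_until_homogeneous,
)
from .synthetic import (
    ScoreModel, SyntheticConfig, generate_pangenome, family_sizes_from_records,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "associate", "fuse", "ssn", "score", "report", "all")

#: stage -> (required artifacts, producing stage)
_REQUIRES = {
    "profile": (("gene_table.tsv", "hits.tsv"), "simulate"),
    "associate": (("gene_table.tsv",), "simulate"),
    "fuse": (("gene_table.tsv", "domains.tsv"), "simulate"),
    "ssn": (("pairs.tsv", "gene_table.tsv"), "simulate"),
    "score": (("family_stats.tsv", "neighborhoods.tsv"), "associate"),
    "report": (("candidate_scores.tsv",), "score"),
}
_REQUIRES_EXTRA = {
    "ssn": ((("profiles.tsv",), "profile"),
            (("family_stats.tsv", "neighborhoods.tsv"), "associate"),
            (("fusions.tsv",), "fuse")),
    "score": ((("profiles.tsv",), "profile"), (("fusions.tsv",), "fuse")),
    "report": ((("ssn_edgelist.tsv",), "ssn"),
               (("neighborhoods.tsv", "family_stats.tsv"), "associate"),
               (("profiles.tsv",), "profile"), (("fusions.tsv",), "fuse")),
}


@dataclass
class PipelineConfig:
    """All knobs of a run; every numeric default is the pipeline's standard."""

    outdir: str = "qsalvage_run"
    seed: int = 0
    min_identity: float = 20.0
    max_evalue: float = 1e-10
    window: int = 10
    color_distance: int = 3
    max_median_distance: float = 2.0
    min_clustering_ratio: float = 0.002
    rep_identity: float = 90.0
    collapse_nodes: bool = True
    target_identity: float = 40.0
    as_step: float = 5.0
    majority: float = 0.9
    z_min: float = 1.0
    fusion_min_len: int = 500
    fusion_max_len: int = 2000
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    transporter_accessions: tuple = ()
    marker_accessions: tuple = ()     # ((marker, (acc, ...)), ...)
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        checks = [
            (0 < self.min_identity <= 100, "min_identity in (0, 100]"),
            (self.max_evalue > 0, "max_evalue > 0"),
            (self.window >= 1, "window >= 1"),
            (self.color_distance >= 1, "color_distance >= 1"),
            (self.max_median_distance >= 1, "max_median_distance >= 1"),
            (0 <= self.min_clustering_ratio < 1, "min_clustering_ratio in [0, 1)"),
            (0 < self.rep_identity <= 100, "rep_identity in (0, 100]"),
            (0 < self.target_identity <= 100, "target_identity in (0, 100]"),
            (self.as_step > 0, "as_step > 0"),
            (0 < self.majority <= 1, "majority in (0, 1]"),
            (0 < self.fusion_min_len <= self.fusion_max_len,
             "0 < fusion_min_len <= fusion_max_len"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: expected {msg}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["transporter_accessions"] = list(self.transporter_accessions)
        d["marker_accessions"] = [
            [m, list(a)] for m, a in self.marker_accessions
        ]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "transporter_accessions" in d:
            d["transporter_accessions"] = tuple(d["transporter_accessions"])
        if "marker_accessions" in d:
            d["marker_accessions"] = tuple(
                (m, tuple(a)) for m, a in d["marker_accessions"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path):
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    # -- derived helpers ----------------------------------------------------

    def marker_set(self):
        return MarkerSet(accessions=self.marker_accessions)

    def synthetic_config(self):
        kw = dict(self.synthetic)
        if "score_model" in kw:
            kw["score_model"] = ScoreModel(**kw["score_model"])
        if "profile_mix" in kw:
            kw["profile_mix"] = tuple((c, float(p)) for c, p in kw["profile_mix"])
        kw.setdefault("seed", self.seed)
        kw.setdefault("window", self.window)
        return SyntheticConfig(**kw)

    def fusion_transporter_accessions(self):
        if self.transporter_accessions:
            return set(self.transporter_accessions)
        accs = set(KNOWN_TRANSPORTER_ACCESSIONS)
        accs.add(self.synthetic_config().planted_family)
        accs.add(self.synthetic_config().fusion_partner)
        return accs


class MissingArtifactError(RuntimeError):
    pass


def _require(outdir, stage):
    needed = []
    if stage in _REQUIRES:
        needed.append(_REQUIRES[stage])
    needed.extend(_REQUIRES_EXTRA.get(stage, ()))
    for files, producer in needed:
        for f in files:
            if not (outdir / f).exists():
                raise MissingArtifactError(
                    f"stage '{stage}' needs {f}; run '{producer}' first"
                )


def _config_hash(config):
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _write_frame(df, path):
    qio._atomic_write_text(path, df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# rehydration of stage artifacts
# ---------------------------------------------------------------------------

def _read_profiles(path):
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(QPathwayProfile(
            genome_id=row.genome_id,
            has_tgt=bool(row.has_tgt),
            makes_preQ1=bool(row.makes_preQ1),
            finishes_Q=bool(row.finishes_Q),
            has_queF=bool(row.has_queF),
            has_queL=bool(row.has_queL),
            has_hydrolase=bool(row.has_hydrolase),
            has_known_transporter=bool(row.has_known_transporter),
            category=row.category,
            transporter_gap=bool(row.transporter_gap),
            salvage_substrates=frozenset(
                s for s in str(row.salvage_substrates).split(";") if s
            ),
            partial_synthesis=bool(row.partial_synthesis),
            caveat=PREDICTION_CAVEAT,
        ))
    return out


def _read_neighborhoods(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        NeighborhoodRecord(
            signature_protein_id=row.signature_protein_id,
            signature_marker=row.signature_marker,
            neighbor_protein_id=row.neighbor_protein_id,
            neighbor_families=frozenset(
                f for f in str(row.neighbor_families).split(";") if f
            ),
            gene_distance=int(row.gene_distance),
            genome_id=str(row.genome_id),
            neighbor_is_signature=bool(row.neighbor_is_signature),
        )
        for row in df.itertuples(index=False)
    ]


def _read_stats(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        FamilyAssociationStats(
            family_accession=row.family_accession,
            n_neighbor_occurrences=int(row.n_neighbor_occurrences),
            n_genomes=int(row.n_genomes),
            median_distance=float(row.median_distance),
            family_total_members=int(row.family_total_members),
            clustering_ratio=float(row.clustering_ratio),
            passes_filters=bool(row.passes_filters),
        )
        for row in df.itertuples(index=False)
    ]


def _read_fusions(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        FusionCall(
            protein_id=row.protein_id,
            genome_id=str(row.genome_id),
            length_aa=int(row.length_aa),
            signature_domain=row.signature_domain,
            partner_domains=frozenset(
                f for f in str(row.partner_domains).split(";") if f
            ),
            domain_order=tuple(str(row.domain_order).split(";")),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_stage(stage, config):
    """Run one pipeline stage (or ``all``); returns the output directory.

    Raises MissingArtifactError (naming the stage to run first) when an
    upstream artifact is absent, ValueError on validation failures.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # provenance copy; outdir normalized so identical runs in different
    # locations produce byte-identical artifact directories
    provenance = config.to_dict()
    provenance["outdir"] = "."
    qio._atomic_write_text(
        outdir / "config_used.yaml",
        yaml.safe_dump(provenance, sort_keys=True, default_flow_style=False),
    )
    logger.info("stage=%s config_hash=%s outdir=%s",
                stage, _config_hash(config), outdir)

    if stage == "all":
        for s in ("simulate", "profile", "associate", "fuse", "ssn", "score", "report"):
            run_stage(s, config)
        return outdir

    _require(outdir, stage)
    markers = config.marker_set()

    if stage == "simulate":
        pg = generate_pangenome(config.synthetic_config(), markers)
        pg.write(outdir)
        logger.info("simulate: %d genomes, %d proteins, %d hits, %d pairs",
                    len(pg.truth.genomes), len(pg.records), len(pg.hits),
                    len(pg.pairs))

    elif stage == "profile":
        records = qio.read_gene_table(outdir / "gene_table.tsv")
        hits = qio.read_hit_table(outdir / "hits.tsv")
        genomes = sorted({r.genome_id for r in records})
        matrix = call_presence(hits, genomes, markers,
                               config.min_identity, config.max_evalue)
        matrix.to_tsv(outdir / "presence_matrix.tsv")
        profiles = profile_table(matrix, markers)
        _write_frame(profiles_to_frame(profiles), outdir / "profiles.tsv")

    elif stage == "associate":
        records = _records_with_domains(outdir)
        sig_accs = {m: markers.accessions_for(m) for m in markers.signature_markers}
        neigh = extract_neighborhoods(records, sig_accs, config.window)
        _write_frame(neighborhoods_to_frame(neigh), outdir / "neighborhoods.tsv")
        sizes = family_sizes_from_records(records)
        stats = family_stats(neigh, sizes, config.max_median_distance,
                             config.min_clustering_ratio)
        _write_frame(stats_to_frame(stats), outdir / "family_stats.tsv")
        logger.info("associate: %d neighborhood records, %d families, %d pass filters",
                    len(neigh), len(stats), sum(s.passes_filters for s in stats))

    elif stage == "fuse":
        records = _records_with_domains(outdir)
        sig = set(markers.accessions_for("bTGT"))
        calls = detect_fusions(records, sig, config.fusion_transporter_accessions(),
                               config.fusion_min_len, config.fusion_max_len)
        _write_frame(fusions_to_frame(calls), outdir / "fusions.tsv")
        logger.info("fuse: %d fusion calls", len(calls))

    elif stage == "ssn":
        records = qio.read_gene_table(outdir / "gene_table.tsv")
        pairs = qio.read_pair_table(outdir / "pairs.tsv")
        profiles = _read_profiles(outdir / "profiles.tsv")
        neigh = _read_neighborhoods(outdir / "neighborhoods.tsv")
        stats = _read_stats(outdir / "family_stats.tsv")
        fusions = _read_fusions(outdir / "fusions.tsv")
        profile_of = {p.genome_id: p for p in profiles}
        genome_of = {r.protein_id: r.genome_id for r in records}

        in_pairs = {pid for p in pairs for pid in (p.protein_a, p.protein_b)}
        proteins = [r for r in records if r.protein_id in in_pairs]
        attributes = {
            pid: {"profile_category": profile_of[genome_of[pid]].category}
            for pid in in_pairs
        }
        cutoff = config.rep_identity if config.collapse_nodes else 100.0
        nodes = collapse_representatives(pairs, proteins, cutoff, attributes)
        for node in nodes.values():
            node.attributes["member_genomes"] = {
                m: genome_of[m] for m in node.members
            }
        t0 = initial_threshold(pairs, config.target_identity)
        net = build_network(nodes, pairs, t0)
        net, report, visited = refine_until_homogeneous(
            net, "profile_category", config.as_step, config.majority,
        )
        candidates = {s.family_accession for s in stats if s.passes_filters}
        if candidates:
            net = cluster_profile_overlay(net, profiles, neigh, fusions,
                                          candidates, config.color_distance)
        qio.write_network(net, outdir / "ssn_edgelist.tsv", "edgelist_tsv")
        qio.write_network(net, outdir / "ssn.graphml", "graphml")
        hom = pd.DataFrame(
            [{
                "cluster_id": c.cluster_id, "size": c.size,
                "modal_label": c.modal_label,
                "majority_fraction": round(c.majority_fraction, 6),
            } for c in report.clusters],
            columns=["cluster_id", "size", "modal_label", "majority_fraction"],
        )
        _write_frame(hom, outdir / "homogeneity.tsv")
        _write_frame(
            pd.DataFrame({"threshold": [round(t, 6) for t in visited]}),
            outdir / "ssn_thresholds.tsv",
        )
        logger.info("ssn: initial AS %.2f, final AS %.2f after %d step(s), "
                    "%d nodes, %d clusters",
                    t0, net.threshold, len(visited) - 1, len(net.nodes),
                    len(net.clusters))

    elif stage == "score":
        stats = _read_stats(outdir / "family_stats.tsv")
        neigh = _read_neighborhoods(outdir / "neighborhoods.tsv")
        profiles = _read_profiles(outdir / "profiles.tsv")
        fusions = _read_fusions(outdir / "fusions.tsv")
        scores = score_candidates(stats, neigh, profiles, config.weights,
                                  fusions, config.z_min)
        scores = annotate_selection(scores, config.z_min)
        _write_frame(scores_to_frame(scores), outdir / "candidate_scores.tsv")
        logger.info("score: %d families scored, %d selected",
                    len(scores), sum(c.selected for c in scores))

    elif stage == "report":
        stats = _read_stats(outdir / "family_stats.tsv")
        neigh = _read_neighborhoods(outdir / "neighborhoods.tsv")
        profiles = _read_profiles(outdir / "profiles.tsv")
        fusions = _read_fusions(outdir / "fusions.tsv")
        net = qio.read_network(outdir / "ssn_edgelist.tsv")
        scores = score_candidates(stats, neigh, profiles, config.weights,
                                  fusions, config.z_min)
        scores = annotate_selection(scores, config.z_min)
        candidates = {s.family_accession for s in stats if s.passes_filters}
        if not candidates:
            candidates = {s.family_accession for s in stats}
        enrich = cluster_enrichment(net, neigh, candidates) if candidates else []
        _write_frame(enrichment_to_frame(enrich), outdir / "enrichment.tsv")
        report = build_report(scores, enrich, fusions, profiles)
        _write_frame(report, outdir / "report.tsv")
        qio._atomic_write_text(
            outdir / "report.json",
            report.to_json(orient="records", indent=1) + "\n",
        )
        logger.info("report: %d selected candidate families", len(report))

    return outdir


def _records_with_domains(outdir):
    from .records import attach_domains

    records = qio.read_gene_table(outdir / "gene_table.tsv")
    domains_path = outdir / "domains.tsv"
    if domains_path.exists():
        records = attach_domains(records, qio.read_domain_table(domains_path))
    return records
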