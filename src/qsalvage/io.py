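"""Readers and writers for every external representation the pipeline touches.

Dialects
--------
gene-table TSV   header: genome_id, contig_id, gene_index, strand, protein_id,
                 length_aa, families (semicolon-separated accessions, may be empty)
GFF3             CDS features; protein id from ID/protein_id/locus_tag attribute;
                 gene_index is recomputed per contig from coordinate order
domain TSV       header: protein_id, accession, start_aa, end_aa (1-based inclusive)
hit TSV          BLAST tabular (outfmt-6 compatible): query marker, subject,
                 pident, ..., evalue, bitscore (>= 6 columns; last two are
                 evalue and bitscore)
pair TSV         header: protein_a, protein_b, percent_identity, and one of
                 alignment_score | evalue
network          GraphML (via networkx) or a two-section edge-list TSV that
                 round-trips node attributes and AS values bit-exactly

Parsers never silently drop rows: every malformed row raises with its line
number, and duplicate identifiers raise listing the offender.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import networkx as nx

from .records import HitRecord, PairScore, ProteinRecord, dedupe_pairs

GENE_TABLE_COLUMNS = [
    "genome_id", "contig_id", "gene_index", "strand",
    "protein_id", "length_aa", "families",
]

# E-values of exactly 0 are clipped here before taking -log10
MIN_EVALUE = 1e-300


def _atomic_write_text(path, text):
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(path, dialect="tsv", genome_id=None):
    """Read protein/gene records from a gene-table TSV or a GFF3 file.

    Returns records sorted by (genome_id, contig_id, gene_index).  For the
    GFF3 dialect, ``genome_id`` defaults to the file stem and gene_index is
    assigned from CDS coordinate order per contig.
    """
    if dialect == "tsv":
        records = _read_gene_tsv(path)
    elif dialect == "gff3":
        records = _read_gene_gff3(path, genome_id)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")

    seen, dupes = set(), []
    for r in records:
        if r.protein_id in seen:
            dupes.append(r.protein_id)
        seen.add(r.protein_id)
    if dupes:
        raise ValueError(f"duplicate protein_id(s): {sorted(set(dupes))}")

    index_seen = set()
    for r in records:
        k = (r.genome_id, r.contig_id, r.gene_index)
        if k in index_seen:
            raise ValueError(
                f"duplicate gene_index {r.gene_index} on contig {r.contig_id} "
                f"of genome {r.genome_id}"
            )
        index_seen.add(k)

    records.sort(key=lambda r: (r.genome_id, r.contig_id, r.gene_index))
    return records


def _read_gene_tsv(path):
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"gene table missing column(s) {missing}; header was {header}")
    col = {c: header.index(c) for c in GENE_TABLE_COLUMNS}
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        try:
            fam_field = parts[col["families"]]
            families = frozenset(f for f in fam_field.split(";") if f)
            records.append(
                ProteinRecord(
                    protein_id=parts[col["protein_id"]],
                    genome_id=parts[col["genome_id"]],
                    contig_id=parts[col["contig_id"]],
                    gene_index=int(parts[col["gene_index"]]),
                    strand=parts[col["strand"]],
                    length_aa=int(parts[col["length_aa"]]),
                    families=families,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_gene_gff3(path, genome_id=None):
    from gffutils.feature import feature_from_line

    if genome_id is None:
        genome_id = Path(path).stem
    per_contig_count = {}
    per_contig_last_start = {}
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line ({exc})") from exc
            if feat.featuretype != "CDS":
                continue
            attrs = feat.attributes
            pid = None
            for key in ("ID", "protein_id", "locus_tag"):
                if key in attrs and attrs[key]:
                    pid = attrs[key][0]
                    break
            if pid is None:
                raise ValueError(f"{path}:{lineno}: CDS without ID/protein_id/locus_tag")
            last = per_contig_last_start.get(feat.seqid)
            if last is not None and feat.start < last:
                raise ValueError(
                    f"{path}:{lineno}: CDS start {feat.start} on contig {feat.seqid} "
                    f"is not monotone (previous start {last})"
                )
            per_contig_last_start[feat.seqid] = feat.start
            idx = per_contig_count.get(feat.seqid, 0)
            per_contig_count[feat.seqid] = idx + 1
            # nt span -> aa length, stop codon excluded (floor 1 for short ORFs)
            length_aa = max(1, (feat.end - feat.start + 1) // 3 - 1)
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    gene_index=idx,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    length_aa=length_aa,
                )
            )
    return records


def write_gene_table(records, path):
    """Write records as a gene-table TSV (round-trip safe, domains excluded)."""
    lines = ["\t".join(GENE_TABLE_COLUMNS)]
    for r in records:
        lines.append("\t".join([
            r.genome_id, r.contig_id, str(r.gene_index), r.strand,
            r.protein_id, str(r.length_aa), ";".join(sorted(r.families)),
        ]))
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

def read_domain_table(path):
    """Read (protein_id, accession, start_aa, end_aa) rows."""
    lines = Path(path).read_text().splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0] == "protein_id":
            continue
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        try:
            out.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer domain coordinate") from exc
    return out


def write_domain_table(domains, path):
    lines = ["\t".join(["protein_id", "accession", "start_aa", "end_aa"])]
    for pid, acc, start, end in domains:
        lines.append(f"{pid}\t{acc}\t{start}\t{end}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# hit tables (BLAST tabular)
# ---------------------------------------------------------------------------

def read_hit_table(path, genome_of=None):
    """Read a BLAST outfmt-6-style hit table into HitRecords.

    ``genome_of`` maps a subject id to its genome (callable or mapping);
    by default the genome is the part of the subject id before the first '|'.
    No filtering happens here — thresholding is the profiler's job.
    """
    if genome_of is None:
        genome_of = lambda s: s.split("|")[0]
    elif not callable(genome_of):
        mapping = dict(genome_of)
        genome_of = mapping.__getitem__

    hits = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
        try:
            pident = float(parts[2])
            evalue = float(parts[-2])
            bitscore = float(parts[-1])
        except ValueError as exc:
            raise ValueError(
                f"{path}:{lineno}: non-numeric pident/evalue/bitscore field"
            ) from exc
        subject = parts[1]
        hits.append(
            HitRecord(
                marker_id=parts[0],
                subject_protein_id=subject,
                genome_id=genome_of(subject),
                percent_identity=pident,
                e_value=evalue,
                bitscore=bitscore,
            )
        )
    return hits


def write_hit_table(hits, path):
    """Write hits in 12-column outfmt-6 layout (filler columns zeroed)."""
    lines = []
    for h in hits:
        lines.append("\t".join([
            h.marker_id, h.subject_protein_id, repr(h.percent_identity),
            "0", "0", "0", "0", "0", "0", "0",
            repr(h.e_value), repr(h.bitscore),
        ]))
    _atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# pairwise similarity tables
# ---------------------------------------------------------------------------

def read_pair_table(path):
    """Read an all-vs-all pair table into deduplicated PairScores.

    Header must contain protein_a, protein_b, percent_identity, and either an
    ``alignment_score`` column or an ``evalue`` column (AS = -log10 evalue).
    Duplicate unordered pairs keep the maximum AS.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    required = ["protein_a", "protein_b", "percent_identity"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"pair table missing column(s) {missing}")
    has_as = "alignment_score" in header
    if not has_as and "evalue" not in header:
        raise ValueError("pair table needs an alignment_score or evalue column")
    col = {c: header.index(c) for c in header}
    pairs = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            if has_as:
                as_ = float(parts[col["alignment_score"]])
            else:
                ev = max(float(parts[col["evalue"]]), MIN_EVALUE)
                as_ = -math.log10(ev)
            pairs.append(
                PairScore(
                    protein_a=parts[col["protein_a"]],
                    protein_b=parts[col["protein_b"]],
                    percent_identity=float(parts[col["percent_identity"]]),
                    alignment_score=max(as_, 0.0),
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed pair row ({exc})") from exc
    return dedupe_pairs(pairs)


def write_pair_table(pairs, path):
    lines = ["\t".join(["protein_a", "protein_b", "percent_identity", "alignment_score"])]
    for p in pairs:
        lines.append(
            f"{p.protein_a}\t{p.protein_b}\t{p.percent_identity!r}\t{p.alignment_score!r}"
        )
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_NODE_COLUMNS = [
    "node_id", "members", "profile_category", "candidate_families",
    "filled", "has_tgt",
]


def write_network(ssn, path, format="edgelist_tsv"):
    """Write an SSN to GraphML or the two-section edge-list TSV dialect.

    The TSV dialect is round-trip safe: node ids, the attributes used for
    coloring, and edge AS values are reproduced bit-exactly by
    :func:`read_network`.
    """
    if format == "edgelist_tsv":
        lines = ["#threshold\t" + repr(float(ssn.threshold)), "#nodes"]
        lines.append("\t".join(_NODE_COLUMNS))
        for nid in sorted(ssn.nodes):
            node = ssn.nodes[nid]
            a = node.attributes
            lines.append("\t".join([
                nid,
                ";".join(sorted(node.members)),
                str(a.get("profile_category", "")),
                ";".join(sorted(a.get("candidate_families", ()))),
                "1" if a.get("filled") else "0",
                "1" if a.get("has_tgt", True) else "0",
            ]))
        lines.append("#edges")
        lines.append("\t".join(["node_a", "node_b", "alignment_score"]))
        for a, b, as_ in sorted(ssn.edges):
            lines.append(f"{a}\t{b}\t{as_!r}")
        _atomic_write_text(path, "\n".join(lines) + "\n")
    elif format == "graphml":
        g = nx.Graph(threshold=float(ssn.threshold))
        for nid in sorted(ssn.nodes):
            node = ssn.nodes[nid]
            a = node.attributes
            g.add_node(
                nid,
                members=";".join(sorted(node.members)),
                profile_category=str(a.get("profile_category", "")),
                candidate_families=";".join(sorted(a.get("candidate_families", ()))),
                filled=bool(a.get("filled", False)),
                has_tgt=bool(a.get("has_tgt", True)),
            )
        for a, b, as_ in sorted(ssn.edges):
            g.add_edge(a, b, alignment_score=float(as_))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path):
    """Read the edge-list TSV dialect back into an SSN."""
    from .ssn import SSN, SSNNode

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#threshold\t"):
        raise ValueError(f"{path}: not an edge-list network file")
    threshold = float(lines[0].split("\t", 1)[1])
    nodes, edges = {}, []
    section = None
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "#nodes":
            section = "nodes"
            continue
        if line == "#edges":
            section = "edges"
            continue
        if not line.strip() or line.split("\t")[0] in ("node_id", "node_a"):
            continue
        parts = line.split("\t")
        if section == "nodes":
            if len(parts) != len(_NODE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: bad node row")
            nid, members, cat, cand, filled, has_tgt = parts
            nodes[nid] = SSNNode(
                node_id=nid,
                members=tuple(m for m in members.split(";") if m),
                attributes={
                    "profile_category": cat,
                    "candidate_families": frozenset(c for c in cand.split(";") if c),
                    "filled": filled == "1",
                    "has_tgt": has_tgt == "1",
                },
            )
        elif section == "edges":
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: bad edge row")
            edges.append((parts[0], parts[1], float(parts[2])))
        else:
            raise ValueError(f"{path}:{lineno}: row outside #nodes/#edges sections")
    return SSN.from_parts(nodes, edges, threshold)
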