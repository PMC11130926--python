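"""Q-metabolism profiling from marker presence/absence.

Queuosine (Q) is made de novo only by bacteria: QueD/E/C/F build the preQ1
base from GTP, bTGT inserts it at position 34 of GUN-anticodon tRNAs, and
QueA plus QueG or QueH finish the synthesis on the tRNA.  Organisms missing
parts of this pathway can salvage intermediates — preQ0/preQ1 bases, the free
queuine (q) base directly (substrate-shifted bTGT), or q indirectly via the
queuine lyase QueL, with the hydrolases Qng1/QueK releasing q from Q
nucleosides.  Salvage requires import, and only two transporter families are
known (QPTR and the ECF-type QueT/QrtT), so a genome classified as a salvager
with no known transporter has a "transporter gap" — the discovery signal this
package exists to chase.

Presence calls use homology-hit thresholds of >= 20% identity and E-value
<= 1e-10 (both inclusive).  Classification is a total rule table over the
derived capability flags; it is a *prediction*, and every profile carries a
caveat field saying so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

# Ordered categories
NON_USER = "non_user"
DE_NOVO_Q = "de_novo_Q"
DE_NOVO_PREQ1_TERMINAL = "de_novo_preQ1_terminal"
PREQ_SALVAGER = "preQ_salvager"
Q_SALVAGER_INDIRECT = "q_salvager_indirect"
Q_SALVAGER_DIRECT = "q_salvager_direct"

CATEGORIES = (
    NON_USER, DE_NOVO_Q, DE_NOVO_PREQ1_TERMINAL,
    PREQ_SALVAGER, Q_SALVAGER_INDIRECT, Q_SALVAGER_DIRECT,
)

#: categories predicted to depend on importing a Q precursor
SALVAGE_REQUIRING = frozenset({PREQ_SALVAGER, Q_SALVAGER_INDIRECT, Q_SALVAGER_DIRECT})

PREDICTION_CAVEAT = (
    "computational prediction from marker presence/absence; "
    "not experimental ground truth"
)

#: accessions the source databases use for the anchor markers; all other
#: markers default to their own name as accession (override via config).
DEFAULT_ACCESSIONS = {
    "bTGT": ["bTGT", "IPR004803"],
    "Qng1": ["Qng1", "IPR019438"],
    "QueK": ["QueK", "IPR023186"],
    "QPTR": ["QPTR", "IPR003744", "PF02592"],
    "QrtT": ["QrtT", "PF12822"],
}


@dataclass(frozen=True)
class MarkerSet:
    """The marker families consulted for profiling, grouped by pathway role."""

    synthesis: tuple = ("QueD", "QueE", "QueC", "QueF")
    insertion: tuple = ("bTGT",)
    finishing: tuple = ("QueA", "QueG", "QueH")
    salvage_enzymes: tuple = ("QueL", "Qng1", "QueK")
    transporters: tuple = ("QPTR", "QueT", "QrtT")
    accessions: tuple = ()  # ((marker, (acc, ...)), ...) overrides

    def __post_init__(self):
        names = self.all_markers()
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique across groups")

    def all_markers(self):
        return (
            list(self.synthesis) + list(self.insertion) + list(self.finishing)
            + list(self.salvage_enzymes) + list(self.transporters)
        )

    def accessions_for(self, marker):
        """Family accessions recognized for a marker (always includes its name)."""
        for m, accs in self.accessions:
            if m == marker:
                return list(accs)
        return DEFAULT_ACCESSIONS.get(marker, [marker])

    @property
    def signature_markers(self):
        """Markers whose neighborhoods are mined for candidate transporters."""
        return ("bTGT", "Qng1", "QueK")


@dataclass
class PresenceMatrix:
    """Genomes x markers boolean calls plus the thresholds that produced them."""

    genomes: list
    markers: list
    calls: pd.DataFrame
    min_identity: float
    max_evalue: float

    def row(self, genome_id):
        return self.calls.loc[genome_id].to_dict()

    def to_tsv(self, path):
        df = self.calls.astype(int)
        df.index.name = "genome_id"
        header = (
            f"# presence calls at min_identity={self.min_identity!r}, "
            f"max_evalue={self.max_evalue!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class QPathwayProfile:
    """Predicted Q-metabolism capabilities of one genome."""

    genome_id: str
    has_tgt: bool
    makes_preQ1: bool
    finishes_Q: bool
    has_queF: bool
    has_queL: bool
    has_hydrolase: bool
    has_known_transporter: bool
    category: str
    transporter_gap: bool
    salvage_substrates: frozenset
    partial_synthesis: bool = False
    caveat: str = PREDICTION_CAVEAT


def call_presence(hits, genomes, markers=None, min_identity=20.0, max_evalue=1e-10):
    """Call marker presence per genome from homology hits.

    A cell is present iff some hit for that marker in that genome has
    percent_identity >= min_identity AND e_value <= max_evalue (inclusive
    boundaries).  Genomes without any passing hit get an all-false row.
    A hit referencing a genome outside ``genomes`` raises: silent id
    mismatches would otherwise deflate presence everywhere.
    """
    if markers is None:
        markers = MarkerSet()
    if not genomes:
        raise ValueError("genome list must be non-empty")
    if min_identity <= 0 or max_evalue <= 0:
        raise ValueError("thresholds must be positive")
    names = markers.all_markers()
    genome_set = set(genomes)
    calls = pd.DataFrame(False, index=list(genomes), columns=names)
    for h in hits:
        if h.genome_id not in genome_set:
            raise ValueError(f"hit references unknown genome {h.genome_id!r}")
        if h.marker_id not in calls.columns:
            continue  # hits for non-marker queries are legal and ignored
        if h.percent_identity >= min_identity and h.e_value <= max_evalue:
            calls.at[h.genome_id, h.marker_id] = True
    return PresenceMatrix(
        genomes=list(genomes), markers=names, calls=calls,
        min_identity=float(min_identity), max_evalue=float(max_evalue),
    )


def classify_profile(genome_id, row, markers=None):
    """Classify one genome's Q-pathway profile from its presence row.

    The rule table, evaluated in order (synthesis dominates salvage):

    1. no bTGT                                   -> non_user
    2. QueDECF complete and finishing complete   -> de_novo_Q
    3. QueDECF complete, finishing incomplete    -> de_novo_preQ1_terminal
    4. no QueDECF, finishing complete, QueL      -> q_salvager_indirect
    5. no QueDECF, finishing complete            -> preQ_salvager
    6. no QueDECF, finishing incomplete          -> q_salvager_direct

    transporter_gap is set for salvage-requiring categories lacking every
    known transporter family (QPTR, QueT, QrtT).
    """
    if markers is None:
        markers = MarkerSet()
    known = set(markers.all_markers())
    unknown = set(row) - known
    if unknown:
        raise ValueError(f"unknown marker(s) in presence row: {sorted(unknown)}")
    missing = known - set(row)
    if missing:
        raise ValueError(f"presence row missing marker(s): {sorted(missing)}")

    p = lambda m: bool(row[m])
    has_tgt = p("bTGT")
    makes_preQ1 = all(p(m) for m in ("QueD", "QueE", "QueC", "QueF"))
    finishes_Q = p("QueA") and (p("QueG") or p("QueH"))
    has_queF = p("QueF")
    has_queL = p("QueL")
    has_hydrolase = p("Qng1") or p("QueK")
    has_known_transporter = any(p(m) for m in markers.transporters)
    n_synth = sum(p(m) for m in ("QueD", "QueE", "QueC", "QueF"))
    partial_synthesis = 0 < n_synth < 4

    substrates = frozenset()
    if not has_tgt:
        category = NON_USER
    elif makes_preQ1 and finishes_Q:
        category = DE_NOVO_Q
    elif makes_preQ1:
        category = DE_NOVO_PREQ1_TERMINAL
    elif finishes_Q and has_queL:
        category = Q_SALVAGER_INDIRECT
        substrates = frozenset({"q", "preQ1"} | ({"preQ0"} if has_queF else set()))
    elif finishes_Q:
        category = PREQ_SALVAGER
        substrates = frozenset({"preQ1"} | ({"preQ0"} if has_queF else set()))
    else:
        category = Q_SALVAGER_DIRECT
        substrates = frozenset({"q"} | ({"Q"} if has_hydrolase else set()))

    transporter_gap = category in SALVAGE_REQUIRING and not has_known_transporter

    return QPathwayProfile(
        genome_id=genome_id,
        has_tgt=has_tgt,
        makes_preQ1=makes_preQ1,
        finishes_Q=finishes_Q,
        has_queF=has_queF,
        has_queL=has_queL,
        has_hydrolase=has_hydrolase,
        has_known_transporter=has_known_transporter,
        category=category,
        transporter_gap=transporter_gap,
        salvage_substrates=substrates,
        partial_synthesis=partial_synthesis,
    )


def profile_table(matrix, markers=None):
    """Classify every genome in a presence matrix, preserving order."""
    if markers is None:
        markers = MarkerSet()
    profiles = [
        classify_profile(g, matrix.row(g), markers) for g in matrix.genomes
    ]
    counts = {}
    for pr in profiles:
        counts[pr.category] = counts.get(pr.category, 0) + 1
    logger.info(
        "profiled %d genomes: %s", len(profiles),
        ", ".join(f"{c}={counts.get(c, 0)}" for c in CATEGORIES),
    )
    return profiles


def profiles_to_frame(profiles):
    """Tabulate profiles for TSV export."""
    rows = []
    for p in profiles:
        rows.append({
            "genome_id": p.genome_id,
            "category": p.category,
            "has_tgt": int(p.has_tgt),
            "makes_preQ1": int(p.makes_preQ1),
            "finishes_Q": int(p.finishes_Q),
            "has_queF": int(p.has_queF),
            "has_queL": int(p.has_queL),
            "has_hydrolase": int(p.has_hydrolase),
            "has_known_transporter": int(p.has_known_transporter),
            "transporter_gap": int(p.transporter_gap),
            "partial_synthesis": int(p.partial_synthesis),
            "salvage_substrates": ";".join(sorted(p.salvage_substrates)),
            "caveat": p.caveat,
        })
    return pd.DataFrame(rows)


def category_counts(profiles):
    out = {c: 0 for c in CATEGORIES}
    for p in profiles:
        out[p.category] += 1
    return out
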