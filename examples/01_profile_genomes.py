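"""Classify the Q-metabolism profile of a few genomes from homology hits.

Builds a tiny hit table by hand (three genomes with very different marker
content), calls marker presence at the 20% identity / 1e-10 E-value
thresholds, and prints each genome's predicted category.
"""

from qsalvage import HitRecord, MarkerSet, call_presence, profile_table

markers = MarkerSet()


def hit(marker, genome, pident=60.0, evalue=1e-80):
    return HitRecord(marker, f"{genome}|{marker.lower()}", genome,
                     pident, evalue, 250.0)


hits = [
    # full de novo pathway, plus a known transporter
    *(hit(m, "Ecoli_like") for m in
      ("QueD", "QueE", "QueC", "QueF", "bTGT", "QueA", "QueG", "QPTR")),
    # bTGT only: must import queuine directly, and no known transporter
    hit("bTGT", "Actino_like"),
    # finishing enzymes without synthesis: salvages preQ bases
    *(hit(m, "Synergist_like") for m in ("bTGT", "QueF", "QueA", "QueH")),
    # a hit that fails the identity threshold contributes nothing
    hit("QueD", "Actino_like", pident=15.0),
]

genomes = ["Ecoli_like", "Actino_like", "Synergist_like"]
matrix = call_presence(hits, genomes, markers)
for profile in profile_table(matrix, markers):
    subs = ",".join(sorted(profile.salvage_substrates)) or "-"
    print(f"{profile.genome_id:16s} category={profile.category:22s} "
          f"substrates={subs:12s} transporter_gap={profile.transporter_gap}")

print()
print("A transporter gap marks genomes predicted to need a Q-precursor")
print("importer while encoding none of the known transporter families —")
print("exactly the genomes where new transporters are worth hunting.")
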