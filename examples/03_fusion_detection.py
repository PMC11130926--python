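"""Detect Rosetta-stone fusions of bTGT with transporter domains.

A single protein carrying both a tRNA-guanine transglycosylase domain and a
transporter domain is strong evidence that the transporter handles a Q
precursor.  Calls require both domain classes on a 500-2000 aa protein.
"""

from qsalvage import DomainHit, ProteinRecord, detect_fusions

proteins = [
    # MFS permease fused to bTGT: a genuine call
    ProteinRecord("Tpau_0550_like", "tsuk", "c1", 0, "+", 820, domains=(
        DomainHit("bTGT", 12, 370), DomainHit("PF07690", 410, 790))),
    # too short to be a real two-domain fusion
    ProteinRecord("short_one", "gX", "c1", 1, "+", 430, domains=(
        DomainHit("bTGT", 5, 200), DomainHit("PF07690", 210, 420))),
    # bTGT alone is just the signature enzyme
    ProteinRecord("plain_tgt", "gY", "c1", 2, "+", 780, domains=(
        DomainHit("bTGT", 10, 360),)),
]

calls = detect_fusions(proteins, {"bTGT"}, {"PF07690", "PF03176"})
for c in calls:
    print(f"fusion: {c.protein_id} ({c.genome_id}, {c.length_aa} aa) "
          f"domains={'-'.join(c.domain_order)}")
print(f"\n{len(calls)} fusion call(s) from {len(proteins)} proteins.")
print("Only the full-length two-domain protein is called; the short protein")
print("and the signature-only protein are rejected by the length and")
print("domain-class rules.")
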