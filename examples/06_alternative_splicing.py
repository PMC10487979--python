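"""Classify alternative-splicing events and detect uORFs.

Builds transcript pairs differing by one named splicing operation, runs the
intron-chain classifier on each, and scans a constructed 5' leader for
upstream open reading frames.
"""

from intronarch import classify_as_events, find_uorfs
from intronarch.models import Transcript

constitutive = Transcript("t.1", [(0, 100), (200, 300), (400, 500), (600, 700)])
variants = {
    "exon 2 skipped": Transcript("t.skip", [(0, 100), (400, 500), (600, 700)]),
    "donor of intron 1 shifted": Transcript("t.don", [(0, 88), (200, 300), (400, 500), (600, 700)]),
    "intron 2 retained": Transcript("t.ret", [(0, 100), (200, 500), (600, 700)]),
    "alternative first exon": Transcript("t.afe", [(487, 500), (600, 700)]),
}
for label, alt in variants.items():
    events = classify_as_events("gene1", [constitutive, alt])
    print(f"{label:>28} -> {[e.event_type for e in events]}")

leader = "ATG" + "GCT" * 21 + "TAA"  # a 22-aa upstream ORF
transcript = leader + "CCAA" + "ATG" + "GGC" * 200
for u in find_uorfs(transcript, main_start_offset=len(leader) + 4, transcript_id="t.afe"):
    print(f"uORF at {u.start}..{u.stop_end}: {u.length_aa} aa "
          f"(initiator Met counted, stop excluded)")
print("(event types come solely from comparing the two intron chains;")
print(" alternative first-exon usage is filed as 'other')")
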