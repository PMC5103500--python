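"""Single and structured motif extraction with quorum.

A motif is valid when it k-occurs (a window within distance k) in at least
`quorum` input sequences, and strictly valid because it is read off one of
the sequences with no error.  Structured motifs chain several boxes with
bounded spacer lengths between them — the geometry of composite
transcription-factor binding sites.
"""

from flasm import (ImplantPlan, StructuredMotifSpec, implant,
                   random_sequences, single_motif_extract,
                   structured_motif_extract)

# --- single motifs: one shared tetramer across three toy sequences
seqs = ["AACGTT", "CACGTG", "TACGTA"]
for rec in single_motif_extract(seqs, length=4, max_distance=0, quorum=3):
    print(f"single motif {rec.motif}: occurs in {rec.quorum_count}/3 sequences, "
          f"per-sequence hits {rec.seq_hits}")

# --- structured motifs: implant boxes 12-[2..6]-10 into 4 of 6 random
#     100-bp sequences, one substitution per box copy, and recover them
spec = StructuredMotifSpec(((12, 3), (10, 2)), ((2, 6),))
background = random_sequences(6, 100, seed=5)
seqs, truth = implant(background, ImplantPlan(spec, (0, 1, 2, 3), (1, 1), seed=6))
records = structured_motif_extract(seqs, spec, quorum=4, model="hamming")
reported = {r.boxes for r in records}
print(f"\nstructured spec {spec.notation}, quorum 4: "
      f"{len(records)} valid motif(s) reported")
print("implanted copies recovered:",
      sum(tr.boxes in reported for tr in truth), "of", len(truth))
print("example record:", records[0].motif, "quorum", records[0].quorum_count)
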