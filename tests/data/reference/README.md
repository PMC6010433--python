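# External reference data (not bundled)

Three acceptance checks in `tests/test_acceptance.py` run the pipeline on
curated external sequence data that cannot be redistributed here. To run
them, place the following plain-text files in this directory:

- `aep_alignment.fasta` — the curated alignment of 442 mature C13-domain
  plant AEP sequences (aligned FASTA, `-` gaps).
- `aep_labels.tsv` — headered TSV (`id`, `class`) labelling the 6 known
  ligases (OaAEP1, OaAEP1_b, OaAEP3, OaAEP4, PxAEP3b, butelase-1) and the
  12 known proteases; all other ids default to unknown.
- `butelase.fasta` — protein sequences of butelase-1 (GenBank KF918345)
  and butelase-2 (KR912009), ids `butelase1` / `butelase2`.
- `pxaep3.fasta` — mature enzyme domains of PxAEP3a (MG720072) and
  PxAEP3b (MG720076), ids `PxAEP3a` / `PxAEP3b`.

Without these files the three checks fail with a message naming what is
missing; the rest of the suite is self-contained.
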