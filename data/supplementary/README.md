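# Supplementary data layout

The three benchmark-reproduction tests in `tests/test_acceptance.py` look for
the original full-scale datasets here. None of these files ship with the
repository; converted from their distribution spreadsheets to TSV they are:

- `assays.tsv` — assay_id, description, species, document_id (optionally
  compound_ids, '|'-separated)
- `compounds.tsv` — compound_id, name, atc_codes ('|'-separated), max_phase
- `links.tsv` — assay_id, compound_id (many-to-many)
- `mouse_strains.tsv`, `rat_strains.tsv` — species, name, strain_type,
  synonyms ('|'), substrains ('|'); the MGD/RGD-style listing layout used by
  `vivominer.lexicon.load_strain_listing`
- `gold_brat/` — the 500 gold-annotated descriptions as BRAT `.txt`/`.ann`
  pairs
- `*.obo` — phenotype ontologies (optional; the phenotype benchmark needs
  them)

Without these files the three tests fail with an explanatory message; the rest
of the suite runs on generated data.
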