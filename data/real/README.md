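# Optional study data

Two checks in `tests/test_acceptance.py` compare the package's output with
the published analysis of the deposited COI dataset. The sequences are not
redistributed here; to enable those checks, place:

* `coi_79x608.fasta` — the 79 northwestern-Pacific-group sequences from
  GenBank accessions LC224174-LC224278 and LC474498-LC474506, aligned and
  trimmed to the common 608 bp.
* `populations.tsv` — two tab-separated columns (accession, population)
  assigning the 15 site-7 (Shichigahama) individuals to `Tohoku` and the
  remaining 64 to `NWP`.
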