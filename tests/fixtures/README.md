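# Test fixtures

The reference-sequence tests expect `Q9ZP09.fasta` (α-gliadin, 268 aa)
and `P10386.fasta` (LMW glutenin subunit, 288 aa) in this directory.
They are not redistributed with the repository; on a machine with
internet access fetch them once with

    python scripts/fetch_accessions.py

All other fixtures are generated programmatically at test time by the
`glutencg.synthetic` module.
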