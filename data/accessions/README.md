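# Local accession store

Save the three WBPH mitogenome records here (FASTA, optionally GenBank
flat files) to enable the reproduction suite and the record-dependent
acceptance tests:

* `MK907866.fasta` — WBPHTA (Korea, Taean)
* `NC_021417.fasta` — WBPHHN (China, Hainan)
* `KC512915.fasta` — WBPHYN (China, Yunnan)

With network access, `python scripts/fetch_accessions.py` downloads all
of them from NCBI. The library itself never touches the network.
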