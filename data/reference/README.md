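# Reference data (not distributed)

The published-value reproduction tests in `tests/test_acceptance.py` expect
the following small public files in this directory. They are not shipped
with the package; download them once on a machine with network access:

| file          | source                                                  |
|---------------|---------------------------------------------------------|
| `7zh7.cif`    | https://files.rcsb.org/download/7ZH7.cif (cat AA fibril) |
| `6dso.cif`    | https://files.rcsb.org/download/6DSO.cif (mouse)         |
| `6mst.cif`    | https://files.rcsb.org/download/6MST.cif (human)         |
| `Q1T770.fasta`| https://rest.uniprot.org/uniprotkb/Q1T770.fasta (cat SAA precursor) |
| `B0M1H2.fasta`| https://rest.uniprot.org/uniprotkb/B0M1H2.fasta (cheetah SAA) |
| `P0DJI8.fasta`| https://rest.uniprot.org/uniprotkb/P0DJI8.fasta (human SAA1) |
| `P05367.fasta`| https://rest.uniprot.org/uniprotkb/P05367.fasta (mouse SAA2) |

Without these files the corresponding tests fail with a message pointing
here; the rest of the suite and `scripts/acceptance.py` run entirely on
synthetic data.
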