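annotations: annotations.tsv
barcodes: barcodes.tsv
canonical_junctions:
  BRCA1:
  - - '1'
    - '2'
  - - '2'
    - '3'
  - - '3'
    - '4'
  - - '4'
    - '5'
  - - '5'
    - '6'
  - - '6'
    - '7'
  - - '7'
    - '8'
  - - '8'
    - '9'
  - - '9'
    - '10'
  - - '10'
    - '11'
  - - '11'
    - '12'
  - - '12'
    - '13'
  - - '13'
    - '14'
  - - '14'
    - '15'
  - - '15'
    - '16'
  - - '16'
    - '17'
  - - '17'
    - '18'
  - - '18'
    - '19'
  - - '19'
    - '20'
  - - '20'
    - '21'
  - - '21'
    - '22'
  - - '22'
    - '23'
  - - '23'
    - '24'
  BRCA2:
  - - '1'
    - '2'
  - - '2'
    - '3'
  - - '3'
    - '4'
  - - '4'
    - '5'
  - - '5'
    - '6'
  - - '6'
    - '7'
  - - '7'
    - '8'
  - - '8'
    - '9'
  - - '9'
    - '10'
  - - '10'
    - '11'
  - - '11'
    - '12'
  - - '12'
    - '13'
  - - '13'
    - '14'
  - - '14'
    - '15'
  - - '15'
    - '16'
  - - '16'
    - '17'
  - - '17'
    - '18'
  - - '18'
    - '19'
  - - '19'
    - '20'
  - - '20'
    - '21'
  - - '21'
    - '22'
  - - '22'
    - '23'
  - - '23'
    - '24'
  - - '24'
    - '25'
  - - '25'
    - '26'
  - - '26'
    - '27'
exons: exons.tsv
genes:
- BRCA1
- BRCA2
probes: probes.tsv
umi_length: 7
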