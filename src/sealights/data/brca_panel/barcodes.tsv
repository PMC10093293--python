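sample	barcode
S01	ACCATCGG
S02	GAAAGCAC
S03	TATGGGAC
S04	ATCCCGAG
S05	AGGGGGTA
S06	TTTTTTTG
S07	GCTGACAG
S08	GGCATTTC
S09	TGAGCATC
S10	ATGTTAGT
S11	CATCGTAT
S12	CTTGATTG
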