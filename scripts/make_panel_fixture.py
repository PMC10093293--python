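"""One-off generator of the packaged BRCA1/BRCA2 fixture panel.

Probe sequences are synthetic random placeholders (the real oligo
sequences are not public); everything else mirrors the reference design
arithmetic: 114 junction probes, 30 SNP-allele probes (6+4 SNPs x 3
probes), 3 intronic BRCA1 probes = 147 total.
"""
import numpy as np
import pandas as pd
from pathlib import Path

import sealights.panel as sp

rng = np.random.default_rng(20230406)
BASES = "ACGT"
used = set()

def seq(length=None):
    while True:
        n = int(length or rng.integers(20, 31))
        s = "".join(BASES[i] for i in rng.integers(0, 4, n))
        if s not in used:
            used.add(s)
            return s

genes = {
    "BRCA1": {"n_exons": 24, "alts": [("5q", 5.5), ("8p", 7.5), ("11q", 11.5), ("13p", 12.5), ("14q", 14.5)]},
    "BRCA2": {"n_exons": 27, "alts": [("6q", 6.5), ("12p", 11.5), ("18p", 17.5)]},
}

exons, probes = [], []
for gene, info in genes.items():
    n = info["n_exons"]
    for i in range(1, n + 1):
        exons.append(sp.ExonDef(gene, str(i), float(i), True))
        if i > 1:
            probes.append(sp.Probe(f"{gene}_e{i}_a", gene, "acceptor", seq(), "junction", str(i)))
        if i < n:
            probes.append(sp.Probe(f"{gene}_e{i}_d", gene, "donor", seq(), "junction", str(i)))
    for label, ordinal in info["alts"]:
        exons.append(sp.ExonDef(gene, label, ordinal, False))
        probes.append(sp.Probe(f"{gene}_e{label}_a", gene, "acceptor", seq(), "junction", label))
        probes.append(sp.Probe(f"{gene}_e{label}_d", gene, "donor", seq(), "junction", label))

# SNP probes: per SNP two allele-specific donor-side probes + shared acceptor-side partner
for gene, n_snps in (("BRCA1", 6), ("BRCA2", 4)):
    for k in range(1, n_snps + 1):
        snp = f"{gene}_snp{k}"
        probes.append(sp.Probe(f"{snp}_A", gene, "donor", seq(), "snp_allele", None, snp, "A"))
        probes.append(sp.Probe(f"{snp}_B", gene, "donor", seq(), "snp_allele", None, snp, "B"))
        probes.append(sp.Probe(f"{snp}_P", gene, "acceptor", seq(), "snp_allele", None, snp, "N"))

# intronic DNA-contamination controls (BRCA1)
probes.append(sp.Probe("BRCA1_int1_d", "BRCA1", "donor", seq(), "intronic"))
probes.append(sp.Probe("BRCA1_int2_a", "BRCA1", "acceptor", seq(), "intronic"))
probes.append(sp.Probe("BRCA1_int3_a", "BRCA1", "acceptor", seq(), "intronic"))

# barcodes: 12 samples, length 8, pairwise Hamming distance >= 3
barcodes = {}
pool = []
while len(pool) < 12:
    cand = "".join(BASES[i] for i in rng.integers(0, 4, 8))
    if all(sp.hamming(cand, b) >= 3 for b in pool):
        pool.append(cand)
for i, bc in enumerate(pool, 1):
    barcodes[f"S{i:02d}"] = bc

canonical = {
    gene: [(str(i), str(i + 1)) for i in range(1, info["n_exons"])]
    for gene, info in genes.items()
}

# known-junction annotations: deduped circRNA names from the reference tables
tables = pd.read_csv("src/sealights/data/annotations/tables_1_to_4.tsv", sep="\t",
                     dtype={"donor": str, "acceptor": str})
ann = []
for name, grp in tables.groupby("name", sort=True):
    r = grp.iloc[0]
    ann.append(sp.KnownJunctionAnnotation(r["gene"], r["donor"], r["acceptor"], name, r["status"]))

panel = sp.ProbePanel(
    genes=list(genes),
    exons=exons,
    probes=probes,
    canonical_junctions=canonical,
    barcodes=barcodes,
    umi_length=7,
    annotations=ann,
)
panel.validate()
print(panel.summary())
out = sp.save_panel(panel, Path("src/sealights/data/brca_panel"), name="panel")
back = sp.load_panel(out)
print("round-trip ok:", back.summary() == panel.summary())
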