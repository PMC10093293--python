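"""Synthetic read generator for the ligation-probe assay.

Emulates the assay's observables from a declarative per-sample transcript
mixture: every canonical-transcript molecule yields one ligation product
per canonical junction of its gene; alternative-junction and backsplice
molecules yield one product at their junction; SNP molecules pair an
allele-specific probe with its shared partner; genomic-DNA contaminants
pair intronic probes.  Each product is tagged with an independent uniform
random UMI (7 bases by default, 16,384 possible tags), amplified into
``reads_per_molecule`` PCR copies sharing that UMI, and sequenced with
independent per-base substitution errors.

Ground truth (molecule counts and distinct-UMI counts per junction) is
emitted alongside the reads so the read-processing pipeline can be
checked for exact molecule recovery.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .panel import Probe, ProbePanel, PanelError

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneMix:
    """Transcript mixture of one gene in one sample (molecule counts)."""

    linear_molecules: int = 0
    alt_junction_molecules: dict[tuple[str, str], int] = field(default_factory=dict)
    circ_molecules: dict[tuple[str, str], int] = field(default_factory=dict)
    circ_internal_linear: bool = False


@dataclass
class SampleSpec:
    name: str
    barcode: str
    genes: dict[str, GeneMix] = field(default_factory=dict)
    snp_allele_fractions: dict[str, float] = field(default_factory=dict)
    snp_molecules: dict[str, int] = field(default_factory=dict)
    dna_contamination_molecules: int = 0


@dataclass
class SimulationConfig:
    panel: ProbePanel
    samples: list[SampleSpec]
    error_rate: float = 0.0
    seed: int = 0
    reads_per_molecule: int = 3
    capture_efficiency: float = 1.0
    barcode_in_read: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError(f"error_rate {self.error_rate} outside [0, 0.1]")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must be in (0, 1]")
        for s in self.samples:
            if s.barcode not in self.panel.barcodes.values():
                raise ValueError(f"sample {s.name}: barcode {s.barcode} not in panel")
            for frac in s.snp_allele_fractions.values():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError("snp allele fraction outside [0, 1]")
            for mix in s.genes.values():
                counts = [mix.linear_molecules, *mix.alt_junction_molecules.values(),
                          *mix.circ_molecules.values()]
                if any(c < 0 for c in counts):
                    raise ValueError("negative molecule count")


@dataclass(frozen=True)
class _Product:
    """One ligation product: a probe pair plus its truth annotation."""

    sample: str
    gene: str
    donor: str
    acceptor: str
    junction_class: str
    left: Probe
    right: Probe


def random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)].astype("U1"))


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        # substitute with one of the three other bases
        others = [b for b in BASES if b != arr[i]]
        arr[i] = others[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _internal_linear_junctions(
    panel: ProbePanel, gene: str, donor: str, acceptor: str
) -> list[tuple[str, str]]:
    """Canonical junctions enclosed by a backsplice (acceptor..donor span)."""
    lo = panel.ordinal(gene, acceptor)
    hi = panel.ordinal(gene, donor)
    return [
        (d, a)
        for d, a in panel.canonical_junctions.get(gene, [])
        if lo <= panel.ordinal(gene, d) and panel.ordinal(gene, a) <= hi
    ]


def _enumerate_products(config: SimulationConfig) -> Iterator[_Product]:
    """Deterministic product stream (one entry per molecule-junction event)."""
    panel = config.panel
    for spec in config.samples:
        for gene in sorted(spec.genes):
            mix = spec.genes[gene]
            # canonical transcript molecules: one product per canonical junction
            for donor, acceptor in panel.canonical_junctions.get(gene, []):
                prod = _junction_product(panel, spec.name, gene, donor, acceptor)
                for _ in range(mix.linear_molecules):
                    yield prod
            for (donor, acceptor), n in sorted(mix.alt_junction_molecules.items()):
                prod = _junction_product(panel, spec.name, gene, donor, acceptor)
                for _ in range(n):
                    yield prod
            for (donor, acceptor), n in sorted(mix.circ_molecules.items()):
                prod = _junction_product(panel, spec.name, gene, donor, acceptor)
                internal = (
                    [
                        _junction_product(panel, spec.name, gene, d, a)
                        for d, a in _internal_linear_junctions(panel, gene, donor, acceptor)
                    ]
                    if mix.circ_internal_linear
                    else []
                )
                for _ in range(n):
                    yield prod
                    yield from internal
        # SNP products: allele probe (donor side) ligated to shared partner
        for snp_id in sorted(spec.snp_allele_fractions):
            frac_a = spec.snp_allele_fractions[snp_id]
            n = spec.snp_molecules.get(snp_id, 0)
            probes = [p for p in config.panel.probes if p.snp_id == snp_id]
            try:
                probe_a = next(p for p in probes if p.allele == "A")
                probe_b = next(p for p in probes if p.allele == "B")
                partner = next(p for p in probes if p.allele not in ("A", "B"))
            except StopIteration:
                raise PanelError(f"schema error: incomplete probe set for SNP {snp_id}")
            gene = probe_a.gene
            yield from (
                _Product(spec.name, gene, snp_id, allele, "snp_allele",
                         probe_a if allele == "A" else probe_b, partner)
                for allele in _allele_series(n, frac_a)
            )
        # genomic-DNA contaminants: intronic probe pair
        if spec.dna_contamination_molecules:
            intronic = [p for p in panel.probes if p.kind == "intronic"]
            lefts = [p for p in intronic if p.side == "donor"]
            rights = [p for p in intronic if p.side == "acceptor"]
            if not lefts or not rights:
                raise PanelError(
                    "schema error: DNA contamination requires intronic probes on both sides"
                )
            for i in range(spec.dna_contamination_molecules):
                left = lefts[i % len(lefts)]
                right = rights[i % len(rights)]
                yield _Product(
                    spec.name, left.gene, left.probe_id, right.probe_id,
                    "intronic_control", left, right,
                )


def _allele_series(n: int, frac_a: float) -> list[str]:
    """Deterministic allele sequence with round(n*frac_a) copies of allele A."""
    n_a = int(round(n * frac_a))
    return ["A"] * n_a + ["B"] * (n - n_a)


def _junction_product(
    panel: ProbePanel, sample: str, gene: str, donor: str, acceptor: str
) -> _Product:
    left = panel.junction_probe(gene, donor, "donor")
    right = panel.junction_probe(gene, acceptor, "acceptor")
    d_ord, a_ord = panel.ordinal(gene, donor), panel.ordinal(gene, acceptor)
    if a_ord > d_ord:
        cls = "linear_canonical" if panel.is_canonical(gene, donor, acceptor) else "linear_alternative"
    else:
        cls = "backsplice"
    return _Product(sample, gene, donor, acceptor, cls, left, right)


def simulate_reads(
    config: SimulationConfig,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate reads and ground truth.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(header, sequence)`` records (also written as FASTQ if
    ``fastq_path`` is given; ``.gz`` suffix enables compression) and
    ``truth`` is a per-junction table with molecule and distinct-UMI
    counts.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    panel = config.panel
    rng = np.random.default_rng(config.seed)
    barcode_of = {s.name: s.barcode for s in config.samples}

    reads: list[tuple[str, str]] = []
    truth_umis: dict[tuple, set[str]] = {}
    truth_molecules: dict[tuple, int] = {}
    truth_class: dict[tuple, str] = {}

    for idx, product in enumerate(_enumerate_products(config)):
        if config.capture_efficiency < 1.0 and rng.random() >= config.capture_efficiency:
            continue
        umi = random_umi(rng, panel.umi_length)
        key = (
            product.sample, product.gene, product.donor, product.acceptor,
            product.left.probe_id, product.right.probe_id,
        )
        truth_umis.setdefault(key, set()).add(umi)
        truth_molecules[key] = truth_molecules.get(key, 0) + 1
        truth_class[key] = product.junction_class
        template = umi + product.left.sequence + product.right.sequence
        if config.barcode_in_read:
            template = template + barcode_of[product.sample]
        for copy in range(config.reads_per_molecule):
            seq = _mutate(template, rng, config.error_rate)
            header = f"mol{idx}:{copy} sample={product.sample} bc={barcode_of[product.sample]}"
            reads.append((header, seq))

    truth = pd.DataFrame(
        [
            {
                "sample": k[0], "gene": k[1], "donor": k[2], "acceptor": k[3],
                "left_probe_id": k[4], "right_probe_id": k[5],
                "class": truth_class[k],
                "molecules": truth_molecules[k],
                "umi_distinct": len(truth_umis[k]),
            }
            for k in sorted(truth_umis)
        ]
    )

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    with open(path, "wb") as raw:
        fh: IO
        if path.suffix == ".gz":
            # fixed mtime/filename keep the archive byte-stable across runs
            fh = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        else:
            fh = raw
        try:
            for header, seq in reads:
                fh.write(f"@{header}\n{seq}\n+\n{'I' * len(seq)}\n".encode())
        finally:
            if fh is not raw:
                fh.close()


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (header, sequence) from a plain or gzipped FASTQ file."""
    path = Path(path)
    open_fn = gzip.open if path.suffix == ".gz" else open
    with open_fn(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # separator
            fh.readline()  # qualities
            yield header[1:].strip(), seq


def _parse_junction_key(key: str) -> tuple[str, str]:
    donor, acceptor = key.split("-")
    return donor, acceptor


def load_sim_config(path: str | Path, panel: ProbePanel) -> SimulationConfig:
    """Build a SimulationConfig from a YAML/JSON scenario description.

    Junctions are written ``"<donor>-<acceptor>"`` (e.g. ``"20-18"``,
    ``"5q-3"``); see the packaged scenario files for the schema.
    """
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    samples = []
    for s in doc["samples"]:
        genes = {}
        for gene, mix in (s.get("genes") or {}).items():
            genes[gene] = GeneMix(
                linear_molecules=int(mix.get("linear_molecules", 0)),
                alt_junction_molecules={
                    _parse_junction_key(k): int(v)
                    for k, v in (mix.get("alt_junction_molecules") or {}).items()
                },
                circ_molecules={
                    _parse_junction_key(k): int(v)
                    for k, v in (mix.get("circ_molecules") or {}).items()
                },
                circ_internal_linear=bool(mix.get("circ_internal_linear", False)),
            )
        samples.append(
            SampleSpec(
                name=s["name"],
                barcode=s["barcode"],
                genes=genes,
                snp_allele_fractions={
                    k: float(v) for k, v in (s.get("snp_allele_fractions") or {}).items()
                },
                snp_molecules={k: int(v) for k, v in (s.get("snp_molecules") or {}).items()},
                dna_contamination_molecules=int(s.get("dna_contamination_molecules", 0)),
            )
        )
    return SimulationConfig(
        panel=panel,
        samples=samples,
        error_rate=float(doc.get("error_rate", 0.0)),
        seed=int(doc.get("seed", 0)),
        reads_per_molecule=int(doc.get("reads_per_molecule", 3)),
        capture_efficiency=float(doc.get("capture_efficiency", 1.0)),
        barcode_in_read=bool(doc.get("barcode_in_read", False)),
    )


# ---------------------------------------------------------------------------
# count-level sampling (no reads) — used for cohort-scale studies
# ---------------------------------------------------------------------------

def sample_distinct_umis(
    molecule_counts: np.ndarray, umi_space: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct-UMI counts for junctions with the given molecule counts.

    Draws each molecule's UMI uniformly from ``umi_space`` tags and counts
    occupied tags per junction — the same occupancy process the read-level
    simulator realises, without materialising reads.  Expected value is
    ``U*(1-(1-1/U)^m)`` for ``m`` molecules over ``U`` tags.
    """
    molecule_counts = np.asarray(molecule_counts, dtype=np.int64)
    total = int(molecule_counts.sum())
    if total == 0:
        return np.zeros_like(molecule_counts)
    junction_ids = np.repeat(np.arange(molecule_counts.size), molecule_counts)
    umis = rng.integers(0, umi_space, size=total)
    occupancy = np.bincount(
        junction_ids * umi_space + umis, minlength=molecule_counts.size * umi_space
    )
    return (occupancy.reshape(molecule_counts.size, umi_space) > 0).sum(axis=1)


def expected_distinct_umis(m, umi_space: int = 16384):
    """E[distinct UMIs] after tagging m molecules from a pool of umi_space."""
    m = np.asarray(m, dtype=float)
    return umi_space * (1.0 - (1.0 - 1.0 / umi_space) ** m)


def distinct_umi_sd(m, umi_space: int = 16384):
    """Exact standard deviation of the occupancy count for m molecules."""
    m = np.asarray(m, dtype=float)
    u = float(umi_space)
    q1 = (1.0 - 1.0 / u) ** m
    q2 = (1.0 - 2.0 / u) ** m
    var = u * (u - 1.0) * q2 + u * q1 - (u * q1) ** 2
    return np.sqrt(np.maximum(var, 0.0))
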