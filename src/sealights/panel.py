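"""Probe-panel model: exon definitions, ligation probes, barcodes.

The assay interrogates splice junctions with pairs of oligonucleotide
probes placed at exon boundaries: a *donor*-side probe sits at the 3'
boundary of an exon, an *acceptor*-side probe at the 5' boundary.  When a
splicing (or backsplicing) event juxtaposes the two boundaries on a
transcript, the probes are ligated and the product is sequenced.  The
panel additionally carries allele-specific SNP probes (allelic-imbalance
readout) and intronic probes (genomic-DNA contamination control).

A panel on disk is a manifest (YAML or JSON) pointing at TSV tables for
exons, probes and barcodes, plus the UMI length and the per-gene list of
canonical junctions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

VALID_SIDES = {"donor", "acceptor"}
VALID_KINDS = {"junction", "snp_allele", "intronic"}
DNA_ALPHABET = set("ACGT")

PROBE_LEN_MIN = 20
PROBE_LEN_MAX = 30


class PanelError(ValueError):
    """Raised when a panel file violates a structural invariant."""


@dataclass(frozen=True)
class ExonDef:
    """One exon (or alternative exon boundary) of a targeted gene.

    ``ordinal`` ranks exons in 5'->3' transcript order.  Alternative
    boundaries within an exon (labels with a ``p``/``q`` suffix, e.g.
    ``5q`` for the distal part of exon 5) get ordinals offset by 0.5 from
    the parent exon so that the linear/backsplice classification stays a
    pure ordinal comparison.
    """

    gene: str
    label: str
    ordinal: float
    in_canonical: bool = True


@dataclass(frozen=True)
class Probe:
    probe_id: str
    gene: str
    side: str  # donor | acceptor
    sequence: str
    kind: str = "junction"  # junction | snp_allele | intronic
    exon_label: str | None = None
    snp_id: str | None = None
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.side not in VALID_SIDES:
            raise PanelError(f"schema error: probe {self.probe_id}: bad side {self.side!r}")
        if self.kind not in VALID_KINDS:
            raise PanelError(f"schema error: probe {self.probe_id}: bad kind {self.kind!r}")
        if self.kind == "intronic" and self.exon_label is not None:
            raise PanelError(
                f"schema error: intronic probe {self.probe_id} must not reference an exon"
            )
        if self.kind == "snp_allele" and (self.snp_id is None or self.allele is None):
            raise PanelError(
                f"schema error: snp_allele probe {self.probe_id} needs snp_id and allele"
            )


@dataclass(frozen=True)
class KnownJunctionAnnotation:
    gene: str
    donor_label: str
    acceptor_label: str
    name: str
    status: str  # known | novel
    note: str = ""


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ProbePanel:
    """A validated in-memory probe panel."""

    genes: list[str]
    exons: list[ExonDef]
    probes: list[Probe]
    canonical_junctions: dict[str, list[tuple[str, str]]]
    barcodes: dict[str, str]
    umi_length: int = 7
    annotations: list[KnownJunctionAnnotation] = field(default_factory=list)

    # ---- derived lookups (built lazily) -------------------------------
    def __post_init__(self) -> None:
        self._exon_index = {(e.gene, e.label): e for e in self.exons}
        self._probe_index = {p.probe_id: p for p in self.probes}

    def exon(self, gene: str, label: str) -> ExonDef:
        try:
            return self._exon_index[(gene, str(label))]
        except KeyError:
            raise PanelError(f"schema error: unknown exon {gene}/{label}") from None

    def probe(self, probe_id: str) -> Probe:
        try:
            return self._probe_index[probe_id]
        except KeyError:
            raise PanelError(f"schema error: unknown probe {probe_id}") from None

    def ordinal(self, gene: str, label: str) -> float:
        return self.exon(gene, label).ordinal

    def probes_for(self, gene: str, exon_label: str, side: str) -> list[Probe]:
        return [
            p
            for p in self.probes
            if p.gene == gene and p.exon_label == str(exon_label) and p.side == side
        ]

    def junction_probe(self, gene: str, exon_label: str, side: str) -> Probe:
        cands = [p for p in self.probes_for(gene, exon_label, side) if p.kind == "junction"]
        if not cands:
            raise PanelError(
                f"schema error: no {side}-side junction probe on {gene} exon {exon_label}"
            )
        return cands[0]

    @property
    def umi_space(self) -> int:
        return 4 ** self.umi_length

    def summary(self) -> dict[str, int]:
        """Probe-category census of the panel."""
        kinds = pd.Series([p.kind for p in self.probes]).value_counts()
        return {
            "junction_probes": int(kinds.get("junction", 0)),
            "snp_probes": int(kinds.get("snp_allele", 0)),
            "intronic_probes": int(kinds.get("intronic", 0)),
            "total_probes": len(self.probes),
            "genes": len(self.genes),
            "exons": len(self.exons),
            "barcodes": len(self.barcodes),
            "canonical_junctions": sum(len(v) for v in self.canonical_junctions.values()),
        }

    def is_canonical(self, gene: str, donor_label: str, acceptor_label: str) -> bool:
        return (str(donor_label), str(acceptor_label)) in set(
            map(tuple, self.canonical_junctions.get(gene, []))
        )

    def validate(self, barcode_tolerance: int = 1) -> None:
        """Check every structural invariant; raise PanelError on the first violation."""
        # unique, well-formed sequences
        seen: dict[str, str] = {}
        for p in self.probes:
            if not (PROBE_LEN_MIN <= len(p.sequence) <= PROBE_LEN_MAX):
                raise PanelError(
                    f"schema error: probe {p.probe_id} length {len(p.sequence)} "
                    f"outside [{PROBE_LEN_MIN}, {PROBE_LEN_MAX}]"
                )
            if set(p.sequence) - DNA_ALPHABET:
                raise PanelError(f"schema error: probe {p.probe_id} has non-ACGT characters")
            if p.sequence in seen:
                raise PanelError(
                    f"ambiguous panel: probes {seen[p.sequence]} and {p.probe_id} "
                    "share a sequence"
                )
            seen[p.sequence] = p.probe_id
        # prefix ambiguity at the matching offset (shorter probe a prefix of a longer one)
        seqs = sorted(seen)
        for a, b in zip(seqs, seqs[1:]):
            if b.startswith(a):
                raise PanelError(
                    f"ambiguous panel: probe {seen[a]} is a prefix of probe {seen[b]}"
                )
        # exon references resolve
        for p in self.probes:
            if p.exon_label is not None and (p.gene, p.exon_label) not in self._exon_index:
                raise PanelError(
                    f"schema error: probe {p.probe_id} references unknown exon "
                    f"{p.gene}/{p.exon_label}"
                )
        # unique ordinals per gene
        for gene in self.genes:
            ords = [e.ordinal for e in self.exons if e.gene == gene]
            if len(ords) != len(set(ords)):
                raise PanelError(f"schema error: duplicate exon ordinals in {gene}")
        # canonical junctions have probes on both sides
        for gene, pairs in self.canonical_junctions.items():
            for donor, acceptor in pairs:
                self.exon(gene, donor)
                self.exon(gene, acceptor)
                self.junction_probe(gene, donor, "donor")
                self.junction_probe(gene, acceptor, "acceptor")
        # barcode distance floor
        floor = 2 * barcode_tolerance + 1
        names = sorted(self.barcodes)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(self.barcodes[a]) != len(self.barcodes[b]) or (
                    hamming(self.barcodes[a], self.barcodes[b]) < floor
                ):
                    raise PanelError(
                        f"barcode collision: samples {a} and {b} are within "
                        f"Hamming distance {floor - 1}"
                    )


def junction_name(
    gene: str, donor_label: str, acceptor_label: str, junction_class: str, panel: ProbePanel | None = None
) -> str:
    """Canonical display name of a junction.

    Backsplices are named ``<gene>_circRNA_<donor>-<acceptor>`` and linear
    junctions ``<gene>_mRNA_<donor>-<acceptor>``; alternative-boundary
    labels keep their p/q suffix.
    """
    if panel is not None:
        panel.exon(gene, donor_label)  # raises on unknown labels
        panel.exon(gene, acceptor_label)
    if junction_class in ("backsplice", "circRNA"):
        stem = "circRNA"
    elif junction_class in (
        "linear",
        "linear_canonical",
        "linear_alternative",
        "mRNA",
    ):
        stem = "mRNA"
    else:
        raise ValueError(f"unknown junction class {junction_class!r}")
    return f"{gene}_{stem}_{donor_label}-{acceptor_label}"


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _read_manifest(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def load_panel(path: str | Path, barcode_tolerance: int = 1) -> ProbePanel:
    """Load and validate a panel from its manifest file.

    The manifest names the exon/probe/barcode TSV tables (paths relative
    to the manifest), the UMI length, the canonical junction list per
    gene, and optionally a junction-annotation TSV.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"schema error: panel manifest {path} not found")
    manifest = _read_manifest(path)
    base = path.parent

    exons_df = pd.read_csv(base / manifest["exons"], sep="\t", dtype={"label": str})
    probes_df = pd.read_csv(
        base / manifest["probes"], sep="\t",
        dtype={"exon_label": str, "snp_id": str, "allele": str},
    )
    barcodes_df = pd.read_csv(base / manifest["barcodes"], sep="\t")

    exons = [
        ExonDef(r.gene, str(r.label), float(r.ordinal), bool(r.in_canonical))
        for r in exons_df.itertuples()
    ]
    probes = [
        Probe(
            probe_id=r.probe_id,
            gene=r.gene,
            side=r.side,
            sequence=r.sequence,
            kind=r.kind,
            exon_label=_opt(r.exon_label),
            snp_id=_opt(r.snp_id),
            allele=_opt(r.allele),
        )
        for r in probes_df.itertuples()
    ]
    barcodes = dict(zip(barcodes_df["sample"], barcodes_df["barcode"]))

    canonical: dict[str, list[tuple[str, str]]] = {}
    for gene, pairs in manifest["canonical_junctions"].items():
        canonical[gene] = [(str(d), str(a)) for d, a in pairs]

    annotations: list[KnownJunctionAnnotation] = []
    if manifest.get("annotations"):
        ann_df = pd.read_csv(
            base / manifest["annotations"], sep="\t",
            dtype={"donor": str, "acceptor": str},
        )
        for r in ann_df.itertuples():
            note = getattr(r, "note", "")
            annotations.append(
                KnownJunctionAnnotation(
                    gene=r.gene,
                    donor_label=str(r.donor),
                    acceptor_label=str(r.acceptor),
                    name=r.name,
                    status=r.status,
                    note="" if pd.isna(note) else str(note),
                )
            )

    panel = ProbePanel(
        genes=list(manifest["genes"]),
        exons=exons,
        probes=probes,
        canonical_junctions=canonical,
        barcodes=barcodes,
        umi_length=int(manifest.get("umi_length", 7)),
        annotations=annotations,
    )
    panel.validate(barcode_tolerance=barcode_tolerance)
    return panel


def save_panel(panel: ProbePanel, directory: str | Path, name: str = "panel") -> Path:
    """Write a panel back to a manifest + TSV bundle; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"gene": e.gene, "label": e.label, "ordinal": e.ordinal, "in_canonical": e.in_canonical}
            for e in panel.exons
        ]
    ).to_csv(directory / "exons.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "gene": p.gene,
                "exon_label": p.exon_label or "",
                "side": p.side,
                "kind": p.kind,
                "snp_id": p.snp_id or "",
                "allele": p.allele or "",
                "sequence": p.sequence,
            }
            for p in panel.probes
        ]
    ).to_csv(directory / "probes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(panel.barcodes.items()), columns=["sample", "barcode"]
    ).to_csv(directory / "barcodes.tsv", sep="\t", index=False)

    manifest = {
        "genes": panel.genes,
        "umi_length": panel.umi_length,
        "exons": "exons.tsv",
        "probes": "probes.tsv",
        "barcodes": "barcodes.tsv",
        "canonical_junctions": {
            g: [[d, a] for d, a in pairs] for g, pairs in panel.canonical_junctions.items()
        },
    }
    if panel.annotations:
        pd.DataFrame(
            [
                {
                    "gene": a.gene,
                    "donor": a.donor_label,
                    "acceptor": a.acceptor_label,
                    "name": a.name,
                    "status": a.status,
                    "note": a.note,
                }
                for a in panel.annotations
            ]
        ).to_csv(directory / "annotations.tsv", sep="\t", index=False)
        manifest["annotations"] = "annotations.tsv"

    manifest_path = directory / f"{name}.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
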