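"""Junction classification and splicing-anomaly detection.

The order of the ligated probes encodes the transcript topology: a
donor-side (3' boundary) probe joined to the acceptor-side (5' boundary)
probe of a *downstream* exon is linear splicing; joined to the acceptor
probe of the *same or an upstream* exon it is backsplicing, i.e. a
circRNA junction (equal exon = single-exon circle).  SNP-allele and
intronic probe pairs are routed to their own control classes; anything
else (wrong probe orientation, cross-gene pair) is an artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import KnownJunctionAnnotation, Probe, ProbePanel, junction_name

LINEAR_CLASSES = ("linear_canonical", "linear_alternative")


@dataclass(frozen=True)
class Anomaly:
    gene: str
    donor_label: str
    acceptor_label: str
    kind: str  # skipping | unexpected_backsplice | novel
    relative_abundance: float
    status: str  # known | novel
    samples: tuple[str, ...]


def classify_pair(left: Probe, right: Probe, panel: ProbePanel) -> str:
    """Class of a single ordered probe pair (pure function of the panel)."""
    if "intronic" in (left.kind, right.kind):
        return "intronic_control"
    if "snp_allele" in (left.kind, right.kind):
        return "snp_allele"
    if left.side != "donor" or right.side != "acceptor":
        return "artifact"
    if left.gene != right.gene:
        return "artifact"  # putative fusion; out of scope
    donor_ord = panel.ordinal(left.gene, left.exon_label)
    acceptor_ord = panel.ordinal(right.gene, right.exon_label)
    if acceptor_ord > donor_ord:
        if panel.is_canonical(left.gene, left.exon_label, right.exon_label):
            return "linear_canonical"
        return "linear_alternative"
    return "backsplice"


def classify(counts: pd.DataFrame, panel: ProbePanel) -> pd.DataFrame:
    """Attach a class and display name to every counted probe pair.

    Every row receives exactly one class; UMI counts are untouched, so
    class totals conserve the input total.
    """
    classes, names = [], []
    for r in counts.itertuples():
        left = panel.probe(r.left_probe_id)
        right = panel.probe(r.right_probe_id)
        cls = classify_pair(left, right, panel)
        classes.append(cls)
        if cls in ("backsplice", *LINEAR_CLASSES):
            names.append(junction_name(r.gene, r.donor, r.acceptor, cls))
        else:
            names.append(f"{r.gene}_{cls}_{r.donor}-{r.acceptor}")
    out = counts.copy()
    out["class"] = classes
    out["name"] = names
    out["pseudo_circ"] = False
    return out


def gene_totals(classified: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, gene) linear and circular UMI totals.

    SNP-allele and intronic UMIs measure alleles and contamination, not
    junction abundance, and are excluded from both totals.
    """
    rows = []
    for (sample, gene), grp in classified.groupby(["sample", "gene"], sort=True):
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "umi_linear_total": int(grp.loc[grp["class"].isin(LINEAR_CLASSES), "umi_count"].sum()),
                "umi_circ_total": int(grp.loc[grp["class"] == "backsplice", "umi_count"].sum()),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "gene", "umi_linear_total", "umi_circ_total"])


def _annotation_index(
    annotations: list[KnownJunctionAnnotation],
) -> dict[tuple[str, str, str], KnownJunctionAnnotation]:
    return {(a.gene, a.donor_label, a.acceptor_label): a for a in annotations}


def detect_anomalies(
    classified: pd.DataFrame,
    panel: ProbePanel,
    min_rel_abundance: float = 0.01,
) -> list[Anomaly]:
    """Non-canonical junctions above a relative-abundance floor.

    Relative abundance normalises a junction's UMI count by the mean
    canonical-junction UMI count of its gene in the same sample (the
    same per-junction denominator the circRNA/mRNA ratio uses).  The
    default 1% floor matches the sensitivity the assay's QC threshold
    guarantees for alternative transcripts.
    """
    known = _annotation_index(panel.annotations)
    found: dict[tuple[str, str, str], dict] = {}
    for (sample, gene), grp in classified.groupby(["sample", "gene"], sort=True):
        n_canonical = len(panel.canonical_junctions.get(gene, []))
        if n_canonical == 0:
            continue
        canonical_umi = grp.loc[grp["class"] == "linear_canonical", "umi_count"].sum()
        if canonical_umi == 0:
            raise ValueError(f"cannot normalize: no canonical UMI for {gene} in {sample}")
        mean_canonical = canonical_umi / n_canonical
        candidates = grp[grp["class"].isin(["linear_alternative", "backsplice"])]
        for _, r in candidates.iterrows():
            key = (gene, r["donor"], r["acceptor"])
            annotated = known.get(key)
            if r["class"] == "backsplice" and annotated is not None:
                continue  # expected physiological circRNA
            rel = r["umi_count"] / mean_canonical
            if rel < min_rel_abundance:
                continue
            if r["class"] == "backsplice":
                kind = "unexpected_backsplice"
            elif (
                panel.ordinal(gene, r["acceptor"]) > panel.ordinal(gene, r["donor"]) + 1
            ):
                kind = "skipping"
            else:
                kind = "novel"
            entry = found.setdefault(
                key,
                {
                    "kind": kind,
                    "rel": 0.0,
                    "samples": [],
                    "status": annotated.status if annotated else "novel",
                },
            )
            entry["rel"] = max(entry["rel"], rel)
            entry["samples"].append(sample)
    anomalies = [
        Anomaly(
            gene=k[0],
            donor_label=k[1],
            acceptor_label=k[2],
            kind=v["kind"],
            relative_abundance=v["rel"],
            status=v["status"],
            samples=tuple(sorted(set(v["samples"]))),
        )
        for k, v in found.items()
    ]
    return sorted(anomalies, key=lambda a: -a.relative_abundance)


def annotate_pseudo_circ(
    classified: pd.DataFrame,
    duplications: list[tuple[str, str, str]] | None,
) -> pd.DataFrame:
    """Flag backsplices explainable by a germline tandem duplication.

    A tandem duplication of exons ``first..last`` places a second copy of
    ``first`` downstream of ``last``, so *linear* splicing across the
    duplication boundary mimics a backsplice (donor = last, acceptor =
    first).  The assay cannot distinguish the two; the flag records the
    external germline knowledge.  Counts are never altered.
    """
    out = classified.copy()
    if "pseudo_circ" not in out.columns:
        out["pseudo_circ"] = False
    if not duplications:
        return out
    for gene, first_exon, last_exon in duplications:
        mask = (
            (out["class"] == "backsplice")
            & (out["gene"] == gene)
            & (out["donor"] == str(last_exon))
            & (out["acceptor"] == str(first_exon))
        )
        out.loc[mask, "pseudo_circ"] = True
    return out
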