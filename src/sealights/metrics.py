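"""Quality control, circRNA/mRNA ratios, detection frequencies, allelic balance.

Two ratio statistics summarise the balance between backsplicing and
linear splicing of a gene in a sample, both computed from distinct-UMI
counts:

* per-circRNA ratio (percent): UMIs of one circular junction divided by
  the *average* linear-junction UMI count,
  ``100 * umi_circ / (sum(linear UMIs) / n_canonical)``;
* overall ratio (circular junctions per 100 linear junctions):
  ``100 * sum(circ UMIs) / sum(linear UMIs)``.

"Linear UMIs" sums canonical and alternative linear junctions, while the
divisor ``n_canonical`` counts only the canonical junction pairs of the
gene's reference transcript.  A circRNA's *relative proportion* is its
share of the gene's total circular UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import LINEAR_CLASSES
from .panel import ProbePanel, junction_name
from .readproc import saturation_corrected


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (reference-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc(
    classified: pd.DataFrame,
    threshold: int = 1500,
    mode: str = "combined",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample UMI-depth quality control.

    A sample passes when its transcript-junction UMI total (linear +
    circular classes over the target genes) reaches ``threshold`` —
    summed over genes in ``combined`` mode (default), or in every gene
    in ``per-gene`` mode.  ``contamination_fraction`` is the share of
    intronic-control UMIs among all UMIs of the sample.
    """
    if mode not in ("combined", "per-gene"):
        raise ValueError(f"unknown QC mode {mode!r}")
    junction_classes = (*LINEAR_CLASSES, "backsplice")
    rows = []
    for sample, grp in classified.groupby("sample", sort=True):
        target = grp[grp["gene"].isin(genes)] if genes is not None else grp
        per_gene = (
            target[target["class"].isin(junction_classes)]
            .groupby("gene")["umi_count"]
            .sum()
        )
        if genes is not None:
            per_gene = per_gene.reindex(genes, fill_value=0)
        combined = int(per_gene.sum())
        if mode == "combined":
            passed = combined >= threshold
        else:
            passed = bool(len(per_gene)) and bool((per_gene >= threshold).all())
        total_umi = int(grp["umi_count"].sum())
        intronic_umi = int(grp.loc[grp["class"] == "intronic_control", "umi_count"].sum())
        row = {"sample": sample, "umi_total": combined, "pass": passed,
               "contamination_fraction": intronic_umi / total_umi if total_umi else 0.0}
        for gene, v in per_gene.items():
            row[f"umi_{gene}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows)


def pass_rate(passed: int, total: int, ndigits: int = 1) -> float:
    """QC pass rate in percent, half-up rounded."""
    if total <= 0:
        raise ValueError("empty cohort")
    return round_half_up(100.0 * passed / total, ndigits)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def _gene_slice(classified: pd.DataFrame, sample: str, gene: str) -> pd.DataFrame:
    return classified[(classified["sample"] == sample) & (classified["gene"] == gene)]


def relative_proportions(
    classified: pd.DataFrame, sample: str, gene: str
) -> dict[str, float]:
    """Each circRNA's share of the gene's circular UMIs (sums to 1)."""
    grp = _gene_slice(classified, sample, gene)
    circ = grp[grp["class"] == "backsplice"]
    total = circ["umi_count"].sum()
    if total == 0:
        return {}
    return {r.name: r.umi_count / total for r in circ.itertuples()}


def _linear_umi(grp: pd.DataFrame) -> int:
    return int(grp.loc[grp["class"].isin(LINEAR_CLASSES), "umi_count"].sum())


def ratio_eq1(
    classified: pd.DataFrame,
    panel: ProbePanel,
    sample: str,
    gene: str,
    circ_junction: tuple[str, str],
) -> float:
    """Per-circRNA ratio (%): circular UMIs over the mean linear-junction UMIs."""
    grp = _gene_slice(classified, sample, gene)
    linear_umi = _linear_umi(grp)
    if linear_umi == 0:
        raise ValueError(f"no mRNA signal for {gene} in {sample}")
    n_canonical = len(panel.canonical_junctions.get(gene, []))
    donor, acceptor = str(circ_junction[0]), str(circ_junction[1])
    circ = grp[
        (grp["class"] == "backsplice")
        & (grp["donor"] == donor)
        & (grp["acceptor"] == acceptor)
    ]
    umi_circ = int(circ["umi_count"].sum())
    return 100.0 * umi_circ / (linear_umi / n_canonical)


def ratio_eq2(
    classified: pd.DataFrame,
    sample: str,
    gene: str,
    corrected: bool = False,
    umi_space: int = 16384,
) -> float:
    """Overall circRNA/mRNA ratio: circular junctions per 100 linear junctions.

    With ``corrected=True`` the distinct-UMI counts are first inverted
    through the occupancy curve to molecule-scale estimates, removing the
    downward bias of the linear denominator at high per-junction depth.
    """
    grp = _gene_slice(classified, sample, gene)
    linear = grp.loc[grp["class"].isin(LINEAR_CLASSES), "umi_count"]
    circ = grp.loc[grp["class"] == "backsplice", "umi_count"]
    if corrected:
        linear_total = float(np.sum(saturation_corrected(linear.to_numpy(), umi_space))) if len(linear) else 0.0
        circ_total = float(np.sum(saturation_corrected(circ.to_numpy(), umi_space))) if len(circ) else 0.0
    else:
        linear_total = float(linear.sum())
        circ_total = float(circ.sum())
    if linear_total == 0:
        raise ValueError(f"no mRNA signal for {gene} in {sample}")
    return 100.0 * circ_total / linear_total


def ratio_table(classified: pd.DataFrame, panel: ProbePanel) -> pd.DataFrame:
    """Per-circRNA ratio summary for every sample-gene with circular signal."""
    rows = []
    pairs = classified[["sample", "gene"]].drop_duplicates().itertuples(index=False)
    for sample, gene in pairs:
        grp = _gene_slice(classified, sample, gene)
        circ = grp[grp["class"] == "backsplice"]
        if circ.empty:
            continue
        props = relative_proportions(classified, sample, gene)
        overall = ratio_eq2(classified, sample, gene)
        n_canonical = len(panel.canonical_junctions.get(gene, []))
        for r in circ.itertuples():
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "name": r.name,
                    "donor": r.donor,
                    "acceptor": r.acceptor,
                    "umi_count": r.umi_count,
                    "relative_proportion": props[r.name],
                    "ratio1_pct": ratio_eq1(classified, panel, sample, gene, (r.donor, r.acceptor)),
                    "overall_ratio": overall,
                    "n_canonical": n_canonical,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level detection frequency
# ---------------------------------------------------------------------------

def frequency_percent(count: int, n: int, ndigits: int = 2) -> float:
    """Detection frequency in percent from (count, group size), half-up."""
    if n <= 0:
        raise ValueError("empty group")
    return round_half_up(100.0 * count / n, ndigits)


def detection_frequency(
    classified: pd.DataFrame,
    gene: str,
    donor: str,
    acceptor: str,
    group_samples: list[str],
    presence_threshold: int = 1,
) -> tuple[int, float]:
    """(count, percent) of group samples in which a junction is detected.

    Presence is ``umi_count >= presence_threshold`` (default 1) in a
    QC-passing sample; the caller supplies the QC-passing group.
    """
    if not group_samples:
        raise ValueError("empty group")
    hits = classified[
        (classified["gene"] == gene)
        & (classified["donor"] == str(donor))
        & (classified["acceptor"] == str(acceptor))
        & (classified["umi_count"] >= presence_threshold)
        & (classified["sample"].isin(group_samples))
    ]["sample"].nunique()
    return int(hits), frequency_percent(int(hits), len(group_samples))


# ---------------------------------------------------------------------------
# allelic balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPResult:
    snp_id: str
    a: int
    b: int
    allele_fraction: float
    p_value: float
    imbalanced: bool
    status: str  # ok | insufficient


def allele_balance(
    classified: pd.DataFrame,
    sample: str,
    snp_id: str,
    p_threshold: float = 0.01,
    fraction_band: tuple[float, float] = (0.3, 0.7),
    min_umi: int = 20,
) -> SNPResult:
    """Exact binomial test of allele-A UMIs against the balanced 50:50 model.

    Imbalance — an indirect readout of allele loss or nonsense-mediated
    decay — is called when the two-sided p-value falls below
    ``p_threshold`` *and* the allele fraction leaves ``fraction_band``.
    """
    grp = classified[
        (classified["sample"] == sample)
        & (classified["class"] == "snp_allele")
        & (classified["donor"] == snp_id)
    ]
    if grp.empty:
        raise ValueError(f"unknown snp_id {snp_id!r} (no counts in sample {sample})")
    a = int(grp.loc[grp["acceptor"] == "A", "umi_count"].sum())
    b = int(grp.loc[grp["acceptor"] == "B", "umi_count"].sum())
    n = a + b
    if n < min_umi:
        return SNPResult(snp_id, a, b, a / n if n else float("nan"), 1.0, False, "insufficient")
    test = stats.binomtest(a, n, 0.5, alternative="two-sided")
    fraction = a / n
    imbalanced = test.pvalue < p_threshold and not (
        fraction_band[0] <= fraction <= fraction_band[1]
    )
    return SNPResult(snp_id, a, b, fraction, float(test.pvalue), imbalanced, "ok")
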