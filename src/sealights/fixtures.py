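"""Packaged reference data and cohort-scale synthetic scenarios.

Ships three text fixtures under ``sealights/data``:

* ``brca_panel/`` — the BRCA1/BRCA2 probe panel (147 probes: 114
  junction, 30 SNP-allele, 3 intronic; probe sequences are synthetic
  placeholders, the reference design arithmetic is preserved);
* ``annotations/tables_1_to_4.tsv`` — the reference circRNA repertoire
  tables (relative proportions, detection frequencies with counts and
  group sizes, per-circRNA ratios, novel status);
* ``annotations/qc_pass_counts.tsv`` — per-tissue QC pass counts.

The cohort scenario builder turns the reference repertoire into a
declarative 38-normal + 90-tumor simulation whose per-sample true
overall ratios are drawn around the reference group means, for
parameter-recovery and power studies at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .panel import ProbePanel, load_panel
from .simulate import GeneMix, SampleSpec, SimulationConfig, sample_distinct_umis
from .readproc import saturation_corrected

#: group means of the overall circRNA/mRNA ratio (per 100 linear junctions)
#: and the per-sample dispersion used by the cohort scenario
SCENARIO_MEANS = {
    "BRCA1": {"normal": 1.89, "tumor": 1.14},
    "BRCA2": {"normal": 0.51, "tumor": 0.23},
}
SCENARIO_SD = {"BRCA1": 0.5, "BRCA2": 0.1}
N_NORMAL, N_TUMOR = 38, 90
RATIO_FLOOR = 0.02


def data_path(*parts: str) -> Path:
    return Path(resources.files("sealights").joinpath("data", *parts))


def load_brca_panel() -> ProbePanel:
    """The packaged BRCA1/BRCA2 fixture panel."""
    return load_panel(data_path("brca_panel", "panel.yaml"))


def load_reference_tables(validate: bool = True) -> pd.DataFrame:
    """The transcribed circRNA repertoire tables.

    With ``validate=True`` every frequency cell is checked against its
    own (count, group size) pair through the half-up rounding rule.
    """
    df = pd.read_csv(
        data_path("annotations", "tables_1_to_4.tsv"), sep="\t",
        dtype={"donor": str, "acceptor": str},
    )
    if validate:
        for group in ("normal", "tumor"):
            recomputed = [
                metrics.frequency_percent(c, n)
                for c, n in zip(df[f"freq_count_{group}"], df[f"n_{group}"])
            ]
            bad = df.loc[
                ~np.isclose(recomputed, df[f"freq_pct_{group}"], atol=1e-9), "name"
            ]
            if len(bad):
                raise ValueError(
                    f"fixture self-consistency failure ({group} frequency): {list(bad)}"
                )
    return df


def load_qc_pass_counts() -> pd.DataFrame:
    """Per-tissue QC pass counts; ``recomputed_pct`` derives from the counts."""
    df = pd.read_csv(data_path("annotations", "qc_pass_counts.tsv"), sep="\t")
    df["recomputed_pct"] = [
        metrics.pass_rate(p, t) for p, t in zip(df["passed"], df["total"])
    ]
    return df


def circ_repertoire(gene: str, group: str = "normal") -> pd.DataFrame:
    """The gene's reference circRNA repertoire (main table) with weights.

    Returns donor/acceptor/status plus the group's relative proportions
    renormalised to sum to 1 — the circRNA abundance weights used by the
    cohort scenario.
    """
    tables = load_reference_tables(validate=False)
    main = tables[tables["table"].isin([1, 2]) & (tables["gene"] == gene)].copy()
    col = f"rel_prop_{group}"
    main["weight"] = main[col] / main[col].sum()
    return main[["gene", "name", "donor", "acceptor", "status", "weight"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort scenario
# ---------------------------------------------------------------------------

def _drawn_ratios(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Per-sample true ratios: Normal draw recentred to the exact group mean."""
    z = rng.standard_normal(n)
    r = mean + sd * (z - z.mean())
    return np.maximum(r, RATIO_FLOOR)


def build_reference_cohort_scenario(
    seed: int,
    panel: ProbePanel | None = None,
    linear_junction_molecules: int = 100_000,
) -> tuple[SimulationConfig, pd.DataFrame, pd.DataFrame]:
    """Declarative 38-normal + 90-tumor cohort mirroring the reference study design.

    Per sample and gene, the canonical transcript contributes
    ``linear_junction_molecules`` linear-junction molecules (split evenly
    over the gene's canonical junctions) and the circRNA pool holds
    ``ratio_i / 100`` of that, distributed over the reference repertoire
    with the tabulated relative proportions as weights.  Returns
    ``(config, metadata, truth)`` where truth carries each sample-gene's
    realised (integer-count) true overall ratio.
    """
    panel = panel or load_brca_panel()
    rng = np.random.default_rng(seed)
    barcodes = sorted(panel.barcodes.values())

    names = [f"N{i:03d}" for i in range(1, N_NORMAL + 1)] + [
        f"T{i:03d}" for i in range(1, N_TUMOR + 1)
    ]
    tissues = ["normal"] * N_NORMAL + ["tumor"] * N_TUMOR
    ratios = {
        gene: np.concatenate(
            [
                _drawn_ratios(rng, N_NORMAL, SCENARIO_MEANS[gene]["normal"], SCENARIO_SD[gene]),
                _drawn_ratios(rng, N_TUMOR, SCENARIO_MEANS[gene]["tumor"], SCENARIO_SD[gene]),
            ]
        )
        for gene in SCENARIO_MEANS
    }
    repertoire = {
        (gene, group): circ_repertoire(gene, group)
        for gene in SCENARIO_MEANS
        for group in ("normal", "tumor")
    }

    samples, truth_rows = [], []
    for i, (name, tissue) in enumerate(zip(names, tissues)):
        genes: dict[str, GeneMix] = {}
        for gene in SCENARIO_MEANS:
            n_canonical = len(panel.canonical_junctions[gene])
            per_junction = int(round(linear_junction_molecules / n_canonical))
            linear_total = per_junction * n_canonical
            circ_total = int(round(ratios[gene][i] / 100.0 * linear_total))
            rep = repertoire[(gene, tissue)]
            alloc = rng.multinomial(circ_total, rep["weight"].to_numpy())
            circ = {
                (d, a): int(n)
                for d, a, n in zip(rep["donor"], rep["acceptor"], alloc)
                if n > 0
            }
            genes[gene] = GeneMix(linear_molecules=per_junction, circ_molecules=circ)
            truth_rows.append(
                {
                    "sample": name,
                    "gene": gene,
                    "tissue": tissue,
                    "linear_molecules": linear_total,
                    "circ_molecules": circ_total,
                    "true_ratio": 100.0 * circ_total / linear_total,
                }
            )
        samples.append(SampleSpec(name=name, barcode=barcodes[i % len(barcodes)], genes=genes))

    config = SimulationConfig(panel=panel, samples=samples, error_rate=0.0, seed=int(rng.integers(2**31)))
    subtypes = rng.choice(["luminal", "HER2+", "TNBC"], size=N_TUMOR, p=[0.55, 0.15, 0.3])
    grades = rng.choice(["II", "III"], size=N_TUMOR)
    metadata = pd.DataFrame(
        {
            "sample": names,
            "tissue": tissues,
            "subtype": ["NA"] * N_NORMAL + list(subtypes),
            "grade": ["NA"] * N_NORMAL + list(grades),
        }
    )
    return config, metadata, pd.DataFrame(truth_rows)


def simulate_cohort_counts(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Distinct-UMI counts for a cohort scenario without materialising reads.

    Applies the same UMI-occupancy process as the read simulator at the
    molecule-count level (exact, not approximated), returning a
    classified-counts table (sample, gene, donor, acceptor, class,
    umi_count).
    """
    panel = config.panel
    rng = np.random.default_rng(seed)
    frames = []
    for spec in config.samples:
        for gene in sorted(spec.genes):
            mix = spec.genes[gene]
            keys: list[tuple[str, str, str]] = []
            mols: list[int] = []
            for d, a in panel.canonical_junctions.get(gene, []):
                keys.append((d, a, "linear_canonical"))
                mols.append(mix.linear_molecules)
            for (d, a), n in sorted(mix.alt_junction_molecules.items()):
                keys.append((d, a, "linear_alternative"))
                mols.append(n)
            for (d, a), n in sorted(mix.circ_molecules.items()):
                keys.append((d, a, "backsplice"))
                mols.append(n)
            distinct = sample_distinct_umis(np.array(mols), panel.umi_space, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": spec.name,
                        "gene": gene,
                        "donor": [k[0] for k in keys],
                        "acceptor": [k[1] for k in keys],
                        "class": [k[2] for k in keys],
                        "umi_count": distinct,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def cohort_overall_ratios(
    counts: pd.DataFrame, corrected: bool = True, umi_space: int = 16384
) -> pd.DataFrame:
    """Vectorised overall circRNA/mRNA ratio per (sample, gene).

    ``corrected`` inverts UMI counts through the occupancy curve before
    summing — the right choice when per-junction depth approaches the
    tag-space size, as in the parameter-recovery scenario.
    """
    df = counts.copy()
    value = (
        saturation_corrected(df["umi_count"].to_numpy(), umi_space)
        if corrected
        else df["umi_count"].to_numpy(dtype=float)
    )
    df["value"] = value
    df["is_circ"] = df["class"] == "backsplice"
    df["is_linear"] = df["class"].isin(["linear_canonical", "linear_alternative"])
    agg = df.groupby(["sample", "gene"]).apply(
        lambda g: 100.0 * g.loc[g["is_circ"], "value"].sum() / g.loc[g["is_linear"], "value"].sum(),
        include_groups=False,
    )
    return agg.rename("overall_ratio").reset_index()
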