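"""Joint quantification of linear splicing and backsplicing from
ligation-probe sequencing reads: UMI-based junction counting, splice
class assignment, circRNA/mRNA ratio statistics, splicing profiles, and
cohort comparison."""

from .panel import ExonDef, KnownJunctionAnnotation, PanelError, Probe, ProbePanel, junction_name, load_panel, save_panel
from .simulate import GeneMix, SampleSpec, SimulationConfig, load_sim_config, simulate_reads
from .readproc import ReadAssignment, collapse_umis, count_reads, demultiplex, match_probes, saturation_corrected
from .junctions import Anomaly, annotate_pseudo_circ, classify, classify_pair, detect_anomalies, gene_totals
from .metrics import SNPResult, allele_balance, detection_frequency, frequency_percent, qc, ratio_eq1, ratio_eq2, ratio_table, relative_proportions
from .cohort import build_cohort_table, compare_groups, group_summary
from .profiles import render_profile
from . import fixtures

__version__ = "0.1.0"

__all__ = [
    "ExonDef", "Probe", "ProbePanel", "KnownJunctionAnnotation", "PanelError",
    "junction_name", "load_panel", "save_panel",
    "GeneMix", "SampleSpec", "SimulationConfig", "load_sim_config", "simulate_reads",
    "ReadAssignment", "demultiplex", "match_probes", "collapse_umis", "count_reads",
    "saturation_corrected",
    "Anomaly", "classify", "classify_pair", "detect_anomalies", "annotate_pseudo_circ",
    "gene_totals",
    "SNPResult", "qc", "relative_proportions", "ratio_eq1", "ratio_eq2", "ratio_table",
    "detection_frequency", "frequency_percent", "allele_balance",
    "build_cohort_table", "compare_groups", "group_summary",
    "render_profile",
    "fixtures",
]
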