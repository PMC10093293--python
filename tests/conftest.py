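import numpy as np
import pytest

from sealights.panel import ExonDef, Probe, ProbePanel

BASES = "ACGT"


def _seq(rng: np.random.Generator, length: int = 24) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def make_toy_panel(
    n_exons: int = 4,
    gene: str = "GENE1",
    barcodes: dict[str, str] | None = None,
    seed: int = 11,
    umi_length: int = 7,
) -> ProbePanel:
    """Small programmatic panel: every exon carries probes on both sides."""
    rng = np.random.default_rng(seed)
    exons = [ExonDef(gene, str(i), float(i)) for i in range(1, n_exons + 1)]
    probes = []
    for i in range(1, n_exons + 1):
        probes.append(Probe(f"{gene}_e{i}_a", gene, "acceptor", _seq(rng), "junction", str(i)))
        probes.append(Probe(f"{gene}_e{i}_d", gene, "donor", _seq(rng), "junction", str(i)))
    if barcodes is None:
        barcodes = {"A": "AAAAAAAA", "B": "CCCCTTTT"}
    panel = ProbePanel(
        genes=[gene],
        exons=exons,
        probes=probes,
        canonical_junctions={gene: [(str(i), str(i + 1)) for i in range(1, n_exons)]},
        barcodes=barcodes,
        umi_length=umi_length,
    )
    panel.validate()
    return panel


@pytest.fixture(scope="session")
def brca_panel():
    from sealights.fixtures import load_brca_panel

    return load_brca_panel()


@pytest.fixture()
def toy_panel():
    return make_toy_panel()
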