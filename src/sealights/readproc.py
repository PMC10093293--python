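"""Read processing: demultiplex, probe-pair identification, UMI collapse.

Reads have a positionally rigid structure — UMI, then the left (donor)
probe sequence, then the right (acceptor) probe sequence, optionally the
sample barcode — so probe identification is fixed-offset Hamming
comparison against the panel, not alignment.  Distinct UMIs are counted
per (sample, probe pair): the unit of quantification is the number of
independent ligation events at a junction, PCR duplicates sharing a UMI
collapse to one molecule.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .panel import Probe, ProbePanel


@dataclass(frozen=True)
class ReadAssignment:
    sample: str | None
    left_probe_id: str | None
    right_probe_id: str | None
    umi: str | None
    status: str  # assigned | no_barcode | no_probe_match | ambiguous


def _capped_hamming(a: str, b: str, cap: int) -> int:
    """Hamming distance, abandoned (returns cap+1) once it exceeds cap."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return cap + 1
    return d


class _ProbeMatcher:
    """Fixed-offset probe lookup with an exact-match fast path."""

    def __init__(self, panel: ProbePanel, max_mismatch: int):
        self.max_mismatch = max_mismatch
        self.exact: dict[str, Probe] = {p.sequence: p for p in panel.probes}
        self.by_length: dict[int, list[Probe]] = {}
        for p in panel.probes:
            self.by_length.setdefault(len(p.sequence), []).append(p)
        self.lengths = sorted(self.by_length)

    def match_at(self, seq: str, offset: int) -> tuple[Probe | None, str]:
        """Best probe starting at ``offset``; returns (probe, status)."""
        best: Probe | None = None
        best_d = self.max_mismatch + 1
        tie = False
        for length in self.lengths:
            segment = seq[offset : offset + length]
            if len(segment) < length:
                continue
            exact_hit = self.exact.get(segment)
            if exact_hit is not None:
                if best_d == 0:
                    tie = True
                else:
                    best, best_d, tie = exact_hit, 0, False
                continue
            for probe in self.by_length[length]:
                d = _capped_hamming(segment, probe.sequence, self.max_mismatch)
                if d < best_d:
                    best, best_d, tie = probe, d, False
                elif d == best_d and d <= self.max_mismatch and probe is not best:
                    tie = True
        if best_d > self.max_mismatch:
            return None, "no_probe_match"
        if tie:
            return None, "ambiguous"
        return best, "assigned"


def match_probes(
    read: str,
    panel: ProbePanel,
    max_mismatch: int = 2,
    sample: str | None = None,
    matcher: _ProbeMatcher | None = None,
) -> ReadAssignment:
    """Identify the ligated probe pair and UMI of one read.

    The UMI is the first ``panel.umi_length`` bases; the left probe is
    matched immediately after it and the right probe immediately after
    the left, each against every panel probe of compatible length within
    ``max_mismatch`` substitutions.  A tie for the best match yields
    status ``ambiguous``.
    """
    if matcher is None:
        matcher = _ProbeMatcher(panel, max_mismatch)
    u = panel.umi_length
    if len(read) < u + 2 * min(matcher.lengths, default=0):
        return ReadAssignment(sample, None, None, None, "no_probe_match")
    umi = read[:u]
    left, status = matcher.match_at(read, u)
    if left is None:
        return ReadAssignment(sample, None, None, umi, status)
    right, status = matcher.match_at(read, u + len(left.sequence))
    if right is None:
        return ReadAssignment(sample, left.probe_id, None, umi, status)
    return ReadAssignment(sample, left.probe_id, right.probe_id, umi, "assigned")


def demultiplex(
    reads: Iterable[tuple[str, str]],
    panel: ProbePanel,
    max_mismatch: int = 1,
    barcode_in_read: bool = False,
) -> tuple[dict[str, list[tuple[str, str]]], Counter]:
    """Assign reads to samples by barcode.

    The barcode is taken from the ``bc=`` field of the read header
    (default) or from the read tail (``barcode_in_read``).  A read is
    assigned to the unique sample barcode within ``max_mismatch``
    substitutions — unambiguous whenever the panel's barcode set keeps
    pairwise distance >= 2*max_mismatch + 1 — and tallied ``no_barcode``
    otherwise.
    """
    sample_of = {bc: name for name, bc in panel.barcodes.items()}
    bc_lengths = {len(bc) for bc in sample_of}
    per_sample: dict[str, list[tuple[str, str]]] = {name: [] for name in panel.barcodes}
    tally: Counter = Counter()
    for header, seq in reads:
        observed = None
        if barcode_in_read:
            if len(bc_lengths) == 1:
                observed = seq[-next(iter(bc_lengths)) :]
        else:
            for token in header.split():
                if token.startswith("bc="):
                    observed = token[3:]
                    break
        assigned = None
        if observed is not None:
            assigned = sample_of.get(observed)
            if assigned is None:
                hits = [
                    name
                    for bc, name in sample_of.items()
                    if len(bc) == len(observed)
                    and _capped_hamming(bc, observed, max_mismatch) <= max_mismatch
                ]
                if len(hits) == 1:
                    assigned = hits[0]
        if assigned is None:
            tally["no_barcode"] += 1
        else:
            per_sample[assigned].append((header, seq))
            tally["assigned"] += 1
    return per_sample, tally


def collapse_umis(
    assignments: Iterable[ReadAssignment],
    directional: bool = False,
) -> pd.DataFrame:
    """Collapse assigned reads to distinct-UMI counts per probe pair.

    Returns one row per (sample, left_probe_id, right_probe_id) with
    ``umi_count`` (distinct UMIs, optionally after directional Hamming-1
    merging of likely sequencing-error UMIs) and ``read_count``.  The
    result is independent of the order of the input stream.
    """
    umis: dict[tuple, Counter] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        key = (a.sample, a.left_probe_id, a.right_probe_id)
        umis.setdefault(key, Counter())[a.umi] += 1
    rows = []
    for key in sorted(umis, key=lambda k: tuple(str(x) for x in k)):
        counter = umis[key]
        n_umis = _directional_count(counter) if directional else len(counter)
        rows.append(
            {
                "sample": key[0],
                "left_probe_id": key[1],
                "right_probe_id": key[2],
                "umi_count": n_umis,
                "read_count": sum(counter.values()),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "left_probe_id", "right_probe_id", "umi_count", "read_count"]
    )


def _directional_count(counter: Counter) -> int:
    """Directional UMI merge: absorb u2 into u1 if d(u1,u2)=1 and
    count(u1) >= 2*count(u2) - 1 (ties broken by count then sequence)."""
    order = sorted(counter, key=lambda u: (-counter[u], u))
    absorbed: set[str] = set()
    for i, parent in enumerate(order):
        if parent in absorbed:
            continue
        for child in order[i + 1 :]:
            if child in absorbed:
                continue
            if counter[parent] >= 2 * counter[child] - 1 and _capped_hamming(parent, child, 1) <= 1:
                absorbed.add(child)
    return len(counter) - len(absorbed)


def saturation_corrected(umi_count, umi_space: int = 16384):
    """Occupancy-corrected molecule estimate m_hat = -U*ln(1 - k/U).

    Inverts the expected distinct-UMI curve; optional — raw distinct-UMI
    counts remain the default unit of all reported quantities.
    """
    if isinstance(umi_count, (int, float)):
        if umi_count >= umi_space:
            raise ValueError("UMI count saturates the tag space; cannot correct")
        return -umi_space * math.log(1.0 - umi_count / umi_space)
    import numpy as np

    k = np.asarray(umi_count, dtype=float)
    return -umi_space * np.log(1.0 - k / umi_space)


def _junction_fields(left: Probe, right: Probe) -> tuple[str, str, str]:
    """(gene, donor, acceptor) labels for a probe pair, matching truth keys."""
    if "snp_allele" in (left.kind, right.kind):
        snp = left if left.allele in ("A", "B") else right
        return snp.gene, str(snp.snp_id), str(snp.allele)
    if "intronic" in (left.kind, right.kind):
        return left.gene, left.probe_id, right.probe_id
    return left.gene, str(left.exon_label), str(right.exon_label)


def count_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    panel: ProbePanel,
    barcode_mismatch: int = 1,
    probe_mismatch: int = 2,
    barcode_in_read: bool = False,
    directional: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full read-to-counts pipeline for one FASTQ stream.

    Returns ``(counts, stats)``: per-junction distinct-UMI counts with
    resolved gene/donor/acceptor labels, and the unassigned-read tally.
    """
    if isinstance(reads, (str, Path)):
        from .simulate import read_fastq

        reads = read_fastq(reads)
    per_sample, tally = demultiplex(
        reads, panel, max_mismatch=barcode_mismatch, barcode_in_read=barcode_in_read
    )
    tally["barcode_assigned"] = tally.pop("assigned", 0)
    matcher = _ProbeMatcher(panel, probe_mismatch)

    def _assignments() -> Iterator[ReadAssignment]:
        for sample in sorted(per_sample):
            for _, seq in per_sample[sample]:
                a = match_probes(seq, panel, probe_mismatch, sample=sample, matcher=matcher)
                tally[a.status] += 1
                yield a

    counts = collapse_umis(_assignments(), directional=directional)
    genes, donors, acceptors = [], [], []
    for r in counts.itertuples():
        gene, donor, acceptor = _junction_fields(panel.probe(r.left_probe_id), panel.probe(r.right_probe_id))
        genes.append(gene)
        donors.append(donor)
        acceptors.append(acceptor)
    counts.insert(1, "gene", genes)
    counts.insert(2, "donor", donors)
    counts.insert(3, "acceptor", acceptors)
    stats = pd.DataFrame(sorted(tally.items()), columns=["status", "reads"])
    return counts, stats
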