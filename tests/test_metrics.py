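"""QC, ratio statistics, detection frequencies, allelic balance."""

import math

import numpy as np
import pandas as pd
import pytest

from sealights import metrics
from sealights.fixtures import (
    build_reference_cohort_scenario,
    cohort_overall_ratios,
    load_reference_tables,
    load_qc_pass_counts,
    simulate_cohort_counts,
)


def _counts(rows):
    df = pd.DataFrame(
        rows, columns=["sample", "gene", "donor", "acceptor", "class", "umi_count"]
    )
    df["name"] = [
        f"{g}_{'circRNA' if c == 'backsplice' else 'mRNA'}_{d}-{a}"
        for g, d, a, c in zip(df["gene"], df["donor"], df["acceptor"], df["class"])
    ]
    return df


def uniform_gene(sample="S", gene="BRCA1", n_junctions=20, umi=50, circ=None, alt=None):
    rows = [
        (sample, gene, str(i), str(i + 1), "linear_canonical", umi)
        for i in range(1, n_junctions + 1)
    ]
    for (d, a), n in (circ or {}).items():
        rows.append((sample, gene, d, a, "backsplice", n))
    for (d, a), n in (alt or {}).items():
        rows.append((sample, gene, d, a, "linear_alternative", n))
    return _counts(rows)


class TestQC:
    def _two_gene_counts(self, umi1, umi2):
        rows = [("S", "BRCA1", "1", "2", "linear_canonical", umi1),
                ("S", "BRCA2", "1", "2", "linear_canonical", umi2)]
        return _counts(rows)

    def test_combined_mode_threshold_arithmetic(self):
        table = metrics.qc(self._two_gene_counts(1000, 600), mode="combined")
        assert table.loc[0, "pass"]
        assert table.loc[0, "umi_total"] == 1600

    def test_per_gene_mode_fails_same_totals(self):
        table = metrics.qc(self._two_gene_counts(1000, 600), mode="per-gene")
        assert not table.loc[0, "pass"]

    def test_contamination_fraction(self):
        rows = [("S", "BRCA1", "1", "2", "linear_canonical", 900),
                ("S", "BRCA1", "i1", "i2", "intronic_control", 100)]
        table = metrics.qc(_counts(rows))
        assert table.loc[0, "contamination_fraction"] == pytest.approx(0.1)

    def test_research_set_pass_rates(self):
        qc_counts = load_qc_pass_counts()
        research = qc_counts[qc_counts["cohort"] == "research"].set_index("tissue")
        assert metrics.pass_rate(
            int(research.loc["breast_tumor", "passed"]),
            int(research.loc["breast_tumor", "total"]),
        ) == 94.7
        assert metrics.pass_rate(
            int(research.loc["breast_normal_adjacent", "passed"]),
            int(research.loc["breast_normal_adjacent", "total"]),
        ) == 40.0


class TestRatios:
    def test_eq1_direct_arithmetic(self):
        # circ UMI 5 against 1000 linear UMIs over 20 canonical junctions -> 10%
        rows = [("S", "BRCA1", str(i), str(i + 1), "linear_canonical", 50) for i in range(1, 21)]
        rows.append(("S", "BRCA1", "20", "18", "backsplice", 5))
        df = _counts(rows)

        class FakePanel:
            canonical_junctions = {"BRCA1": [(str(i), str(i + 1)) for i in range(1, 21)]}

        assert metrics.ratio_eq1(df, FakePanel(), "S", "BRCA1", ("20", "18")) == pytest.approx(10.0)

    def test_eq1_zero_circ_is_zero(self, brca_panel):
        df = uniform_gene(n_junctions=23)
        assert metrics.ratio_eq1(df, brca_panel, "S", "BRCA1", ("20", "18")) == 0.0

    def test_eq1_no_linear_signal_errors(self, brca_panel):
        df = uniform_gene(n_junctions=23, umi=0, circ={("20", "18"): 5})
        with pytest.raises(ValueError, match="no mRNA signal"):
            metrics.ratio_eq1(df, brca_panel, "S", "BRCA1", ("20", "18"))

    def test_eq2_direct_arithmetic(self):
        rows = [("S", "G", "1", "2", "linear_canonical", 1000),
                ("S", "G", "3", "2", "backsplice", 15)]
        assert metrics.ratio_eq2(_counts(rows), "S", "G") == pytest.approx(1.5)

    def test_eq2_no_circ_is_zero(self):
        rows = [("S", "G", "1", "2", "linear_canonical", 1000)]
        assert metrics.ratio_eq2(_counts(rows), "S", "G") == 0.0

    def test_eq1_proportional_to_relative_proportion(self, brca_panel):
        df = uniform_gene(
            n_junctions=23, circ={("20", "18"): 30, ("17", "15"): 10, ("9", "9"): 5}
        )
        props = metrics.relative_proportions(df, "S", "BRCA1")
        ratios = {
            name: metrics.ratio_eq1(df, brca_panel, "S", "BRCA1", (d, a))
            for (d, a), name in [
                (("20", "18"), "BRCA1_circRNA_20-18"),
                (("17", "15"), "BRCA1_circRNA_17-15"),
                (("9", "9"), "BRCA1_circRNA_9-9"),
            ]
        }
        quotients = {n: ratios[n] / props[n] for n in ratios}
        assert max(quotients.values()) - min(quotients.values()) < 1e-9

    def test_eq2_equals_umi_weighted_eq1_aggregate(self, brca_panel):
        df = uniform_gene(n_junctions=23, circ={("20", "18"): 30, ("9", "9") : 7},
                          alt={("7", "14"): 12})
        linear_umi = df.loc[df["class"].isin(
            ["linear_canonical", "linear_alternative"]), "umi_count"].sum()
        n_canon = len(brca_panel.canonical_junctions["BRCA1"])
        total_ratio1 = sum(
            metrics.ratio_eq1(df, brca_panel, "S", "BRCA1", j)
            for j in [("20", "18"), ("9", "9")]
        )
        circ_umi = df.loc[df["class"] == "backsplice", "umi_count"].sum()
        assert total_ratio1 * (linear_umi / n_canon) == pytest.approx(100 * circ_umi, abs=1e-9)
        assert metrics.ratio_eq2(df, "S", "BRCA1") == pytest.approx(
            100 * circ_umi / linear_umi
        )

    def test_monotonicity_in_circ_and_linear_umis(self):
        base = [("S", "G", "1", "2", "linear_canonical", 1000),
                ("S", "G", "3", "2", "backsplice", 15)]
        r0 = metrics.ratio_eq2(_counts(base), "S", "G")
        more_circ = base + [("S", "G", "4", "2", "backsplice", 5)]
        more_linear = base + [("S", "G", "2", "3", "linear_canonical", 500)]
        assert metrics.ratio_eq2(_counts(more_circ), "S", "G") > r0
        assert metrics.ratio_eq2(_counts(more_linear), "S", "G") < r0

    def test_relative_proportions_sum_to_one(self):
        df = uniform_gene(circ={("20", "18"): 50, ("9", "9"): 50})
        props = metrics.relative_proportions(df, "S", "BRCA1")
        assert props == {
            "BRCA1_circRNA_20-18": pytest.approx(0.5),
            "BRCA1_circRNA_9-9": pytest.approx(0.5),
        }
        single = uniform_gene(circ={("20", "18"): 7})
        assert list(metrics.relative_proportions(single, "S", "BRCA1").values()) == [1.0]

    def test_zero_circ_gives_empty_map(self):
        assert metrics.relative_proportions(uniform_gene(), "S", "BRCA1") == {}

    def test_proportion_recovery_through_umi_collisions(self, brca_panel):
        from sealights.simulate import sample_distinct_umis

        rng = np.random.default_rng(42)
        rows = [("S", "BRCA1", str(i), str(i + 1), "linear_canonical", 100)
                for i in range(1, 24)]
        mols = np.array([300, 100, 100])
        k = sample_distinct_umis(mols, 16384, rng)
        for (d, a), umi in zip([("20", "18"), ("17", "15"), ("9", "9")], k):
            rows.append(("S", "BRCA1", d, a, "backsplice", int(umi)))
        props = metrics.relative_proportions(_counts(rows), "S", "BRCA1")
        assert props["BRCA1_circRNA_20-18"] == pytest.approx(0.6, abs=0.02)
        assert props["BRCA1_circRNA_17-15"] == pytest.approx(0.2, abs=0.02)


class TestRatioProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=8),
        st.integers(min_value=1, max_value=100_000),
    )
    def test_eq1_quotient_with_proportion_constant_across_circs(self, circ_umis, linear_umi):
        """ratio1_j / relative_proportion_j is the same for every circRNA j
        of a gene-sample (algebraic identity of the two definitions)."""
        rows = [("S", "G", "1", "2", "linear_canonical", linear_umi)]
        junctions = []
        for j, umi in enumerate(circ_umis):
            d, a = str(10 + j), str(3 + j)
            junctions.append((d, a))
            rows.append(("S", "G", d, a, "backsplice", umi))
        df = _counts(rows)

        class FakePanel:
            canonical_junctions = {"G": [("1", "2")]}

        props = metrics.relative_proportions(df, "S", "G")
        quotients = [
            metrics.ratio_eq1(df, FakePanel(), "S", "G", (d, a))
            / props[f"G_circRNA_{d}-{a}"]
            for d, a in junctions
        ]
        assert max(quotients) - min(quotients) <= 1e-9 * max(quotients)


class TestDetectionFrequency:
    @pytest.mark.parametrize(
        "count,n,expected",
        [(83, 90, 92.22), (35, 38, 92.11), (0, 38, 0.0), (19, 38, 50.0)],
    )
    def test_rounding_examples(self, count, n, expected):
        assert metrics.frequency_percent(count, n) == expected

    def test_reproduces_every_reference_frequency_cell(self):
        tables = load_reference_tables(validate=False)
        for group in ("normal", "tumor"):
            for _, r in tables.iterrows():
                assert metrics.frequency_percent(
                    int(r[f"freq_count_{group}"]), int(r[f"n_{group}"])
                ) == pytest.approx(r[f"freq_pct_{group}"])

    def test_detection_counting(self):
        rows = [(f"S{i}", "G", "3", "2", "backsplice", 2) for i in range(6)]
        rows += [("S9", "G", "3", "2", "backsplice", 0)]
        df = _counts(rows)
        group = [f"S{i}" for i in range(6)] + ["S9", "S10"]
        count, pct = metrics.detection_frequency(df, "G", "3", "2", group)
        assert (count, pct) == (6, 75.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty group"):
            metrics.detection_frequency(uniform_gene(), "BRCA1", "3", "2", [])


class TestAlleleBalance:
    def _snp_counts(self, a, b, snp="BRCA1_snp1"):
        rows = [("S", "BRCA1", snp, "A", "snp_allele", a),
                ("S", "BRCA1", snp, "B", "snp_allele", b)]
        return _counts(rows)

    def test_balanced_symmetric_counts(self):
        res = metrics.allele_balance(self._snp_counts(50, 50), "S", "BRCA1_snp1")
        assert res.allele_fraction == 0.5
        assert res.p_value == 1.0
        assert not res.imbalanced

    def test_strong_imbalance_flagged(self):
        # oracle: exact two-sided binomial tail by direct summation
        n, a = 100, 95
        pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
        p_exact = sum(p for p in pmf if p <= pmf[a] * (1 + 1e-12))
        res = metrics.allele_balance(self._snp_counts(95, 5), "S", "BRCA1_snp1")
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)
        assert res.imbalanced

    def test_insufficient_coverage(self):
        res = metrics.allele_balance(self._snp_counts(9, 5), "S", "BRCA1_snp1")
        assert res.status == "insufficient"
        assert not res.imbalanced

    def test_unknown_snp_errors(self):
        with pytest.raises(ValueError, match="unknown snp_id"):
            metrics.allele_balance(self._snp_counts(5, 5), "S", "nope")

    def test_loss_of_wild_type_recovered_from_simulation(self, brca_panel):
        from sealights.readproc import count_reads
        from sealights.junctions import classify
        from sealights.simulate import GeneMix, SampleSpec, SimulationConfig, simulate_reads

        def sample(name, frac):
            return SampleSpec(
                name, brca_panel.barcodes[name],
                genes={"BRCA1": GeneMix(linear_molecules=5)},
                snp_allele_fractions={"BRCA1_snp2": frac},
                snp_molecules={"BRCA1_snp2": 120},
            )

        cfg = SimulationConfig(
            brca_panel, [sample("S01", 0.9), sample("S02", 0.5)], seed=17
        )
        reads, _ = simulate_reads(cfg)
        counts, _ = count_reads(reads, brca_panel)
        classified = classify(counts, brca_panel)
        tumor = metrics.allele_balance(classified, "S01", "BRCA1_snp2")
        normal = metrics.allele_balance(classified, "S02", "BRCA1_snp2")
        assert tumor.imbalanced
        assert not normal.imbalanced


class TestParameterRecovery:
    def test_overall_ratio_unbiased_across_truth_grid(self):
        """Overall-ratio estimates are unbiased (within Monte-Carlo error)
        for true ratios spanning the physiological range."""
        from sealights.simulate import sample_distinct_umis
        from sealights.readproc import saturation_corrected

        rng = np.random.default_rng(2024)
        n_junctions, linear_total = 20, 100_000
        per_junction = linear_total // n_junctions
        for true_ratio in (0.5, 1.14, 1.89, 5.0):
            estimates = []
            for _ in range(20):
                circ = int(round(true_ratio / 100 * linear_total))
                mols = np.array([per_junction] * n_junctions + [circ])
                k = sample_distinct_umis(mols, 16384, rng)
                m_hat = saturation_corrected(k.astype(float))
                estimates.append(100 * m_hat[-1] / m_hat[:-1].sum())
            assert np.mean(estimates) == pytest.approx(true_ratio, abs=0.05)
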