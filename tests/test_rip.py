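"""RIP enrichment: filter semantics, factor arithmetic, calling, intersection."""

import math

import numpy as np
import pandas as pd
import pytest

from slamkit.rip import (
    CountMatrix,
    EnrichmentConfig,
    call_enriched,
    enrichment_factor,
    filter_low_counts,
    intersect_experiments,
    rank_transcripts,
)
from slamkit.synthetic import SimConfig, gen_counts


def matrix(rows: dict, columns=("IP_1", "control_1")) -> CountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    df.index.name = "transcript_id"
    return CountMatrix.from_frame(df)


NO_NORM = dict(pseudocount=0.0, normalization="none")


class TestCountMatrix:
    def test_requires_both_roles(self):
        df = pd.DataFrame({"IP_1": [1], "IP_2": [2]}, index=["t1"])
        with pytest.raises(ValueError, match="one IP and one control"):
            CountMatrix.from_frame(df)

    def test_rejects_negative_counts_and_duplicate_ids(self):
        df = pd.DataFrame({"IP_1": [-1], "control_1": [2]}, index=["t1"])
        with pytest.raises(ValueError, match="nonnegative"):
            CountMatrix.from_frame(df)
        df2 = pd.DataFrame({"IP_1": [1, 2], "control_1": [2, 3]}, index=["t1", "t1"])
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix.from_frame(df2)

    def test_unpaired_replicates_rejected(self):
        df = pd.DataFrame({"IP_1": [1], "control_2": [2]}, index=["t1"])
        with pytest.raises(ValueError, match="replicate id"):
            CountMatrix.from_frame(df).replicate_pairs()


class TestFilterLowCounts:
    def test_strict_threshold_semantics(self):
        m = matrix({"weak": [49, 3], "edge": [50, 0], "strong": [500, 100]})
        kept = filter_low_counts(m, 50).counts.index.tolist()
        assert kept == ["edge", "strong"]  # 49 removed, exactly 50 retained

    def test_min_count_zero_is_identity(self):
        m = matrix({"a": [0, 0], "b": [1, 2]})
        assert filter_low_counts(m, 0).counts.equals(m.counts)


class TestEnrichmentFactor:
    def test_plain_ratio(self):
        m = matrix({"t": [40, 10]})
        table = enrichment_factor(m, EnrichmentConfig(**NO_NORM))
        assert table.at["t", "factor"] == pytest.approx(4.0)

    def test_pseudocount_rescues_zero_control(self):
        m = matrix({"t": [40, 0]})
        cfg = EnrichmentConfig(pseudocount=1.0, normalization="none")
        assert enrichment_factor(m, cfg).at["t", "factor"] == pytest.approx(41.0)

    def test_zero_control_without_pseudocount_raises(self):
        m = matrix({"t": [40, 0]})
        with pytest.raises(ZeroDivisionError, match="pseudocount"):
            enrichment_factor(m, EnrichmentConfig(**NO_NORM))

    def test_geometric_mean_of_replicate_ratios(self):
        m = matrix(
            {"t": [20, 10, 80, 10]}, columns=("IP_1", "control_1", "IP_2", "control_2")
        )
        cfg = EnrichmentConfig(**NO_NORM)
        table = enrichment_factor(m, cfg)
        assert table.at["t", "factor"] == pytest.approx(math.sqrt(2 * 8))  # 4.0
        arith = EnrichmentConfig(replicate_combine="mean-of-ratios", **NO_NORM)
        assert enrichment_factor(m, arith).at["t", "factor"] == pytest.approx(5.0)

    def test_oracle_equivalence_small_matrix(self):
        """Factors equal an independent brute-force recomputation."""
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 200, size=(10, 4))
        df = pd.DataFrame(
            counts, columns=["IP_1", "control_1", "IP_2", "control_2"],
            index=[f"t{i}" for i in range(10)],
        )
        cfg = EnrichmentConfig(pseudocount=1.0, normalization="counts-per-million")
        table = enrichment_factor(CountMatrix.from_frame(df), cfg)
        # oracle: plain python, written from the definition
        col_sums = {c: sum(df[c]) for c in df.columns}
        for t in df.index:
            logs = []
            for rep in ("1", "2"):
                ip = df.at[t, f"IP_{rep}"] / col_sums[f"IP_{rep}"] * 1e6 + 1.0
                ct = df.at[t, f"control_{rep}"] / col_sums[f"control_{rep}"] * 1e6 + 1.0
                logs.append(math.log(ip / ct))
            expected = math.exp(sum(logs) / len(logs))
            assert table.at[t, "factor"] == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_under_cpm(self):
        """Scaling any sample column leaves CPM-normalized factors unchanged."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.integers(1, 500, size=(20, 2)), columns=["IP_1", "control_1"],
            index=[f"t{i}" for i in range(20)],
        )
        cfg = EnrichmentConfig(pseudocount=0.0, normalization="counts-per-million")
        base = enrichment_factor(CountMatrix.from_frame(df), cfg)["factor"]
        scaled_df = df.copy()
        scaled_df["IP_1"] = scaled_df["IP_1"] * 7
        scaled = enrichment_factor(CountMatrix.from_frame(scaled_df), cfg)["factor"]
        assert np.allclose(base, scaled)

    def test_monotonic_in_ip_count(self):
        cfg = EnrichmentConfig(pseudocount=1.0, normalization="none")
        factors = [
            enrichment_factor(matrix({"t": [ip, 10], "u": [5, 5]}), cfg).at["t", "factor"]
            for ip in (0, 10, 40, 400)
        ]
        assert factors == sorted(factors)


class TestCalling:
    def test_threshold_is_strict(self):
        table = pd.DataFrame({"factor": [4.0, 4.01, 3.99]}, index=["at", "above", "below"])
        assert call_enriched(table, 4.0) == {"above"}

    def test_empty_table(self):
        assert call_enriched(pd.DataFrame({"factor": []}), 4.0) == set()

    def test_intersection_and_exclusive_counts(self):
        v = intersect_experiments({"x", "y", "z"}, {"y", "z", "w"})
        assert v.shared == {"y", "z"}
        assert (v.n_only_a, v.n_only_b) == (1, 1)
        assert intersect_experiments({"a"}, {"b"}).shared == frozenset()

    def test_ranking_descending_with_id_tiebreak(self):
        table = pd.DataFrame({"factor": [2.0, 8.0, 4.0]}, index=["a", "b", "c"])
        assert rank_transcripts(table) == ["b", "c", "a"]
        ties = pd.DataFrame({"factor": [1.0, 1.0, 1.0]}, index=["c", "a", "b"])
        assert rank_transcripts(ties) == ["a", "b", "c"]


class TestPlantedRecovery:
    def test_sensitivity_and_fdp_across_seeds(self):
        """Planted 8-fold transcripts at depth 1e6: sensitivity >= 0.95, FDP <= 0.1."""
        sens, fdp = [], []
        for seed in range(20):
            a, _, truth = gen_counts(SimConfig(seed=seed))
            cfg = EnrichmentConfig(min_count=50)
            table = enrichment_factor(filter_low_counts(a, cfg.min_count), cfg)
            called = call_enriched(table, cfg.threshold)
            tp = len(called & truth.enriched_a)
            sens.append(tp / len(truth.enriched_a))
            fdp.append((len(called) - tp) / max(len(called), 1))
        assert np.mean(sens) >= 0.95
        assert np.mean(fdp) <= 0.1

    def test_strongest_planted_transcript_ranks_first(self):
        a, _, truth = gen_counts(SimConfig(seed=4))
        table = enrichment_factor(filter_low_counts(a, 50), EnrichmentConfig())
        assert rank_transcripts(table)[0] == truth.bait


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(threshold=1.0), dict(min_count=-1), dict(pseudocount=-0.5),
                   dict(normalization="tpm"), dict(replicate_combine="median")],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnrichmentConfig(**kwargs)
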