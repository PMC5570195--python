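import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifcore import (
    Alphabet,
    EncodingScheme,
    IndelPolicy,
    LigandRecord,
    RescalingDescriptor,
    TrainConfig,
    make_partition,
    rescale_targets,
    run_cv,
    scan_motif_lengths,
)
from motifcore.errors import DegenerateDataError, ValidationError
from motifcore.training_pipeline import regression_metrics


class TestRescaling:
    def test_ic50_closed_form_endpoints(self):
        d = RescalingDescriptor("ic50_log")
        assert d.apply([50000.0])[0] == pytest.approx(0.0, abs=1e-12)
        assert d.apply([1.0])[0] == pytest.approx(1.0, abs=1e-12)

    def test_ic50_mid_value_matches_high_precision_oracle(self):
        # 1 - ln(500)/ln(50000) evaluated symbolically to 15 digits
        d = RescalingDescriptor("ic50_log")
        assert d.apply([500.0])[0] == pytest.approx(0.425625189808507, abs=1e-12)

    def test_ic50_clamps_out_of_range_raw_values(self):
        d = RescalingDescriptor("ic50_log")
        assert d.apply([1e9])[0] == 0.0
        assert d.apply([0.01])[0] == 1.0

    @pytest.mark.parametrize("kind", ["ic50_log", "minmax", "log"])
    def test_invert_round_trip(self, kind):
        raw = np.array([2.0, 10.0, 120.0, 4999.0, 30000.0])
        d = RescalingDescriptor(kind).fit(raw)
        t = d.apply(raw)
        assert np.all((t >= 0) & (t <= 1))
        np.testing.assert_allclose(d.invert(t), raw, rtol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.001, 0.999))
    def test_ic50_scaled_invert_identity_on_unit_interval(self, v):
        d = RescalingDescriptor("ic50_log")
        assert d.apply(d.invert([v]))[0] == pytest.approx(v, abs=1e-9)

    def test_none_requires_unit_interval(self):
        records = [LigandRecord("ACGT", 1.5)]
        with pytest.raises(ValidationError):
            rescale_targets(records, RescalingDescriptor("none"))

    def test_degenerate_minmax(self):
        with pytest.raises(DegenerateDataError):
            RescalingDescriptor("minmax").fit(np.array([3.0, 3.0, 3.0]))


def _recs(seqs, targets=None):
    targets = targets if targets is not None else [0.5] * len(seqs)
    return [LigandRecord(s, t) for s, t in zip(seqs, targets)]


class TestMakePartition:
    def test_random_round_robin_balance(self):
        part = make_partition(_recs(["ACGTACGTA"] * 10), k=5, method="random", seed=3)
        counts = np.bincount(part.fold_of_record, minlength=5)
        assert list(counts) == [2] * 5

    def test_identical_sequences_cluster_together(self):
        recs = _recs(["ACGTACGTA", "ACGTACGTA", "TTTTTTTTT", "GGGGGGGGG"])
        part = make_partition(recs, k=2, method="clustered", seed=0)
        assert part.fold_of_record[0] == part.fold_of_record[1]

    def test_clustered_matches_all_pairs_common_substring_oracle(self):
        """Cluster memberships equal brute-force single linkage over pairs
        sharing an identical subsequence of length >= 8."""
        seqs = [
            "ACDEFGHIKLMN",  # shares ACDEFGHI with the next
            "ACDEFGHIWWWW",
            "WWWWACDEFGHI",  # shares ACDEFGHI too -> one cluster of 3
            "MNPQRSTVWYAC",
            "YYMNPQRSTVWY",  # shares MNPQRSTV with previous
            "CCCCCCCCCCCC",
            "DDDDDDDDDDDD",
            "EEEEEEEEEEEE",
            "FFFFFFFFFFFF",
            "GGGGGGGGGGGG",
            "HHHHHHHHHHHH",
            "KKKKKKKKKKKK",
        ]
        recs = _recs(seqs)
        part = make_partition(recs, k=3, method="clustered", seed=0, similarity_threshold=8)

        def share(a, b, k=8):
            subs = {a[i : i + k] for i in range(len(a) - k + 1)}
            return any(b[i : i + k] in subs for i in range(len(b) - k + 1))

        # brute-force single linkage
        n = len(seqs)
        comp = list(range(n))
        changed = True
        while changed:
            changed = False
            for i, j in itertools.combinations(range(n), 2):
                if share(seqs[i], seqs[j]) and comp[i] != comp[j]:
                    tgt, src = min(comp[i], comp[j]), max(comp[i], comp[j])
                    comp = [tgt if c == src else c for c in comp]
                    changed = True
        for i, j in itertools.combinations(range(n), 2):
            same_cluster = comp[i] == comp[j]
            same_fold = part.fold_of_record[i] == part.fold_of_record[j]
            if same_cluster:
                assert same_fold  # clusters never split across folds
        assert len(set(part.fold_of_record)) == 3

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            make_partition(_recs(["AAAA"] * 3), k=5)
        with pytest.raises(ValidationError):
            make_partition(_recs(["AAAA"] * 10), k=1)


class TestRegressionMetrics:
    def test_matches_textbook_definitions_on_printed_vectors(self):
        """RMSE/PCC/SRC recomputed from first principles (explicit rank
        transform with midranks for ties)."""
        t = np.array([0.1, 0.4, 0.4, 0.8, 0.9, 0.3])
        p = np.array([0.2, 0.3, 0.5, 0.7, 0.85, 0.35])
        m = regression_metrics(t, p)
        rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(t, p)) / len(t))

        def pearson(x, y):
            mx, my = sum(x) / len(x), sum(y) / len(y)
            num = sum((a - mx) * (b - my) for a, b in zip(x, y))
            den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
            return num / den

        def midranks(x):
            order = sorted(range(len(x)), key=lambda i: x[i])
            ranks = [0.0] * len(x)
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                    j += 1
                for k in range(i, j + 1):
                    ranks[order[k]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        assert m["rmse"] == pytest.approx(rmse, abs=1e-12)
        assert m["pcc"] == pytest.approx(pearson(t, p), abs=1e-12)
        assert m["src"] == pytest.approx(pearson(midranks(t), midranks(p)), abs=1e-12)

    def test_perfect_predictions(self):
        t = np.array([0.1, 0.5, 0.9])
        m = regression_metrics(t, t)
        assert (m["rmse"], m["pcc"], m["src"]) == (0.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_constant_predictions_flagged_as_degenerate(self):
        m = regression_metrics(np.array([0.1, 0.5]), np.array([0.3, 0.3]))
        assert m["pcc"] == 0.0 and m["src"] == 0.0 and m["degenerate"]


class TestRunCv:
    def test_every_record_predicted_exactly_once(self, dna, fast_config):
        rng = np.random.default_rng(5)
        recs = [
            LigandRecord("".join(rng.choice(list("ACGT"), 8)), float(rng.uniform()))
            for _ in range(30)
        ]
        scheme = EncodingScheme("sparse", dna, motif_length=5)
        part = make_partition(recs, 3, "random", seed=1)
        report, model = run_cv(recs, scheme, IndelPolicy(), fast_config, part)
        assert len(report.predictions) == 30
        assert np.isfinite(report.predictions).all()
        assert sorted(report.record_indices) == list(range(30))
        assert len(model.members) == 3  # one member per fold here

    def test_unalignable_records_get_fallback_predictions(self, dna, fast_config):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(28)] + ["ACG", "ACG"]
        recs = [LigandRecord(s, float(rng.uniform())) for s in seqs]
        scheme = EncodingScheme("sparse", dna, motif_length=5)
        part = make_partition(recs, 3, "random", seed=1)
        report, _ = run_cv(recs, scheme, IndelPolicy(), fast_config, part)
        assert report.n_unalignable == 2
        assert len(report.predictions) == 30
        assert np.isfinite(report.predictions).all()

    def test_scan_rejects_empty_interval(self, dna, fast_config):
        recs = _recs(["ACGTACGT"] * 10)
        part = make_partition(recs, 2, "random", seed=0)
        scheme = EncodingScheme("sparse", dna, motif_length=5)
        with pytest.raises(ValidationError):
            scan_motif_lengths(recs, (8, 6), scheme, IndelPolicy(), fast_config, part)

    def test_pan_specific_requires_resolvable_receptors(self, dna, fast_config):
        from motifcore import ReceptorTable

        recs = [LigandRecord("ACGTACGT", 0.5, receptor_name="R9")] * 10
        table = ReceptorTable({"R1": "ACGT"})
        scheme = EncodingScheme("sparse", dna, motif_length=5, pseudo_length=4)
        part = make_partition(recs, 2, "random", seed=0)
        with pytest.raises(ValidationError, match="R9"):
            run_cv(recs, scheme, IndelPolicy(), fast_config, part, receptor_table=table)
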