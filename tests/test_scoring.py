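"""CNR, BTIF and PAS: hand-worked examples, oracle equivalence, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from pascore import (
    ArrRole,
    BTIFConfig,
    CNRTable,
    ExpressionMatrix,
    Pathway,
    PathwayActivationScorer,
    PathwayDB,
    ScoringError,
    compute_btif,
    compute_cnr,
    compute_pas,
    score_matrix,
)
from pascore.scoring import default_floor, pas_sum


def _em(values, genes, samples, controls=()):
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples),
        control_ids=controls,
    )


def _cnr_table(genes, samples, log_cnr, btif=None):
    log_cnr = pd.DataFrame(log_cnr, index=genes, columns=samples, dtype=float)
    return CNRTable(
        genes=list(genes),
        case_samples=list(samples),
        cnr=10.0 ** log_cnr,
        log_cnr=log_cnr,
        btif=None if btif is None else pd.DataFrame(btif, index=genes, columns=samples),
    )


def pas_oracle(db, cnr):
    """Naive triple loop over pathways, case samples and member genes."""
    out = {}
    for pathway in db:
        for s_idx, sample in enumerate(cnr.case_samples):
            total = 0.0
            for gene, role in pathway.members.items():
                if gene in cnr.genes:
                    g_idx = cnr.genes.index(gene)
                    total += (
                        float(role)
                        * float(cnr.btif.iloc[g_idx, s_idx])
                        * float(cnr.log_cnr.iloc[g_idx, s_idx])
                    )
            out[(pathway.id, sample)] = total
    return out


class TestComputeCNR:
    def test_hand_ratio(self):
        case = _em([[10.0]], ["G"], ["S1"])
        controls = _em([[4.0, 6.0]], ["G"], ["C1", "C2"])
        t = compute_cnr(case, controls, floor=1e-6)
        assert t.cnr.iloc[0, 0] == pytest.approx(2.0)
        assert t.log_cnr.iloc[0, 0] == pytest.approx(math.log10(2.0))

    def test_case_equal_to_control_mean(self):
        case = _em([[5.0]], ["G"], ["S1"])
        controls = _em([[4.0, 6.0]], ["G"], ["C1", "C2"])
        t = compute_cnr(case, controls, floor=1e-6)
        assert t.cnr.iloc[0, 0] == pytest.approx(1.0)
        assert t.log_cnr.iloc[0, 0] == pytest.approx(0.0)

    def test_both_floored(self):
        case = _em([[0.0]], ["G"], ["S1"])
        controls = _em([[0.0, 0.0]], ["G"], ["C1", "C2"])
        t = compute_cnr(case, controls, floor=0.01)
        assert t.cnr.iloc[0, 0] == 1.0
        assert t.log_cnr.iloc[0, 0] == 0.0

    def test_log_cnr_recomputable(self, rng):
        case = _em(rng.lognormal(2, 1, (6, 3)), [f"G{i}" for i in range(6)], list("XYZ"))
        controls = _em(
            rng.lognormal(2, 1, (6, 4)), [f"G{i}" for i in range(6)], list("ABCD")
        )
        t = compute_cnr(case, controls)
        np.testing.assert_allclose(t.log_cnr, np.log10(t.cnr), atol=1e-12)
        assert (t.cnr.to_numpy() > 0).all()

    def test_gene_mismatch_rejected(self):
        case = _em([[1.0]], ["G1"], ["S1"])
        controls = _em([[1.0, 1.0]], ["G2"], ["C1", "C2"])
        with pytest.raises(ScoringError, match="gene set"):
            compute_cnr(case, controls)

    def test_nonpositive_floor_rejected(self):
        case = _em([[1.0]], ["G"], ["S1"])
        controls = _em([[1.0, 1.0]], ["G"], ["C1", "C2"])
        with pytest.raises(ScoringError, match="floor"):
            compute_cnr(case, controls, floor=0.0)

    def test_geometric_control_average(self):
        case = _em([[10.0]], ["G"], ["S1"])
        controls = _em([[1.0, 100.0]], ["G"], ["C1", "C2"])
        arith = compute_cnr(case, controls, floor=1e-6)
        geo = compute_cnr(case, controls, floor=1e-6, control_average="geometric")
        assert arith.cnr.iloc[0, 0] == pytest.approx(10.0 / 50.5)
        assert geo.cnr.iloc[0, 0] == pytest.approx(1.0)  # geometric mean = 10

    def test_default_floor_is_relative_to_median(self):
        values = np.array([[0.0, 10.0, 1000.0]])
        assert default_floor(values) == pytest.approx(1e-6 * 505.0)


class TestComputeBTIF:
    @staticmethod
    def _setup(case_log10):
        controls = _em(
            [[10**5.0, 10**5.1, 10**4.9]], ["G"], ["C1", "C2", "C3"]
        )
        case = _em([[10**case_log10]], ["G"], ["S1"])
        cnr = compute_cnr(case, controls, floor=1e-6)
        return case, controls, cnr

    def test_inside_interval_not_flagged(self):
        case, controls, cnr = self._setup(5.05)
        t = compute_btif(case, controls, cnr, BTIFConfig(z_threshold=1.96), floor=1e-6)
        assert t.btif.iloc[0, 0] == 0  # |0.05| < 1.96 * 0.1

    def test_outside_interval_flagged(self):
        case, controls, cnr = self._setup(6.0)
        t = compute_btif(case, controls, cnr, BTIFConfig(z_threshold=1.96), floor=1e-6)
        assert t.btif.iloc[0, 0] == 1  # |1.0| > 0.196

    def test_min_fold_gate_vetoes(self):
        # far outside the tolerance interval, but under a 2-fold change
        controls = _em([[100.0, 100.2, 99.8]], ["G"], ["C1", "C2", "C3"])
        case = _em([[100.0 * 10**0.1]], ["G"], ["S1"])
        cnr = compute_cnr(case, controls, floor=1e-6)
        gated = compute_btif(
            case, controls, cnr, BTIFConfig(z_threshold=1.96, min_fold=2.0), floor=1e-6
        )
        ungated = compute_btif(
            case, controls, cnr, BTIFConfig(z_threshold=1.96), floor=1e-6
        )
        assert ungated.btif.iloc[0, 0] == 1
        assert gated.btif.iloc[0, 0] == 0

    def test_constant_controls_flag_iff_different(self):
        controls = _em([[7.0, 7.0], [7.0, 7.0]], ["G1", "G2"], ["C1", "C2"])
        case = _em([[7.0], [9.0]], ["G1", "G2"], ["S1"])
        cnr = compute_cnr(case, controls, floor=1e-6)
        t = compute_btif(case, controls, cnr, floor=1e-6)
        assert t.btif["S1"].tolist() == [0, 1]

    def test_single_control_requires_all_on_mode(self):
        controls = _em([[5.0]], ["G"], ["C1"])
        case = _em([[10.0]], ["G"], ["S1"])
        cnr = compute_cnr(case, controls, floor=1e-6)
        with pytest.raises(ScoringError, match="btif_all_on"):
            compute_btif(case, controls, cnr, floor=1e-6)
        t = compute_btif(case, controls, cnr, floor=1e-6, all_on=True)
        assert (t.btif.to_numpy() == 1).all()

    @pytest.mark.parametrize("bad", [dict(z_threshold=0.0), dict(min_fold=0.5)])
    def test_config_validation(self, bad):
        with pytest.raises(ScoringError):
            BTIFConfig(**bad)


class TestComputePAS:
    def test_hand_worked_example(self):
        db = PathwayDB(
            pathways=[
                Pathway(
                    id="P",
                    name="x",
                    members={"A": ArrRole(1.0), "B": ArrRole(-1.0), "C": ArrRole(0.5)},
                )
            ]
        )
        cnr = _cnr_table(
            ["A", "B", "C"], ["S1"], [[1.0], [-1.0], [2.0]], btif=[[1], [1], [0]]
        )
        pas = compute_pas(cnr, db)
        assert pas.pas.loc["P", "S1"] == pytest.approx(2.0)
        assert pas.n_contributing.loc["P", "S1"] == 2

    def test_all_flags_zero_gives_zero(self):
        db = PathwayDB(pathways=[Pathway(id="P", name="x", members={"A": 1.0})])
        cnr = _cnr_table(["A"], ["S1"], [[3.0]], btif=[[0]])
        pas = compute_pas(cnr, db)
        assert pas.pas.loc["P", "S1"] == 0.0
        assert pas.n_contributing.loc["P", "S1"] == 0

    def test_zero_weight_member_never_contributes(self, rng):
        base = {"A": ArrRole(1.0)}
        with_zero = {"A": ArrRole(1.0), "Z": ArrRole(0.0)}
        log_cnr = [[1.7], [rng.normal()]]
        cnr = _cnr_table(["A", "Z"], ["S1"], log_cnr, btif=[[1], [1]])
        p1 = compute_pas(cnr, PathwayDB(pathways=[Pathway(id="P", name="x", members=base)]))
        p2 = compute_pas(
            cnr, PathwayDB(pathways=[Pathway(id="P", name="x", members=with_zero)])
        )
        assert p1.pas.loc["P", "S1"] == p2.pas.loc["P", "S1"]

    def test_member_absent_from_data_contributes_zero(self):
        db = PathwayDB(
            pathways=[Pathway(id="P", name="x", members={"A": 1.0, "MISSING": -1.0})]
        )
        cnr = _cnr_table(["A"], ["S1"], [[1.5]], btif=[[1]])
        assert compute_pas(cnr, db).pas.loc["P", "S1"] == pytest.approx(1.5)

    def test_pathway_with_no_genes_in_data_scores_zero(self, caplog):
        db = PathwayDB(pathways=[Pathway(id="P", name="x", members={"NOPE": 1.0})])
        cnr = _cnr_table(["A"], ["S1"], [[1.0]], btif=[[1]])
        with caplog.at_level("WARNING"):
            pas = compute_pas(cnr, db)
        assert pas.pas.loc["P", "S1"] == 0.0
        assert any("no member genes" in r.message for r in caplog.records)

    def test_unfilled_btif_rejected(self):
        db = PathwayDB(pathways=[Pathway(id="P", name="x", members={"A": 1.0})])
        cnr = _cnr_table(["A"], ["S1"], [[1.0]])
        with pytest.raises(ScoringError, match="BTIF"):
            compute_pas(cnr, db)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(25):
            genes = [f"G{i}" for i in range(rng.integers(3, 10))]
            samples = [f"S{j}" for j in range(rng.integers(1, 4))]
            db = PathwayDB(
                pathways=[
                    Pathway(
                        id=f"P{k}",
                        name="x",
                        members={
                            g: ArrRole(rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0]))
                            for g in rng.choice(
                                genes + ["ABSENT"],
                                size=rng.integers(1, len(genes) + 1),
                                replace=False,
                            )
                        },
                    )
                    for k in range(rng.integers(1, 5))
                ]
            )
            cnr = _cnr_table(
                genes,
                samples,
                rng.normal(0, 2, (len(genes), len(samples))),
                btif=rng.integers(0, 2, (len(genes), len(samples))),
            )
            expected = pas_oracle(db, cnr)
            pas = compute_pas(cnr, db)
            for (pid, s), v in expected.items():
                assert pas.pas.loc[pid, s] == pytest.approx(v, abs=1e-12)

    def test_invariant_under_gene_row_permutation(self, rng):
        genes = [f"G{i}" for i in range(6)]
        db = PathwayDB(
            pathways=[Pathway(id="P", name="x", members={g: 1.0 for g in genes[:4]})]
        )
        log_cnr = rng.normal(0, 1, (6, 2))
        btif = rng.integers(0, 2, (6, 2))
        cnr = _cnr_table(genes, ["S1", "S2"], log_cnr, btif=btif)
        perm = rng.permutation(6)
        cnr_p = _cnr_table(
            [genes[i] for i in perm], ["S1", "S2"], log_cnr[perm], btif=btif[perm]
        )
        pd.testing.assert_frame_equal(
            compute_pas(cnr, db).pas, compute_pas(cnr_p, db).pas
        )

    def test_linearity_split_additivity(self, rng):
        genes = [f"G{i}" for i in range(8)]
        members = {g: ArrRole(rng.choice([-1.0, 1.0, 0.5])) for g in genes}
        half1 = dict(list(members.items())[:4])
        half2 = dict(list(members.items())[4:])
        cnr = _cnr_table(
            genes, ["S1"], rng.normal(0, 1, (8, 1)), btif=rng.integers(0, 2, (8, 1))
        )
        full = compute_pas(
            cnr, PathwayDB(pathways=[Pathway(id="P", name="x", members=members)])
        )
        parts = compute_pas(
            cnr,
            PathwayDB(
                pathways=[
                    Pathway(id="P1", name="x", members=half1),
                    Pathway(id="P2", name="x", members=half2),
                ]
            ),
        )
        assert full.pas.loc["P", "S1"] == pytest.approx(
            parts.pas.loc["P1", "S1"] + parts.pas.loc["P2", "S1"], abs=1e-12
        )

    def test_duplicated_member_list_doubles_the_sum(self):
        terms = [(1.0, 1, 1.0), (-1.0, 1, -1.0), (0.5, 0, 2.0)]
        assert pas_sum(terms) == 2.0
        assert pas_sum(terms + terms) == 2 * pas_sum(terms)

    def test_sign_convention(self):
        """Up-regulated activators push PAS positive; up-regulated repressors negative."""
        activators = PathwayDB(
            pathways=[Pathway(id="P", name="x", members={"A": 1.0, "B": 1.0})]
        )
        repressors = PathwayDB(
            pathways=[Pathway(id="P", name="x", members={"A": -1.0, "B": -1.0})]
        )
        cnr = _cnr_table(["A", "B"], ["S1"], [[0.8], [1.2]], btif=[[1], [1]])
        assert compute_pas(cnr, activators).pas.loc["P", "S1"] > 0
        assert compute_pas(cnr, repressors).pas.loc["P", "S1"] < 0


class TestScorerEstimator:
    def test_sklearn_contract(self, tiny_db):
        from sklearn.base import clone

        scorer = PathwayActivationScorer(pathways=tiny_db, z_threshold=2.5)
        params = scorer.get_params()
        assert params["z_threshold"] == 2.5
        clone(scorer)
        scorer.set_params(min_fold=2.0)
        assert scorer.min_fold == 2.0

    def test_unfitted_raises(self, tiny_db):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            PathwayActivationScorer(pathways=tiny_db).transform(
                pd.DataFrame([[1.0]], columns=["EGFR"])
            )

    def test_fit_transform_matches_functional_path(self, tiny_db, tiny_expression):
        cnr, pas = score_matrix(tiny_expression, tiny_db, floor=1e-6)
        scorer = PathwayActivationScorer(pathways=tiny_db, floor=1e-6).fit(
            tiny_expression.controls_frame().T
        )
        est = scorer.transform(tiny_expression.cases_frame().T)
        np.testing.assert_allclose(est.to_numpy().T, pas.pas.to_numpy())
        counts = scorer.contributing_counts(tiny_expression.cases_frame().T)
        np.testing.assert_array_equal(
            counts.to_numpy().T, pas.n_contributing.to_numpy()
        )

    def test_mismatched_gene_order_rejected(self, tiny_db, tiny_expression):
        scorer = PathwayActivationScorer(pathways=tiny_db).fit(
            tiny_expression.controls_frame().T
        )
        shuffled = tiny_expression.cases_frame().T[
            list(reversed(tiny_expression.genes))
        ]
        with pytest.raises(ScoringError, match="gene set"):
            scorer.transform(shuffled)

    def test_no_db_means_no_transform(self, tiny_expression):
        scorer = PathwayActivationScorer().fit(tiny_expression.controls_frame().T)
        with pytest.raises(ScoringError, match="PathwayDB"):
            scorer.transform(tiny_expression.cases_frame().T)


class TestScoreMatrix:
    def test_n_contributing_zero_implies_pas_zero(self, tiny_db, tiny_expression):
        _, pas = score_matrix(tiny_expression, tiny_db)
        zero_mask = pas.n_contributing.to_numpy() == 0
        assert (pas.pas.to_numpy()[zero_mask] == 0).all()

    def test_requires_controls_and_cases(self, tiny_db, tiny_expression):
        from dataclasses import replace

        with pytest.raises(ScoringError, match="control"):
            score_matrix(replace(tiny_expression, control_ids=()), tiny_db)
        all_controls = replace(
            tiny_expression, control_ids=tuple(tiny_expression.samples)
        )
        with pytest.raises(ScoringError, match="case"):
            score_matrix(all_controls, tiny_db)
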