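"""Aligned-rank-transform ANOVA: alignment algebra, tests, post hoc."""

import numpy as np
import pandas as pd
import pytest

import predfr as pf
from predfr.art import AlignedRankANOVA, FactorialObservation, align_responses


def toy_2x2():
    """Additive 2x2 layout: responses {A1B1: 1,2; A1B2: 3,4; A2B1: 5,6; A2B2: 7,8}."""
    cells = [("A1", "B1", (1, 2)), ("A1", "B2", (3, 4)),
             ("A2", "B1", (5, 6)), ("A2", "B2", (7, 8))]
    return [
        FactorialObservation(a, b, y) for a, b, ys in cells for y in ys
    ]


class TestAlignment:
    def test_interaction_alignment_is_residuals(self):
        """Additive toy: interaction estimate 0 everywhere, aligned = +/-0.5."""
        aligned = align_responses(toy_2x2(), "AxB")
        assert aligned.tolist() == [-0.5, 0.5] * 4

    def test_constant_response_aligns_to_zero(self):
        obs = [FactorialObservation(a, b, 3.0)
               for a in ("A1", "A2") for b in ("B1", "B2") for _ in range(3)]
        for effect in ("A", "B", "AxB"):
            assert np.allclose(align_responses(obs, effect), 0.0)

    def test_aligned_values_sum_to_zero(self):
        rng = np.random.default_rng(0)
        obs = [
            FactorialObservation(a, b, rng.poisson(3))
            for a in ("A1", "A2", "A3") for b in ("B1", "B2") for _ in range(5)
        ]
        for effect in ("A", "B", "AxB"):
            assert abs(align_responses(obs, effect).sum()) < 1e-9

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            align_responses(toy_2x2(), "C")

    def test_empty_cell_error_names_cell(self):
        obs = [FactorialObservation("A1", "B1", 1.0),
               FactorialObservation("A1", "B2", 2.0),
               FactorialObservation("A2", "B1", 3.0)]
        with pytest.raises(ValueError, match="A2.*B2"):
            align_responses(obs, "A")


class TestArtAnova:
    def test_additive_toy_interaction_F_zero(self):
        res = pf.art_anova(toy_2x2())
        assert res.effects["AxB"].F == 0.0
        assert res.effects["AxB"].p == 1.0

    def test_constant_response_degenerate_convention(self):
        obs = [FactorialObservation(a, b, 2.0)
               for a in ("A1", "A2") for b in ("B1", "B2") for _ in range(3)]
        res = pf.art_anova(obs)
        for t in res.effects.values():
            assert t.F == 0.0
            assert t.p == 1.0

    def test_study_design_degrees_of_freedom(self, nochoice_frame):
        """4x2 factorial with 10 replicates per cell: df = (3, 1, 3) over 72."""
        res = pf.art_anova(nochoice_frame)
        assert (res.effects["A"].df_num, res.effects["A"].df_den) == (3, 72)
        assert (res.effects["B"].df_num, res.effects["B"].df_den) == (1, 72)
        assert (res.effects["AxB"].df_num, res.effects["AxB"].df_den) == (3, 72)

    def test_stripped_anova_diagnostic(self, nochoice_frame):
        """Plain ANOVA on aligned responses: F ~ 0 for every non-target effect."""
        res = pf.art_anova(nochoice_frame)
        for target, others in res.diagnostics["stripped_F"].items():
            for other, F in others.items():
                assert F == pytest.approx(0.0, abs=1e-8), (target, other)
        assert res.diagnostics["aligned_sum_max"] < 1e-8

    def test_rank_data_equals_parametric_anova_on_ranks(self):
        """Tie-free rank-valued additive data with a null B margin: ART F for A
        equals the parametric two-way F on the raw ranks."""
        cells = [("A1", "B1", (1, 4)), ("A1", "B2", (2, 3)),
                 ("A2", "B1", (5, 8)), ("A2", "B2", (6, 7))]
        obs = [FactorialObservation(a, b, y) for a, b, ys in cells for y in ys]
        art = pf.art_anova(obs)
        from predfr.art import _Layout, _anova_on
        layout = _Layout(obs)
        parametric = _anova_on(layout, layout.y)
        assert art.effects["A"].F == pytest.approx(parametric["A"].F, rel=1e-10)

    def test_permutation_invariance(self, nochoice_frame):
        res1 = pf.art_anova(nochoice_frame)
        shuffled = nochoice_frame.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        res2 = pf.art_anova(shuffled)
        for effect in ("A", "B", "AxB"):
            assert res1.effects[effect].F == pytest.approx(
                res2.effects[effect].F, rel=1e-10
            )
            assert res1.effects[effect].p == pytest.approx(
                res2.effects[effect].p, rel=1e-10
            )

    def test_unbalanced_design_runs(self, nochoice_frame):
        res = pf.art_anova(nochoice_frame.iloc[:-1])
        assert res.effects["A"].df_den == 71
        assert 0.0 <= res.effects["A"].p <= 1.0

    def test_too_few_observations_rejected(self):
        obs = [FactorialObservation(a, b, float(i))
               for i, (a, b) in enumerate(
                   [("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2")])]
        with pytest.raises(ValueError):
            pf.art_anova(obs)


@pytest.fixture(scope="module")
def dominant_species_frame():
    """One species consumes heavily; the other three do not consume at all."""
    rng = np.random.default_rng(8)
    rows = []
    for sp in ("dom", "sp2", "sp3", "sp4"):
        for stage in ("I", "II"):
            for _ in range(10):
                y = rng.binomial(5, 0.6 if sp == "dom" else 0.0)
                rows.append({"factor_A": sp, "factor_B": stage, "response": y})
    return pd.DataFrame(rows)


class TestPosthoc:
    def test_dominant_species_pattern(self, dominant_species_frame):
        ph = pf.art_posthoc(dominant_species_frame, "A")
        dom = ph[(ph.level_1 == "dom") | (ph.level_2 == "dom")]
        rest = ph[(ph.level_1 != "dom") & (ph.level_2 != "dom")]
        assert (dom.p_adj < 0.05).all()
        assert (rest.p_adj > 0.99).all()

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(9)
        rows = [
            {"factor_A": sp, "factor_B": st, "response": y}
            for sp in ("s1", "s2")
            for st in ("I", "II")
            for y in rng.permutation([0, 1, 2, 3, 4])
        ]
        ph = pf.art_posthoc(pd.DataFrame(rows), "A")
        assert (ph.p_adj > 0.5).all()

    def test_holm_at_least_raw(self, nochoice_frame):
        ph = pf.art_posthoc(nochoice_frame, "A", adjustment="holm")
        assert (ph.p_adj >= ph.p_raw - 1e-12).all()

    def test_interaction_cell_contrasts(self, nochoice_frame):
        ph = pf.art_posthoc(nochoice_frame, "AxB")
        assert len(ph) == 8 * 7 // 2
        assert (ph.p_adj <= 1.0).all()

    def test_unknown_adjustment_rejected(self, nochoice_frame):
        with pytest.raises(ValueError, match="adjustment"):
            pf.art_posthoc(nochoice_frame, "A", adjustment="bonferroni-ish")


def test_null_type_I_error_calibrated():
    """On i.i.d. binomial null data the ART tests reject near the nominal 5%.

    400 simulated 4x2x10 datasets; the tolerance is 3 binomial MC standard
    errors around 0.05.
    """
    rng = np.random.default_rng(123)
    fa = np.repeat(["s1", "s2", "s3", "s4"], 20)
    fb = np.tile(np.repeat(["I", "II"], 10), 4)
    nsim = 400
    rejections = {"A": 0, "B": 0, "AxB": 0}
    for _ in range(nsim):
        y = rng.binomial(5, 0.3, size=80).astype(float)
        res = AlignedRankANOVA(
            pd.DataFrame({"factor_A": fa, "factor_B": fb, "response": y})
        ).fit()
        for k, t in res.effects.items():
            rejections[k] += t.p < 0.05
    tol = 3 * np.sqrt(0.05 * 0.95 / nsim)
    for effect, count in rejections.items():
        assert abs(count / nsim - 0.05) < tol, (effect, count / nsim)
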