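"""Grading from high-confidence findings and Bayesian fracture retrieval."""

import numpy as np
import pytest

from tilegrade.bayes import (
    AGE_NODE,
    CPDTable,
    Inference,
    NetworkSpec,
    TileGrade,
    default_structure,
)
from tilegrade.fusion import Thresholds
from tilegrade.records import FRACTURE_TYPES, FractureType
from tilegrade.refinement import candidate_probabilities, initial_grade, refine
from tilegrade.synthetic import default_generator_cpds

from oracles_util import enumeration_marginal

PSD = FractureType.PSD
SI_DIV = FractureType.SI_ANTERIOR_DIVERGENT


def _evidence(positives, age60=False):
    ev = {t.value: (t in positives) for t in FRACTURE_TYPES}
    ev[AGE_NODE] = age60
    return ev


class TestInitialGrade:
    def test_no_findings_young_patient_grades_A(self, spec, gen_cpds):
        p_R, p_T, grade = initial_grade(spec, gen_cpds, frozenset(), age60=False)
        assert p_R < 0.5 and p_T < 0.5
        assert grade is TileGrade.A

    def test_posteriors_match_enumeration(self, spec, gen_cpds):
        fx_high = {PSD, FractureType.SACRAL_DIASTATIC}
        p_R, p_T, _ = initial_grade(spec, gen_cpds, fx_high, age60=False)
        ev = _evidence(fx_high)
        assert p_R == pytest.approx(enumeration_marginal(spec, gen_cpds, ev, "R"), abs=1e-9)
        assert p_T == pytest.approx(enumeration_marginal(spec, gen_cpds, ev, "T"), abs=1e-9)

    def test_posteriors_in_unit_interval(self, spec, gen_cpds, rng):
        for _ in range(10):
            fx = {t for t in FRACTURE_TYPES if rng.random() < 0.4}
            p_R, p_T, _ = initial_grade(spec, gen_cpds, fx, age60=bool(rng.integers(2)))
            assert 0.0 <= p_R <= 1.0 and 0.0 <= p_T <= 1.0

    def test_heavy_findings_grade_C(self, spec, gen_cpds):
        fx = {PSD, FractureType.SI_PARALLEL, FractureType.SACRAL_DIASTATIC}
        _, p_T, grade = initial_grade(spec, gen_cpds, fx, age60=True)
        assert p_T >= 0.5
        assert grade is TileGrade.C


class TestCandidateProbabilities:
    def test_candidate_independent_of_evidence_gets_prior(self):
        # two independent roots: evidence on one cannot move the other
        spec = NetworkSpec(("psd", "ring_fx"), frozenset())
        cpds = {
            "psd": CPDTable("psd", (), np.array(0.2)),
            "ring_fx": CPDTable("ring_fx", (), np.array(0.7)),
        }
        q = candidate_probabilities(spec, cpds, {"psd": True}, {FractureType.RING_FX})
        assert q[FractureType.RING_FX] == pytest.approx(0.7)

    def test_deterministic_forcing_gives_one(self, spec):
        cpds = default_generator_cpds(spec)
        forced = dict(cpds)
        # si_anterior_divergent forced whenever R=1
        forced[SI_DIV.value] = CPDTable(
            SI_DIV.value, spec.parents(SI_DIV.value), np.array([[0.0, 0.0], [1.0, 1.0]])
        )
        # psd present only under R=1 -> evidence forces R=1
        forced[PSD.value] = CPDTable(
            PSD.value, spec.parents(PSD.value), np.array([[0.0, 0.0], [1.0, 1.0]])
        )
        ev = _evidence({PSD})
        del ev[SI_DIV.value]
        ev_with = {**ev, SI_DIV.value: False}
        q = candidate_probabilities(spec, forced, ev_with, {SI_DIV})
        assert q[SI_DIV] == pytest.approx(1.0)

    def test_matches_enumeration(self, spec, gen_cpds, rng):
        for _ in range(10):
            positives = {t for t in FRACTURE_TYPES if rng.random() < 0.3}
            candidates = {t for t in FRACTURE_TYPES if t not in positives and rng.random() < 0.5}
            ev = _evidence(positives, age60=bool(rng.integers(2)))
            q = candidate_probabilities(spec, gen_cpds, ev, candidates)
            for t, val in q.items():
                loo = {k: v for k, v in ev.items() if k != t.value}
                assert val == pytest.approx(
                    enumeration_marginal(spec, gen_cpds, loo, t.value), abs=1e-9
                )

    def test_positive_candidate_rejected(self, spec, gen_cpds):
        with pytest.raises(ValueError, match="already positive"):
            candidate_probabilities(spec, gen_cpds, _evidence({PSD}), {PSD})


class TestRefine:
    def test_equal_sets_reduce_to_initial_grade(self, spec, gen_cpds):
        fx = frozenset({PSD})
        res = refine(spec, gen_cpds, fx, fx, False, Thresholds())
        p_R, p_T, grade = initial_grade(spec, gen_cpds, fx, False)
        assert res.added == ()
        assert res.p_R_final == pytest.approx(p_R)
        assert res.p_T_final == pytest.approx(p_T)
        assert res.tile_final is grade

    def test_retrieval_raises_rotational_posterior(self, spec):
        cpds = default_generator_cpds(spec)
        # make the R-specific finding strongly co-occur with any R evidence
        cpds = {
            **cpds,
            SI_DIV.value: CPDTable(
                SI_DIV.value, spec.parents(SI_DIV.value),
                np.array([[0.01, 0.01], [0.95, 0.95]]),
            ),
            PSD.value: CPDTable(
                PSD.value, spec.parents(PSD.value),
                np.array([[0.01, 0.3], [0.9, 0.9]]),
            ),
        }
        res = refine(
            spec, cpds,
            fx_high=frozenset({PSD}),
            fx_low=frozenset({PSD, SI_DIV}),
            age60=False,
            thresholds=Thresholds(z_star=0.5),
        )
        assert [t for t, _ in res.added] == [SI_DIV]
        assert all(q >= 0.5 for _, q in res.added)
        assert res.p_R_final > res.p_R_initial

    def test_monotone_initial_subset_of_final(self, spec, gen_cpds, rng):
        for _ in range(25):
            low = frozenset(t for t in FRACTURE_TYPES if rng.random() < 0.6)
            high = frozenset(t for t in low if rng.random() < 0.5)
            res = refine(spec, gen_cpds, high, low, bool(rng.integers(2)), Thresholds())
            initial_pos = {k for k, v in res.initial_evidence.items() if v and k != AGE_NODE}
            final_pos = {k for k, v in res.final_evidence.items() if v and k != AGE_NODE}
            assert initial_pos <= final_pos
            assert {t.value for t, _ in res.added} == final_pos - initial_pos
            assert {t for t, _ in res.added} <= low - high

    def test_unreachable_z_star_adds_nothing(self, spec, gen_cpds):
        res = refine(
            spec, gen_cpds,
            frozenset(), frozenset(FRACTURE_TYPES), False,
            Thresholds(z_star=1.0 + 1e-12),
        )
        assert res.added == ()
        assert res.p_R_final == res.p_R_initial

    def test_deterministic_and_order_independent(self, spec, gen_cpds):
        high = frozenset({PSD})
        low = frozenset(FRACTURE_TYPES)
        a = refine(spec, gen_cpds, high, low, True, Thresholds(z_star=0.3))
        b = refine(spec, gen_cpds, high, low, True, Thresholds(z_star=0.3))
        assert a == b

    def test_additions_logged_with_probability_at_time_of_addition(self, spec, gen_cpds):
        res = refine(spec, gen_cpds, frozenset({PSD, FractureType.SI_PARALLEL}),
                     frozenset(FRACTURE_TYPES), True, Thresholds(z_star=0.3))
        for t, q in res.added:
            assert 0.3 <= q <= 1.0

    def test_high_not_subset_of_low_rejected(self, spec, gen_cpds):
        with pytest.raises(ValueError, match="subset"):
            refine(spec, gen_cpds, frozenset({PSD}), frozenset(), False, Thresholds())

    def test_terminates_within_seven_additions_randomised(self, rng):
        from oracles_util import random_boolean_dag  # noqa: F401  (structure fixed here)

        spec = default_structure()
        for _ in range(50):
            # random CPDs on the clinical structure
            cpds = {}
            for node in spec.nodes:
                parents = spec.parents(node)
                shape = (2,) * len(parents)
                p1 = 0.05 + 0.9 * rng.random(shape)
                cpds[node] = CPDTable(node, parents, p1 if parents else np.array(float(p1)))
            low = frozenset(t for t in FRACTURE_TYPES if rng.random() < 0.7)
            high = frozenset(t for t in low if rng.random() < 0.4)
            res = refine(spec, cpds, high, low, bool(rng.integers(2)),
                         Thresholds(z_star=float(rng.uniform(0.2, 0.9))))
            assert len(res.added) <= 7
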