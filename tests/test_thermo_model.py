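"""Occupancy ensemble, quenching, long-range repression, and rate law."""

import numpy as np
import pytest

from crmdecode.sequence_sites import BindingSite, CRMRecord
from crmdecode.thermo_model import (
    Cooperativity,
    OracleSizeError,
    TFSpec,
    ThermoModelSpec,
    ValidationError,
    enumerate_configurations,
    interaction_strength,
    predict_construct,
    predict_mutant_series,
    site_occupancies,
    transcription_rate,
)

from conftest import random_matrix


def make_site(tf, start, length=6, q=1.0):
    return BindingSite(tf, start, start + length, "+", "A" * length, q, 0.0)


def simple_spec(theta=2.0, conditions=None, tfs=None):
    if tfs is None:
        tfs = (
            TFSpec("Act", "activator", activation_efficiency=1.0),
            TFSpec(
                "Rep",
                "repressor",
                quenching_efficiency=1.0,
                longrange_efficiency=0.5,
            ),
        )
    if conditions is None:
        conditions = {"base": {tf.name: 1.0 for tf in tfs}}
    return ThermoModelSpec(tfs=tfs, theta=theta, conditions=conditions)


def random_instance(rng, n_sites, tf_names=("Act", "Rep")):
    """Random overlapping/non-overlapping site layout for oracle checks."""
    sites = []
    pos = 0
    for _ in range(n_sites):
        pos += int(rng.integers(0, 12))  # gaps of 0 allow overlaps
        length = int(rng.integers(4, 9))
        tf = tf_names[int(rng.integers(0, len(tf_names)))]
        sites.append(make_site(tf, pos, length, q=float(rng.uniform(0.05, 1.0))))
        pos += int(rng.integers(1, length))  # next may overlap current
    sites.sort(key=lambda s: s.start)
    return sites


class TestEnumeration:
    def test_zero_sites_single_empty_configuration(self):
        spec = simple_spec()
        configs = enumerate_configurations([], spec, "base")
        assert len(configs) == 1
        assert configs[0].bound == () and configs[0].weight == 1.0

    def test_two_overlapping_sites_exclusion(self):
        spec = simple_spec()
        sites = [make_site("Act", 0), make_site("Act", 3)]
        configs = enumerate_configurations(sites, spec, "base")
        assert sorted(c.bound for c in configs) == [(), (0,), (1,)]

    def test_three_disjoint_sites_power_set(self):
        spec = simple_spec()
        sites = [make_site("Act", i * 10) for i in range(3)]
        assert len(enumerate_configurations(sites, spec, "base")) == 8

    def test_oracle_guard(self):
        spec = simple_spec()
        sites = [make_site("Act", i * 10) for i in range(23)]
        with pytest.raises(OracleSizeError):
            enumerate_configurations(sites, spec, "base")


class TestOccupancy:
    def test_single_site_half_occupied_at_unit_weight(self):
        spec = simple_spec()
        occ = site_occupancies([make_site("Act", 0, q=1.0)], spec, "base")
        assert occ.occupancies[0] == pytest.approx(0.5)

    def test_two_overlapping_unit_sites_one_third(self):
        spec = simple_spec()
        sites = [make_site("Act", 0), make_site("Act", 3)]
        occ = site_occupancies(sites, spec, "base")
        assert occ.occupancies == pytest.approx((1 / 3, 1 / 3))

    def test_zero_concentration_zero_occupancy(self):
        spec = simple_spec(conditions={"off": {"Act": 0.0, "Rep": 1.0}})
        sites = [make_site("Act", 0), make_site("Rep", 10)]
        occ = site_occupancies(sites, spec, "off")
        assert occ.occupancies[0] == 0.0
        assert occ.occupancies[1] == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        spec = simple_spec(conditions={"bad": {"Act": -1.0, "Rep": 1.0}})
        with pytest.raises(ValidationError):
            site_occupancies([make_site("Act", 0)], spec, "bad")

    @pytest.mark.parametrize("seed", range(40))
    def test_dp_matches_enumeration(self, seed):
        """DP occupancies equal the brute-force ensemble on random layouts."""
        rng = np.random.default_rng(seed)
        spec = simple_spec(
            conditions={"c": {"Act": float(rng.uniform(0.1, 3)), "Rep": float(rng.uniform(0.1, 3))}}
        )
        sites = random_instance(rng, int(rng.integers(1, 11)))
        occ = site_occupancies(sites, spec, "c")
        configs = enumerate_configurations(sites, spec, "c")
        z = sum(c.weight for c in configs)
        for i in range(len(sites)):
            brute = sum(c.weight for c in configs if i in c.bound) / z
            assert occ.occupancies[i] == pytest.approx(brute, abs=1e-10)

    def test_configuration_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        spec = simple_spec()
        sites = random_instance(rng, 6)
        configs = enumerate_configurations(sites, spec, "base")
        z = sum(c.weight for c in configs)
        assert sum(c.weight / z for c in configs) == pytest.approx(1.0)

    def test_cooperativity_boosts_adjacent_pair(self):
        tfs = (
            TFSpec(
                "Act",
                "activator",
                cooperativity=Cooperativity(partner="Act", omega=5.0, max_gap=20),
            ),
        )
        spec = ThermoModelSpec(tfs=tfs, theta=2.0, conditions={"c": {"Act": 1.0}})
        sites = [make_site("Act", 0), make_site("Act", 10)]
        occ = site_occupancies(sites, spec, "c")
        configs = enumerate_configurations(sites, spec, "c")
        z = sum(c.weight for c in configs)
        pair = [c for c in configs if c.bound == (0, 1)][0]
        assert pair.weight == pytest.approx(5.0)  # 1 * 1 * omega
        assert occ.occupancies[0] == pytest.approx((1 + 5) / (1 + 1 + 1 + 5))


class TestInteractionStrength:
    def test_weighted_sum_without_repressors(self):
        spec = simple_spec()
        sites = [make_site("Act", 0), make_site("Act", 300)]
        occ_half = type(site_occupancies(sites, spec, "base"))(
            condition="base", occupancies=(0.5, 0.5)
        )
        e, e_post, prof = interaction_strength(occ_half, sites, spec)
        assert e == pytest.approx(1.0)
        assert e_post == pytest.approx(e)
        assert prof.repressor_activity == {}

    def test_quenching_within_range_single_factor(self):
        spec = simple_spec()
        sites = [make_site("Act", 0), make_site("Rep", 56)]  # gap 50bp
        occ = type(site_occupancies(sites, spec, "base"))(
            condition="base", occupancies=(0.8, 0.5)
        )
        e, e_post, prof = interaction_strength(occ, sites, spec)
        assert prof.activator_activity[0] == pytest.approx(0.8 * 0.5)  # (1-1*0.5)
        assert e == pytest.approx(0.4)
        # beta_R = 0.5, O = 0.5 -> long-range factor 0.75
        assert e_post == pytest.approx(0.4 * 0.75)

    def test_quenching_beyond_range_inactive(self):
        spec = simple_spec()
        sites = [make_site("Act", 0, 6), make_site("Rep", 157)]  # gap 151 bp
        occ = type(site_occupancies(sites, spec, "base"))(
            condition="base", occupancies=(0.8, 0.9)
        )
        e, e_post, _ = interaction_strength(occ, sites, spec)
        assert e == pytest.approx(0.8)  # no quenching
        assert e_post == pytest.approx(0.8 * (1 - 0.5 * 0.9))

    def test_full_dominant_repression(self):
        tfs = (
            TFSpec("Act", "activator"),
            TFSpec("Rep", "repressor", longrange_efficiency=1.0),
        )
        spec = simple_spec(tfs=tfs)
        sites = [make_site("Act", 0), make_site("Rep", 500)]
        occ = type(site_occupancies(sites, spec, "base"))(
            condition="base", occupancies=(1.0, 1.0)
        )
        _, e_post, _ = interaction_strength(occ, sites, spec)
        assert e_post == 0.0


class TestRateLaw:
    def test_basal_and_saturated_rates(self):
        spec = simple_spec(theta=2.0)
        assert transcription_rate(0.0, spec) == pytest.approx(np.exp(-2.0))
        assert transcription_rate(2.0, spec) == pytest.approx(1.0)
        assert transcription_rate(5.0, spec) == pytest.approx(1.0)

    def test_strictly_increasing_below_barrier(self):
        spec = simple_spec(theta=3.0)
        grid = np.linspace(0, 3, 50)
        rates = [transcription_rate(e, spec) for e in grid]
        assert all(b > a for a, b in zip(rates, rates[1:]))


def _two_tf_setup(rng):
    act = random_matrix(rng, "Act", 6)
    rep = random_matrix(rng, "Rep", 6)
    from crmdecode.synthetic_data import simulate_crm

    promoter, _ = simulate_crm(
        60, [(act, 20, "+")], seed=1, crm_id="prom", role="promoter"
    )
    return act, rep, promoter


class TestPredict:
    def test_promoter_only_fold_is_one(self):
        rng = np.random.default_rng(3)
        act, rep, promoter = _two_tf_setup(rng)
        spec = simple_spec()
        pred = predict_construct(promoter, None, spec, [act, rep], "base")
        assert pred.fold_vs_promoter_only == pytest.approx(1.0)

    def test_activator_distal_fold_at_least_one(self):
        rng = np.random.default_rng(4)
        act, rep, promoter = _two_tf_setup(rng)
        from crmdecode.synthetic_data import simulate_crm

        distal, _ = simulate_crm(80, [(act, 10, "+"), (act, 40, "+")], seed=2)
        spec = simple_spec()
        pred = predict_construct(promoter, distal, spec, [act, rep], "base")
        assert pred.fold_vs_promoter_only >= 1.0

    def test_repressor_only_distal_fold_at_most_one(self):
        rng = np.random.default_rng(5)
        act, rep, promoter = _two_tf_setup(rng)
        from crmdecode.synthetic_data import simulate_crm

        distal, _ = simulate_crm(80, [(rep, 10, "+"), (rep, 40, "+")], seed=3)
        spec = simple_spec()
        with_d = predict_construct(promoter, distal, spec, [act, rep], "base")
        assert with_d.fold_vs_promoter_only <= 1.0

    def test_missing_condition_is_validation_error(self):
        rng = np.random.default_rng(6)
        act, rep, promoter = _two_tf_setup(rng)
        spec = simple_spec()
        with pytest.raises(ValidationError):
            predict_construct(promoter, None, spec, [act, rep], "nonesuch")

    def test_mutant_series_monotonicity_and_promoter_reduction(self):
        """Killing the activator site lowers the fold; killing every distal
        site reduces the construct to the promoter-only baseline."""
        rng = np.random.default_rng(7)
        act, rep, promoter = _two_tf_setup(rng)
        from crmdecode.sequence_sites import (
            apply_mutation_plan,
            design_site_mutation,
            scan_sites,
        )
        from crmdecode.synthetic_data import simulate_crm

        distal, _ = simulate_crm(90, [(act, 30, "+")], seed=4, crm_id="wt")
        sites = [
            s for s in scan_sites(distal, [act, rep], 0.01) if s.tf_name == "Act"
        ]
        target = [s for s in sites if s.start == 30][0]
        plan = design_site_mutation(distal, target, [act, rep], 0.01)
        mutant = apply_mutation_plan(distal, plan)
        spec = simple_spec()
        folds = predict_mutant_series(
            [("wt", promoter, distal), ("m1", promoter, mutant)],
            spec,
            [act, rep],
            ["base"],
        )
        wt = folds[folds.construct == "wt"]["fold"].iloc[0]
        m1 = folds[folds.construct == "m1"]["fold"].iloc[0]
        assert m1 <= wt
        if not scan_sites(mutant, [act, rep], 0.01):
            assert m1 == pytest.approx(1.0)

    def test_site_deletion_equals_site_removal(self):
        """Ablating a site by mutation matches dropping it from the site
        list when the mutation creates no new sites."""
        rng = np.random.default_rng(8)
        act, rep, promoter = _two_tf_setup(rng)
        from crmdecode.sequence_sites import (
            apply_mutation_plan,
            design_site_mutation,
            scan_sites,
        )
        from crmdecode.thermo_model import (
            assemble_construct,
            site_occupancies as occ_fn,
        )
        from crmdecode.synthetic_data import simulate_crm

        distal, _ = simulate_crm(100, [(act, 20, "+"), (rep, 60, "+")], seed=5)
        spec = simple_spec()
        construct = assemble_construct(promoter, distal, 200)
        sites = scan_sites(construct, [act, rep], 0.01)
        target = [s for s in sites if s.tf_name == "Rep"][-1]

        # route 1: mutate the distal CRM, re-run the full chain
        d_target = [
            s for s in scan_sites(distal, [act, rep], 0.01) if s.tf_name == "Rep"
        ][-1]
        plan = design_site_mutation(distal, d_target, [act, rep], 0.01)
        mutant = apply_mutation_plan(distal, plan)
        pred_mut = predict_construct(
            promoter, mutant, spec, [act, rep], "base", spacer_bp=200
        )
        # route 2: drop the site from the wildtype list
        kept = [s for s in sites if s.key != target.key]
        occ = occ_fn(kept, spec, "base")
        e, e_post, _ = interaction_strength(occ, kept, spec)
        rate_removed = transcription_rate(e_post, spec)
        prom_pred = predict_construct(
            promoter, None, spec, [act, rep], "base", spacer_bp=200
        )
        fold_removed = rate_removed / prom_pred.rate
        assert pred_mut.fold_vs_promoter_only == pytest.approx(
            fold_removed, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_concentration_monotonicity(self, seed):
        """More activator never lowers the rate; more repressor never
        raises it."""
        rng = np.random.default_rng(seed)
        spec_lo = simple_spec(conditions={"c": {"Act": 1.0, "Rep": 1.0}})
        spec_hi_act = simple_spec(conditions={"c": {"Act": 2.5, "Rep": 1.0}})
        spec_hi_rep = simple_spec(conditions={"c": {"Act": 1.0, "Rep": 2.5}})
        sites = random_instance(rng, int(rng.integers(2, 8)))

        def rate(spec):
            occ = site_occupancies(sites, spec, "c")
            _, e_post, _ = interaction_strength(occ, sites, spec)
            return transcription_rate(e_post, spec)

        assert rate(spec_hi_act) >= rate(spec_lo) - 1e-12
        assert rate(spec_hi_rep) <= rate(spec_lo) + 1e-12
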