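import numpy as np
import pytest

from steppekit.arrival_model import ArrivalParams, model_curve
from steppekit.io_tables import MISSING
from steppekit.mismatch import pairwise_mismatch_matrix
from steppekit.synthetic_data import (
    PedigreeSpec,
    SimulationConfig,
    kinship_coefficient,
    simulate_cohort,
    simulate_diversity_cohort,
    simulate_genotypes,
    simulate_pedigree,
    three_generation_pedigree,
    true_degree,
)

TRUTH = ArrivalParams(p0=0.1, pe=0.8, te=2750.0)


def cohort_arrays(cfg):
    records, observations, truth = simulate_cohort(cfg)
    props = np.array([observations[r.id].steppe_prop for r in records])
    dates = np.array([truth[r.id] for r in records])
    return records, props, dates


class TestCohort:
    def test_noise_free_observations_lie_on_model_curve(self):
        cfg = SimulationConfig(
            n_individuals=80, noise_sd=0.0, zero_ancestry_fraction=0.0,
            true_params=TRUTH, seed=1,
        )
        _, props, dates = cohort_arrays(cfg)
        np.testing.assert_allclose(props, model_curve(dates, TRUTH), atol=1e-12)

    def test_pre_arrival_individuals_have_zero_ancestry(self):
        cfg = SimulationConfig(
            n_individuals=60, noise_sd=0.0, zero_ancestry_fraction=0.0,
            true_params=TRUTH, seed=2,
        )
        _, props, dates = cohort_arrays(cfg)
        assert (props[dates > TRUTH.te] == 0.0).all()
        assert (props[dates < TRUTH.te] > 0.0).all()

    def test_residual_sd_matches_configured_noise(self):
        # law-of-large-numbers check on the truncated-resampling noise
        cfg = SimulationConfig(
            n_individuals=10_000, noise_sd=0.05, zero_ancestry_fraction=0.0,
            true_params=TRUTH, seed=3,
        )
        _, props, dates = cohort_arrays(cfg)
        resid = props - np.asarray(model_curve(dates, TRUTH))
        # restrict to observations away from the [0,1] bounds, where
        # truncation does not reshape the noise
        mid = (props > 0.15) & (props < 0.85) & (dates < TRUTH.te)
        assert 0.045 <= resid[mid].std() <= 0.055

    def test_reported_interval_contains_true_date_and_props_bounded(self):
        cfg = SimulationConfig(n_individuals=200, seed=4)
        records, observations, truth = simulate_cohort(cfg)
        for r in records:
            assert r.date.contains(truth[r.id])
            assert 0.0 <= observations[r.id].steppe_prop <= 1.0

    def test_zero_ancestry_individuals_are_female_biased(self):
        cfg = SimulationConfig(
            n_individuals=400, zero_ancestry_fraction=0.3, seed=5
        )
        records, observations, truth = simulate_cohort(cfg)
        zeros = [
            r for r in records
            if observations[r.id].steppe_prop == 0.0 and truth[r.id] < cfg.true_params.te
        ]
        assert len(zeros) > 10
        female_frac = np.mean([r.sex == "female" for r in zeros])
        assert female_frac > 0.7

    def test_cohort_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_individuals=50, seed=6)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]


class TestGenotypes:
    def test_null_cohort_mismatch_matches_analytic_expectation(self):
        """With everyone from one pool, E[pairwise mismatch] = mean 2p(1-p)."""
        cfg = SimulationConfig(
            n_individuals=20, n_snps=20_000, n_x_snps=0, fst_sources=0.0,
            missing_rate=0.0, noise_sd=0.0, zero_ancestry_fraction=0.0,
            true_params=ArrivalParams(0.1, 0.8, 100.0),  # everyone pre-arrival
            date_span=(4800.0, 3000.0), seed=7,
        )
        records, observations, _ = simulate_cohort(cfg)
        assert all(o.steppe_prop == 0.0 for o in observations.values())
        g, bk = simulate_genotypes(cfg, observations)
        mism, nov = pairwise_mismatch_matrix(g, chroms="all")
        iu = np.triu_indices(g.n_individuals, 1)
        observed = (mism[iu] / nov[iu]).mean()
        expected = np.mean(2.0 * bk.pool_neolithic * (1.0 - bk.pool_neolithic))
        assert abs(observed - expected) < 0.005

    def test_full_missingness(self):
        cfg = SimulationConfig(n_individuals=5, n_snps=100, n_x_snps=10,
                               missing_rate=1.0, seed=8)
        _, observations, _ = simulate_cohort(cfg)
        g, _ = simulate_genotypes(cfg, observations)
        assert (g.calls == MISSING).all()

    def test_male_bias_shifts_x_source_fraction(self):
        cfg = SimulationConfig(n_individuals=60, n_snps=2000, n_x_snps=500,
                               male_admixture_bias=0.4, seed=9)
        _, observations, _ = simulate_cohort(cfg)
        g, bk = simulate_genotypes(cfg, observations)
        assert bk.mean_steppe_fraction_auto > bk.mean_steppe_fraction_x
        # bookkeeping matches the realized source draws
        is_x = g.is_x
        assert bk.source[:, ~is_x].mean() > bk.source[:, is_x].mean()

    def test_genotypes_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(n_individuals=10, n_snps=500, n_x_snps=50, seed=10)
        _, observations, _ = simulate_cohort(cfg)
        g1, _ = simulate_genotypes(cfg, observations)
        g2, _ = simulate_genotypes(cfg, observations)
        assert g1 == g2


class TestDiversityCohort:
    def test_gap_is_injected_exactly_in_expectation(self):
        g, records = simulate_diversity_cohort(8, 8, 30_000, mismatch_gap=0.009, seed=11)
        mism, nov = pairwise_mismatch_matrix(g, chroms="all")
        ids = np.array(g.individuals)
        before = np.flatnonzero(np.char.startswith(ids, "B"))
        after = np.flatnonzero(np.char.startswith(ids, "A"))
        def group_mean(rows):
            iu = [(i, j) for i in rows for j in rows if i < j]
            return np.mean([mism[i, j] / nov[i, j] for i, j in iu])
        observed_gap = group_mean(after) - group_mean(before)
        assert abs(observed_gap - 0.009) < 0.003


@pytest.fixture(scope="module")
def ped():
    rng = np.random.default_rng(0)
    pool = rng.uniform(0.1, 0.9, 30_000)
    spec = three_generation_pedigree(n_unrelated=4)
    spec = PedigreeSpec(
        sexes={**spec.sexes, "TWIN": "male"},
        parents=dict(spec.parents),
        clones={"TWIN": "S"},
    )
    return simulate_pedigree(pool, spec, missing_rate=0.0, seed=42)


class TestPedigree:
    def rate(self, ped, a, b):
        g = ped.genotypes
        mism, nov = pairwise_mismatch_matrix(g, chroms="all")
        i, j = g.index_of(a), g.index_of(b)
        return mism[i, j] / nov[i, j]

    def test_relative_mismatch_ratios_match_allele_draw_enumeration(self, ped):
        """Enumerating pseudo-haploid draws: identical genomes halve the
        unrelated mismatch rate, one shared IBD allele scales it by 3/4."""
        unrelated = np.mean(
            [self.rate(ped, "U0", u) for u in ("U1", "U2", "U3")]
        )
        parent_offspring = self.rate(ped, "F", "S")
        twins = self.rate(ped, "TWIN", "S")
        assert abs(parent_offspring / unrelated - 0.75) < 0.03
        assert abs(twins / unrelated - 0.5) < 0.03

    def test_uniparental_labels_follow_transmission_lines(self, ped):
        assert ped.mt_labels["S"] == ped.mt_labels["M"]  # maternal line
        assert ped.mt_labels["D"] == ped.mt_labels["M"]
        assert ped.mt_labels["F"] == ped.mt_labels["GM"]
        assert ped.y_labels["S"] == ped.y_labels["F"] == ped.y_labels["GF"]
        assert ped.y_labels["D"] is None

    def test_truth_degrees_from_kinship_coefficients(self, ped):
        t = ped.truth_degrees
        assert t[frozenset(("F", "S"))] == "first"
        assert t[frozenset(("S", "D"))] == "first"  # full siblings
        assert t[frozenset(("GF", "S"))] == "second"  # grandparent
        assert t[frozenset(("AUNT", "S"))] == "second"  # avuncular
        assert t[frozenset(("U0", "S"))] == "unrelated"
        assert t[frozenset(("TWIN", "S"))] == "identical"

    def test_kinship_coefficient_values(self):
        spec = three_generation_pedigree(n_unrelated=0)
        phi = {frozenset(k): v for k, v in kinship_coefficient(spec).items()}
        assert phi[frozenset(("F", "S"))] == pytest.approx(0.25)
        assert phi[frozenset(("S", "D"))] == pytest.approx(0.25)
        assert phi[frozenset(("GF", "S"))] == pytest.approx(0.125)
        assert phi[frozenset(("GF", "M"))] == 0.0
        assert true_degree(0.25) == "first"
        assert true_degree(0.125) == "second"

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PedigreeSpec(
                sexes={"A": "male", "B": "female", "C": "male"},
                parents={"A": ("C", "B"), "C": ("A", "B")},
            )

    def test_father_must_be_male(self):
        with pytest.raises(ValueError, match="not male"):
            PedigreeSpec(
                sexes={"A": "female", "B": "female", "C": "male"},
                parents={"C": ("A", "B")},
            )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_individuals": 0},
        {"date_span": (1700.0, 4800.0)},
        {"noise_sd": -0.1},
        {"missing_rate": 1.5},
        {"fst_sources": 1.0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)
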