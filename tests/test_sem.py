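import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from soilnet.errors import DataError, SpecificationError
from soilnet.sem import (
    CHEM_MEDIATORS,
    ContributionLedger,
    FittedPathModel,
    PathSpec,
    aicc,
    backward_eliminate,
    count_sem_models,
    dsep_basis_set,
    fishers_c,
    fit_equation,
    relative_contributions,
    evaluate_claims,
)


class TestFishersC:
    def test_all_ones_gives_zero(self):
        assert fishers_c([1.0, 1.0]) == (0.0, 4, 1.0)

    def test_hand_value(self):
        c, df, p = fishers_c([0.05, 0.05])
        assert c == pytest.approx(11.983, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0175, abs=1e-4)

    def test_empty_set_saturated(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = rng.uniform(0.01, 1.0, size=5)
            c0, *_ = fishers_c(ps)
            i = rng.integers(5)
            ps[i] *= 0.5
            c1, *_ = fishers_c(ps)
            assert c1 > c0

    def test_out_of_range_raises(self):
        with pytest.raises(DataError):
            fishers_c([1.5])


class TestAicc:
    def test_hand_correction(self):
        # n=10, k=3: correction = 2*3*4/6 = 4
        assert aicc(0.0, 10, 3) == pytest.approx(-0.0 + 6 + 4.0)

    def test_large_n_limit(self):
        assert aicc(-50.0, 10**6, 3) - (100 + 6) < 0.01

    def test_zero_params_no_correction(self):
        assert aicc(-10.0, 50, 0) == pytest.approx(20.0)

    def test_always_at_least_aic(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 100))
            k = int(rng.integers(0, n - 2))
            ll = float(rng.normal(scale=20))
            assert aicc(ll, n, k) >= -2 * ll + 2 * k

    def test_undefined_raises(self):
        with pytest.raises(DataError):
            aicc(0.0, 4, 3)


class TestBasisSet:
    def test_saturated_dag_empty(self):
        nodes = ["a", "b", "c"]
        edges = [("a", "b"), ("a", "c"), ("b", "c")]
        assert dsep_basis_set(nodes, edges) == []

    def test_chain(self):
        claims = dsep_basis_set(["A", "B", "C"], [("A", "B"), ("B", "C")])
        assert claims == [("A", "C", ("B",))]

    def test_common_effect_exogenous_pair(self):
        claims = dsep_basis_set(["A", "B", "C"], [("A", "C"), ("B", "C")])
        assert claims == [("A", "B", ())]

    def test_cyclic_raises(self):
        with pytest.raises(SpecificationError):
            dsep_basis_set(["a", "b"], [("a", "b"), ("b", "a")])

    def test_matches_brute_force_dsep_on_small_dags(self):
        """Every claim in the basis set is a true d-separation, and the
        number of claims equals the number of missing edges, on all DAGs over
        <= 5 nodes from a random family."""
        rng = np.random.default_rng(2)
        nodes = list("abcde")
        for trial in range(30):
            edges = [
                (nodes[i], nodes[j])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            claims = dsep_basis_set(nodes, edges)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            n_missing = 10 - len(edges)
            assert len(claims) == n_missing
            for x, y, cond in claims:
                assert nx.is_d_separator(g, {x}, {y}, set(cond))


class TestFitEquation:
    def test_copy_predictor_beta_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        data = pd.DataFrame({"y": x, "x": x, "z": rng.normal(size=40)})
        fit = fit_equation(data, "y", ["x", "z"], transform="none")
        assert fit.beta["x"] == pytest.approx(1.0, abs=1e-6)
        assert abs(fit.beta["z"]) < 1e-6

    def test_single_predictor_beta_is_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        data = pd.DataFrame({"y": y, "x": x})
        fit = fit_equation(data, "y", ["x"], transform="none")
        assert fit.beta["x"] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_standardized_recovery(self):
        """y = 0.6 x1 + 0.3 x2 + noise: mean estimated betas match the
        analytically standardized truth within 0.05."""
        b1, b2, sd = 0.6, 0.3, 0.2
        sigma_y = np.sqrt(b1**2 + b2**2 + sd**2)
        betas = []
        rng = np.random.default_rng(5)
        for _ in range(300):
            x1 = rng.normal(size=30)
            x2 = rng.normal(size=30)
            y = b1 * x1 + b2 * x2 + rng.normal(0, sd, 30)
            data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            fit = fit_equation(data, "y", ["x1", "x2"], transform="none")
            betas.append([fit.beta["x1"], fit.beta["x2"]])
        mean = np.mean(betas, axis=0)
        assert mean[0] == pytest.approx(b1 / sigma_y, abs=0.05)
        assert mean[1] == pytest.approx(b2 / sigma_y, abs=0.05)

    def test_collinear_raises(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        data = pd.DataFrame({"y": rng.normal(size=30), "a": x, "b": 2 * x})
        with pytest.raises(DataError, match="collinear"):
            fit_equation(data, "y", ["a", "b"], transform="none")

    def test_too_small_n_raises(self):
        data = pd.DataFrame(np.random.default_rng(7).normal(size=(5, 4)),
                            columns=list("yabc"))
        with pytest.raises(DataError):
            fit_equation(data, "y", ["a", "b", "c"], transform="none")


def simple_spec(response="m", extra_noise=False):
    plant = ["productivity", "diversity"]
    mediators = ["total_n", "ph"]
    edges = [("productivity", "total_n"), ("diversity", "ph"),
             ("total_n", response), ("ph", response)]
    if extra_noise:
        plant = plant + ["axis1"]
        edges = edges + [("axis1", response)]
    return PathSpec(plant_vars=plant, mediators=mediators, response=response,
                    edges=edges, grouping="sowing_density")


def simulate_chain(n=30, seed=0, noise=0.3, strong=0.7):
    rng = np.random.default_rng(seed)
    productivity = rng.normal(size=n)
    diversity = rng.normal(size=n)
    axis1 = rng.normal(size=n)
    total_n = strong * productivity + noise * rng.normal(size=n)
    ph = strong * diversity + noise * rng.normal(size=n)
    m = strong * total_n + strong * ph + noise * rng.normal(size=n)
    return pd.DataFrame({
        "productivity": productivity, "diversity": diversity, "axis1": axis1,
        "total_n": total_n, "ph": ph, "m": m,
        "sowing_density": ["low", "mid", "high"] * (n // 3),
    })


class TestBackwardElimination:
    def test_strong_model_keeps_all_edges(self):
        kept_all = 0
        for s in range(10):
            data = simulate_chain(seed=s)
            model = backward_eliminate(simple_spec(), data, transform="none",
                                       compute_dsep=False)
            kept_all += set(model.edges) == set(simple_spec().edges)
        assert kept_all >= 9

    def test_noise_predictor_removed(self):
        removed = 0
        for s in range(10):
            data = simulate_chain(seed=100 + s)
            spec = simple_spec(extra_noise=True)
            model = backward_eliminate(spec, data, transform="none",
                                       compute_dsep=False)
            removed += ("axis1", "m") not in model.edges
        assert removed >= 9

    def test_empty_candidate_set(self):
        data = simulate_chain(seed=1)
        spec = PathSpec(plant_vars=["productivity"], mediators=["total_n"],
                        response=None, edges=[], grouping="sowing_density")
        model = backward_eliminate(spec, data, transform="none",
                                   compute_dsep=False)
        assert model.edges == []
        assert len(model.history) == 1

    def test_history_records_every_step(self):
        data = simulate_chain(seed=2)
        spec = simple_spec()
        model = backward_eliminate(spec, data, transform="none",
                                   compute_dsep=False)
        assert model.history[0][1] is None
        assert len(model.history) == len(spec.edges) + 1
        assert all(np.isfinite(h[2]) for h in model.history)

    def test_dsep_on_true_model_accepts(self):
        accepted = 0
        for s in range(5):
            data = simulate_chain(seed=200 + s, n=60)
            model = backward_eliminate(simple_spec(), data, transform="none")
            accepted += model.model_p > 0.1
        assert accepted >= 3  # true structure should usually fit


class TestModelCounting:
    def test_paper_shaped_inventory(self):
        inventory = {
            "natural": {"biomass": 3, "prok_clusters": 9, "fungal_clusters": 21},
            "abandoned": {"biomass": 3, "prok_clusters": 10, "fungal_clusters": 18},
        }
        assert count_sem_models(inventory) == 64

    def test_small_inventory(self):
        inventory = {
            "natural": {"clusters": 2, "biomass": 1},
            "abandoned": {"clusters": 2, "biomass": 1},
        }
        assert count_sem_models(inventory) == 6


class TestContributions:
    def make_model(self, spec, edges, betas, ps):
        eqs = {}
        by_resp = {}
        for (s, d) in edges:
            by_resp.setdefault(d, []).append(s)
        from soilnet.sem import EquationFit

        for resp, preds in by_resp.items():
            eqs[resp] = EquationFit(
                response=resp, predictors=preds,
                beta=pd.Series({p: betas[(p, resp)] for p in preds}),
                se=pd.Series({p: 0.1 for p in preds}),
                p=pd.Series({p: ps[(p, resp)] for p in preds}),
                n=30, loglik=0.0, k_params=2, aicc=0.0, transform="none",
                mixed=False,
            )
        return FittedPathModel(
            spec=spec, edges=edges, equations=eqs, claims=[], fisher_c=0.0,
            df=0, model_p=1.0, aicc=0.0, n=30, history=[],
        )

    def test_direct_arithmetic(self):
        spec = PathSpec(plant_vars=["productivity"], mediators=["total_n"],
                        response="m", edges=[("productivity", "m")])
        model = self.make_model(spec, [("productivity", "m")],
                                {("productivity", "m"): 0.5},
                                {("productivity", "m"): 0.01})
        ledger = relative_contributions({"m": model}, {"m": 0.4})
        g = ("year", "overall", "direct")
        assert ledger.raw[g] == pytest.approx(0.2)
        assert ledger.potential[g] == 1
        assert ledger.scaled[g] == pytest.approx(0.2)

    def test_indirect_arithmetic(self):
        edges = [("productivity", "total_n"), ("diversity", "total_n"),
                 ("total_n", "m")]
        spec = PathSpec(plant_vars=["productivity", "diversity"],
                        mediators=["total_n"], response="m", edges=edges)
        betas = {("productivity", "total_n"): 0.5,
                 ("diversity", "total_n"): 0.0, ("total_n", "m"): 0.4}
        ps = {("productivity", "total_n"): 0.001,
              ("diversity", "total_n"): 0.9, ("total_n", "m"): 0.001}
        model = self.make_model(spec, edges, betas, ps)
        ledger = relative_contributions({"m": model}, {"m": 0.5})
        g = ("year", "overall", "indirect")
        # one significant indirect path: |0.5 * 0.4| * 0.5 = 0.1, 2 candidates
        assert ledger.raw[g] == pytest.approx(0.1)
        assert ledger.potential[g] == 2
        assert ledger.scaled[g] == pytest.approx(0.05)

    def test_no_retained_paths_zero_ledger(self):
        spec = PathSpec(plant_vars=["productivity"], mediators=["total_n"],
                        response="m", edges=[("productivity", "m")])
        model = self.make_model(spec, [], {}, {})
        ledger = relative_contributions({"m": model}, {"m": 0.4})
        assert all(v == 0.0 for v in ledger.raw.values())

    def test_conservation(self):
        edges = [("productivity", "total_n"), ("total_n", "m"),
                 ("diversity", "m")]
        spec = PathSpec(plant_vars=["productivity", "diversity"],
                        mediators=["total_n"], response="m", edges=edges)
        betas = {("productivity", "total_n"): 0.6, ("total_n", "m"): 0.5,
                 ("diversity", "m"): -0.3}
        ps = {k: 0.001 for k in betas}
        model = self.make_model(spec, edges, betas, ps)
        ledger = relative_contributions({"m": model}, {"m": 1.0})
        raw_total = sum(ledger.raw.values())
        recon = sum(ledger.scaled[g] * ledger.potential[g]
                    for g in ContributionLedger.GROUPS)
        assert recon == pytest.approx(raw_total)

    def test_missing_size_raises(self):
        spec = PathSpec(plant_vars=["productivity"], mediators=["total_n"],
                        response="m", edges=[("productivity", "m")])
        model = self.make_model(spec, [], {}, {})
        with pytest.raises(DataError, match="size"):
            relative_contributions({"m": model}, {})
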