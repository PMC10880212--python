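"""BUM fitting, FDR thresholding and MWCS extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import brentq

from netpharm import (
    Network,
    NodeScores,
    extract_mwcs,
    fdr_threshold_tau,
    fit_bum,
    score_nodes,
    synth_bum_sample,
)
from netpharm.active_subnet import BUMFit, bum_fdr
from netpharm.exceptions import InsufficientDataError, ParameterError

from conftest import random_connected_graph


def _fit(lam=0.6, a=0.4):
    return BUMFit(lam=lam, a=a, loglik=0.0)


def test_fit_recovers_known_mixture():
    fit = fit_bum(synth_bum_sample(10_000, 0.7, 0.3, seed=42))
    assert fit.lam == pytest.approx(0.7, abs=0.05)
    assert fit.a == pytest.approx(0.3, abs=0.05)


def test_uniform_pvalues_look_all_null():
    p = np.random.default_rng(5).uniform(size=10_000)
    fit = fit_bum(p)
    assert fit.pi_upper >= 0.95


def test_degenerate_input_warns():
    with pytest.warns(UserWarning):
        fit_bum(np.full(100, 0.5))


def test_too_few_pvalues():
    with pytest.raises(InsufficientDataError):
        fit_bum(np.linspace(0.01, 0.99, 30))


def test_fit_beats_every_grid_start():
    """Returned loglik dominates the likelihood at each multi-start point."""
    p = synth_bum_sample(2000, 0.5, 0.5, seed=3)
    logp = np.log(np.clip(p, 1e-12, 1.0))
    fit = fit_bum(p)
    for lam0 in (0.15, 0.5, 0.85):
        for a0 in (0.15, 0.5, 0.85):
            ll0 = float(np.sum(np.log(lam0 + (1 - lam0) * a0 * np.exp((a0 - 1) * logp))))
            assert fit.loglik >= ll0 - 1e-9


def test_tau_round_trips_the_fdr():
    for lam, a, fdr in [(0.5, 0.5, 0.05), (0.7, 0.3, 0.05), (0.9, 0.2, 0.01)]:
        fit = _fit(lam, a)
        tau = fdr_threshold_tau(fit, fdr)
        assert bum_fdr(fit, tau) == pytest.approx(fdr, abs=1e-9)


def test_tau_closed_form_matches_bisection_oracle():
    fit = _fit(0.5, 0.5)
    tau = fdr_threshold_tau(fit, 0.05)
    tau_oracle = brentq(lambda t: bum_fdr(fit, t) - 0.05, 1e-12, 1 - 1e-12, xtol=1e-14)
    assert tau == pytest.approx(tau_oracle, abs=1e-9)


def test_tau_limits_and_validation():
    fit = _fit(0.5, 0.5)
    with pytest.warns(UserWarning):
        assert fdr_threshold_tau(fit, 1 - 1e-9) == pytest.approx(1.0)
    with pytest.raises(ParameterError):
        fdr_threshold_tau(fit, 0.0)
    # requested rate above the null fraction -> everything passes
    strong = _fit(1e-5, 1e-5)
    with pytest.warns(UserWarning):
        assert fdr_threshold_tau(strong, 0.5) == 1.0


def test_node_score_fixtures():
    fit = _fit(0.6, 0.5)
    ns = score_nodes({"A": 1.0}, fit, 0.05)
    tau = ns.tau
    ns = score_nodes({"AT_TAU": tau, "BELOW": tau / np.e, "WAY_UP": 0.9}, fit, 0.05)
    assert ns.scores["AT_TAU"] == pytest.approx(0.0, abs=1e-12)
    assert ns.scores["BELOW"] == pytest.approx(0.5)  # (a-1)*(-1) with a = 0.5
    rng = np.random.default_rng(8)
    pv = {f"G{i}": float(rng.uniform(1e-6, 1)) for i in range(200)}
    ns = score_nodes(pv, fit, 0.05)
    for g, p in pv.items():
        assert (ns.scores[g] > 0) == (p < ns.tau)


def _exhaustive_mwcs(net: Network, scores: dict[str, float]):
    """Exact optimum by enumerating every connected node subset."""
    nodes = sorted(net.nodes)
    best_score, best_set = -np.inf, None
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = net.graph.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            s = sum(scores[v] for v in subset)
            if s > best_score:
                best_score, best_set = s, set(subset)
    return best_score, best_set


def _ns(scores: dict[str, float]) -> NodeScores:
    return NodeScores(tau=0.05, scores=scores, fit=_fit())


def test_mwcs_path_fixture():
    net = Network([("A", "B"), ("B", "C")])
    sub = extract_mwcs(net, _ns({"A": 2.0, "B": -1.0, "C": 2.0}))
    assert sub.nodes == {"A", "B", "C"}
    assert sum(sub.node_scores.values()) == pytest.approx(3.0)


def test_mwcs_star_fixture():
    net = Network([("H", "L1"), ("H", "L2"), ("H", "L3")])
    sub = extract_mwcs(net, _ns({"H": -5.0, "L1": 1.0, "L2": 1.0, "L3": 1.0}))
    assert sub.nodes == {"L1"}  # connecting all would score 3 - 5 < 1


def test_mwcs_all_negative_returns_best_single_node():
    net = Network([("A", "B"), ("B", "C")])
    with pytest.warns(UserWarning):
        sub = extract_mwcs(net, _ns({"A": -3.0, "B": -1.0, "C": -2.0}))
    assert sub.nodes == {"B"}


def test_mwcs_uncovered_nodes_get_floor_score():
    net = Network([("A", "B"), ("B", "C")])
    sub = extract_mwcs(net, _ns({"A": 2.0, "C": 3.0}))  # B unscored
    assert "C" in sub.nodes


@pytest.mark.parametrize("seed", range(10))
def test_mwcs_heuristic_near_optimal_on_small_graphs(seed):
    """>= 0.8x the exhaustive optimum on random <=10-node instances;
    exact whenever positive nodes form <=2 components."""
    rng = np.random.default_rng(seed)
    net = random_connected_graph(10, 0.35, seed=seed)
    scores = {v: float(rng.normal(0, 2)) for v in sorted(net.nodes)}
    opt_score, _ = _exhaustive_mwcs(net, scores)
    sub = extract_mwcs(net, _ns(scores))
    got = sum(scores[v] for v in sub.nodes)
    assert nx.is_connected(sub.graph)
    if opt_score > 0:
        assert got >= 0.8 * opt_score - 1e-9
    else:
        assert got == pytest.approx(opt_score)
    pos = [v for v, s in scores.items() if s > 0]
    n_comp = nx.number_connected_components(net.graph.subgraph(pos)) if pos else 0
    if n_comp <= 2 and pos:
        assert got == pytest.approx(opt_score)


def test_mwcs_output_always_connected_and_dominates_singletons():
    rng = np.random.default_rng(77)
    for seed in range(10):
        net = random_connected_graph(25, 0.15, seed=seed + 100)
        scores = {v: float(rng.normal(0, 1.5)) for v in sorted(net.nodes)}
        sub = extract_mwcs(net, _ns(scores))
        assert nx.is_connected(sub.graph)
        total = sum(scores[v] for v in sub.nodes)
        assert total >= max(scores.values()) - 1e-12


def test_planted_module_recovery():
    """With a strongly perturbed dense module, the extracted subnetwork
    overlaps the planted module (Jaccard >= 0.6) in >= 90% of seeds."""
    from netpharm import SyntheticScenario, synth_module, synth_ppi, synth_pvalues

    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        sc = SyntheticScenario(seed=seed, n_nodes=150, module_size=20)
        net = synth_ppi(sc)
        module = synth_module(net, 20, sc.rng())
        pv = synth_pvalues(net, module, sc.a_signal, seed=seed + 1000)
        fit = fit_bum(list(pv.values()))
        sub = extract_mwcs(net, score_nodes(pv, fit, 0.05))
        jac = len(sub.nodes & module) / len(sub.nodes | module)
        hits += jac >= 0.6
    assert hits >= 0.9 * n_seeds
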