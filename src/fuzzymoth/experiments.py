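"""Seeded property experiments for the whole stack.

Each function runs one self-contained study on synthetic data and returns a
dictionary of scalar metrics.  They are the single source of truth for both
the acceptance test suite and the reproduction script: the same code path
produces the asserted and the reported numbers.

Problem sizes are chosen to finish on a single desktop core in minutes: the
clustering and hierarchy studies use a 12-moth, 3-group cohort with 300
records per moth; WWO training budgets are in the hundreds-to-thousands of
evaluations (the published budget of 100,000 remains available through the
configuration for full-scale runs).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import behavior, control, pfcm, pfdae, pfn as pf, synth, wwo

__all__ = ["pfn_metric_suite", "closure_suite", "wwo_sphere_study",
           "pfcm_study", "pretraining_gain_study", "denoising_study",
           "hierarchy_study", "control_study", "published_constants"]


def _random_pfns(n: int, rng: np.random.Generator) -> np.ndarray:
    return pf.arr_project_valid(rng.random((n, 4)))


def pfn_metric_suite(n: int = 10_000, seed: int = 0) -> dict:
    """Metric axioms of the Pythagorean distance on random valid PFNs plus
    the two closed-form reference values."""
    rng = np.random.default_rng(seed)
    P1, P2, P3 = (_random_pfns(n, rng) for _ in range(3))
    d12, d21 = pf.arr_pfn_distance(P1, P2), pf.arr_pfn_distance(P2, P1)
    d13, d23 = pf.arr_pfn_distance(P1, P3), pf.arr_pfn_distance(P2, P3)
    return {
        "n": n,
        "symmetry_max_abs_diff": float(np.abs(d12 - d21).max()),
        "identity_max": float(pf.arr_pfn_distance(P1, P1).max()),
        "triangle_violations": int((d12 > d13 + d23 + 1e-12).sum()),
        "range_violations": int(((d12 < 0) | (d12 > 1 + 1e-12)).sum()),
        "hand_distance_06_08": pf.pfn_distance(
            pf.make_pfn(0.6, 0.6, 0.8, 0.8), pf.make_pfn(0.8, 0.8, 0.6, 0.6)),
        "hand_distance_vertices": pf.pfn_distance(
            pf.make_pfn(1, 1, 0, 0), pf.make_pfn(0, 0, 1, 1)),
    }


def closure_suite(n: int = 10_000, seed: int = 1) -> dict:
    """Validity of the algebraic sum, scalar law and activation on random
    inputs, plus the scalar-law reference value at lambda = 1/2."""
    rng = np.random.default_rng(seed)
    P1, P2 = _random_pfns(n, rng), _random_pfns(n, rng)
    lam = rng.random(n) * 3
    half = pf.pfn_scale(0.5, pf.make_pfn(0.8, 0.8, 0.6, 0.6))
    return {
        "n": n,
        "add_violations": int((~pf.is_valid_arr(pf.arr_add(P1, P2))).sum()),
        "scale_violations": int((~pf.is_valid_arr(pf.arr_scale(lam, P1))).sum()),
        "activate_violations": int((~pf.is_valid_arr(pf.arr_activate(P1))).sum()),
        "scale_half_mu": half.mu_hi,
        "scale_half_nu": half.nu_hi,
        "scale_half_mu_err": abs(half.mu_hi - np.sqrt(0.4)),
        "scale_half_nu_err": abs(half.nu_hi - np.sqrt(0.6)),
    }


def wwo_sphere_study(dim: int = 10, budget: int = 20_000, n_seeds: int = 20,
                     seed: int = 2) -> dict:
    """WWO vs uniform random search on the sphere function at equal budget."""
    space = wwo.SearchSpace(-5.12 * np.ones(dim), 5.12 * np.ones(dim))
    sphere = lambda x: float(np.sum(x * x))   # noqa: E731
    ss = np.random.SeedSequence(seed)
    bests, wins, mono = [], 0, True
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        res = wwo.optimize(sphere, space, wwo.OptimizerConfig(budget=budget),
                           rng)
        ctrl = wwo.random_search(sphere, space, budget, rng)
        bests.append(res.fun)
        wins += res.fun < ctrl.fun
        fs = [f for _, f in res.trace]
        mono &= all(b <= a for a, b in zip(fs, fs[1:]))
    return {"n": n_seeds, "budget": budget,
            "median_best": float(np.median(bests)),
            "wins_vs_random": int(wins), "trace_monotone": bool(mono)}


def _two_group_pfns(n, sep, rng):
    labels = np.repeat([0, 1], n // 2)
    mu = 0.25 + sep * labels[:, None] + 0.05 * rng.standard_normal((n, 4))
    return pf.arr_fuzzify(np.clip(mu, 0.01, 0.99)), labels


def pfcm_study(seed: int = 3) -> dict:
    """Objective monotonicity, membership stochasticity, exact equivalence
    with crisp FCM in squared-degree coordinates, and two-sided cluster
    recovery (separated vs zero-separation data)."""
    from scipy.spatial.distance import cdist
    rng = np.random.default_rng(seed)
    trace_viol, colsum_err, equiv_diff = 0, 0.0, 0.0
    for t in range(20):
        data = pf.arr_fuzzify(rng.random((20, 4)))
        V0 = data[rng.choice(20, 3, replace=False)]
        U, V, trace = pfcm.pfcm_cluster(data, pfcm.ClusterConfig(c=3), V0=V0)
        trace_viol += sum(b > a + 1e-9 for a, b in zip(trace, trace[1:]))
        colsum_err = max(colsum_err, float(np.abs(U.sum(0) - 1).max()))
        Phi = pfcm._sq_degrees(data).reshape(20, -1)
        Vr = pfcm._sq_degrees(V0).reshape(3, -1)
        U_ref, U_prev = None, None
        Vc = Vr.copy()
        for _ in range(200):
            d2 = np.maximum(cdist(Vc, Phi, "sqeuclidean"), 1e-30)
            inv = d2 ** (-1.0)
            U_ref = inv / inv.sum(0)
            Vc = (U_ref**2 @ Phi) / (U_ref**2).sum(1)[:, None]
            if U_prev is not None and np.max(np.abs(U_ref - U_prev)) < 1e-5:
                break
            U_prev = U_ref
        equiv_diff = max(equiv_diff, float(np.abs(U - U_ref).max()))
    data_sep, labels = _two_group_pfns(60, 0.45, np.random.default_rng(seed + 1))
    km = pfcm.PythagoreanFuzzyCMeans(n_clusters=2, random_state=seed).fit(data_sep)
    ari_sep = adjusted_rand_score(labels, km.labels_)
    data_null, _ = _two_group_pfns(60, 0.0, np.random.default_rng(seed + 2))
    km0 = pfcm.PythagoreanFuzzyCMeans(n_clusters=2, random_state=seed).fit(data_null)
    ari_null = adjusted_rand_score(labels, km0.labels_)
    return {"n": 20, "trace_violations": int(trace_viol),
            "colsum_max_err": colsum_err,
            "fcm_equivalence_max_diff": equiv_diff,
            "ari_separated": float(ari_sep), "ari_null": float(ari_null)}


def _lowrank(n, rng, D=12, rank=3):
    X = rng.random((n, rank)) @ rng.random((rank, D))
    return (X - X.min()) / (X.max() - X.min())


def pretraining_gain_study(n_seeds: int = 5, budget: int = 1_500,
                           seed: int = 4) -> dict:
    """Trained single-layer reconstruction loss relative to the mean loss of
    random parameter draws, on low-rank data (D = 12, rank 3)."""
    ratios = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        X = _lowrank(200, rng)
        layer, _ = pfdae.train_layer(X, 4, budget, 0.2, rng)
        trained = pfdae.layer_loss(layer, X, 0.0)
        rand = np.mean([pfdae.layer_loss(
            pfdae.genome_to_params(rng.random(pfdae.genome_length(12, 4)),
                                   12, 4), X, 0.0) for _ in range(20)])
        ratios.append(trained / rand)
    return {"n": n_seeds, "median_loss_ratio": float(np.median(ratios)),
            "max_loss_ratio": float(np.max(ratios))}


def denoising_study(n_rep: int = 20, budget: int = 2_000,
                    seed: int = 5) -> dict:
    """Held-out reconstruction of corrupted inputs: stack pretrained with
    masking noise 0.2 versus an identically budgeted stack pretrained
    without noise, paired over seeds."""
    wins, diffs = 0, []
    ss = np.random.SeedSequence(seed)
    for k, child in enumerate(ss.spawn(n_rep)):
        rng = np.random.default_rng(child)
        Xtr, Xte = _lowrank(150, rng), _lowrank(100, rng)
        st = int(rng.integers(2**31))
        m_dn = pfdae.PFDDAE((12, 6, 4), noise_level=0.2, budget=budget,
                            random_state=st).fit(Xtr)
        m_ae = pfdae.PFDDAE((12, 6, 4), noise_level=0.0, budget=budget,
                            random_state=st).fit(Xtr)
        e_dn = m_dn.reconstruction_error(Xte, 0.2, np.random.default_rng(k),
                                         n_draws=5)
        e_ae = m_ae.reconstruction_error(Xte, 0.2, np.random.default_rng(k),
                                         n_draws=5)
        wins += e_dn < e_ae
        diffs.append(e_ae - e_dn)
    return {"n": n_rep, "denoising_wins": int(wins),
            "mean_error_gap": float(np.mean(diffs))}


def _fit_hier(records, cohort, probes, seed, n_groups=3):
    amb, stim, resp = probes
    m = behavior.HierarchicalBehaviorLearner(
        n_groups=n_groups, budget_common=160, budget_group=80,
        budget_individual=48, cluster_budget=100, random_state=seed)
    m.fit(records, shapes=cohort.shapes, probe_resp=resp, probe_amb=amb,
          probe_stim=stim)
    return m


def hierarchy_study(n_rep: int = 20, n_moths: int = 12, n_groups: int = 3,
                    records_per_moth: int = 300, seed: int = 6) -> dict:
    """Hierarchical Behavior Learner versus a depth- and parameter-matched
    monolithic fuzzy stack on held-out records, paired over seeds, plus
    group recovery from clustering the computed moth profiles."""
    amb, stim = synth.probe_settings()
    mono_widths = (80, 61, 34, 20, 12, 8, 7)
    mono_budget = 160 + n_groups * 80 + n_moths * 48
    wins, hier_errs, mono_errs, aris = 0, [], [], []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_rep):
        rng = np.random.default_rng(child)
        s = int(rng.integers(2**31))
        cohort = synth.generate_cohort(n_moths, n_groups, seed=s)
        records = synth.generate_dataset(cohort, records_per_moth, seed=s + 1)
        resp = synth.probe_responses(cohort, seed=s + 2)
        idx = rng.permutation(len(records))
        cut = int(0.8 * len(records))
        train = records.iloc[idx[:cut]]
        test = records.iloc[idx[cut:]]
        hier = _fit_hier(train, cohort, (amb, stim, resp), s, n_groups)
        mono = behavior.MonolithicBehaviorLearner(
            widths=mono_widths, budget=mono_budget, random_state=s).fit(train)
        he, me = hier.score_records(test), mono.score_records(test)
        wins += he < me
        hier_errs.append(he)
        mono_errs.append(me)
        aris.append(adjusted_rand_score(cohort.labels, hier.grouper_.labels_))
    return {"n": n_rep, "hierarchy_wins": int(wins),
            "mean_hierarchical_error": float(np.mean(hier_errs)),
            "mean_monolithic_error": float(np.mean(mono_errs)),
            "mean_grouping_ari": float(np.mean(aris))}


def control_study(n_train: int = 1_000, n_test: int = 200,
                  seed: int = 7) -> dict:
    """Closed-loop control on invertible synthetic dynamics.

    The Behavior Learner is trained on the cohort's records; the Control
    Learner is fine-tuned against the ground-truth dynamics (physical
    feedback) and evaluated on held-out maneuver instructions against the
    deterministic dynamics (primary) and the noisy dynamics and
    default-split training (secondary).  Also checks that the
    model-feedback weight drops when the Behavior Learner degrades.
    """
    rng = np.random.default_rng(seed)
    s = int(rng.integers(2**31))
    cohort = synth.generate_cohort(12, 3, seed=s)
    records = synth.generate_dataset(cohort, 150, seed=s + 1)
    resp = synth.probe_responses(cohort, seed=s + 2)
    amb, stim = synth.probe_settings()
    bm = _fit_hier(records, cohort, (amb, stim, resp), s)
    ins_tr = synth.make_instructions(cohort, n_train, seed=s + 3)
    ins_te = synth.make_instructions(cohort, n_test, seed=s + 4)
    phys = control.synthetic_responder(cohort, np.random.default_rng(s + 5))

    cl = control.ControlLearner(budget_pretrain=300, budget_finetune=1_000,
                                t_p_fraction=1.0, random_state=s)
    cl.fit(ins_tr, bm, physical_responder=phys)
    det = control.synthetic_responder(cohort, noise=False)
    noisy = control.synthetic_responder(cohort, np.random.default_rng(s + 6))
    sr_det, _ = cl.evaluate(ins_te, det)
    sr_noisy, _ = cl.evaluate(ins_te, noisy)

    # secondary: the published majority-model-feedback split
    cl_split = control.ControlLearner(budget_pretrain=300,
                                      budget_finetune=500,
                                      t_p_fraction=0.1, random_state=s)
    cl_split.fit(ins_tr, bm, physical_responder=phys)
    sr_split, _ = cl_split.evaluate(ins_te, det)

    # random-stimulus control at the same instruction set
    s_rand = 0.3 + 0.4 * np.random.default_rng(s + 7).random((n_test, 32))
    prod = det(s_rand, ins_te)
    rel = ins_te[[f"rel{i+1}" for i in range(7)]].to_numpy() > 0.5
    sr_rand, _ = control.evaluate_success_rate(
        ins_te[[f"req{i+1}" for i in range(7)]].to_numpy(), prod, rel)

    errs = list(bm.training_errors_.values())
    w_m = control.compute_wm(errs, len(ins_tr))
    w_m_degraded = control.compute_wm([e + 0.05 for e in errs], len(ins_tr))
    return {"n": n_test, "success_rate": float(sr_det),
            "success_rate_noisy_responder": float(sr_noisy),
            "success_rate_default_split": float(sr_split),
            "success_rate_random_stimuli": float(sr_rand),
            "w_m": float(w_m), "w_m_degraded": float(w_m_degraded),
            "behavior_error": float(np.mean(errs))}


def published_constants() -> dict:
    """The fixed defaults that mirror the published settings."""
    from .io import RunConfig
    cfg = RunConfig()
    return {
        "output_weight_sum": float(sum(cfg.output_weights)),
        "output_weights": list(cfg.output_weights),
        "common_widths": list(cfg.common_widths),
        "group_widths": list(cfg.group_widths),
        "individual_widths": list(cfg.individual_widths),
        "control_widths": list(cfg.control_widths),
        "n_groups": cfg.n_groups, "fuzzifier": cfg.fuzzifier,
        "step_ms": cfg.step_ms, "success_tol": cfg.success_tol,
        "wwo_budget": cfg.wwo_budget,
    }
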