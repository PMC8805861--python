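"""End-to-end validation experiments shared by the acceptance test suite and
``scripts/acceptance.py``.

Each experiment recomputes a property of the pipeline from scratch on
synthetic data with known ground truth.  Problem sizes are fixed here (they
are the package's validation conditions; see docs/methods.md): connectivity
checks run at the study's 207-time-point scale with 20 regions, the
monotonicity check runs at the study's 200-node network scale, and the
cohort-level experiments use the 15-vs-95 group design.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
from scipy.stats import fisher_exact

sys.path.insert(0, str(Path(__file__).resolve().parent))

from _oracles import (  # noqa: E402
    all_digraphs,
    bfs_distances,
    clustering_oracle,
    degrees_oracle,
    diameter_oracle,
    efficiency_oracle,
    local_efficiency_oracle,
    transitivity_oracle,
)

from dirconn.connectivity import (  # noqa: E402
    AntisymmetricCorrelation,
    LaggedCorrelation,
    SymmetricCorrelation,
    ZeroLagCorrelation,
    antisymmetric_part,
    clip_connections,
    granger_matrix,
    lagged_correlation,
    symmetric_part,
)
from dirconn.graphs import (  # noqa: E402
    default_density_grid,
    degrees,
    directed_clustering,
    directed_distances,
    global_efficiency,
    local_efficiency,
    threshold_by_density,
    transitivity,
)
from dirconn.stats import GroupPermutationTest, fdr_bh  # noqa: E402
from dirconn.synthetic import (  # noqa: E402
    _covariates,
    make_group_cohort,
    random_digraph,
    random_ground_truth,
    simulate_var,
)


def _spawn(seed: int, n: int) -> list[int]:
    """n independent child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# 1. decomposition identity
# ---------------------------------------------------------------------------


def decomposition_identity(seed: int, n_matrices: int = 100) -> dict:
    """Max entrywise |A + S - 2L| over lagged matrices of random time series."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_matrices):
        x = rng.standard_normal((20, 207))
        L = lagged_correlation(x, 1 + i % 3)
        A = antisymmetric_part(L, clip=False).weights
        S = symmetric_part(L, clip=False).weights
        worst = max(worst, float(np.abs(A + S - 2 * L.weights).max()))
    return {"max_abs_error": worst, "n": n_matrices}


# ---------------------------------------------------------------------------
# 2. lag-0 equivalence
# ---------------------------------------------------------------------------


def lag_zero_equivalence(seed: int, n_subjects: int = 10) -> dict:
    """Zero-lag vs lagged(d=0) entrywise, and binarized symmetric(d=0) vs
    binarized zero-lag networks across the density grid."""
    gt = random_ground_truth(n_regions=12, seed=seed)
    grid = default_density_grid()
    worst = 0.0
    mismatches = 0
    n_networks = 0
    for s in _spawn(seed, n_subjects):
        ts = simulate_var(gt, T=207, seed=s)
        z_raw = ZeroLagCorrelation(clip=False).fit_transform([ts.data])[0]
        l0 = LaggedCorrelation(lag=0).fit_transform([ts.data])[0]
        worst = max(worst, float(np.abs(z_raw - l0).max()))
        S = SymmetricCorrelation(lag=0).fit_transform([ts.data])[0]
        Z = ZeroLagCorrelation().fit_transform([ts.data])[0]
        for d in grid:
            try:
                a = threshold_by_density(S, float(d)).adjacency
                b = threshold_by_density(Z, float(d)).adjacency
            except ValueError:
                continue
            mismatches += int((a != b).sum())
            n_networks += 1
    return {"max_abs_error": worst, "network_mismatches": mismatches, "n": n_networks}


# ---------------------------------------------------------------------------
# 3. graph-measure oracle equivalence
# ---------------------------------------------------------------------------


def _check_graph(a: np.ndarray) -> float:
    err = 0.0
    D, diam, _ = directed_distances(a)
    Do = bfs_distances(a)
    # -1 sentinel for unreachable: also catches inf-vs-finite disagreement
    d1 = np.where(np.isinf(D), -1.0, D)
    d2 = np.where(np.isinf(Do), -1.0, Do)
    err = max(err, float(np.abs(d1 - d2).max()))
    do = diameter_oracle(a)
    if not (np.isnan(diam) and np.isnan(do)):
        err = max(err, abs(diam - do))
    d_in, d_out, _ = degrees(a)
    o_in, o_out = degrees_oracle(a)
    err = max(err, float(np.abs(d_in - o_in).max()), float(np.abs(d_out - o_out).max()))
    ge = global_efficiency(a)
    e_in, e_out, _, _, E = efficiency_oracle(a)
    err = max(err, float(np.abs(ge["e_in"] - e_in).max()),
              float(np.abs(ge["e_out"] - e_out).max()), abs(ge["E"] - E))
    le = local_efficiency(a)
    l_in, l_out = local_efficiency_oracle(a)
    err = max(err, float(np.abs(le["le_in"] - l_in).max()),
              float(np.abs(le["le_out"] - l_out).max()))
    err = max(err, float(np.abs(directed_clustering(a) - clustering_oracle(a)).max()))
    err = max(err, abs(transitivity(a) - transitivity_oracle(a)))
    return err


def graph_oracle_equivalence(seed: int, n5_sample: int = 3000, n10: int = 200) -> dict:
    """All binary measures vs explicit enumeration oracles: exhaustive over
    every digraph on <= 4 nodes, a seeded sample of 5-node digraphs, and
    random 10-node digraphs."""
    worst = 0.0
    count = 0
    for n in (2, 3, 4):
        for a in all_digraphs(n):
            worst = max(worst, _check_graph(a))
            count += 1
    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 2, size=(n5_sample, 20))
    off = ~np.eye(5, dtype=bool)
    for m in masks:
        a = np.zeros((5, 5))
        a[off] = m
        worst = max(worst, _check_graph(a))
        count += 1
    for i in range(n10):
        p = 0.1 + 0.8 * (i % 10) / 9
        worst = max(worst, _check_graph(random_digraph(10, p, seed=seed + i)))
        count += 1
    return {"max_abs_error": worst, "n": count}


# ---------------------------------------------------------------------------
# 4. monotonicity in density
# ---------------------------------------------------------------------------


def monotonicity(seed: int, n_matrices: int = 50, n_nodes: int = 200) -> dict:
    """Nondecreasing E, LE, mean clustering and transitivity over nested
    thresholds of random weight matrices at the study's network size."""
    rng = np.random.default_rng(seed)
    grid_fast = default_density_grid(0.02, 0.50, 0.02)
    grid_le = np.array([0.05, 0.15, 0.25, 0.35, 0.45])
    violations = 0
    worst_drop = 0.0
    checks = 0
    for _ in range(n_matrices):
        w = clip_connections(rng.random((n_nodes, n_nodes)))
        prev = {"E": -np.inf, "C": -np.inf, "T": -np.inf}
        for d in grid_fast:
            net = threshold_by_density(w, float(d))
            vals = {
                "E": global_efficiency(net)["E"],
                "C": float(directed_clustering(net).mean()),
                "T": transitivity(net),
            }
            for k, v in vals.items():
                checks += 1
                if v < prev[k] - 1e-12:
                    violations += 1
                    worst_drop = max(worst_drop, prev[k] - v)
                prev[k] = v
        prev_le = -np.inf
        for d in grid_le:
            v = local_efficiency(threshold_by_density(w, float(d)))["LE"]
            checks += 1
            if v < prev_le - 1e-12:
                violations += 1
                worst_drop = max(worst_drop, prev_le - v)
            prev_le = v
    return {"violations": violations, "worst_drop": worst_drop, "n": checks}


# ---------------------------------------------------------------------------
# 5. statistical calibration
# ---------------------------------------------------------------------------


def _null_cohort_values(rng):
    """Null measure values for the 15/95 design: covariate signal + noise,
    no group effect."""
    cov_c = _covariates(rng, 15, "control")
    cov_p = _covariates(rng, 95, "patient")
    age = np.concatenate([cov_c["age"], cov_p["age"]])
    sex = np.concatenate([cov_c["sex"], cov_p["sex"]])
    motion = np.column_stack(
        [np.concatenate([cov_c[f"motion_{i}"], cov_p[f"motion_{i}"]]) for i in range(1, 7)]
    )
    groups = np.array([0] * 15 + [1] * 95)
    covariates = np.column_stack([age, sex, motion])
    signal = 0.3 * (age - 70.0) / 10.0 + 0.2 * sex
    return groups, covariates, signal


def type_i_calibration(seed: int, n_datasets: int = 200, n_perm: int = 1000) -> dict:
    """Rejection rate at alpha=0.05 on null cohorts (no group effect but
    group-correlated covariates)."""
    rejections = 0
    for s in _spawn(seed, n_datasets):
        rng = np.random.default_rng(s)
        groups, covariates, signal = _null_cohort_values(rng)
        v = signal + rng.standard_normal(len(groups))
        p = GroupPermutationTest(n_perm=n_perm, seed=s).fit(v, groups, covariates).p_values_[0]
        rejections += p < 0.05
    return {"rate": rejections / n_datasets, "n": n_datasets}


def fdr_control(
    seed: int,
    n_datasets: int = 200,
    n_regions: int = 50,
    frac_true: float = 0.10,
    effect: float = 1.2,
    n_perm: int = 500,
    q: float = 0.05,
) -> dict:
    """Empirical FDR of BH over nodal permutation tests with planted effects."""
    n_true = int(round(frac_true * n_regions))
    fdps = []
    for s in _spawn(seed, n_datasets):
        rng = np.random.default_rng(s)
        groups, covariates, signal = _null_cohort_values(rng)
        v = signal[:, None] + rng.standard_normal((len(groups), n_regions))
        v[groups == 1, :n_true] += effect
        test = GroupPermutationTest(n_perm=n_perm, seed=s).fit(v, groups, covariates)
        rejected, _ = fdr_bh(test.p_values_, q)
        n_rej = int(rejected.sum())
        false_rej = int(rejected[n_true:].sum())
        fdps.append(false_rej / n_rej if n_rej else 0.0)
    return {"empirical_fdr": float(np.mean(fdps)), "n": n_datasets}


# ---------------------------------------------------------------------------
# 6. direction recovery (antisymmetric vs zero-lag pipelines)
# ---------------------------------------------------------------------------

_SOURCE, _TARGET = 3, 7  # planted j -> k lag-1 coupling, coefficient 0.8


def _nodal_in_auc(mats: np.ndarray, grid: np.ndarray):
    """AUC of the pipeline's nodal in-measures (in-degree and
    in-global-efficiency, the in-measures of the study driver's nodal
    comparison family) over the cohort's attainable density range."""
    n_off = mats.shape[1] * (mats.shape[1] - 1)
    attain = min(float((w > 0).sum()) / n_off for w in mats)
    g = grid[grid <= attain + 1e-9]
    out = {"in_degree": [], "in_global_eff": []}
    for w in mats:
        curves = {k: [] for k in out}
        for d in g:
            net = threshold_by_density(w, float(d))
            curves["in_degree"].append(net.adjacency.sum(axis=0))
            curves["in_global_eff"].append(global_efficiency(net)["e_in"])
        for k in out:
            out[k].append(np.trapezoid(np.asarray(curves[k]), g, axis=0))
    return {k: np.asarray(v) for k, v in out.items()}


def direction_recovery(seed: int, n_replicates: int = 50, n_perm: int = 1000) -> dict:
    """Planted-direction detection rates of the antisymmetric vs zero-lag
    nodal AUC pipelines at the 15-vs-95, T=207 study design."""
    grid = default_density_grid()
    hits_antisym = 0
    hits_zerolag = 0
    for rep, s in enumerate(_spawn(seed, n_replicates)):
        base = random_ground_truth(n_regions=20, seed=s)
        cohort = make_group_cohort(
            n_regions=20,
            T=207,
            effects=[(_SOURCE, _TARGET, 1, 0.8)],
            base=base,
            seed=s,
        )
        groups = (cohort.subjects["group"] == "patient").to_numpy()
        covariates = cohort.subjects[cohort.covariate_columns].to_numpy(float)
        for name, est in (
            ("antisym", AntisymmetricCorrelation(lag=1)),
            ("zerolag", ZeroLagCorrelation()),
        ):
            mats = est.fit_transform(cohort.timeseries)
            aucs = _nodal_in_auc(mats, grid)
            p_at_target = [
                GroupPermutationTest(n_perm=n_perm, seed=s)
                .fit(v, groups, covariates)
                .p_values_[_TARGET]
                for v in aucs.values()
            ]
            hit = min(p_at_target) < 0.05
            if name == "antisym":
                hits_antisym += hit
            else:
                hits_zerolag += hit
    table = [
        [hits_antisym, n_replicates - hits_antisym],
        [hits_zerolag, n_replicates - hits_zerolag],
    ]
    _, fisher_p = fisher_exact(table, alternative="greater")
    return {
        "rate_antisym": hits_antisym / n_replicates,
        "rate_zerolag": hits_zerolag / n_replicates,
        "fisher_p": float(fisher_p),
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# 7. Granger sanity
# ---------------------------------------------------------------------------


def granger_sanity(seed: int, n_null: int = 100, n_directed: int = 100) -> dict:
    """Null F magnitudes for independent series and direction accuracy for a
    planted x1(t) = 0.9 x2(t-1) coupling."""
    null_f = []
    for s in _spawn(seed, n_null):
        rng = np.random.default_rng(s)
        F = granger_matrix(rng.standard_normal((2, 1000)), order=1, clip=False).weights
        null_f.extend([F[0, 1], F[1, 0]])
    correct = 0
    for s in _spawn(seed + 1, n_directed):
        rng = np.random.default_rng(s)
        x2 = rng.standard_normal(207)
        x1 = np.zeros(207)
        x1[1:] = 0.9 * x2[:-1] + rng.standard_normal(206)
        F = granger_matrix(np.vstack([x1, x2]), order=1).weights
        correct += F[1, 0] > F[0, 1]  # F_{2->1} must dominate
    return {
        "null_f_95pct": float(np.percentile(null_f, 95)),
        "direction_accuracy": correct / n_directed,
        "n_null": n_null,
        "n_directed": n_directed,
    }
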