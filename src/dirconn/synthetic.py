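"""Synthetic ground-truth generators: VAR cohorts and canonical fixture graphs.

Real resting-state inputs are regional activation series whose directed
interactions arise from signal propagation with temporal lags.  The generator
emulates that structure with a stable vector autoregression (VAR): region i at
time t is a linear combination of all regions at the previous ``p`` steps plus
white Gaussian innovation,

    x(t) = sum_l B[l] x(t-l) + eps(t),      eps ~ N(0, noise_sd^2 I),

so the nonzero off-diagonal coefficients ARE the true directed edges
(``B[l][i, j]`` = influence of region j on region i at lag l+1).  Stability is
enforced through the spectral radius of the companion matrix.  Cohorts mimic
the study design: a small control group and a larger patient group (default
15 vs 95 subjects, 207 time points), subject-level coefficient jitter,
age/sex/motion covariates, and a named set of coefficient perturbations that
distinguishes the patient group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RegionTimeSeries

__all__ = [
    "VarGroundTruth",
    "random_ground_truth",
    "simulate_var",
    "Cohort",
    "make_group_cohort",
    "fixture_networks",
    "random_digraph",
]

#: Samples discarded before recording a VAR realization.
BURN_IN = 500


@dataclass
class VarGroundTruth:
    """A VAR(p) generative model with a known directed edge list."""

    coefficients: np.ndarray  # (p, n, n); [l, i, j] = j -> i at lag l+1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 3 or (
            self.coefficients.shape[1] != self.coefficients.shape[2]
        ):
            raise ValueError("coefficients must have shape (p, n, n)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_regions(self) -> int:
        return self.coefficients.shape[1]

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    def companion_matrix(self) -> np.ndarray:
        p, n, _ = self.coefficients.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coefficients), axis=1)
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion_matrix())).max())

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0

    def true_edges(self) -> list[tuple[int, int, int]]:
        """List of (source j, target i, lag) for nonzero off-diagonal
        coefficients."""
        edges = []
        for l, B in enumerate(self.coefficients, start=1):
            for i, j in zip(*np.nonzero(B)):
                if i != j:
                    edges.append((int(j), int(i), l))
        return edges

    def perturbed(self, effects, jitter_sd: float = 0.0, rng=None) -> "VarGroundTruth":
        """Copy with coefficient deltas applied and optional Gaussian jitter
        on the nonzero coefficients.

        ``effects``: iterable of (source j, target i, lag, delta).
        """
        B = self.coefficients.copy()
        for j, i, lag, delta in effects or []:
            B[lag - 1, i, j] += delta
        if jitter_sd > 0:
            rng = np.random.default_rng() if rng is None else rng
            mask = B != 0
            B = B + jitter_sd * rng.standard_normal(B.shape) * mask
        return VarGroundTruth(B, self.noise_sd, self.seed)


def random_ground_truth(
    n_regions: int = 20,
    edge_density: float = 0.10,
    coupling: float = 0.20,
    self_coupling: float = 0.20,
    noise_sd: float = 1.0,
    seed: int = 0,
    max_radius: float = 0.90,
) -> VarGroundTruth:
    """Random sparse stable VAR(1) ground truth.

    Off-diagonal couplings of magnitude ``coupling`` (random sign) are planted
    on an Erdos-Renyi directed support of the given density; every region
    keeps a positive self-lag of ``self_coupling``.  The default self-lag is
    modest (0.2): with white innovations and no hemodynamic convolution it
    stands for residual neuronal-level autocorrelation only, since in real
    BOLD data most of the autocorrelation is imposed by the hemodynamic
    filter that this generator deliberately does not model.  Coefficients are
    rescaled if needed so the companion spectral radius stays below
    ``max_radius``.
    """
    rng = np.random.default_rng(seed)
    B = np.zeros((1, n_regions, n_regions))
    support = rng.random((n_regions, n_regions)) < edge_density
    np.fill_diagonal(support, False)
    signs = rng.choice([-1.0, 1.0], size=(n_regions, n_regions))
    B[0] = np.where(support, coupling * signs, 0.0)
    B[0] += self_coupling * np.eye(n_regions)
    gt = VarGroundTruth(B, noise_sd=noise_sd, seed=seed)
    rad = gt.spectral_radius()
    if rad >= max_radius:
        gt = VarGroundTruth(B * (max_radius / rad) * 0.99, noise_sd=noise_sd, seed=seed)
    return gt


def simulate_var(
    gt: VarGroundTruth,
    T: int = 207,
    seed: int | None = None,
    burn_in: int = BURN_IN,
    subject_id: str = "subject",
) -> RegionTimeSeries:
    """Seeded Gaussian-innovation VAR realization of length ``T`` after
    burn-in discard."""
    if not gt.is_stable():
        raise ValueError(
            f"unstable VAR ground truth (companion spectral radius "
            f"{gt.spectral_radius():.3f} >= 1)"
        )
    rng = np.random.default_rng(gt.seed if seed is None else seed)
    p, n = gt.order, gt.n_regions
    total = T + burn_in
    x = np.zeros((n, total + p))
    eps = gt.noise_sd * rng.standard_normal((n, total + p))
    for t in range(p, total + p):
        acc = eps[:, t].copy()
        for l in range(p):
            acc += gt.coefficients[l] @ x[:, t - 1 - l]
        x[:, t] = acc
    return RegionTimeSeries(data=x[:, -T:], subject_id=subject_id)


@dataclass
class Cohort:
    """Synthetic study cohort: per-subject series, covariate table, truth."""

    timeseries: list[RegionTimeSeries]
    subjects: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def covariate_columns(self) -> list[str]:
        return ["age", "sex"] + [f"motion_{i}" for i in range(1, 7)]


def _covariates(rng, n, group: str) -> dict:
    # Age/sex distributions echo the study sample (controls older, more male);
    # motion parameters collapse to one mean-absolute summary each.
    if group == "control":
        age = rng.normal(72.0, 8.0, n)
        sex = (rng.random(n) < 0.87).astype(int)
    else:
        age = rng.normal(68.0, 10.0, n)
        sex = (rng.random(n) < 0.68).astype(int)
    cov = {"age": np.round(age, 1), "sex": sex}
    for i in range(1, 7):
        cov[f"motion_{i}"] = np.abs(rng.normal(0.0, 0.1, n))
    return cov


def make_group_cohort(
    n_controls: int = 15,
    n_patients: int = 95,
    n_regions: int = 20,
    T: int = 207,
    effects=None,
    jitter_sd: float = 0.05,
    confound_strength: float = 0.0,
    base: VarGroundTruth | None = None,
    seed: int = 0,
) -> Cohort:
    """Two-group VAR cohort with a known planted group effect.

    ``effects`` lists (source j, target i, lag, delta) coefficient changes
    applied to the patient group only; ``None`` gives a null cohort.  Every
    subject gets an independent jittered copy of the ground truth, so the
    cohort has realistic between-subject variability.  ``confound_strength``
    scales the coefficients with the subject's standardized age, mixing the
    covariate into the connectivity.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        base = random_ground_truth(n_regions=n_regions, seed=int(rng.integers(2**31)))
    series: list[RegionTimeSeries] = []
    rows = []
    counts = {"control": n_controls, "patient": n_patients}
    for group in ("control", "patient"):
        n = counts[group]
        cov = _covariates(rng, n, group)
        for i in range(n):
            sid = f"{'CTR' if group == 'control' else 'PD'}{i:03d}"
            gt_i = base.perturbed(
                effects if group == "patient" else None, jitter_sd=jitter_sd, rng=rng
            )
            if confound_strength:
                z_age = (cov["age"][i] - 70.0) / 10.0
                gt_i = VarGroundTruth(
                    gt_i.coefficients * (1.0 + confound_strength * z_age),
                    gt_i.noise_sd,
                    gt_i.seed,
                )
            if not gt_i.is_stable():  # jitter pushed past stability; rescale
                gt_i = VarGroundTruth(
                    gt_i.coefficients * (0.95 / gt_i.spectral_radius()), gt_i.noise_sd
                )
            ts = simulate_var(gt_i, T=T, seed=int(rng.integers(2**31)), subject_id=sid)
            series.append(ts)
            rows.append(
                {"subject_id": sid, "group": group}
                | {k: v[i] for k, v in cov.items()}
            )
    subjects = pd.DataFrame(rows)
    truth = {
        "base_coefficients": base.coefficients,
        "effects": list(effects or []),
        "true_edges": base.true_edges(),
        "seed": seed,
        "n_regions": n_regions,
        "T": T,
    }
    return Cohort(timeseries=series, subjects=subjects, truth=truth)


# ---------------------------------------------------------------------------
# Canonical fixture digraphs
# ---------------------------------------------------------------------------


def random_digraph(n: int, p: float, seed: int = 0) -> np.ndarray:
    """Erdos-Renyi directed adjacency (binary, loop-free)."""
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def fixture_networks() -> dict[str, np.ndarray]:
    """Named binary digraphs with known hand-computed measures."""
    cycle3 = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    dag_triangle = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=float)
    bidirectional_triangle = np.ones((3, 3)) - np.eye(3)
    complete4 = np.ones((4, 4)) - np.eye(4)
    star = np.zeros((5, 5))
    star[0, 1:] = 1.0
    star[1:, 0] = 1.0
    two_cliques = np.zeros((6, 6))
    two_cliques[:3, :3] = bidirectional_triangle
    two_cliques[3:, 3:] = bidirectional_triangle
    return {
        "cycle3": cycle3,
        "dag_triangle": dag_triangle,
        "bidirectional_triangle": bidirectional_triangle,
        "complete4": complete4,
        "star": star,
        "two_cliques": two_cliques,
    }
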