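"""Study orchestration: connect -> threshold -> measure -> AUC -> compare.

``run_study`` drives the full replica of the analysis chain from a single
:class:`RunConfig`: per-subject connectivity at every requested method and
temporal lag, group-representative average matrices and weight histograms,
graph-measure curves across the density grid, AUC tables, covariate-adjusted
permutation comparisons (global per density, nodal on AUC with BH-FDR across
regions), and clinical-score correlations for regions surviving the group
test.  Outputs are long-format TSV tables, one directory per lag x method,
plus a JSON manifest with the configuration hash and seeds.  Multiple lags
are deliberately NOT corrected across by default (exploratory design); set
``fdr_across_lags`` to pool them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectivity import (
    AntisymmetricCorrelation,
    GrangerCausality,
    LaggedCorrelation,
    SymmetricCorrelation,
    ZeroLagCorrelation,
    group_average_matrix,
    weight_histogram,
)
from .containers import ConnectivityMatrix
from .graphs import GraphMeasures, default_density_grid, directed_distances, threshold_by_density
from .stats import clinical_correlation, fdr_bh, permutation_test_global, permutation_test_nodal_auc
from .synthetic import make_group_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "lag_diagnostics"]

_GLOBAL_FOR_COMPARISON = ("E", "LE", "clustering_mean", "transitivity", "modularity")
_NODAL_FOR_COMPARISON = (
    "in_degree",
    "out_degree",
    "degree",
    "in_global_eff",
    "out_global_eff",
    "global_eff",
)


@dataclass
class RunConfig:
    """Validated configuration for a full study run."""

    methods: list[str] = field(
        default_factory=lambda: ["lagged", "antisymmetric", "symmetric", "zerolag"]
    )
    lags: list[int] = field(default_factory=lambda: list(range(1, 8)))
    granger_order: int = 1
    density_start: float = 0.01
    density_stop: float = 0.50
    density_step: float = 0.01
    mode: str = "binary"
    measures: str | list = "all"
    n_restarts: int = 100
    n_perm: int = 10_000
    seed: int = 0
    fdr_q: float = 0.05
    fdr_across_lags: bool = False
    group_col: str = "group"
    covariate_cols: list[str] = field(
        default_factory=lambda: ["age", "sex"] + [f"motion_{i}" for i in range(1, 7)]
    )
    score_cols: list[str] = field(default_factory=list)
    input_dir: str | None = None
    synthetic: dict | None = None
    output_dir: str = "dirconn_results"

    def __post_init__(self) -> None:
        known = {"lagged", "antisymmetric", "symmetric", "zerolag", "granger"}
        bad = set(self.methods) - known
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if any(l < 1 for l in self.lags):
            raise ValueError("lags must be >= 1 (lag 0 is the zero-lag method)")
        if not 0 < self.density_start <= self.density_stop <= 0.5:
            raise ValueError("densities must satisfy 0 < start <= stop <= 0.5")
        if self.mode not in ("binary", "weighted"):
            raise ValueError("mode must be 'binary' or 'weighted'")
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("either input_dir or a synthetic spec is required")

    def density_grid(self) -> np.ndarray:
        return default_density_grid(self.density_start, self.density_stop, self.density_step)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _estimator(method: str, lag: int, order: int):
    if method == "lagged":
        return LaggedCorrelation(lag=lag, clip=True)
    if method == "antisymmetric":
        return AntisymmetricCorrelation(lag=lag)
    if method == "symmetric":
        return SymmetricCorrelation(lag=lag)
    if method == "zerolag":
        return ZeroLagCorrelation()
    if method == "granger":
        return GrangerCausality(order=order)
    raise ValueError(f"unknown method {method!r}")


def _load_cohort(config: RunConfig):
    if config.input_dir is not None:
        root = Path(config.input_dir)
        subjects = dio.read_subjects(root / "subjects.tsv")
        series = [
            dio.read_timeseries(root / f"{sid}.tsv", subject_id=sid)
            for sid in subjects["subject_id"]
        ]
        return series, subjects
    cohort = make_group_cohort(seed=config.seed, **(config.synthetic or {}))
    return cohort.timeseries, cohort.subjects


def _comparison_frame(comp) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "measure": comp.measure,
            "feature": comp.feature_names,
            "observed_diff": comp.observed,
            "p_value": comp.p_values,
            "ci_low": comp.ci_low,
            "ci_high": comp.ci_high,
        }
    )
    if comp.p_adjusted is not None:
        df["p_adjusted"] = comp.p_adjusted
        df["rejected"] = comp.rejected
    return df


def _run_branch(method, lag, series, subjects, config, grid, outdir):
    """One lag x method branch; returns its result tables."""
    est = _estimator(method, lag, config.granger_order)
    mats = est.fit_transform(series)
    labels = series[0].region_labels
    sids = subjects["subject_id"].tolist()
    groups = subjects[config.group_col].to_numpy()
    cov = subjects[config.covariate_cols].to_numpy(dtype=float) if config.covariate_cols else None
    group_names = list(pd.unique(groups))

    # group-representative averages + weight histograms
    hist_rows = []
    for gname in group_names:
        members = [
            ConnectivityMatrix(m, method if method != "lagged" else "lagged",
                               lag, True, labels, s)
            for m, s, g in zip(mats, sids, groups) if g == gname
        ]
        avg = group_average_matrix(members)
        dio.write_matrix(avg, outdir / f"group_average_{gname}.tsv")
        counts, edges = weight_histogram(avg, n_bins=50)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hist_rows.extend(
            {"group": gname, "bin_center": c, "count": int(k)}
            for c, k in zip(centers, counts)
        )
    pd.DataFrame(hist_rows).to_csv(outdir / "weight_histograms.tsv", sep="\t", index=False)

    # cap the grid at the cohort-wide attainable density so every subject is
    # evaluated on a common grid (clipped matrices may have <50% positives)
    n_off = mats.shape[1] * (mats.shape[1] - 1)
    attain = min(float((w > 0).sum()) / n_off for w in mats)
    branch_grid = grid[grid <= attain + 1e-9]
    if branch_grid.size < 2:
        raise ValueError(
            f"attainable density range too small (max {attain:.3f}) for the grid"
        )
    if branch_grid.size < grid.size:
        logger.warning(
            "capping density grid at %.2f (cohort attainable maximum)", branch_grid[-1]
        )

    gm = GraphMeasures(
        densities=branch_grid,
        mode=config.mode,
        measures=config.measures,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    curves = gm.curves(mats, subject_ids=sids)
    curves.to_csv(outdir / "measures.tsv", sep="\t", index=False)
    auc_frames = []
    for sid, grp in curves.groupby("subject", sort=False):
        from .graphs import auc_over_densities

        a = auc_over_densities(grp)
        a.insert(0, "subject", sid)
        auc_frames.append(a)
    auc = pd.concat(auc_frames, ignore_index=True)
    auc.to_csv(outdir / "auc.tsv", sep="\t", index=False)

    # global per-density comparisons
    global_tables = []
    for meas in _GLOBAL_FOR_COMPARISON:
        sub = curves[(curves["measure"] == meas) & (curves["region"] == "GLOBAL")]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="subject", columns="density", values="value").loc[sids]
        comp = permutation_test_global(
            wide.to_numpy(), groups, cov,
            n_perm=config.n_perm, seed=config.seed,
            measure=meas, densities=list(wide.columns),
        )
        global_tables.append(_comparison_frame(comp))
    global_df = (
        pd.concat(global_tables, ignore_index=True) if global_tables else pd.DataFrame()
    )
    global_df.to_csv(outdir / "global_comparisons.tsv", sep="\t", index=False)

    # nodal AUC comparisons with FDR across regions
    nodal_tables, surviving = [], {}
    for meas in _NODAL_FOR_COMPARISON:
        sub = auc[(auc["measure"] == meas) & (auc["region"] != "GLOBAL")]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="subject", columns="region", values="auc").loc[sids]
        comp = permutation_test_nodal_auc(
            wide.to_numpy(), groups, cov,
            n_perm=config.n_perm, seed=config.seed,
            measure=meas, region_labels=list(wide.columns), q=config.fdr_q,
        )
        surviving[meas] = [r for r, rej in zip(comp.feature_names, comp.rejected) if rej]
        nodal_tables.append(_comparison_frame(comp))
    nodal_df = pd.concat(nodal_tables, ignore_index=True) if nodal_tables else pd.DataFrame()
    nodal_df.to_csv(outdir / "nodal_auc_comparisons.tsv", sep="\t", index=False)

    # clinical correlations, only in regions surviving the group test
    clin_rows = []
    if config.score_cols:
        patients = groups == group_names[-1]
        for meas, regions in surviving.items():
            sub = auc[(auc["measure"] == meas)]
            wide = sub.pivot_table(index="subject", columns="region", values="auc").loc[sids]
            for region in regions:
                for score in config.score_cols:
                    svals = subjects.set_index("subject_id").loc[sids, score].to_numpy(float)
                    r, p = clinical_correlation(
                        wide[region].to_numpy()[patients], svals[patients],
                        cov[patients] if cov is not None else None,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    clin_rows.append(
                        {"measure": meas, "region": region, "score": score, "r": r, "p": p}
                    )
    clin_df = pd.DataFrame(clin_rows, columns=["measure", "region", "score", "r", "p"])
    clin_df.to_csv(outdir / "clinical_correlations.tsv", sep="\t", index=False)

    return {
        "matrices": mats,
        "curves": curves,
        "auc": auc,
        "global_comparisons": global_df,
        "nodal_comparisons": nodal_df,
        "clinical": clin_df,
    }


def run_study(config: RunConfig) -> dict:
    """Execute the configured study; returns the results bundle and writes
    all tables under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.density_grid()
    series, subjects = _load_cohort(config)
    dio.write_subjects(subjects, out / "subjects.tsv")

    branches = []
    for method in config.methods:
        if method in ("zerolag", "granger"):
            branches.append((method, config.granger_order if method == "granger" else 0))
        else:
            branches.extend((method, lag) for lag in config.lags)

    results: dict = {}
    mats_by_lag: dict[int, list[np.ndarray]] = {}
    for method, lag in branches:
        tag = f"{method}_lag{lag}" if method != "granger" else f"granger_p{lag}"
        branch_dir = out / tag
        branch_dir.mkdir(exist_ok=True)
        logger.info("running branch %s", tag)
        try:
            results[(method, lag)] = _run_branch(
                method, lag, series, subjects, config, grid, branch_dir
            )
        except Exception as exc:
            raise RuntimeError(f"stage '{tag}' failed: {exc}") from exc
        if method == "antisymmetric":
            mats_by_lag[lag] = list(results[(method, lag)]["matrices"])

    if mats_by_lag:
        diag = lag_diagnostics(mats_by_lag)
        diag.to_csv(out / "lag_diagnostics.tsv", sep="\t", index=False)
        results["lag_diagnostics"] = diag

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_subjects": len(series),
        "n_regions": series[0].n_regions,
        "branches": [f"{m}:{l}" for m, l in branches],
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def lag_diagnostics(
    mats_by_lag: dict[int, list], diameter_density: float = 0.15
) -> pd.DataFrame:
    """Per-lag histogram spread and mean diameter table.

    The SD of the positive connection strengths of the group-average matrix
    narrows with increasing lag once the generative lag is passed (large lags
    assign similar weights to many connections and cannot resolve directional
    flow), and the mean network diameter grows; together these justify
    restricting analyses to small lags.
    """
    rows = []
    for lag in sorted(mats_by_lag):
        mats = [m if isinstance(m, np.ndarray) else m.weights for m in mats_by_lag[lag]]
        avg = np.mean(mats, axis=0)
        off = avg[~np.eye(avg.shape[0], dtype=bool)]
        pos = off[off > 0]
        diams = []
        for m in mats:
            try:
                net = threshold_by_density(m, diameter_density, mode="binary")
            except ValueError:
                continue
            _, diam, _ = directed_distances(net)
            diams.append(diam)
        rows.append(
            {
                "lag": lag,
                "hist_sd": float(pos.std(ddof=1)) if pos.size > 1 else 0.0,
                "hist_mean": float(pos.mean()) if pos.size else 0.0,
                "mean_diameter": float(np.nanmean(diams)) if diams else float("nan"),
            }
        )
    return pd.DataFrame(rows)
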