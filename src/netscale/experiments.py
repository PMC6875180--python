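"""Scale-sweep orchestration: the full pipeline at several parcellation scales.

``run_scale_sweep`` executes, for every requested node count N:
parcellation -> per-subject networks -> AUC nodal-metric features -> KS/FDR
screening -> repeated linear-SVM cross-validation -> mRMR effectiveness and
redundancy analysis, on a single synthetic cohort that is shared across
scales.  The report collects, per scale: achieved node count, total and
discriminative feature counts (per metric), CV accuracy / sensitivity /
specificity, the accuracy-vs-feature-count curve, the P-vs-MID regression,
mean pairwise redundancy of the selected features, and the
redundancy-vs-centroid-distance regression.

Everything is a pure function of the config, so a rerun with the same config
reproduces the report exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .classification import accuracy_vs_feature_count, repeated_kfold
from .metrics import METRIC_NAMES, build_feature_table
from .mrmr import (
    discretize,
    per_feature_mid,
    redundancy_distance_regression,
    redundancy_matrix,
    subset_mid_curve,
)
from .network import sparsity_grid
from .parcellation import centroid_distances, subdivide_atlas
from .screening import screen_features, select_features
from .synthetic import CohortSpec, generate_atlas, generate_cohort

__all__ = ["SweepConfig", "run_scale_sweep", "same_feature_count_comparison"]

from scipy import stats


@dataclass
class SweepConfig:
    """All tunables of the scale-sweep experiment."""

    # synthetic atlas
    shape: tuple[int, int, int] = (12, 12, 12)
    n_parents: int = 8
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    # synthetic cohort
    n_patients: int = 19
    n_controls: int = 14
    n_timepoints: int = 238
    n_effect_regions: int = 3
    effect_size: float = 0.4
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    nuisance_amp: float = 0.5
    # network construction
    sparsity_start: float = 0.08
    sparsity_stop: float = 0.28
    sparsity_step: float = 0.05
    edge_ranking: str = "signed"
    # scales, screening, classification, mRMR
    scales: tuple[int, ...] = (16, 32, 64)
    q: float = 0.05
    ks_method: str = "asymp"
    cv_k: int = 10
    cv_repeats: int = 20
    curve_step: int = 3
    curve_repeats: int = 5
    curve_max_features: int | None = 60
    mrmr_alpha: float = 1.0
    seed: int = 0


def _regression(x: np.ndarray, y: np.ndarray) -> dict:
    reg = stats.linregress(x, y)
    n = x.size
    r2 = reg.rvalue**2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2) if n > 2 else float("nan")
    return {
        "slope": float(reg.slope),
        "adjusted_r2": float(adj),
        "p_value": float(reg.pvalue),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def build_cohort(cfg: SweepConfig):
    """Generate the atlas and cohort a sweep config describes."""
    atlas = generate_atlas(cfg.shape, cfg.n_parents, cfg.spacing, seed=cfg.seed)
    effect = frozenset(int(r) for r in atlas.region_ids[: cfg.n_effect_regions])
    spec = CohortSpec(
        n_patients=cfg.n_patients,
        n_controls=cfg.n_controls,
        n_timepoints=cfg.n_timepoints,
        effect_regions=effect,
        effect_size=cfg.effect_size,
        noise_sd=cfg.noise_sd,
        ar_coef=cfg.ar_coef,
        nuisance_amp=cfg.nuisance_amp,
        seed=cfg.seed,
    )
    return atlas, generate_cohort(atlas, spec)


def analyze_scale(cfg: SweepConfig, atlas, cohort, N: int, seed: int) -> dict:
    """Run every pipeline stage for one parcellation scale."""
    grid = sparsity_grid(cfg.sparsity_start, cfg.sparsity_stop, cfg.sparsity_step)
    parc = subdivide_atlas(atlas, N, seed=seed)
    table = build_feature_table(cohort, parc, grid=grid, ranking=cfg.edge_ranking)
    screen = screen_features(table, q=cfg.q, method=cfg.ks_method)
    selected = select_features(screen, mode="fdr", param=cfg.q)
    per_metric = {
        m: int(screen.loc[screen["selected"] & (screen["metric"] == m)].shape[0])
        for m in METRIC_NAMES
    }

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCF]))
    out: dict = {
        "target_N": int(N),
        "achieved_N": int(parc.achieved_N),
        "total_features": int(table.n_features),
        "n_discriminative": int(selected.size),
        "discriminative_per_metric": per_metric,
    }

    if selected.size >= 1:
        cv = repeated_kfold(
            table.X, table.group, feature_idx=selected,
            k=cfg.cv_k, repeats=cfg.cv_repeats, seed=int(rng.integers(2**31)),
        )
        out["cv"] = {
            "accuracy": cv.accuracy,
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
            "train_accuracy": cv.train_accuracy,
        }
    else:
        out["cv"] = None

    p_order = np.lexsort(
        (np.arange(table.n_features), screen["p"].to_numpy())
    )
    curve = accuracy_vs_feature_count(
        table.X, table.group, p_order,
        step=cfg.curve_step, repeats=cfg.curve_repeats, k=cfg.cv_k,
        seed=int(rng.integers(2**31)), max_features=cfg.curve_max_features,
    )
    out["accuracy_curve"] = curve

    disc = discretize(table.X, alpha=cfg.mrmr_alpha)
    scores, order = per_feature_mid(disc, table.group)
    out["mid_scores_mean"] = float(scores.mean())
    out["p_vs_mid"] = _regression(screen["p"].to_numpy(), scores)
    sizes, means = subset_mid_curve(scores, p_order, step=cfg.curve_step)
    out["subset_mid_curve"] = {"n_features": sizes, "mean_mid": means}

    if selected.size >= 2:
        red = redundancy_matrix(disc, selected)
        node_dist = centroid_distances(parc)
        nodes = screen["node"].to_numpy()[selected]
        node_pos = {int(n): i for i, n in enumerate(parc.node_ids)}
        iu, ju = np.triu_indices(selected.size, k=1)
        ni = np.array([node_pos[int(n)] for n in nodes])
        distinct = ni[iu] != ni[ju]
        red_pairs = red[iu, ju][distinct]
        dist_pairs = node_dist[ni[iu], ni[ju]][distinct]
        out["mean_redundancy"] = float(red[iu, ju].mean())
        out["redundancy_vs_distance"] = (
            redundancy_distance_regression(red_pairs, dist_pairs)
            if red_pairs.size >= 3 and np.unique(dist_pairs).size >= 2
            else None
        )
    else:
        out["mean_redundancy"] = None
        out["redundancy_vs_distance"] = None

    # internal handles for follow-up analyses (not serialized)
    out["_table"] = table
    out["_screen"] = screen
    out["_parc"] = parc
    return out


def run_scale_sweep(cfg: SweepConfig) -> dict:
    """Execute the full multiscale experiment described by ``cfg``."""
    atlas, cohort = build_cohort(cfg)
    root = np.random.SeedSequence([int(cfg.seed), 0x5CA1E])
    scale_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(len(cfg.scales))]
    report = {
        "config": asdict(cfg),
        "truth_regions": sorted(cohort.truth),
        "scales": [
            analyze_scale(cfg, atlas, cohort, N, seed)
            for N, seed in zip(cfg.scales, scale_seeds)
        ],
    }
    return report


def report_to_json(report: dict, path: str) -> None:
    """Serialize a sweep report, dropping in-memory artifact handles."""
    clean = {
        k: v for k, v in report.items() if not k.startswith("_")
    }
    clean["scales"] = [
        {k: v for k, v in sc.items() if not k.startswith("_")}
        for sc in report["scales"]
    ]
    with open(path, "w") as fh:
        json.dump(_jsonable(clean), fh, indent=2, sort_keys=True)


def same_feature_count_comparison(
    report: dict,
    counts: list[int],
    cv_repeats: int = 20,
    cv_k: int = 10,
    seed: int = 0,
) -> dict:
    """CV accuracy with the same number of top-P features at every scale.

    A cell is omitted (None) when a scale has fewer discriminative features
    than the requested count, mirroring how small parcellations run out of
    significant features.
    """
    if not counts:
        raise ValueError("counts must be nonempty")
    rng = np.random.default_rng(seed)
    cells: dict[int, dict[int, float | None]] = {}
    for sc in report["scales"]:
        table = sc["_table"]
        screen = sc["_screen"]
        p = screen["p"].to_numpy()
        order = np.lexsort((np.arange(p.size), p))
        n_disc = sc["n_discriminative"]
        row: dict[int, float | None] = {}
        for c in counts:
            if c > n_disc:
                row[c] = None
                continue
            res = repeated_kfold(
                table.X, table.group, feature_idx=order[:c],
                k=cv_k, repeats=cv_repeats, seed=int(rng.integers(2**31)),
            )
            row[c] = res.accuracy
        cells[sc["target_N"]] = row
    return cells
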