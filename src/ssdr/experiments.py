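"""Desk-scale reproductions of the computational experiments.

Three scripted studies mirror the clinical evaluation protocol on
synthetic phantoms: a view-count sweep (4/6/8/10/12 projections), a
limited-angle comparison (45/90/180 degree coverage at 8 views), and a
stage ablation (stage 1 only / stage 2 only / full cascade). Every run
trains on phantoms, evaluates on held-out phantoms against the cropped
ground truth, and reports mean +/- SD of SSIM/PSNR/MSE/MAE. All
randomness flows from the plan's seed list, so tables reproduce
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .containers import AngleScheme
from .geometry import crop_common_support, make_scheme, project_set
from .metrics import MetricsReport, evaluate
from .network import CascadeConfig, UNetConfig
from .phantom import PhantomSpec, make_dataset
from .training import SelfSupervisedReconstruction, TrainConfig

__all__ = [
    "ExperimentPlan",
    "run_view_sweep",
    "run_limited_angle",
    "run_stage_ablation",
    "dose_reduction_factor",
    "GOLD_STANDARD_VIEWS",
]

#: Rotational views acquired by the conventional reconstruction sweep.
GOLD_STANDARD_VIEWS = 133


def dose_reduction_factor(n_gold: int = GOLD_STANDARD_VIEWS,
                          n_sparse: int = 8) -> float:
    """Radiation-dose reduction of sparse acquisition: views are
    proportional to dose, so 8 instead of ~133 views exposes the
    patient to ~1/16.6 of the dose."""
    if n_sparse < 1 or n_gold < 1:
        raise ValueError("view counts must be positive")
    return n_gold / n_sparse


def _desk_unet(base: int, depth1: int, depth2: int) -> CascadeConfig:
    # the full-resolution refiner is deliberately shallower: its
    # receptive field must stay small relative to the grid (as at
    # clinical scale), so that the low-resolution stage is the only
    # source of global context
    return CascadeConfig(stage1=UNetConfig(depth=depth1, base_features=base),
                         stage2=UNetConfig(depth=depth2, base_features=base),
                         patch_z=None)


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything one experiment needs, fully seeded.

    ``desk()`` is the reference fixture (8 train + 2 held-out phantoms,
    32^3 low / 64^3 high grids); ``mini()`` is the multi-seed sweep
    fixture (16^3 / 32^3) used where several trainings per condition
    are averaged.
    """

    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    view_counts: tuple[int, ...] = (4, 6, 8, 10, 12)
    coverage_spans: tuple[float, ...] = (45.0, 90.0, 180.0)
    limited_angle_views: int = 8
    ablation_views: int = 8
    seeds: tuple[int, ...] = (0,)
    n_train: int = 8
    n_test: int = 2
    low_shape: tuple[int, int, int] = (32, 32, 32)
    high_shape: tuple[int, int, int] = (64, 64, 64)
    cascade_config: CascadeConfig = field(
        default_factory=lambda: _desk_unet(4, 2, 2))
    train_config: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr_stage1=2e-3, lr_stage2=2e-3, lr_decay=0.98,
        epochs_stage1=60, epochs_stage2=12, seed=0))
    out_dir: str | None = None

    def __post_init__(self):
        if self.phantom_spec.grid_shape != self.high_shape:
            object.__setattr__(
                self, "phantom_spec",
                replace(self.phantom_spec, grid_shape=self.high_shape))
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")

    @classmethod
    def desk(cls, **kw) -> "ExperimentPlan":
        return cls(**kw)

    @classmethod
    def mini(cls, seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
             **kw) -> "ExperimentPlan":
        spec = PhantomSpec(grid_shape=(32, 32, 32), n_branches=3,
                           radius_range=(1.0, 2.0),
                           aneurysm_radius_range=(1.5, 2.5))
        defaults = dict(
            phantom_spec=spec,
            seeds=tuple(seeds),
            n_train=3,
            n_test=2,
            low_shape=(16, 16, 16),
            high_shape=(32, 32, 32),
            cascade_config=_desk_unet(4, 2, 1),
            train_config=TrainConfig(lr_stage1=2e-3, lr_stage2=2e-3,
                                     lr_decay=0.98, epochs_stage1=60,
                                     epochs_stage2=20, seed=0),
        )
        defaults.update(kw)
        return cls(**defaults)


def _run_condition(plan: ExperimentPlan, scheme: AngleScheme, mode: str,
                   seed: int) -> list[MetricsReport]:
    """Train one model for one (scheme, mode, seed) condition and
    evaluate it on the held-out phantoms."""
    base_seed = 10_000 + 100 * int(seed)
    vols = make_dataset(plan.n_train + plan.n_test, plan.phantom_spec,
                        base_seed)
    train_vols = vols[: plan.n_train]
    test_vols = vols[plan.n_train:]
    model = SelfSupervisedReconstruction.from_volumes(
        train_vols, scheme,
        low_shape=plan.low_shape, high_shape=plan.high_shape,
        cascade_config=plan.cascade_config,
        train_config=plan.train_config, mode=mode)
    fit = model.fit(seed=seed)
    reports = []
    for gt in test_vols:
        rec = fit.reconstruct(project_set(gt, scheme))
        reports.append(evaluate(crop_common_support(gt), rec))
    return reports


def _aggregate(rows: dict[str, list[MetricsReport]],
               label: str) -> pd.DataFrame:
    out = []
    for key, reports in rows.items():
        df = pd.DataFrame([r.as_dict() for r in reports])
        entry = {label: key, "n_evals": len(reports)}
        for m in ("ssim", "psnr", "mse", "mae"):
            entry[f"{m}_mean"] = float(df[m].mean())
            entry[f"{m}_sd"] = float(df[m].std(ddof=1)) if len(df) > 1 else 0.0
        out.append(entry)
    return pd.DataFrame(out)


def _maybe_write(df: pd.DataFrame, plan: ExperimentPlan, name: str):
    if plan.out_dir:
        path = Path(plan.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        df.to_csv(path / f"{name}.csv", index=False)


def run_view_sweep(plan: ExperimentPlan) -> pd.DataFrame:
    """Train/evaluate one cascade per view count (180-degree coverage),
    averaging the held-out metrics over the plan's seeds."""
    rows: dict[int, list[MetricsReport]] = {}
    for n_views in plan.view_counts:
        scheme = make_scheme(n_views, 180.0)
        reports: list[MetricsReport] = []
        for seed in plan.seeds:
            reports.extend(_run_condition(plan, scheme, "cascade", seed))
        rows[n_views] = reports
    df = _aggregate(rows, "n_views")
    _maybe_write(df, plan, "view_sweep")
    return df


def run_limited_angle(plan: ExperimentPlan) -> pd.DataFrame:
    """Fixed view count, varying angular coverage span."""
    rows: dict[float, list[MetricsReport]] = {}
    for span in plan.coverage_spans:
        scheme = make_scheme(plan.limited_angle_views, span)
        reports: list[MetricsReport] = []
        for seed in plan.seeds:
            reports.extend(_run_condition(plan, scheme, "cascade", seed))
        rows[span] = reports
    df = _aggregate(rows, "coverage_span")
    _maybe_write(df, plan, "limited_angle")
    return df


def run_stage_ablation(plan: ExperimentPlan) -> pd.DataFrame:
    """Stage 1 only vs stage 2 only vs the full cascade."""
    scheme = make_scheme(plan.ablation_views, 180.0)
    rows: dict[str, list[MetricsReport]] = {}
    for mode in ("stage1", "stage2", "cascade"):
        reports: list[MetricsReport] = []
        for seed in plan.seeds:
            reports.extend(_run_condition(plan, scheme, mode, seed))
        rows[mode] = reports
    df = _aggregate(rows, "stages")
    _maybe_write(df, plan, "stage_ablation")
    return df
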