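"""Self-supervised optimisation of the cascade.

The only training signal is projection consistency: the predicted
volume is forward-projected (MIP) at the input view angles and the
squared difference to the corresponding input 2D views is minimised.
No 3D labels enter the procedure. Each stage is trained with Adam
under an exponentially decaying learning rate, the per-epoch training
and validation losses are recorded, and the checkpoint with the
smallest validation loss is kept.

The statsmodels-style entry point is
:class:`SelfSupervisedReconstruction` (model built from projection
sets) whose :meth:`~SelfSupervisedReconstruction.fit` returns a
:class:`ReconstructionFit` results object; :func:`train_stage` and
:func:`train_cascade` are the underlying procedures.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .containers import AngleScheme, ProjectionSet, Volume, as_volume_array
from .geometry import crop_common_support, forward_mip
from .network import CascadeConfig, CascadeModel
from .preprocess import assemble, normalize_views, resize_views

__all__ = [
    "TrainConfig",
    "LossRecord",
    "TrainingDiverged",
    "projection_loss",
    "train_stage",
    "train_cascade",
    "reconstruct",
    "SelfSupervisedReconstruction",
    "ReconstructionFit",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults follow the clinical recipe
    (stage-1/stage-2 initial learning rates 0.001/0.03, exponential
    decay 0.9 per epoch, 1500/400 epochs). Desk-scale runs override the
    epoch counts and learning rates."""

    lr_stage1: float = 0.001
    lr_stage2: float = 0.03
    lr_decay: float = 0.9
    epochs_stage1: int = 1500
    epochs_stage2: int = 400
    batch: int = 1
    seed: int = 0
    loss_reduction: str = "mean"
    freeze_stage1: bool = True

    def __post_init__(self):
        if self.lr_stage1 <= 0 or self.lr_stage2 <= 0:
            raise ValueError("learning rates must be > 0")
        if not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs_stage1 < 1 or self.epochs_stage2 < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")


@dataclass
class LossRecord:
    """Per-epoch training/validation loss plus the best checkpoint."""

    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = float("inf")

    @property
    def lr_history(self):
        return getattr(self, "_lr_history", [])


def projection_loss(pred, projections: ProjectionSet,
                    reduction: str = "mean"):
    """Sum over views of the squared projection mismatch.

    ``sum``: ``sum_i ||MIP(pred, theta_i) - X_i||^2`` over all pixels.
    ``mean`` divides by (n_views * pixels per view). Zero exactly when
    every projection matches its input. Accepts a
    :class:`~ssdr.autodiff.Tensor` (differentiable) or an
    array/:class:`Volume` (returns a float).
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    angles = projections.angles
    targets = projections.stack()
    n_pix = targets.size
    if isinstance(pred, Tensor):
        total = None
        for angle, target in zip(angles, targets):
            d = ad.mip(pred, angle) - Tensor(target)
            term = d.square().sum()
            total = term if total is None else total + term
        return total * (1.0 / n_pix) if reduction == "mean" else total
    vol = as_volume_array(pred)
    total = 0.0
    for angle, target in zip(angles, targets):
        d = forward_mip(vol, angle).image.astype(np.float64) - target
        total += float(np.sum(d * d))
    return total / n_pix if reduction == "mean" else total


def _case_loss(model: CascadeModel, stage: int, case: dict,
               config: TrainConfig, build_graph: bool):
    channels = case["channels_low" if stage == 1 else "channels_high"]
    targets = case["targets_low" if stage == 1 else "targets_high"]
    if build_graph:
        x = Tensor(channels)
        if stage == 1:
            pred = model.forward_stage1(x)
        else:
            y1 = case.get("y1")
            if y1 is not None and not config.freeze_stage1:
                low = model.forward_stage1(Tensor(case["channels_low"]))
                y1_t = ad.resample_linear(low, channels.shape[1:])
            else:
                y1_t = None if y1 is None else Tensor(y1)
            pred = model.forward_stage2(x, y1_t)
        return projection_loss(pred, targets, config.loss_reduction)
    with ad.no_grad():
        loss = _case_loss(model, stage, case, config, True)
    return float(loss.data)


def train_stage(model: CascadeModel, cases: list[dict], config: TrainConfig,
                stage: int, val_cases: list[dict] | None = None,
                epochs: int | None = None) -> LossRecord:
    """Optimise one stage with Adam and per-epoch exponential LR decay.

    ``cases`` carry precomputed multi-view channels and projection
    targets (see :func:`train_cascade`). Returns the loss record; the
    model is left at the checkpoint with the smallest validation loss.
    """
    if not cases:
        raise ValueError("training dataset is empty")
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    val_cases = val_cases if val_cases else cases
    lr0 = config.lr_stage1 if stage == 1 else config.lr_stage2
    n_epochs = int(epochs if epochs is not None
                   else (config.epochs_stage1 if stage == 1
                         else config.epochs_stage2))
    params = model.stage1_params if stage == 1 else model.stage2_params
    if stage == 2 and not config.freeze_stage1:
        params = params + model.stage1_params
    opt = ad.Adam(params, lr=lr0)
    record = LossRecord()
    lr_history = []
    best_state = None
    for epoch in range(n_epochs):
        lr = lr0 * config.lr_decay ** epoch
        lr_history.append(lr)
        order = np.random.default_rng(
            (int(config.seed), stage, epoch)).permutation(len(cases))
        epoch_losses = []
        for ci in order:
            loss = _case_loss(model, stage, cases[ci], config, True)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise TrainingDiverged(
                    f"stage {stage}: loss became non-finite at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_losses.append(lv)
        val_loss = float(np.mean(
            [_case_loss(model, stage, c, config, False) for c in val_cases]))
        if not np.isfinite(val_loss):
            raise TrainingDiverged(
                f"stage {stage}: validation loss non-finite at epoch {epoch}")
        record.train.append(float(np.mean(epoch_losses)))
        record.val.append(val_loss)
        if val_loss < record.best_val:
            record.best_val = val_loss
            record.best_epoch = epoch
            best_state = [p.data.copy() for p in params]
    if best_state is not None:
        for p, arr in zip(params, best_state):
            p.data = arr
    record._lr_history = lr_history
    return record


def _resample_volume(vol: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear resampling (numpy path of the differentiable op)."""
    with ad.no_grad():
        return ad.resample_linear(Tensor(vol), tuple(int(s) for s in target_shape)).data


def build_cases(projection_sets: list[ProjectionSet], scheme: AngleScheme,
                low_shape: tuple[int, int, int],
                high_shape: tuple[int, int, int]) -> list[dict]:
    """Precompute per-case channels and loss targets at both scales.

    Projection detector shapes are tied to the grids: high views are
    (U, V) = (X_high, Z_high), low views (X_low, Z_low).
    """
    cases = []
    for pset in projection_sets:
        pset = normalize_views(pset)
        high_det = (high_shape[0], high_shape[2])
        low_det = (low_shape[0], low_shape[2])
        p_high = resize_views(pset, high_det)
        p_low = resize_views(pset, low_det)
        cases.append({
            "channels_high": assemble(p_high, scheme, "high",
                                      depth=high_shape[1]).channels,
            "channels_low": assemble(p_low, scheme, "low",
                                     depth=low_shape[1]).channels,
            "targets_high": p_high,
            "targets_low": p_low,
        })
    return cases


def _attach_y1(model: CascadeModel, cases: list[dict]):
    for case in cases:
        with ad.no_grad():
            low = model.forward_stage1(Tensor(case["channels_low"]))
        y1 = np.clip(low.data, 0.0, 1.0)
        case["y1"] = _resample_volume(y1, case["channels_high"].shape[1:])


def train_cascade(projection_sets: list[ProjectionSet], scheme: AngleScheme,
                  low_shape: tuple[int, int, int],
                  high_shape: tuple[int, int, int],
                  cascade_config: CascadeConfig | None = None,
                  train_config: TrainConfig | None = None,
                  mode: str = "cascade"):
    """Train the two-stage reconstructor self-supervised.

    ``mode``: ``cascade`` (both stages, stage 1 first and frozen per
    config), ``stage1`` (low-resolution net only) or ``stage2``
    (full-resolution net without the cascade input channel).
    Returns ``(model, {"stage1": LossRecord, "stage2": LossRecord})``
    (records present for the stages actually trained).
    """
    if mode not in ("cascade", "stage1", "stage2"):
        raise ValueError("mode must be cascade, stage1 or stage2")
    train_config = train_config or TrainConfig()
    model = CascadeModel(cascade_config, seed=train_config.seed)
    cases = build_cases(projection_sets, scheme, low_shape, high_shape)
    n = len(cases)
    n_val = max(1, n // 10) if n >= 2 else 0
    train_cases = cases[: n - n_val] if n_val else cases
    val_cases = cases[n - n_val:] if n_val else cases
    records: dict[str, LossRecord] = {}
    if mode in ("cascade", "stage1"):
        records["stage1"] = train_stage(model, train_cases, train_config, 1,
                                        val_cases)
    if mode in ("cascade", "stage2"):
        if mode == "cascade":
            _attach_y1(model, cases)
        records["stage2"] = train_stage(model, train_cases, train_config, 2,
                                        val_cases)
    return model, records


def reconstruct(model: CascadeModel, projections: ProjectionSet,
                scheme: AngleScheme, low_shape, high_shape,
                mode: str = "cascade") -> Volume:
    """Run the trained pipeline on one case and return the final volume
    (clamped to [0, 1] and cropped to the common support)."""
    case = build_cases([projections], scheme, low_shape, high_shape)[0]
    with ad.no_grad():
        if mode == "stage1":
            low = model.forward_stage1(Tensor(case["channels_low"]))
            out = _resample_volume(np.clip(low.data, 0, 1), high_shape)
        elif mode == "stage2":
            pred = model.forward_stage2(Tensor(case["channels_high"]), None)
            out = pred.data
        else:
            low = model.forward_stage1(Tensor(case["channels_low"]))
            y1 = _resample_volume(np.clip(low.data, 0, 1), high_shape)
            pred = model.forward_stage2(Tensor(case["channels_high"]),
                                        Tensor(y1))
            out = pred.data
    return crop_common_support(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class SelfSupervisedReconstruction:
    """Self-supervised sparse-view reconstruction model.

    Built from the training projection sets (no 3D labels); ``fit``
    trains the cascade and returns a :class:`ReconstructionFit`.
    """

    def __init__(self, projection_sets: list[ProjectionSet],
                 scheme: AngleScheme,
                 low_shape: tuple[int, int, int] = (32, 32, 32),
                 high_shape: tuple[int, int, int] = (64, 64, 64),
                 cascade_config: CascadeConfig | None = None,
                 train_config: TrainConfig | None = None,
                 mode: str = "cascade"):
        if not projection_sets:
            raise ValueError("need at least one training case")
        self.projection_sets = list(projection_sets)
        self.scheme = scheme
        self.low_shape = tuple(low_shape)
        self.high_shape = tuple(high_shape)
        self.cascade_config = cascade_config or CascadeConfig()
        self.train_config = train_config or TrainConfig()
        self.mode = mode

    @classmethod
    def from_volumes(cls, volumes: list[Volume], scheme: AngleScheme,
                     **kwargs) -> "SelfSupervisedReconstruction":
        """Convenience constructor: simulate the acquisition by forward
        projecting ground-truth volumes at the scheme angles."""
        from .geometry import project_set
        psets = [project_set(v, scheme) for v in volumes]
        return cls(psets, scheme, **kwargs)

    def fit(self, seed: int | None = None) -> "ReconstructionFit":
        cfg = self.train_config
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        model, records = train_cascade(
            self.projection_sets, self.scheme, self.low_shape,
            self.high_shape, self.cascade_config, cfg, self.mode)
        return ReconstructionFit(self, model, records, cfg)


class ReconstructionFit:
    """Results of fitting the self-supervised cascade."""

    def __init__(self, model_spec: SelfSupervisedReconstruction,
                 model: CascadeModel, records: dict, train_config: TrainConfig):
        self.spec = model_spec
        self.model = model
        self.records = records
        self.train_config = train_config

    def reconstruct(self, projections: ProjectionSet) -> Volume:
        return reconstruct(self.model, projections, self.spec.scheme,
                           self.spec.low_shape, self.spec.high_shape,
                           self.spec.mode)

    def loss_dataframe(self):
        import pandas as pd
        frames = []
        for stage, rec in self.records.items():
            frames.append(pd.DataFrame({
                "stage": stage,
                "epoch": np.arange(len(rec.train)),
                "train_loss": rec.train,
                "val_loss": rec.val,
            }))
        return pd.concat(frames, ignore_index=True)

    def plot_loss(self, ax=None):
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for stage, rec in self.records.items():
            ax.semilogy(rec.train, label=f"{stage} train")
            ax.semilogy(rec.val, "--", label=f"{stage} val")
        ax.set_xlabel("epoch")
        ax.set_ylabel("projection-consistency loss")
        ax.legend()
        return ax

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Self-supervised sparse-view reconstruction\n")
        buf.write("=" * 44 + "\n")
        buf.write(f"views:            {len(self.spec.scheme)} "
                  f"(coverage {self.spec.scheme.coverage_span:g} deg)\n")
        buf.write(f"training cases:   {len(self.spec.projection_sets)}\n")
        buf.write(f"grids:            low {self.spec.low_shape}, "
                  f"high {self.spec.high_shape}\n")
        buf.write(f"mode:             {self.spec.mode}\n")
        buf.write(f"parameters:       {self.model.parameter_count()}\n")
        for stage, rec in self.records.items():
            buf.write(
                f"{stage}: epochs {len(rec.train)}, "
                f"final train loss {rec.train[-1]:.3e}, "
                f"best val loss {rec.best_val:.3e} @ epoch {rec.best_epoch}\n")
        return buf.getvalue()
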