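"""Training loop, repetition harness and statistical comparison.

Protocol: AdamW (lr 1e-4), focal Tversky loss, batch size 8, at most 50
epochs with early stopping after 15 consecutive epochs without a strictly
lower validation loss; the returned weights are the snapshot with minimum
validation loss.  Experiments repeat the whole pipeline (fresh data draw,
fresh 60/20/20 split, fresh initialisation) and compare variants with a
two-sided paired t-test at the 0.1 and 0.05 levels.  Every knob is a
config field so the same harness runs at clinical scale or desk scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize as _sk_resize

from .arch import ReflexNet, build_variant
from .losses import LossConfig, focal_tversky_loss
from .metrics import METRIC_NAMES, MetricsReport, evaluate_dataset
from .nn import AdamW, Tensor, no_grad
from .synthetic import Sample, SceneParams, generate_dataset

log = logging.getLogger("reflexseg")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class AugmentConfig:
    """Random horizontal flip and random crop-and-resize for training."""

    random_crop_fraction: float = 0.8   # retained area fraction >= this
    hflip_prob: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.random_crop_fraction <= 1.0:
            raise ValueError("random_crop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    max_epochs: int = 50
    patience: int = 15
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    reps: int = 30
    # desk-scale knobs
    channel_scale: float = 1.0
    image_size: int = 512
    n_samples: int = 408
    #: re-draw the train/val/test split every repetition (alternative:
    #: keep the split fixed and only re-initialise weights)
    redraw_split: bool = True

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    df: int
    significant_10: bool
    significant_05: bool


@dataclass
class ExperimentResult:
    """Per-repetition metric table and its mean +/- std summary."""

    per_rep: pd.DataFrame   # columns: rep, variant, dice, iou, precision, recall
    summary: pd.DataFrame   # index: variant; columns: <metric>_mean/_std

    def metric_vector(self, variant: str, metric: str) -> np.ndarray:
        sel = self.per_rep[self.per_rep.variant == variant]
        return sel.sort_values("rep")[metric].to_numpy()


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items (ties go to the
    later split, so 408 at 0.6/0.2/0.2 gives 245/81/82)."""
    base = [int(np.floor(f * n)) for f in fractions]
    rem = [f * n - b for f, b in zip(fractions, base)]
    leftover = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-rem[i], -i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_dataset(samples: list, fractions: tuple[float, float, float],
                  seed: int) -> tuple[list, list, list]:
    """Seeded shuffle then disjoint, exhaustive 3-way split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(samples)
    sizes = split_sizes(n, fractions)
    if min(sizes) < 1:
        raise ValueError(f"{n} samples are too few for nonempty splits")
    perm = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for size in sizes:
        out.append([samples[i] for i in perm[start:start + size]])
        start += size
    return tuple(out)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_sample(sample: Sample, rng: np.random.Generator,
                   cfg: AugmentConfig = AugmentConfig(),
                   max_retries: int = 10) -> Sample:
    """Jointly flip/crop an image and its mask; the mask stays binary.

    A crop that would remove all foreground is redrawn; after
    ``max_retries`` failures the crop is skipped for this sample.
    """
    image, mask = sample.image, sample.mask
    if rng.uniform() < cfg.hflip_prob:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if cfg.random_crop_fraction < 1.0:
        h, w = mask.shape
        for _ in range(max_retries):
            side = np.sqrt(rng.uniform(cfg.random_crop_fraction, 1.0))
            ch, cw = max(1, round(h * side)), max(1, round(w * side))
            top = rng.integers(0, h - ch + 1)
            left = rng.integers(0, w - cw + 1)
            mcrop = mask[top:top + ch, left:left + cw]
            if mcrop.sum() == 0 and mask.sum() > 0:
                continue
            icrop = image[top:top + ch, left:left + cw]
            image = _sk_resize(icrop, (h, w), order=1, mode="edge",
                               anti_aliasing=False,
                               preserve_range=True).astype(np.float32)
            mask = _sk_resize(mcrop.astype(np.float32), (h, w), order=0,
                              mode="edge", anti_aliasing=False,
                              preserve_range=True).astype(np.uint8)
            break
    return Sample(image=np.ascontiguousarray(image),
                  mask=np.ascontiguousarray(mask),
                  metadata=dict(sample.metadata))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a strictly
    lower monitored loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0

    def update(self, loss: float) -> bool:
        """Record an epoch's loss; returns True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        x, y = samples
    else:
        if len(samples) == 0:
            raise ValueError("sample sets must be nonempty")
        x = np.stack([s.image for s in samples])
        y = np.stack([s.mask for s in samples])
    x = np.ascontiguousarray(x.astype(np.float32))
    y = y.astype(np.float32)[..., None]
    return x, y


def _eval_loss(net: ReflexNet, x: np.ndarray, y: np.ndarray,
               loss_cfg: LossConfig, batch_size: int) -> float:
    net.eval()
    losses, weights = [], []
    with no_grad():
        for lo in range(0, len(x), batch_size):
            xb, yb = x[lo:lo + batch_size], y[lo:lo + batch_size]
            pred = net(Tensor(xb))
            losses.append(focal_tversky_loss(pred, yb, loss_cfg).item())
            weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train(network: ReflexNet, train_set, val_set,
          cfg: TrainConfig = TrainConfig()
          ) -> tuple[dict[str, np.ndarray], dict]:
    """Optimise the network; returns (min-val-loss weights, history).

    ``train_set``/``val_set`` are lists of :class:`Sample` or ``(images,
    masks)`` array pairs.  The network is left loaded with the returned
    best weights.
    """
    xt, yt = _to_arrays(train_set)
    xv, yv = _to_arrays(val_set)
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("training and validation sets must be nonempty")
    train_samples = None
    if cfg.augment is not None and not isinstance(train_set, tuple):
        train_samples = list(train_set)

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(network.parameters(), lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    best_state, best_val = None, np.inf
    history = {"train_loss": [], "val_loss": [], "best_epoch": 0}

    for epoch in range(1, cfg.max_epochs + 1):
        network.train()
        perm = rng.permutation(len(xt))
        epoch_losses = []
        for lo in range(0, len(perm), cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            if train_samples is not None:
                aug = [augment_sample(train_samples[i], rng, cfg.augment)
                       for i in idx]
                xb, yb = _to_arrays(aug)
            else:
                xb, yb = xt[idx], yt[idx]
            pred = network(Tensor(xb))
            loss = focal_tversky_loss(pred, yb, cfg.loss)
            lval = loss.item()
            if not np.isfinite(lval):
                raise TrainingError(
                    f"non-finite training loss {lval} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lval)
        val_loss = _eval_loss(network, xv, yv, cfg.loss, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        log.info("epoch %d: train %.4f val %.4f", epoch,
                 history["train_loss"][-1], val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = network.state_dict()
            history["best_epoch"] = epoch
        if stopper.update(val_loss):
            break
    network.load_state_dict(best_state)
    return best_state, history


def predict_masks(network: ReflexNet, samples, threshold: float = 0.5,
                  batch_size: int = 8) -> list[np.ndarray]:
    """Binary predicted masks for a list of samples (or image array)."""
    if isinstance(samples, np.ndarray):
        x = np.ascontiguousarray(samples, dtype=np.float32)
    else:
        x, _ = _to_arrays(samples)
    network.eval()
    out = []
    with no_grad():
        for lo in range(0, len(x), batch_size):
            pred = network(Tensor(x[lo:lo + batch_size])).numpy()
            out.extend((p[..., 0] > threshold).astype(np.uint8) for p in pred)
    return out


def evaluate_network(network: ReflexNet, samples,
                     threshold: float = 0.5) -> MetricsReport:
    preds = predict_masks(network, samples, threshold)
    truths = [s.mask for s in samples]
    return evaluate_dataset(preds, truths, threshold)


# ---------------------------------------------------------------------------
# repetitions and statistics
# ---------------------------------------------------------------------------

def _rep_seeds(master_seed: int, rep: int) -> tuple[int, int, int]:
    state = np.random.SeedSequence([master_seed, rep]).generate_state(3)
    return tuple(int(v) % (2 ** 31) for v in state)


def run_repetitions(variants: list[str], scene_params: SceneParams,
                    cfg: TrainConfig) -> ExperimentResult:
    """Repeat (draw data, split, train every variant, test) ``cfg.reps``
    times.

    Within a repetition all variants see byte-identical train/val/test
    data and the same initialisation seed, so per-rep metric vectors are
    paired.  A failed repetition is recorded as NaN with a warning rather
    than aborting the experiment.
    """
    if not variants:
        raise ValueError("at least one variant is required")
    rows = []
    fixed_seeds = _rep_seeds(cfg.seed, 0)
    for rep in range(cfg.reps):
        data_seed, split_seed, init_seed = _rep_seeds(cfg.seed, rep)
        if not cfg.redraw_split:
            data_seed, split_seed = fixed_seeds[0], fixed_seeds[1]
        params = replace(scene_params, seed=data_seed,
                         image_size=cfg.image_size)
        samples, _ = generate_dataset(params, cfg.n_samples)
        train_s, val_s, test_s = split_dataset(samples, cfg.split, split_seed)
        for variant in variants:
            row = {"rep": rep, "variant": variant}
            try:
                net = build_variant(variant, channel_scale=cfg.channel_scale,
                                    seed=init_seed)
                train(net, train_s, val_s, replace(cfg, seed=init_seed))
                report = evaluate_network(net, test_s)
                row.update({m: getattr(report, m) for m in METRIC_NAMES})
            except (TrainingError, FloatingPointError) as err:
                warnings.warn(f"repetition {rep} variant {variant} failed: "
                              f"{err}", stacklevel=2)
                row.update({m: np.nan for m in METRIC_NAMES})
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("variant")[list(METRIC_NAMES)].agg(
        ["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return ExperimentResult(per_rep=per_rep, summary=summary)


def paired_t_test(a, b) -> PairedTestResult:
    """Two-sided paired t-test on equal-length per-repetition vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t_statistic=float(t), p_value=float(p), df=n - 1,
                            significant_10=p < 0.1, significant_05=p < 0.05)


def format_report(result: ExperimentResult,
                  reference: str | None = None) -> pd.DataFrame:
    """Render a variant x metric table of "mean +/- std" strings.

    For each metric the best-mean variant (or ``reference``) is compared
    with every other variant by paired t-test; ``*`` marks significance
    at 0.1 and ``**`` at 0.05.
    """
    variants = list(dict.fromkeys(result.per_rep.variant))
    out = {}
    for metric in METRIC_NAMES:
        means = {v: np.nanmean(result.metric_vector(v, metric))
                 for v in variants}
        best = reference or max(means, key=means.get)
        col = {}
        for v in variants:
            cell = f"{means[v]:.3f} ± " \
                   f"{np.nanstd(result.metric_vector(v, metric), ddof=1):.3f}"
            if v != best:
                test = paired_t_test(result.metric_vector(best, metric),
                                     result.metric_vector(v, metric))
                cell += "**" if test.significant_05 else \
                    ("*" if test.significant_10 else "")
            col[v] = cell
        out[metric] = col
    return pd.DataFrame(out).loc[variants]


__all__ = [
    "TrainConfig", "AugmentConfig", "TrainingError", "EarlyStopper",
    "PairedTestResult", "ExperimentResult", "split_sizes", "split_dataset",
    "augment_sample", "train", "predict_masks", "evaluate_network",
    "run_repetitions", "paired_t_test", "format_report",
]
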