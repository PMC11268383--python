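"""Patient-stratified splitting and the training protocol.

Training follows the protocol used for the hyperspectral patch classifier:
SGD with Nesterov momentum 0.9, batch size 16, initial learning rate 1e-3
halved every five epochs, 15 epochs, cross-entropy loss, optional
hyperspectral RandAugment on the training inputs only, and selection of the
checkpoint from the epoch with the maximum validation weighted-F1 score
(ties broken toward the earliest epoch).  Splits are patient-disjoint so no
subject contributes to more than one of train/validation/test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import autodiff as ad
from .augment import HyperspectralRandAugment, TransformRanges
from .model import SpectralSpatialTransformer

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 15
    batch_size: int = 16
    lr0: float = 1e-3
    momentum: float = 0.9  # Nesterov
    lr_decay: float = 0.5
    lr_decay_every: int = 5
    augment: bool = False
    augment_ranges: TransformRanges | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: ``lr0 * lr_decay ** floor(epoch / lr_decay_every)``."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_decay_every)


def split_by_patient(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Patient-disjoint train/val/test split with approximate class balance.

    Patients are grouped by their majority label, shuffled within each
    label group (seeded), and dealt greedily to the split with the largest
    remaining record deficit, so per-split class proportions track the
    global ones as closely as the patient blocks allow.
    """
    for col in ("patient_id", "label"):
        if col in manifest and manifest[col].isna().any():
            raise ValueError(f"manifest has missing {col}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients = manifest.groupby("patient_id")["label"].agg(
        lambda s: s.value_counts().idxmax()
    )
    if len(patients) < 3:
        raise ValueError("need at least as many patients as splits")
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    counts = manifest["patient_id"].value_counts()
    assigned: dict[str, list] = {n: [] for n in names}
    # deal each label group separately so per-split class proportions
    # track the global ones as closely as the patient blocks allow
    for label in sorted(patients.unique()):
        group = sorted(patients.index[patients == label])
        rng.shuffle(group)
        group_total = int(sum(counts[p] for p in group))
        filled = {n: 0 for n in names}
        for pid in group:
            deficits = {
                n: fractions[i] - filled[n] / group_total for i, n in enumerate(names)
            }
            target = max(names, key=lambda n: deficits[n])
            assigned[target].append(pid)
            filled[target] += int(counts[pid])
    out = {
        n: manifest[manifest["patient_id"].isin(assigned[n])].reset_index(drop=True)
        for n in names
    }
    for a in names:
        for b in names:
            if a < b and set(out[a]["patient_id"]) & set(out[b]["patient_id"]):
                raise AssertionError("patient leaked across splits")
    return out


class _NesterovSGD:
    """SGD with Nesterov momentum over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], momentum: float):
        self.params = params
        self.mu = momentum
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        for k, g in grads.items():
            v = self.vel[k]
            v *= self.mu
            v += g
            self.params[k] -= lr * (g + self.mu * v)


def train_model(
    model: SpectralSpatialTransformer,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    wavelengths: np.ndarray | None = None,
    normalize=None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Train in place; return (best checkpoint params, per-epoch log).

    The returned checkpoint is a copy of the parameters at the epoch with
    the maximum validation weighted F1 (earliest epoch on ties).  The log
    has one row per epoch with ``epoch, lr, train_loss, val_f1, val_acc``.
    ``normalize``, if given, maps a raw batch to network inputs and is
    applied after augmentation (augmentation operates on raw [0, 1]
    transmittance).  Aborts with the last finite log if the loss diverges
    to NaN.
    """
    Xtr, ytr = train_set
    Xva, yva = val_set
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    augmenter = (
        HyperspectralRandAugment(
            ranges=cfg.augment_ranges,
            wavelengths=wavelengths,
            random_state=cfg.seed,
        )
        if cfg.augment
        else None
    )
    opt = _NesterovSGD(model.params, cfg.momentum)
    rows = []
    best_f1, best_epoch, best_params = -np.inf, -1, None
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        order = np.random.default_rng((cfg.seed, epoch)).permutation(len(Xtr))
        losses = []
        diverged = False
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = Xtr[idx]
            if augmenter is not None:
                # per-sample child seeds keyed by (epoch, dataset index)
                sample_ids = np.asarray([epoch * len(Xtr) + i for i in idx])
                xb = augmenter.transform(xb, sample_ids=sample_ids)
            if normalize is not None:
                xb = normalize(xb)
            logits = model.forward(
                xb,
                train=True,
                dropout_rng=np.random.default_rng((cfg.seed, epoch, int(start), 7)),
            )
            loss = ad.cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss.data):
                logger.error("training diverged (non-finite loss) at epoch %d", epoch)
                diverged = True
                break
            loss.backward()
            opt.step(model.gradients(), lr)
            losses.append(float(loss.data))
        if diverged:
            break
        proba = model.predict_proba(normalize(Xva) if normalize is not None else Xva)
        pred = proba.argmax(axis=1)
        val_f1 = float(f1_score(yva, pred, average="weighted"))
        val_acc = float((pred == yva).mean())
        rows.append(
            dict(
                epoch=epoch,
                lr=lr,
                train_loss=float(np.mean(losses)),
                val_f1=val_f1,
                val_acc=val_acc,
            )
        )
        if val_f1 > best_f1:  # strict: ties keep the earliest epoch
            best_f1, best_epoch = val_f1, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    log = pd.DataFrame(rows)
    if best_params is None:
        raise RuntimeError("no finite training epoch completed")
    log.attrs["best_epoch"] = best_epoch
    return best_params, log
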