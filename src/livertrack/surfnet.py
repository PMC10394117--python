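"""Surface-image registration network (the surface regressor).

A residual convolutional network maps a body-surface heightmap to the liver
boundary displacement field: entrance convolution, a stack of residual
modules (feature count doubling, spatial size halved by each module's
stride-2 second convolution), then three parallel linear heads emitting the
LR, AP and SI displacement components at the N liver boundary nodes, in mm.

Trained per phantom "patient" with the mean-squared node-displacement loss

    L_surf = (1/N) sum_p || d_p - d_p^gt ||^2 .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grid import BoundaryDVF
from .nn import autodiff as ad
from .surface import BACKGROUND, SurfaceImage

__all__ = [
    "SurfNetConfig", "SurfNet", "build_surf_net", "surf_loss",
    "TrainSchedule", "train_surf", "predict_boundary_dvf",
]


@dataclass(frozen=True)
class SurfNetConfig:
    """Architecture of the surface regressor.

    The full-scale network uses 12 entrance features and 5 residual modules
    on 260 x 260 images; the desk default is narrower and shallower so it
    trains on a CPU.
    """

    input_shape: tuple = (64, 64)
    n_nodes: int = 162
    entrance_features: int = 8
    n_residual_modules: int = 4
    kernel: int = 3
    seed: int = 0

    @classmethod
    def full_scale(cls, n_nodes: int) -> "SurfNetConfig":
        return cls(input_shape=(260, 260), n_nodes=n_nodes,
                   entrance_features=12, n_residual_modules=5)


class _ResidualModule2d(nn.Module):
    """Two 3x3 convolutions (second with stride 2) + 1x1 strided shortcut."""

    def __init__(self, cin, cout, rng, k=3):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, k=k, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, k=k, stride=2, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.short = nn.Conv2d(cin, cout, k=1, stride=2, pad=0, rng=rng)

    def forward(self, x):
        y = ad.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return ad.relu(y + self.short(x))


class SurfNet(nn.Module):
    def __init__(self, cfg: SurfNetConfig):
        super().__init__()
        h, w = cfg.input_shape
        if h % (2 ** cfg.n_residual_modules) or w % (2 ** cfg.n_residual_modules):
            raise ValueError(
                f"input shape {cfg.input_shape} is not divisible by "
                f"2**{cfg.n_residual_modules}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.entrance_features
        self.entrance = nn.Conv2d(1, c, k=cfg.kernel, rng=rng)
        self.bn0 = nn.BatchNorm2d(c)
        mods = []
        for k in range(cfg.n_residual_modules):
            mods.append(_ResidualModule2d(c, 2 * c, rng, k=cfg.kernel))
            c *= 2
        self.modules2d = nn.Sequential(*mods)
        hf = h // 2 ** cfg.n_residual_modules
        wf = w // 2 ** cfg.n_residual_modules
        self.flat_features = c * hf * wf
        # three parallel heads, one Cartesian component each
        self.head_lr = nn.Linear(self.flat_features, cfg.n_nodes, rng=rng, scale=0.1)
        self.head_ap = nn.Linear(self.flat_features, cfg.n_nodes, rng=rng, scale=0.1)
        self.head_si = nn.Linear(self.flat_features, cfg.n_nodes, rng=rng, scale=0.1)
        # input standardization constants, set from the prior surface image
        self.register_buffer("norm_mean", np.zeros(1))
        self.register_buffer("norm_sd", np.ones(1))

    def feature_counts(self):
        """Feature-map count of the entrance layer and each residual module."""
        c = self.cfg.entrance_features
        return [c] + [c * 2 ** (k + 1) for k in range(self.cfg.n_residual_modules)]

    def set_normalization(self, prior: SurfaceImage):
        fg = prior.foreground
        self.norm_mean[...] = prior.heights[fg].mean()
        self.norm_sd[...] = max(prior.heights[fg].std(), 1e-6)

    def normalize(self, image: SurfaceImage) -> np.ndarray:
        """Standardize heights; background pixels map to 0 afterwards."""
        h = (image.heights - self.norm_mean[0]) / self.norm_sd[0]
        return np.where(image.foreground, h, 0.0)

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """(B, 1, H, W) standardized heightmaps -> (B, N, 3) DVFs in mm."""
        y = ad.relu(self.bn0(self.entrance(x)))
        y = self.modules2d(y)
        y = ad.reshape(y, (y.shape[0], self.flat_features))
        return ad.stack_last([self.head_lr(y), self.head_ap(y), self.head_si(y)])


def build_surf_net(cfg: SurfNetConfig) -> SurfNet:
    """Construct the surface regressor for a given configuration."""
    return SurfNet(cfg)


def surf_loss(pred, gt):
    """Mean squared node displacement error (1/N) sum_p ||d_p - d_p^gt||^2.

    Accepts (N, 3) arrays / BoundaryDVFs (returns float) or autodiff tensors
    with matching shapes, possibly batched, (returns a Tensor).
    """
    p = pred.d if isinstance(pred, BoundaryDVF) else pred
    g = gt.d if isinstance(gt, BoundaryDVF) else gt
    if isinstance(p, ad.Tensor) or isinstance(g, ad.Tensor):
        pt = p if isinstance(p, ad.Tensor) else ad.constant(p)
        gt_ = g if isinstance(g, ad.Tensor) else ad.constant(g)
        if pt.shape != gt_.shape:
            raise ValueError("shape mismatch in surf_loss")
        diff = pt - gt_
        n = pt.shape[-2]
        return ad.sum_all(diff * diff) * (1.0 / (n * int(np.prod(pt.shape[:-2], initial=1))))
    p = np.asarray(p, float)
    g = np.asarray(g, float)
    if p.shape != g.shape:
        raise ValueError("shape mismatch in surf_loss")
    return float(((p - g) ** 2).sum() / p.shape[-2] / np.prod(p.shape[:-2], initial=1))


@dataclass(frozen=True)
class TrainSchedule:
    """Optimizer/schedule hyperparameters shared by the training loops."""

    lr: float = 2e-4
    weight_decay: float = 1e-7
    epochs: int = 200
    batch_size: int = 16
    plateau_factor: float = 0.6     # reduce the learning rate by 40 %
    plateau_patience: int = 10
    step_size: int = None           # when set, use a fixed-step schedule
    step_gamma: float = 0.6


def train_surf(model: SurfNet, train_cases, val_cases,
               schedule: TrainSchedule = None, seed: int = 0,
               augment=None, verbose: bool = False):
    """Train the surface regressor on pre-simulated cases.

    Parameters
    ----------
    train_cases, val_cases : sequences of ``(image (H, W) standardized array,
        target (N, 3) mm)`` pairs.  When ``augment`` is given, training
        cases may be arbitrary objects that ``augment`` materializes.
    augment : optional callable ``(case, rng) -> (image, target)`` applied
        to every training example each epoch (on-the-fly rigid translation
        and surface noise live here).  Validation cases stay as plain
        pairs.

    Returns the model loaded with the best-validation-loss checkpoint and a
    history list of per-epoch (train_loss, val_loss, lr).
    """
    sched = schedule or TrainSchedule()
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=sched.lr,
                  weight_decay=sched.weight_decay)
    reducer = nn.ReduceLROnPlateau(opt, sched.plateau_factor,
                                   sched.plateau_patience)

    def materialize(case, train):
        if augment is not None and train:
            return augment(case, rng)
        return case

    best = (np.inf, model.state_dict())
    history = []
    n = len(train_cases)
    for epoch in range(sched.epochs):
        model.train()
        order = rng.permutation(n)
        tr_loss = 0.0
        for start in range(0, n, sched.batch_size):
            idx = order[start:start + sched.batch_size]
            imgs, tgts = zip(*[materialize(train_cases[i], True) for i in idx])
            x = ad.constant(np.stack(imgs)[:, None])
            y = ad.constant(np.stack(tgts))
            model.zero_grad()
            pred = model(x)
            loss = surf_loss(pred, y)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"surface-regressor training diverged at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            tr_loss += loss.item() * len(idx)
        tr_loss /= n

        model.eval()
        val_loss = evaluate_surf(model, val_cases)
        history.append((tr_loss, val_loss, opt.lr))
        if verbose:
            print(f"[surf] epoch {epoch:3d} train {tr_loss:9.4f} "
                  f"val {val_loss:9.4f} lr {opt.lr:.2e}")
        if val_loss < best[0]:
            best = (val_loss, model.state_dict())
        reducer.step(val_loss)
    model.load_state_dict(best[1])
    model.eval()
    return model, history


def evaluate_surf(model: SurfNet, cases, batch_size: int = 32) -> float:
    """Mean surf_loss of the model over a case list (no gradients kept)."""
    model.eval()
    total = 0.0
    for start in range(0, len(cases), batch_size):
        chunk = cases[start:start + batch_size]
        imgs, tgts = zip(*chunk)
        pred = model(ad.constant(np.stack(imgs)[:, None]))
        total += surf_loss(pred.data, np.stack(tgts)) * len(chunk)
    return total / len(cases)


def predict_boundary_dvf(model: SurfNet, image: SurfaceImage) -> BoundaryDVF:
    """Infer the liver boundary DVF from one surface image (mm)."""
    arr = model.normalize(image)
    if arr.shape != tuple(model.cfg.input_shape):
        raise ValueError(
            f"image shape {arr.shape} != configured {model.cfg.input_shape}"
        )
    model.eval()
    out = model(ad.constant(arr[None, None]))
    return BoundaryDVF(out.data[0], mesh_ref="liver")
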