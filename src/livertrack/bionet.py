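"""Deep biomechanical propagation: DC/AC decomposition, nearest-neighbor
gridding, a 3-D U-Net predicting intra-liver displacement, and its
region-weighted training loss.

The boundary displacement field is split into a spatially uniform (DC)
component, which is pure rigid translation and is added back after
inference, and a zero-mean oscillating (AC) component, which is gridded into
a volumetric image and propagated into the liver interior by the U-Net.
Supervision comes from the linear-elastic reference solver; the loss
down-weights voxels outside a 1 cm dilation of the prior liver contour by
100x since the field there is irrelevant for tumor localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import nn
from .grid import BoundaryDVF, GridError, GridSpec, VolumetricDVF
from .mesh import TriMesh
from .nn import autodiff as ad

__all__ = [
    "DCACDecomposition", "BioRegionWeights", "BioUNetConfig", "BioUNet",
    "decompose_dc_ac", "grid_ac", "liver_band", "build_bio_unet",
    "bio_loss", "predict_intra_dvf", "train_bio",
]


@dataclass
class DCACDecomposition:
    """dc: uniform translation (mm); ac: zero-mean residual per node."""

    dc: np.ndarray            # (3,)
    ac: BoundaryDVF

    def reconstruct(self) -> BoundaryDVF:
        return BoundaryDVF(self.ac.d + self.dc, mesh_ref=self.ac.mesh_ref)


@dataclass(frozen=True)
class BioRegionWeights:
    """Loss weights for the liver band vs the outside region."""

    inside: float = 1.0
    outside: float = 0.01
    margin_mm: float = 10.0

    def __post_init__(self):
        if self.inside < 0 or self.outside < 0 or self.margin_mm < 0:
            raise ValueError("region weights must be non-negative")


def decompose_dc_ac(dvf: BoundaryDVF) -> DCACDecomposition:
    """Split a boundary field into its node-mean (DC) and residual (AC).

    The DC part is the per-component arithmetic mean over nodes, the
    simplest translation-extracting decomposition; the AC residual is
    exactly zero-mean and dc + ac reconstructs the input exactly.
    """
    if dvf.n_nodes == 0:
        raise ValueError("cannot decompose an empty boundary DVF")
    dc = dvf.d.mean(axis=0)
    return DCACDecomposition(dc, BoundaryDVF(dvf.d - dc, mesh_ref=dvf.mesh_ref))


def liver_band(liver_mask: np.ndarray, grid: GridSpec,
               margin_mm: float = 10.0) -> np.ndarray:
    """Binary dilation of the prior liver mask by a metric margin."""
    r = [max(int(np.ceil(margin_mm / s)), 0) for s in grid.spacing]
    zz = [np.arange(-k, k + 1) * s for k, s in zip(r, grid.spacing)]
    dist = np.sqrt(sum(np.square(z).reshape([-1 if i == j else 1 for j in range(3)])
                       for i, z in enumerate(zz)))
    struct = dist <= margin_mm + 1e-9
    return ndimage.binary_dilation(liver_mask, structure=struct)


def grid_ac(ac: BoundaryDVF, mesh: TriMesh, grid: GridSpec,
            band: np.ndarray = None, liver_mask: np.ndarray = None,
            margin_mm: float = 10.0) -> np.ndarray:
    """Nearest-neighbor gridding of the AC component into a 3-channel volume.

    Every voxel inside the liver band (the 1 cm-dilated prior liver mask, or
    an explicit ``band``) takes the AC value of its nearest boundary node;
    voxels outside the band are zero.
    """
    if ac.n_nodes != mesh.n_nodes:
        raise GridError("AC field and mesh node counts differ")
    if band is None:
        if liver_mask is None:
            raise GridError("grid_ac needs either a band or a liver mask")
        band = liver_band(liver_mask, grid, margin_mm)
    if band.shape != tuple(grid.shape):
        raise GridError("band does not match the grid")
    out = np.zeros(tuple(grid.shape) + (3,))
    idx = np.argwhere(band)
    if len(idx):
        pts = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
        _, nearest = cKDTree(mesh.nodes).query(pts)
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = ac.d[nearest]
    return out


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BioUNetConfig:
    """Encoder-decoder depth/width.  The full-scale model uses 5 contraction
    blocks from 8 features; the desk default is 3 blocks, same growth rule.
    """

    grid_shape: tuple = (16, 16, 16)
    entrance_features: int = 8
    depth: int = 3
    leaky_slope: float = 0.2
    seed: int = 0

    @classmethod
    def full_scale(cls, grid_shape=(64, 64, 64)) -> "BioUNetConfig":
        return cls(grid_shape=grid_shape, entrance_features=8, depth=5)


class BioUNet(nn.Module):
    """3-D U-Net: stride-2 contraction blocks with feature doubling, a
    bottleneck convolution, and upsample+conv expansion blocks with skip
    concatenation; leaky rectifier activations throughout."""

    def __init__(self, cfg: BioUNetConfig):
        super().__init__()
        side = np.array(cfg.grid_shape)
        if np.any(side % (2 ** cfg.depth)):
            raise ValueError(
                f"grid {cfg.grid_shape} not divisible by 2**{cfg.depth}; "
                "reduce the depth"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        s = cfg.leaky_slope
        c = cfg.entrance_features
        self.entrance = nn.Conv3d(3, c, rng=rng)
        enc, widths = [], []
        for _ in range(cfg.depth):
            enc.append(nn.Conv3d(c, 2 * c, stride=2, rng=rng))
            widths.append(c)
            c *= 2
        self.enc = enc
        for i, l in enumerate(enc):
            setattr(self, f"enc{i}", l)
        self.bottleneck = nn.Conv3d(c, c, rng=rng)
        dec = []
        for i in range(cfg.depth):
            skip = widths[-(i + 1)]
            dec.append(nn.Conv3d(c + skip, c // 2, rng=rng))
            c //= 2
        self.dec = dec
        for i, l in enumerate(dec):
            setattr(self, f"dec{i}", l)
        self.out_conv = nn.Conv3d(c, 3, rng=rng, zero_init=True)
        self.slope = s

    def contraction_feature_counts(self):
        c = self.cfg.entrance_features
        return [c] + [c * 2 ** (k + 1) for k in range(self.cfg.depth)]

    def forward(self, x: ad.Tensor) -> ad.Tensor:
        """(B, 3, D, H, W) gridded AC -> (B, 3, D, H, W) deformable field."""
        s = self.slope
        y = ad.leaky_relu(self.entrance(x), s)
        skips = [y]
        for layer in self.enc:
            y = ad.leaky_relu(layer(y), s)
            skips.append(y)
        y = ad.leaky_relu(self.bottleneck(y), s)
        for i, layer in enumerate(self.dec):
            y = ad.upsample_nearest(y)
            y = ad.concat([y, skips[-(i + 2)]], axis=1)
            y = ad.leaky_relu(layer(y), s)
        return self.out_conv(y)


def build_bio_unet(cfg: BioUNetConfig) -> BioUNet:
    return BioUNet(cfg)


def bio_loss(pred, gt, band: np.ndarray, weights: BioRegionWeights = None):
    """Region-weighted similarity: inside-band MSE * 1.0 plus outside-band
    MSE * 0.01, each mean taken over its own voxel set (all 3 components).

    Accepts numpy arrays (returns float) or autodiff tensors shaped
    (3,) + grid or grid + (3,).
    """
    w = weights or BioRegionWeights()
    p = pred.field if isinstance(pred, VolumetricDVF) else pred
    g = gt.field if isinstance(gt, VolumetricDVF) else gt
    tensor = isinstance(p, ad.Tensor) or isinstance(g, ad.Tensor)
    shape = p.shape if not tensor else (p.shape if isinstance(p, ad.Tensor) else g.shape)
    if tuple(shape) != tuple(g.shape if hasattr(g, "shape") else np.shape(g)):
        raise GridError("bio_loss: field shapes differ")
    # accept channel-first or channel-last layout
    if shape[0] == 3 and shape[1:] == band.shape:
        inside = np.broadcast_to(band, (3,) + band.shape)
    elif shape[:-1] == band.shape and shape[-1] == 3:
        inside = np.broadcast_to(band[..., None], band.shape + (3,))
    else:
        raise GridError("bio_loss: band does not match the fields")
    n_in = max(int(inside.sum()), 1)
    n_out = max(int(inside.size - inside.sum()), 1)
    if tensor:
        pt = p if isinstance(p, ad.Tensor) else ad.constant(p)
        gt_ = g if isinstance(g, ad.Tensor) else ad.constant(g)
        d2 = (pt - gt_) * (pt - gt_)
        mse_in = ad.sum_all(d2 * ad.constant(inside.astype(float))) * (1.0 / n_in)
        mse_out = ad.sum_all(d2 * ad.constant((~inside).astype(float))) * (1.0 / n_out)
        return mse_in * w.inside + mse_out * w.outside
    d2 = (np.asarray(p, float) - np.asarray(g, float)) ** 2
    mse_in = d2[inside].sum() / n_in
    mse_out = d2[~inside].sum() / n_out
    return float(w.inside * mse_in + w.outside * mse_out)


# ---------------------------------------------------------------------------
# inference / training
# ---------------------------------------------------------------------------

def predict_intra_dvf(model: BioUNet, boundary_dvf: BoundaryDVF,
                      mesh: TriMesh, grid: GridSpec, band: np.ndarray,
                      liver_mask: np.ndarray = None) -> VolumetricDVF:
    """Propagate a boundary field into the liver interior.

    Decompose into DC + AC, grid the AC, infer the deformable interior field
    with the U-Net, then add the DC translation back at every voxel.  The
    returned field is meaningful inside the liver band (the network is
    supervised there); the DC component alone fills the rest.
    """
    if band.shape != tuple(grid.shape):
        raise GridError("band does not match the Bio grid")
    if tuple(grid.shape) != tuple(model.cfg.grid_shape):
        raise GridError("grid does not match the Bio model configuration")
    dec = decompose_dc_ac(boundary_dvf)
    ac_vol = grid_ac(dec.ac, mesh, grid, band=band)
    model.eval()
    pred = model(ad.constant(np.moveaxis(ac_vol, -1, 0)[None]))
    field = np.moveaxis(pred.data[0], 0, -1) + dec.dc
    return VolumetricDVF(field, grid)


def train_bio(model: BioUNet, train_cases, val_cases, schedule=None,
              seed: int = 0, weights: BioRegionWeights = None,
              boundary_noise_mm: float = 0.0, verbose: bool = False,
              train_ids=None, test_ids=None):
    """Train the population interior-motion model.

    Cases are ``(ac_volume (grid+(3,)), target (grid+(3,)), band)`` triples
    pooled across a population of phantoms.  ``train_ids`` and ``test_ids``
    are phantom identifiers; the model must never see a test phantom during
    training, so any overlap raises.  ``boundary_noise_mm`` adds iid
    Gaussian noise to the input AC volume each epoch, emulating
    upstream-model errors.  Plateau schedule: reduce the learning rate by
    10 % after 10 stagnant epochs.
    """
    if train_ids is not None and test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(
                f"population model would train on test phantoms: {overlap}"
            )
    from .surfnet import TrainSchedule

    sched = schedule or TrainSchedule(epochs=800, weight_decay=0.0,
                                      plateau_factor=0.9, plateau_patience=10,
                                      batch_size=8)
    w = weights or BioRegionWeights()
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=sched.lr, weight_decay=0.0)
    reducer = nn.ReduceLROnPlateau(opt, sched.plateau_factor,
                                   sched.plateau_patience)

    def batch_loss(idx, cases, train):
        xs, ys, bands = [], [], []
        for i in idx:
            ac, tgt, band = cases[i]
            if train and boundary_noise_mm > 0:
                noisy = ac + rng.normal(0.0, boundary_noise_mm, size=ac.shape)
                ac = np.where(np.abs(ac).sum(-1, keepdims=True) > 0, noisy, ac)
            xs.append(np.moveaxis(ac, -1, 0))
            ys.append(np.moveaxis(tgt, -1, 0))
            bands.append(np.broadcast_to(band, (3,) + band.shape))
        x = ad.constant(np.stack(xs))
        y = ad.constant(np.stack(ys))
        inside = np.stack(bands)
        pred = model(x)
        d2 = (pred - y) * (pred - y)
        n_in = max(int(inside.sum()), 1)
        n_out = max(int(inside.size - inside.sum()), 1)
        mse_in = ad.sum_all(d2 * ad.constant(inside.astype(float))) * (1.0 / n_in)
        mse_out = ad.sum_all(d2 * ad.constant((~inside).astype(float))) * (1.0 / n_out)
        return mse_in * w.inside + mse_out * w.outside

    best = (np.inf, model.state_dict())
    history = []
    n = len(train_cases)
    for epoch in range(sched.epochs):
        model.train()
        order = rng.permutation(n)
        tr = 0.0
        for start in range(0, n, sched.batch_size):
            idx = order[start:start + sched.batch_size]
            model.zero_grad()
            loss = batch_loss(idx, train_cases, True)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"biomechanical-model training diverged at epoch {epoch}"
                )
            loss.backward()
            opt.step()
            tr += loss.item() * len(idx)
        tr /= n
        model.eval()
        val = float(np.mean([
            batch_loss([i], val_cases, False).item()
            for i in range(len(val_cases))
        ]))
        history.append((tr, val, opt.lr))
        if verbose:
            print(f"[bio] epoch {epoch:3d} train {tr:9.5f} val {val:9.5f} "
                  f"lr {opt.lr:.2e}")
        if val < best[0]:
            best = (val, model.state_dict())
        reducer.step(val)
    model.load_state_dict(best[1])
    model.eval()
    return model, history
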