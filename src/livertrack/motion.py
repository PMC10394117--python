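"""PCA respiratory motion model, training-set augmentation, test scenarios.

The motion model represents a phase's displacement field as a linear
combination of a mean field and the first three principal motion components,

    D^t(x) = sum_i  w_i^t  D_i(x),   i = 0..3,  w_0^t = 1,

fitted on the per-phase fields of a breathing cycle.  Training augmentation
randomly rescales the coefficients; test scenarios deliberately scale beyond
the training ranges or add rigid translations beyond the training range, to
probe robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BoundaryDVF, VolumetricDVF

__all__ = [
    "PCAMotionModel",
    "ScenarioSpec",
    "fit_pca",
    "synthesize_dvf",
    "augment_training_set",
    "AugmentedCase",
    "sample_rigid_translation",
    "make_test_scenarios",
    "TRAIN_PHASES",
    "VALIDATION_PHASES",
    "TEST_PHASES",
    "SCALING_RANGES_TRAIN",
    "SCALING_COUNTS",
]

TRAIN_PHASES = ("10%", "20%", "30%", "40%")
VALIDATION_PHASES = ("70%", "80%")
TEST_PHASES = ("50%", "60%", "90%")

#: training/validation scaling ranges for coefficients w0..w3
SCALING_RANGES_TRAIN = ((0.95, 1.05), (-1.5, 3.0), (-1.5, 3.0), (-1.5, 1.5))
#: number of independent factors sampled per coefficient (Cartesian product)
SCALING_COUNTS = (4, 6, 4, 2)
#: test ranges for scenario type 1 (strictly containing the training ranges
#: on the positive side)
TYPE1_RANGES = ((1.0, 1.0), (0.0, 5.0), (0.0, 5.0), (0.0, 2.5))


@dataclass
class PCAMotionModel:
    """Mean field D0, unit-norm components D1..D3, per-phase coefficients."""

    mean: np.ndarray           # flattened (M,)
    components: np.ndarray     # (3, M), unit norm, mutually orthogonal
    coefficients: dict         # phase label -> (4,) with [0] == 1
    field_shape: tuple         # shape of one input field, e.g. (nx,ny,nz,3)
    grid: object = None        # GridSpec when fitted on volumetric fields

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def phase_coefficients(self, phase: str) -> np.ndarray:
        return self.coefficients[phase]


def _flatten(dvf) -> np.ndarray:
    if isinstance(dvf, VolumetricDVF):
        return dvf.field.ravel()
    if isinstance(dvf, BoundaryDVF):
        return dvf.d.ravel()
    return np.asarray(dvf, float).ravel()


def fit_pca(per_phase_dvfs, phase_labels=None) -> PCAMotionModel:
    """Fit the rank-3 PCA motion model to per-phase displacement fields.

    The mean field is the arithmetic mean; components are the top-3 right
    singular vectors of the centered data matrix, stored unit-norm with the
    per-phase coefficients absorbing the scale (projection of each centered
    phase onto the components).  Requires at least 4 phases.
    """
    fields = [_flatten(d) for d in per_phase_dvfs]
    if len(fields) < 4:
        raise ValueError("PCA motion model needs at least 4 phases")
    first = per_phase_dvfs[0]
    if isinstance(first, VolumetricDVF):
        shape, grid = first.field.shape, first.grid
    elif isinstance(first, BoundaryDVF):
        shape, grid = first.d.shape, None
    else:
        shape, grid = np.asarray(first).shape, None
    X = np.stack(fields)                      # (P, M)
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD of the centered data matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:3]
    # degenerate directions (zero singular value) stay as returned by the
    # SVD; their coefficients are ~0 so they never contribute
    proj = Xc @ comps.T                       # (P, 3)
    labels = list(phase_labels) if phase_labels is not None else [
        f"{i * 100 // len(fields)}%" for i in range(len(fields))
    ]
    coeffs = {lab: np.concatenate([[1.0], proj[i]]) for i, lab in enumerate(labels)}
    return PCAMotionModel(mean, comps, coeffs, shape, grid)


def synthesize_dvf(model: PCAMotionModel, w) -> np.ndarray:
    """Linear combination sum_i w_i D_i; returns an array of field_shape.

    ``w`` has 4 entries: w0 scales the mean field, w1..w3 the components.
    """
    w = np.asarray(w, float)
    flat = w[0] * model.mean + w[1:] @ model.components
    return flat.reshape(model.field_shape)


def synthesize_volumetric(model: PCAMotionModel, w, translation=None) -> VolumetricDVF:
    """Volumetric field for a coefficient vector plus optional rigid shift."""
    if model.grid is None:
        raise ValueError("model was not fitted on volumetric fields")
    f = synthesize_dvf(model, w)
    if translation is not None:
        f = f + np.asarray(translation, float)
    return VolumetricDVF(f, model.grid)


@dataclass(frozen=True)
class AugmentedCase:
    """One augmented motion case: a phase with rescaled PCA coefficients."""

    phase: str
    scalings: tuple            # (s0, s1, s2, s3)
    coefficients: tuple        # scaled w_i, ready for synthesize_dvf

    def as_dict(self):
        return {"phase": self.phase, "scalings": list(self.scalings),
                "coefficients": list(self.coefficients)}


def augment_training_set(model: PCAMotionModel, phases, seed: int,
                         counts=SCALING_COUNTS,
                         ranges=SCALING_RANGES_TRAIN) -> list:
    """Coefficient-rescaling augmentation over the designated phases.

    Per phase, ``counts`` = (4, 6, 4, 2) scaling factors are sampled
    independently and uniformly from ``ranges`` for w0..w3 and combined as a
    full Cartesian product: 192 cases per phase, 768 for the four training
    phases, 384 for the two validation phases.
    """
    allowed = set(TRAIN_PHASES) | set(VALIDATION_PHASES)
    phases = list(phases)
    for p in phases:
        if p not in allowed:
            raise ValueError(
                f"phase {p!r} is not in the designated training/validation sets"
            )
        if p not in model.coefficients:
            raise ValueError(f"model has no coefficients for phase {p!r}")
    rng = np.random.default_rng(seed)
    cases = []
    for p in phases:
        w = model.phase_coefficients(p)
        factors = [rng.uniform(lo, hi, size=n)
                   for (lo, hi), n in zip(ranges, counts)]
        grids = np.meshgrid(*factors, indexing="ij")
        s = np.stack([g.ravel() for g in grids], axis=1)   # (prod(counts), 4)
        for row in s:
            cases.append(AugmentedCase(p, tuple(row), tuple(row * w)))
    return cases


def sample_rigid_translation(range_mm: float, rng) -> np.ndarray:
    """Rigid setup-error translation, each component ~ U[-range, +range] mm."""
    if range_mm < 0:
        raise ValueError("translation range must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if range_mm == 0:
        return np.zeros(3)
    return rng.uniform(-range_mm, range_mm, size=3)


@dataclass(frozen=True)
class ScenarioSpec:
    """One test scenario: phase, coefficient scalings, rigid translation."""

    scenario_type: int         # 1: amplitude scaling; 2/3/4: LR/AP/SI shift
    phase: str
    scalings: tuple            # (s0, s1, s2, s3)
    translation: tuple         # (3,) mm

    def __post_init__(self):
        if self.scenario_type == 1:
            if any(abs(t) > 0 for t in self.translation):
                raise ValueError("type-1 scenarios carry no translation")
        elif self.scenario_type in (2, 3, 4):
            if tuple(self.scalings) != (1.0, 1.0, 1.0, 1.0):
                raise ValueError("translation scenarios keep unit scalings")
            nz = [i for i, t in enumerate(self.translation) if t != 0]
            if len(nz) > 1 or (nz and nz[0] != self.scenario_type - 2):
                raise ValueError("translation must lie along the scenario axis")
        else:
            raise ValueError(f"invalid scenario type {self.scenario_type}")


def make_test_scenarios(model: PCAMotionModel, scenario_type: int, seed: int,
                        phases=TEST_PHASES, n_type1_per_phase: int = 25) -> list:
    """Generate the test scenarios of one type over the held-out phases.

    Type 1 samples ``n_type1_per_phase`` coefficient-scaling tuples per phase
    with s1, s2 ~ U[0, 5] and s3 ~ U[0, 2.5] (beyond the training ranges).
    Types 2-4 keep unit scalings and translate along LR/AP/SI respectively by
    11 uniformly spaced values from -10 to 10 mm: 33 scenarios in total.
    """
    if scenario_type not in (1, 2, 3, 4):
        raise ValueError(f"invalid scenario type {scenario_type}")
    for p in phases:
        if p not in model.coefficients:
            raise ValueError(f"model has no coefficients for phase {p!r}")
    rng = np.random.default_rng(seed)
    out = []
    if scenario_type == 1:
        for p in phases:
            for _ in range(n_type1_per_phase):
                s = tuple(rng.uniform(lo, hi) for lo, hi in TYPE1_RANGES)
                out.append(ScenarioSpec(1, p, s, (0.0, 0.0, 0.0)))
    else:
        axis = scenario_type - 2
        shifts = np.linspace(-10.0, 10.0, 11)
        for p in phases:
            for v in shifts:
                t = [0.0, 0.0, 0.0]
                t[axis] = float(v)
                out.append(ScenarioSpec(scenario_type, p,
                                        (1.0, 1.0, 1.0, 1.0), tuple(t)))
    return out


def scenario_field(model: PCAMotionModel, spec: ScenarioSpec) -> VolumetricDVF:
    """Materialize a scenario's volumetric ground-truth displacement field."""
    w = model.phase_coefficients(spec.phase) * np.asarray(spec.scalings)
    return synthesize_volumetric(model, w, translation=spec.translation)
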