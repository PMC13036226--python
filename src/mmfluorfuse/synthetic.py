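"""Synthetic paired fluorescence images + 80-parameter vectors.

No public dataset accompanies the phenotyping study this package targets,
so this generator is a statistical stand-in, not a physiological model.
It emulates three things the downstream modules need:

* the five-level structure of the labeling (QY_max drawn uniformly within
  each level's bin, so labels round-trip exactly through level assignment);
* the marginal moments of the key parameters (Fm, NPQ_Lss, qP_Lss,
  Rfd_Lss), correlated with QY_max with physiologically signed couplings
  (photochemical quenching and fluorescence decline fall with stress,
  non-photochemical quenching rises);
* level-dependent visual phenotypes: leaflet brightness tracks QY_max,
  interior lesion spots appear from level 3, and level 5 adds depressed
  grayish margins.

The 75 background parameters are Gaussian with small level-dependent mean
offsets (centred and variance-normalised so each recovers its configured
marginal mean/std exactly).  Real fluorescence parameters co-vary broadly
with stress; this is what makes the level structure discoverable by
unsupervised clustering, as the labeling rationale assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FluorImage, LabeledSample, ParameterRecord, assign_level

# ---------------------------------------------------------------- parameter names

_KEY_PARAMS = ("Fm", "QY_max", "NPQ_Lss", "qP_Lss", "Rfd_Lss")


def _background_names() -> list[str]:
    quantities = ("NPQ", "qP", "qL", "QY", "Rfd", "Fm", "Ft", "ETR")
    phases = ("L1", "L2", "L3", "L4", "D1", "D2", "D3", "Lss", "Peak", "Min")
    names = [f"{q}_{p}" for q in quantities for p in phases]
    names = [n for n in names if n not in _KEY_PARAMS]
    return names[:75]


#: canonical 80-parameter column order used by the generator
PARAM_NAMES: list[str] = list(_KEY_PARAMS) + _background_names()
assert len(PARAM_NAMES) == 80

#: QY_max bins per level; level 1's ceiling and level 5's floor follow the
#: observed data range (max 0.90, min 0.20)
QY_BINS = {1: (0.79, 0.90), 2: (0.61, 0.79), 3: (0.46, 0.61),
           4: (0.31, 0.46), 5: (0.20, 0.31)}

#: observed raw per-level counts backing the default level proportions
RAW_LEVEL_COUNTS = (255, 159, 168, 290, 359)

#: key-parameter marginal (mean, std) and sign of coupling to QY_max
KEY_MOMENTS = {
    "Fm": (11797.78, 6568.85, +1.0),
    "NPQ_Lss": (0.38, 0.29, -1.0),
    "qP_Lss": (0.48, 0.22, +1.0),
    "Rfd_Lss": (0.79, 0.53, +1.0),
}


@dataclass
class GeneratorConfig:
    n_samples: int = 1231
    level_proportions: tuple = tuple(c / sum(RAW_LEVEL_COUNTS)
                                     for c in RAW_LEVEL_COUNTS)
    corr: float = 0.6               # |rho| between key parameters and QY_max
    level_effect_scale: float = 1.0  # between-level dispersion of background params
    image_size: tuple[int, int] = (1024, 768)  # (width, height)
    seed: int = 0
    param_moments: dict = field(default_factory=dict)  # name -> (mean, std) overrides

    def __post_init__(self):
        if abs(sum(self.level_proportions) - 1.0) > 1e-9:
            raise ValueError("level proportions must sum to 1")
        if not 0.0 <= self.corr < 1.0:
            raise ValueError("corr must lie in [0, 1)")

    def moments_for(self, name: str) -> tuple[float, float]:
        if name in self.param_moments:
            return tuple(self.param_moments[name])
        if name in KEY_MOMENTS:
            m, s, _ = KEY_MOMENTS[name]
            return (m, s)
        return (0.0, 1.0)


# ------------------------------------------------------- analytic QY moments

def qy_mixture_moments(cfg: GeneratorConfig) -> tuple[float, float]:
    """Exact mean/std of QY_max under the uniform-within-bin mixture."""
    m = 0.0
    m2 = 0.0
    for lvl, p in zip(range(1, 6), cfg.level_proportions):
        lo, hi = QY_BINS[lvl]
        mid = 0.5 * (lo + hi)
        m += p * mid
        m2 += p * (mid ** 2 + (hi - lo) ** 2 / 12.0)
    var = m2 - m ** 2
    return m, float(np.sqrt(var))


_STRUCTURE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _level_structure(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-level background means (5, 75) and within-level stds (75,).

    Raw level offsets are drawn once per config seed, then centred with the
    level proportions and scaled so each background parameter has marginal
    mean 0 and variance 1 exactly.
    """
    key = (cfg.seed, cfg.level_effect_scale, tuple(cfg.level_proportions))
    if key in _STRUCTURE_CACHE:
        return _STRUCTURE_CACHE[key]
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0xB16,))
    rng = np.random.default_rng(ss)
    p = np.asarray(cfg.level_proportions)
    mu = rng.normal(0.0, cfg.level_effect_scale, size=(5, 75))
    mu -= (p[:, None] * mu).sum(axis=0, keepdims=True)
    between = (p[:, None] * mu ** 2).sum(axis=0)
    within = np.sqrt(np.maximum(1.0 - between, 0.04))
    total = np.sqrt(between + within ** 2)
    out = (mu / total, within / total)
    _STRUCTURE_CACHE[key] = out
    return out


def _truncated_normal(rng: np.random.Generator, bound: float = 4.0) -> float:
    """Standard normal truncated to [-bound, bound], by rejection."""
    while True:
        x = rng.normal()
        if abs(x) <= bound:
            return float(x)


# ------------------------------------------------------------------- vectors

def generate_parameter_vector(level: int, cfg: GeneratorConfig,
                              seed: int) -> ParameterRecord:
    """Draw one 80-parameter record consistent with the requested level."""
    if level not in QY_BINS:
        raise ValueError(f"level must be in 1..5, got {level}")
    rng = np.random.default_rng(seed)
    lo, hi = QY_BINS[level]
    qy = float(rng.uniform(lo, hi))

    qmean, qstd = qy_mixture_moments(cfg)
    zq = (qy - qmean) / qstd
    rho = cfg.corr
    values: dict[str, float] = {}
    for name in ("Fm", "NPQ_Lss", "qP_Lss", "Rfd_Lss"):
        m, s = cfg.moments_for(name)
        sign = KEY_MOMENTS[name][2]
        eps = _truncated_normal(rng)
        values[name] = m + s * (sign * rho * zq + np.sqrt(1.0 - rho ** 2) * eps)
    values["QY_max"] = qy

    mu, within = _level_structure(cfg)
    eps_bg = rng.normal(size=75)
    bg = mu[level - 1] + within * eps_bg
    for j, name in enumerate(PARAM_NAMES[5:]):
        m, s = cfg.moments_for(name)
        values[name] = m + s * bg[j]

    ordered = {n: values[n] for n in PARAM_NAMES}
    return ParameterRecord(sample_id=f"S{seed & 0xFFFFFFFF:010d}",
                           variety_id="synthetic", treatment="salt",
                           values=ordered)


# -------------------------------------------------------------------- images

def render_leaf_image(level: int, qy_max: float,
                      size: tuple[int, int] = (1024, 768),
                      seed: int = 0) -> FluorImage:
    """Render a pseudo-colored leaf mock-up on a dark background.

    2-4 elliptical leaflets whose base intensity is affine in ``qy_max``;
    level >= 3 adds low-intensity interior spots, level 5 depresses and
    grays the leaflet margins.  Deterministic under ``seed``.
    """
    if level not in QY_BINS:
        raise ValueError(f"level must be in 1..5, got {level}")
    w, h = size
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    intensity = np.zeros((h, w))
    margin = np.zeros((h, w), dtype=bool)

    base = 0.15 + 0.75 * float(qy_max)  # strictly increasing in qy_max
    n_leaf = int(rng.integers(2, 5))
    cx0, cy0 = w / 2.0, h / 2.0
    scale = min(w, h)
    leaf_params = []
    for _ in range(n_leaf):
        cx = cx0 + rng.uniform(-0.18, 0.18) * w
        cy = cy0 + rng.uniform(-0.18, 0.18) * h
        a = rng.uniform(0.10, 0.16) * scale
        b = rng.uniform(0.16, 0.26) * scale
        th = rng.uniform(0.0, np.pi)
        leaf_params.append((cx, cy, a, b, th))
        dx, dy = xx - cx, yy - cy
        u = (dx * np.cos(th) + dy * np.sin(th)) / a
        v = (-dx * np.sin(th) + dy * np.cos(th)) / b
        r2 = u ** 2 + v ** 2
        inside = r2 <= 1.0
        shade = base * (1.0 - 0.15 * r2)
        intensity[inside] = np.maximum(intensity[inside], shade[inside])
        if level == 5:
            margin |= inside & (r2 > 0.75 ** 2)

    if level >= 3:
        n_spots = 4 * (level - 2)
        for _ in range(n_spots):
            cx, cy, a, b, th = leaf_params[int(rng.integers(0, n_leaf))]
            sx = cx + rng.uniform(-0.5, 0.5) * a
            sy = cy + rng.uniform(-0.5, 0.5) * b
            sr = rng.uniform(0.015, 0.035) * scale
            spot = (xx - sx) ** 2 + (yy - sy) ** 2 <= sr ** 2
            intensity[spot] *= 0.35

    if level == 5:
        intensity[margin] *= 0.30

    bg = 0.02
    i = np.where(intensity > 0, intensity, bg)
    # pseudo-color ramp, monotone in intensity on every channel
    r = np.clip(i, 0, 1)
    g = np.clip(0.9 * i + 0.05, 0, 1)
    b = np.clip(0.15 + 0.2 * i, 0, 1)
    px = np.stack([r, g, b], axis=-1)
    if level == 5:  # wilted grayish margins: pull channels together
        gray = px[margin].mean(axis=-1, keepdims=True)
        px[margin] = 0.7 * gray + 0.3 * px[margin]
    return FluorImage(np.clip(px, 0.0, 1.0), source_size=(w, h))


# ------------------------------------------------------------------- dataset

def generate_parameter_records(cfg: GeneratorConfig) -> tuple[list[ParameterRecord], np.ndarray]:
    """Draw levels per the configured proportions and one record each.

    Uses RNG streams independent of image rendering, so records are
    identical whether or not images are generated.
    """
    if cfg.n_samples < 10:
        raise ValueError(f"n_samples must be >= 10, got {cfg.n_samples}")
    root = np.random.SeedSequence(cfg.seed)
    lvl_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    levels = lvl_rng.choice(np.arange(1, 6), size=cfg.n_samples,
                            p=np.asarray(cfg.level_proportions))
    param_seeds = np.random.SeedSequence(cfg.seed, spawn_key=(2,)).generate_state(cfg.n_samples)
    records = []
    for i, (lvl, ps) in enumerate(zip(levels, param_seeds)):
        rec = generate_parameter_vector(int(lvl), cfg, int(ps))
        rec.sample_id = f"S{i:05d}"
        rec.variety_id = f"V{i % 178:03d}"
        records.append(rec)
    return records, levels.astype(int)


def generate_dataset(cfg: GeneratorConfig, render_images: bool = True
                     ) -> tuple[list[LabeledSample], pd.DataFrame]:
    """Generate labeled samples and a manifest table.

    Every sample is internally consistent: its level equals the level
    assigned from its generated QY_max.
    """
    records, levels = generate_parameter_records(cfg)
    img_seeds = np.random.SeedSequence(cfg.seed, spawn_key=(3,)).generate_state(cfg.n_samples)
    samples = []
    rows = []
    for rec, lvl, iseed in zip(records, levels, img_seeds):
        img = None
        if render_images:
            img = render_leaf_image(int(lvl), rec.qy_max, size=cfg.image_size,
                                    seed=int(iseed))
        samples.append(LabeledSample(image=img, params=rec, level=int(lvl)))
        rows.append({"sample_id": rec.sample_id, "image_path": "",
                     "level": int(lvl), "split": ""})
    manifest = pd.DataFrame(rows)
    return samples, manifest
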