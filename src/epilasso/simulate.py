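"""Synthetic benchmark generator for perturbation-screen epistasis.

Emulates an siRNA off-target prediction matrix: X is i.i.d. Bernoulli
binary (each entry marks a predicted silencing of gene j by siRNA i), a
small set of main, pairwise and three-way silencing effects is planted with
Gaussian coefficients, and the phenotype is the cumulative silencing signal
plus Gaussian noise scaled so that Var(signal)/Var(noise) equals the
requested signal-to-noise ratio (default 5).

Pairwise effects are planted independently of main effects - no hierarchy
is imposed - so hierarchy-constrained fitting genuinely loses candidates.
Planted interactions whose realized column is empty (the member genes never
co-silenced in any sample) are undetectable by any method; the generator
reports expressed/unexpressed counts so evaluation can condition on
expressibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, Tuple

import numpy as np

from .sparse import InteractionId, SparseBinaryMatrix, interaction_column

#: Benchmark presets: (n, p, n_main, n_pair, n_triple).  "small" is the
#: ideal 10-siRNAs-per-gene scenario; "large" has only two per gene; "wide"
#: is the p >> n worst case; "threeway" plants 1,000 triples (the
#: "threeway-wide" variant swaps its n and p).
PRESETS: Dict[str, Tuple[int, int, int, int, int]] = {
    "small": (1000, 100, 10, 50, 0),
    "large": (8000, 4000, 40, 200, 0),
    "wide": (1000, 10000, 100, 500, 0),
    "threeway": (4000, 400, 10, 100, 1000),
    "threeway-wide": (400, 4000, 10, 100, 1000),
}


@dataclass
class SimulationConfig:
    n: int
    p: int
    n_main: int = 0
    n_pair: int = 0
    n_triple: int = 0
    snr: float = 5.0
    density: float = 0.05
    effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for count, avail, what in (
            (self.n_main, self.p, "main"),
            (self.n_pair, comb(self.p, 2), "pairwise"),
            (self.n_triple, comb(self.p, 3), "three-way"),
        ):
            if count < 0 or count > avail:
                raise ValueError(f"{what} effect count {count} infeasible for p={self.p}")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SimulationConfig":
        n, p, nm, npair, ntri = PRESETS[name]
        cfg = cls(n=n, p=p, n_main=nm, n_pair=npair, n_triple=ntri)
        return replace(cfg, **overrides) if overrides else cfg


#: Planted truth: sorted interaction id -> nonzero true coefficient.
TrueEffects = Dict[InteractionId, float]


def simulate_design(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SparseBinaryMatrix:
    """i.i.d. Bernoulli(density) binary design matrix, reproducible from seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dense = rng.random((cfg.n, cfg.p)) < cfg.density
    return SparseBinaryMatrix.from_dense(dense.astype(np.int8))


def _sample_distinct_ids(
    rng: np.random.Generator, p: int, order: int, count: int
) -> list:
    if count > comb(p, order):
        raise ValueError(f"cannot draw {count} distinct order-{order} ids from p={p}")
    if order == 1:
        return [(int(i),) for i in rng.choice(p, size=count, replace=False)]
    chosen: set = set()
    while len(chosen) < count:
        chosen.add(tuple(sorted(int(v) for v in rng.choice(p, size=order, replace=False))))
    return sorted(chosen)


def assign_effects(cfg: SimulationConfig, rng: np.random.Generator) -> TrueEffects:
    """Uniformly sample distinct effect ids per order with Gaussian sizes.

    Coefficients are Normal(0, effect_sd^2), resampled while
    |beta| < 0.1 * effect_sd so every planted effect is unambiguously
    nonzero.  No hierarchy constraint is imposed.
    """
    effects: TrueEffects = {}
    for order, count in ((1, cfg.n_main), (2, cfg.n_pair), (3, cfg.n_triple)):
        for id in _sample_distinct_ids(rng, cfg.p, order, count):
            b = float(rng.normal(0.0, cfg.effect_sd))
            while abs(b) < 0.1 * cfg.effect_sd:
                b = float(rng.normal(0.0, cfg.effect_sd))
            effects[id] = b
    return effects


def simulate_phenotype(
    X: SparseBinaryMatrix,
    effects: TrueEffects,
    snr: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, float]:
    """Cumulative planted signal plus Gaussian noise at the requested SNR.

    Noise variance is Var(signal)/snr (population variance over samples).
    Returns (y, realized noise standard deviation).  Raises when the signal
    has zero variance (no planted effect expressed) and snr is finite.
    """
    s = np.zeros(X.n_rows)
    for id, b in effects.items():
        sup, vals = interaction_column(X, id)
        if vals is not None:
            s[sup] += b * vals
        else:
            s[sup] += b
    if np.isinf(snr):
        return s, 0.0
    var_s = float(np.var(s))
    if var_s == 0.0:
        raise ValueError("planted signal has zero variance; cannot set finite SNR")
    sd = float(np.sqrt(var_s / snr))
    return s + rng.normal(0.0, sd, size=X.n_rows), sd


@dataclass
class SimulatedDataset:
    X: SparseBinaryMatrix
    y: np.ndarray
    effects: TrueEffects
    noise_sd: float
    n_expressed: int
    n_unexpressed: int
    config: SimulationConfig = field(repr=False, default=None)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full reproducible benchmark instance from (cfg, cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    X = simulate_design(cfg, rng)
    effects = assign_effects(cfg, rng)
    y, sd = simulate_phenotype(X, effects, cfg.snr, rng)
    expressed = sum(
        1 for id in effects if interaction_column(X, id)[0].size > 0
    )
    return SimulatedDataset(
        X=X,
        y=y,
        effects=effects,
        noise_sd=sd,
        n_expressed=expressed,
        n_unexpressed=len(effects) - expressed,
        config=cfg,
    )
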