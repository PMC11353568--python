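"""Seeded multi-family genotype/phenotype simulator.

Families diverge under a Balding-Nichols model: each marker has an ancestral
allele frequency drawn uniformly on ``maf_range`` and family-specific
frequencies drawn from a Beta with that mean and variance
``p (1 - p) * fst``; dosages are Binomial(2, family frequency).  A
configurable set of *shift markers* receives extra frequency divergence
(pushed toward the opposite allele) in one designated family, and carries no
phenotype effect — these markers discriminate that family from the rest
without being informative about the trait, which is exactly the mismatch the
penalty-weighting method targets.

Phenotypes are additive: ``y = trait_mean + b_env + X_qtl . effects + noise``
with QTL effects standard normal and the noise variance set within each
environment so that ``Var(g) / Var(y) = h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import PhenotypeTable
from .solver import GenotypeMatrix


@dataclass
class SimulationConfig:
    """Shape and signal parameters of one simulated dataset.

    ``lines_per_family`` may be a single count or one count per family;
    ``shift_markers`` phenotype-irrelevant markers get divergent frequencies
    in ``shift_family`` (default: the last family); ``h2`` is the within-
    environment fraction of phenotypic variance that is genetic.
    """

    n_families: int = 6
    lines_per_family: object = 100
    p: int = 1000
    fst: float = 0.05
    maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 50
    h2: float = 0.5
    shift_markers: int = 0
    shift_family: int | None = None
    n_envs: int = 1
    env_effect_sd: float = 1.0
    trait_mean: float = 10.0
    traits: tuple = ("trait_1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.p < 1 or self.n_envs < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        if self.shift_markers > self.p - self.n_qtl:
            raise ValueError("shift_markers cannot exceed p - n_qtl")
        if self.shift_family is not None and not (
                0 <= self.shift_family < self.n_families):
            raise ValueError("shift_family out of range")
        self.traits = tuple(self.traits)

    @property
    def family_sizes(self) -> np.ndarray:
        if np.isscalar(self.lines_per_family):
            sizes = np.full(self.n_families, int(self.lines_per_family))
        else:
            sizes = np.asarray(self.lines_per_family, dtype=int)
            if sizes.size != self.n_families:
                raise ValueError("lines_per_family length != n_families")
        if (sizes < 1).any():
            raise ValueError("every family needs at least one line")
        return sizes


def maize1_like(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset emulating the larger maize trial shape: 1000 lines in 6
    families, 4085 markers, 11 environments, two flowering traits."""
    cfg = SimulationConfig(
        n_families=6, lines_per_family=(167, 167, 167, 167, 166, 166),
        p=4085, fst=0.05, maf_range=(0.05, 0.5), n_qtl=50, h2=0.5,
        shift_markers=0, n_envs=11, env_effect_sd=1.0, trait_mean=10.0,
        traits=("GDD_ASI", "GDD_DTT"), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimTruth:
    """Ground truth behind a simulated phenotype table."""

    qtl_idx: dict
    qtl_effects: dict
    genetic_values: dict  # trait -> per-line genetic value (line order)
    line_ids: np.ndarray
    shift_marker_idx: np.ndarray = field(default_factory=lambda: np.array([], int))


def simulate_genotypes(config: SimulationConfig):
    """Balding-Nichols family genotypes; returns (GenotypeMatrix, labels)."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.maf_range
    anc = rng.uniform(lo, hi, cfg.p)
    k = cfg.n_families
    if cfg.fst <= 1e-9:
        freq = np.tile(anc, (k, 1))
    else:
        a = anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - anc) * (1.0 - cfg.fst) / cfg.fst
        freq = rng.beta(a, b, size=(k, cfg.p))
    shift_idx = np.array([], dtype=int)
    shift_fam = cfg.shift_family if cfg.shift_family is not None else k - 1
    if cfg.shift_markers > 0:
        shift_idx = np.sort(rng.choice(cfg.p, cfg.shift_markers,
                                       replace=False))
        freq[shift_fam, shift_idx] = np.clip(1.0 - anc[shift_idx],
                                             0.01, 0.99)
    sizes = cfg.family_sizes
    dosages = np.vstack([rng.binomial(2, freq[f], size=(sizes[f], cfg.p))
                         for f in range(k)]).astype(np.float64)
    n = sizes.sum()
    line_ids = np.array([f"L{i + 1:05d}" for i in range(n)], dtype=object)
    families = np.repeat([f"F{f + 1}" for f in range(k)], sizes)
    geno = GenotypeMatrix(
        values=dosages, line_ids=line_ids,
        marker_ids=np.array([f"M{j + 1:05d}" for j in range(cfg.p)],
                            dtype=object),
        attrs={"shift_marker_idx": shift_idx,
               "shift_family": f"F{shift_fam + 1}",
               "ancestral_freq": anc})
    return geno, np.asarray(families, dtype=object)


def simulate_phenotypes(geno: GenotypeMatrix, families,
                        config: SimulationConfig) -> PhenotypeTable:
    """Additive phenotypes over environments; QTL avoid the shift markers."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    shift_idx = np.asarray(geno.attrs.get("shift_marker_idx", []), dtype=int)
    eligible = np.setdiff1d(np.arange(geno.p), shift_idx)
    if cfg.n_qtl > eligible.size:
        raise ValueError("not enough non-shift markers to place the QTL")
    n = geno.n
    qtl_idx, qtl_eff, gvals = {}, {}, {}
    rows = {"line_id": [], "family": [], "env": []}
    trait_cols = {t: [] for t in cfg.traits}
    env_labels = [f"E{e + 1}" for e in range(cfg.n_envs)]

    for trait in cfg.traits:
        idx = np.sort(rng.choice(eligible, cfg.n_qtl, replace=False))
        eff = rng.standard_normal(cfg.n_qtl)
        g = geno.values[:, idx] @ eff
        g = g - g.mean()  # trait_mean is the population mean by construction
        qtl_idx[trait], qtl_eff[trait], gvals[trait] = idx, eff, g

    for env in env_labels:
        rows["line_id"].extend(geno.line_ids)
        rows["family"].extend(families)
        rows["env"].extend([env] * n)
        for trait in cfg.traits:
            g = gvals[trait]
            sd_g = float(g.std())
            b_env = rng.normal(0.0, cfg.env_effect_sd)
            if cfg.h2 == 1.0:
                if sd_g == 0.0:
                    raise ValueError("h2 = 1 with zero genetic variance")
                y = cfg.trait_mean + b_env + g
            elif cfg.h2 == 0.0:
                sd_e = sd_g if sd_g > 0 else 1.0
                y = cfg.trait_mean + b_env + rng.normal(0.0, sd_e, n)
            else:
                if sd_g == 0.0:
                    raise ValueError("h2 > 0 with zero genetic variance")
                sd_e = sd_g * np.sqrt((1.0 - cfg.h2) / cfg.h2)
                y = cfg.trait_mean + b_env + g + rng.normal(0.0, sd_e, n)
            trait_cols[trait].extend(y)

    df = pd.DataFrame({**{k: v for k, v in rows.items()},
                       **{t: np.asarray(v) for t, v in trait_cols.items()}})
    truth = SimTruth(qtl_idx=qtl_idx, qtl_effects=qtl_eff,
                     genetic_values=gvals, line_ids=geno.line_ids,
                     shift_marker_idx=shift_idx)
    return PhenotypeTable(df=df, truth=truth)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: (GenotypeMatrix, PhenotypeTable)."""
    geno, families = simulate_genotypes(config)
    pheno = simulate_phenotypes(geno, families, config)
    return geno, pheno


def weir_cockerham_fst(X, families) -> float:
    """Multi-population Weir-Cockerham theta over biallelic dosage markers.

    Ratio-of-averages estimator (variance components a, b, c per locus,
    summed across loci).  Monomorphic markers contribute nothing.
    """
    X = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    families = np.asarray(families)
    pops = sorted(set(families), key=str)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two families")
    n_i = np.array([np.sum(families == f) for f in pops], dtype=float)
    p_i = np.vstack([X[families == f].mean(axis=0) / 2.0 for f in pops])
    h_i = np.vstack([(X[families == f] == 1).mean(axis=0) for f in pops])
    n_bar = n_i.mean()
    n_c = (r * n_bar - np.sum(n_i ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                               - (r - 1) / r * s2 - h_bar / 4.0)
                         / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    denom = np.sum(a + b + c)
    if denom <= 0:
        raise ValueError("no polymorphic markers; F_ST undefined")
    return float(np.sum(a) / denom)
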