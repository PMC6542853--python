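"""Synthetic factorial RNA-seq datasets with known ground truth.

The generator emulates a 2x2 factorial bulk RNA-seq experiment: four
conditions (vehicle, treatment A, treatment B, combined A+B) with ``n_reps``
replicates each and roughly 15,000 expressed genes. Counts for gene ``g`` in
sample ``j`` of condition ``c`` are negative-binomial with mean

    s_j * mu0_g * 2 ** (betaA_g * [A in c] + betaB_g * [B in c] + gamma_g * [c = COMBO])

and variance ``mu + alpha_disp * mu**2``. The combined-condition log2 effect
is therefore the sum of the single-treatment effects plus the interaction
``gamma``; a gene is exactly additive iff ``gamma == 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CONDITIONS, CountMatrix, ValidationError

TRUTH_COLUMNS = ("gene_id", "mu0", "betaA", "betaB", "gamma", "alpha_disp")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the factorial negative-binomial count simulation.

    Defaults emulate deep bulk RNA-seq of a homogeneous cell line treated in
    triplicate: regulated-gene fractions mirror a design in which, of 15,000
    expressed genes, ~2,329 respond to A only, ~994 to B only and ~800 to
    both; effect magnitudes |beta| are uniform on
    ``[effect_loc, effect_loc + effect_scale]`` (default 0.5..3 log2 units)
    with independent Rademacher signs, so induced and repressed genes are
    balanced; baseline means are log-normal (median 300 counts); dispersions
    are log-normal (median 0.02); the interaction ``gamma`` defaults to a
    point mass at zero (purely additive regulation).
    """

    n_genes: int = 15000
    n_reps: int = 3
    frac_A_only: float = 2329 / 15000
    frac_B_only: float = 994 / 15000
    frac_both: float = 800 / 15000
    effect_loc: float = 0.5
    effect_scale: float = 2.5
    gamma_sd: float = 0.0
    mu0_meanlog: float = math.log(300.0)
    mu0_sdlog: float = 1.5
    disp_meanlog: float = math.log(0.02)
    disp_sdlog: float = 0.8
    libsize_factors: Optional[Sequence] = None
    libsize_sdlog: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2")
        fr = (self.frac_A_only, self.frac_B_only, self.frac_both)
        if any(f < 0 for f in fr):
            raise ValidationError("regulated-gene fractions must be >= 0")
        if sum(fr) > 1.0 + 1e-12:
            raise ValidationError(f"regulated-gene fractions sum to {sum(fr)} > 1")
        for name in ("effect_scale", "gamma_sd", "mu0_sdlog", "disp_sdlog", "libsize_sdlog"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.effect_loc < 0:
            raise ValidationError("effect_loc must be >= 0")
        if self.libsize_factors is not None:
            ls = np.asarray(self.libsize_factors, dtype=float)
            if ls.shape != (4 * self.n_reps,) or np.any(ls <= 0):
                raise ValidationError(
                    f"libsize_factors must be {4 * self.n_reps} positive multipliers"
                )

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


def _streams(seed: int):
    """One global seed drives separate truth and counts generator streams."""
    truth_ss, counts_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(truth_ss), np.random.default_rng(counts_ss)


def generate_truth(params: SimulationParams) -> pd.DataFrame:
    """Draw the per-gene ground truth table.

    Exactly ``round(n_genes * frac)`` genes fall in each regulated class
    (A-only, B-only, both), laid out in leading blocks; the remainder are
    unregulated (betaA = betaB = gamma = 0). Reproducible given ``params.seed``.
    """
    rng, _ = _streams(params.seed)
    n = params.n_genes
    n_a = _round_half_up(n * params.frac_A_only)
    n_b = _round_half_up(n * params.frac_B_only)
    n_ab = _round_half_up(n * params.frac_both)
    if n_a + n_b + n_ab > n:
        raise ValidationError("regulated-gene counts exceed n_genes after rounding")
    width = max(5, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    mu0 = rng.lognormal(params.mu0_meanlog, params.mu0_sdlog, size=n)
    alpha = rng.lognormal(params.disp_meanlog, params.disp_sdlog, size=n)

    def draw_effects(k: int) -> np.ndarray:
        mag = rng.uniform(params.effect_loc, params.effect_loc + params.effect_scale, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        return mag * sign

    betaA = np.zeros(n)
    betaB = np.zeros(n)
    betaA[:n_a] = draw_effects(n_a)
    betaB[n_a : n_a + n_b] = draw_effects(n_b)
    betaA[n_a + n_b : n_a + n_b + n_ab] = draw_effects(n_ab)
    betaB[n_a + n_b : n_a + n_b + n_ab] = draw_effects(n_ab)

    gamma = np.zeros(n)
    regulated = (betaA != 0) | (betaB != 0)
    if params.gamma_sd > 0:
        gamma[regulated] = rng.normal(0.0, params.gamma_sd, size=int(regulated.sum()))

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu0": mu0,
            "betaA": betaA,
            "betaB": betaB,
            "gamma": gamma,
            "alpha_disp": alpha,
        }
    )


def _condition_log2_effect(truth: pd.DataFrame) -> np.ndarray:
    """Per-gene log2 effect for each of the four conditions (genes x 4)."""
    betaA = truth["betaA"].to_numpy(float)
    betaB = truth["betaB"].to_numpy(float)
    gamma = truth["gamma"].to_numpy(float)
    zero = np.zeros_like(betaA)
    return np.column_stack([zero, betaA, betaB, betaA + betaB + gamma])


def simulate_counts(truth: pd.DataFrame, params: SimulationParams):
    """Draw a (CountMatrix, design) pair from a truth table.

    Library-size factors are taken from ``params.libsize_factors`` or drawn
    log-normally (sigma ``libsize_sdlog``) from the counts stream; dispersion
    zero genes are Poisson. Sample ids are ``<condition>_r<replicate>``.
    """
    missing = set(TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise ValidationError(f"truth table lacks column(s): {sorted(missing)}")
    mu0 = truth["mu0"].to_numpy(float)
    if np.any(mu0 <= 0):
        raise ValidationError("mu0 must be > 0 for every gene")
    alpha = truth["alpha_disp"].to_numpy(float)
    if np.any(alpha < 0):
        raise ValidationError("alpha_disp must be >= 0 for every gene")

    _, rng = _streams(params.seed)
    n_samples = 4 * params.n_reps
    if params.libsize_factors is not None:
        s = np.asarray(params.libsize_factors, dtype=float)
    else:
        s = rng.lognormal(0.0, params.libsize_sdlog, size=n_samples)

    sample_ids = []
    cond_of_sample = []
    reps = []
    for c in CONDITIONS:
        for r in range(1, params.n_reps + 1):
            sample_ids.append(f"{c.lower()}_r{r}")
            cond_of_sample.append(c)
            reps.append(r)

    log2eff = _condition_log2_effect(truth)  # genes x 4
    cond_idx = np.array([CONDITIONS.index(c) for c in cond_of_sample])
    mean = mu0[:, None] * np.exp2(log2eff[:, cond_idx]) * s[None, :]

    counts = np.empty(mean.shape, dtype=np.int64)
    pois = alpha == 0
    if pois.any():
        counts[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = alpha[~pois][:, None]
        m = mean[~pois]
        r_nb = 1.0 / a
        p_nb = r_nb / (r_nb + m)
        counts[~pois] = rng.negative_binomial(np.broadcast_to(r_nb, m.shape), p_nb)

    cm = CountMatrix(tuple(truth["gene_id"].astype(str)), tuple(sample_ids), counts)
    design = pd.DataFrame(
        {"sample_id": sample_ids, "condition": cond_of_sample, "replicate": reps}
    )
    return cm, design


def simulate_dataset(params: SimulationParams):
    """Convenience wrapper: truth, counts and design from one parameter set."""
    truth = generate_truth(params)
    cm, design = simulate_counts(truth, params)
    return truth, cm, design
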