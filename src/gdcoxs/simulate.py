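"""Simulators for copy-number / expression interaction studies.

Two study designs are generated:

* a *similarity* design — a segmented copy-number matrix plus a ladder of
  expression matrices obtained by adding successively more Gaussian noise,
  so the interaction score can be checked to track the known, decreasing
  similarity;
* a *power* design — two conditions with independently simulated
  copy-number matrices and one shared expression matrix that tracks the
  first condition's copy numbers (standard-normal noise added to them),
  so the expression interacts with the copy numbers of condition A but
  not of condition B: a true difference in interaction between the
  conditions. The matching null variant draws one common copy-number and
  expression pair over all samples and splits it into two groups, so no
  differential interaction exists and rejection rates estimate the
  type-I error.

Copy-number variables are ternary: for each variable an alteration
frequency ``f`` is drawn from a predefined grid, exactly ``round(f * n)``
samples are altered (chosen uniformly without replacement), and each
altered sample receives +1 or -1 with equal probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .divergence import DistanceMetric
from .interaction import group_ias, permutation_diff_test, _ias_fn_for
from .io import MatrixKind, OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "simulate_cna",
    "simulate_ge",
    "simulate_ge_ladder",
    "similarity_experiment",
    "power_experiment",
    "POWER_METHODS",
]

#: Differential-interaction methods the power study can compare.
POWER_METHODS = (
    "gdcoxs",
    "dcoxs_kernel",
    "mantel_euclidean",
    "mantel_manhattan",
    "mantel_mahalanobis",
)


@dataclass
class SimulationScenario:
    """Parameters of a simulation run.

    ``cna_freq_choices`` is the grid of per-variable alteration
    frequencies; ``sd_ladder`` the cumulative noise standard deviations of
    the expression ladder; ``ge_noise_sd`` the noise scale coupling the
    power design's shared expression matrix to the first condition's copy
    numbers. The defaults are the study's standard conditions. The seed
    makes every derived table reproducible.
    """

    n_samples: int = 100
    n_cna_vars: int = 50
    n_ge_vars: int | None = None
    cna_freq_choices: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    sd_ladder: tuple[float, ...] = (0.01, 0.1, 0.2, 0.3, 0.4)
    ge_noise_sd: float = 0.7
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 < f < 1.0 for f in self.cna_freq_choices):
            raise ValueError("alteration frequencies must lie in (0, 1)")
        if any(s2 <= s1 for s1, s2 in zip(self.sd_ladder, self.sd_ladder[1:])):
            raise ValueError("sd_ladder must be strictly increasing")
        if self.sd_ladder and self.sd_ladder[0] <= 0:
            raise ValueError("sd_ladder values must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_cna(
    n_samples: int,
    n_vars: int,
    freq_choices: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    rng: np.random.Generator | None = None,
) -> OmicsMatrix:
    """Simulate a segmented ternary copy-number matrix.

    Per variable: an alteration frequency ``f`` is drawn uniformly from
    ``freq_choices``; exactly ``round(f * n_samples)`` samples (at least
    one) are altered; each altered sample is +1 or -1 with probability
    one half (a single Bernoulli trial, outcome 0 mapped to -1); all other
    samples are neutral (0).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng() if rng is None else rng
    values = np.zeros((n_vars, n_samples))
    for g in range(n_vars):
        f = freq_choices[rng.integers(len(freq_choices))]
        k = int(round(f * n_samples))
        if k < 1:
            logger.warning(
                "alteration frequency %.3f yields no altered sample at n=%d; "
                "forcing one",
                f,
                n_samples,
            )
            k = 1
        altered = rng.choice(n_samples, size=k, replace=False)
        signs = np.where(rng.binomial(1, 0.5, size=k) == 1, 1.0, -1.0)
        values[g, altered] = signs
    gene_ids = [f"cna_{g}" for g in range(n_vars)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    return OmicsMatrix(values, gene_ids, sample_ids, MatrixKind.CNA)


def simulate_ge(
    n_samples: int, n_vars: int, rng: np.random.Generator | None = None
) -> OmicsMatrix:
    """Standard-normal expression matrix (the power design's shared GE)."""
    rng = np.random.default_rng() if rng is None else rng
    values = rng.standard_normal((n_vars, n_samples))
    return OmicsMatrix(
        values,
        [f"ge_{g}" for g in range(n_vars)],
        [f"s{j}" for j in range(n_samples)],
        MatrixKind.GE,
    )


def simulate_ge_ladder(
    cna: OmicsMatrix,
    sd_ladder: Sequence[float] = (0.01, 0.1, 0.2, 0.3, 0.4),
    rng: np.random.Generator | None = None,
    n_ge_vars: int | None = None,
) -> list[OmicsMatrix]:
    """Expression ladder of decreasing similarity to a copy-number matrix.

    The first expression matrix adds Gaussian noise with
    ``sd = sd_ladder[0]`` to the copy-number values; each subsequent
    matrix adds fresh noise with the next ladder SD to its predecessor, so
    similarity to the copy-number matrix decreases down the ladder. When
    ``n_ge_vars`` exceeds the number of copy-number variables, copy-number
    rows are resampled with replacement to fill the extra expression rows.
    """
    if not sd_ladder or sd_ladder[0] <= 0:
        raise ValueError("sd_ladder must start with a positive SD")
    rng = np.random.default_rng() if rng is None else rng
    base = cna.values
    if n_ge_vars is not None and n_ge_vars != base.shape[0]:
        if n_ge_vars < base.shape[0]:
            raise ValueError("n_ge_vars must be >= the number of CNA variables")
        extra = rng.integers(base.shape[0], size=n_ge_vars - base.shape[0])
        base = np.vstack([base, base[extra, :]])
    ladder: list[OmicsMatrix] = []
    current = base
    sample_ids = list(cna.sample_ids)
    for level, sd in enumerate(sd_ladder, start=1):
        current = current + rng.normal(0.0, sd, size=current.shape)
        ladder.append(
            OmicsMatrix(
                current,
                [f"ge_{g}" for g in range(current.shape[0])],
                sample_ids,
                MatrixKind.GE,
            )
        )
    return ladder


def similarity_experiment(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    n_vars_grid: Sequence[int] = (20, 50, 100),
) -> pd.DataFrame:
    """Interaction score versus expression noise (the similarity study).

    For every replicate and variable count: simulate a copy-number matrix,
    build the expression ladder, and compute the interaction score of each
    (copy-number, expression) pair within the single simulated condition
    through the full shrinkage-normal divergence path. Returns a long
    table with columns ``n_vars, sd_level, replicate, ias``.
    """
    rng = scenario.rng() if rng is None else rng
    rows = []
    for rep in range(scenario.n_replicates):
        for n_vars in n_vars_grid:
            cna = simulate_cna(
                scenario.n_samples, n_vars, scenario.cna_freq_choices, rng
            )
            ladder = simulate_ge_ladder(cna, scenario.sd_ladder, rng)
            for sd, ge in zip(scenario.sd_ladder, ladder):
                ias = group_ias(cna.values, ge.values, "gdcoxs")
                rows.append((n_vars, sd, rep, ias))
    return pd.DataFrame(rows, columns=["n_vars", "sd_level", "replicate", "ias"])


def _power_cell(
    n_samples: int,
    set_size: int,
    scenario: SimulationScenario,
    methods: Sequence[str],
    n_replicates: int,
    n_permutations: int,
    alpha: float,
    rng: np.random.Generator,
    null: bool,
) -> list[tuple[str, int, int, float, int]]:
    rejections = {m: 0 for m in methods}
    intractable = {m: 0 for m in methods}
    ias_fns = {m: _ias_fn_for(m) for m in methods}
    mask_a = np.zeros(2 * n_samples, dtype=bool)
    mask_a[:n_samples] = True
    for _ in range(n_replicates):
        if null:
            # one common draw over all samples, split into two groups:
            # exchangeable samples, no differential interaction
            cna_full = simulate_cna(
                2 * n_samples, set_size, scenario.cna_freq_choices, rng
            ).values
            ge_full = cna_full + scenario.ge_noise_sd * rng.standard_normal(
                cna_full.shape
            )
        else:
            cna_a = simulate_cna(
                n_samples, set_size, scenario.cna_freq_choices, rng
            ).values
            cna_b = simulate_cna(
                n_samples, set_size, scenario.cna_freq_choices, rng
            ).values
            # the shared expression matrix tracks condition A's copy numbers
            ge = cna_a + scenario.ge_noise_sd * rng.standard_normal(cna_a.shape)
            cna_full = np.hstack([cna_a, cna_b])
            ge_full = np.hstack([ge, ge])
        for m in methods:
            # independent permutation stream per method, common data
            _, _, _, p = permutation_diff_test(
                cna_full, ge_full, mask_a, n_permutations, rng, ias_fns[m]
            )
            if not np.isfinite(p):
                intractable[m] += 1  # counted as a non-rejection
            elif p < alpha:
                rejections[m] += 1
    out = []
    for m in methods:
        if intractable[m]:
            logger.info(
                "power cell n=%d, d=%d, method=%s: %d intractable replicate(s)",
                n_samples,
                set_size,
                m,
                intractable[m],
            )
        out.append(
            (m, n_samples, set_size, rejections[m] / n_replicates, intractable[m])
        )
    return out


def power_experiment(
    scenario: SimulationScenario,
    n_permutations: int = 100,
    alpha: float = 0.05,
    methods: Sequence[str] = ("gdcoxs", "dcoxs_kernel"),
    rng: np.random.Generator | None = None,
    n_samples_grid: Sequence[int] = (100, 200, 400),
    set_size_grid: Sequence[int] = (10, 20, 30),
    null: bool = False,
) -> pd.DataFrame:
    """Rejection rates of the differential-interaction test (power study).

    Per grid cell (samples per condition, set size) and replicate: two
    copy-number matrices are simulated independently, and one shared
    expression matrix — condition A's copy numbers plus standard-normal
    noise scaled by ``scenario.ge_noise_sd`` — is used in both conditions,
    so only condition A truly interacts: a true differential interaction.
    With ``null=True`` a single copy-number/expression draw over all
    samples is split into two exchangeable groups (no differential
    interaction), which measures the type-I error. Power is the fraction of replicates whose
    permutation p-value falls below ``alpha``; a replicate flagged
    intractable counts as a non-rejection and is tallied in the
    ``intractable`` column.
    """
    unknown = set(methods) - set(POWER_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {sorted(unknown)}")
    rng = scenario.rng() if rng is None else rng
    rows = []
    for n in n_samples_grid:
        for d in set_size_grid:
            rows.extend(
                _power_cell(
                    n,
                    d,
                    scenario,
                    methods,
                    scenario.n_replicates,
                    n_permutations,
                    alpha,
                    rng,
                    null,
                )
            )
    return pd.DataFrame(
        rows, columns=["method", "n_samples", "set_size", "power", "intractable"]
    )
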