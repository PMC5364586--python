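"""Copy-number-aware simulation of plasma cfDNA methylation sequencing data.

A simulated cancer plasma sample mixes the full methylation profile of one
normal plasma sample and one solid tumor sample at a random ctDNA fraction
theta, then generates sequencing counts per CpG cluster:

1. theta ~ Uniform(theta_L, theta_U);
2. an integer copy number c_k ~ Cat(p_0..p_5) per cluster (mean copy
   number 2; with the default probabilities 30% of clusters carry an
   aberration);
3. one normal profile (v_k) and one tumor profile (u_k) drawn uniformly
   from the sample pools;
4. the locus burden is copy-number adjusted,
   theta_k' = theta c_k / (theta c_k + 2 (1 - theta)), and
   x_k = (1 - theta_k') v_k + theta_k' u_k;
5. coverage n_k ~ Poisson(Z B_k), where B_k renormalizes the alignment
   bias b_k (the background probability that a sequenced CpG dinucleotide
   maps to cluster k) by the copy-number-scaled DNA amount
   b_k (1 - theta + theta c_k / 2);
6. methylated counts m_k ~ Binomial(n_k, x_k).

Normal plasma samples are simulated by mixing two normal-pool profiles at
a random ratio with every copy number fixed at 2 (no CNA in normal cfDNA).

The bias vector shipped here is synthetic: proportional to the cluster's
probed-site count, optionally Dirichlet-perturbed, standing in for a bias
profile estimated from real read alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clusters import CpGCluster, is_na
from .io import ArrayProfile, SeqProfile

__all__ = [
    "CnaModel",
    "SimScenario",
    "DEFAULT_CNA_PROBS",
    "cna_preset",
    "default_bias",
    "sample_copy_numbers",
    "adjust_theta",
    "adjust_bias",
    "simulate_cancer_plasma",
    "simulate_normal_plasma",
]

#: copy-number probabilities p_0..p_5 for the 30% aberration setting
DEFAULT_CNA_PROBS = (0.005, 0.16, 0.7, 0.105, 0.025, 0.005)


@dataclass(frozen=True)
class CnaModel:
    """Categorical copy-number model over c in {0..5}.

    Constraints: probabilities sum to one, and the mean copy number is
    exactly two so that aberrations do not change the average DNA amount.
    """

    probs: tuple[float, ...] = DEFAULT_CNA_PROBS

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.size != 6 or np.any(p < 0):
            raise ValueError("need 6 nonnegative probabilities p_0..p_5")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
        if abs(float(np.arange(6) @ p) - 2.0) > 1e-9:
            raise ValueError(f"mean copy number must be 2, got {np.arange(6) @ p}")

    @property
    def mean_copy_number(self) -> float:
        return float(np.arange(6) @ np.asarray(self.probs))

    @property
    def cna_rate(self) -> float:
        """Probability of any aberration, P(c != 2)."""
        return 1.0 - self.probs[2]


def cna_preset(rate: float) -> CnaModel:
    """A CnaModel with aberration probability ``rate``.

    Scales the non-diploid mass of the default 30% vector proportionally,
    which preserves both constraints (sum 1, mean copy number 2) for any
    rate in [0, 1); rate=0.3 returns the default vector exactly.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("CNA rate must be in [0, 1)")
    base = np.asarray(DEFAULT_CNA_PROBS)
    scale = rate / (1.0 - base[2])
    p = base * scale
    p[2] = 1.0 - rate
    return CnaModel(tuple(p))


@dataclass
class SimScenario:
    """All simulator knobs for one study condition.

    ``bias`` maps cluster_id -> b_k with sum 1 over all clusters; ``Z`` is
    the total cytosine budget (expected total coverage when every cluster
    is usable); pools are cluster-level array profiles keyed by class.
    """

    theta_range: tuple[float, float]
    Z: int
    bias: dict[str, float]
    cna: CnaModel
    normal_pool: list[ArrayProfile]
    tumor_pools: dict[int, list[ArrayProfile]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.theta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"need 0 <= theta_L <= theta_U <= 1, got ({lo}, {hi})")
        if self.Z <= 0:
            raise ValueError("total cytosine budget Z must be > 0")
        tot = sum(self.bias.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"bias must sum to 1, got {tot}")


def default_bias(
    clusters: Sequence[CpGCluster],
    rng: np.random.Generator | None = None,
    dirichlet_conc: float | None = None,
) -> dict[str, float]:
    """Synthetic alignment bias: b_k proportional to probed-site count.

    With ``dirichlet_conc`` set, the vector is resampled from a Dirichlet
    centered on it (alpha_k = conc * K * b_k), adding controllable
    sample-to-sample depth noise while preserving the mean.
    """
    w = np.array([c.site_count for c in clusters], dtype=float)
    if w.sum() <= 0:
        raise ValueError("clusters have no probed sites")
    b = w / w.sum()
    if dirichlet_conc is not None:
        if rng is None:
            raise ValueError("Dirichlet perturbation requires an rng")
        b = rng.dirichlet(dirichlet_conc * b.size * b)
    return {c.cluster_id: float(x) for c, x in zip(clusters, b)}


def sample_copy_numbers(cna: CnaModel, K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. integer copy numbers c_1..c_K from the categorical model."""
    return rng.choice(6, size=K, p=np.asarray(cna.probs))


def adjust_theta(theta, c):
    """Locus-specific burden theta' = theta c / (theta c + 2 (1 - theta)).

    A deleted locus (c=0) contributes no tumor DNA (theta'=0); a diploid
    locus leaves the fraction unchanged; amplification increases it.
    """
    theta = np.asarray(theta, dtype=float)
    c = np.asarray(c, dtype=float)
    num = theta * c
    den = num + 2.0 * (1.0 - theta)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def adjust_bias(bias: np.ndarray, theta: float, c: np.ndarray) -> np.ndarray:
    """Copy-number-adjusted bias B_k ∝ b_k (1 - theta + theta c_k / 2), sum 1."""
    b = np.asarray(bias, dtype=float)
    w = b * (1.0 - theta + theta * np.asarray(c, dtype=float) / 2.0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("adjusted bias has zero total mass")
    return w / tot


def _pick(pool: Sequence[ArrayProfile], rng: np.random.Generator) -> ArrayProfile:
    if not pool:
        raise ValueError("empty sample pool")
    return pool[int(rng.integers(len(pool)))]


def _counts(
    cluster_ids: Sequence[str],
    x: np.ndarray,
    B: np.ndarray,
    usable: np.ndarray,
    Z: int,
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    counts: dict[str, tuple[int, int]] = {}
    for k, cid in enumerate(cluster_ids):
        if not usable[k]:
            continue
        n = int(rng.poisson(Z * B[k]))
        m = int(rng.binomial(n, x[k])) if n > 0 else 0
        counts[cid] = (m, n)
    return counts


def simulate_cancer_plasma(
    scenario: SimScenario,
    tumor_class: int,
    rng: np.random.Generator,
    sample_id: str = "sim_cancer",
) -> tuple[SeqProfile, dict]:
    """Simulate one cancer plasma sequencing profile (steps 1-6).

    Clusters where either drawn profile is NA are skipped (recorded in the
    truth record under ``dropped``); the bias is *not* renormalized over
    the usable clusters, so the expected total coverage is Z times the
    usable-cluster bias mass.

    Returns the profile and a truth record with theta, the tumor class,
    the source sample ids, and the per-cluster copy numbers.
    """
    if tumor_class not in scenario.tumor_pools:
        raise ValueError(f"no tumor pool for class {tumor_class}")
    cluster_ids = list(scenario.bias)
    b = np.array([scenario.bias[cid] for cid in cluster_ids])
    lo, hi = scenario.theta_range
    theta = float(rng.uniform(lo, hi))
    c = sample_copy_numbers(scenario.cna, len(cluster_ids), rng)
    normal = _pick(scenario.normal_pool, rng)
    tumor = _pick(scenario.tumor_pools[tumor_class], rng)
    v = np.array([normal.levels.get(cid, np.nan) for cid in cluster_ids])
    u = np.array([tumor.levels.get(cid, np.nan) for cid in cluster_ids])
    usable = ~(np.isnan(v) | np.isnan(u))
    theta_loc = adjust_theta(theta, c)
    x = np.where(usable, (1.0 - theta_loc) * np.nan_to_num(v) + theta_loc * np.nan_to_num(u), 0.0)
    B = adjust_bias(b, theta, c)
    counts = _counts(cluster_ids, x, B, usable, scenario.Z, rng)
    truth = {
        "sample_id": sample_id,
        "theta": theta,
        "tumor_class": tumor_class,
        "normal_sample": normal.sample_id,
        "tumor_sample": tumor.sample_id,
        "copy_numbers": c,
        "dropped": [cid for k, cid in enumerate(cluster_ids) if not usable[k]],
    }
    return SeqProfile(sample_id, counts), truth


def simulate_normal_plasma(
    scenario: SimScenario,
    rng: np.random.Generator,
    sample_id: str = "sim_normal",
    ratio: float | None = None,
) -> tuple[SeqProfile, dict]:
    """Simulate one normal plasma profile by mixing two normal samples.

    Two distinct pool entries are mixed at ``ratio`` (Uniform(0,1) when not
    given); no CNA step (all copy numbers 2), so the bias is unchanged.
    """
    if len(scenario.normal_pool) < 2:
        raise ValueError("normal-normal mixing needs at least two pool samples")
    cluster_ids = list(scenario.bias)
    b = np.array([scenario.bias[cid] for cid in cluster_ids])
    i, j = rng.choice(len(scenario.normal_pool), size=2, replace=False)
    p1, p2 = scenario.normal_pool[int(i)], scenario.normal_pool[int(j)]
    r = float(rng.uniform()) if ratio is None else float(ratio)
    if not 0.0 <= r <= 1.0:
        raise ValueError("mixing ratio must be in [0, 1]")
    v1 = np.array([p1.levels.get(cid, np.nan) for cid in cluster_ids])
    v2 = np.array([p2.levels.get(cid, np.nan) for cid in cluster_ids])
    usable = ~(np.isnan(v1) | np.isnan(v2))
    x = np.where(usable, (1.0 - r) * np.nan_to_num(v1) + r * np.nan_to_num(v2), 0.0)
    counts = _counts(cluster_ids, x, b, usable, scenario.Z, rng)
    truth = {
        "sample_id": sample_id,
        "theta": 0.0,
        "tumor_class": 0,
        "mix_ratio": r,
        "normal_samples": (p1.sample_id, p2.sample_id),
        "dropped": [cid for k, cid in enumerate(cluster_ids) if not usable[k]],
    }
    return SeqProfile(sample_id, counts), truth
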