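"""Synthetic reference pools emulating public solid-tumor / normal-plasma data.

Builds a fully self-contained study system: T tumor classes plus normal
plasma, each with per-cluster true Beta distributions of methylation
levels, and sample pools drawn from them.  A controllable fraction of
clusters is *informative*: one randomly chosen class (possibly normal) has
its mean offset from the shared baseline by at least ``separation``,
mimicking the one-class-differs structure of hyper-/hypomethylation
markers; the remaining clusters share a single mean across classes.

This generator defines the study conditions for the simulation experiments
in this package: it does not emulate batch effects, probe artifacts, or
between-cluster correlation of real methylomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clusters import NA, CpGCluster, CpGSite, build_clusters
from .io import ArrayProfile, write_array_profiles

__all__ = ["SynthRefConfig", "SynthReference", "generate_reference", "export_pools"]

#: organ labels used when T == 5, mirroring a five-organ tumor study design
FIVE_ORGANS = ("breast", "colon", "kidney", "liver", "lung")

#: class means are kept inside [MEAN_LO, MEAN_HI]
MEAN_LO, MEAN_HI = 0.02, 0.98


@dataclass(frozen=True)
class SynthRefConfig:
    """Knobs of the synthetic reference generator.

    separation is the minimum true methylation range of an informative
    cluster (the deviant-class offset is drawn uniformly between it and
    0.9, space permitting); concentration is the range of the Beta
    precision alpha+beta drawn per (cluster, class), spanning tight
    tissue-specific and noisy clusters.
    """

    T: int = 5
    K_total: int = 2000
    frac_informative: float = 0.75
    separation: float = 0.3
    concentration: tuple[float, float] = (20.0, 200.0)
    pool_size: int = 120
    na_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("need at least one tumor class")
        if not 0.0 < self.frac_informative <= 1.0:
            raise ValueError("frac_informative must be in (0, 1]")
        if not 0.0 < self.separation <= MEAN_HI - MEAN_LO:
            raise ValueError(
                f"separation must be in (0, {MEAN_HI - MEAN_LO}]; "
                f"{self.separation} leaves no room for two class means in "
                f"[{MEAN_LO}, {MEAN_HI}]"
            )
        lo, hi = self.concentration
        if not 0 < lo <= hi:
            raise ValueError("concentration range must be positive and ordered")
        if self.pool_size < 5:
            raise ValueError("pool_size must be >= 5 (minimum fitting size)")
        if not 0.0 <= self.na_rate < 1.0:
            raise ValueError("na_rate must be in [0, 1)")


@dataclass
class SynthReference:
    """Generated truth plus pools: the in-memory study system."""

    config: SynthRefConfig
    clusters: list[CpGCluster]
    true_params: dict[int, dict[str, tuple[float, float]]]
    true_means: dict[int, dict[str, float]]
    pools: list[ArrayProfile]
    class_names: dict[int, str]

    def pools_by_class(self) -> dict[int, list[ArrayProfile]]:
        out: dict[int, list[ArrayProfile]] = {t: [] for t in self.class_names}
        for p in self.pools:
            out[p.class_label].append(p)
        return out

    def true_mr(self, cluster_id: str) -> float:
        means = [self.true_means[t][cluster_id] for t in self.class_names]
        return max(means) - min(means)


def _synth_clusters(K: int, rng: np.random.Generator) -> list[CpGCluster]:
    """Synthetic genomic coordinates: K clusters of 3-10 probed sites on chr1."""
    sites: list[CpGSite] = []
    pos = 1000
    for _ in range(K):
        n_sites = int(rng.integers(3, 11))
        for _ in range(n_sites):
            sites.append(CpGSite("chr1", pos))
            pos += int(rng.integers(20, 180))
        pos += 500  # > 2 * flank: guarantees a cluster break
    clusters = build_clusters(sites, flank_bp=100, min_probes=3)
    assert len(clusters) == K
    return clusters


def generate_reference(config: SynthRefConfig) -> SynthReference:
    """Generate true per-class Beta parameters and sample pools.

    Deterministic for a given config (single seeded generator).  For each
    informative cluster the deviant class mean differs from the shared
    baseline by an offset >= config.separation, so the true MR of those
    clusters is guaranteed to reach the separation target.
    """
    rng = np.random.default_rng(config.seed)
    clusters = _synth_clusters(config.K_total, rng)
    T = config.T
    classes = list(range(T + 1))
    if T == 5:
        class_names = {0: "normal", **{t: FIVE_ORGANS[t - 1] for t in range(1, 6)}}
    else:
        class_names = {0: "normal", **{t: f"tumor{t}" for t in range(1, T + 1)}}

    n_inf = int(round(config.frac_informative * config.K_total))
    informative = np.zeros(config.K_total, dtype=bool)
    informative[rng.choice(config.K_total, size=n_inf, replace=False)] = True

    true_params: dict[int, dict[str, tuple[float, float]]] = {t: {} for t in classes}
    true_means: dict[int, dict[str, float]] = {t: {} for t in classes}
    clo, chi = config.concentration
    for k, cl in enumerate(clusters):
        cid = cl.cluster_id
        if informative[k]:
            off_hi = min(0.9, MEAN_HI - MEAN_LO)
            off = float(rng.uniform(config.separation, max(config.separation, off_hi)))
            off = min(off, MEAN_HI - MEAN_LO)
            low = float(rng.uniform(MEAN_LO, MEAN_HI - off))
            pair = (low, low + off)
            deviant = int(rng.integers(0, T + 1))
            if rng.uniform() < 0.5:
                baseline_mean, deviant_mean = pair
            else:
                deviant_mean, baseline_mean = pair
            means = {t: (deviant_mean if t == deviant else baseline_mean) for t in classes}
        else:
            mu = float(rng.uniform(MEAN_LO, MEAN_HI))
            means = {t: mu for t in classes}
        for t in classes:
            kappa = float(rng.uniform(clo, chi))
            mu = means[t]
            true_params[t][cid] = (mu * kappa, (1.0 - mu) * kappa)
            true_means[t][cid] = mu

    pools: list[ArrayProfile] = []
    cids = [c.cluster_id for c in clusters]
    for t in classes:
        a = np.array([true_params[t][cid][0] for cid in cids])
        b = np.array([true_params[t][cid][1] for cid in cids])
        for s in range(config.pool_size):
            levels = rng.beta(a, b)
            if config.na_rate > 0:
                na_mask = rng.uniform(size=levels.size) < config.na_rate
                levels = np.where(na_mask, np.nan, levels)
            name = f"{class_names[t]}_{s:04d}"
            pools.append(ArrayProfile(name, t, dict(zip(cids, levels.tolist()))))
    return SynthReference(config, clusters, true_params, true_means, pools, class_names)


def export_pools(
    ref: SynthReference,
    matrix_path,
    manifest_path,
    truth_path=None,
) -> None:
    """Write pools as an array matrix + manifest (round-trip exact), and
    optionally the generator truth (class names, true Beta params) as JSON."""
    by_class = ref.pools_by_class()
    for t, members in by_class.items():
        if not members:
            raise ValueError(f"class {t} ({ref.class_names[t]}) has no pool samples")
    write_array_profiles(ref.pools, matrix_path, manifest_path)
    if truth_path is not None:
        doc = {
            "class_names": {str(t): n for t, n in ref.class_names.items()},
            "true_params": {
                str(t): {cid: list(ab) for cid, ab in ref.true_params[t].items()}
                for t in ref.class_names
            },
        }
        Path(truth_path).write_text(json.dumps(doc))
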