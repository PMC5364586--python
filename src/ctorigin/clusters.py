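"""CpG cluster construction and cluster-level methylation summaries.

Whole-genome bisulfite sequencing of plasma cell-free DNA is shallow
(typically a few reads per CpG), so single CpG sites are too noisy to use
as features.  Nearby probed CpG sites are therefore merged into *CpG
clusters*: a site's flanking region is the window ``flank_bp`` up- and
downstream of it, adjacent sites whose flanking regions overlap are merged
(transitively), and only clusters containing at least ``min_probes`` probed
sites are kept.  The cluster is the feature unit ``k`` everywhere else in
this package.

Coordinates are 0-based half-open throughout.  Missing methylation values
are represented by ``math.nan`` ("NA" on disk); NA is a value, never an
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "NA",
    "is_na",
    "CpGSite",
    "CpGCluster",
    "UnsortedSitesError",
    "build_clusters",
    "assign_sites",
    "cluster_level_from_array",
    "cluster_level_from_counts",
]

NA: float = math.nan


def is_na(x) -> bool:
    """True for the NA sentinel (None or NaN)."""
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class CpGSite:
    """A CpG site covered by a probe; ``pos`` is 0-based."""

    chrom: str
    pos: int
    probe_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"CpG site position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class CpGCluster:
    """A merged interval of nearby probed CpG sites (0-based half-open)."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    site_count: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"cluster {self.cluster_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )
        if self.site_count < 1:
            raise ValueError(f"cluster {self.cluster_id}: site_count must be >= 1")


def make_cluster_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


class UnsortedSitesError(ValueError):
    """Input site table is not sorted by (chromosome block, position)."""


def _check_sorted(sites: Sequence[CpGSite]) -> None:
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = -1
    for i, s in enumerate(sites):
        if s.chrom != prev_chrom:
            if s.chrom in seen_chroms:
                raise UnsortedSitesError(
                    f"site {i}: chromosome {s.chrom!r} appears in more than one block"
                )
            seen_chroms.add(s.chrom)
            prev_chrom = s.chrom
            prev_pos = -1
        if s.pos <= prev_pos:
            raise UnsortedSitesError(
                f"site {i}: position {s.pos} on {s.chrom} is not strictly "
                f"increasing (previous {prev_pos}); sort the table and drop "
                "duplicate (chrom, pos) rows"
            )
        prev_pos = s.pos


def build_clusters(
    sites: Sequence[CpGSite],
    flank_bp: int = 100,
    min_probes: int = 3,
) -> list[CpGCluster]:
    """Group probed CpG sites into CpG clusters.

    Two adjacent sites on the same chromosome belong to one cluster iff
    their +/- ``flank_bp`` flanking regions overlap, i.e. their distance is
    at most ``2 * flank_bp`` (flanking regions are closed base intervals,
    so touching counts as overlap); membership is the transitive closure of
    this relation.  Clusters with fewer than ``min_probes`` sites are
    discarded.  The emitted interval spans ``min(pos) - flank_bp`` (floored
    at 0) to ``max(pos) + flank_bp``.

    Raises
    ------
    UnsortedSitesError
        If ``sites`` is not sorted by (chromosome block, strictly
        increasing position).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    sites = list(sites)
    if not sites:
        return []
    _check_sorted(sites)

    clusters: list[CpGCluster] = []
    run: list[CpGSite] = [sites[0]]

    def flush(run: list[CpGSite]) -> None:
        if len(run) < min_probes:
            return
        chrom = run[0].chrom
        start = max(0, run[0].pos - flank_bp)
        end = run[-1].pos + flank_bp
        clusters.append(
            CpGCluster(make_cluster_id(chrom, start, end), chrom, start, end, len(run))
        )

    for s in sites[1:]:
        prev = run[-1]
        if s.chrom == prev.chrom and s.pos - prev.pos <= 2 * flank_bp:
            run.append(s)
        else:
            flush(run)
            run = [s]
    flush(run)
    return clusters


def assign_sites(
    sites: Iterable[CpGSite], clusters: Sequence[CpGCluster]
) -> dict[str, list[CpGSite]]:
    """Map each cluster_id to the probed sites its interval contains.

    A site can land in at most one cluster because clusters on a
    chromosome are non-overlapping.
    """
    by_chrom: dict[str, list[CpGCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    out: dict[str, list[CpGSite]] = {c.cluster_id: [] for c in clusters}
    for s in sites:
        for c in by_chrom.get(s.chrom, ()):
            if c.start <= s.pos <= c.end:
                out[c.cluster_id].append(s)
                break
    return out


def cluster_level_from_array(levels: Iterable[float]) -> float:
    """Cluster methylation level from per-site array levels.

    Returns the mean of the non-NA site levels; NA iff strictly more than
    half of the cluster's sites are NA ("more than half" is strict, so 2 NA
    of 4 sites still yields a value).
    """
    vals = list(levels)
    if not vals:
        return NA
    ok = [v for v in vals if not is_na(v)]
    n_na = len(vals) - len(ok)
    if 2 * n_na > len(vals):
        return NA
    return sum(ok) / len(ok)


def cluster_level_from_counts(m: int, n: int, min_total: int = 30) -> float:
    """Cluster methylation level from sequencing counts: m/n, NA if n < min_total.

    The floor (default 30 total cytosines) guards against unreliable
    ratios from shallow coverage.
    """
    if not 0 <= m <= n:
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if n < min_total:
        return NA
    return m / n
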