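"""Tab-separated readers and writers for the tabular formats the tool touches.

Formats (all TSV with a header row, coordinates 0-based half-open, NA
spelled "NA"):

* site table        — chrom, pos, probe_id
* cluster table     — cluster_id, chrom, start, end, site_count (+ BED export)
* array matrix      — cluster_id + one column per sample, levels in [0,1] or NA,
                      with a separate two-column sample -> class_label manifest
* sequencing profile— cluster_id, meth_count, total_count (one sample per file)

Floats are serialized with ``repr`` so read(write(x)) round-trips bit-exactly.
Malformed rows raise :class:`ParseError` naming file, line, and column.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .clusters import NA, CpGCluster, CpGSite, is_na

__all__ = [
    "ParseError",
    "ArrayProfile",
    "SeqProfile",
    "read_site_table",
    "write_site_table",
    "read_cluster_table",
    "write_cluster_table",
    "write_clusters_bed",
    "read_array_profiles",
    "write_array_profiles",
    "read_seq_profile",
    "write_seq_profile",
]


class ParseError(ValueError):
    """A malformed row; message carries file, 1-based line, and column."""

    def __init__(self, path, lineno: int, column: str, detail: str):
        super().__init__(f"{path}:{lineno}: column {column!r}: {detail}")
        self.path, self.lineno, self.column = str(path), lineno, column


@dataclass
class ArrayProfile:
    """Array-style methylation profile: per-cluster levels in [0,1] or NA."""

    sample_id: str
    class_label: int
    levels: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, v in self.levels.items():
            if not is_na(v) and not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"sample {self.sample_id}, cluster {cid}: level {v} not in [0,1]"
                )


@dataclass
class SeqProfile:
    """Sequencing-style profile: per-cluster (methylated, total) cytosine counts."""

    sample_id: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, (m, n) in self.counts.items():
            if not 0 <= m <= n:
                raise ValueError(
                    f"sample {self.sample_id}, cluster {cid}: need 0 <= m <= n, "
                    f"got m={m}, n={n}"
                )


def _fmt(x: float) -> str:
    return "NA" if is_na(x) else repr(float(x))


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if row and any(cell.strip() for cell in row):
                yield lineno, row


def _header(path, row: list[str], expected: Sequence[str]) -> None:
    if [c.strip() for c in row[: len(expected)]] != list(expected):
        raise ParseError(path, 1, expected[0], f"expected header {list(expected)}, got {row}")


def _to_int(path, lineno: int, column: str, cell: str) -> int:
    try:
        return int(cell)
    except ValueError:
        raise ParseError(path, lineno, column, f"not an integer: {cell!r}") from None


def _to_level(path, lineno: int, column: str, cell: str) -> float:
    if cell.strip() in ("NA", "", "nan", "NaN"):
        return NA
    try:
        v = float(cell)
    except ValueError:
        raise ParseError(path, lineno, column, f"not a number: {cell!r}") from None
    if not 0.0 <= v <= 1.0:
        raise ParseError(path, lineno, column, f"level {v} outside [0,1]")
    return v


# ---------------------------------------------------------------- site tables


def read_site_table(path) -> list[CpGSite]:
    rows = iter(_rows(path))
    try:
        _, head = next(rows)
    except StopIteration:
        return []
    _header(path, head, ("chrom", "pos", "probe_id"))
    sites: list[CpGSite] = []
    seen: set[tuple[str, int]] = set()
    for lineno, row in rows:
        if len(row) < 2:
            raise ParseError(path, lineno, "pos", "row has fewer than 2 fields")
        chrom = row[0].strip()
        pos = _to_int(path, lineno, "pos", row[1])
        if pos < 0:
            raise ParseError(path, lineno, "pos", f"negative position {pos}")
        if (chrom, pos) in seen:
            raise ParseError(path, lineno, "pos", f"duplicate site ({chrom}, {pos})")
        seen.add((chrom, pos))
        probe = row[2].strip() if len(row) > 2 and row[2].strip() else None
        sites.append(CpGSite(chrom, pos, probe))
    return sites


def write_site_table(sites: Iterable[CpGSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tprobe_id\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.probe_id or ''}\n")


# ------------------------------------------------------------- cluster tables


def read_cluster_table(path) -> list[CpGCluster]:
    rows = iter(_rows(path))
    try:
        _, head = next(rows)
    except StopIteration:
        return []
    _header(path, head, ("cluster_id", "chrom", "start", "end", "site_count"))
    out = []
    for lineno, row in rows:
        if len(row) < 5:
            raise ParseError(path, lineno, "site_count", "row has fewer than 5 fields")
        try:
            out.append(
                CpGCluster(
                    row[0].strip(),
                    row[1].strip(),
                    _to_int(path, lineno, "start", row[2]),
                    _to_int(path, lineno, "end", row[3]),
                    _to_int(path, lineno, "site_count", row[4]),
                )
            )
        except ValueError as e:
            if isinstance(e, ParseError):
                raise
            raise ParseError(path, lineno, "cluster_id", str(e)) from None
    return out


def write_cluster_table(clusters: Iterable[CpGCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tstart\tend\tsite_count\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.site_count}\n")


def write_clusters_bed(clusters: Iterable[CpGCluster], path) -> None:
    """BED4 export (chrom, start, end, cluster_id)."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\n")


# ------------------------------------------------------------- array matrices


def read_array_profiles(matrix_path, manifest_path) -> list[ArrayProfile]:
    """Read an array-level matrix plus its sample -> class_label manifest."""
    labels: dict[str, int] = {}
    rows = iter(_rows(manifest_path))
    try:
        _, head = next(rows)
    except StopIteration:
        raise ParseError(manifest_path, 1, "sample_id", "empty manifest") from None
    _header(manifest_path, head, ("sample_id", "class_label"))
    for lineno, row in rows:
        if len(row) < 2:
            raise ParseError(manifest_path, lineno, "class_label", "row has fewer than 2 fields")
        labels[row[0].strip()] = _to_int(manifest_path, lineno, "class_label", row[1])

    rows = iter(_rows(matrix_path))
    try:
        _, head = next(rows)
    except StopIteration:
        raise ParseError(matrix_path, 1, "cluster_id", "empty matrix") from None
    if head[0].strip() != "cluster_id":
        raise ParseError(matrix_path, 1, "cluster_id", f"expected first column 'cluster_id', got {head[0]!r}")
    sample_ids = [c.strip() for c in head[1:]]
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ParseError(matrix_path, 1, missing[0], "sample missing from manifest")
    profiles = [ArrayProfile(s, labels[s]) for s in sample_ids]
    for lineno, row in rows:
        if len(row) != len(sample_ids) + 1:
            raise ParseError(
                matrix_path, lineno, "cluster_id",
                f"expected {len(sample_ids) + 1} fields, got {len(row)}",
            )
        cid = row[0].strip()
        for p, cell, sid in zip(profiles, row[1:], sample_ids):
            p.levels[cid] = _to_level(matrix_path, lineno, sid, cell)
    return profiles


def write_array_profiles(profiles: Sequence[ArrayProfile], matrix_path, manifest_path) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    order: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for cid in p.levels:
            if cid not in seen:
                seen.add(cid)
                order.append(cid)
    with open(manifest_path, "w") as fh:
        fh.write("sample_id\tclass_label\n")
        for p in profiles:
            fh.write(f"{p.sample_id}\t{p.class_label}\n")
    with open(matrix_path, "w") as fh:
        fh.write("cluster_id\t" + "\t".join(p.sample_id for p in profiles) + "\n")
        for cid in order:
            cells = "\t".join(_fmt(p.levels.get(cid, NA)) for p in profiles)
            fh.write(f"{cid}\t{cells}\n")


# --------------------------------------------------------- sequencing profiles


def read_seq_profile(path, sample_id: str | None = None) -> SeqProfile:
    rows = iter(_rows(path))
    try:
        _, head = next(rows)
    except StopIteration:
        raise ParseError(path, 1, "cluster_id", "empty sequencing profile") from None
    _header(path, head, ("cluster_id", "meth_count", "total_count"))
    if sample_id is None:
        sample_id = Path(path).stem
    prof = SeqProfile(sample_id)
    for lineno, row in rows:
        if len(row) < 3:
            raise ParseError(path, lineno, "total_count", "row has fewer than 3 fields")
        cid = row[0].strip()
        m = _to_int(path, lineno, "meth_count", row[1])
        n = _to_int(path, lineno, "total_count", row[2])
        if m < 0 or n < 0:
            raise ParseError(path, lineno, "meth_count", f"negative count (m={m}, n={n})")
        if m > n:
            raise ParseError(path, lineno, "meth_count", f"m={m} exceeds n={n}")
        if cid in prof.counts:
            raise ParseError(path, lineno, "cluster_id", f"duplicate cluster {cid}")
        prof.counts[cid] = (m, n)
    return prof


def write_seq_profile(profile: SeqProfile, path) -> None:
    profile.validate()
    with open(path, "w") as fh:
        fh.write("cluster_id\tmeth_count\ttotal_count\n")
        for cid, (m, n) in profile.counts.items():
            fh.write(f"{cid}\t{m}\t{n}\n")
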