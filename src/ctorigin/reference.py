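"""Reference panel construction: feature selection and per-class Beta models.

For every CpG cluster k and every class t (t = 0 is normal plasma, t = 1..T
are solid tumor types) the methylation level across individuals is modeled
as Beta(alpha_kt, beta_kt), fitted by the method of moments from a labeled
training pool of array-style profiles.  Features are selected by the
methylation range (MR): the spread max - min of the per-class mean levels.
Clusters whose MR reaches the cutoff (default 0.25) in the training pass,
and which admit a valid Beta fit in every class, form the panel used by
both the simulator and the likelihood machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clusters import NA, is_na
from .io import ArrayProfile, ParseError, _fmt, _rows, _to_int

__all__ = [
    "ClassBetaModel",
    "ReferencePanel",
    "fit_beta_moments",
    "compute_mr",
    "select_features",
    "build_panel",
    "read_panel",
    "write_panel",
]

#: clamp levels into [EPS_LEVEL, 1 - EPS_LEVEL] before taking moments
EPS_LEVEL = 1e-6
#: variance floor; also the degenerate-cluster fallback scale
VAR_FLOOR = 1e-6


@dataclass
class ClassBetaModel:
    """Per-cluster (alpha, beta) Beta parameters for one class."""

    class_id: int
    params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, (a, b) in self.params.items():
            if not (math.isfinite(a) and math.isfinite(b) and a > 0 and b > 0):
                raise ValueError(f"class {self.class_id}, cluster {cid}: invalid Beta({a}, {b})")


@dataclass
class ReferencePanel:
    """Fitted Beta models for classes 0..T plus the selected feature set."""

    models: dict[int, ClassBetaModel]
    selected_features: list[str]
    mr: dict[str, float]
    class_names: dict[int, str]
    mr_cutoff: float = 0.25

    @property
    def n_tumor_classes(self) -> int:
        return max(self.models) if self.models else 0

    def validate(self) -> None:
        classes = sorted(self.models)
        if classes != list(range(len(classes))):
            raise ValueError(f"classes must be contiguous 0..T, got {classes}")
        for model in self.models.values():
            model.validate()
        for cid in self.selected_features:
            if self.mr.get(cid, NA) < self.mr_cutoff:
                raise ValueError(f"selected cluster {cid} has MR below cutoff")
            for t, model in self.models.items():
                if cid not in model.params:
                    raise ValueError(f"selected cluster {cid} missing from class {t}")


def fit_beta_moments(
    values: Iterable[float], min_samples: int = 5
) -> tuple[float, float] | None:
    """Method-of-moments Beta fit of per-sample methylation levels.

    With sample mean mu and variance s2 (ddof=1), the common factor is
    c = mu(1-mu)/s2 - 1 and (alpha, beta) = (mu*c, (1-mu)*c).  To keep the
    parameters finite and positive for degenerate clusters, levels are
    clamped to [1e-6, 1-1e-6], the variance is floored at 1e-6, and if
    s2 >= mu(1-mu) (no valid Beta) it is pulled back to 0.999*mu(1-mu).

    Returns None when fewer than ``min_samples`` non-NA values are given.
    """
    vals = np.asarray([v for v in values if not is_na(v)], dtype=float)
    if vals.size < min_samples:
        return None
    vals = np.clip(vals, EPS_LEVEL, 1.0 - EPS_LEVEL)
    mu = float(vals.mean())
    s2 = float(vals.var(ddof=1))
    return _moments_to_ab(mu, s2)


def _moments_to_ab(mu: float, s2: float) -> tuple[float, float]:
    mu = min(max(mu, EPS_LEVEL), 1.0 - EPS_LEVEL)
    cap = mu * (1.0 - mu)
    if s2 < VAR_FLOOR:
        s2 = VAR_FLOOR
    if s2 >= cap:
        s2 = 0.999 * cap
    c = cap / s2 - 1.0
    return mu * c, (1.0 - mu) * c


def compute_mr(class_means: Mapping[int, float] | Sequence[float]) -> float:
    """Methylation range: max - min of the per-class mean levels.

    NA means are ignored; with fewer than two usable classes the MR itself
    is NA (the cluster cannot discriminate anything).
    """
    means = list(class_means.values()) if isinstance(class_means, Mapping) else list(class_means)
    ok = [m for m in means if not is_na(m)]
    if len(ok) < 2:
        return NA
    return max(ok) - min(ok)


def select_features(
    mr: Mapping[str, float],
    fitted: Mapping[str, bool] | None = None,
    mr_cutoff: float = 0.25,
) -> set[str]:
    """Clusters with MR >= cutoff ("no less than" is inclusive) and, when
    ``fitted`` is given, a valid Beta fit in every class."""
    out = set()
    for cid, r in mr.items():
        if is_na(r) or r < mr_cutoff:
            continue
        if fitted is not None and not fitted.get(cid, False):
            continue
        out.add(cid)
    return out


def build_panel(
    pools: Sequence[ArrayProfile],
    mr_cutoff: float = 0.25,
    min_samples: int = 5,
    class_names: Mapping[int, str] | None = None,
) -> ReferencePanel:
    """Fit per-class Beta models and select features from a labeled pool.

    MR uses the per-class sample means over the same training samples used
    for the moment fits (one training pass).  A cluster is selected iff its
    MR reaches the cutoff and every class 0..T has >= ``min_samples``
    usable values there.
    """
    if not pools:
        raise ValueError("empty training pool")
    classes = sorted({p.class_label for p in pools})
    if classes[0] != 0:
        raise ValueError("training pool must include normal plasma (class 0)")
    if classes != list(range(len(classes))):
        raise ValueError(f"class labels must be contiguous 0..T, got {classes}")

    by_class: dict[int, list[ArrayProfile]] = {t: [] for t in classes}
    for p in pools:
        by_class[p.class_label].append(p)

    cluster_ids: list[str] = []
    seen: set[str] = set()
    for p in pools:
        for cid in p.levels:
            if cid not in seen:
                seen.add(cid)
                cluster_ids.append(cid)

    models = {t: ClassBetaModel(t) for t in classes}
    mr: dict[str, float] = {}
    fitted_all: dict[str, bool] = {}
    for cid in cluster_ids:
        means: dict[int, float] = {}
        ok = True
        fits: dict[int, tuple[float, float]] = {}
        for t in classes:
            vals = [p.levels[cid] for p in by_class[t] if cid in p.levels and not is_na(p.levels[cid])]
            fit = fit_beta_moments(vals, min_samples=min_samples)
            if fit is None:
                ok = False
                means[t] = NA
            else:
                fits[t] = fit
                means[t] = float(np.mean(vals))
        mr[cid] = compute_mr(means)
        fitted_all[cid] = ok
        if ok:
            for t, ab in fits.items():
                models[t].params[cid] = ab

    selected = sorted(select_features(mr, fitted_all, mr_cutoff))
    names = dict(class_names) if class_names else {t: ("normal" if t == 0 else f"tumor{t}") for t in classes}
    panel = ReferencePanel(models, selected, mr, names, mr_cutoff)
    panel.validate()
    return panel


# ------------------------------------------------------------- serialization


def write_panel(panel: ReferencePanel, path) -> None:
    """Serialize a panel to TSV (bit-exact round-trip via repr floats)."""
    classes = sorted(panel.models)
    with open(path, "w") as fh:
        fh.write("#ctorigin-panel\tv1\n")
        fh.write(f"#mr_cutoff\t{_fmt(panel.mr_cutoff)}\n")
        fh.write("#classes\t" + ",".join(f"{t}:{panel.class_names.get(t, '')}" for t in classes) + "\n")
        cols = ["cluster_id", "mr"] + [f"{p}_{t}" for t in classes for p in ("alpha", "beta")]
        fh.write("\t".join(cols) + "\n")
        for cid in panel.selected_features:
            row = [cid, _fmt(panel.mr[cid])]
            for t in classes:
                a, b = panel.models[t].params[cid]
                row += [_fmt(a), _fmt(b)]
            fh.write("\t".join(row) + "\n")


def read_panel(path) -> ReferencePanel:
    mr_cutoff = 0.25
    class_names: dict[int, str] = {}
    rows = list(_rows(path))
    body_start = 0
    for i, (lineno, row) in enumerate(rows):
        if not row[0].startswith("#"):
            body_start = i
            break
        if row[0] == "#mr_cutoff":
            mr_cutoff = float(row[1])
        elif row[0] == "#classes":
            for part in row[1].split(","):
                t, _, name = part.partition(":")
                class_names[int(t)] = name
    else:
        raise ParseError(path, 1, "cluster_id", "panel file has no header row")

    lineno, head = rows[body_start]
    if head[:2] != ["cluster_id", "mr"]:
        raise ParseError(path, lineno, "cluster_id", f"unexpected panel header {head[:2]}")
    classes = sorted(class_names) if class_names else list(range((len(head) - 2) // 2))
    if len(head) != 2 + 2 * len(classes):
        raise ParseError(path, lineno, "mr", "column count does not match declared classes")
    models = {t: ClassBetaModel(t) for t in classes}
    mr: dict[str, float] = {}
    selected: list[str] = []
    for lineno, row in rows[body_start + 1:]:
        if len(row) != len(head):
            raise ParseError(path, lineno, "cluster_id", f"expected {len(head)} fields, got {len(row)}")
        cid = row[0]
        mr[cid] = float(row[1])
        selected.append(cid)
        for j, t in enumerate(classes):
            a = float(row[2 + 2 * j])
            b = float(row[3 + 2 * j])
            models[t].params[cid] = (a, b)
    if not class_names:
        class_names = {t: ("normal" if t == 0 else f"tumor{t}") for t in classes}
    panel = ReferencePanel(models, selected, mr, class_names, mr_cutoff)
    panel.validate()
    return panel
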