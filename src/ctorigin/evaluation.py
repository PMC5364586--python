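"""Evaluation protocol: data partitioning, simulation runs, and metrics.

The protocol mirrors a standard liquid-biopsy benchmarking design: per
class, 75% of the reference pool trains the panel (feature selection +
Beta fits) and the held-out 25% feeds the simulator; simulated test
samples span ten ctDNA-burden bins (theta, theta+10%], theta = 0..90%,
each bin pairing cancer samples of every tumor class with a non-cancer arm
of normal-mixing samples.  Experiments are repeated over several random
partitions and all predictions are pooled into a single confusion matrix.

Metrics: the multi-class *error rate* (fraction of incorrect predictions
over all predictions), Pearson correlation and RMSE between true and
predicted burden (over cancer samples), and per-bin error rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .inference import ThetaGrid, predict_many
from .io import ArrayProfile, SeqProfile
from .reference import build_panel
from .simulator import (
    SimScenario,
    cna_preset,
    default_bias,
    simulate_cancer_plasma,
    simulate_normal_plasma,
)
from .synthref import SynthRefConfig, SynthReference, generate_reference

__all__ = [
    "EvalReport",
    "ExperimentConfig",
    "partition_data",
    "burden_metrics",
    "burden_bins",
    "make_report",
    "run_experiment",
    "uniform_guess_predictor",
]

#: one prediction record: true label, predicted label, true theta,
#: predicted theta, bin label ("" for records outside the bin design)
Record = dict


def partition_data(
    pools: Sequence[ArrayProfile],
    train_frac: float = 0.75,
    rng: np.random.Generator | None = None,
) -> tuple[list[ArrayProfile], list[ArrayProfile]]:
    """Per-class random split into disjoint train and test sets."""
    if not 0.0 < train_frac <= 1.0:
        raise ValueError("train_frac must be in (0, 1]")
    rng = rng or np.random.default_rng()
    by_class: dict[int, list[ArrayProfile]] = {}
    for p in pools:
        by_class.setdefault(p.class_label, []).append(p)
    train: list[ArrayProfile] = []
    test: list[ArrayProfile] = []
    for t in sorted(by_class):
        members = by_class[t]
        order = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    if not test:
        warnings.warn("train_frac leaves an empty test set", stacklevel=2)
    return train, test


def burden_metrics(true_theta: Sequence[float], pred_theta: Sequence[float]) -> tuple[float, float]:
    """(Pearson correlation, root mean squared error) of burden estimates."""
    t = np.asarray(true_theta, dtype=float)
    p = np.asarray(pred_theta, dtype=float)
    if t.size != p.size or t.size < 2:
        raise ValueError("need at least 2 paired burden values")
    if t.std() == 0.0 or p.std() == 0.0:
        pcc = float("nan")  # correlation undefined for constant vectors
    else:
        pcc = float(np.corrcoef(t, p)[0, 1])
    rmse = float(np.sqrt(np.mean((t - p) ** 2)))
    return pcc, rmse


def burden_bins(n_bins: int = 10) -> list[tuple[float, float]]:
    """Left-open/right-closed bins (theta, theta+1/n] partitioning (0, 1]."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bins)]


def bin_label(lo: float, hi: float) -> str:
    return f"({lo:.2f},{hi:.2f}]"


@dataclass
class EvalReport:
    """Pooled evaluation outcome over one or more runs."""

    confusion: np.ndarray  # (T+1, T+1): rows true class, cols predicted
    error_rate: float
    pcc: float
    rmse: float
    per_bin: dict[str, float]
    n_predictions: int
    class_names: dict[int, str] = field(default_factory=dict)
    per_run: list["EvalReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "pcc": self.pcc,
            "rmse": self.rmse,
            "n_predictions": self.n_predictions,
            "per_bin": self.per_bin,
            "confusion": self.confusion.tolist(),
            "class_names": {str(t): n for t, n in self.class_names.items()},
        }


def make_report(
    records: Sequence[Record],
    n_tumor_classes: int,
    class_names: dict[int, str] | None = None,
) -> EvalReport:
    """Score a pooled set of prediction records."""
    T = n_tumor_classes
    conf = np.zeros((T + 1, T + 1), dtype=int)
    for r in records:
        conf[r["true_label"], r["pred_label"]] += 1
    n = len(records)
    errors = sum(1 for r in records if r["true_label"] != r["pred_label"])
    cancer = [r for r in records if r["true_label"] != 0]
    if len(cancer) >= 2:
        pcc, rmse = burden_metrics(
            [r["true_theta"] for r in cancer], [r["pred_theta"] for r in cancer]
        )
    else:
        pcc, rmse = float("nan"), float("nan")
    per_bin: dict[str, float] = {}
    for lab in sorted({r["bin"] for r in records if r["bin"]}):
        sub = [r for r in records if r["bin"] == lab]
        per_bin[lab] = sum(1 for r in sub if r["true_label"] != r["pred_label"]) / len(sub)
    return EvalReport(
        confusion=conf,
        error_rate=errors / n if n else float("nan"),
        pcc=pcc,
        rmse=rmse,
        per_bin=per_bin,
        n_predictions=n,
        class_names=dict(class_names or {}),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one simulation experiment."""

    ref_config: SynthRefConfig = SynthRefConfig()
    train_frac: float = 0.75
    mr_cutoff: float = 0.25
    min_fit_samples: int = 5
    grid_j: int = 100
    lambda_threshold: float = 0.023
    #: sequencing depth (fold coverage per CpG); the per-cluster cytosine
    #: budget is depth * CpG content, with content modeled as
    #: cpgs_per_site CpG dinucleotides per probed site
    seq_depth: float = 4.0
    cpgs_per_site: float = 3.0
    cna_rate: float = 0.3
    samples_per_class_per_bin: int = 20
    n_bins: int = 10
    seed: int = 0


#: predictor interface: (profiles, panel, rng) -> [(predicted label, theta_hat)]
Predictor = Callable[[Sequence[SeqProfile], object, np.random.Generator], list[tuple[int, float]]]


def mle_predictor(grid_j: int = 100, lambda_threshold: float = 0.023) -> Predictor:
    """The package's own grid-search MLE wrapped in the predictor interface."""

    def predict(profiles, panel, rng):
        results = predict_many(
            profiles, panel, grid=ThetaGrid(grid_j), lambda_threshold=lambda_threshold
        )
        return [(r.predicted_label, r.theta_hat) for r in results]

    return predict


def uniform_guess_predictor(n_classes: int) -> Predictor:
    """Baseline stub guessing uniformly among the T+1 classes."""

    def predict(profiles, panel, rng):
        return [(int(rng.integers(0, n_classes)), 0.0) for _ in profiles]

    return predict


def simulate_bin(
    scenario: SimScenario,
    bin_range: tuple[float, float],
    tumor_classes: Sequence[int],
    n_cancer_per_class: int,
    n_normal: int,
    rng: np.random.Generator,
    tag: str = "",
) -> tuple[list[SeqProfile], list[Record]]:
    """Simulate one burden bin's test subset: cancer per class + a normal arm.

    Record entries carry the truth; ``pred_label``/``pred_theta`` are
    filled in by the caller after prediction.
    """
    lab = bin_label(*bin_range)
    scen = replace(scenario, theta_range=bin_range)
    profiles: list[SeqProfile] = []
    records: list[Record] = []
    for t in tumor_classes:
        for i in range(n_cancer_per_class):
            sid = f"{tag}c{t}_{lab}_{i}"
            prof, truth = simulate_cancer_plasma(scen, t, rng, sample_id=sid)
            profiles.append(prof)
            records.append(
                {"true_label": t, "true_theta": truth["theta"], "bin": lab, "sample_id": sid}
            )
    for i in range(n_normal):
        sid = f"{tag}n_{lab}_{i}"
        prof, truth = simulate_normal_plasma(scenario, rng, sample_id=sid)
        profiles.append(prof)
        records.append({"true_label": 0, "true_theta": 0.0, "bin": lab, "sample_id": sid})
    return profiles, records


def run_experiment(
    config: ExperimentConfig,
    n_runs: int = 10,
    predictor: Predictor | None = None,
    reference: SynthReference | None = None,
) -> EvalReport:
    """Run the full partition -> fit -> simulate -> predict -> score protocol.

    Per run: a fresh 75/25 partition of the reference pools, a panel fitted
    on the training side, test samples simulated from the held-out side
    across all burden bins, and predictions scored.  Predictions from all
    runs are pooled before the confusion matrix and error rate are
    computed; per-run reports are attached for inspection.
    """
    ref = reference if reference is not None else generate_reference(config.ref_config)
    T = ref.config.T
    if predictor is None:
        predictor = mle_predictor(config.grid_j, config.lambda_threshold)
    bias = default_bias(ref.clusters)
    total_sites = sum(c.site_count for c in ref.clusters)
    Z = int(round(config.seq_depth * config.cpgs_per_site * total_sites))
    bins = burden_bins(config.n_bins)
    tumor_classes = list(range(1, T + 1))

    all_records: list[Record] = []
    per_run: list[EvalReport] = []
    for run in range(n_runs):
        rng = np.random.default_rng([config.seed, run])
        train, test = partition_data(ref.pools, config.train_frac, rng)
        panel = build_panel(
            train, config.mr_cutoff, config.min_fit_samples, ref.class_names
        )
        test_by_class: dict[int, list[ArrayProfile]] = {t: [] for t in range(T + 1)}
        for p in test:
            test_by_class[p.class_label].append(p)
        scenario = SimScenario(
            theta_range=(0.0, 1.0),
            Z=Z,
            bias=bias,
            cna=cna_preset(config.cna_rate),
            normal_pool=test_by_class[0],
            tumor_pools={t: test_by_class[t] for t in tumor_classes},
        )
        profiles: list[SeqProfile] = []
        records: list[Record] = []
        for b in bins:
            p_bin, r_bin = simulate_bin(
                scenario,
                b,
                tumor_classes,
                config.samples_per_class_per_bin,
                config.samples_per_class_per_bin,
                rng,
                tag=f"run{run}_",
            )
            profiles.extend(p_bin)
            records.extend(r_bin)
        preds = predictor(profiles, panel, rng)
        for rec, (label, theta_hat) in zip(records, preds):
            rec["pred_label"] = label
            rec["pred_theta"] = theta_hat
        per_run.append(make_report(records, T, ref.class_names))
        all_records.extend(records)

    report = make_report(all_records, T, ref.class_names)
    report.per_run = per_run
    return report
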