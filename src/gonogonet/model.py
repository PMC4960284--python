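"""Experiment model and results objects.

The central object is :class:`EquivalenceExperiment`, a model of one
simulated go/no-go experiment: a trial table over a stimulus layout plus the
training hyperparameters.  Calling :meth:`~EquivalenceExperiment.fit` runs
``n_runs`` independent simulated participants — each run initializes a fresh
network from its own seed, trains to the stopping criterion, and then
evaluates the four transitivity-test compounds with frozen weights — and
returns an :class:`ExperimentResults` carrying every run's trajectory, test
activations, classifications and class-formation status, with aggregate
statistics, a ``summary()`` table, CSV/JSON export and a test-activation
plot.

Per-run seeds are derived as ``numpy.random.SeedSequence((base_seed,
run_index))``, so run *i* is identical no matter how many runs are
requested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .network import (
    Network,
    TrainingConfig,
    TrainingTrace,
    compute_rms,
    forward,
    init_network,
    train_to_criterion,
)
from .protocol import (
    ResponseClassification,
    StimulusLayout,
    Trial,
    build_experiment1,
    build_experiment2,
    classify,
    encode_compound,
    trials_from_csv,
)

__all__ = [
    "EquivalenceExperiment",
    "ExperimentResults",
    "RunResult",
    "run_once",
    "evaluate_pattern",
    "compare_experiments",
]

DEFAULT_N_HIDDEN = 3


@dataclass(frozen=True)
class RunResult:
    """Outcome of one simulated participant."""

    run_index: int
    trace: TrainingTrace
    test_activations: dict
    test_classifications: dict
    class_formed: bool
    inverse_pattern: bool

    @property
    def converged(self) -> bool:
        return self.trace.converged


class EquivalenceExperiment:
    """Model of a simulated go/no-go equivalence experiment.

    Parameters
    ----------
    trials
        Training and test trials (see :class:`gonogonet.protocol.Trial`).
    layout
        Stimulus-to-input-unit assignment the trials are encoded against.
    config
        Backpropagation hyperparameters; defaults to the published
        conditions (learning rate 0.3, zero momentum, stop at error
        <= 0.0025).
    n_hidden
        Hidden-layer width.  The published architecture does not record it;
        the default of 3 units is the width that reproduces the published
        formation/inverse-pattern rates (see the methods note).
    go_min, nogo_max
        Response-band edges used to score test activations.
    staged_pretraining
        If true, ``additional_training`` trials are first trained to
        criterion on their own before joint training of the full table
        (sensitivity analysis; default is a single joint phase).
    """

    def __init__(
        self,
        trials: Sequence[Trial],
        layout: StimulusLayout,
        config: TrainingConfig | None = None,
        n_hidden: int = DEFAULT_N_HIDDEN,
        go_min: float = 0.85,
        nogo_max: float = 0.15,
        staged_pretraining: bool = False,
        name: str = "custom",
    ):
        if not any(t.is_training for t in trials):
            raise ValueError("experiment needs at least one training trial")
        if not go_min > nogo_max:
            raise ValueError("go_min must exceed nogo_max")
        self.trials = tuple(trials)
        self.layout = layout
        self.config = config or TrainingConfig()
        self.n_hidden = int(n_hidden)
        self.go_min = float(go_min)
        self.nogo_max = float(nogo_max)
        self.staged_pretraining = bool(staged_pretraining)
        self.name = name

        self.training_trials = tuple(t for t in self.trials if t.is_training)
        self.test_trials = tuple(t for t in self.trials if not t.is_training)
        self._X_train = np.array(
            [encode_compound(t.compound, layout) for t in self.training_trials]
        )
        self._y_train = np.array([float(t.target) for t in self.training_trials])

    # -- constructors -------------------------------------------------------

    @classmethod
    def experiment1(cls, config: TrainingConfig | None = None, **kw) -> "EquivalenceExperiment":
        """The condition with auxiliary-class (X, Y, Z) training: 11 training trials."""
        layout, trials = build_experiment1()
        return cls(trials, layout, config, name="exp1", **kw)

    @classmethod
    def experiment2(cls, config: TrainingConfig | None = None, **kw) -> "EquivalenceExperiment":
        """The condition without auxiliary-class training: 8 training trials."""
        layout, trials = build_experiment2()
        return cls(trials, layout, config, name="exp2", **kw)

    @classmethod
    def from_csv(cls, path, layout: StimulusLayout | None = None, **kw) -> "EquivalenceExperiment":
        """Build a custom experiment from a trial-table CSV."""
        layout, trials = trials_from_csv(path, layout)
        return cls(trials, layout, name=str(path), **kw)

    @property
    def trials_per_epoch(self) -> int:
        return len(self.training_trials)

    def resolved_params(self) -> dict:
        """Flat dictionary of every parameter that defines the model."""
        d = dataclasses.asdict(self.config)
        d.update(
            experiment=self.name,
            n_hidden=self.n_hidden,
            go_min=self.go_min,
            nogo_max=self.nogo_max,
            staged_pretraining=self.staged_pretraining,
            layout="|".join(self.layout.labels),
            trials_per_epoch=self.trials_per_epoch,
        )
        return d

    # -- fitting ------------------------------------------------------------

    def fit(self, n_runs: int = 6, base_seed: int = 0) -> "ExperimentResults":
        """Run ``n_runs`` independent simulated participants."""
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        runs = [run_once(self, run_index=i, base_seed=base_seed) for i in range(n_runs)]
        return ExperimentResults(self, runs, base_seed)

    def _train_network(self, rng: np.random.Generator) -> tuple[Network, TrainingTrace]:
        net = init_network(len(self.layout), self.n_hidden, self.config, rng)
        if self.staged_pretraining:
            pre_idx = [
                i
                for i, t in enumerate(self.training_trials)
                if t.phase == "additional_training"
            ]
            if pre_idx:
                tr0 = train_to_criterion(
                    net, self._X_train[pre_idx], self._y_train[pre_idx], self.config, rng
                )
                tr1 = train_to_criterion(net, self._X_train, self._y_train, self.config, rng)
                converged = tr0.converged and tr1.converged
                epochs = (
                    tr0.epochs_to_criterion + tr1.epochs_to_criterion if converged else -1
                )
                iters = (
                    tr0.iterations_to_criterion + tr1.iterations_to_criterion
                    if converged
                    else -1
                )
                return net, TrainingTrace(
                    epochs, iters, tr0.rms_history + tr1.rms_history, converged
                )
        return net, train_to_criterion(net, self._X_train, self._y_train, self.config, rng)


def _expected_label(band: tuple) -> str:
    return "go" if band[0] >= 0.5 else "no_go"


def evaluate_pattern(
    activations: dict,
    test_trials: Sequence[Trial],
    go_min: float = 0.85,
    nogo_max: float = 0.15,
) -> tuple[bool, bool]:
    """Score test activations: (classes formed, inverse pattern).

    Classes are formed when every test compound's activation falls in its
    expected band; the pattern is inverse when every same-class compound
    classifies no-go and every mixed-class compound classifies go.  The two
    can never hold simultaneously.
    """
    matches, inverted = [], []
    for t in test_trials:
        label = classify(activations[t.compound.name], go_min, nogo_max).label
        expected = _expected_label(t.expected_band)
        matches.append(label == expected)
        inverted.append(label == ("no_go" if expected == "go" else "go"))
    return all(matches), all(inverted)


def run_once(model: EquivalenceExperiment, run_index: int, base_seed: int = 0) -> RunResult:
    """One simulated participant: init, train to criterion, frozen test."""
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, run_index)))
    net, trace = model._train_network(rng)

    w_ih_before, w_ho_before = net.w_ih.copy(), net.w_ho.copy()
    activations: dict[str, float] = {}
    labels: dict[str, ResponseClassification] = {}
    for t in model.test_trials:
        a = forward(net, encode_compound(t.compound, model.layout))
        activations[t.compound.name] = a
        labels[t.compound.name] = classify(a, model.go_min, model.nogo_max)
    assert np.array_equal(net.w_ih, w_ih_before) and np.array_equal(
        net.w_ho, w_ho_before
    ), "testing must not change weights"

    formed, inverted = evaluate_pattern(
        activations, model.test_trials, model.go_min, model.nogo_max
    )
    class_formed = trace.converged and formed
    inverse_pattern = trace.converged and inverted
    return RunResult(run_index, trace, activations, labels, class_formed, inverse_pattern)


class ExperimentResults:
    """Aggregate outcome of a fitted :class:`EquivalenceExperiment`.

    Mean epoch/iteration statistics are computed over converged runs only;
    non-convergent runs are counted separately.
    """

    def __init__(self, model: EquivalenceExperiment, runs: Sequence[RunResult], base_seed: int):
        self.model = model
        self.runs = list(runs)
        self.base_seed = base_seed

    # -- aggregates ---------------------------------------------------------

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.runs)

    @property
    def n_nonconverged(self) -> int:
        return self.n_runs - self.n_converged

    @property
    def n_class_formed(self) -> int:
        return sum(r.class_formed for r in self.runs)

    @property
    def n_inverse_pattern(self) -> int:
        return sum(r.inverse_pattern for r in self.runs)

    @property
    def class_formation_rate(self) -> float:
        return self.n_class_formed / self.n_runs

    @property
    def mean_epochs(self) -> float:
        eps = [r.trace.epochs_to_criterion for r in self.runs if r.converged]
        return float(np.mean(eps)) if eps else float("nan")

    @property
    def mean_iterations(self) -> float:
        its = [r.trace.iterations_to_criterion for r in self.runs if r.converged]
        return float(np.mean(its)) if its else float("nan")

    @property
    def all_nonconverged(self) -> bool:
        return self.n_converged == 0

    # -- tabular views ------------------------------------------------------

    def per_run_frame(self) -> pd.DataFrame:
        """One row per run: training trajectory summary and test outcomes."""
        test_names = [t.compound.name for t in self.model.test_trials]
        rows = []
        for r in self.runs:
            row = {
                "run": r.run_index,
                "converged": r.converged,
                "epochs": r.trace.epochs_to_criterion,
                "iterations": r.trace.iterations_to_criterion,
            }
            for name in test_names:
                row[f"act_{name}"] = r.test_activations[name]
                row[f"label_{name}"] = r.test_classifications[name].label
            row["class_formed"] = r.class_formed
            row["inverse_pattern"] = r.inverse_pattern
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report mirroring the per-run and aggregate results."""
        lines = [
            f"Go/no-go equivalence simulation — {self.model.name}",
            f"  runs: {self.n_runs}  (base_seed={self.base_seed})",
            f"  trials/epoch: {self.model.trials_per_epoch}, "
            f"hidden units: {self.model.n_hidden}, "
            f"lr: {self.model.config.learning_rate}, "
            f"momentum: {self.model.config.momentum}, "
            f"stop: {self.model.config.criterion_metric} <= "
            f"{self.model.config.rms_threshold}",
            "",
            self.per_run_frame().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            f"  mean epochs to criterion     : {self.mean_epochs:.1f}",
            f"  mean iterations to criterion : {self.mean_iterations:.1f}",
            f"  runs forming classes         : {self.n_class_formed}/{self.n_runs}",
            f"  runs with inverse pattern    : {self.n_inverse_pattern}/{self.n_runs}",
            f"  non-convergent runs          : {self.n_nonconverged}/{self.n_runs}",
        ]
        if self.all_nonconverged:
            lines.append("  WARNING: no run reached the stopping criterion")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "package_version": __version__,
            "config": self.model.resolved_params(),
            "base_seed": self.base_seed,
            "n_runs": self.n_runs,
            "mean_epochs": self.mean_epochs,
            "mean_iterations": self.mean_iterations,
            "n_class_formed": self.n_class_formed,
            "n_inverse_pattern": self.n_inverse_pattern,
            "n_nonconverged": self.n_nonconverged,
            "all_nonconverged": self.all_nonconverged,
            "per_run": self.per_run_frame().to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        self.per_run_frame().to_csv(path, index=False)

    # -- plotting -----------------------------------------------------------

    def plot_test_activations(self, ax=None):
        """Per-run test activations with the go/no-go threshold lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        test_names = [t.compound.name for t in self.model.test_trials]
        markers = ["o", "s", "^", "D", "v", "P", "X", "*"]
        for j, name in enumerate(test_names):
            ax.plot(
                [r.run_index + 1 for r in self.runs],
                [r.test_activations[name] for r in self.runs],
                markers[j % len(markers)],
                linestyle="none",
                label=name,
            )
        ax.axhline(self.model.go_min, linestyle="--", color="gray")
        ax.axhline(self.model.nogo_max, linestyle="--", color="gray")
        ax.set_xlabel("run")
        ax.set_ylabel("test activation")
        ax.set_ylim(-0.02, 1.02)
        ax.set_xticks([r.run_index + 1 for r in self.runs])
        ax.set_title(self.model.name)
        ax.legend(loc="center right", fontsize="small")
        return ax


def compare_experiments(
    results_a: ExperimentResults,
    results_b: ExperimentResults,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Contrast two fitted experiments (e.g. with vs without auxiliary training).

    Reports the ratio of mean iteration counts, the difference in
    class-formation rates, and a bootstrap (two-proportion resampling)
    confidence interval for that difference.
    """
    if len(results_a.model.test_trials) != len(results_b.model.test_trials):
        raise ValueError("experiments must share the test-phase structure")
    rng = np.random.default_rng(seed)
    pa, pb = results_a.class_formation_rate, results_b.class_formation_rate
    na, nb = results_a.n_runs, results_b.n_runs
    boots = rng.binomial(na, pa, n_boot) / na - rng.binomial(nb, pb, n_boot) / nb
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "name_a": results_a.model.name,
        "name_b": results_b.model.name,
        "mean_iterations_a": results_a.mean_iterations,
        "mean_iterations_b": results_b.mean_iterations,
        "iteration_ratio_b_over_a": results_b.mean_iterations
        / results_a.mean_iterations,
        "formation_rate_a": pa,
        "formation_rate_b": pb,
        "formation_rate_difference_a_minus_b": pa - pb,
        "formation_rate_difference_ci95": (float(lo), float(hi)),
        "n_boot": n_boot,
    }
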