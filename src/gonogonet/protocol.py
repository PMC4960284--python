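"""Stimuli, layouts, trial tables and go/no-go response classification.

The go/no-go procedure with compound stimuli presents an unordered pair of
stimuli on every trial.  A *go* response is reinforced for compounds whose
elements belong to the same stimulus class and withheld (*no-go*) for
mixed-class compounds.  Here a compound is encoded as a binary input vector
over a fixed ordering of the stimuli (the layout): the two member positions
carry 1, every other position 0.  Because the pair is unordered, a relation
and its symmetric counterpart share one vector, which is why the procedure
supports transitivity tests but not symmetry tests.

Two experiments are built in:

* Experiment 1 — two three-member classes (A1,B1,C1 and A2,B2,C2) plus an
  auxiliary class (X,Y,Z) whose within-class compounds are trained alongside
  the baseline relations, emulating the pre-experimental history of a verbal
  human participant.  11 training compounds, 4 transitivity-test compounds.
* Experiment 2 — the same baseline without the auxiliary class: 8 training
  compounds, the same 4 test compounds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "StimulusLayout",
    "Compound",
    "Trial",
    "ResponseClassification",
    "GO_BAND",
    "NOGO_BAND",
    "encode_compound",
    "decode_vector",
    "classify",
    "build_experiment1",
    "build_experiment2",
    "build_layout",
    "trials_to_frame",
    "trials_to_csv",
    "trials_from_csv",
    "load_golden_table",
]

GO_BAND = (0.85, 1.00)
NOGO_BAND = (0.00, 0.15)

PHASES = ("additional_training", "training", "test")


@dataclass(frozen=True)
class Stimulus:
    """A named experimental stimulus and its class membership."""

    label: str
    class_id: str
    set_tag: str = "experimental"  # or "additional"


class StimulusLayout:
    """An ordered assignment of stimuli to input-layer positions.

    The ordering is part of the experimental design: stimuli are arranged so
    that no two adjacent input units refer to stimuli of the same class.
    """

    def __init__(self, stimuli: Sequence[Stimulus], enforce_adjacency: str = "error"):
        stimuli = tuple(stimuli)
        labels = [s.label for s in stimuli]
        if len(set(labels)) != len(labels):
            raise ValueError("stimulus labels must be unique within a layout")
        violations = [
            (a.label, b.label)
            for a, b in zip(stimuli, stimuli[1:])
            if a.class_id == b.class_id
        ]
        if violations:
            msg = f"adjacent same-class stimuli in layout: {violations}"
            if enforce_adjacency == "error":
                raise ValueError(msg)
            if enforce_adjacency == "warn":
                import warnings

                warnings.warn(msg, stacklevel=2)
            elif enforce_adjacency != "ignore":
                raise ValueError("enforce_adjacency must be error|warn|ignore")
        self.stimuli = stimuli
        self._index = {s.label: i for i, s in enumerate(stimuli)}

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.stimuli)

    def position(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"stimulus {label!r} is not in the layout {self.labels}"
            ) from None

    def stimulus(self, label: str) -> Stimulus:
        return self.stimuli[self.position(label)]

    def __repr__(self) -> str:
        return f"StimulusLayout({'|'.join(self.labels)})"


@dataclass(frozen=True)
class Compound:
    """An unordered pair of two distinct stimulus labels."""

    members: frozenset

    def __init__(self, a: str, b: str | None = None):
        if b is None and isinstance(a, (frozenset, set, tuple, list)):
            pair = frozenset(a)
        else:
            pair = frozenset((a, b))
        if len(pair) != 2:
            raise ValueError(f"a compound needs two distinct stimuli, got {pair}")
        object.__setattr__(self, "members", pair)

    @property
    def name(self) -> str:
        return "".join(sorted(self.members))

    def __repr__(self) -> str:
        return f"Compound({self.name})"


@dataclass(frozen=True)
class Trial:
    """One go/no-go trial: a compound, its phase, and its consequence.

    Training trials (phases ``additional_training`` and ``training``) carry a
    binary reinforcement target.  Test trials carry an expected activation
    band instead; the band is used only to score the frozen network, never
    for learning.
    """

    compound: Compound
    phase: str
    target: int | None = None
    expected_band: tuple | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.phase == "test":
            if self.expected_band is None or self.target is not None:
                raise ValueError("test trials carry a band, not a target")
        else:
            if self.target not in (0, 1) or self.expected_band is not None:
                raise ValueError("training trials carry a binary target, not a band")

    @property
    def is_training(self) -> bool:
        return self.phase != "test"


@dataclass(frozen=True)
class ResponseClassification:
    """Outcome of scoring one test activation against the response bands."""

    activation: float
    label: str  # go | no_go | inconsistent
    go_min: float = 0.85
    nogo_max: float = 0.15


def classify(
    activation: float, go_min: float = 0.85, nogo_max: float = 0.15
) -> ResponseClassification:
    """Map an output activation to go / no_go / inconsistent.

    Band edges are inclusive (activation >= go_min counts as go,
    <= nogo_max as no-go) so every value in [0, 1] receives exactly one
    label.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError(f"activation must lie in [0, 1], got {activation}")
    if not go_min > nogo_max:
        raise ValueError("go_min must exceed nogo_max")
    if activation >= go_min:
        label = "go"
    elif activation <= nogo_max:
        label = "no_go"
    else:
        label = "inconsistent"
    return ResponseClassification(float(activation), label, go_min, nogo_max)


def encode_compound(compound: Compound, layout: StimulusLayout) -> np.ndarray:
    """Binary input vector for a compound: 1 at each member position, else 0."""
    v = np.zeros(len(layout))
    for label in compound.members:
        v[layout.position(label)] = 1.0
    return v


def decode_vector(vector: np.ndarray, layout: StimulusLayout) -> Compound:
    """Inverse of :func:`encode_compound`."""
    vector = np.asarray(vector)
    if vector.shape != (len(layout),):
        raise ValueError("vector length does not match layout")
    on = np.flatnonzero(vector)
    if len(on) != 2:
        raise ValueError(f"a compound vector must have exactly two 1s, got {len(on)}")
    return Compound(layout.labels[on[0]], layout.labels[on[1]])


# ---------------------------------------------------------------------------
# Built-in experiments

def _class_of(label: str) -> str:
    return label[-1] if label[-1].isdigit() else "aux"


def _make_layout(order: Iterable[str], additional: frozenset = frozenset()) -> StimulusLayout:
    return StimulusLayout(
        [
            Stimulus(
                lab,
                _class_of(lab) if lab not in additional else "aux",
                "additional" if lab in additional else "experimental",
            )
            for lab in order
        ]
    )


_EXP1_ORDER = ("A1", "Z", "B2", "X", "C1", "Y", "C2", "B1", "A2")
_EXP2_ORDER = ("A1", "B2", "C1", "C2", "B1", "A2")
_AUX = frozenset({"X", "Y", "Z"})

# (compound, target) in table order; auxiliary-class rows first in Exp. 1
_EXP1_TRAIN = (
    (("X", "Y"), 1),
    (("Y", "Z"), 1),
    (("X", "Z"), 1),
    (("A1", "B1"), 1),
    (("A1", "B2"), 0),
    (("B1", "C1"), 1),
    (("B1", "C2"), 0),
    (("A2", "B2"), 1),
    (("A2", "B1"), 0),
    (("B2", "C2"), 1),
    (("B2", "C1"), 0),
)
_EXP2_TRAIN = (
    (("A1", "B1"), 1),
    (("A1", "B2"), 0),
    (("B1", "C1"), 1),
    (("B1", "C2"), 0),
    (("A2", "B2"), 1),
    (("A2", "B1"), 0),
    (("B2", "C2"), 1),
    (("B2", "C1"), 0),
)
_TEST = (
    (("A1", "C1"), GO_BAND),
    (("A1", "C2"), NOGO_BAND),
    (("A2", "C2"), GO_BAND),
    (("A2", "C1"), NOGO_BAND),
)


def _build(order, train, additional):
    layout = _make_layout(order, additional)
    trials = []
    for pair, target in train:
        phase = "additional_training" if set(pair) <= additional else "training"
        trials.append(Trial(Compound(*pair), phase, target=target))
    for pair, band in _TEST:
        trials.append(Trial(Compound(*pair), "test", expected_band=band))
    return layout, trials


def build_experiment1():
    """Layout and trial list of the condition with auxiliary-class training.

    Returns the 9-stimulus layout (A1 Z B2 X C1 Y C2 B1 A2), 11 training
    trials (XY, YZ, XZ and the AB/BC baseline) and 4 transitivity-test
    trials.
    """
    return _build(_EXP1_ORDER, _EXP1_TRAIN, _AUX)


def build_experiment2():
    """Layout and trial list of the condition without auxiliary-class training.

    Returns the 6-stimulus layout (A1 B2 C1 C2 B1 A2), 8 training trials and
    the same 4 transitivity-test trials.
    """
    return _build(_EXP2_ORDER, _EXP2_TRAIN, frozenset())


def build_layout(stimuli: Sequence[Stimulus]) -> StimulusLayout:
    """Arrange arbitrary stimuli so no two same-class stimuli are adjacent.

    Greedy interleaving: repeatedly place a stimulus from the largest
    remaining class whose class differs from the previously placed one.
    Raises if no such arrangement exists (one class holding more than half
    of all positions).
    """
    from collections import defaultdict

    pools: dict[str, list[Stimulus]] = defaultdict(list)
    for s in stimuli:
        pools[s.class_id].append(s)
    placed: list[Stimulus] = []
    total = sum(len(v) for v in pools.values())
    for _ in range(total):
        prev = placed[-1].class_id if placed else None
        candidates = sorted(
            (cid for cid, pool in pools.items() if pool and cid != prev),
            key=lambda cid: -len(pools[cid]),
        )
        if not candidates:
            raise ValueError(
                "no adjacency-respecting layout exists for these class sizes"
            )
        placed.append(pools[candidates[0]].pop())
    return StimulusLayout(placed)


# ---------------------------------------------------------------------------
# CSV import/export

def _band_str(band: tuple) -> str:
    return f"{band[0]:.2f}~{band[1]:.2f}"


def trials_to_frame(trials: Sequence[Trial], layout: StimulusLayout) -> pd.DataFrame:
    """Tabular view of a trial list, including the encoded bit vectors."""
    rows = []
    for t in trials:
        a, b = sorted(t.compound.members)
        vec = encode_compound(t.compound, layout)
        rows.append(
            {
                "phase": t.phase,
                "stimulus_a": a,
                "stimulus_b": b,
                "vector": "".join(str(int(v)) for v in vec),
                "target_or_band": str(t.target)
                if t.is_training
                else _band_str(t.expected_band),
            }
        )
    return pd.DataFrame(rows)


def trials_to_csv(trials: Sequence[Trial], layout: StimulusLayout, path) -> None:
    trials_to_frame(trials, layout).to_csv(path, index=False)


def trials_from_csv(path, layout: StimulusLayout | None = None):
    """Read a trial table written by :func:`trials_to_csv`.

    If no layout is given, one is constructed from the stimuli that appear
    in the file via :func:`build_layout`, with classes inferred from the
    trailing digit of each label (non-digit labels form one auxiliary
    class).
    """
    df = pd.read_csv(path, dtype=str)
    required = {"phase", "stimulus_a", "stimulus_b", "target_or_band"}
    if not required <= set(df.columns):
        raise ValueError(f"trial CSV must have columns {sorted(required)}")
    if layout is None:
        seen: dict[str, Stimulus] = {}
        for _, row in df.iterrows():
            for lab in (row.stimulus_a, row.stimulus_b):
                seen.setdefault(
                    lab,
                    Stimulus(
                        lab,
                        _class_of(lab),
                        "additional" if _class_of(lab) == "aux" else "experimental",
                    ),
                )
        layout = build_layout(list(seen.values()))
    trials = []
    for _, row in df.iterrows():
        comp = Compound(row.stimulus_a, row.stimulus_b)
        if row.phase == "test":
            lo, hi = (float(v) for v in row.target_or_band.split("~"))
            trials.append(Trial(comp, "test", expected_band=(lo, hi)))
        else:
            trials.append(Trial(comp, row.phase, target=int(row.target_or_band)))
    return layout, trials


def load_golden_table(experiment: str) -> pd.DataFrame:
    """Packaged reference trial tables (``"exp1"`` or ``"exp2"``)."""
    if experiment not in ("exp1", "exp2"):
        raise ValueError("experiment must be 'exp1' or 'exp2'")
    name = f"table_{experiment}.csv"
    text = resources.files("gonogonet.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), dtype=str)
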