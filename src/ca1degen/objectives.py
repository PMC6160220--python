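"""Optimization objectives and the absolute z-score cost.

An objective is one electrophysiological feature under one step amplitude
with an experimental mean ± sd.  An individual's score on an objective is the
absolute deviation of its model feature from the mean in units of the sd
(z = |value − mean| / sd); its total score is the plain sum over objectives.
An individual is *acceptable* when every objective scores strictly below 2 sd.
Undefined features (e.g. ISI statistics when the model does not spike) and
failed simulations receive a fixed penalty of 250 per objective — large
enough to dominate any feasible score while staying finite for rank-based
selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .efeatures import FeatureStatistics, FeatureValue, extract_features
from .simulator import IntegrationError, build_model, run_protocol
from .templates import EtypeTemplate, StimulusProtocol, load_template

__all__ = [
    "PENALTY_SCORE",
    "ACCEPTANCE_SD",
    "default_objective_keys",
    "Objective",
    "ObjectiveSet",
    "ScoreReport",
    "score_objective",
    "total_score",
    "ModelEvaluator",
    "evaluate_individual",
]

PENALTY_SCORE = 250.0
ACCEPTANCE_SD = 2.0  # strict: all z < 2


def default_objective_keys(amplitudes: list[float]) -> set[tuple[str, float]]:
    """The curated (feature, amplitude) pairs used as default optimization
    constraints: spike counts everywhere, subthreshold features on
    hyperpolarizing steps, firing-pattern features where they are robust
    (accommodation near rheobase, spike latency at strong drive)."""
    keys: set[tuple[str, float]] = set()
    for a in amplitudes:
        keys.add(("spike_count", a))
        if a < 0:
            keys |= {
                ("voltage_base", a),
                ("voltage_deflection", a),
                ("steady_state_voltage", a),
                ("input_resistance", a),
            }
        else:
            keys |= {("mean_ISI", a), ("AP_amplitude_mean", a)}
    pos = sorted(a for a in amplitudes if a > 0)
    if pos:
        keys.add(("adaptation_index", pos[0]))
        keys.add(("time_to_first_spike", pos[-1]))
    return keys


@dataclass(frozen=True)
class Objective:
    feature: str
    protocol_amplitude: float
    exp_mean: float
    exp_sd: float

    def __post_init__(self) -> None:
        if self.exp_sd <= 0:
            raise ValueError(f"{self.feature}: exp_sd must be > 0 (apply the sd floor)")

    @property
    def key(self) -> tuple[str, float]:
        return (self.feature, self.protocol_amplitude)


@dataclass
class ObjectiveSet:
    etype: str
    objectives: list[Objective]

    def __post_init__(self) -> None:
        if not self.objectives:
            raise ValueError("objective set must be non-empty")
        keys = [o.key for o in self.objectives]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (feature, amplitude) objectives")

    def __len__(self) -> int:
        return len(self.objectives)

    @property
    def amplitudes(self) -> list[float]:
        return sorted({o.protocol_amplitude for o in self.objectives})

    def features_at(self, amplitude: float) -> list[str]:
        return [o.feature for o in self.objectives if o.protocol_amplitude == amplitude]

    @classmethod
    def from_statistics(cls, etype: str, stats: FeatureStatistics) -> "ObjectiveSet":
        objs = [
            Objective(name, amp, mean, sd)
            for (name, amp), (mean, sd, _n) in sorted(stats.stats.items())
        ]
        return cls(etype, objs)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "etype": self.etype,
            "objectives": [
                {"feature": o.feature, "amplitude": o.protocol_amplitude,
                 "mean": o.exp_mean, "sd": o.exp_sd}
                for o in self.objectives
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ObjectiveSet":
        doc = json.loads(Path(path).read_text())
        return cls(
            doc["etype"],
            [Objective(o["feature"], o["amplitude"], o["mean"], o["sd"])
             for o in doc["objectives"]],
        )


@dataclass
class ScoreReport:
    """Per-objective absolute z-scores for one individual."""

    scores: dict[tuple[str, float], float]
    values: dict[tuple[str, float], float | None] = field(default_factory=dict)
    failed: bool = False  # simulation diverged / could not be evaluated

    @property
    def total(self) -> float:
        return float(sum(self.scores.values()))

    @property
    def acceptable(self) -> bool:
        return all(z < ACCEPTANCE_SD for z in self.scores.values())

    def z_vector(self, objset: ObjectiveSet) -> np.ndarray:
        return np.array([self.scores[o.key] for o in objset.objectives])


def score_objective(value: FeatureValue | float | None, obj: Objective) -> float:
    """z = |value − mean| / sd; undefined values take the fixed penalty."""
    if isinstance(value, FeatureValue):
        value = value.value if value.defined else None
    if value is None:
        return PENALTY_SCORE
    return abs(float(value) - obj.exp_mean) / obj.exp_sd


def total_score(values: dict[tuple[str, float], float | None] | list[FeatureValue],
                objset: ObjectiveSet) -> ScoreReport:
    """Score a full set of feature values against an objective set.

    ``values`` maps (feature, amplitude) to a value or None; a missing key is
    a contract error (use None for an undefined feature).
    """
    if isinstance(values, list):
        values = {(fv.name, fv.protocol_amplitude): (fv.value if fv.defined else None)
                  for fv in values}
    scores = {}
    for o in objset.objectives:
        if o.key not in values:
            raise KeyError(f"missing value for objective {o.key}")
        scores[o.key] = score_objective(values[o.key], o)
    return ScoreReport(scores=scores, values=dict(values))


class ModelEvaluator:
    """Builds, simulates and scores models of one e-type against an
    objective set (the fitness function handed to the optimizer).

    Evaluation is deterministic: identical parameters yield an identical
    report.  Integration failures are absorbed into an all-penalty report so
    an evolution never crashes on a pathological parameter vector.
    """

    def __init__(
        self,
        template: str | EtypeTemplate,
        objectives: ObjectiveSet,
        morphology=None,
        dt: float = 0.025,
        settle: float = 200.0,
    ):
        self.template = load_template(template) if isinstance(template, str) else template
        self.objectives = objectives
        self.mesh = self.template.make_mesh(morphology)
        self.dt = dt
        self.settle = settle
        base = self.template.protocol
        self.protocol = StimulusProtocol(
            amplitudes=objectives.amplitudes,
            delay=base.delay, duration=base.duration, post=base.post,
        )

    def penalty_report(self) -> ScoreReport:
        return ScoreReport(
            scores={o.key: PENALTY_SCORE for o in self.objectives.objectives},
            values={o.key: None for o in self.objectives.objectives},
            failed=True,
        )

    def evaluate(self, params: dict[str, float]) -> ScoreReport:
        try:
            model = build_model(self.mesh, self.template, params)
            traces = run_protocol(model, self.protocol, dt=self.dt, settle=self.settle)
        except IntegrationError:
            return self.penalty_report()
        values: dict[tuple[str, float], float | None] = {}
        for trace in traces:
            feats = self.objectives.features_at(trace.protocol_amplitude)
            if not feats:
                continue
            for fv in extract_features(trace, feats):
                values[(fv.name, fv.protocol_amplitude)] = (
                    fv.value if fv.defined else None
                )
        return total_score(values, self.objectives)

    __call__ = evaluate


def evaluate_individual(
    params: dict[str, float],
    context: ModelEvaluator,
    objset: ObjectiveSet | None = None,
) -> ScoreReport:
    """Convenience wrapper: build → simulate → extract → score one parameter
    vector with a pre-built :class:`ModelEvaluator` context."""
    if objset is not None and objset is not context.objectives:
        context = ModelEvaluator(context.template, objset, dt=context.dt,
                                 settle=context.settle)
    return context.evaluate(params)
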