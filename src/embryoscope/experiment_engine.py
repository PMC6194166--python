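"""Protocol engine: trials, blocks, phases, scrambling, session logs.

Implements the four-experiment protocol around a tuned category pair:

1. pre-training test (2 blocks, no feedback) -> feedback training to
   criterion (three consecutive 40-trial blocks at d' >= 1.68) ->
   post-training test;
2. server runs: trained experts decide and produce an explanation plus a
   self-rating on each trial;
3. client runs: decisions and/or explanations from a server trial are shown
   to a client together with the *same* stimuli, under a perceived-source
   label (expert/naive), and the client decides and rates;
4. scrambling controls: 4A permutes the server's decisions across trials
   (explanations and stimuli untouched); 4B additionally swaps the two
   sample-stimulus labels on a random half of trials, destroying the cue the
   explanations point to.

All randomness is drawn from per-trial streams derived from
(master seed, subject id, trial id), so logs are reproducible regardless of
the order in which subjects are simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from numpy.random import Generator, default_rng

from . import sdt_analysis
from .observer_models import (
    ClientParams,
    ExplanationRecord,
    PrototypeLearner,
    RatingRecord,
    SerParams,
    client_decide,
    client_rate,
    generate_explanation,
)
from .shape_space import CategoryPair, ShapeSpace

PHASES = ("pre_test", "training", "post_test", "explain", "client_eval")


class UntrainedServerError(RuntimeError):
    """Server operations require a subject trained to criterion."""


def trial_rng(master_seed: int, subject_id: str, trial_id: int) -> Generator:
    """Per-trial stream derived from (master seed, subject, trial)."""
    return default_rng(
        [master_seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode()), trial_id]
    )


# --------------------------------------------------------------------------- #
# trials and logs

@dataclass(frozen=True)
class Trial:
    """One query-plus-two-samples screen, in PC-loading coordinates."""

    trial_id: int
    query: np.ndarray        # (2,)
    true_label: str
    sample_p: np.ndarray     # (2,)
    sample_q: np.ndarray     # (2,)
    side_of_p: str           # "left" | "right"
    feedback_enabled: bool
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.side_of_p not in ("left", "right"):
            raise ValueError("side_of_p must be 'left' or 'right'")
        for name in ("query", "sample_p", "sample_q"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(2)
            )


@dataclass(frozen=True)
class TrialRecord:
    """A Trial plus the subject's response, as logged."""

    trial_id: int
    block: int
    phase: str
    query_x: float
    query_y: float
    true_label: str
    sample_p_x: float
    sample_p_y: float
    sample_q_x: float
    sample_q_y: float
    side_of_p: str
    feedback_enabled: bool
    response: str
    correct: bool


@dataclass
class SessionLog:
    """Ordered trial records for one subject in one phase/condition."""

    subject_id: str
    role: str                      # "server" | "client"
    block_size: int = 40
    condition: dict = field(default_factory=dict)
    records: list[TrialRecord] = field(default_factory=list)
    criterion_block: Optional[int] = None
    converged: Optional[bool] = None

    def block_dprimes(self, correction: str = "log_linear") -> list[float]:
        """d' of each completed block, in order."""
        out = []
        n_full = len(self.records) // self.block_size
        for b in range(n_full):
            chunk = self.records[b * self.block_size : (b + 1) * self.block_size]
            tally = sdt_analysis.tally_sdt(chunk, correction=correction)
            out.append(sdt_analysis.compute_dprime(tally))
        return out

    def accuracy(self) -> float:
        return float(np.mean([r.correct for r in self.records]))

    def validate(self) -> None:
        """Block contiguity/size and response-consistency invariants."""
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        for i, rec in enumerate(self.records):
            expected_block = i // self.block_size + 1
            if rec.block != expected_block:
                raise ValueError(
                    f"record {i}: block {rec.block}, expected {expected_block}"
                )
            if rec.response not in ("P", "Q"):
                raise ValueError(f"record {i}: bad response {rec.response!r}")
            if rec.correct != (rec.response == rec.true_label):
                raise ValueError(f"record {i}: correct flag inconsistent")


def _record(trial: Trial, block: int, response: str) -> TrialRecord:
    return TrialRecord(
        trial_id=trial.trial_id,
        block=block,
        phase=trial.phase,
        query_x=float(trial.query[0]),
        query_y=float(trial.query[1]),
        true_label=trial.true_label,
        sample_p_x=float(trial.sample_p[0]),
        sample_p_y=float(trial.sample_p[1]),
        sample_q_x=float(trial.sample_q[0]),
        sample_q_y=float(trial.sample_q[1]),
        side_of_p=trial.side_of_p,
        feedback_enabled=trial.feedback_enabled,
        response=response,
        correct=response == trial.true_label,
    )


def build_trial(
    pair: CategoryPair,
    space: Optional[ShapeSpace],
    phase: str,
    seed: int | Generator,
    trial_id: int = 0,
) -> Trial:
    """Draw one trial: random query category and side, fresh category samples.

    The query category and the left/right placement of the P sample are both
    fair Bernoulli draws; feedback is enabled only during training.  ``space``
    is accepted for axis validation but trials live in loading coordinates.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    if space is not None:
        for axis in pair.axes:
            if not 1 <= axis <= space.n_components:
                raise ValueError(f"axis {axis} not present in shape space")
    true_label = pair.labels[int(rng.random() < 0.5)]
    query = rng.multivariate_normal(
        pair.spec(true_label).mean, pair.spec(true_label).covariance, method="svd"
    )
    sample_p = rng.multivariate_normal(
        pair.spec_p.mean, pair.spec_p.covariance, method="svd"
    )
    sample_q = rng.multivariate_normal(
        pair.spec_q.mean, pair.spec_q.covariance, method="svd"
    )
    side_of_p = "left" if rng.random() < 0.5 else "right"
    return Trial(
        trial_id=trial_id,
        query=query,
        true_label=true_label,
        sample_p=sample_p,
        sample_q=sample_q,
        side_of_p=side_of_p,
        feedback_enabled=phase == "training",
        phase=phase,
    )


# --------------------------------------------------------------------------- #
# criterion rule and phases

def reached_criterion(
    block_dprimes: Sequence[float],
    threshold: float = 1.68,
    run_length: int = 3,
) -> Optional[int]:
    """1-based index of the block completing the first run of ``run_length``
    consecutive blocks with d' >= threshold, or None.

    The boundary counts: d' exactly at the threshold qualifies.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    run = 0
    for i, dp in enumerate(block_dprimes):
        run = run + 1 if dp >= threshold else 0
        if run >= run_length:
            return i + 1
    return None


@dataclass(frozen=True)
class FixedBlocks:
    """Stop rule: run exactly n_blocks blocks."""

    n_blocks: int


@dataclass(frozen=True)
class CriterionRule:
    """Stop rule: halt at the block completing the criterion run.

    ``continue_blocks`` optionally keeps training that many blocks past
    criterion.  If criterion is not reached within ``max_blocks``, the phase
    ends with an explicit non-convergence flag on the log (no exception).
    """

    threshold: float = 1.68
    run_length: int = 3
    max_blocks: int = 60
    continue_blocks: int = 0


StopRule = Union[FixedBlocks, CriterionRule]


def run_phase(
    pair: CategoryPair,
    space: Optional[ShapeSpace],
    subject: PrototypeLearner,
    phase: str,
    stop_rule: StopRule,
    seed: int,
    block_size: int = 40,
    trial_id_start: int = 0,
) -> SessionLog:
    """Execute one phase block by block and return the session log.

    Training trials feed the subject's learner; test-phase trials do not.
    Under a CriterionRule the subject's ``trained`` flag is set on success.
    """
    log = SessionLog(
        subject_id=subject.subject_id,
        role="server",
        block_size=block_size,
        condition={"phase": phase, "seed": seed},
    )
    if isinstance(stop_rule, FixedBlocks):
        max_blocks = stop_rule.n_blocks
    else:
        max_blocks = stop_rule.max_blocks
    trial_id = trial_id_start
    dprimes: list[float] = []
    extra_remaining: Optional[int] = None
    for block in range(1, max_blocks + 1):
        for _ in range(block_size):
            rng = trial_rng(seed, subject.subject_id, trial_id)
            trial = build_trial(pair, space, phase, rng, trial_id=trial_id)
            response = subject.decide(trial.query, rng)
            log.records.append(_record(trial, block, response))
            if trial.feedback_enabled:
                subject.learn(trial.query, trial.true_label)
            trial_id += 1
        tally = sdt_analysis.tally_sdt(
            log.records[-block_size:], correction="log_linear"
        )
        dprimes.append(sdt_analysis.compute_dprime(tally))
        if isinstance(stop_rule, CriterionRule):
            if extra_remaining is not None:
                extra_remaining -= 1
                if extra_remaining <= 0:
                    break
                continue
            hit = reached_criterion(
                dprimes, stop_rule.threshold, stop_rule.run_length
            )
            if hit is not None:
                log.criterion_block = hit
                log.converged = True
                subject.trained = True
                if stop_rule.continue_blocks > 0:
                    extra_remaining = stop_rule.continue_blocks
                    continue
                break
    if isinstance(stop_rule, CriterionRule) and log.criterion_block is None:
        log.converged = False
    return log


# --------------------------------------------------------------------------- #
# server datasets and scrambling

@dataclass
class ServerDataset:
    """Per-trial stimuli paired with a server's decision and explanation.

    Under ``scramble_mode='none'`` each decision/explanation pair comes from
    the same original trial; scrambling permutes the decisions (4A) and
    additionally flips the sample labels on a random half of trials (4B).
    The multisets of decisions and explanations are always preserved.
    """

    server_id: str
    trials: list[Trial]
    decisions: list[str]
    explanations: list[ExplanationRecord]
    scramble_mode: str = "none"                 # "none" | "4A" | "4B"
    label_flipped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.scramble_mode not in ("none", "4A", "4B"):
            raise ValueError("scramble_mode must be 'none', '4A' or '4B'")
        if len(self.label_flipped) == 0:
            self.label_flipped = np.zeros(len(self.trials), dtype=bool)
        if not (
            len(self.trials) == len(self.decisions) == len(self.explanations)
            == len(self.label_flipped)
        ):
            raise ValueError("dataset columns must have equal lengths")

    def __len__(self) -> int:
        return len(self.trials)


def collect_server_dataset(
    pair: CategoryPair,
    space: Optional[ShapeSpace],
    server: PrototypeLearner,
    n_trials: int,
    seed: int,
    locality_mix: float = 0.5,
    validity_by_locality=None,
    ser_params: SerParams = SerParams(),
) -> ServerDataset:
    """Run a trained server through explanation trials (no feedback).

    Each trial yields the server's decision, a templated explanation with
    latent cue validity, and the SER_S self-rating.  Untrained servers are
    refused: only criterion-trained experts serve.
    """
    if not server.trained:
        raise UntrainedServerError(
            f"server {server.subject_id!r} has not reached the training criterion"
        )
    trials, decisions, explanations = [], [], []
    for trial_id in range(n_trials):
        rng = trial_rng(seed, server.subject_id, trial_id)
        trial = build_trial(pair, space, "explain", rng, trial_id=trial_id)
        decision = server.decide(trial.query, rng)
        explanation = generate_explanation(
            server.state,
            trial_id=trial_id,
            decision=decision,
            server_id=server.subject_id,
            locality_mix=locality_mix,
            validity_by_locality=validity_by_locality,
            ser_params=ser_params,
            seed=rng,
        )
        trials.append(trial)
        decisions.append(decision)
        explanations.append(explanation)
    return ServerDataset(server.subject_id, trials, decisions, explanations)


def scramble_server_dataset(
    data: ServerDataset,
    mode: str,
    seed: int,
    variant: str = "sample_labels",
) -> ServerDataset:
    """Apply the 4A/4B reliability manipulations to an unscrambled dataset.

    4A permutes decisions uniformly at random across trials, leaving
    explanations and stimuli in place.  4B additionally destroys the mapping
    between the explanations' cue and the correct category: with the default
    ``variant='sample_labels'`` each trial's two sample labels are swapped
    with probability 1/2; ``variant='query_labels'`` instead permutes the
    displayed query labels across trials (flipping trials where the permuted
    label disagrees).  Multisets are preserved; deterministic per seed.
    """
    if data.scramble_mode != "none":
        raise ValueError("dataset is already scrambled")
    if mode not in ("4A", "4B"):
        raise ValueError("mode must be '4A' or '4B'")
    rng = default_rng(seed)
    perm = rng.permutation(len(data))
    decisions = [data.decisions[i] for i in perm]
    flipped = np.zeros(len(data), dtype=bool)
    if mode == "4B":
        if variant == "sample_labels":
            flipped = rng.random(len(data)) < 0.5
        elif variant == "query_labels":
            perm2 = rng.permutation(len(data))
            labels = [t.true_label for t in data.trials]
            flipped = np.array(
                [labels[perm2[i]] != labels[i] for i in range(len(data))]
            )
        else:
            raise ValueError("variant must be 'sample_labels' or 'query_labels'")
    return ServerDataset(
        server_id=data.server_id,
        trials=list(data.trials),
        decisions=decisions,
        explanations=list(data.explanations),
        scramble_mode=mode,
        label_flipped=flipped,
    )


# --------------------------------------------------------------------------- #
# client experiments

def run_client_experiment(
    data: ServerDataset,
    client: ClientParams,
    provided: tuple[bool, bool],
    perceived_source: str,
    seed: int,
    client_id: str = "C0",
    block_size: int = 40,
) -> tuple[SessionLog, list[RatingRecord]]:
    """Run a client over a server dataset in original trial order.

    ``provided`` is (decisions, explanations).  On each trial the client
    decides via its fall-through policy and, when an explanation is shown,
    rates it (OUR/OER) under the perceived-source label.  The log carries the
    full condition metadata.
    """
    provide_decisions, provide_explanations = provided
    log = SessionLog(
        subject_id=client_id,
        role="client",
        block_size=block_size,
        condition={
            "server_id": data.server_id,
            "provided_decisions": provide_decisions,
            "provided_explanations": provide_explanations,
            "perceived_source": perceived_source,
            "scramble_mode": data.scramble_mode,
            "seed": seed,
        },
    )
    ratings: list[RatingRecord] = []
    for i, trial in enumerate(data.trials):
        rng = trial_rng(seed, client_id, trial.trial_id)
        decision = data.decisions[i] if provide_decisions else None
        explanation = data.explanations[i] if provide_explanations else None
        response = client_decide(
            client,
            trial,
            decision,
            explanation,
            perceived_source,
            rng,
            cue_flip=bool(data.label_flipped[i]),
        )
        block = i // block_size + 1
        log.records.append(
            _record(replace(trial, phase="client_eval"), block, response)
        )
        if explanation is not None:
            ratings.append(
                client_rate(
                    client,
                    explanation,
                    perceived_source,
                    rng,
                    trial_id=trial.trial_id,
                    client_id=client_id,
                )
            )
    return log, ratings
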