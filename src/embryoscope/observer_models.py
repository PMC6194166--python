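"""Simulated observers: servers who learn and explain, clients who consume.

The human studies being modelled report behaviour only; no computational
observer is specified there.  The agents here are therefore explicit
stand-ins, parameterised so that the simulated experiments reproduce the
qualitative result patterns:

* an *ideal observer* that knows both category Gaussians (difficulty
  calibration reference; its Monte-Carlo d' equals the Mahalanobis distance
  between the category means),
* an *exemplar observer* that only compares the query to the two labelled
  samples on screen (the actual trial format),
* a *prototype learner* whose category-centre beliefs drift toward labelled
  feedback examples (weakly guided learning: labels, no instruction),
* explanation generation with a latent scalar *cue validity* per locality
  class (spatially local cues are more valid than global ones), and a server
  self-rating (SER_S) whose mean is independent of validity — servers rate
  their explanations well regardless of how useful they are,
* client decision and rating policies, including the conformity bias: the
  same server data are weighted and rated higher when attributed to an
  expert source.

Every stochastic operation takes an explicit seed or numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import numpy as np
from numpy.random import Generator, default_rng
from scipy.stats import truncnorm

from .shape_space import CategoryPair

__all__ = [
    "ObserverState",
    "ExplanationRecord",
    "ClientParams",
    "RatingRecord",
    "SerParams",
    "PrototypeLearner",
    "ideal_observer_decide",
    "exemplar_observer_decide",
    "prototype_decide",
    "learner_update",
    "simulate_learning_curve",
    "generate_explanation",
    "client_decide",
    "client_rate",
    "load_template_bank",
    "DEFAULT_VALIDITY_BY_LOCALITY",
]

#: Default cue validity per locality class: local explanations point to the
#: correct category far more reliably than global ones.
DEFAULT_VALIDITY_BY_LOCALITY: dict[str, float] = {"local": 0.85, "global": 0.55}

_REGIONS = (
    "neck",
    "right side of the neck",
    "tail",
    "nerve tail",
    "upper ridge",
    "left lobe",
    "top right groove",
)


def _as_rng(seed: int | Generator) -> Generator:
    return seed if isinstance(seed, Generator) else default_rng(seed)


# --------------------------------------------------------------------------- #
# state and record types

@dataclass(frozen=True)
class ObserverState:
    """Current category-centre beliefs of a prototype observer.

    ``perceptual_noise_sd`` is isotropic Gaussian noise (in PC-loading units)
    added to perceived positions; ``learning_rate`` is the fraction of the
    prototype-to-example distance moved on each feedback trial.
    """

    prototype_p: np.ndarray
    prototype_q: np.ndarray
    perceptual_noise_sd: float = 0.3
    learning_rate: float = 0.08
    n_updates: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1]")
        if self.perceptual_noise_sd < 0:
            raise ValueError("perceptual_noise_sd must be >= 0")
        object.__setattr__(
            self, "prototype_p", np.asarray(self.prototype_p, dtype=float).reshape(2)
        )
        object.__setattr__(
            self, "prototype_q", np.asarray(self.prototype_q, dtype=float).reshape(2)
        )

    @classmethod
    def untrained(
        cls, perceptual_noise_sd: float = 0.3, learning_rate: float = 0.08
    ) -> "ObserverState":
        """Both prototypes at the origin: decisions start at chance."""
        return cls(np.zeros(2), np.zeros(2), perceptual_noise_sd, learning_rate)


@dataclass(frozen=True)
class ExplanationRecord:
    """A server's written explanation plus its latent usefulness.

    ``cue_validity`` is the probability that following the explanation alone
    yields the correct category; ``ser_s`` is the server's 0-100 self-rating
    of how well the explanation accounts for the decision.
    """

    trial_id: int
    server_id: str
    text: str
    locality: str           # "local" | "global"
    cue_validity: float
    ser_s: float

    def __post_init__(self) -> None:
        if self.locality not in ("local", "global"):
            raise ValueError("locality must be 'local' or 'global'")
        if not 0.5 <= self.cue_validity <= 1.0:
            raise ValueError("cue_validity must be in [0.5, 1]")
        if not 0.0 <= self.ser_s <= 100.0:
            raise ValueError("ser_s must be in [0, 100]")
        if not self.text:
            raise ValueError("explanation text must be nonempty")


@dataclass(frozen=True)
class ClientParams:
    """Decision/rating strategy of a client consuming server data.

    ``compliance_weight`` is the propensity to copy a provided decision,
    ``explanation_weight`` the propensity to follow a provided explanation
    cue, both only when the source is perceived as expert; server inputs from
    a perceived-naive source are ignored entirely.  ``conformity_bias`` is
    the rating inflation (0-100 points) applied when the source is labelled
    expert.  ``own_noise_sd`` governs the client's own exemplar comparison:
    the naive default is large enough that unaided performance sits at
    chance; ``own_state`` (a trained prototype observer) marks an expert
    client.
    """

    expertise: str = "naive"            # "naive" | "expert"
    compliance_weight: float = 0.6
    explanation_weight: float = 0.8
    conformity_bias: float = 15.0
    rating_noise_sd: float = 10.0
    own_noise_sd: float = 25.0
    own_state: Optional[ObserverState] = None

    def __post_init__(self) -> None:
        if self.expertise not in ("naive", "expert"):
            raise ValueError("expertise must be 'naive' or 'expert'")
        for name in ("compliance_weight", "explanation_weight"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.conformity_bias < 0:
            raise ValueError("conformity_bias must be >= 0")
        if self.rating_noise_sd < 0 or self.own_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class RatingRecord:
    """A client's 0-100 ratings of one explanation.

    ``our`` rates semantic understandability, ``oer`` rates how well the
    explanation accounts for the decision; the two are deliberately distinct
    quantities.
    """

    trial_id: int
    client_id: str
    our: float
    oer: float
    perceived_source: str   # "expert" | "naive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.our <= 100.0 and 0.0 <= self.oer <= 100.0):
            raise ValueError("ratings must be in [0, 100]")
        if self.perceived_source not in ("expert", "naive"):
            raise ValueError("perceived_source must be 'expert' or 'naive'")


@dataclass(frozen=True)
class SerParams:
    """Truncated-Gaussian parameters for the server self-rating SER_S.

    The mean deliberately does not depend on cue validity: self-assessed
    explanation quality is uninformative about actual efficacy.
    """

    mean: float = 85.0
    sd: float = 12.0


# --------------------------------------------------------------------------- #
# decision rules

def _tie_break(rng: Generator, labels: tuple[str, str]) -> str:
    return labels[int(rng.random() < 0.5)]


def ideal_observer_decide(
    query: np.ndarray,
    pair: CategoryPair,
    noise_sd: float,
    seed: int | Generator,
) -> str:
    """Maximum-likelihood category of a noisy query under the two Gaussians.

    Isotropic Gaussian noise of ``noise_sd`` is added to the query before the
    likelihoods are compared; exact ties are broken uniformly at random.
    """
    rng = _as_rng(seed)
    x = np.asarray(query, dtype=float).reshape(2)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=2)
    ll = []
    for spec in (pair.spec_p, pair.spec_q):
        d = x - spec.mean
        cov = spec.covariance
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError("category covariance must be positive-definite here")
        ll.append(-0.5 * (d @ np.linalg.solve(cov, d)) - 0.5 * logdet)
    if abs(ll[0] - ll[1]) < 1e-12:
        return _tie_break(rng, pair.labels)
    return pair.labels[0] if ll[0] > ll[1] else pair.labels[1]


def exemplar_observer_decide(
    query: np.ndarray,
    sample_p: np.ndarray,
    sample_q: np.ndarray,
    noise_sd: float,
    seed: int | Generator,
    labels: tuple[str, str] = ("P", "Q"),
) -> str:
    """Nearest-labelled-sample decision after independent perceptual noise.

    Mirrors the on-screen task: one sample per category, pick whichever the
    query looks closer to.  Noise is added independently to all three points.
    """
    rng = _as_rng(seed)
    pts = [np.asarray(p, dtype=float).reshape(2) for p in (query, sample_p, sample_q)]
    if noise_sd > 0:
        pts = [p + rng.normal(0.0, noise_sd, size=2) for p in pts]
    d_p = np.linalg.norm(pts[0] - pts[1])
    d_q = np.linalg.norm(pts[0] - pts[2])
    if abs(d_p - d_q) < 1e-12:
        return _tie_break(rng, labels)
    return labels[0] if d_p < d_q else labels[1]


def prototype_decide(
    state: ObserverState,
    query: np.ndarray,
    seed: int | Generator,
    labels: tuple[str, str] = ("P", "Q"),
) -> str:
    """Nearest-prototype decision with the observer's perceptual noise."""
    rng = _as_rng(seed)
    x = np.asarray(query, dtype=float).reshape(2)
    if state.perceptual_noise_sd > 0:
        x = x + rng.normal(0.0, state.perceptual_noise_sd, size=2)
    d_p = np.linalg.norm(x - state.prototype_p)
    d_q = np.linalg.norm(x - state.prototype_q)
    if abs(d_p - d_q) < 1e-12:
        return _tie_break(rng, labels)
    return labels[0] if d_p < d_q else labels[1]


def learner_update(
    state: ObserverState, query: np.ndarray, true_label: str
) -> ObserverState:
    """Move the prototype of the fed-back category toward the example.

    Delta-rule update: prototype += learning_rate * (query - prototype); the
    other prototype is unchanged; the update counter increments.
    """
    x = np.asarray(query, dtype=float).reshape(2)
    lr = state.learning_rate
    if true_label == "P":
        new_p = state.prototype_p + lr * (x - state.prototype_p)
        return replace(state, prototype_p=new_p, n_updates=state.n_updates + 1)
    if true_label == "Q":
        new_q = state.prototype_q + lr * (x - state.prototype_q)
        return replace(state, prototype_q=new_q, n_updates=state.n_updates + 1)
    raise ValueError(f"unknown label {true_label!r}")


class PrototypeLearner:
    """Stateful wrapper pairing an ObserverState with the trial interface.

    ``trained`` is set by the protocol engine once the training criterion is
    reached; server-only operations refuse untrained subjects.
    """

    def __init__(self, state: ObserverState | None = None, subject_id: str = "S0"):
        self.state = state if state is not None else ObserverState.untrained()
        self.subject_id = subject_id
        self.trained = False

    def decide(self, query: np.ndarray, rng: Generator) -> str:
        return prototype_decide(self.state, query, rng)

    def learn(self, query: np.ndarray, true_label: str) -> None:
        self.state = learner_update(self.state, query, true_label)


def simulate_learning_curve(
    pair: CategoryPair,
    state0: ObserverState,
    n_blocks: int,
    block_size: int = 40,
    seed: int | Generator = 0,
) -> tuple[np.ndarray, ObserverState]:
    """Feedback training by blocks; returns (per-block d' series, final state).

    Each trial draws a query from a random category, the observer decides by
    nearest prototype, and the true label drives a prototype update.  Block
    d' uses the log-linear correction so perfect blocks stay finite.
    """
    from . import sdt_analysis

    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = _as_rng(seed)
    state = state0
    dprimes = np.empty(n_blocks)
    for b in range(n_blocks):
        records = []
        for _ in range(block_size):
            label = pair.labels[int(rng.random() < 0.5)]
            query = rng.multivariate_normal(
                pair.spec(label).mean, pair.spec(label).covariance, method="svd"
            )
            response = prototype_decide(state, query, rng)
            records.append((response, label))
            state = learner_update(state, query, label)
        tally = sdt_analysis.tally_sdt(records, positive_category=pair.labels[0])
        dprimes[b] = sdt_analysis.compute_dprime(tally, correction="log_linear")
    return dprimes, state


# --------------------------------------------------------------------------- #
# explanations and ratings

def load_template_bank() -> dict[str, list[str]]:
    """Read the packaged plain-text template bank, keyed by locality."""
    text = (
        resources.files("embryoscope.data")
        .joinpath("explanation_templates.txt")
        .read_text(encoding="utf-8")
    )
    bank: dict[str, list[str]] = {"local": [], "global": []}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        locality, template = line.split("\t", 1)
        bank[locality].append(template)
    return bank


_TEMPLATE_BANK: dict[str, list[str]] | None = None


def _template_bank() -> dict[str, list[str]]:
    global _TEMPLATE_BANK
    if _TEMPLATE_BANK is None:
        _TEMPLATE_BANK = load_template_bank()
    return _TEMPLATE_BANK


def generate_explanation(
    server_state: ObserverState,
    trial_id: int,
    decision: str,
    server_id: str = "S0",
    locality_mix: float = 0.5,
    validity_by_locality: Mapping[str, float] | None = None,
    ser_params: SerParams = SerParams(),
    seed: int | Generator = 0,
) -> ExplanationRecord:
    """Draw a templated explanation with latent cue validity and SER_S.

    Locality ~ Bernoulli(``locality_mix`` for local); cue validity is the
    fixed value for that locality class; the text is rendered from the
    plain-text template bank; SER_S is a truncated Gaussian on [0, 100] whose
    mean is independent of cue validity (the self-rating carries no
    information about efficacy).
    """
    if not 0.0 <= locality_mix <= 1.0:
        raise ValueError("locality_mix must be a probability")
    validity = dict(
        validity_by_locality
        if validity_by_locality is not None
        else DEFAULT_VALIDITY_BY_LOCALITY
    )
    for v in validity.values():
        if not 0.5 <= v <= 1.0:
            raise ValueError("cue validities must be in [0.5, 1]")
    rng = _as_rng(seed)
    locality = "local" if rng.random() < locality_mix else "global"
    bank = _template_bank()[locality]
    template = bank[rng.integers(len(bank))]
    other = "Q" if decision == "P" else "P"
    text = template.format(
        cat=decision, other=other, region=_REGIONS[rng.integers(len(_REGIONS))]
    )
    a = (0.0 - ser_params.mean) / ser_params.sd
    b = (100.0 - ser_params.mean) / ser_params.sd
    ser_s = float(
        truncnorm.ppf(rng.random(), a, b, loc=ser_params.mean, scale=ser_params.sd)
    )
    return ExplanationRecord(
        trial_id=trial_id,
        server_id=server_id,
        text=text,
        locality=locality,
        cue_validity=validity[locality],
        ser_s=ser_s,
    )


# --------------------------------------------------------------------------- #
# client policies

def client_decide(
    params: ClientParams,
    trial,
    server_decision: Optional[str],
    explanation: Optional[ExplanationRecord],
    perceived_source: str,
    seed: int | Generator,
    cue_flip: bool = False,
) -> str:
    """Fall-through client policy over server decision, explanation, self.

    (i) a provided decision from a perceived-expert source is copied with
    probability ``compliance_weight``; (ii) otherwise a provided explanation
    from a perceived-expert source is followed with probability
    ``explanation_weight`` (its cue points to the correct category with
    probability ``cue_validity``, inverted when ``cue_flip`` marks scrambled
    sample labels); (iii) otherwise the client decides by its own observer
    model.  Server inputs attributed to a naive source are ignored entirely.
    """
    rng = _as_rng(seed)
    if perceived_source == "expert":
        if server_decision is not None and rng.random() < params.compliance_weight:
            return server_decision
        if explanation is not None and rng.random() < params.explanation_weight:
            validity = explanation.cue_validity
            if cue_flip:
                validity = 1.0 - validity
            other = "Q" if trial.true_label == "P" else "P"
            return trial.true_label if rng.random() < validity else other
    if params.own_state is not None:
        return prototype_decide(params.own_state, trial.query, rng)
    return exemplar_observer_decide(
        trial.query, trial.sample_p, trial.sample_q, params.own_noise_sd, rng
    )


def _base_oer(params: ClientParams, cue_validity: float) -> float:
    # Naive clients cannot judge efficacy: flat base. Expert clients' judged
    # explainability tracks the latent validity (training effect on OER).
    if params.expertise == "expert":
        return 10.0 + 160.0 * (cue_validity - 0.5)
    return 40.0


def client_rate(
    params: ClientParams,
    explanation: ExplanationRecord,
    perceived_source: str,
    seed: int | Generator,
    trial_id: int | None = None,
    client_id: str = "C0",
) -> RatingRecord:
    """Understandability (OUR) and explainability (OER) ratings, 0-100.

    Both ratings gain ``conformity_bias`` points when the source is labelled
    expert, then Gaussian noise, then clipping to [0, 100].  OUR has a flat
    (high) base: the text is understandable regardless of usefulness.  OER's
    base depends on cue validity only for expert clients.
    """
    rng = _as_rng(seed)
    bias = params.conformity_bias if perceived_source == "expert" else 0.0
    base_our = 70.0
    our = base_our + bias + rng.normal(0.0, params.rating_noise_sd)
    oer = (
        _base_oer(params, explanation.cue_validity)
        + bias
        + rng.normal(0.0, params.rating_noise_sd)
    )
    return RatingRecord(
        trial_id=explanation.trial_id if trial_id is None else trial_id,
        client_id=client_id,
        our=float(np.clip(our, 0.0, 100.0)),
        oer=float(np.clip(oer, 0.0, 100.0)),
        perceived_source=perceived_source,
    )
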