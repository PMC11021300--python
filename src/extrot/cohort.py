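"""Synthetic participant cohorts for the extended-rotation paradigm.

Each simulated participant is a bundle of latent generative parameters: a
linear angle-to-response-time law for mental (internal) rotation, error rates,
a motor/decision intercept for keyboard-driven (extended) rotation, a
metacognitive bias on the perceived speed difference between the two
strategies, and a logistic strategy-choice policy. Cohorts are drawn from
configurable parameter distributions so every downstream analysis can be
exercised without any experimental data.

Units: times in milliseconds, angles in degrees, probabilities in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, asdict, replace
from typing import Optional

import numpy as np

__all__ = [
    "ChoicePolicy",
    "ParticipantProfile",
    "Distribution",
    "CohortConfig",
    "CohortConfigError",
    "sample_profile",
    "sample_cohort",
    "internal_response",
    "perceived_rt_delta",
    "choose_strategy",
    "scenario_preset",
    "profiles_to_csv",
    "ANGLE_SET",
    "DEADLINE_MS",
]

ANGLE_SET = (60, 120, 180)
DEADLINE_MS = 12_000.0


class CohortConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class ChoicePolicy:
    """Logistic per-trial strategy choice.

    P(extended) = logistic(beta0 + beta_rt * delta_rt_s + beta_acc * delta_acc
                           + beta_angle * angle + beta_stick * s_prev)

    where ``delta_rt_s`` is the perceived internal-minus-extended RT advantage
    of the extended strategy in seconds, ``delta_acc`` the perceived accuracy
    difference (internal minus extended, proportion), ``angle`` the trial angle
    in degrees and ``s_prev`` is +1 after an extended trial, -1 after an
    internal one, 0 on the first choice trial. Large ``|beta_stick|`` yields a
    pure perseverator.
    """

    beta0: float = 0.0
    beta_rt: float = 0.0
    beta_acc: float = 0.0
    beta_angle: float = 0.0
    beta_stick: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise CohortConfigError(f"policy field {f.name} must be finite")


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent generative parameters of one simulated performer."""

    a_int: float          # internal RT intercept, ms
    b_int: float          # internal RT slope, ms/degree
    sigma_rt: float       # RT noise SD, ms
    eps0_int: float       # internal error rate at 0 degrees
    eps1_int: float       # internal error increment per degree
    a_man: float          # manual motor/decision intercept, ms
    eps_man: float        # manual error probability on reliable trials
    rt_bias: float        # metacognitive bias on the perceived RT delta, ms
    policy: ChoicePolicy = field(default_factory=ChoicePolicy)

    def __post_init__(self):
        checks = [
            (self.b_int > 0, "b_int must be > 0"),
            (self.sigma_rt >= 0, "sigma_rt must be >= 0"),
            (self.a_int >= 0, "a_int must be >= 0"),
            (self.a_man >= 0, "a_man must be >= 0"),
        ]
        for prob, name in [
            (self.eps0_int, "eps0_int"),
            (self.eps1_int, "eps1_int"),
            (self.eps_man, "eps_man"),
        ]:
            checks.append((0.0 <= prob <= 0.5, f"{name} must be in [0, 0.5]"))
        for ok, msg in checks:
            if not ok:
                raise CohortConfigError(msg)

    def error_rate(self, angle: float) -> float:
        """Internal error probability at ``angle``, clamped to [0, 0.5]."""
        return float(np.clip(self.eps0_int + self.eps1_int * angle, 0.0, 0.5))


@dataclass(frozen=True)
class Distribution:
    """One marginal parameter distribution: point mass, normal, or lognormal.

    ``normal`` and ``lognormal`` are parameterised by their mean and SD on the
    natural (data) scale; samples violating profile invariants are redrawn
    (truncation by rejection), so configured moments are only approximate when
    truncation actually bites.
    """

    family: str = "point"          # point | normal | lognormal
    mean: float = 0.0
    sd: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "point":
            return self.mean
        if self.family == "normal":
            return float(rng.normal(self.mean, self.sd))
        if self.family == "lognormal":
            if self.mean <= 0:
                raise CohortConfigError("lognormal mean must be > 0")
            s2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - s2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(s2)))
        raise CohortConfigError(f"unknown distribution family {self.family!r}")


_PROFILE_FIELDS = (
    "a_int", "b_int", "sigma_rt", "eps0_int", "eps1_int",
    "a_man", "eps_man", "rt_bias",
)
_POLICY_FIELDS = ("beta0", "beta_rt", "beta_acc", "beta_angle", "beta_stick")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, per-field parameter distributions, scenario label, seed."""

    n_participants: int
    distributions: dict
    scenario: str = "custom"
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise CohortConfigError("n_participants must be >= 1")
        for name in list(_PROFILE_FIELDS) + list(_POLICY_FIELDS):
            if name not in self.distributions:
                raise CohortConfigError(f"missing distribution for field {name!r}")
            if not isinstance(self.distributions[name], Distribution):
                raise CohortConfigError(f"distribution for {name!r} has wrong type")


def _profile_rng(config: CohortConfig, draw_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, draw_index]))


def sample_profile(config: CohortConfig, draw_index: int) -> ParticipantProfile:
    """Draw one participant profile; deterministic given (seed, draw_index).

    Invalid draws (e.g. a negative intercept from a wide normal) are rejected
    and redrawn field-wise, so all profile invariants hold by construction.
    """
    if not 0 <= draw_index < config.n_participants:
        raise CohortConfigError(
            f"draw_index {draw_index} out of range [0, {config.n_participants})"
        )
    rng = _profile_rng(config, draw_index)

    def draw(name, lo, hi):
        dist = config.distributions[name]
        for _ in range(1000):
            v = dist.sample(rng)
            if lo <= v <= hi if hi is not None else lo <= v:
                return v
        raise CohortConfigError(
            f"distribution for {name!r} cannot produce values in its valid range"
        )

    values = {
        "a_int": draw("a_int", 0.0, None),
        "b_int": draw("b_int", np.nextafter(0.0, 1.0), None),
        "sigma_rt": draw("sigma_rt", 0.0, None),
        "eps0_int": draw("eps0_int", 0.0, 0.5),
        "eps1_int": draw("eps1_int", 0.0, 0.5),
        "a_man": draw("a_man", 0.0, None),
        "eps_man": draw("eps_man", 0.0, 0.5),
        "rt_bias": config.distributions["rt_bias"].sample(rng),
    }
    policy = ChoicePolicy(**{
        name: config.distributions[name].sample(rng) for name in _POLICY_FIELDS
    })
    return ParticipantProfile(policy=policy, **values)


def sample_cohort(config: CohortConfig) -> list:
    """All ``n_participants`` profiles of the cohort."""
    return [sample_profile(config, i) for i in range(config.n_participants)]


def internal_response(profile: ParticipantProfile, angle: float,
                      rng: np.random.Generator) -> tuple:
    """One mental-rotation trial: ``(rt_ms, correct)``.

    RT is linear in angle (intercept ``a_int``, slope ``b_int``) with additive
    Gaussian noise, truncated to (0, 12000]; a draw that reaches the 12-s
    deadline is a timeout and is scored incorrect. Error probability is
    ``clamp(eps0_int + eps1_int * angle, 0, 0.5)``.
    """
    if angle not in ANGLE_SET:
        raise ValueError(f"angle must be one of {ANGLE_SET}, got {angle}")
    rt = profile.a_int + profile.b_int * angle
    if profile.sigma_rt > 0:
        rt += rng.normal(0.0, profile.sigma_rt)
    rt = float(min(max(rt, 1.0), DEADLINE_MS))
    if rt >= DEADLINE_MS:
        return DEADLINE_MS, False
    correct = rng.random() >= profile.error_rate(angle)
    return rt, bool(correct)


def perceived_rt_delta(profile: ParticipantProfile, true_delta: float,
                       rng: Optional[np.random.Generator] = None,
                       perception_sd: float = 0.0) -> float:
    """Perceived internal-minus-extended RT difference, ms.

    The participant's belief is the true difference shifted by the
    metacognitive bias ``rt_bias`` (plus optional perception noise, off by
    default)."""
    delta = true_delta + profile.rt_bias
    if perception_sd > 0.0:
        if rng is None:
            raise ValueError("perception noise requires an rng")
        delta += rng.normal(0.0, perception_sd)
    return float(delta)


def choose_strategy(policy: ChoicePolicy, perceived_rt_delta_ms: float,
                    perceived_acc_delta: float, angle: float,
                    previous: Optional[str], rng: np.random.Generator) -> str:
    """Sample one strategy, ``"internal"`` or ``"extended"``.

    All delta conventions are internal minus extended: a positive RT delta
    means the extended strategy is faster and (for positive ``beta_rt``)
    favours choosing it.
    """
    stick = {"extended": 1.0, "internal": -1.0, None: 0.0}[previous]
    logit = (policy.beta0
             + policy.beta_rt * perceived_rt_delta_ms / 1000.0
             + policy.beta_acc * perceived_acc_delta
             + policy.beta_angle * angle
             + policy.beta_stick * stick)
    p_ext = 1.0 / (1.0 + np.exp(-logit))
    return "extended" if rng.random() < p_ext else "internal"


def _point(v):
    return Distribution("point", v)


def scenario_preset(name: str, n_participants: int = 54, seed: int = 0) -> CohortConfig:
    """Built-in cohort scenarios.

    ``exp1``
        Heterogeneous population for the speed-uncalibrated condition: manual
        rotation is faster than mental rotation by an intercept gap of about
        half a second (mean a_int - a_man = 511 ms, between-participant SD
        ~200 ms). Choices weight the perceived speed advantage, so strategy
        use is strongly tilted toward the extended strategy and spread out to
        both extremes (the bimodal pattern).
    ``exp2``
        Same population structure with a nearly homogeneous intercept gap of
        511 ms; with the matching 511-ms lockout the realised RT differences
        shrink to noise, choices are dominated by the metacognitive bias, and
        strategy use is unimodal around one half.
    ``noiseless``
        Deterministic error-free performers for kinematic identities.
    """
    base = {
        "sigma_rt": Distribution("normal", 400.0, 50.0),
        "eps0_int": _point(0.02),
        "eps1_int": Distribution("normal", 0.0004, 0.0001),
        "eps_man": _point(0.05),
        "beta0": _point(0.0),
        "beta_acc": _point(4.0),
        "beta_angle": _point(0.003),
        "beta_stick": _point(1.0),
    }
    if name == "exp1":
        dists = dict(base)
        dists.update({
            "a_int": Distribution("normal", 1911.0, 250.0),
            "b_int": Distribution("lognormal", 4.0, 1.2),
            "a_man": Distribution("normal", 1400.0, 150.0),
            "rt_bias": Distribution("normal", 0.0, 250.0),
            "beta_rt": _point(4.0),
        })
    elif name == "exp2":
        dists = dict(base)
        dists.update({
            "a_int": Distribution("normal", 1911.0, 30.0),
            "b_int": Distribution("lognormal", 4.0, 1.2),
            "a_man": Distribution("normal", 1400.0, 30.0),
            "rt_bias": Distribution("normal", 0.0, 250.0),
            "beta_rt": _point(4.0),
        })
    elif name == "noiseless":
        dists = {
            "a_int": _point(1911.0), "b_int": _point(2.0),
            "sigma_rt": _point(0.0), "eps0_int": _point(0.0),
            "eps1_int": _point(0.0), "a_man": _point(1400.0),
            "eps_man": _point(0.0), "rt_bias": _point(0.0),
            "beta0": _point(0.0), "beta_rt": _point(0.0),
            "beta_acc": _point(0.0), "beta_angle": _point(0.0),
            "beta_stick": _point(0.0),
        }
    else:
        raise CohortConfigError(f"unknown scenario preset {name!r}")
    return CohortConfig(n_participants=n_participants, distributions=dists,
                        scenario=name, seed=seed)


def profiles_to_csv(profiles, path) -> None:
    """One row per participant, policy betas flattened into columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant"] + list(_PROFILE_FIELDS) + list(_POLICY_FIELDS))
        for i, prof in enumerate(profiles):
            row = [i] + [getattr(prof, f) for f in _PROFILE_FIELDS]
            row += [getattr(prof.policy, f) for f in _POLICY_FIELDS]
            writer.writerow(row)
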