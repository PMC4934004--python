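"""Synthetic e-diary generator.

Person-level (homebase, autoregressive slope, log within-person variance)
triplets are drawn from group-specific trivariate normal populations; each
person's ratings follow a stationary within-day AR(1) process whose chain is
broken at day boundaries (the first prompt of each day starts from the
stationary distribution).  Optional integer-Likert discretization and random
non-compliance emulate the two study designs (15-min x 24 h and hourly x 48 h
protocols).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from affectdyn import emotions
from affectdyn.data import LONG_COLUMNS, EmaRecord, EmaSeries, records_to_frame

logger = logging.getLogger(__name__)

_MAX_REJECTION_ROUNDS = 10_000


@dataclass
class PopulationSpec:
    """Group-specific trivariate normal population of person parameters.

    ``reference_means`` holds (homebase, autoregressive slope, log
    within-person variance) for the reference group; each entry of
    ``group_deltas`` is a 3-vector offset added for that group.  The
    between-person covariance is shared across groups.
    """

    reference_group: str
    reference_means: np.ndarray
    between_person_cov: np.ndarray
    group_deltas: Mapping[str, np.ndarray] = field(default_factory=dict)
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        self.reference_means = np.asarray(self.reference_means, dtype=float)
        self.between_person_cov = np.asarray(self.between_person_cov, dtype=float)
        self.group_deltas = {g: np.asarray(d, dtype=float) for g, d in self.group_deltas.items()}
        if self.reference_means.shape != (3,):
            raise ValueError("reference_means must be a 3-vector")
        cov = self.between_person_cov
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("between_person_cov must be symmetric 3x3")
        eig = np.linalg.eigvalsh(cov)
        if self.allow_degenerate:
            if np.any(eig < -1e-10):
                raise ValueError("between_person_cov must be positive semi-definite")
        elif np.any(eig <= 0):
            raise ValueError("between_person_cov must be positive definite")
        for g in self.groups:
            mean = self.group_mean(g)
            if abs(mean[1]) >= 1:
                raise ValueError(f"group {g!r}: mean autoregressive slope {mean[1]} not in (-1, 1)")

    @property
    def groups(self) -> list[str]:
        out = [self.reference_group]
        out += [g for g in self.group_deltas if g != self.reference_group]
        return out

    def group_mean(self, group: str) -> np.ndarray:
        if group == self.reference_group:
            return self.reference_means.copy()
        if group not in self.group_deltas:
            raise KeyError(f"unknown group label {group!r}")
        return self.reference_means + self.group_deltas[group]


@dataclass
class SamplingDesign:
    """Prompting schedule, rating scale and compliance of one study arm."""

    n_days: int
    prompts_per_day: int
    scale_min: float
    scale_max: float
    compliance: float = 1.0
    discretize: bool = False

    def __post_init__(self) -> None:
        if self.prompts_per_day < 2:
            raise ValueError("prompts_per_day must be >= 2")
        if not (0 < self.compliance <= 1):
            raise ValueError("compliance must be in (0, 1]")
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass
class PersonParams:
    """Person-specific triplet: homebase, AR(1) slope, log within-person variance."""

    person_id: str
    group: str
    mu: float
    phi: float
    log_sigma2: float

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")


def draw_person_params(
    pop: PopulationSpec,
    group: str,
    n: int,
    seed,
    id_prefix: Optional[str] = None,
    return_rejections: bool = False,
):
    """Draw ``n`` person triplets for ``group`` from the population.

    Draws with an autoregressive slope outside (-1, 1) are rejected and
    redrawn; the number of rejected draws is logged (and returned when
    ``return_rejections`` is set).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = pop.group_mean(group)
    cov = pop.between_person_cov
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else f"{group}_"

    if np.allclose(cov, 0):
        if not pop.allow_degenerate:
            raise ValueError("zero between_person_cov requires allow_degenerate=True")
        draws = np.tile(mean, (n, 1))
        rejections = 0
    else:
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            # PSD-but-singular covariance (allow_degenerate): eigen factor
            w, V = np.linalg.eigh(cov)
            chol = V * np.sqrt(np.clip(w, 0, None))
        draws = np.empty((n, 3))
        filled = 0
        rejections = 0
        for _ in range(_MAX_REJECTION_ROUNDS):
            need = n - filled
            if need == 0:
                break
            cand = mean + rng.standard_normal((need, 3)) @ chol.T
            ok = np.abs(cand[:, 1]) < 1
            rejections += int(need - ok.sum())
            take = cand[ok]
            draws[filled : filled + len(take)] = take
            filled += len(take)
        else:
            raise RuntimeError("slope rejection sampling failed to terminate; check the population slope support")
    if rejections:
        logger.info("draw_person_params: rejected %d draws with |phi| >= 1 (group=%s)", rejections, group)

    params = [
        PersonParams(f"{prefix}{i:04d}", group, draws[i, 0], draws[i, 1], draws[i, 2]) for i in range(n)
    ]
    if return_rejections:
        return params, rejections
    return params


def simulate_series(params: PersonParams, design: SamplingDesign, seed) -> EmaSeries:
    """Simulate one person's ratings under the within-day AR(1) model.

    Each day's first prompt is drawn from the stationary distribution
    N(mu, sigma^2 / (1 - phi^2)); subsequent prompts follow
    ``y_t = mu + phi (y_{t-1} - mu) + e_t`` with ``e_t ~ N(0, sigma^2)``.
    ``log_sigma2 = -inf`` is the noise-free limit (constant series).
    """
    if not abs(params.phi) < 1:
        raise ValueError("|phi| >= 1: no stationary start exists")
    rng = np.random.default_rng(seed)
    mu, phi = params.mu, params.phi
    sigma2 = float(np.exp(params.log_sigma2))
    stat_sd = np.sqrt(sigma2 / (1 - phi**2))
    sd = np.sqrt(sigma2)

    n_days, ppd = design.n_days, design.prompts_per_day
    y = np.empty(n_days * ppd)
    for d in range(n_days):
        eps = rng.standard_normal(ppd)
        base = d * ppd
        y[base] = mu + stat_sd * eps[0]
        for t in range(1, ppd):
            y[base + t] = mu + phi * (y[base + t - 1] - mu) + sd * eps[t]

    if design.discretize:
        logger.warning(
            "simulate_series: discretizing to integers in [%g, %g]; rounding/clipping biases parameter recovery",
            design.scale_min,
            design.scale_max,
        )
        y = np.clip(np.round(y), design.scale_min, design.scale_max)

    frame = pd.DataFrame(
        {
            "day": np.repeat(np.arange(n_days), ppd),
            "prompt_index": np.tile(np.arange(ppd), n_days),
            "y": y,
        }
    )
    return EmaSeries(params.person_id, params.group, frame)


def apply_missingness(series: EmaSeries, compliance: float, seed) -> EmaSeries:
    """Independently retain each prompt with probability ``compliance``.

    Prompt indices of retained rows are unchanged, so downstream lag
    construction can detect the gaps.
    """
    if not (0 < compliance <= 1):
        raise ValueError("compliance must be in (0, 1]")
    if compliance == 1:
        return EmaSeries(series.person_id, series.group, series.data.copy())
    rng = np.random.default_rng(seed)
    keep = rng.random(len(series.data)) < compliance
    return EmaSeries(series.person_id, series.group, series.data.loc[keep].reset_index(drop=True))


def simulate_emotion_records(series: EmaSeries, seed) -> list[EmaRecord]:
    """Map a valence-scale series onto emotion/intensity prompt answers.

    The rounded value determines the answer: 0 maps to "no emotion", positive
    values to a positive-emotion item (or the unnameable item marked
    pleasant), negative values to a negative-emotion item (or unnameable /
    unpleasant), with intensity ``min(|round(v)|, 11)``.  Feeding the records
    back through :func:`affectdyn.preprocess.compute_valence` recovers
    ``round(v)`` clamped to [-11, 11].
    """
    vals = series.values
    if np.any(np.abs(vals) > 11):
        raise ValueError("series values must lie in [-11, 11] for emotion coding")
    rng = np.random.default_rng(seed)
    pos_items = emotions.POSITIVE_EMOTIONS + (emotions.UNNAMEABLE,)
    neg_items = emotions.NEGATIVE_EMOTIONS + (emotions.UNNAMEABLE,)

    records = []
    for (_, row), v in zip(series.data.iterrows(), vals):
        r = int(np.round(v))
        day, idx = int(row["day"]), int(row["prompt_index"])
        if r == 0:
            rec = EmaRecord(series.person_id, series.group, day, idx, emotions.NO_EMOTION)
        else:
            intensity = min(abs(r), 11)
            if r > 0:
                item = pos_items[rng.integers(len(pos_items))]
                pleas = emotions.PLEASANT if item == emotions.UNNAMEABLE else None
            else:
                item = neg_items[rng.integers(len(neg_items))]
                pleas = emotions.UNPLEASANT if item == emotions.UNNAMEABLE else None
            rec = EmaRecord(series.person_id, series.group, day, idx, item, intensity, pleas)
        records.append(rec)
    return records


def _series_to_distress_frame(series: EmaSeries) -> pd.DataFrame:
    frame = series.data.copy()
    frame.insert(0, "person_id", series.person_id)
    frame.insert(1, "group", series.group)
    frame["item"] = "distress"
    frame["intensity"] = np.nan
    frame["pleasantness"] = None
    frame = frame.rename(columns={"y": "distress"})
    return frame[LONG_COLUMNS]


def simulate_study(config: Mapping, seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate a whole multi-group study into the long CSV format.

    ``config`` mirrors the YAML schema::

        outcome: distress            # or "emotion"
        seed: 20240101
        population:
          reference_group: BPD
          reference_means: [5.0, 0.4, 0.0]
          between_person_cov: [[0.5, 0, 0], [0, 0.02, 0], [0, 0, 0.1]]
          group_deltas:
            HC: [-3.0, -0.1, -0.5]
        design:
          n_days: 2
          prompts_per_day: 25
          scale_min: 0
          scale_max: 9
          compliance: 0.92
          discretize: false
        group_sizes:
          BPD: 20
          HC: 20

    ``seed`` overrides ``config["seed"]``.
    """
    pop_cfg = dict(config["population"])
    pop = PopulationSpec(
        reference_group=pop_cfg["reference_group"],
        reference_means=pop_cfg["reference_means"],
        between_person_cov=pop_cfg["between_person_cov"],
        group_deltas=pop_cfg.get("group_deltas", {}),
        allow_degenerate=pop_cfg.get("allow_degenerate", False),
    )
    design = SamplingDesign(**config["design"])
    group_sizes = dict(config["group_sizes"])
    outcome = config.get("outcome", "distress")
    if outcome not in ("distress", "emotion"):
        raise ValueError(f"unknown outcome kind {outcome!r}")
    master = seed if seed is not None else config.get("seed", 0)

    for g in group_sizes:
        pop.group_mean(g)  # raises on unknown labels

    frames = []
    ss = np.random.SeedSequence([int(master), 0xA55])
    group_seeds = ss.spawn(len(group_sizes))
    for (group, size), gseed in zip(sorted(group_sizes.items()), group_seeds):
        person_seed, series_seed, miss_seed, emo_seed = gseed.spawn(4)
        params = draw_person_params(pop, group, size, person_seed)
        s_children = series_seed.spawn(size)
        m_children = miss_seed.spawn(size)
        e_children = emo_seed.spawn(size)
        for p, s_sd, m_sd, e_sd in zip(params, s_children, m_children, e_children):
            series = simulate_series(p, design, s_sd)
            series = apply_missingness(series, design.compliance, m_sd)
            if outcome == "distress":
                frames.append(_series_to_distress_frame(series))
            else:
                frames.append(records_to_frame(simulate_emotion_records(series, e_sd)))
    return pd.concat(frames, ignore_index=True)


def load_study_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def true_params_frame(config: Mapping) -> pd.DataFrame:
    """Tabulate the generative group means implied by a study config."""
    pop_cfg = dict(config["population"])
    pop = PopulationSpec(
        reference_group=pop_cfg["reference_group"],
        reference_means=pop_cfg["reference_means"],
        between_person_cov=pop_cfg["between_person_cov"],
        group_deltas=pop_cfg.get("group_deltas", {}),
        allow_degenerate=pop_cfg.get("allow_degenerate", False),
    )
    rows = [
        {"group": g, "homebase": m[0], "autoreg": m[1], "log_var": m[2]}
        for g in pop.groups
        for m in [pop.group_mean(g)]
    ]
    return pd.DataFrame(rows)
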