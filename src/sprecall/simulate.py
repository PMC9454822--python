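"""Synthetic lexicons, study lists and recall responses.

The generator emulates the statistical structure the analysis chain
assumes: a Zipfian (decaying-exponential rank-frequency) lexicon, study
lists drawn as pure low-frequency, pure high-frequency, or mixed
(stratified over equal-log-width frequency bins), and binary recall from a
logistic model with a per-subject Gaussian random intercept, a linear SP
effect, and optional linear + quadratic presentation-order effects:

    logit P(recall_ij) = gamma00 + u_0j + beta_sp * SP_ij
                         + beta_order1 * pos_ij + beta_order2 * pos_ij^2,
    u_0j ~ Normal(0, psi).

Everything is deterministic given the seed; per-stage substreams are
derived from (seed, stage-name) so stages can be regenerated independently.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .lexicon import Lexicon, partition_log_bins
from .surprisal import SPConfig, StudyList, compute_sp, sp_table

__all__ = [
    "LexiconParams",
    "DesignParams",
    "EffectParams",
    "SimulationConfig",
    "stage_rng",
    "simulate_lexicon",
    "sample_study_list",
    "simulate_recall",
    "simulate_dataset",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child generator for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class LexiconParams:
    """Zipf curve freq(r) = a*exp(-b*r) with multiplicative log-normal noise.

    Defaults span roughly 3.5 decades of frequency over 2,000 ranks, the
    kind of range word-frequency norms cover.
    """

    n_words: int = 2000
    a: float = 1000.0
    b: float = 0.004
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_words < 3:
            raise ValueError("n_words must be >= 3")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DesignParams:
    """Study design: one list of ``list_length`` words per subject by default."""

    n_subjects: int = 45
    list_length: int = 34
    condition: str = "mixed"  # pure_lf | pure_hf | mixed
    n_lists: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.list_length < 1 or self.n_lists < 1:
            raise ValueError("n_subjects, list_length and n_lists must be >= 1")
        if self.condition not in ("pure_lf", "pure_hf", "mixed"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class EffectParams:
    """Generative coefficients on the logit scale.

    The default scenario places mean recall near .39 for mixed 34-word
    lists under the default lexicon (gamma00 balances the positive SP
    effect at the typical SP values such lists produce).
    """

    gamma00: float = -1.35
    beta_sp: float = 0.5
    beta_order1: float = 0.0
    beta_order2: float = 0.0
    psi: float = 0.5

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError("psi must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    lexicon: LexiconParams = field(default_factory=LexiconParams)
    design: DesignParams = field(default_factory=DesignParams)
    effects: EffectParams = field(default_factory=EffectParams)
    seed: int = 0


def simulate_lexicon(params: LexiconParams, seed: int) -> Lexicon:
    """Draw a synthetic Zipfian lexicon; word r gets a*exp(-b*r) times a
    log-normal noise factor."""
    rng = stage_rng(seed, "lexicon")
    r = np.arange(1, params.n_words + 1, dtype=float)
    freqs = params.a * np.exp(-params.b * r)
    if params.noise_sd > 0:
        freqs = freqs * np.exp(rng.normal(0.0, params.noise_sd, size=r.size))
    words = np.array([f"w{int(i):06d}" for i in r], dtype=object)
    return Lexicon(words=words, freqs=freqs)


def sample_study_list(
    lexicon: Lexicon,
    length: int,
    condition: str,
    rng: np.random.Generator,
) -> StudyList:
    """Sample a study list without replacement.

    pure_lf / pure_hf draw from the bottom / top bin of the ten
    equal-log-width frequency bins; mixed repeatedly picks a non-exhausted
    bin uniformly, then a word uniformly within it (stratified sampling).
    """
    part = partition_log_bins(lexicon, 10)
    bins = part.assign(lexicon.freqs)
    if condition == "pure_lf":
        pool = np.flatnonzero(bins == 0)
    elif condition == "pure_hf":
        pool = np.flatnonzero(bins == part.k - 1)
    elif condition == "mixed":
        pool = None
    else:
        raise ValueError(f"unknown condition {condition!r}")

    if pool is not None:
        if length > pool.size:
            raise ValueError(
                f"requested {length} words but the {condition} pool has {pool.size}"
            )
        chosen = rng.choice(pool, size=length, replace=False)
    else:
        if length > lexicon.total:
            raise ValueError(
                f"requested {length} words but the lexicon has {lexicon.total}"
            )
        remaining = [list(np.flatnonzero(bins == j)) for j in range(part.k)]
        chosen_list: list[int] = []
        for _ in range(length):
            open_bins = [j for j in range(part.k) if remaining[j]]
            j = open_bins[rng.integers(len(open_bins))]
            pos = rng.integers(len(remaining[j]))
            chosen_list.append(remaining[j].pop(int(pos)))
        chosen = np.array(chosen_list)
        rng.shuffle(chosen)
    return StudyList(
        words=tuple(lexicon.words[chosen].astype(str)),
        freqs=lexicon.freqs[chosen],
    )


def simulate_recall(
    study_lists: dict[int, list[StudyList]],
    effects: EffectParams,
    lexicon: Lexicon,
    seed: int,
    sp_config: SPConfig = SPConfig(),
) -> pd.DataFrame:
    """Bernoulli recall responses for per-subject study lists.

    Returns a long-format frame with columns Subj, List, Order, word, WF,
    log10WF, SP, Resp. Trials whose SP is non-finite (zero-width interval)
    are dropped; the number removed is stored in ``df.attrs["n_dropped"]``.
    """
    rng = stage_rng(seed, "recall")
    rows = []
    for subj in sorted(study_lists):
        u0 = rng.normal(0.0, np.sqrt(effects.psi)) if effects.psi > 0 else 0.0
        for list_id, sl in enumerate(study_lists[subj], start=1):
            with warnings.catch_warnings():
                # degenerate-SP trials are dropped below, silently
                warnings.simplefilter("ignore", UserWarning)
                tab = sp_table(compute_sp(sl, lexicon, sp_config))
            pos = tab["position"].to_numpy(dtype=float)
            sp = tab["sp"].to_numpy(dtype=float)
            eta = (
                effects.gamma00
                + u0
                + effects.beta_sp * sp
                + effects.beta_order1 * pos
                + effects.beta_order2 * pos**2
            )
            resp = rng.random(pos.size) < expit(eta)
            rows.append(
                pd.DataFrame(
                    {
                        "Subj": subj,
                        "List": list_id,
                        "Order": tab["position"].to_numpy(),
                        "word": tab["word"].to_numpy(),
                        "WF": tab["interval_high"].to_numpy(),
                        "SP": sp,
                        "Resp": resp.astype(int),
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    finite = np.isfinite(df["SP"].to_numpy())
    n_dropped = int((~finite).sum())
    df = df.loc[finite].reset_index(drop=True)
    df["log10WF"] = np.log10(df["WF"])
    df.attrs["n_dropped"] = n_dropped
    return df


def simulate_dataset(config: SimulationConfig) -> tuple[Lexicon, pd.DataFrame]:
    """Run the full generative chain: lexicon -> lists -> recall responses."""
    lexicon = simulate_lexicon(config.lexicon, config.seed)
    rng = stage_rng(config.seed, "lists")
    lists = {
        subj: [
            sample_study_list(
                lexicon, config.design.list_length, config.design.condition, rng
            )
            for _ in range(config.design.n_lists)
        ]
        for subj in range(1, config.design.n_subjects + 1)
    }
    trials = simulate_recall(lists, config.effects, lexicon, config.seed)
    return lexicon, trials
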